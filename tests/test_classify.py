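"""Reference-curve construction, outlier categories and mechanism labels."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from foldstab import (
    ThermoParams,
    PopulationSeries,
    build_reference,
    reference_from_params,
    classify_residue,
    mechanism_decomposition,
    group_by_secondary_structure,
    fit_stability,
    gibbs_helmholtz,
    folded_fraction,
    max_stability_temp,
    cold_denaturation_temp,
)
from foldstab.classify import ClassificationRecord
from foldstab.datasets import (
    yfh1_thermo_params,
    yfh1_rad_records,
    REPORTED_OUTLIER_RESIDUES,
)

GRID = np.arange(278.0, 313.1, 2.5)


def pop_from(p, label="r"):
    return PopulationSeries(label, GRID, folded_fraction(GRID, gibbs_helmholtz(GRID, p)))


def params_from_shape(ts: float, dg_max: float, dcp: float) -> ThermoParams:
    """Independent construction: solve (dHm, Tm) for a given curve shape.

    Closed-form elimination of dHm via Ts = Tm exp(-dHm/(Tm dCp)) leaves
    dG(Ts) = dCp [Tm ln(Tm/Ts) - Tm + Ts], solved for Tm by bracketed root
    search.  Lets tests build curves that differ in exactly one mechanism.
    """
    f = lambda tm: dcp * (tm * np.log(tm / ts) - tm + ts) - dg_max
    tm = brentq(f, ts + 1e-6, ts + 120.0)
    dhm = tm * dcp * np.log(tm / ts)
    return ThermoParams(dhm, tm, dcp)


@pytest.fixture
def reference():
    p0 = ThermoParams(25.0, 300.0, 2.7)
    pops = [pop_from(p0, f"{i} Ref") for i in range(3)]
    rad = {f"{i} Ref": 0.05 for i in range(3)}
    return build_reference(pops, rad, threshold=0.1)


class TestBuildReference:
    def test_identical_members_equal_common_fit(self, reference):
        p0 = ThermoParams(25.0, 300.0, 2.7)
        common = fit_stability(pop_from(p0))
        assert reference.params.T_m == pytest.approx(common.params.T_m, abs=1e-8)
        assert reference.members == ["0 Ref", "1 Ref", "2 Ref"]

    def test_symmetric_perturbations_cancel(self):
        p0 = ThermoParams(25.0, 300.0, 2.7)
        base = folded_fraction(GRID, gibbs_helmholtz(GRID, p0))
        eps = 0.01 * np.sin(GRID)
        pops = [PopulationSeries("a", GRID, np.clip(base + eps, 0, 1)),
                PopulationSeries("b", GRID, np.clip(base - eps, 0, 1))]
        ref = build_reference(pops, {"a": 0.01, "b": 0.01})
        unperturbed = fit_stability(pop_from(p0))
        assert ref.params.T_m == pytest.approx(unperturbed.params.T_m, abs=1e-6)
        assert ref.params.dH_m == pytest.approx(unperturbed.params.dH_m, rel=1e-6)

    def test_noisy_members_average_out(self):
        rng = np.random.default_rng(3)
        p0 = ThermoParams(25.0, 300.0, 2.7)
        base = folded_fraction(GRID, gibbs_helmholtz(GRID, p0))
        pops, rad = [], {}
        for i in range(11):
            label = f"{i} Syn"
            noisy = np.clip(base * np.exp(0.03 * rng.standard_normal(len(GRID))), 0, 1)
            pops.append(PopulationSeries(label, GRID, noisy))
            rad[label] = 0.05
        ref = build_reference(pops, rad)
        assert abs(ref.params.T_m - 300.0) < 0.3

    def test_selection_respects_threshold_and_flags(self):
        p0 = ThermoParams(25.0, 300.0, 2.7)
        pops = [pop_from(p0, "a"), pop_from(p0, "b"), pop_from(p0, "c")]
        with pytest.raises(ValueError, match=">= 2 members"):
            build_reference(pops, {"a": 0.05, "b": 0.5, "c": 0.5})

    def test_parameter_mean_mode(self):
        params = {"a": ThermoParams(20.0, 298.0, 2.0),
                  "b": ThermoParams(30.0, 302.0, 3.0)}
        ref = reference_from_params(params, {"a": 0.01, "b": 0.02})
        assert ref.params.dH_m == pytest.approx(25.0)
        assert ref.params.T_m == pytest.approx(300.0)
        assert ref.params.dCp == pytest.approx(2.5)


class TestCategories:
    def test_identical_member_is_consistent(self, reference):
        fit = fit_stability(pop_from(ThermoParams(25.0, 300.0, 2.7)))
        rec = classify_residue(fit, reference)
        assert rec.category == "consistent"
        assert rec.mean_abs_dT == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("dtm,dtc,category", [
        (-0.5, +1.0, "consistent"),     # mean 0.75
        (-2.0, -5.0, "outlier"),        # mean 3.5
        (-1.8, -2.6, "intermediate"),   # mean 2.2
    ])
    def test_threshold_rule(self, reference, dtm, dtc, category):
        # build a residue whose Tm and Tc shift by the requested amounts
        target_tm = reference.T_m + dtm
        target_tc = reference.T_c + dtc

        def make(dcp):
            f = lambda dhm: (cold_denaturation_temp(
                ThermoParams(dhm, target_tm, dcp)) - target_tc)
            from scipy.optimize import brentq as bq
            dhm = bq(f, 5.0, 80.0)
            return ThermoParams(dhm, target_tm, dcp)

        p = make(reference.params.dCp)
        rec = classify_residue(p, reference)
        assert rec.dT_m == pytest.approx(dtm, abs=1e-6)
        assert rec.dT_c == pytest.approx(dtc, abs=1e-6)
        assert rec.category == category

    def test_category_sign_symmetric(self, reference):
        # thresholds act on |dTm|, |dTc|: mirrored shifts classify alike
        for dtm, dtc in [(-2.0, -5.0), (2.0, 5.0)]:
            target_tm = reference.T_m + dtm
            target_tc = reference.T_c + dtc
            f = lambda dhm: (cold_denaturation_temp(
                ThermoParams(dhm, target_tm, reference.params.dCp)) - target_tc)
            dhm = brentq(f, 5.0, 80.0)
            rec = classify_residue(ThermoParams(dhm, target_tm,
                                                reference.params.dCp), reference)
            assert rec.category == "outlier"

    def test_flagged_fit_unclassifiable(self, reference):
        pop = PopulationSeries("flat", GRID, np.full_like(GRID, 0.4))
        rec = classify_residue(fit_stability(pop), reference)
        assert rec.category == "unclassifiable"


class TestMechanisms:
    def test_mechanism_i_higher_enthalpy_same_ts(self, reference):
        ts, dcp = reference.T_s, reference.params.dCp
        dg_ref = gibbs_helmholtz(ts, reference.params)
        p = params_from_shape(ts, dg_ref * 1.5, dcp)
        mech = mechanism_decomposition(p, reference)
        assert set(mech) == {"I"}
        assert mech["I"] > 0
        # mechanism I alone leaves Ts unchanged
        assert abs(max_stability_temp(p) - ts) < 0.1

    def test_mechanism_ii_broader_same_maximum(self, reference):
        ts, dcp = reference.T_s, reference.params.dCp
        dg_ref = gibbs_helmholtz(ts, reference.params)
        p = params_from_shape(ts, dg_ref, dcp * 0.7)
        mech = mechanism_decomposition(p, reference)
        assert "II" in mech and mech["II"] < 0
        # maximum stays within 1 %
        assert gibbs_helmholtz(max_stability_temp(p), p) == pytest.approx(
            dg_ref, rel=0.01)

    def test_mechanism_iii_translation(self, reference):
        # rigid -5 K translation of the reference curve, refit
        from foldstab.simulate import fit_naive_curve
        T = np.arange(270.0, 306.0, 1.0)
        shifted = gibbs_helmholtz(T + 5.0, reference.params)
        p = fit_naive_curve(T, shifted, init=reference.params)
        mech = mechanism_decomposition(p, reference)
        assert "III" in mech and mech["III"] < 0
        assert mech["III"] == pytest.approx(-5.0, abs=0.3)
        # shape preserved: profiles superimpose after translating back
        back = gibbs_helmholtz(T, p)
        np.testing.assert_allclose(back, shifted,
                                   atol=0.01 * shifted.max())

    def test_no_labels_for_identical_curve(self, reference):
        assert mechanism_decomposition(reference.params, reference) == {}


class TestSecondaryStructureGrouping:
    def records(self):
        return [ClassificationRecord(f"{i} Xaa", -0.1 * i, -0.2 * i, "consistent")
                for i in range(1, 7)]

    def test_all_loop_without_annotations(self):
        df = group_by_secondary_structure(self.records(), None)
        assert list(df.element) == ["loop"]
        assert df.n.iloc[0] == 6

    def test_partition_into_elements(self):
        ann = {"1 Xaa": "H1", "2 Xaa": "H1", "3 Xaa": "S1"}
        df = group_by_secondary_structure(self.records(), ann)
        assert sorted(df.element) == ["H1", "S1", "loop"]
        assert df.n.sum() == 6

    def test_counts_match_categories(self):
        recs = self.records()
        recs[0] = ClassificationRecord("1 Xaa", -4.0, -4.0, "outlier")
        ann = pd.DataFrame({"residue_label": [r.residue_label for r in recs],
                            "element": ["H1"] * 6})
        df = group_by_secondary_structure(recs, ann)
        assert df.n_outlier.iloc[0] == 1
        assert df.n_consistent.iloc[0] == 5


class TestPublishedOutliers:
    def test_outlier_shifts_are_cold_dominated(self):
        """Published outliers: both unfolding temperatures drop, Tc more than Tm."""
        params = yfh1_thermo_params()
        ref = reference_from_params(params, yfh1_rad_records(), threshold=0.1)
        assert ref.params.T_m == pytest.approx(300.3, abs=0.1)
        assert ref.T_c == pytest.approx(282.4, abs=0.5)
        by_num = {int(l.split()[0]): l for l in params if not l.endswith("sc")}
        recs = [classify_residue(params[by_num[n]], ref)
                for n in REPORTED_OUTLIER_RESIDUES]
        dtm = np.array([r.dT_m for r in recs])
        dtc = np.array([r.dT_c for r in recs])
        assert dtc.mean() < dtm.mean() < 0
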