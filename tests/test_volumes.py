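"""Volume normalization, population conversion, curve fitting and error bands."""

import numpy as np
import pytest

from foldstab import (
    ThermoParams,
    VolumeSeries,
    PopulationSeries,
    normalize_volumes,
    volumes_to_populations,
    fit_stability,
    propagate_errors,
    gibbs_helmholtz,
    gibbs_helmholtz_gradient,
    folded_fraction,
    read_volume_table,
    write_volume_table,
    write_fit_table,
)


def series(T, V, ref=None, label="x"):
    T = np.asarray(T, dtype=float)
    return VolumeSeries(label, T, np.asarray(V, dtype=float),
                        np.ones_like(T) if ref is None else np.asarray(ref, float))


def population_from(p: ThermoParams, T):
    T = np.asarray(T, dtype=float)
    return PopulationSeries("gen", T, folded_fraction(T, gibbs_helmholtz(T, p)))


class TestNormalization:
    def test_divides_by_reference(self):
        s = normalize_volumes(series([278, 280], [3, 1], ref=[2, 2]))
        np.testing.assert_allclose(s.normalized, [1.5, 0.5])

    def test_identity_when_equal(self):
        s = normalize_volumes(series([278, 280], [2, 4], ref=[2, 4]))
        np.testing.assert_allclose(s.normalized, [1.0, 1.0])

    def test_zero_reference_names_temperature(self):
        with pytest.raises(ValueError, match="280"):
            normalize_volumes(series([278, 280], [1, 1], ref=[1, 0]))

    def test_temperatures_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            series([280, 278], [1, 1])


class TestPopulations:
    def test_hand_example(self):
        # V=[10,8,2] at [278,298,313]: baseline 2, plateau 10,
        # apparent a=[1,0.75,0]; anchoring 0.70 at 298 rescales by 0.9333
        s = series([278, 298, 313], [10, 8, 2])
        pop = volumes_to_populations(s, anchor_T=298.0, anchor_fraction=0.70)
        np.testing.assert_allclose(pop.f_F, [14 / 15, 0.70, 0.0], atol=1e-12)
        assert pop.excluded_temperatures == [313.0]
        assert pop.anchor_T == 298.0

    def test_anchor_hits_fraction_exactly(self, row70):
        T = np.arange(278.0, 313.1, 2.5)
        f = folded_fraction(T, gibbs_helmholtz(T, row70))
        pop = volumes_to_populations(series(T, f), anchor_T=298.15,
                                     anchor_fraction=0.70)
        i = int(np.argmin(np.abs(T - 298.15)))
        assert pop.f_F[i] == pytest.approx(0.70, abs=1e-10)

    def test_direct_mode_round_trip(self, row70):
        # volumes on the population scale come back bit-exact
        T = np.arange(278.0, 313.1, 2.5)
        f = folded_fraction(T, gibbs_helmholtz(T, row70))
        pop = volumes_to_populations(series(T, f), anchor_T=None,
                                     v_u_rule="zero", scale_mode="direct")
        np.testing.assert_allclose(pop.f_F, f, atol=1e-12)
        assert pop.excluded_temperatures == []

    def test_flat_series_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            volumes_to_populations(series([278, 288, 298, 313], [1, 1, 1, 1]))

    def test_anchoring_idempotent_under_duplicate_row(self, row70):
        # the anchor uses the nearest grid temperature; feeding the same
        # series twice through the transform changes nothing
        T = np.arange(278.0, 313.1, 2.5)
        f = folded_fraction(T, gibbs_helmholtz(T, row70))
        pop1 = volumes_to_populations(series(T, f))
        pop2 = volumes_to_populations(series(T, f))
        np.testing.assert_array_equal(pop1.f_F, pop2.f_F)

    def test_population_sum_invariant(self, row70):
        T = np.arange(278.0, 313.1, 2.5)
        f = folded_fraction(T, gibbs_helmholtz(T, row70))
        pop = volumes_to_populations(series(T, f))
        np.testing.assert_allclose(pop.f_F + pop.f_U, 1.0, atol=1e-15)
        assert np.all((pop.f_F >= 0) & (pop.f_F <= 1))


class TestFitting:
    def test_noiseless_round_trip(self, row70):
        T = np.arange(278.0, 310.6, 2.5)
        fit = fit_stability(population_from(row70, T))
        assert fit.ok
        assert fit.params.dH_m == pytest.approx(row70.dH_m, rel=1e-6)
        assert fit.params.T_m == pytest.approx(row70.T_m, rel=1e-6)
        assert fit.params.dCp == pytest.approx(row70.dCp, rel=1e-6)
        assert np.all(np.abs(fit.residuals) < 1e-8)

    def test_noiseless_round_trip_random_draws(self):
        rng = np.random.default_rng(11)
        T = np.arange(278.0, 313.1, 2.5)
        for _ in range(50):
            p = ThermoParams(rng.uniform(14, 35), rng.uniform(294, 302),
                             rng.uniform(1.3, 4.2))
            fit = fit_stability(population_from(p, T))
            assert fit.ok
            for got, want in zip(fit.params.as_tuple(), p.as_tuple()):
                assert got == pytest.approx(want, rel=1e-6)

    def test_noisy_recovery_single_seed(self, row70):
        T = np.arange(278.0, 313.1, 2.5)
        f = folded_fraction(T, gibbs_helmholtz(T, row70))
        rng = np.random.default_rng(123)
        noisy = f * np.exp(0.03 * rng.standard_normal(len(T)))
        pop = volumes_to_populations(series(T, noisy), anchor_T=None,
                                     v_u_rule="zero", scale_mode="direct")
        fit = fit_stability(pop)
        assert fit.ok
        assert abs(fit.params.T_m - row70.T_m) < 1.0

    def test_flat_series_flagged(self):
        T = np.arange(278.0, 313.1, 2.5)
        pop = PopulationSeries("flat", T, np.full_like(T, 0.4))
        fit = fit_stability(pop)
        assert not fit.ok
        assert "flat-series" in fit.flags

    def test_too_few_points_rejected(self, row70):
        T = np.array([278.0, 285.0, 290.0, 295.0, 300.0])
        with pytest.raises(ValueError, match="usable temperatures"):
            fit_stability(population_from(row70, T))

    def test_excluded_top_temperature_not_fitted(self, row70):
        T = np.arange(278.0, 313.1, 2.5)
        f = folded_fraction(T, gibbs_helmholtz(T, row70))
        pop = volumes_to_populations(series(T, f))
        fit = fit_stability(pop)
        assert 313.0 in fit.excluded_temperatures
        assert fit.n_points == len(T) - 1


class TestErrorPropagation:
    def test_zero_covariance(self, row70):
        fit = fit_stability(population_from(row70, np.arange(278.0, 310.6, 2.5)))
        fit.params.covariance = np.zeros((3, 3))
        np.testing.assert_allclose(propagate_errors(fit, [280.0, 300.0]), 0.0)

    def test_dhm_only_vanishes_at_tm(self, row70):
        fit = fit_stability(population_from(row70, np.arange(278.0, 310.6, 2.5)))
        fit.params.covariance = np.diag([0.3, 0.0, 0.0])
        sig = propagate_errors(fit, [fit.params.T_m])
        assert sig[0] == pytest.approx(0.0, abs=1e-10)

    def test_missing_covariance_raises(self, row70):
        fit = fit_stability(population_from(row70, np.arange(278.0, 310.6, 2.5)))
        fit.params.covariance = None
        with pytest.raises(ValueError, match="covariance"):
            propagate_errors(fit, [300.0])

    def test_band_matches_monte_carlo(self, row70):
        # linear propagation vs brute-force parameter sampling
        rng = np.random.default_rng(5)
        cov = np.array([[0.4, 0.02, 0.01],
                        [0.02, 0.09, 0.004],
                        [0.01, 0.004, 0.02]])
        p = ThermoParams(*row70.as_tuple(), covariance=cov)
        T = np.array([280.0, 290.0, 305.0])
        g = gibbs_helmholtz_gradient(T, p)
        sig = np.sqrt(np.einsum("ti,ij,tj->t", g, cov, g))
        draws = rng.multivariate_normal(p.as_tuple(), cov, size=100_000)
        dg = np.empty((len(draws), len(T)))
        for k, (dH, Tm, dCp) in enumerate(draws):
            dg[k] = gibbs_helmholtz(T, ThermoParams(dH, Tm, dCp))
        np.testing.assert_allclose(dg.std(axis=0), sig, rtol=0.02)


class TestTabularIO:
    def test_long_format_round_trip(self, tmp_path, row70):
        T = np.arange(278.0, 313.1, 2.5)
        f = folded_fraction(T, gibbs_helmholtz(T, row70))
        orig = [series(T, f, label="70 Leu"), series(T, f * 0.9, label="71 Glu")]
        path = tmp_path / "vol.tsv"
        write_volume_table(orig, path)
        back = read_volume_table(path)
        assert [s.residue_label for s in back] == ["70 Leu", "71 Glu"]
        np.testing.assert_allclose(back[0].volumes, orig[0].volumes)

    def test_wide_format(self, tmp_path):
        path = tmp_path / "wide.tsv"
        path.write_text(
            "residue_label\t278.0\t280.5\t283.0\n"
            "__reference__\t2.0\t2.0\t2.0\n"
            "70 Leu\t1.0\t0.9\t0.8\n"
        )
        back = read_volume_table(path)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].ref_volumes, 2.0)
        np.testing.assert_allclose(back[0].volumes, [1.0, 0.9, 0.8])

    def test_fit_table_schema(self, tmp_path, row70):
        fit = fit_stability(population_from(row70, np.arange(278.0, 310.6, 2.5)))
        df = write_fit_table([fit], tmp_path / "fit.tsv")
        assert set(df.columns) >= {"residue_label", "dH_kcal_mol", "dS_kcal_mol_K",
                                   "dCp_kcal_mol_K", "Tm_K", "Tc_K", "Ts_K",
                                   "converged", "n_points"}
        assert df.Tc_K.iloc[0] == pytest.approx(283.18, abs=0.05)
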