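"""Classify residues against the buried-core reference stability curve.

The reference curve averages the folded populations of the hydrophobic-core
reporters (RAD < 0.1) temperature by temperature and fits the averaged
series; residues are then compared to it through the shifts of their two
unfolding temperatures, dTm = Tm - Tm(ref) and dTc = Tc - Tc(ref).  A
residue is *consistent* when the mean of |dTm| and |dTc| is below 1.5 K,
an *outlier* above 3 K, *intermediate* in between.

Outlier curves are further decomposed into the three canonical ways a
stability curve can change:

* mechanism I   — raising dHs (enthalpy at the maximum): same shape,
                  uniformly higher curve;
* mechanism II  — reducing dCp: broader curve, same maximum (the curvature
                  is -dCp/T);
* mechanism III — shifting the whole curve along T (an entropy change moves
                  Ts, since Ts = Tm exp(-dSm/dCp)).

Real curves usually mix the three; every component whose magnitude exceeds
a configurable fraction of the reference scale is labelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .thermo import (
    ThermoParams,
    max_stability_temp,
    cold_denaturation_temp,
    NoColdDenaturationError,
)
from .volumes import PopulationSeries, FitResult, fit_stability

__all__ = [
    "ReferenceCurve",
    "ClassificationRecord",
    "build_reference",
    "reference_from_params",
    "classify_residue",
    "mechanism_decomposition",
    "group_by_secondary_structure",
    "CONSISTENT_MAX_K",
    "OUTLIER_MIN_K",
]

#: Residues whose unfolding temperatures differ on average by less than
#: this are consistent with the reference (K).
CONSISTENT_MAX_K = 1.5

#: ... and by more than this are outliers (K).
OUTLIER_MIN_K = 3.0


@dataclass
class ReferenceCurve:
    """Buried-core average stability curve."""

    members: list[str]
    params: ThermoParams
    averaged: PopulationSeries | None = None
    fit: FitResult | None = None

    @property
    def T_m(self) -> float:
        return self.params.T_m

    @property
    def T_c(self) -> float:
        return cold_denaturation_temp(self.params)

    @property
    def T_s(self) -> float:
        return max_stability_temp(self.params)

    @property
    def width(self) -> float:
        """Tm - Tc, the temperature span over which the protein is folded."""
        return self.T_m - self.T_c


@dataclass
class ClassificationRecord:
    """One residue's deviation from the reference curve."""

    residue_label: str
    dT_m: float
    dT_c: float
    category: str
    mechanisms: dict[str, float] = field(default_factory=dict)

    @property
    def mean_abs_dT(self) -> float:
        return (abs(self.dT_m) + abs(self.dT_c)) / 2.0

    @property
    def mechanism_labels(self) -> list[str]:
        return sorted(self.mechanisms.keys())


def _residue_number(label: str) -> int:
    return int(str(label).split()[0])


def build_reference(
    populations: list[PopulationSeries],
    rad_records,
    threshold: float = 0.1,
    fits: dict[str, FitResult] | None = None,
    **fit_kwargs,
) -> ReferenceCurve:
    """Average the populations of the RAD-selected core and fit them.

    ``rad_records`` may be RADRecord objects or a mapping label -> RAD.
    Residues with flagged fits (when ``fits`` is supplied) are dropped from
    the member set.  Averaging is per temperature over the members that
    have a value at that temperature.
    """
    if isinstance(rad_records, dict):
        rad_map = {str(k): float(v) for k, v in rad_records.items()}
    else:
        rad_map = {r.residue_label: r.RAD for r in rad_records}
    selected = []
    for pop in populations:
        rad = rad_map.get(pop.residue_label)
        if rad is None or rad >= threshold:
            continue
        if fits is not None:
            f = fits.get(pop.residue_label)
            if f is not None and not f.ok:
                continue
        selected.append(pop)
    if len(selected) < 2:
        raise ValueError(
            f"reference needs >= 2 members below RAD {threshold}, "
            f"got {len(selected)}"
        )

    all_T = np.unique(np.concatenate([p.temperatures for p in selected]))
    sums = np.zeros_like(all_T)
    counts = np.zeros_like(all_T)
    for p in selected:
        idx = np.searchsorted(all_T, p.temperatures)
        sums[idx] += p.f_F
        counts[idx] += 1
    mean_f = sums / np.maximum(counts, 1)
    excluded = sorted({t for p in selected for t in p.excluded_temperatures})
    avg = PopulationSeries(
        residue_label="RAD_0.1 average",
        temperatures=all_T,
        f_F=mean_f,
        excluded_temperatures=excluded,
    )
    fit = fit_stability(avg, **fit_kwargs)
    return ReferenceCurve(
        members=[p.residue_label for p in selected],
        params=fit.params,
        averaged=avg,
        fit=fit,
    )


def reference_from_params(
    params: dict[str, ThermoParams],
    rad_records,
    threshold: float = 0.1,
) -> ReferenceCurve:
    """Reference built by averaging member *parameters* instead of populations.

    The alternative mode: member dHm, Tm, dCp are arithmetically averaged.
    Useful when only fitted parameters (not population series) are
    available, e.g. when working from a published parameter table.
    """
    if isinstance(rad_records, dict):
        rad_map = {str(k): float(v) for k, v in rad_records.items()}
    else:
        rad_map = {r.residue_label: r.RAD for r in rad_records}
    members = [lbl for lbl, rad in rad_map.items()
               if rad < threshold and lbl in params]
    if len(members) < 2:
        raise ValueError(f"reference needs >= 2 members below RAD {threshold}")
    dH = float(np.mean([params[m].dH_m for m in members]))
    Tm = float(np.mean([params[m].T_m for m in members]))
    dCp = float(np.mean([params[m].dCp for m in members]))
    return ReferenceCurve(members=members, params=ThermoParams(dH, Tm, dCp))


def classify_residue(
    fit: FitResult | ThermoParams,
    ref: ReferenceCurve,
    consistent_max: float = CONSISTENT_MAX_K,
    outlier_min: float = OUTLIER_MIN_K,
    mechanism_fraction: float = 0.10,
    label: str | None = None,
) -> ClassificationRecord:
    """Compare one residue's curve to the reference and categorize it.

    ``fit`` may be a FitResult or bare ThermoParams; in the latter case
    pass ``label`` to name the residue in the record.
    """
    if isinstance(fit, FitResult):
        if not fit.ok:
            return ClassificationRecord(fit.residue_label, float("nan"),
                                        float("nan"), "unclassifiable")
        params, label = fit.params, label or fit.residue_label
    else:
        params, label = fit, label or "?"

    try:
        tc = cold_denaturation_temp(params)
    except NoColdDenaturationError:
        return ClassificationRecord(label, params.T_m - ref.T_m, float("nan"),
                                    "unclassifiable")
    d_tm = params.T_m - ref.T_m
    d_tc = tc - ref.T_c
    mean_abs = (abs(d_tm) + abs(d_tc)) / 2.0
    if mean_abs < consistent_max:
        category = "consistent"
    elif mean_abs > outlier_min:
        category = "outlier"
    else:
        category = "intermediate"
    mechanisms = mechanism_decomposition(params, ref, fraction=mechanism_fraction)
    return ClassificationRecord(label, d_tm, d_tc, category, mechanisms)


def mechanism_decomposition(
    params: ThermoParams | FitResult,
    ref: ReferenceCurve,
    fraction: float = 0.10,
) -> dict[str, float]:
    """Signed magnitudes of the three curve-change mechanisms vs the reference.

    Returns a dict with keys among {"I", "II", "III"}:

    * I   -> ddH_s = dH_s - dH_s(ref), kcal/mol (labelled when |ddH_s|
             exceeds ``fraction`` x |dH_s(ref)|);
    * II  -> ddCp = dCp - dCp(ref), kcal/mol/K (fraction of dCp(ref));
    * III -> dT_s = T_s - T_s(ref), K (fraction of the reference curve's
             width Tm - Tc, the natural temperature scale of the problem).
    """
    if isinstance(params, FitResult):
        params = params.params
    out: dict[str, float] = {}
    dd_hs = params.dH_s - ref.params.dH_s
    if abs(dd_hs) > fraction * abs(ref.params.dH_s):
        out["I"] = float(dd_hs)
    dd_cp = params.dCp - ref.params.dCp
    if abs(dd_cp) > fraction * abs(ref.params.dCp):
        out["II"] = float(dd_cp)
    d_ts = max_stability_temp(params) - ref.T_s
    if abs(d_ts) > fraction * ref.width:
        out["III"] = float(d_ts)
    return out


def group_by_secondary_structure(
    records: list[ClassificationRecord],
    annotations: dict[str, str] | pd.DataFrame | None,
) -> pd.DataFrame:
    """Per-secondary-structure-element summary of classification results.

    ``annotations`` maps residue_label -> element (e.g. H1, S3, loop); a
    DataFrame with columns residue_label, element is also accepted.
    Unannotated residues fall into "loop".  Returns one row per element
    with residue list, mean dTm/dTc and per-category counts.
    """
    if annotations is None:
        ann = {}
    elif isinstance(annotations, pd.DataFrame):
        ann = dict(zip(annotations["residue_label"].astype(str),
                       annotations["element"].astype(str)))
    else:
        ann = {str(k): str(v) for k, v in annotations.items()}

    rows = []
    for rec in records:
        rows.append({
            "element": ann.get(rec.residue_label, "loop"),
            "residue_label": rec.residue_label,
            "dT_m": rec.dT_m,
            "dT_c": rec.dT_c,
            "category": rec.category,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["element", "residues", "n", "mean_dTm_K",
                                     "mean_dTc_K", "n_consistent",
                                     "n_intermediate", "n_outlier",
                                     "n_unclassifiable"])
    out = []
    for element, grp in df.groupby("element", sort=True):
        counts = grp["category"].value_counts()
        out.append({
            "element": element,
            "residues": ",".join(grp["residue_label"]),
            "n": len(grp),
            "mean_dTm_K": grp["dT_m"].mean(),
            "mean_dTc_K": grp["dT_c"].mean(),
            "n_consistent": int(counts.get("consistent", 0)),
            "n_intermediate": int(counts.get("intermediate", 0)),
            "n_outlier": int(counts.get("outlier", 0)),
            "n_unclassifiable": int(counts.get("unclassifiable", 0)),
        })
    return pd.DataFrame(out)
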