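"""End-to-end runs: volumes -> fits -> classification, plus simulation runs.

Everything a shell user or script touches goes through a RunConfig: input
paths, anchoring policy, RAD and classification thresholds, fit settings
and the seed.  Each run logs its silent decisions (anchor used, excluded
temperatures, clipped points, flagged residues) and writes deterministic
TSV tables that the package's own readers can load back.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .thermo import ThermoParams
from .volumes import (
    FitResult,
    normalize_volumes,
    volumes_to_populations,
    fit_stability,
    propagate_errors,
    read_volume_table,
    write_volume_table,
    write_fit_table,
    DEFAULT_ANCHOR_T,
    DEFAULT_ANCHOR_FRACTION,
)
from .rad import read_structure, rad_from_structure, read_rad_table, write_rad_table
from .classify import (
    build_reference,
    classify_residue,
    group_by_secondary_structure,
    CONSISTENT_MAX_K,
    OUTLIER_MIN_K,
)
from .simulate import (
    SyntheticSpec,
    generate_series,
    recovery_experiment,
    ts_robustness_experiment,
)

logger = logging.getLogger("foldstab")

__all__ = ["RunConfig", "run_fit", "run_classify", "run_simulate"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run; round-trips losslessly through JSON."""

    volumes: str | None = None
    structure: str | None = None
    rad_table: str | None = None
    secondary_structure: str | None = None
    anchor_T: float | None = DEFAULT_ANCHOR_T
    anchor_fraction: float = DEFAULT_ANCHOR_FRACTION
    v_u_rule: str = "highest_T"
    scale_mode: str = "anchor"
    core_rad: float = 0.1
    exclusion_rad: float = 0.5
    consistent_K: float = CONSISTENT_MAX_K
    outlier_K: float = OUTLIER_MIN_K
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.core_rad <= 0 or self.exclusion_rad <= 0:
            raise ValueError("RAD thresholds must be positive")
        if self.core_rad >= self.exclusion_rad:
            raise ValueError("core RAD threshold must be below the exclusion one")
        if self.consistent_K <= 0 or self.outlier_K <= 0:
            raise ValueError("classification thresholds must be positive")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def _load_populations(config: RunConfig):
    series_list = [normalize_volumes(s) for s in read_volume_table(config.volumes)]
    populations, skipped = [], []
    for s in series_list:
        try:
            pop = volumes_to_populations(
                s,
                anchor_T=config.anchor_T if config.scale_mode == "anchor" else None,
                anchor_fraction=config.anchor_fraction,
                v_u_rule=config.v_u_rule,
                scale_mode=config.scale_mode,
            )
        except ValueError as exc:
            logger.warning("skipping %s: %s", s.residue_label, exc)
            skipped.append((s.residue_label, str(exc)))
            continue
        if pop.n_clipped:
            logger.info("%s: clipped %d population points into [0, 1]",
                        pop.residue_label, pop.n_clipped)
        populations.append(pop)
    return populations, skipped


def run_fit(config: RunConfig) -> dict:
    """Fit every residue of the input volume table.

    Returns a dict with the per-residue parameter table (Table-1 style),
    the per-temperature dG +/- sigma table and the FitResult objects.
    Deterministic for a fixed config.
    """
    if config.volumes is None:
        raise ValueError("run_fit needs config.volumes")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    populations, skipped = _load_populations(config)
    if not populations:
        raise ValueError(
            "no fittable residues; diagnostics: "
            + "; ".join(f"{lbl}: {msg}" for lbl, msg in skipped)
        )
    logger.info("anchoring policy: %s / %s (anchor %s K -> fraction %s)",
                config.v_u_rule, config.scale_mode, config.anchor_T,
                config.anchor_fraction)
    fits: list[FitResult] = []
    curve_rows = []
    for pop in populations:
        fit = fit_stability(pop, restart_seed=config.seed + 20210906)
        fits.append(fit)
        if fit.flags:
            logger.warning("%s flagged: %s", fit.residue_label, ",".join(fit.flags))
        logger.info("%s: excluded temperatures %s", fit.residue_label,
                    fit.excluded_temperatures)
        if fit.ok and fit.params.covariance is not None:
            mask = pop.fit_mask()
            T = pop.temperatures[mask]
            from .thermo import gibbs_helmholtz
            dg = gibbs_helmholtz(T, fit.params)
            sig = propagate_errors(fit, T)
            for t, g, s in zip(T, dg, sig):
                curve_rows.append({"residue_label": fit.residue_label,
                                   "temperature_K": t, "dG_kcal_mol": g,
                                   "sigma_dG_kcal_mol": s})
    params_table = write_fit_table(fits, out_dir / "fit_params.tsv")
    curves_table = pd.DataFrame(curve_rows)
    curves_table.to_csv(out_dir / "stability_curves.tsv", sep="\t",
                        index=False, float_format="%.6g")
    config.to_json(out_dir / "run_config.json")
    return {"params_table": params_table, "curves_table": curves_table,
            "fits": fits, "populations": populations, "skipped": skipped}


def _load_rad(config: RunConfig):
    if config.rad_table is not None:
        return read_rad_table(config.rad_table)
    if config.structure is not None:
        model = read_structure(config.structure)
        return rad_from_structure(model)
    raise ValueError("classification needs a RAD table or a structure file")


def run_classify(config: RunConfig) -> dict:
    """Build the RAD-selected reference and classify every fitted residue."""
    fit_out = run_fit(config)
    rad_records = _load_rad(config)
    out_dir = Path(config.out_dir)
    fits = {f.residue_label: f for f in fit_out["fits"]}
    reference = build_reference(
        fit_out["populations"], rad_records, threshold=config.core_rad,
        fits=fits, restart_seed=config.seed + 20210906,
    )
    logger.info("reference members (RAD < %g): %s", config.core_rad,
                ", ".join(reference.members))
    records = [
        classify_residue(f, reference, consistent_max=config.consistent_K,
                         outlier_min=config.outlier_K)
        for f in fit_out["fits"]
    ]
    class_table = pd.DataFrame([
        {"residue_label": r.residue_label, "dTm_K": r.dT_m, "dTc_K": r.dT_c,
         "mean_abs_dT_K": r.mean_abs_dT, "category": r.category,
         "mechanisms": ";".join(f"{k}={v:+.3g}" for k, v in sorted(r.mechanisms.items()))}
        for r in records
    ])
    class_table.to_csv(out_dir / "classification.tsv", sep="\t", index=False,
                       float_format="%.6g")
    ss = (pd.read_csv(config.secondary_structure, sep="\t")
          if config.secondary_structure else None)
    ss_table = group_by_secondary_structure(records, ss)
    ss_table.to_csv(out_dir / "secondary_structure_summary.tsv", sep="\t",
                    index=False, float_format="%.6g")
    write_rad_table(rad_records, out_dir / "rad.tsv")
    return {"reference": reference, "records": records,
            "class_table": class_table, "ss_table": ss_table, **fit_out}


def run_simulate(config: RunConfig, spec: SyntheticSpec | None = None,
                 n_residues: int = 5, n_reps: int = 50,
                 robustness_reps: int = 20) -> dict:
    """Generate a synthetic dataset and its recovery/robustness reports."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = spec or SyntheticSpec(seed=config.seed)
    series_list = []
    for i in range(n_residues):
        s = dataclasses.replace(base, seed=(base.seed + 7919 * i) % (2**31),
                                residue_label=f"{61 + i} Syn")
        series_list.append(generate_series(s)[0])
    write_volume_table(series_list, out_dir / "synthetic_volumes.tsv")
    recovery = recovery_experiment(base.true_params, n_reps=n_reps,
                                   noise_sigma=base.noise_sigma,
                                   grid=base.grid, seed=config.seed)
    recovery.to_csv(out_dir / "recovery.tsv", sep="\t", index=False,
                    float_format="%.6g")
    ok = recovery[recovery.ok]
    recovery_summary = pd.DataFrame([{
        "n_ok": len(ok), "n_total": len(recovery),
        "bias_Tm_K": ok.err_Tm.mean(), "median_abs_err_Tm_K": ok.err_Tm.abs().median(),
        "bias_Tc_K": ok.err_Tc.mean(), "median_abs_err_Tc_K": ok.err_Tc.abs().median(),
        "bias_Ts_K": ok.err_Ts.mean(), "median_abs_err_Ts_K": ok.err_Ts.abs().median(),
    }])
    recovery_summary.to_csv(out_dir / "recovery_summary.tsv", sep="\t",
                            index=False, float_format="%.6g")
    robustness = ts_robustness_experiment(n_reps=robustness_reps, seed=config.seed)
    robustness.to_csv(out_dir / "ts_robustness.tsv", sep="\t", index=False,
                      float_format="%.6g")
    config.to_json(out_dir / "run_config.json")
    return {"series": series_list, "recovery": recovery,
            "recovery_summary": recovery_summary, "robustness": robustness}
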