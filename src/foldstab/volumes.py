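"""From raw HSQC peak volumes to populations to fitted stability curves.

The measurement chain this module models: at each temperature of a melting
series a residue's amide cross-peak volume V_exp is divided by the volume of
a reference peak recorded in the same spectrum (an internal-standard amide
whose intensity tracks instrumental non-linearity, not unfolding).  The
normalized volumes are converted to folded/unfolded populations and the
populations are fitted with the two-state Gibbs-Helmholtz model by damped
least squares (Levenberg-Marquardt).

Population conversion supports two policies:

``highest_T`` (default, the melting-experiment convention)
    The series' highest temperature is taken as fully unfolded, so its
    normalized volume is the unfolded baseline V_U; the maximum normalized
    volume is the folded plateau V_F.  The apparent folded fraction
    a(T) = (V - V_U) / (V_F - V_U) is then rescaled multiplicatively so the
    folded fraction at the anchor temperature (nearest grid point to the
    requested anchor, default 298.15 K) equals the independently known
    anchor value (default 0.70).  The baseline temperature is excluded from
    fitting, since its unfolded fraction is 1 by construction.

``zero``
    Volumes are already on the population scale (folded-peak volume
    proportional to folded fraction with unit constant, unfolded baseline
    zero).  Used with ``scale_mode="direct"`` for simulation studies where
    the generator's scale is known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit

from .constants import R_KCAL
from .thermo import (
    ThermoParams,
    gibbs_helmholtz_gradient,
    max_stability_temp,
    cold_denaturation_temp,
    NoColdDenaturationError,
)

__all__ = [
    "VolumeSeries",
    "PopulationSeries",
    "FitResult",
    "normalize_volumes",
    "volumes_to_populations",
    "fit_stability",
    "propagate_errors",
    "read_volume_table",
    "write_volume_table",
    "read_population_table",
    "write_fit_table",
]

#: Minimum number of distinct usable temperatures for a 3-parameter fit.
MIN_FIT_POINTS = 6

#: Room temperature used to pick the anchoring grid point.
DEFAULT_ANCHOR_T = 298.15

#: Folded population imposed at the anchor temperature.
DEFAULT_ANCHOR_FRACTION = 0.70


@dataclass
class VolumeSeries:
    """One residue's peak-volume melting series.

    ``residue_label`` is "<number> <code>" with side-chain indoles flagged by
    a trailing "sc", e.g. ``"131 Trp sc"``.
    """

    residue_label: str
    temperatures: np.ndarray
    volumes: np.ndarray
    ref_volumes: np.ndarray
    normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.ref_volumes = np.asarray(self.ref_volumes, dtype=float)
        n = len(self.temperatures)
        if len(self.volumes) != n or len(self.ref_volumes) != n:
            raise ValueError("temperatures, volumes, ref_volumes must align")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError(
                f"{self.residue_label}: temperatures must be strictly increasing"
            )
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass
class PopulationSeries:
    """Per-temperature folded/unfolded fractions for one residue."""

    residue_label: str
    temperatures: np.ndarray
    f_F: np.ndarray
    anchor_T: float | None = None
    anchor_folded_fraction: float | None = None
    excluded_temperatures: list = field(default_factory=list)
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.f_F = np.asarray(self.f_F, dtype=float)
        if len(self.f_F) != len(self.temperatures):
            raise ValueError("temperatures and f_F must align")
        if np.any((self.f_F < -1e-12) | (self.f_F > 1 + 1e-12)):
            raise ValueError("folded fractions must lie in [0, 1]")

    @property
    def f_U(self) -> np.ndarray:
        return 1.0 - self.f_F

    def fit_mask(self) -> np.ndarray:
        """Boolean mask of temperatures kept for fitting."""
        excluded = np.asarray(self.excluded_temperatures, dtype=float)
        if excluded.size == 0:
            return np.ones_like(self.temperatures, dtype=bool)
        return ~np.isclose(self.temperatures[:, None], excluded[None, :]).any(axis=1)


@dataclass
class FitResult:
    """Outcome of fitting one residue's population series."""

    residue_label: str
    params: ThermoParams
    residuals: np.ndarray
    converged: bool
    excluded_temperatures: list
    flags: list = field(default_factory=list)
    n_points: int = 0

    @property
    def ok(self) -> bool:
        return self.converged and not self.flags


def normalize_volumes(series: VolumeSeries) -> VolumeSeries:
    """Divide each peak volume by the reference-peak volume at the same T."""
    bad = np.flatnonzero(series.ref_volumes <= 0)
    if bad.size:
        t_bad = ", ".join(f"{series.temperatures[i]:g} K" for i in bad)
        raise ValueError(
            f"{series.residue_label}: non-positive reference volume at {t_bad}"
        )
    return VolumeSeries(
        residue_label=series.residue_label,
        temperatures=series.temperatures,
        volumes=series.volumes,
        ref_volumes=series.ref_volumes,
        normalized=series.volumes / series.ref_volumes,
    )


def volumes_to_populations(
    series: VolumeSeries,
    anchor_T: float | None = DEFAULT_ANCHOR_T,
    anchor_fraction: float = DEFAULT_ANCHOR_FRACTION,
    v_u_rule: str = "highest_T",
    scale_mode: str = "anchor",
) -> PopulationSeries:
    """Convert normalized volumes into folded/unfolded populations.

    Parameters
    ----------
    anchor_T:
        Requested anchor temperature; the nearest measured temperature is
        used.  ``None`` (or ``scale_mode != "anchor"``) disables anchoring.
    anchor_fraction:
        Folded population imposed at the anchor temperature.
    v_u_rule:
        ``"highest_T"``: unfolded baseline V_U is the normalized volume at
        the series' highest temperature (excluded from fitting).
        ``"zero"``: baseline is 0 (volumes already population-scaled).
    scale_mode:
        ``"anchor"``: divide by (V_F - V_U) with V_F the maximum normalized
        volume, then rescale to hit the anchor.  ``"direct"``: use
        (V - V_U) unrescaled as the folded fraction (generator scale known).
    """
    if series.normalized is None:
        series = normalize_volumes(series)
    v = series.normalized
    T = series.temperatures

    excluded: list[float] = []
    if v_u_rule == "highest_T":
        v_u = v[-1]
        excluded.append(float(T[-1]))
    elif v_u_rule == "zero":
        v_u = 0.0
    else:
        raise ValueError(f"unknown v_u_rule {v_u_rule!r}")

    if scale_mode == "anchor":
        v_f = float(np.max(v))
        if math.isclose(v_f, v_u, rel_tol=0.0, abs_tol=1e-12 * max(1.0, abs(v_f))):
            raise ValueError(
                f"{series.residue_label}: degenerate series, folded plateau "
                "equals unfolded baseline (flat volumes)"
            )
        a = (v - v_u) / (v_f - v_u)
        anchor_used: float | None = None
        anchor_frac_used: float | None = None
        if anchor_T is not None:
            i = int(np.argmin(np.abs(T - anchor_T)))
            anchor_used = float(T[i])
            if a[i] <= 0:
                raise ValueError(
                    f"{series.residue_label}: apparent folded fraction at the "
                    f"anchor temperature {anchor_used:g} K is not positive; "
                    "cannot anchor"
                )
            a = a * (anchor_fraction / a[i])
            anchor_frac_used = anchor_fraction
    elif scale_mode == "direct":
        a = v - v_u
        anchor_used = None
        anchor_frac_used = None
    else:
        raise ValueError(f"unknown scale_mode {scale_mode!r}")

    clipped = int(np.sum((a < 0) | (a > 1)))
    f_F = np.clip(a, 0.0, 1.0)
    return PopulationSeries(
        residue_label=series.residue_label,
        temperatures=T,
        f_F=f_F,
        anchor_T=anchor_used,
        anchor_folded_fraction=anchor_frac_used,
        excluded_temperatures=excluded,
        n_clipped=clipped,
    )


def _initial_guess(T: np.ndarray, f_F: np.ndarray) -> ThermoParams:
    """Heuristic start: Tm from the steepest high-temperature drop."""
    dT = np.diff(T)
    slope = np.diff(f_F) / dT
    mid = T[:-1] + dT / 2.0
    # steepest decrease in the upper half of the grid
    upper = mid >= np.median(T)
    if np.any(upper) and np.any(slope[upper] < 0):
        idx = np.flatnonzero(upper)[np.argmin(slope[upper])]
        tm0 = float(mid[idx])
    else:
        tm0 = float(T[np.argmax(f_F)] + 5.0)
    return ThermoParams(dH_m=25.0, T_m=tm0, dCp=2.5)


def fit_stability(
    pop: PopulationSeries,
    init: ThermoParams | None = None,
    n_restarts: int = 5,
    restart_seed: int = 20210906,
    t_m_range: tuple[float, float] = (250.0, 400.0),
) -> FitResult:
    """Fit (dHm, Tm, dCp) to an unfolded-fraction series by damped least squares.

    Minimizes sum over kept temperatures of
    [f_U_obs(T) - f_U_model(T; dHm, Tm, dCp)]^2 with the Levenberg-Marquardt
    algorithm, then derives the covariance from the final Jacobian as
    s^2 (J^T J)^{-1} with s^2 the residual variance.  Non-convergence and
    unphysical optima (dHm <= 0, dCp <= 0, Tm outside ``t_m_range``) are
    flagged, never silently reported.
    """
    mask = pop.fit_mask()
    T = pop.temperatures[mask]
    f_u_obs = pop.f_U[mask]
    n = len(T)
    if n < MIN_FIT_POINTS:
        raise ValueError(
            f"{pop.residue_label}: need >= {MIN_FIT_POINTS} usable temperatures, "
            f"got {n}"
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        dH, Tm, dCp = theta
        if Tm <= 0:  # keep LM steps out of the log's domain error
            return np.full(n, 1e3)
        ratio = T / Tm
        dG = dH * (1.0 - ratio) + dCp * ((T - Tm) - T * np.log(ratio))
        return expit(-dG / (R_KCAL * T)) - f_u_obs

    def physical(theta: np.ndarray) -> bool:
        return theta[0] > 0 and theta[2] > 0 and t_m_range[0] <= theta[1] <= t_m_range[1]

    start = init if init is not None else _initial_guess(pop.temperatures, pop.f_F)
    rng = np.random.default_rng(restart_seed)
    theta0 = np.array(start.as_tuple())
    best = None
    for attempt in range(n_restarts + 1):
        guess = theta0 if attempt == 0 else theta0 * rng.uniform(0.7, 1.3, 3)
        guess = np.clip(guess, [1e-3, 200.0, 1e-4], [200.0, 450.0, 50.0])
        try:
            sol = least_squares(residual, guess, method="lm", xtol=1e-14,
                                ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
        if sol.success and physical(sol.x):
            best = sol if sol.cost <= best.cost else best
            if best.success and physical(best.x):
                break

    flags: list[str] = []
    if best is None:
        params = start
        return FitResult(pop.residue_label, params, np.full(n, np.nan),
                         converged=False,
                         excluded_temperatures=list(pop.excluded_temperatures),
                         flags=["no-solution"], n_points=n)

    dH, Tm, dCp = best.x
    converged = bool(best.success)
    if not converged:
        flags.append("non-convergent")
    if dH <= 0:
        flags.append("unphysical-dHm")
    if dCp <= 0:
        flags.append("unphysical-dCp")
    if not (t_m_range[0] <= Tm <= t_m_range[1]):
        flags.append("Tm-out-of-range")

    # identifiability guard: a flat series fits any huge-Tm plateau equally
    if np.ptp(f_u_obs) < 1e-6:
        flags.append("flat-series")
        converged = False

    cov = None
    if converged and not flags:
        J = best.jac
        dof = max(n - 3, 1)
        s2 = 2.0 * best.cost / dof
        try:
            JTJ_inv = np.linalg.inv(J.T @ J)
            cov = s2 * JTJ_inv
            cov = (cov + cov.T) / 2.0
        except np.linalg.LinAlgError:
            flags.append("singular-jacobian")
            cov = None

    params = ThermoParams(dH_m=float(dH), T_m=float(Tm), dCp=float(dCp),
                          covariance=cov)
    return FitResult(
        residue_label=pop.residue_label,
        params=params,
        residuals=best.fun,
        converged=converged,
        excluded_temperatures=list(pop.excluded_temperatures),
        flags=flags,
        n_points=n,
    )


def propagate_errors(fit: FitResult, T_grid) -> np.ndarray:
    """Covariance-propagated sigma of DeltaG on a temperature grid.

    sigma^2(T) = g(T)^T Sigma g(T) with g the closed-form gradient of the
    Gibbs-Helmholtz curve in (dHm, Tm, dCp).
    """
    if fit.params.covariance is None:
        raise ValueError(
            f"{fit.residue_label}: fit carries no covariance; cannot propagate"
        )
    g = gibbs_helmholtz_gradient(np.asarray(T_grid, dtype=float), fit.params)
    var = np.einsum("...i,ij,...j->...", g, fit.params.covariance, g)
    return np.sqrt(np.maximum(var, 0.0))


# ---------------------------------------------------------------------------
# Tabular I/O

LONG_COLUMNS = ["residue_label", "temperature_K", "volume", "reference_volume"]


def read_volume_table(path) -> list[VolumeSeries]:
    """Read a delimited volume table (TSV/CSV sniffed by extension).

    Long format: columns residue_label, temperature_K, volume,
    reference_volume.  Wide format: a residue_label column plus one column
    per temperature (header parseable as a float, Kelvin); reference
    volumes may be supplied as a row labelled ``__reference__`` (default 1).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if set(LONG_COLUMNS).issubset(df.columns):
        out = []
        for label, grp in df.groupby("residue_label", sort=False):
            grp = grp.sort_values("temperature_K")
            out.append(VolumeSeries(
                residue_label=str(label),
                temperatures=grp["temperature_K"].to_numpy(),
                volumes=grp["volume"].to_numpy(),
                ref_volumes=grp["reference_volume"].to_numpy(),
            ))
        return out
    # wide format
    temp_cols = [c for c in df.columns if _is_float(c)]
    if "residue_label" not in df.columns or not temp_cols:
        raise ValueError(
            f"{path}: not a recognizable volume table (need long columns "
            f"{LONG_COLUMNS} or wide residue_label + temperature columns)"
        )
    temps = np.array(sorted(float(c) for c in temp_cols))
    col_order = sorted(temp_cols, key=float)
    ref_row = df[df["residue_label"] == "__reference__"]
    refs = (ref_row[col_order].to_numpy(dtype=float).ravel()
            if len(ref_row) else np.ones_like(temps))
    out = []
    for _, row in df[df["residue_label"] != "__reference__"].iterrows():
        out.append(VolumeSeries(
            residue_label=str(row["residue_label"]),
            temperatures=temps,
            volumes=row[col_order].to_numpy(dtype=float),
            ref_volumes=refs,
        ))
    return out


def _is_float(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def write_volume_table(series_list: list[VolumeSeries], path) -> None:
    """Write volume series in the long TSV dialect read_volume_table accepts."""
    rows = []
    for s in series_list:
        for t, v, r in zip(s.temperatures, s.volumes, s.ref_volumes):
            rows.append((s.residue_label, t, v, r))
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_population_table(path) -> list[PopulationSeries]:
    """Read a TSV of residue_label, temperature_K, f_F."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for label, grp in df.groupby("residue_label", sort=False):
        grp = grp.sort_values("temperature_K")
        out.append(PopulationSeries(
            residue_label=str(label),
            temperatures=grp["temperature_K"].to_numpy(),
            f_F=grp["f_F"].to_numpy(),
        ))
    return out


def write_fit_table(fits: list[FitResult], path) -> pd.DataFrame:
    """Write fitted parameters in the standard reporting schema.

    Columns: residue_label, dH_kcal_mol, dS_kcal_mol_K, dCp_kcal_mol_K,
    Tm_K, Tc_K, Ts_K, converged, flags, n_points.  Tc/Ts are blank when the
    curve has no cold branch or the fit is flagged.
    """
    rows = []
    for f in fits:
        p = f.params
        tc = ts = float("nan")
        if f.ok:
            try:
                ts = max_stability_temp(p)
                tc = cold_denaturation_temp(p)
            except (ValueError, NoColdDenaturationError):
                pass
        rows.append({
            "residue_label": f.residue_label,
            "dH_kcal_mol": p.dH_m,
            "dS_kcal_mol_K": p.dS_m,
            "dCp_kcal_mol_K": p.dCp,
            "Tm_K": p.T_m,
            "Tc_K": tc,
            "Ts_K": ts,
            "converged": f.converged,
            "flags": ";".join(f.flags),
            "n_points": f.n_points,
        })
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
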