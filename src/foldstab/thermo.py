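"""Two-state protein stability thermodynamics in closed form.

The central object is the *stability curve*: the free energy of unfolding
DeltaG(T) = G_unfolded - G_folded as a function of absolute temperature,
under the modified Gibbs-Helmholtz model with a temperature-independent
heat-capacity difference dCp:

    DeltaG(T) = dHm * (1 - T/Tm) + dCp * [(T - Tm) - T * ln(T/Tm)]

The curve is an inverted-parabola-like function with two zeros: the heat
melting temperature Tm and, when dCp is large enough, the cold-denaturation
temperature Tc below the temperature of maximum stability
Ts = Tm * exp(-dSm/dCp).  Populations of the folded/unfolded states follow
a Boltzmann two-state law, f_U = exp(-dG/RT) / (1 + exp(-dG/RT)).

Sign convention: DeltaG > 0 means the folded state is stable (f_U < 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .constants import R_KCAL

__all__ = [
    "ThermoParams",
    "StabilityCurve",
    "NoColdDenaturationError",
    "gibbs_helmholtz",
    "gibbs_helmholtz_gradient",
    "unfolded_fraction",
    "folded_fraction",
    "max_stability_temp",
    "cold_denaturation_temp",
    "entropy_at_tm",
    "curvature",
    "naive_stability",
]

#: Default lowest temperature considered when searching for a cold-
#: denaturation zero.  Below ~150 K the two-state solution model has no
#: physical meaning (solvent is deeply frozen).
DEFAULT_TC_FLOOR: float = 150.0


class NoColdDenaturationError(ValueError):
    """Raised when the stability curve has no zero above the search floor."""


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (absolute Kelvin)")
    return T


@dataclass
class ThermoParams:
    """Fitted two-state unfolding parameters for one reporter.

    Parameters
    ----------
    dH_m:
        Unfolding enthalpy at the melting temperature, kcal/mol.
    T_m:
        Heat melting temperature, K.
    dCp:
        Heat-capacity difference (unfolded - folded), kcal/mol/K.
    covariance:
        Optional symmetric 3x3 covariance of (dH_m, T_m, dCp) from the fit.
    """

    dH_m: float
    T_m: float
    dCp: float
    covariance: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.T_m <= 0:
            raise ValueError(f"T_m must be positive Kelvin, got {self.T_m}")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if cov.shape != (3, 3):
                raise ValueError("covariance must be a 3x3 matrix")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")
            self.covariance = cov

    @property
    def dS_m(self) -> float:
        """Unfolding entropy at T_m, kcal/mol/K (= dH_m / T_m)."""
        return self.dH_m / self.T_m

    @property
    def T_s(self) -> float:
        """Temperature of maximum stability, K."""
        return max_stability_temp(self)

    @property
    def T_c(self) -> float:
        """Cold-denaturation temperature, K (lower zero of the curve)."""
        return cold_denaturation_temp(self)

    @property
    def dH_s(self) -> float:
        """Unfolding enthalpy evaluated at T_s, kcal/mol.

        Kirchhoff with constant dCp: dH(T) = dH_m + dCp * (T - T_m).
        """
        return self.dH_m + self.dCp * (self.T_s - self.T_m)

    def is_physical(self, t_range: tuple[float, float] = (250.0, 400.0)) -> bool:
        """Whether the parameters describe a credible folded protein."""
        return (
            self.dH_m > 0
            and self.dCp > 0
            and t_range[0] <= self.T_m <= t_range[1]
        )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dH_m, self.T_m, self.dCp)


def gibbs_helmholtz(T, p: ThermoParams):
    """Unfolding free energy DeltaG(T) in kcal/mol.

    DeltaG = dHm (1 - T/Tm) + dCp [(T - Tm) - T ln(T/Tm)]

    ``T`` may be a scalar or array of absolute temperatures (K).
    """
    T = _check_temperature(T)
    ratio = T / p.T_m
    dG = p.dH_m * (1.0 - ratio) + p.dCp * ((T - p.T_m) - T * np.log(ratio))
    return float(dG) if np.isscalar(dG) or dG.ndim == 0 else dG


def gibbs_helmholtz_gradient(T, p: ThermoParams) -> np.ndarray:
    """Gradient of DeltaG(T) with respect to (dH_m, T_m, dCp).

    Closed form, used for covariance error propagation.  Returns an array of
    shape ``(..., 3)`` matching the shape of ``T``.
    """
    T = _check_temperature(T)
    ratio = T / p.T_m
    g_dH = 1.0 - ratio
    g_Tm = p.dH_m * T / p.T_m**2 + p.dCp * (ratio - 1.0)
    g_dCp = (T - p.T_m) - T * np.log(ratio)
    return np.stack(np.broadcast_arrays(g_dH, g_Tm, g_dCp), axis=-1)


def unfolded_fraction(T, dG):
    """Two-state unfolded population f_U = e^{-dG/RT} / (1 + e^{-dG/RT}).

    ``dG`` in kcal/mol; ``T`` in K.  Vectorized over both arguments.
    """
    T = _check_temperature(T)
    x = -np.asarray(dG, dtype=float) / (R_KCAL * T)
    out = expit(x)
    return float(out) if np.ndim(out) == 0 else out


def folded_fraction(T, dG):
    """Two-state folded population f_F = 1 - f_U."""
    return 1.0 - unfolded_fraction(T, dG)


def max_stability_temp(p: ThermoParams) -> float:
    """Temperature of maximum stability Ts = Tm * exp(-dSm/dCp), K.

    Ts is the zero-entropy point of the stability curve and its argmax.
    """
    if p.dCp <= 0:
        raise ValueError("dCp must be positive for an interior stability maximum")
    return p.T_m * math.exp(-p.dH_m / (p.T_m * p.dCp))


def cold_denaturation_temp(p: ThermoParams, floor: float = DEFAULT_TC_FLOOR) -> float:
    """Lower zero of the stability curve (cold-denaturation temperature), K.

    Bracketed root search on [floor, Ts] to |DeltaG| < 1e-9 kcal/mol.

    Raises
    ------
    NoColdDenaturationError
        If DeltaG stays positive down to ``floor`` (no observable cold
        denaturation) or the curve has no interior maximum.
    """
    if p.dCp <= 0:
        raise NoColdDenaturationError(
            "dCp <= 0: DeltaG has a single zero at Tm and no cold branch"
        )
    ts = max_stability_temp(p)
    if gibbs_helmholtz(ts, p) <= 0:
        raise NoColdDenaturationError(
            "stability curve never positive: protein is never folded"
        )
    if ts <= floor:
        raise NoColdDenaturationError(
            f"maximum-stability temperature {ts:.1f} K at or below floor {floor} K"
        )
    if gibbs_helmholtz(floor, p) > 0:
        raise NoColdDenaturationError(
            f"no cold-denaturation zero above {floor} K"
        )
    return float(brentq(lambda t: gibbs_helmholtz(t, p), floor, ts, xtol=1e-12))


def entropy_at_tm(dH_m: float, T_m: float) -> float:
    """Unfolding entropy at the melting point, dSm = dHm / Tm (kcal/mol/K).

    Follows from DeltaG(Tm) = 0 = dHm - Tm dSm.
    """
    if T_m <= 0:
        raise ValueError("T_m must be positive Kelvin")
    return dH_m / T_m


def curvature(T, p: ThermoParams):
    """Second derivative of the stability curve: d2(DeltaG)/dT2 = -dCp/T.

    The curvature is what makes dCp the controller of the width of the
    stability curve (kcal/mol/K^2).
    """
    T = _check_temperature(T)
    out = -p.dCp / T
    return float(out) if out.ndim == 0 else out


def naive_stability(T, I_f):
    """Apparent stability from raw folded-peak intensity fractions.

    DeltaG~(T) = -RT ln((1 - I_f) / I_f), with I_f the folded-peak intensity
    fraction.  This is the curve an experimenter gets by trusting intensities
    directly; it equals the true DeltaG only when intensities are exactly
    proportional to populations.
    """
    T = _check_temperature(T)
    I_f = np.asarray(I_f, dtype=float)
    if np.any((I_f <= 0) | (I_f >= 1)):
        raise ValueError(
            "folded-peak fraction must lie strictly in (0, 1); "
            "DeltaG~ diverges at I_f = 0 or 1"
        )
    out = -R_KCAL * T * np.log((1.0 - I_f) / I_f)
    return float(out) if out.ndim == 0 else out


@dataclass
class StabilityCurve:
    """Evaluable stability curve with propagated uncertainty band.

    ``sigma(T)`` is the covariance-propagated standard deviation of
    DeltaG(T); zero when the parameters carry no covariance.
    """

    params: ThermoParams
    T_low: float = 260.0
    T_high: float = 320.0

    def dG(self, T):
        return gibbs_helmholtz(T, self.params)

    def sigma(self, T):
        if self.params.covariance is None:
            out = np.zeros_like(np.asarray(T, dtype=float))
            return float(out) if out.ndim == 0 else out
        g = gibbs_helmholtz_gradient(T, self.params)
        var = np.einsum("...i,ij,...j->...", g, self.params.covariance, g)
        var = np.maximum(var, 0.0)
        out = np.sqrt(var)
        return float(out) if out.ndim == 0 else out

    def grid(self, n: int = 200) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(T, dG, sigma) sampled evenly over the validity range."""
        T = np.linspace(self.T_low, self.T_high, n)
        return T, self.dG(T), self.sigma(T)
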