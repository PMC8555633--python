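"""FRAP recovery kinetics: normalization, exponential fitting, and transport.

A bleach-recovery trace is normalized by ratioing against a reference trace
(unbleached cytoplasm for whole-condensate bleaching, or the whole condensate
for internal bleaching) and fitted with the single-exponential recovery model

    I(t) = P * (1 - exp(-t / tau)) + y0,

where y0 is the intensity immediately after the bleach, P the amplitude of
the fluorescence change, and tau the recovery time constant; the plateau is
P + y0 and the recovery half-time is tau * ln 2.  From the half-time and the
bleach-region radius omega, an apparent diffusion coefficient follows as
D ≈ 0.224 * omega^2 / t_half, and an apparent viscosity from Stokes-Einstein,
eta = kB * T / (6 * pi * Rh * D).  The viscosity estimate is qualitative: it
inherits the uncertainty of the hydrodynamic radius and of treating recovery
as pure diffusion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.constants import k as BOLTZMANN_K
from scipy.optimize import curve_fit

LN2 = math.log(2.0)


class NormalizationError(ValueError):
    """Reference trace unusable (non-positive values or mismatched time base)."""


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge."""


@dataclass(frozen=True)
class RecoveryCurve:
    """A normalized bleach-recovery time series (time in seconds, t=0 at bleach)."""

    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and intensity must be equal-length 1-D arrays")
        if len(t) < 5:
            raise ValueError("a recovery curve needs at least 5 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(y)) and np.all(y >= 0)):
            raise ValueError("intensities must be finite and non-negative")


@dataclass(frozen=True)
class FrapFit:
    """Fitted recovery parameters and derived quantities."""

    P: float
    tau: float
    y0: float
    t_half: float
    mobile_fraction: float
    rss: float
    param_sd: tuple[float, float, float]  # (P, tau, y0) standard errors
    tau_at_bound: bool
    plateau_not_reached: bool

    @property
    def plateau(self) -> float:
        return self.P + self.y0

    def predict(self, time: np.ndarray) -> np.ndarray:
        return recovery_model(np.asarray(time, float), self.P, self.tau, self.y0)


def recovery_model(t: np.ndarray, P: float, tau: float, y0: float) -> np.ndarray:
    return P * (1.0 - np.exp(-t / tau)) + y0


def _ratio_normalize(time, bleached, reference) -> RecoveryCurve:
    t = np.asarray(time, float)
    num = np.asarray(bleached, float)
    den = np.asarray(reference, float)
    if not (t.shape == num.shape == den.shape):
        raise NormalizationError("traces must share one time base")
    if np.any(den <= 0):
        raise NormalizationError("reference trace contains non-positive values")
    return RecoveryCurve(t, num / den)


def normalize_whole(time, bleached_condensate, cytoplasm_reference) -> RecoveryCurve:
    """Whole-condensate bleach: ratio against unbleached cytoplasm."""
    return _ratio_normalize(time, bleached_condensate, cytoplasm_reference)


def normalize_internal(time, bleached_subregion, whole_condensate) -> RecoveryCurve:
    """Internal bleach: ratio of the bleached sub-region against the whole condensate."""
    return _ratio_normalize(time, bleached_subregion, whole_condensate)


def fit_recovery(curve: RecoveryCurve, pre_bleach: float = 1.0) -> FrapFit:
    """Bounded least-squares fit of the single-exponential recovery model.

    Initialization: y0 = first intensity, P = last − first, tau = half the
    time span; bounds keep tau in [dt/10, 100·span] and P, y0 non-negative.
    A tau pinned at its bounds, or exceeding half the span (plateau not
    reached within the observation), is flagged rather than rejected.
    """
    t = curve.time - curve.time[0]
    y = curve.intensity
    span = float(t[-1] - t[0])
    dt = float(np.min(np.diff(t)))
    tau_lo, tau_hi = dt / 10.0, 100.0 * span
    p0 = [max(float(y[-1] - y[0]), 1e-6), max(min(span / 2.0, tau_hi), tau_lo),
          max(float(y[0]), 0.0)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                recovery_model, t, y, p0=p0,
                bounds=([0.0, tau_lo, 0.0], [np.inf, tau_hi, np.inf]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError) as err:
        raise FitError(f"recovery fit did not converge: {err}") from err
    P, tau, y0 = (float(v) for v in popt)
    resid = y - recovery_model(t, P, tau, y0)
    sd = tuple(float(s) for s in np.sqrt(np.clip(np.diag(pcov), 0, np.inf)))
    fit = FrapFit(
        P=P, tau=tau, y0=y0,
        t_half=half_time_from_tau(tau),
        mobile_fraction=_mobile_fraction_values(P, y0, pre_bleach),
        rss=float(np.sum(resid**2)),
        param_sd=sd,
        tau_at_bound=bool(np.isclose(tau, tau_lo) or np.isclose(tau, tau_hi)),
        plateau_not_reached=bool(tau > span / 2.0),
    )
    return fit


def half_time_from_tau(tau: float) -> float:
    """Recovery half-time tau·ln 2 (time to reach half the asymptotic change)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return tau * LN2


def half_time(fit: FrapFit) -> float:
    return half_time_from_tau(fit.tau)


def apparent_diffusion(omega_um: float, t_half_s: float) -> float:
    """Apparent diffusion D ≈ 0.224·ω²/t_half, in μm²/s (ω = bleach radius, μm)."""
    if omega_um <= 0 or t_half_s <= 0:
        raise ValueError("omega and t_half must be positive")
    return 0.224 * omega_um**2 / t_half_s


def diffusion_um2s_to_m2s(d_um2_s: float) -> float:
    return d_um2_s * 1e-12


def apparent_viscosity(d_app_um2_s: float, rh_m: float, temperature_k: float) -> float:
    """Stokes-Einstein apparent viscosity eta = kB·T/(6π·Rh·D), in Pa·s.

    D is supplied in μm²/s (interface units) and converted to m²/s internally;
    Rh is the hydrodynamic radius in metres.
    """
    if d_app_um2_s <= 0 or rh_m <= 0 or temperature_k <= 0:
        raise ValueError("D, Rh and T must all be positive")
    d_m2_s = diffusion_um2s_to_m2s(d_app_um2_s)
    return BOLTZMANN_K * temperature_k / (6.0 * math.pi * rh_m * d_m2_s)


def _mobile_fraction_values(P: float, y0: float, pre_bleach: float) -> float:
    if pre_bleach <= y0:
        raise ValueError("pre-bleach level must exceed the post-bleach offset y0")
    return float(np.clip(P / (pre_bleach - y0), 0.0, 1.0))


def mobile_fraction(fit: FrapFit, pre_bleach: float = 1.0) -> float:
    """Mobile fraction (plateau − y0)/(pre_bleach − y0), clipped to [0, 1].

    For ratio-normalized curves the pre-bleach level defaults to 1.
    """
    return _mobile_fraction_values(fit.P, fit.y0, pre_bleach)
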