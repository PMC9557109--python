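"""Post-silking canopy dynamics: Gaussian LAI trajectory and linear Pn decline.

The leaf-area index after silking follows a Gaussian course
``LAI(t) = A·exp(−(t−B)²/(2C²))`` on the days-after-silking axis: A is the
maximum LAI, B the day it occurs, C the curve width.  The duration of higher
LAI (DLAI) is the time for the fitted curve to fall from its maximum to half
of it, ``C·√(2 ln 2)``.

Ear-leaf net photosynthesis declines linearly after full expansion,
``Pn(t) = a − b·t``; with Pi the initial (earliest post-silking) measured Pn,
the active photosynthesis duration (APD) is the time to lose half of Pi
under the fitted decline, ``Pi/(2b)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .data_model_io import DomainError, GasExchangeObservation, LAIObservation

__all__ = [
    "FitError",
    "ConvergenceError",
    "GaussianFit",
    "LinearDecayFit",
    "HALF_LIFE_FACTOR",
    "fit_lai_gaussian",
    "dlai",
    "fit_pn_linear",
    "apd",
    "canopy_photosynthetic_capacity",
    "stage_decline_summary",
    "gaussian_log_quadratic_init",
]

HALF_LIFE_FACTOR = math.sqrt(2.0 * math.log(2.0))  # ≈ 1.17741, half-maximum offset in units of C


class FitError(ValueError):
    """Too few / degenerate observations for a fit."""


class ConvergenceError(RuntimeError):
    """The nonlinear least-squares refinement did not converge."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class GaussianFit:
    """Fitted Gaussian LAI trajectory: lai_max (A), peak_day (B), width (C), R²."""

    lai_max: float
    peak_day: float
    width: float
    r2: float

    @property
    def dlai(self) -> float:
        """Days for the fitted LAI to fall from the maximum to half-maximum."""
        return dlai(self)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.lai_max * np.exp(-((t - self.peak_day) ** 2) / (2.0 * self.width ** 2))


@dataclass(frozen=True)
class LinearDecayFit:
    """Fitted ear-leaf Pn decline y = a − b·x with Pearson r and the initial measured Pn (Pi)."""

    intercept: float
    decline_rate: float
    r: float
    pi: float

    @property
    def apd(self) -> float:
        """Days for Pn to fall from Pi to half of Pi under the fitted decline."""
        return apd(self)

    def predict(self, t) -> np.ndarray:
        return self.intercept - self.decline_rate * np.asarray(t, dtype=float)


def gaussian_log_quadratic_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form Gaussian parameters from a quadratic regression on log(y).

    Exact for noiseless strictly-positive Gaussian data: log y is quadratic in
    t with curvature −1/(2C²).  Used to initialize the nonlinear fit, and as
    an independent oracle in tests.
    """
    mask = y > 0
    if mask.sum() < 3:
        raise FitError("need >= 3 strictly positive observations for log-quadratic init")
    c2, c1, c0 = np.polyfit(t[mask], np.log(y[mask]), 2)
    if c2 >= 0:
        # not peak-shaped in log domain; fall back to heuristics
        a0 = float(y.max())
        b0 = float(t[np.argmax(y)])
        c0w = max((t.max() - t.min()) / 2.0, 1.0)
        return a0, b0, c0w
    width = math.sqrt(-1.0 / (2.0 * c2))
    peak = -c1 / (2.0 * c2)
    amp = math.exp(c0 - c1 ** 2 / (4.0 * c2))
    return amp, peak, width


def fit_lai_gaussian(obs: Sequence[LAIObservation] | Iterable[LAIObservation],
                     max_iter: int = 200, xtol: float = 1e-10) -> GaussianFit:
    """Least-squares Gaussian fit of LAI against days after silking.

    Initialized from the log-quadratic closed form, refined by
    Levenberg–Marquardt.  Requires at least 4 positive observations spanning
    the peak; a flat series is rejected.
    """
    obs = list(obs)
    t = np.array([o.days_after_silking for o in obs], dtype=float)
    y = np.array([o.lai for o in obs], dtype=float)
    if (y > 0).sum() < 4:
        raise FitError(f"need >= 4 positive LAI observations, got {(y > 0).sum()}")
    if np.ptp(y) == 0.0:
        raise FitError("constant LAI series cannot constrain a Gaussian")

    p0 = gaussian_log_quadratic_init(t, y)

    def model(tt, a, b, c):
        return a * np.exp(-((tt - b) ** 2) / (2.0 * c ** 2))

    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, maxfev=max_iter * len(p0) * 10,
                                     xtol=xtol, method="lm")
    except RuntimeError as exc:
        raise ConvergenceError(str(exc), last_iterate=p0) from exc
    a, b, c = float(popt[0]), float(popt[1]), abs(float(popt[2]))
    resid = y - model(t, a, b, c)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    return GaussianFit(lai_max=a, peak_day=b, width=c, r2=min(max(r2, 0.0), 1.0))


def dlai(fit: GaussianFit) -> float:
    """DLAI = C·√(2 ln 2): days from the LAI maximum to half-maximum."""
    if fit.width <= 0:
        raise DomainError(f"Gaussian width must be positive, got {fit.width}")
    return fit.width * HALF_LIFE_FACTOR


def fit_pn_linear(obs: Sequence[GasExchangeObservation] | Iterable[GasExchangeObservation]) -> LinearDecayFit:
    """OLS fit of post-silking ear-leaf Pn against days after silking, as y = a − b·x.

    Only observations at t ≥ 0 (post-silking) enter the fit.  Pi is the
    measured Pn at the earliest post-silking time point (mean if replicated),
    not the fitted intercept.
    """
    post = [o for o in obs if o.days_after_silking >= 0]
    if len(post) < 3:
        raise FitError(f"need >= 3 post-silking observations, got {len(post)}")
    t = np.array([o.days_after_silking for o in post], dtype=float)
    y = np.array([o.pn for o in post], dtype=float)
    if np.ptp(t) == 0.0:
        raise FitError("zero variance in observation times")
    res = stats.linregress(t, y)
    t0 = t.min()
    pi = float(y[t == t0].mean())
    return LinearDecayFit(intercept=float(res.intercept), decline_rate=float(-res.slope),
                          r=abs(float(res.rvalue)), pi=pi)


def apd(fit: LinearDecayFit) -> float:
    """APD = Pi/(2b): days for Pn to fall from Pi to half of Pi at decline rate b."""
    if fit.decline_rate <= 0:
        raise DomainError("APD undefined: Pn does not decline (b <= 0)")
    if fit.pi <= 0:
        raise DomainError(f"initial Pn must be positive, got {fit.pi}")
    return fit.pi / (2.0 * fit.decline_rate)


def canopy_photosynthetic_capacity(pn: float, lai: float) -> float:
    """Canopy photosynthetic capacity = Pn × LAI (µmol CO₂ m⁻² ground s⁻¹)."""
    if pn < 0 or lai < 0:
        raise DomainError(f"pn and lai must be non-negative, got pn={pn}, lai={lai}")
    return pn * lai


def stage_decline_summary(values: Mapping[str, float], reference: float) -> dict[str, float]:
    """Percent change of each stage value relative to a reference: 100·(v − ref)/ref."""
    if reference <= 0:
        raise DomainError(f"reference must be positive, got {reference}")
    return {stage: 100.0 * (v - reference) / reference for stage, v in values.items()}
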