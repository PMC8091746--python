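"""Absorbance-time curves and per-curve kinetic estimators.

A kinetic spectrophotometric assay follows a slow colour-forming reaction
(here triiodide, I3-, read near 350 nm) and converts some feature of each
absorbance-time trace into an analytical response:

* the *initial rate* (slope of the tangent at t -> 0),
* a *pseudo-first-order rate constant* from the slope of log10 A vs t,
* the absorbance at a *fixed time*, or
* the time needed to reach a *fixed absorbance*.

This module owns the curve container and those four per-curve estimators;
calibration across concentrations lives in :mod:`kinspec.calibration`.
All times are seconds internally; unit conversion happens at I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats

from .errors import ComputationError, DataError

__all__ = [
    "AbsorbanceTimeCurve",
    "KineticSeriesSet",
    "InitialRate",
    "initial_rate",
    "pseudo_first_order_k",
    "absorbance_at_time",
    "time_to_absorbance",
    "DEFAULT_WINDOW_END_S",
]

#: Default tangent window for the initial-rate estimator, in seconds.
#: On a 300 s reading grid this uses the first three points (0, 300, 600 s),
#: the early-linear stretch of a rising pseudo-first-order curve.
DEFAULT_WINDOW_END_S = 600.0


@dataclass(frozen=True)
class AbsorbanceTimeCurve:
    """One sample's absorbance readings over time.

    Parameters
    ----------
    sample_id : str
        Identifier of the cuvette/replicate.
    times : array-like of float
        Reading times in seconds, strictly increasing, first >= 0.
    absorbances : array-like of float
        Absorbance in AU, same length as ``times``, all finite.
    concentration : float or None
        Nominal analyte concentration in ug/ml (= mg/L); ``None`` for
        unknowns awaiting inverse prediction.
    wavelength : float
        Reading wavelength in nm (metadata only).
    replicate_index : int
        Replicate counter within a concentration level.
    """

    sample_id: str
    times: np.ndarray
    absorbances: np.ndarray
    concentration: float | None = None
    wavelength: float = 350.0
    replicate_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbances", a)
        if t.ndim != 1 or a.ndim != 1 or t.size != a.size:
            raise DataError("length-mismatch", "times and absorbances must be 1-D and equal length")
        if t.size < 2:
            raise DataError("too-few-points", "a curve needs at least 2 readings")
        if t[0] < 0:
            raise DataError("negative-time", "first reading time must be >= 0")
        if not np.all(np.diff(t) > 0):
            raise DataError("non-increasing-times", "times must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise DataError("non-finite-absorbance", "absorbances must all be finite")
        if self.concentration is not None and self.concentration < 0:
            raise DataError("negative-concentration", "concentration must be non-negative")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass
class KineticSeriesSet:
    """A collection of curves measured under one set of reaction conditions."""

    curves: list[AbsorbanceTimeCurve]
    temperature: float = 25.0
    conditions: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.curves:
            raise DataError("empty-set", "a series set needs at least one curve")

    def standards(self) -> list[AbsorbanceTimeCurve]:
        """Curves with a known nominal concentration (calibration standards)."""
        return [c for c in self.curves if c.concentration is not None]

    def unknowns(self) -> list[AbsorbanceTimeCurve]:
        return [c for c in self.curves if c.concentration is None]


@dataclass(frozen=True)
class InitialRate:
    """Initial tangent slope of an absorbance-time curve."""

    value: float  # AU/s, sign preserved
    window_end: float  # s
    n_points_used: int
    fit_r2: float

    def __post_init__(self) -> None:
        if self.n_points_used < 2:
            raise DataError("insufficient-points", "initial rate needs >= 2 points")
        if self.window_end <= 0:
            raise DataError("bad-window", "window_end must be positive")


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and r^2; r^2 = 1 when residuals vanish."""
    res = stats.linregress(x, y)
    # linregress reports r = 0 for a constant y; a perfect (zero-residual)
    # horizontal fit should score 1, so recompute from residuals in that case.
    yhat = res.slope * x + res.intercept
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if sst == 0.0 else max(0.0, min(1.0, 1.0 - sse / sst))
    return float(res.slope), float(res.intercept), r2


def initial_rate(
    curve: AbsorbanceTimeCurve, window_end: float = DEFAULT_WINDOW_END_S
) -> InitialRate:
    """Estimate the initial reaction rate as the tangent slope near t = 0.

    Fits an ordinary least-squares line to all points with ``t <= window_end``
    and returns its slope in AU/s. The sign is preserved: a fading signal
    yields a negative rate.
    """
    if window_end <= 0:
        raise DataError("bad-window", "window_end must be positive")
    mask = curve.times <= window_end
    if int(mask.sum()) < 2:
        raise DataError(
            "insufficient-points",
            f"only {int(mask.sum())} point(s) at t <= {window_end} s; need >= 2",
        )
    slope, _, r2 = _ols_slope(curve.times[mask], curve.absorbances[mask])
    return InitialRate(value=slope, window_end=float(window_end),
                       n_points_used=int(mask.sum()), fit_r2=r2)


def pseudo_first_order_k(curve: AbsorbanceTimeCurve) -> float:
    """Pseudo-order rate constant from the slope of log10(A) versus t.

    Returns ``k' = -2.303 * slope`` in 1/s, the classical graphical recipe.
    Points with A <= 0 (typically the t = 0 blank reading) are excluded with
    a warning rather than raising. For a rising colour-formation curve the
    log10 A vs t slope is positive, so k' comes out negative and is returned
    as-is; it is the caller's job to interpret the sign.
    """
    pos = curve.absorbances > 0
    n_pos = int(pos.sum())
    if n_pos < 2:
        raise DataError(
            "insufficient-positive-points",
            f"only {n_pos} positive-absorbance point(s); need >= 2 for a log fit",
        )
    if n_pos < curve.n_points:
        warnings.warn(
            f"{curve.sample_id}: excluded {curve.n_points - n_pos} non-positive "
            "absorbance reading(s) from the log fit",
            stacklevel=2,
        )
    slope, _, _ = _ols_slope(curve.times[pos], np.log10(curve.absorbances[pos]))
    return -2.303 * slope


def absorbance_at_time(curve: AbsorbanceTimeCurve, t_fixed: float) -> float:
    """Absorbance at ``t_fixed``: exact grid value, else linear interpolation.

    No extrapolation: ``t_fixed`` must lie within the observed time range.
    """
    if t_fixed < curve.times[0] or t_fixed > curve.times[-1]:
        raise ComputationError(
            "out-of-range",
            f"t_fixed={t_fixed} s outside observed range "
            f"[{curve.times[0]}, {curve.times[-1]}] s",
        )
    hit = np.nonzero(curve.times == t_fixed)[0]
    if hit.size:
        return float(curve.absorbances[hit[0]])
    return float(np.interp(t_fixed, curve.times, curve.absorbances))


def time_to_absorbance(curve: AbsorbanceTimeCurve, a_fixed: float) -> float:
    """First time at which the piecewise-linear curve reaches ``a_fixed``.

    Returns ``times[0]`` when the curve already starts at or above the
    target. Raises ``target-not-reached`` when the target is never attained.
    """
    a = curve.absorbances
    t = curve.times
    if a[0] >= a_fixed:
        return float(t[0])
    for i in range(len(t) - 1):
        a0, a1 = a[i], a[i + 1]
        if a0 < a_fixed <= a1:
            # linear crossing inside segment [i, i+1]
            return float(t[i] + (a_fixed - a0) * (t[i + 1] - t[i]) / (a1 - a0))
    raise ComputationError(
        "target-not-reached", f"curve never reaches A = {a_fixed} AU"
    )
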