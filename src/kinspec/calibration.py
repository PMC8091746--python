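"""Build, select among, and invert kinetic calibration models.

Each of the four kinetic methods reduces a set of standard curves to a
straight line ``y = m*x + b`` linking a transformed response to (possibly
transformed) concentration:

================  =======================  ============  ============
method            response y               x transform   y transform
================  =======================  ============  ============
initial_rate      log10(initial slope)     log10         log10
rate_constant     pseudo-order k' (1/s)    identity      identity
fixed_absorbance  1/t to reach A_fixed     identity      reciprocal
fixed_time        A at t_fixed (AU)        identity      identity
================  =======================  ============  ============

The initial-rate line doubles as the order diagnostic: in
``log10 v = log10 k' + n log10 C`` the slope is the reaction order n and
the antilog of the intercept is the pseudo-order rate constant k'.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, DataError
from .kinetics import (
    DEFAULT_WINDOW_END_S,
    KineticSeriesSet,
    absorbance_at_time,
    initial_rate,
    pseudo_first_order_k,
    time_to_absorbance,
)

__all__ = [
    "LinearFit",
    "CalibrationModel",
    "RateLaw",
    "ConcentrationEstimate",
    "linear_fit",
    "relative_response_filter",
    "build_fixed_time_calibration",
    "select_fixed_time",
    "best_time_by_r2",
    "build_initial_rate_calibration",
    "build_rate_constant_calibration",
    "build_fixed_absorbance_calibration",
    "invert_concentration",
    "DEFAULT_RATE_CONSTANT_RANGE",
]

#: Concentration sub-range (ug/ml) over which the rate-constant method is
#: classically evaluated; configurable per call.
DEFAULT_RATE_CONSTANT_RANGE = (1.0, 8.0)

#: Relative-response acceptance band: keep a standard when its response per
#: unit concentration lies within 98-102% of the mean relative response.
RELATIVE_RESPONSE_BAND = (0.98, 1.02)

_TRANSFORMS = {"identity", "log10", "reciprocal"}


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line with the transforms that produced it.

    ``residual_sd`` is sqrt(SSE/(n-2)), the calibration sigma used for
    LOD/LOQ; it is ``None`` for two-point fits where it is undefined.
    """

    slope: float
    intercept: float
    r2: float
    residual_sd: float | None
    n_points: int
    x_transform: str = "identity"
    y_transform: str = "identity"

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise DataError("insufficient-points", "a line needs >= 2 points")
        if not (0.0 <= self.r2 <= 1.0):
            raise DataError("bad-r2", f"r2={self.r2} outside [0, 1]")
        if self.residual_sd is not None and self.residual_sd < 0:
            raise DataError("bad-sigma", "residual sd must be >= 0")
        if self.x_transform not in _TRANSFORMS or self.y_transform not in _TRANSFORMS:
            raise DataError("bad-transform", "unknown transform label")

    def predict(self, x: float) -> float:
        """Predict the *transformed* response at transformed x."""
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class RateLaw:
    """Reaction order and pseudo-order rate constant from the log-log fit."""

    order_n: float
    k_prime: float

    @property
    def order_rounded(self) -> int:
        return int(round(self.order_n))

    def __post_init__(self) -> None:
        if self.k_prime <= 0:
            raise DataError("bad-k-prime", "k' must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted calibration line plus the method-specific fixed parameter."""

    method: str  # initial_rate | rate_constant | fixed_absorbance | fixed_time
    fit: LinearFit
    linear_range: tuple[float, float]
    fixed_time: float | None = None
    fixed_absorbance: float | None = None
    suitability_warning: bool = False

    def __post_init__(self) -> None:
        if self.method not in {"initial_rate", "rate_constant", "fixed_absorbance", "fixed_time"}:
            raise DataError("bad-method", f"unknown method {self.method!r}")
        lo, hi = self.linear_range
        if not lo < hi:
            raise DataError("bad-range", "linear_range must satisfy lo < hi")
        if (self.method == "fixed_time") != (self.fixed_time is not None):
            raise DataError("bad-fixed-param", "fixed_time present iff method is fixed_time")
        if (self.method == "fixed_absorbance") != (self.fixed_absorbance is not None):
            raise DataError("bad-fixed-param", "fixed_absorbance present iff method is fixed_absorbance")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "x_transform": self.fit.x_transform,
            "y_transform": self.fit.y_transform,
            "slope": self.fit.slope,
            "intercept": self.fit.intercept,
            "r2": self.fit.r2,
            "residual_sd": self.fit.residual_sd,
            "n_points": self.fit.n_points,
            "linear_range": list(self.linear_range),
            "fixed_time": self.fixed_time,
            "fixed_absorbance": self.fixed_absorbance,
            "suitability_warning": self.suitability_warning,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        fit = LinearFit(
            slope=d["slope"], intercept=d["intercept"], r2=d["r2"],
            residual_sd=d["residual_sd"], n_points=d["n_points"],
            x_transform=d["x_transform"], y_transform=d["y_transform"],
        )
        return cls(
            method=d["method"], fit=fit, linear_range=tuple(d["linear_range"]),
            fixed_time=d.get("fixed_time"), fixed_absorbance=d.get("fixed_absorbance"),
            suitability_warning=bool(d.get("suitability_warning", False)),
        )

    @classmethod
    def from_json(cls, s: str) -> "CalibrationModel":
        return cls.from_dict(json.loads(s))

    # -- prediction ---------------------------------------------------------

    def predict_response(self, concentration: float) -> float:
        """Forward-predict the raw (untransformed) response at a concentration."""
        x = np.log10(concentration) if self.fit.x_transform == "log10" else concentration
        y = self.fit.predict(x)
        if self.fit.y_transform == "log10":
            return float(10.0 ** y)
        if self.fit.y_transform == "reciprocal":
            return float(1.0 / y)
        return float(y)


class ConcentrationEstimate(NamedTuple):
    value: float  # ug/ml
    out_of_linear_range: bool


def linear_fit(
    xs: Sequence[float],
    ys: Sequence[float],
    x_transform: str = "identity",
    y_transform: str = "identity",
) -> LinearFit:
    """Ordinary least-squares line through (xs, ys), already transformed.

    r^2 is the squared Pearson correlation (1 for a zero-residual fit);
    residual sd is sqrt(SSE/(n-2)) and absent for n = 2.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("length-mismatch", "xs and ys must be 1-D and equal length")
    if x.size < 2:
        raise DataError("insufficient-points", "need >= 2 points")
    if np.all(x == x[0]):
        raise DataError("degenerate-x", "all x values identical")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if sst == 0.0 else max(0.0, min(1.0, 1.0 - sse / sst))
    sigma = float(np.sqrt(sse / (x.size - 2))) if x.size >= 3 else None
    return LinearFit(
        slope=float(res.slope), intercept=float(res.intercept), r2=r2,
        residual_sd=sigma, n_points=int(x.size),
        x_transform=x_transform, y_transform=y_transform,
    )


def relative_response_filter(
    concs: Sequence[float], responses: Sequence[float]
) -> np.ndarray:
    """Boolean keep-mask for the classical relative-response screen.

    The relative response of standard i is ``r_i = response_i / conc_i``.
    Point i is kept iff ``r_i / mean(r)`` lies in [0.98, 1.02] (inclusive);
    the mean is computed once over all inputs, not iteratively re-trimmed.
    """
    c = np.asarray(concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.shape != y.shape:
        raise DataError("length-mismatch", "concs and responses must match")
    if np.any(c <= 0):
        raise DataError("nonpositive-concentration", "all concentrations must be > 0")
    r = y / c
    ratio = r / np.mean(r)
    lo, hi = RELATIVE_RESPONSE_BAND
    eps = 1e-12  # keep exact-boundary points despite float rounding
    return (ratio >= lo - eps) & (ratio <= hi + eps)


def _standard_responses(
    series: KineticSeriesSet,
    response_fn,
    apply_filter: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentrations and responses for all standards, optionally screened."""
    standards = series.standards()
    concs = np.array([c.concentration for c in standards], dtype=float)
    resp = np.array([response_fn(c) for c in standards], dtype=float)
    if apply_filter:
        keep = relative_response_filter(concs, resp)
        concs, resp = concs[keep], resp[keep]
    return concs, resp


def build_fixed_time_calibration(
    series: KineticSeriesSet,
    t_fixed: float,
    apply_filter: bool = False,
) -> CalibrationModel:
    """Regress absorbance at ``t_fixed`` on concentration (both identity)."""
    concs, resp = _standard_responses(
        series, lambda c: absorbance_at_time(c, t_fixed), apply_filter
    )
    if np.unique(concs).size < 2:
        raise DataError("insufficient-standards", "need >= 2 distinct standard concentrations")
    fit = linear_fit(concs, resp)
    return CalibrationModel(
        method="fixed_time", fit=fit,
        linear_range=(float(concs.min()), float(concs.max())),
        fixed_time=float(t_fixed),
    )


def best_time_by_r2(r2_by_time: dict[float, float]) -> float:
    """Earliest candidate time achieving the maximal r^2 (ties -> earliest)."""
    if not r2_by_time:
        raise DataError("no-candidates", "empty candidate set")
    best = max(r2_by_time.values())
    return min(t for t, r in r2_by_time.items() if r == best)


def select_fixed_time(
    series: KineticSeriesSet, candidate_times: Sequence[float]
) -> tuple[float, pd.DataFrame]:
    """Fit a fixed-time calibration at each candidate; keep the best r^2.

    Ties are broken by the earliest time (a shorter assay for the same
    linearity). Returns the chosen time and the per-candidate fits table.
    """
    if len(candidate_times) == 0:
        raise DataError("no-candidates", "candidate_times is empty")
    rows = []
    for t in sorted(set(float(t) for t in candidate_times)):
        model = build_fixed_time_calibration(series, t)
        rows.append({
            "time_s": t,
            "slope": model.fit.slope,
            "intercept": model.fit.intercept,
            "r2": model.fit.r2,
        })
    table = pd.DataFrame(rows)
    chosen = best_time_by_r2(dict(zip(table["time_s"], table["r2"])))
    return chosen, table


def build_initial_rate_calibration(
    series: KineticSeriesSet,
    window_end: float = DEFAULT_WINDOW_END_S,
    apply_filter: bool = False,
) -> tuple[CalibrationModel, RateLaw]:
    """Log-log regression of initial rate on concentration.

    Fits ``log10 v = log10 k' + n log10 C`` with C in ug/ml: the slope is
    the reaction order n and ``k' = 10**intercept``. Returns the calibration
    model (log10/log10 transforms) together with the rate law.
    """
    standards = series.standards()
    concs = np.array([c.concentration for c in standards], dtype=float)
    if np.any(concs <= 0):
        raise DataError("nonpositive-concentration", "standards must have C > 0")
    rates = np.array(
        [initial_rate(c, window_end).value for c in standards], dtype=float
    )
    if np.any(rates <= 0):
        raise DataError("nonpositive-rate", "all initial rates must be > 0 for the log-log fit")
    if apply_filter:
        keep = relative_response_filter(concs, rates)
        concs, rates = concs[keep], rates[keep]
    if np.unique(concs).size < 3:
        raise DataError("insufficient-standards", "need >= 3 distinct standard concentrations")
    fit = linear_fit(np.log10(concs), np.log10(rates),
                     x_transform="log10", y_transform="log10")
    model = CalibrationModel(
        method="initial_rate", fit=fit,
        linear_range=(float(concs.min()), float(concs.max())),
    )
    law = RateLaw(order_n=fit.slope, k_prime=float(10.0 ** fit.intercept))
    return model, law


def build_rate_constant_calibration(
    series: KineticSeriesSet,
    sub_range: tuple[float, float] = DEFAULT_RATE_CONSTANT_RANGE,
) -> CalibrationModel:
    """Regress the per-curve pseudo-order rate constant on concentration.

    Restricted to standards inside ``sub_range`` (inclusive). A genuinely
    pseudo-first-order system has k' independent of C, so this calibration
    is expected to be poor; a ``suitability_warning`` is attached whenever
    r^2 < 0.99.
    """
    lo, hi = sub_range
    standards = [
        c for c in series.standards() if lo <= c.concentration <= hi
    ]
    if len(standards) < 2 or np.unique([c.concentration for c in standards]).size < 2:
        raise DataError("insufficient-standards",
                        f"need >= 2 distinct standards inside {sub_range}")
    concs = np.array([c.concentration for c in standards], dtype=float)
    ks = np.array([pseudo_first_order_k(c) for c in standards], dtype=float)
    fit = linear_fit(concs, ks)
    flag = fit.r2 < 0.99
    if flag:
        warnings.warn(
            f"rate-constant calibration r2 = {fit.r2:.4f} < 0.99: "
            "k' is weakly related to concentration; method unsuitable",
            stacklevel=2,
        )
    return CalibrationModel(
        method="rate_constant", fit=fit,
        linear_range=(float(concs.min()), float(concs.max())),
        suitability_warning=flag,
    )


def build_fixed_absorbance_calibration(
    series: KineticSeriesSet, a_fixed: float
) -> CalibrationModel:
    """Regress 1/t (time to reach ``a_fixed``) on concentration.

    Standards whose curves never reach the target absorbance are excluded
    with a warning; at least two usable standards are required.
    """
    concs, recip = [], []
    skipped = []
    for c in series.standards():
        try:
            t = time_to_absorbance(c, a_fixed)
        except ComputationError:
            skipped.append(c.sample_id)
            continue
        if t <= 0:
            skipped.append(c.sample_id)  # reached at t=0: 1/t undefined
            continue
        concs.append(c.concentration)
        recip.append(1.0 / t)
    if skipped:
        warnings.warn(
            f"excluded {len(skipped)} standard(s) not usable at A = {a_fixed}: "
            + ", ".join(skipped),
            stacklevel=2,
        )
    concs = np.asarray(concs, dtype=float)
    if concs.size < 2 or np.unique(concs).size < 2:
        raise DataError("insufficient-standards",
                        f"fewer than 2 usable standards reach A = {a_fixed}")
    fit = linear_fit(concs, np.asarray(recip), y_transform="reciprocal")
    return CalibrationModel(
        method="fixed_absorbance", fit=fit,
        linear_range=(float(concs.min()), float(concs.max())),
        fixed_absorbance=float(a_fixed),
    )


def invert_concentration(
    model: CalibrationModel, response: float
) -> ConcentrationEstimate:
    """Solve the calibration line for concentration given a raw response.

    The response is given in natural units for the method (AU for
    fixed-time, AU/s for initial-rate, seconds for fixed-absorbance, 1/s
    for rate-constant); the model's y-transform is applied before solving
    ``x = (y - b)/m`` and the x-transform is undone afterwards. The result
    carries a flag marking estimates outside the fitted linear range.
    """
    m, b = model.fit.slope, model.fit.intercept
    if m == 0:
        raise ComputationError("non-invertible", "calibration slope is zero")
    yt = model.fit.y_transform
    if yt == "log10":
        if response <= 0:
            raise ComputationError("domain-error", "log10 of non-positive response")
        y = np.log10(response)
    elif yt == "reciprocal":
        if response == 0:
            raise ComputationError("domain-error", "reciprocal of zero response")
        y = 1.0 / response
    else:
        y = response
    x = (y - b) / m
    conc = float(10.0 ** x) if model.fit.x_transform == "log10" else float(x)
    lo, hi = model.linear_range
    return ConcentrationEstimate(value=conc, out_of_linear_range=not (lo <= conc <= hi))
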