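"""Analytical method validation: accuracy, precision, sensitivity, and
comparison against a reference method.

Conventions follow standard pharmaceutical-assay validation practice:

* recovery % = 100 * found / taken; RSD % = 100 * SD / mean (sample SD,
  n-1 denominator),
* LOD = 3.3 sigma / m and LOQ = 10 sigma / m with sigma the residual
  standard deviation of the calibration line and m its slope (ICH Q2),
* molar absorptivity epsilon = m * MW * 1000 / l for a slope in AU per
  ug/ml, molar mass MW in g/mol and path length l in cm,
* method comparison by a pooled-variance two-sample t-test plus a
  variance-ratio F-test (larger variance in the numerator).

All values are stored at full precision; rounding happens only in report
rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .calibration import CalibrationModel, LinearFit, invert_concentration
from .errors import ComputationError, DataError
from .kinetics import KineticSeriesSet, absorbance_at_time, initial_rate, time_to_absorbance

__all__ = [
    "RecoveryRow",
    "SensitivityMetrics",
    "MethodComparison",
    "AssayResult",
    "recovery_stats",
    "lod_loq",
    "molar_absorptivity",
    "t_critical",
    "f_critical",
    "compare_methods",
    "assay_formulation",
    "measure_response",
    "CLINDAMYCIN_HCL_MOLAR_MASS",
]

#: Molar mass of clindamycin hydrochloride, C18H33ClN2O5S . HCl, in g/mol.
CLINDAMYCIN_HCL_MOLAR_MASS = 461.44


@dataclass(frozen=True)
class RecoveryRow:
    """One accuracy/precision table row: taken vs found with spread."""

    taken: float  # ug/ml
    found_mean: float  # ug/ml
    sd: float | None  # ug/ml, sample SD (n-1); None when n == 1
    n_replicates: int

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.found_mean / self.taken

    @property
    def rsd_pct(self) -> float | None:
        if self.sd is None:
            return None
        return 100.0 * self.sd / self.found_mean


@dataclass(frozen=True)
class SensitivityMetrics:
    """Detection/quantification limits and Beer-Lambert sensitivity."""

    lod: float  # ug/ml
    loq: float  # ug/ml
    epsilon: float  # L / (mol cm)
    sigma_used: float  # AU
    slope_used: float  # AU per ug/ml
    molar_mass: float  # g/mol
    path_length: float  # cm


@dataclass(frozen=True)
class MethodComparison:
    """Two-sample t and F comparison of replicate recoveries."""

    t_stat: float
    f_stat: float
    t_crit: float
    f_crit: float
    confidence: float
    df_t: int
    df_f: tuple[int, int]
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float

    @property
    def significant_t(self) -> bool:
        return abs(self.t_stat) > self.t_crit

    @property
    def significant_f(self) -> bool:
        return self.f_stat > self.f_crit


@dataclass(frozen=True)
class AssayResult:
    """Formulation assay summary: mean recovery against the label claim."""

    label_claim: float  # mg per dosage unit
    recovery_pct_mean: float
    sd: float | None  # of the replicate recoveries, in % points
    n: int
    estimated_mg: float  # mean estimated content per dosage unit
    comparison: MethodComparison | None = None


def recovery_stats(
    taken: float,
    found: Sequence[float] | tuple[float, float, int],
    summary: bool = False,
) -> RecoveryRow:
    """Accuracy/precision statistics for one concentration level.

    ``found`` is either a sequence of replicate found concentrations or,
    with ``summary=True``, a ``(mean, sd, n)`` triple as printed in a
    published table.
    """
    if taken <= 0:
        raise DataError("bad-taken", "taken concentration must be > 0")
    if summary:
        mean, sd, n = found
        if n < 2 and sd is not None:
            raise DataError("insufficient-replicates", "sd reported with n < 2")
        return RecoveryRow(taken=float(taken), found_mean=float(mean),
                           sd=None if sd is None else float(sd), n_replicates=int(n))
    values = np.asarray(found, dtype=float)
    if values.size < 2:
        raise DataError("insufficient-replicates", "need >= 2 replicate values")
    return RecoveryRow(
        taken=float(taken),
        found_mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n_replicates=int(values.size),
    )


def lod_loq(fit: LinearFit) -> tuple[float, float]:
    """Detection and quantification limits from a calibration line.

    LOD = 3.3 sigma / m, LOQ = 10 sigma / m, with sigma the residual SD of
    the line (requires n >= 3 points) and m its slope. LOQ/LOD = 10/3.3 by
    construction.
    """
    if fit.residual_sd is None:
        raise DataError("no-residual-sd", "fit has no residual sd (needs >= 3 points)")
    if fit.slope <= 0:
        raise DataError("bad-slope", "LOD/LOQ need a positive slope")
    lod = 3.3 * fit.residual_sd / fit.slope
    loq = 10.0 * fit.residual_sd / fit.slope
    return lod, loq


def molar_absorptivity(
    slope: float,
    molar_mass: float = CLINDAMYCIN_HCL_MOLAR_MASS,
    path: float = 1.0,
) -> float:
    """Beer-Lambert molar absorptivity from a mass-concentration slope.

    A slope of m AU per ug/ml corresponds to epsilon = m * MW * 1000 / l
    in L mol^-1 cm^-1 (1 ug/ml = 1e-3 g/L = 1e-3/MW mol/L).
    """
    if slope <= 0 or molar_mass <= 0 or path <= 0:
        raise DataError("bad-input", "slope, molar mass and path must be > 0")
    return slope * molar_mass * 1e3 / path


def t_critical(confidence: float, df: int) -> float:
    """Two-tailed Student t critical value at the given confidence (%) and df."""
    if not 0 < confidence < 100:
        raise DataError("bad-confidence", "confidence must be in (0, 100)")
    if df < 1:
        raise DataError("bad-df", "df must be >= 1")
    alpha = 1.0 - confidence / 100.0
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def f_critical(confidence: float, df1: int, df2: int) -> float:
    """Upper-tail F critical value at the given confidence (%) and dfs."""
    if not 0 < confidence < 100:
        raise DataError("bad-confidence", "confidence must be in (0, 100)")
    if df1 < 1 or df2 < 1:
        raise DataError("bad-df", "both dfs must be >= 1")
    return float(stats.f.ppf(confidence / 100.0, df1, df2))


def compare_methods(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    confidence: float = 95.0,
) -> MethodComparison:
    """Pooled-variance t-test and variance-ratio F-test on two replicate sets.

    The F statistic always puts the larger sample variance in the numerator
    (so F >= 1) and orders the degrees of freedom accordingly. The t-test
    uses the pooled (equal-variance) form with df = n_a + n_b - 2.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("insufficient-replicates", "each sample needs >= 2 replicates")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    # pooled-variance two-sample t
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t_stat = 0.0 if denom == 0 else float((a.mean() - b.mean()) / denom)
    df_t = na + nb - 2
    # variance-ratio F, larger variance on top
    if va >= vb:
        f_stat = 1.0 if vb == va else float(va / vb) if vb > 0 else float("inf")
        df_f = (na - 1, nb - 1)
    else:
        f_stat = float(vb / va) if va > 0 else float("inf")
        df_f = (nb - 1, na - 1)
    return MethodComparison(
        t_stat=t_stat,
        f_stat=f_stat,
        t_crit=t_critical(confidence, df_t),
        f_crit=f_critical(confidence, *df_f),
        confidence=confidence,
        df_t=df_t,
        df_f=df_f,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
    )


def measure_response(curve, model: CalibrationModel) -> float:
    """Read the raw response appropriate to a model's method off a curve."""
    if model.method == "fixed_time":
        return absorbance_at_time(curve, model.fixed_time)
    if model.method == "initial_rate":
        return initial_rate(curve).value
    if model.method == "fixed_absorbance":
        return time_to_absorbance(curve, model.fixed_absorbance)
    if model.method == "rate_constant":
        from .kinetics import pseudo_first_order_k

        return pseudo_first_order_k(curve)
    raise DataError("bad-method", model.method)


def assay_formulation(
    unknown_curves: KineticSeriesSet,
    model: CalibrationModel,
    label_claim: float,
    dilution_map: dict,
) -> AssayResult:
    """Assay a dosage form against its label claim.

    Each unknown curve is one replicate work-up: its raw response is read
    with the model's method, inverted to a solution concentration (ug/ml),
    and scaled back to mg per dosage unit with the dilution record::

        dilution_map = {
            "dilution_factor":  stock->cuvette dilution (e.g. 100),
            "stock_volume_ml":  volume the powder was dissolved in (e.g. 50),
            "weighed_equiv_mg": label-equivalent mg of drug weighed in (e.g. 50),
        }

    mg in flask = conc * dilution_factor * stock_volume_ml / 1000, and the
    per-unit content scales by label_claim / weighed_equiv_mg. Recovery % is
    100 * estimated / label claim, aggregated over replicates.
    """
    if label_claim <= 0:
        raise DataError("bad-claim", "label claim must be > 0")
    curves = unknown_curves.curves
    if not curves:
        raise DataError("no-samples", "no unknown curves supplied")
    factor = float(dilution_map["dilution_factor"])
    stock_ml = float(dilution_map["stock_volume_ml"])
    weighed = float(dilution_map["weighed_equiv_mg"])
    if factor <= 0 or stock_ml <= 0 or weighed <= 0:
        raise DataError("bad-dilution", "dilution factors must be positive")
    recoveries = []
    estimates_mg = []
    for curve in curves:
        response = measure_response(curve, model)
        est = invert_concentration(model, response)
        if est.out_of_linear_range:
            warnings.warn(
                f"{curve.sample_id}: estimate {est.value:.3g} ug/ml outside the "
                f"linear range {model.linear_range}",
                stacklevel=2,
            )
        mg_in_flask = est.value * factor * stock_ml / 1000.0
        mg_per_unit = mg_in_flask * label_claim / weighed
        estimates_mg.append(mg_per_unit)
        recoveries.append(100.0 * mg_per_unit / label_claim)
    rec = np.asarray(recoveries)
    if rec.size == 1:
        warnings.warn("single replicate: sd not defined", stacklevel=2)
        sd = None
    else:
        sd = float(rec.std(ddof=1))
    return AssayResult(
        label_claim=float(label_claim),
        recovery_pct_mean=float(rec.mean()),
        sd=sd,
        n=int(rec.size),
        estimated_mg=float(np.mean(estimates_mg)),
    )
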