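"""Synthetic absorbance-time data with the structure the analysis assumes.

The reporting chemistry is the acid-driven comproportionation of iodate and
iodide to the yellow triiodide chromophore::

    IO3- + 8 I- + 6 H+ -> 3 I3- + 3 H2O

The analyte's hydrochloride supplies the protons, so with iodide and iodate
in large excess the colour-formation kinetics are pseudo-first-order in the
analyte and the final absorbance is proportional to its concentration. The
generator therefore draws each curve from the single-exponential mean model

    A(t) = baseline + plateau_slope * C * (1 - exp(-k_obs * t)) + e,
    e ~ N(0, noise_sd^2) i.i.d.,

which is the simplest model consistent with first-order behaviour in C and
a rising, plateauing signal. Defaults mirror a typical assay design:
standards at {1, 2, 4, 8, 12, 16, 20} ug/ml read every 300 s from 0 to
2400 s at 350 nm, five replicates, homoscedastic noise of 0.001 AU (the
level implied by published found-concentration SDs of ~0.01 ug/ml at the
bottom of the linear range, and the largest homoscedastic noise compatible
with RSD < 2% at 1 ug/ml).

Randomness contract: one root seed; each curve gets an independent
substream keyed by (seed, concentration index, replicate index), so
subsetting the design never shifts another curve's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import DataError
from .kinetics import AbsorbanceTimeCurve, KineticSeriesSet

__all__ = [
    "ReagentMix",
    "SimulationConfig",
    "triiodide_yield",
    "noise_free_absorbance",
    "generate_kinetic_dataset",
    "generate_capsule_samples",
]

#: Stoichiometric coefficients of IO3- + 8 I- + 6 H+ -> 3 I3- + 3 H2O.
IODATE_COEF, IODIDE_COEF, PROTON_COEF, TRIIODIDE_COEF = 1.0, 8.0, 6.0, 3.0


@dataclass(frozen=True)
class ReagentMix:
    """Amounts (mol) of the three reagents feeding triiodide formation."""

    iodate: float
    iodide: float
    protons: float

    def __post_init__(self) -> None:
        if self.iodate < 0 or self.iodide < 0 or self.protons < 0:
            raise DataError("bad-amount", "reagent amounts must be non-negative")


def triiodide_yield(mix: ReagentMix) -> float:
    """Moles of I3- produced at completion, limiting-reagent arithmetic.

    The reaction extent is min(iodate/1, iodide/8, protons/6) and each unit
    of extent yields 3 mol of triiodide.
    """
    extent = min(
        mix.iodate / IODATE_COEF,
        mix.iodide / IODIDE_COEF,
        mix.protons / PROTON_COEF,
    )
    return TRIIODIDE_COEF * extent


@dataclass(frozen=True)
class SimulationConfig:
    """Design and noise parameters for the kinetic-curve generator.

    ``plateau_slope`` (AU per ug/ml) is the long-time calibration
    sensitivity and ``k_obs`` (1/s) the observed colour-formation rate
    constant; together they set the fixed-time slope at time t to
    ``plateau_slope * (1 - exp(-k_obs * t))``, a progression matching
    published fixed-time calibrations of this chemistry (about 0.088 AU
    per ug/ml at 300 s rising to 0.119 at 2400 s).
    """

    concentrations: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    time_grid: tuple[float, ...] = tuple(float(t) for t in range(0, 2401, 300))
    k_obs: float = 4.5e-3  # 1/s
    plateau_slope: float = 0.119  # AU per ug/ml
    baseline: float = 0.0  # AU
    noise_sd: float = 0.001  # AU
    replicates: int = 5
    excipient_bias: float = 0.0  # fractional signal bias from matrix
    seed: int = 0
    wavelength: float = 350.0  # nm
    temperature: float = 25.0  # degC
    reagents: dict = field(default_factory=lambda: {
        "KI": "3 ml of 0.3 M", "KIO3": "1 ml of 0.2 M",
    })

    def __post_init__(self) -> None:
        if self.k_obs <= 0:
            raise DataError("bad-config", "k_obs must be > 0")
        if self.plateau_slope <= 0:
            raise DataError("bad-config", "plateau_slope must be > 0")
        if self.noise_sd < 0:
            raise DataError("bad-config", "noise_sd must be >= 0")
        if self.replicates < 1:
            raise DataError("bad-config", "replicates must be >= 1")
        if len(self.time_grid) < 2:
            raise DataError("bad-config", "time grid needs >= 2 points")

    def to_dict(self) -> dict:
        return asdict(self)


def noise_free_absorbance(
    config: SimulationConfig, concentration: float, times: np.ndarray | None = None
) -> np.ndarray:
    """Mean model A(t) = baseline + plateau_slope*C*(1 - exp(-k_obs*t))."""
    t = np.asarray(config.time_grid if times is None else times, dtype=float)
    return config.baseline + config.plateau_slope * concentration * (
        1.0 - np.exp(-config.k_obs * t)
    )


def _curve_rng(seed: int, conc_index: int, rep_index: int) -> np.random.Generator:
    # substream per curve: subsetting the design never shifts other draws
    return np.random.default_rng([seed, conc_index, rep_index])


def generate_kinetic_dataset(config: SimulationConfig) -> KineticSeriesSet:
    """Simulate calibration-standard curves for every concentration/replicate.

    Deterministic given ``config.seed``; the full config is recorded in the
    returned set's ``conditions`` for provenance.
    """
    times = np.asarray(config.time_grid, dtype=float)
    curves = []
    for ci, conc in enumerate(config.concentrations):
        mean = noise_free_absorbance(config, conc, times)
        for ri in range(config.replicates):
            rng = _curve_rng(config.seed, ci, ri)
            noise = rng.normal(0.0, config.noise_sd, size=times.size) if config.noise_sd > 0 else 0.0
            curves.append(AbsorbanceTimeCurve(
                sample_id=f"std-c{conc:g}-r{ri}",
                times=times,
                absorbances=mean + noise,
                concentration=float(conc),
                wavelength=config.wavelength,
                replicate_index=ri,
            ))
    return KineticSeriesSet(
        curves=curves,
        temperature=config.temperature,
        conditions={"config": config.to_dict()},
    )


def generate_capsule_samples(
    config: SimulationConfig,
    label_claim: float,
    n_units: int,
    target_conc: float = 10.0,
) -> tuple[KineticSeriesSet, dict]:
    """Simulate a capsule assay work-up and its measurement curves.

    Emulates the classical procedure: powder equivalent to 50 mg of drug is
    dissolved in 50 ml (1000 ug/ml stock) and diluted into the calibration
    range (default 10 ug/ml, a 100-fold dilution). Capsules are assumed to
    contain exactly the label claim; any matrix effect enters as the
    multiplicative ``excipient_bias`` on the measured signal. Returns the
    unknown curves (concentration left blank) plus the dilution record
    ``assay_formulation`` needs.
    """
    if label_claim <= 0:
        raise DataError("bad-claim", "label claim must be > 0")
    if n_units < 1:
        raise DataError("bad-n-units", "need at least one dosage unit")
    weighed_equiv_mg = 50.0
    stock_volume_ml = 50.0
    stock_conc = weighed_equiv_mg * 1000.0 / stock_volume_ml  # ug/ml
    dilution_factor = stock_conc / target_conc
    lo = min(config.concentrations)
    hi = max(config.concentrations)
    dilution_map = {
        "dilution_factor": dilution_factor,
        "stock_volume_ml": stock_volume_ml,
        "weighed_equiv_mg": weighed_equiv_mg,
        "target_conc_ug_ml": target_conc,
        "in_linear_range": bool(lo <= target_conc <= hi),
    }
    times = np.asarray(config.time_grid, dtype=float)
    curves = []
    for ui in range(n_units):
        mean = noise_free_absorbance(config, target_conc, times) * (1.0 + config.excipient_bias)
        rng = _curve_rng(config.seed, 10_000 + ui, 0)
        noise = rng.normal(0.0, config.noise_sd, size=times.size) if config.noise_sd > 0 else 0.0
        curves.append(AbsorbanceTimeCurve(
            sample_id=f"capsule-u{ui}",
            times=times,
            absorbances=mean + noise,
            concentration=None,
            wavelength=config.wavelength,
            replicate_index=ui,
        ))
    series = KineticSeriesSet(
        curves=curves,
        temperature=config.temperature,
        conditions={"config": config.to_dict(), "label_claim_mg": label_claim},
    )
    return series, dilution_map
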