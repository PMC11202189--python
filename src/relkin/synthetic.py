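"""Synthetic release experiments with the full measurement chain.

The generator emulates everything the analysis pipeline assumes about a real
long-horizon release run: a true compressed-exponential kinetics, dilution of
the released mass into a fixed bath volume, selection of the reading
instrument by the bath concentration (fluorimeter below 0.06 mg dm**-3,
spectrophotometer up to 14 mg dm**-3, decade dilution above), generation of
the raw optical signal through forward calibration curves (linear for the
fluorimeter, saturating parabola for the spectrophotometer), and additive
Gaussian replicate noise on the signal scale.

Two named presets mirror the study conditions: ``low`` (initial load
0.03763 g dm**-3; true triple m_inf = 3.0 ug, tau0 = 808 h, sigma = 1.37)
and ``high`` (37.63 g dm**-3; 147 ug, 385 h, sigma = 9). Sampling follows an
irregular long-horizon schedule — dense in the first days, then daily —
extending past 12 weeks (2200 h horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibration import (
    INSTRUMENT_RANGES,
    SPECTRO_CEILING,
    CalibrationStandard,
    DilutionRequiredError,
    Instrument,
    select_instrument,
)
from .fitting import ReleaseSeries
from .model import KineticParams, SystemGeometry, mass_released

__all__ = [
    "ExperimentConfig",
    "DEFAULT_CALIBRATION_TRUTH",
    "DEFAULT_NOISE_SD",
    "default_schedule",
    "preset",
    "generate_experiment",
    "generate_calibration_standards",
    "write_measurements",
    "write_standards",
    "write_truth",
    "read_truth",
]

#: forward calibration truths per instrument (ascending polynomial
#: coefficients, signal as a function of concentration in mg dm^-3).
#: The fluorimeter responds linearly; the spectrophotometer saturates
#: (negative curvature) but stays monotone below its 14 mg dm^-3 ceiling.
DEFAULT_CALIBRATION_TRUTH: dict[Instrument, tuple[float, ...]] = {
    Instrument.FLUORIMETER: (2.0, 8000.0),
    Instrument.SPECTROPHOTOMETER: (0.01, 0.155, -0.0025),
}

#: per-read replicate noise, additive Gaussian sd on the signal scale. The
#: fluorimeter value (intensity counts) reproduces trace-level detection
#: limits of a few tenths of a ug dm^-3 through 3.3*sd/slope; the
#: spectrophotometer value is photometric read noise (~1 mA). Calibration
#: standards prepared by dilution carry a larger scatter (~0.01 A, including
#: preparation error); pass that explicitly when emulating a standards
#: series.
DEFAULT_NOISE_SD: dict[Instrument, float] = {
    Instrument.FLUORIMETER: 0.56,
    Instrument.SPECTROPHOTOMETER: 0.001,
}

_HORIZON_H = 2200.0  # > 12 weeks


def default_schedule(horizon: float = _HORIZON_H) -> np.ndarray:
    """Irregular long-horizon sampling times (hours), t = 0 included.

    Every 2 h for the first half-day, every 12 h over the first week, then
    every 24 h out to the horizon — about 100 points over 2200 h.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    times = np.concatenate(
        [
            np.arange(0.0, min(12.0, horizon), 2.0),
            np.arange(12.0, min(168.0, horizon), 12.0),
            np.arange(168.0, horizon + 0.5, 24.0),
        ]
    )
    return np.unique(times[times <= horizon])


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to simulate one release run deterministically."""

    true_params: KineticParams
    geometry: SystemGeometry = field(default_factory=SystemGeometry)
    schedule: np.ndarray = field(default_factory=default_schedule)
    noise_signal_sd: dict[Instrument, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )
    calibration_truth: dict[Instrument, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION_TRUTH)
    )
    proportional_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        sched = np.asarray(self.schedule, dtype=float)
        if sched.size == 0:
            raise ValueError("schedule must be nonempty")
        if sched[0] < 0 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing from t >= 0")
        if any(sd < 0 for sd in self.noise_signal_sd.values()):
            raise ValueError("noise sds must be >= 0")
        object.__setattr__(self, "schedule", sched)


_PRESETS = {
    "low": dict(true_params=KineticParams(3.0, 808.0, 1.37), c0=0.03763, seed=20240605),
    "high": dict(true_params=KineticParams(147.0, 385.0, 9.0), c0=37.63, seed=20240606),
}


def preset(name: str, **overrides) -> ExperimentConfig:
    """Named study scenario: ``low`` or ``high`` initial-load preset.

    Keyword overrides are applied on top of the preset (e.g. ``seed=...``,
    ``schedule=...``, ``noise_signal_sd={...}``).
    """
    try:
        spec = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    geometry = overrides.pop("geometry", SystemGeometry(c0=spec["c0"]))
    cfg = ExperimentConfig(
        true_params=spec["true_params"], geometry=geometry, seed=spec["seed"]
    )
    return replace(cfg, **overrides) if overrides else cfg


def _forward_signal(coeffs: tuple[float, ...], conc: float) -> float:
    return float(np.polynomial.polynomial.polyval(conc, coeffs))


def _decade_dilution(conc: float, ceiling: float = SPECTRO_CEILING) -> float:
    """Smallest power-of-ten dilution bringing `conc` under the ceiling."""
    factor = 1.0
    while conc / factor > ceiling:
        factor *= 10.0
    return factor


def generate_experiment(cfg: ExperimentConfig) -> tuple[pd.DataFrame, ReleaseSeries]:
    """Simulate one run: (raw measurement table, noise-free truth series).

    The table has columns ``time_h, instrument, signal, dilution_factor``;
    the truth series carries the exact released masses for recovery tests.
    Output is deterministic for a given config (seeded RNG).
    """
    rng = np.random.default_rng(cfg.seed)
    V = cfg.geometry.bath_volume
    rows = []
    true_masses = []
    for t in cfg.schedule:
        mass = float(mass_released(t, cfg.true_params))  # ug
        true_masses.append(mass)
        conc = mass / V / 1000.0  # ug/dm3 -> mg/dm3
        try:
            instrument = select_instrument(conc)
            dilution = 1.0
        except DilutionRequiredError:
            instrument = Instrument.SPECTROPHOTOMETER
            dilution = _decade_dilution(conc)
        read_conc = conc / dilution
        clean = _forward_signal(cfg.calibration_truth[instrument], read_conc)
        sd = cfg.noise_signal_sd.get(instrument, 0.0)
        if cfg.proportional_noise:
            sd = sd * max(abs(clean), 1e-12)
        signal = clean + rng.normal(0.0, sd) if sd > 0 else clean
        rows.append(
            {
                "time_h": t,
                "instrument": instrument.value,
                "signal": signal,
                "dilution_factor": dilution,
            }
        )
    table = pd.DataFrame(rows, columns=["time_h", "instrument", "signal", "dilution_factor"])
    truth = ReleaseSeries(cfg.schedule, np.array(true_masses))
    return table, truth


def generate_calibration_standards(
    truth_coefficients: tuple[float, ...],
    levels,
    *,
    instrument: Instrument,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[CalibrationStandard]:
    """Seeded standards: forward truth curve + Gaussian replicate noise.

    Requires at least 3 levels, all inside the instrument's working range;
    replicates default to 3 (triplicate reading of each standard).
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size < 3:
        raise ValueError(f"need >= 3 calibration levels, got {levels.size}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    instrument = Instrument(instrument)
    lo, hi = INSTRUMENT_RANGES[instrument.value]
    if np.any(levels < lo) or np.any(levels > hi):
        raise ValueError(
            f"levels outside the {instrument.value} range [{lo:g}, {hi:g}] mg/dm3"
        )
    rng = np.random.default_rng(seed)
    standards = []
    for level in levels:
        clean = _forward_signal(truth_coefficients, float(level))
        noise = rng.normal(0.0, noise_sd, size=replicates) if noise_sd > 0 else np.zeros(replicates)
        standards.append(
            CalibrationStandard(
                instrument=instrument,
                concentration=float(level),
                replicate_signals=tuple(clean + noise),
            )
        )
    return standards


# standard levels span each instrument's full working range (blank included
# for the fluorimeter) so that every bath concentration a run produces can be
# inverted without leaving the calibrated range
_DEFAULT_LEVELS = {
    Instrument.FLUORIMETER: np.linspace(0.0, 0.06, 8),
    Instrument.SPECTROPHOTOMETER: np.linspace(0.06, 14.0, 10),
}


def default_standards(cfg: ExperimentConfig) -> list[CalibrationStandard]:
    """Standards for both instruments under the config's calibration truth."""
    out: list[CalibrationStandard] = []
    for inst, levels in _DEFAULT_LEVELS.items():
        out.extend(
            generate_calibration_standards(
                cfg.calibration_truth[inst],
                levels,
                instrument=inst,
                replicates=3,
                noise_sd=cfg.noise_signal_sd.get(inst, 0.0),
                seed=cfg.seed + (1 if inst is Instrument.FLUORIMETER else 2),
            )
        )
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O shared with the pipeline

def write_measurements(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_standards(standards: list[CalibrationStandard], path) -> None:
    rows = [
        {
            "instrument": s.instrument.value,
            "concentration_mg_per_dm3": s.concentration,
            "signal": sig,
        }
        for s in standards
        for sig in s.replicate_signals
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_truth(truth: ReleaseSeries, path) -> None:
    pd.DataFrame({"time_h": truth.times, "mass_ug": truth.masses}).to_csv(path, index=False)


def read_truth(path) -> ReleaseSeries:
    df = pd.read_csv(path)
    return ReleaseSeries(df["time_h"].to_numpy(), df["mass_ug"].to_numpy())
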