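"""Signal-to-concentration calibration for the two-instrument measurement chain.

Bath concentrations span five orders of magnitude over a release run, so two
instruments share the working range: a fluorimeter for trace levels
(c <= 0.06 mg dm**-3, linear response) and a UV-Vis spectrophotometer for
higher levels (0.06 < c <= 14 mg dm**-3), whose response saturates and is
described by a parabola. Above 14 mg dm**-3 samples must be diluted before
reading.

Calibration curves are fitted on replicate means (each standard is typically
read in triplicate). Detection limits follow the ICH Q2 residual-scatter
formulas LOD = 3.3*sd/S and LOQ = 10*sd/S, where sd is the residual standard
deviation of the regression and S its slope.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Instrument",
    "CalibrationStandard",
    "CalibrationModel",
    "CalibrationError",
    "CalibrationRangeError",
    "DilutionRequiredError",
    "fit_linear",
    "fit_quadratic",
    "predict",
    "invert",
    "lod_loq",
    "select_instrument",
    "calibration_report",
]

#: fluorimeter/spectrophotometer hand-over concentration, mg dm^-3
INSTRUMENT_THRESHOLD = 0.06
#: spectrophotometer ceiling, mg dm^-3; above this, dilute before reading
SPECTRO_CEILING = 14.0
#: nominal working range per instrument, mg dm^-3
INSTRUMENT_RANGES = {
    "fluorimeter": (0.0, INSTRUMENT_THRESHOLD),
    "spectrophotometer": (INSTRUMENT_THRESHOLD, SPECTRO_CEILING),
}


class Instrument(str, enum.Enum):
    FLUORIMETER = "fluorimeter"
    SPECTROPHOTOMETER = "spectrophotometer"


class CalibrationError(ValueError):
    """A calibration design or fit that cannot be used for inversion."""


class CalibrationRangeError(CalibrationError):
    """Signal outside the image of the calibrated range.

    Carries ``suggested_instrument`` so the pipeline can hint which
    instrument the sample should have been read on.
    """

    def __init__(self, message: str, suggested_instrument: Instrument | None = None):
        super().__init__(message)
        self.suggested_instrument = suggested_instrument


class DilutionRequiredError(CalibrationError):
    """Concentration above the spectrophotometer ceiling; dilute and re-read."""

    def __init__(self, concentration: float, ceiling: float = SPECTRO_CEILING):
        super().__init__(
            f"concentration {concentration:g} mg/dm3 exceeds the "
            f"spectrophotometer ceiling {ceiling:g} mg/dm3; dilute before reading"
        )
        self.concentration = concentration
        self.ceiling = ceiling


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration level: a nominal concentration and its replicate signals."""

    instrument: Instrument
    concentration: float  # mg dm^-3
    replicate_signals: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        sig = tuple(float(s) for s in self.replicate_signals)
        if len(sig) < 1:
            raise ValueError("at least one replicate signal is required")
        object.__setattr__(self, "instrument", Instrument(self.instrument))
        object.__setattr__(self, "replicate_signals", sig)

    @property
    def mean_signal(self) -> float:
        return float(np.mean(self.replicate_signals))


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted signal <-> concentration mapping for one instrument.

    ``coefficients`` are in ascending order: (a0, a1) for a line
    signal = a0 + a1*c, or (b0, b1, b2) for a parabola
    signal = b0 + b1*c + b2*c**2. ``valid_range`` is the concentration span
    of the standards, mg dm**-3; ``lod``/``loq`` are in ug dm**-3.
    """

    instrument: Instrument
    kind: str  # "linear" | "quadratic"
    coefficients: tuple[float, ...]
    residual_sd: float
    r_squared: float
    rmse: float
    valid_range: tuple[float, float]
    lod: float
    loq: float
    inversion_tolerance_sd: float = field(default=2.0)

    @property
    def slope_at_origin(self) -> float:
        return self.coefficients[1]


def _levels(standards: list[CalibrationStandard]):
    if not standards:
        raise CalibrationError("no calibration standards supplied")
    conc = np.array([s.concentration for s in standards], dtype=float)
    means = np.array([s.mean_signal for s in standards], dtype=float)
    order = np.argsort(conc)
    conc, means = conc[order], means[order]
    if np.unique(conc).size != conc.size:
        # merge replicated rows of the same nominal level
        uniq = np.unique(conc)
        means = np.array([means[conc == c].mean() for c in uniq])
        conc = uniq
    instruments = {s.instrument for s in standards}
    if len(instruments) != 1:
        raise CalibrationError("standards mix instruments; fit one instrument at a time")
    return instruments.pop(), conc, means


def _gof(y: np.ndarray, fitted: np.ndarray, n_coef: int):
    resid = y - fitted
    ssr = float(resid @ resid)
    sstot = float(((y - y.mean()) ** 2).sum())
    dof = y.size - n_coef
    residual_sd = float(np.sqrt(ssr / dof)) if dof > 0 else float("nan")
    r2 = 1.0 - ssr / sstot if sstot > 0 else float("nan")
    return residual_sd, r2


def _replicate_rmse(standards: list[CalibrationStandard], coefficients) -> float:
    """RMSE against every individual replicate signal (not the means).

    This is the scatter a single bath reading carries, the scale detection
    limits and error bars are quoted on.
    """
    resid = [
        sig - float(np.polynomial.polynomial.polyval(s.concentration, coefficients))
        for s in standards
        for sig in s.replicate_signals
    ]
    return float(np.sqrt(np.mean(np.square(resid))))


def fit_linear(standards: list[CalibrationStandard]) -> CalibrationModel:
    """Ordinary least squares line through the replicate means.

    Requires >= 3 distinct concentration levels (so the residual standard
    deviation has dof = n - 2). Non-monotone mean signals raise a warning —
    with a genuinely linear response they indicate noisy or disordered
    standards — but do not abort the fit.
    """
    instrument, conc, means = _levels(standards)
    if conc.size < 3:
        raise CalibrationError(
            f"linear calibration needs >= 3 distinct levels, got {conc.size}"
        )
    if np.any(np.diff(means) <= 0):
        warnings.warn("mean calibration signals are not strictly increasing", stacklevel=2)
    a1, a0 = np.polyfit(conc, means, 1)
    fitted = a0 + a1 * conc
    residual_sd, r2 = _gof(means, fitted, 2)
    rmse = _replicate_rmse(standards, (a0, a1))
    lod, loq = lod_loq(residual_sd, a1)
    return CalibrationModel(
        instrument=instrument,
        kind="linear",
        coefficients=(float(a0), float(a1)),
        residual_sd=residual_sd,
        r_squared=r2,
        rmse=rmse,
        valid_range=(float(conc.min()), float(conc.max())),
        lod=lod,
        loq=loq,
    )


def fit_quadratic(standards: list[CalibrationStandard]) -> CalibrationModel:
    """Least-squares parabola through the replicate means.

    Requires >= 4 distinct levels. Saturation curvature (b2 < 0) is expected;
    the fit is rejected if the parabola is not strictly increasing over the
    calibrated range, because inversion would then be ambiguous.
    """
    instrument, conc, means = _levels(standards)
    if conc.size < 4:
        raise CalibrationError(
            f"quadratic calibration needs >= 4 distinct levels, got {conc.size}"
        )
    b2, b1, b0 = np.polyfit(conc, means, 2)
    # derivative b1 + 2*b2*c is linear in c: checking the endpoints suffices
    lo, hi = float(conc.min()), float(conc.max())
    if b1 + 2 * b2 * lo <= 0 or b1 + 2 * b2 * hi <= 0:
        raise CalibrationError(
            "fitted parabola is not monotone increasing over the calibrated "
            f"range [{lo:g}, {hi:g}] mg/dm3; calibration rejected"
        )
    fitted = b0 + b1 * conc + b2 * conc**2
    residual_sd, r2 = _gof(means, fitted, 3)
    rmse = _replicate_rmse(standards, (b0, b1, b2))
    lod, loq = lod_loq(residual_sd, b1)
    return CalibrationModel(
        instrument=instrument,
        kind="quadratic",
        coefficients=(float(b0), float(b1), float(b2)),
        residual_sd=residual_sd,
        r_squared=r2,
        rmse=rmse,
        valid_range=(lo, hi),
        lod=lod,
        loq=loq,
    )


def predict(model: CalibrationModel, concentration):
    """Forward curve: expected signal at `concentration` (mg dm**-3)."""
    c = np.asarray(concentration, dtype=float)
    out = np.polynomial.polynomial.polyval(c, model.coefficients)
    return out if out.ndim else float(out)


def _other_instrument(instrument: Instrument) -> Instrument:
    return (
        Instrument.SPECTROPHOTOMETER
        if instrument is Instrument.FLUORIMETER
        else Instrument.FLUORIMETER
    )


def invert(model: CalibrationModel, signal: float) -> float:
    """Inverse prediction: the concentration (mg dm**-3) producing `signal`.

    Signals slightly outside the image of the calibrated range — within
    ``inversion_tolerance_sd * residual_sd`` — are clamped to the nearest
    range endpoint with a warning, tolerating noise at the edges. Signals
    beyond that band raise :class:`CalibrationRangeError` naming the
    instrument the sample should be switched to.

    For the quadratic curve the root on the increasing branch inside the
    valid range is returned; it is unique by the monotonicity invariant.
    """
    signal = float(signal)
    lo, hi = model.valid_range
    s_lo, s_hi = predict(model, lo), predict(model, hi)
    # absorb float rounding at the exact range-image edges before banding
    eps = 1e-9 * max(1.0, abs(s_lo), abs(s_hi))
    if s_lo - eps <= signal < s_lo:
        signal = s_lo
    elif s_hi < signal <= s_hi + eps:
        signal = s_hi
    band = model.inversion_tolerance_sd * (model.residual_sd if np.isfinite(model.residual_sd) else 0.0)
    if signal < s_lo - band:
        raise CalibrationRangeError(
            f"signal {signal:g} below the calibrated image [{s_lo:g}, {s_hi:g}] "
            f"of the {model.instrument.value}; consider the "
            f"{_other_instrument(model.instrument).value}",
            suggested_instrument=_other_instrument(model.instrument),
        )
    if signal > s_hi + band:
        raise CalibrationRangeError(
            f"signal {signal:g} above the calibrated image [{s_lo:g}, {s_hi:g}] "
            f"of the {model.instrument.value}; consider the "
            f"{_other_instrument(model.instrument).value}",
            suggested_instrument=_other_instrument(model.instrument),
        )
    if signal < s_lo or signal > s_hi:
        warnings.warn(
            f"signal {signal:g} marginally outside the calibrated image; "
            "clamped to the nearest range endpoint",
            stacklevel=2,
        )
        return lo if signal < s_lo else hi

    if model.kind == "linear":
        a0, a1 = model.coefficients
        return (signal - a0) / a1
    b0, b1, b2 = model.coefficients
    if b2 == 0.0:
        return (signal - b0) / b1
    # numerically stable quadratic roots of b2*c^2 + b1*c + (b0 - signal) = 0
    disc = b1 * b1 - 4.0 * b2 * (b0 - signal)
    if disc < 0:
        raise CalibrationRangeError(
            f"signal {signal:g} beyond the saturation maximum of the parabola"
        )
    q = -0.5 * (b1 + np.copysign(np.sqrt(disc), b1))
    roots = [q / b2, (b0 - signal) / q if q != 0 else np.inf]
    tol = 1e-9 * max(1.0, hi)
    candidates = [
        c for c in roots
        if lo - tol <= c <= hi + tol and b1 + 2 * b2 * c > 0
    ]
    if not candidates:
        raise CalibrationRangeError(
            f"no root of the calibration parabola lies on the increasing "
            f"branch within [{lo:g}, {hi:g}] for signal {signal:g}"
        )
    return float(np.clip(candidates[0], lo, hi)) if len(candidates) == 1 else float(candidates[0])


def lod_loq(residual_sd: float, slope: float) -> tuple[float, float]:
    """ICH Q2 detection limits from regression scatter: (LOD, LOQ) in ug dm**-3.

    LOD = 3.3*sd/S and LOQ = 10*sd/S with sd in signal units and S in signal
    per mg dm**-3; the mg -> ug conversion (x1000) is applied so that the
    returned limits are on the trace scale they are conventionally quoted on.
    The ratio LOQ/LOD is identically 10/3.3.
    """
    if slope <= 0:
        raise ValueError("calibration slope must be > 0")
    if residual_sd < 0:
        raise ValueError("residual sd must be >= 0")
    lod = 3.3 * residual_sd / slope * 1000.0
    loq = 10.0 * residual_sd / slope * 1000.0
    return lod, loq


def select_instrument(concentration: float) -> Instrument:
    """Which instrument reads a bath sample of `concentration` (mg dm**-3).

    Fluorimeter for c <= 0.06, spectrophotometer for 0.06 < c <= 14; above
    14 the sample must be diluted first (:class:`DilutionRequiredError`).
    """
    c = float(concentration)
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if c <= INSTRUMENT_THRESHOLD:
        return Instrument.FLUORIMETER
    if c <= SPECTRO_CEILING:
        return Instrument.SPECTROPHOTOMETER
    raise DilutionRequiredError(c)


def calibration_report(model: CalibrationModel) -> str:
    """Human-readable summary of a fitted calibration."""
    names = ("a0", "a1") if model.kind == "linear" else ("b0", "b1", "b2")
    coef = ", ".join(f"{n}={v:.6g}" for n, v in zip(names, model.coefficients))
    lines = [
        f"instrument:   {model.instrument.value}",
        f"curve:        {model.kind} ({coef})",
        f"range:        {model.valid_range[0]:g} - {model.valid_range[1]:g} mg/dm3",
        f"residual sd:  {model.residual_sd:.4g} (signal units)",
        f"R^2:          {model.r_squared:.6f}",
        f"RMSE:         {model.rmse:.4g} (signal units)",
        f"LOD:          {model.lod:.4g} ug/dm3",
        f"LOQ:          {model.loq:.4g} ug/dm3",
    ]
    return "\n".join(lines)
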