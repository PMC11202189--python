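"""End-to-end orchestration: calibrate, convert, fit, derive, report.

A run starts from two delimited text files — calibration standards
(``instrument,concentration_mg_per_dm3,signal``, one row per replicate) and a
kinetic series (``time_h,instrument,signal,dilution_factor``) — plus a config
carrying the geometry, bath constants and fitting options. The pipeline fits
one calibration per instrument, inverts every raw signal to a bath
concentration, converts to released mass, fits the compressed-exponential
model by Levenberg-Marquardt and derives the release descriptors: half-release
time t_0.5 = tau0*ln(2)**(1/sigma), the lifetime power-law coefficient B, the
membrane-to-bath volume ratio phi, the loaded mass and the release yield.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    CalibrationModel,
    CalibrationRangeError,
    Instrument,
    calibration_report,
    fit_linear,
    fit_quadratic,
    invert,
)
from .fitting import (
    FitResult,
    ReleaseSeries,
    fit_release,
    fit_report,
    initial_guess,
)
from .model import (
    KineticParams,
    SystemGeometry,
    b_coefficient,
    half_release_time,
    loaded_mass,
    plateau_time,
    release_yield,
)

__all__ = [
    "RunConfig",
    "RunReport",
    "PipelineError",
    "fit_calibrations",
    "signals_to_series",
    "run_analysis",
    "compare_runs",
    "load_report",
]

_TIME_UNIT_HOURS = {"h": 1.0, "hours": 1.0, "d": 24.0, "days": 24.0}


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one analysis run (YAML-serializable)."""

    calibration_path: str
    kinetics_path: str
    geometry: SystemGeometry = field(default_factory=SystemGeometry)
    time_unit: str = "h"
    sigma_fixed: float | None = None
    max_iter: int = 200
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_unit not in _TIME_UNIT_HOURS:
            raise ValueError(
                f"time_unit must be one of {sorted(_TIME_UNIT_HOURS)}, got {self.time_unit!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        geo = raw.pop("geometry", {})
        return cls(geometry=SystemGeometry(**geo), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        return d


@dataclass
class RunReport:
    """Everything one run produced, ready for serialization."""

    calibrations: dict[str, CalibrationModel]
    fit: FitResult
    derived: dict[str, float]
    provenance: dict[str, str]
    sub_lod_times: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "calibrations": {
                inst: {
                    "kind": m.kind,
                    "coefficients": list(m.coefficients),
                    "residual_sd": m.residual_sd,
                    "r_squared": m.r_squared,
                    "rmse": m.rmse,
                    "valid_range": list(m.valid_range),
                    "lod_ug_per_dm3": m.lod,
                    "loq_ug_per_dm3": m.loq,
                }
                for inst, m in self.calibrations.items()
            },
            "fit": {
                "m_inf_ug": self.fit.params.m_inf,
                "tau0_h": self.fit.params.tau0,
                "sigma": self.fit.params.sigma,
                "stderr": list(self.fit.stderr),
                "covariance": self.fit.covariance.tolist(),
                "r_squared": self.fit.r_squared,
                "rmse_ug": self.fit.rmse,
                "rmse_normalized": self.fit.rmse_normalized,
                "n_iter": self.fit.n_iter,
                "converged": self.fit.converged,
            },
            "derived": dict(self.derived),
            "sub_lod_times_h": list(self.sub_lod_times),
            "provenance": dict(self.provenance),
        }


def fit_calibrations(standards_path) -> dict[Instrument, CalibrationModel]:
    """Fit one calibration per instrument found in the standards file.

    The fluorimeter gets a line, the spectrophotometer a parabola.
    """
    df = pd.read_csv(standards_path)
    required = {"instrument", "concentration_mg_per_dm3", "signal"}
    if not required.issubset(df.columns):
        raise PipelineError(
            "calibrate", f"standards file must have columns {sorted(required)}"
        )
    from .calibration import CalibrationStandard

    models: dict[Instrument, CalibrationModel] = {}
    for inst_name, group in df.groupby("instrument"):
        inst = Instrument(inst_name)
        standards = [
            CalibrationStandard(
                instrument=inst,
                concentration=float(conc),
                replicate_signals=tuple(sub["signal"]),
            )
            for conc, sub in group.groupby("concentration_mg_per_dm3")
        ]
        fitter = fit_linear if inst is Instrument.FLUORIMETER else fit_quadratic
        models[inst] = fitter(standards)
    return models


def signals_to_series(
    measurements: pd.DataFrame,
    calibrations: dict[Instrument, CalibrationModel],
    bath_volume: float,
) -> tuple[ReleaseSeries, tuple[float, ...]]:
    """Convert raw signals to a released-mass series.

    Per row: concentration = invert(model, signal) * dilution_factor
    (mg dm**-3), mass = concentration * bath_volume * 1000 (micrograms).
    Returns the series (sorted by time, with per-point provenance) and the
    times whose concentration fell below the instrument's LOD; sub-LOD
    points are flagged but retained at their point estimate, since early
    points below the detection limit still carry the lag information.
    """
    if bath_volume <= 0:
        raise ValueError("bath_volume must be > 0")
    df = measurements.copy()
    if "dilution_factor" not in df.columns:
        df["dilution_factor"] = 1.0
    if df["time_h"].duplicated().any():
        dupes = sorted(df.loc[df["time_h"].duplicated(), "time_h"].unique())
        raise ValueError(f"duplicate measurement times: {dupes}")
    if (df["dilution_factor"] < 1).any():
        raise ValueError("dilution factors must be >= 1")
    df = df.sort_values("time_h", kind="stable").reset_index(drop=True)
    masses = np.empty(len(df))
    sub_lod: list[float] = []
    provenance = []
    for i, row in df.iterrows():
        inst = Instrument(row["instrument"])
        model = calibrations.get(inst)
        if model is None:
            raise ValueError(f"no calibration fitted for instrument {inst.value!r}")
        try:
            conc = invert(model, row["signal"]) * row["dilution_factor"]
        except CalibrationRangeError as exc:
            hint = (
                f"; switch to the {exc.suggested_instrument.value}"
                if exc.suggested_instrument
                else ""
            )
            raise ValueError(
                f"row at t={row['time_h']:g} h ({inst.value}): {exc}{hint}"
            ) from exc
        if conc * 1000.0 < model.lod:  # conc mg/dm3 -> ug/dm3 against LOD
            sub_lod.append(float(row["time_h"]))
        masses[i] = conc * bath_volume * 1000.0  # mg -> ug
        provenance.append((inst.value, float(row["signal"]), float(conc)))
    series = ReleaseSeries(df["time_h"].to_numpy(), masses, tuple(provenance))
    return series, tuple(sub_lod)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_analysis(cfg: RunConfig) -> RunReport:
    """Full pipeline: calibrate -> convert -> fit -> derive -> report.

    Writes ``report.json`` and ``report.txt`` into ``cfg.output_dir`` when it
    is set. Errors carry the stage they occurred in; a non-converged fit
    still produces a report (flagged), letting the caller decide.
    """
    t_start = time.time()
    try:
        calibrations = fit_calibrations(cfg.calibration_path)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("calibrate", str(exc)) from exc

    try:
        measurements = pd.read_csv(cfg.kinetics_path)
        factor = _TIME_UNIT_HOURS[cfg.time_unit]
        if factor != 1.0:
            measurements = measurements.assign(time_h=measurements["time_h"] * factor)
        series, sub_lod = signals_to_series(
            measurements, calibrations, cfg.geometry.bath_volume
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("convert", str(exc)) from exc

    try:
        init = initial_guess(series)
        fit = fit_release(
            series, init, sigma_fixed=cfg.sigma_fixed, max_iter=cfg.max_iter
        )
    except Exception as exc:
        raise PipelineError("fit", str(exc)) from exc

    p = fit.params
    g = cfg.geometry
    derived = {
        "t_half_h": half_release_time(p),
        "b_coefficient_h_sigma": b_coefficient(p),
        "phi": g.phi,
        "loaded_mass_ug": loaded_mass(g),
        "yield_percent": release_yield(p, g),
        "plateau_time_h": plateau_time(p),
    }
    provenance = {
        "config_hash": _config_hash(cfg),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "software_version": __version__,
        "elapsed_s": f"{time.time() - t_start:.3f}",
        "n_points": str(len(series)),
    }
    report = RunReport(
        calibrations={i.value: m for i, m in calibrations.items()},
        fit=fit,
        derived=derived,
        provenance=provenance,
        sub_lod_times=sub_lod,
    )
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        (out / "report.txt").write_text(render_report(report))
    return report


def render_report(report: RunReport) -> str:
    parts = []
    for inst, model in report.calibrations.items():
        parts.append(f"--- calibration: {inst} ---")
        parts.append(calibration_report(model))
    parts.append("--- kinetic fit ---")
    parts.append(fit_report(report.fit))
    parts.append("--- derived quantities ---")
    labels = {
        "t_half_h": "half-release time t_0.5 [h]",
        "b_coefficient_h_sigma": "lifetime coefficient B [h^sigma]",
        "phi": "membrane/bath volume ratio phi [-]",
        "loaded_mass_ug": "loaded mass [ug]",
        "yield_percent": "release yield [%]",
        "plateau_time_h": "time to 99.9% of plateau [h]",
    }
    for key, value in report.derived.items():
        parts.append(f"{labels.get(key, key):<38} {value:.6g}")
    if report.sub_lod_times:
        parts.append(
            f"sub-LOD points retained at t = "
            + ", ".join(f"{t:g}" for t in report.sub_lod_times)
            + " h"
        )
    parts.append("--- provenance ---")
    for key, value in report.provenance.items():
        parts.append(f"{key}: {value}")
    return "\n".join(parts) + "\n"


def load_report(path) -> dict:
    """Read back a machine-readable ``report.json``."""
    with open(path) as fh:
        return json.load(fh)


def compare_runs(report_a: RunReport, report_b: RunReport) -> dict:
    """Quantitative comparison of two converged runs via normalized curves.

    Ratios are b/a. When the bath and membrane volumes match between runs,
    the ratio of the experimental lifetimes at t_0.5 equals the ratio of the
    membrane lifetimes.
    """
    for name, rep in (("a", report_a), ("b", report_b)):
        if not rep.fit.converged:
            raise ValueError(f"run {name} did not converge; comparison is meaningless")
    pa, pb = report_a.fit.params, report_b.fit.params
    t05_a, t05_b = half_release_time(pa), half_release_time(pb)
    return {
        "normalized_params_a": {"tau0_h": pa.tau0, "sigma": pa.sigma},
        "normalized_params_b": {"tau0_h": pb.tau0, "sigma": pb.sigma},
        "m_inf_ratio": pb.m_inf / pa.m_inf,
        "tau0_ratio": pb.tau0 / pa.tau0,
        "t_half_ratio": t05_b / t05_a,
        "yield_ratio": (
            report_b.derived["yield_percent"] / report_a.derived["yield_percent"]
        ),
        "tau_exp_at_t_half_ratio": (
            (b_coefficient(pb) * t05_b ** (1.0 - pb.sigma))
            / (b_coefficient(pa) * t05_a ** (1.0 - pa.sigma))
        ),
    }
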