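"""Synthetic multi-detector chromatograms with the statistical structure the
algebraic quantification method assumes.

The simulator embodies the two linearity axioms the method rests on:

1. a single analyte's peak area is proportional to its concentration
   (area = response_factor · c, exactly, in the noise-free limit), and
2. a mixture's trace is the pointwise sum of its components' traces.

Each analyte elutes as a unit-area peak (Gaussian, or exponentially modified
Gaussian for tailing) centred at its retention time; a detector sees that
peak scaled by a signed per-(analyte, detector) response factor times the
concentration.  Negative response factors model analytes that absorb less UV
light than the mobile phase (glycerol at 210/270 nm) — a positive-shaped
peak multiplied by a negative factor gives the below-baseline excursion real
instruments record.  Optional additive Gaussian noise and a linear baseline
drift complete the trace.

:func:`make_gor_scenario` ships the default fixture: glycerol plus four
oxidation products on a refractive-index channel and two UV channels, with
overlapped glycerol/DHA peaks near 13.8 min, and the two validation mixtures
(500/5/5 mM and 100/100/100 mM glycerol/DHA/FA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import numpy as np
import scipy.stats
import yaml

from .calibrate import (
    CalibrationCurve,
    CalibrationStandard,
    ResponseMatrix,
    build_response_matrix,
    fit_zero_intercept,
)
from .chromio import (
    Chromatogram,
    DetectorChannel,
    IntegrationWindow,
    RID,
    integrate_window,
    vwd,
)
from .exceptions import ConfigurationError
from .resolve import AreaVector

__all__ = [
    "PeakSpec",
    "DetectorResponseModel",
    "MixtureSpec",
    "Scenario",
    "default_time_grid",
    "simulate_chromatogram",
    "generate_calibration_series",
    "make_gor_scenario",
    "scenario_calibration_curves",
    "scenario_response_matrix",
    "scenario_area_vector",
    "save_scenario",
    "load_scenario",
]

#: Instrument sampling cadence: one point every 0.5 s (0.00833 min),
#: starting at 0.00667 min.
GRID_START_MIN = 0.00667
GRID_STEP_MIN = 0.00833


@dataclass(frozen=True)
class PeakSpec:
    """Elution peak shape for one analyte.

    ``shape`` is ``"gaussian"`` or ``"emg"`` (exponentially modified
    Gaussian; ``tail_tau`` is the exponential tail constant, minutes).
    The profile always has unit area so the detector response factor alone
    carries the sensitivity.
    """

    analyte: str
    retention_time: float
    width_sigma: float
    shape: str = "gaussian"
    tail_tau: float | None = None

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError("peak width sigma must be positive")
        if self.shape not in ("gaussian", "emg"):
            raise ValueError(f"unknown peak shape {self.shape!r}")
        if self.shape == "emg" and (self.tail_tau is None or self.tail_tau <= 0):
            raise ValueError("emg shape requires a positive tail_tau")

    def profile(self, times: np.ndarray) -> np.ndarray:
        """Unit-area peak profile evaluated on ``times``."""
        if self.shape == "gaussian":
            return scipy.stats.norm.pdf(
                times, loc=self.retention_time, scale=self.width_sigma
            )
        k = self.tail_tau / self.width_sigma
        return scipy.stats.exponnorm.pdf(
            times, k, loc=self.retention_time, scale=self.width_sigma
        )


@dataclass(frozen=True)
class DetectorResponseModel:
    """Signed response factors (signal·minutes per mM) per analyte and
    detector, plus the noise and drift model.

    ``response_factors`` maps analyte name -> {detector label -> factor};
    detector labels are the channel's short identifier (``RID``, ``VWD210``,
    ...).  ``noise_sd`` is the standard deviation of additive Gaussian noise
    on the signal trace; ``baseline_drift_slope`` a linear drift in signal
    units per minute.  ``seed`` feeds every random draw, making simulated
    data byte-reproducible.
    """

    response_factors: Mapping[str, Mapping[str, float]]
    noise_sd: float = 0.0
    baseline_drift_slope: float = 0.0
    seed: int = 0

    def factor(self, analyte: str, detector: DetectorChannel) -> float:
        try:
            return float(self.response_factors[analyte][detector.label])
        except KeyError:
            raise ConfigurationError(
                f"no response factor for analyte {analyte!r} on detector "
                f"{detector.label}"
            ) from None


@dataclass(frozen=True)
class MixtureSpec:
    """Analyte concentrations (mM) of one injected solution."""

    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("mixture concentrations must be >= 0")


def default_time_grid(end_min: float = 18.0) -> np.ndarray:
    """The instrument's sampling grid: 0.00833 min spacing from 0.00667 min."""
    n = int(np.floor((end_min - GRID_START_MIN) / GRID_STEP_MIN)) + 1
    return GRID_START_MIN + GRID_STEP_MIN * np.arange(n)


def simulate_chromatogram(
    peaks: Sequence[PeakSpec],
    model: DetectorResponseModel,
    mix: MixtureSpec,
    detector: DetectorChannel,
    times: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Chromatogram:
    """Simulate one detector's trace for a mixture.

    signal(t) = Σ_analytes c·factor·unit_peak(t) + drift·(t − t₀) + noise

    Every analyte present in the mixture must have a peak and a response
    factor for this detector.  With ``noise_sd`` zero the trace is exactly
    the linear sum, so integrating the full peak recovers factor·c up to
    quadrature error.  Pass ``rng`` to share one noise stream across several
    simulated traces; otherwise a fresh generator is seeded from
    ``model.seed``.
    """
    if times is None:
        times = default_time_grid()
    times = np.asarray(times, dtype=float)
    peak_by_analyte = {p.analyte: p for p in peaks}
    signal = np.zeros_like(times)
    for analyte, conc in mix.concentrations.items():
        if conc == 0.0:
            continue
        if analyte not in peak_by_analyte:
            raise ConfigurationError(f"no peak specification for {analyte!r}")
        factor = model.factor(analyte, detector)
        signal += conc * factor * peak_by_analyte[analyte].profile(times)
    if model.baseline_drift_slope:
        signal = signal + model.baseline_drift_slope * (times - times[0])
    if model.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(model.seed)
        signal = signal + rng.normal(0.0, model.noise_sd, size=times.shape)
    return Chromatogram(
        detector,
        times,
        signal,
        {"simulated": True, "mixture": dict(mix.concentrations)},
    )


def generate_calibration_series(
    analyte: str,
    concentrations: Sequence[float],
    model: DetectorResponseModel,
    peaks: Sequence[PeakSpec],
    detector: DetectorChannel,
    window: IntegrationWindow | None = None,
    times: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[CalibrationStandard]:
    """Single-analyte standards: simulate each concentration, integrate.

    With zero noise the areas are exactly proportional to the
    concentrations (up to quadrature and window truncation, both of which
    cancel in the calibrate→quantify round trip because mixture areas are
    truncated identically).
    """
    if len(concentrations) == 0:
        raise ConfigurationError("need at least one calibration concentration")
    if times is None:
        times = default_time_grid()
    if window is None:
        window = IntegrationWindow(float(times[0]), float(times[-1]))
    if rng is None and model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
    standards = []
    for c in concentrations:
        chrom = simulate_chromatogram(
            peaks, model, MixtureSpec({analyte: float(c)}), detector,
            times=times, rng=rng,
        )
        standards.append(
            CalibrationStandard(float(c), integrate_window(chrom, window))
        )
    return standards


# ---------------------------------------------------------------------------
# The default glycerol-oxidation scenario.

@dataclass(frozen=True)
class Scenario:
    """A complete simulated study: peaks, detector response model, the
    detector channels used for the solve, the analytes being quantified,
    calibration concentration series, the shared integration window, and
    named mixtures."""

    peaks: tuple[PeakSpec, ...]
    model: DetectorResponseModel
    detectors: tuple[DetectorChannel, ...]
    analytes: tuple[str, ...]
    calibration_concentrations: Mapping[str, tuple[float, ...]]
    window: IntegrationWindow
    mixtures: Mapping[str, MixtureSpec]


def make_gor_scenario(
    noise_sd: float = 0.0, seed: int = 0
) -> Scenario:
    """Default glycerol-oxidation fixture.

    Five analytes (glycerol, DHA, FA, GCAD, GLAD) eluting between 12 and
    14.5 min, with glycerol and DHA overlapping near 13.6–13.8 min; three
    quantification channels (refractive index, UV at 210 and 270 nm) plus a
    deliberately collinear UV 205 nm channel (response factors exactly
    proportional to 210 nm) for exercising rank-deficiency diagnostics.

    Refractive-index response factors reproduce the benchmark single-analyte
    areas (500 mM glycerol -> 177, 5 mM DHA -> 1.57, 5 mM FA -> 0.319
    counts·min over the 13.2–15.5 min window); UV factors follow the
    qualitative detector behaviour: glycerol weakly negative at 210 nm and
    almost null at 270 nm, DHA and FA comparable at 210 nm, FA at 270 nm at
    0.2% of DHA's sensitivity.  The named mixtures are the two validation
    solutions: glycerol/DHA/FA at 500/5/5 mM and at 100/100/100 mM.
    """
    peaks = (
        PeakSpec("GLAD", 12.0, 0.07),
        PeakSpec("GCAD", 13.1, 0.07),
        PeakSpec("glycerol", 13.6, 0.08),
        PeakSpec("DHA", 13.8, 0.08),
        PeakSpec("FA", 14.4, 0.10),
    )
    window = IntegrationWindow(13.2, 15.5)
    # RID slopes from the benchmark areas; the window truncates < 1e-6 of
    # each peak, so area/concentration is the factor to float precision.
    factors = {
        "glycerol": {"RID": 177.0 / 500.0, "VWD210": -8e-4, "VWD270": -2e-5,
                     "VWD205": -1.6e-3},
        "DHA": {"RID": 1.57 / 5.0, "VWD210": 0.30, "VWD270": 0.20,
                "VWD205": 0.60},
        "FA": {"RID": 0.319 / 5.0, "VWD210": 0.25, "VWD270": 5e-4,
               "VWD205": 0.50},
        "GLAD": {"RID": 0.30, "VWD210": 0.28, "VWD270": 0.15, "VWD205": 0.56},
        "GCAD": {"RID": 0.25, "VWD210": 0.26, "VWD270": 0.12, "VWD205": 0.52},
    }
    model = DetectorResponseModel(
        response_factors=factors, noise_sd=noise_sd, seed=seed
    )
    return Scenario(
        peaks=peaks,
        model=model,
        detectors=(RID, vwd(210), vwd(270)),
        analytes=("glycerol", "DHA", "FA"),
        calibration_concentrations={
            "glycerol": (100.0, 200.0, 300.0, 400.0, 500.0),
            "DHA": (1.0, 2.0, 5.0, 10.0),
            "FA": (1.0, 2.0, 5.0, 10.0),
        },
        window=window,
        mixtures={
            "validation-500-5-5": MixtureSpec(
                {"glycerol": 500.0, "DHA": 5.0, "FA": 5.0}
            ),
            "validation-100-100-100": MixtureSpec(
                {"glycerol": 100.0, "DHA": 100.0, "FA": 100.0}
            ),
        },
    )


def scenario_calibration_curves(
    scenario: Scenario,
    detectors: Sequence[DetectorChannel] | None = None,
    rng: np.random.Generator | None = None,
) -> list[CalibrationCurve]:
    """Run the full calibration protocol on a scenario: simulate each
    analyte's standard series on each detector, integrate the shared window,
    fit through the origin."""
    if detectors is None:
        detectors = scenario.detectors
    times = default_time_grid()
    curves = []
    for det in detectors:
        for analyte in scenario.analytes:
            standards = generate_calibration_series(
                analyte,
                scenario.calibration_concentrations[analyte],
                scenario.model,
                scenario.peaks,
                det,
                window=scenario.window,
                times=times,
                rng=rng,
            )
            curves.append(fit_zero_intercept(standards, analyte, det))
    return curves


def scenario_response_matrix(
    scenario: Scenario,
    detectors: Sequence[DetectorChannel] | None = None,
    rng: np.random.Generator | None = None,
) -> ResponseMatrix:
    """Calibrate a scenario and assemble its response matrix."""
    if detectors is None:
        detectors = scenario.detectors
    curves = scenario_calibration_curves(scenario, detectors, rng)
    return build_response_matrix(curves, scenario.analytes, detectors)


def scenario_area_vector(
    scenario: Scenario,
    mixture: str | MixtureSpec,
    detectors: Sequence[DetectorChannel] | None = None,
    rng: np.random.Generator | None = None,
) -> AreaVector:
    """Simulate a mixture on each detector and integrate the shared window."""
    if isinstance(mixture, str):
        mixture = scenario.mixtures[mixture]
    if detectors is None:
        detectors = scenario.detectors
    times = default_time_grid()
    areas = []
    for det in detectors:
        chrom = simulate_chromatogram(
            scenario.peaks, scenario.model, mixture, det, times=times, rng=rng
        )
        areas.append(integrate_window(chrom, scenario.window))
    return AreaVector(tuple(detectors), np.array(areas), scenario.window)


# ---------------------------------------------------------------------------
# Scenario persistence (structured text).

def _detector_to_label(det: DetectorChannel) -> str:
    return det.label


def _detector_from_label(label: str) -> DetectorChannel:
    if label == "RID":
        return RID
    if label.startswith("VWD"):
        return vwd(float(label[3:]))
    raise ValueError(f"unknown detector label {label!r}")


def save_scenario(scenario: Scenario, dest: str | IO[str]) -> None:
    """Write a scenario as YAML (peaks, response factors, noise, window,
    detectors, mixtures)."""
    doc = {
        "peaks": [
            {
                "analyte": p.analyte,
                "retention_time": p.retention_time,
                "width_sigma": p.width_sigma,
                "shape": p.shape,
                **({"tail_tau": p.tail_tau} if p.tail_tau is not None else {}),
            }
            for p in scenario.peaks
        ],
        "response_factors": {
            a: dict(d) for a, d in scenario.model.response_factors.items()
        },
        "noise_sd": scenario.model.noise_sd,
        "baseline_drift_slope": scenario.model.baseline_drift_slope,
        "seed": scenario.model.seed,
        "detectors": [_detector_to_label(d) for d in scenario.detectors],
        "analytes": list(scenario.analytes),
        "calibration_concentrations": {
            a: list(c) for a, c in scenario.calibration_concentrations.items()
        },
        "window": {"start": scenario.window.start, "end": scenario.window.end},
        "mixtures": {
            name: dict(m.concentrations) for name, m in scenario.mixtures.items()
        },
    }
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    else:
        yaml.safe_dump(doc, dest, sort_keys=False)


def load_scenario(source: str | IO[str]) -> Scenario:
    """Read a scenario written by :func:`save_scenario`."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(source)
    peaks = tuple(
        PeakSpec(
            p["analyte"], float(p["retention_time"]), float(p["width_sigma"]),
            p.get("shape", "gaussian"),
            float(p["tail_tau"]) if p.get("tail_tau") is not None else None,
        )
        for p in doc["peaks"]
    )
    model = DetectorResponseModel(
        response_factors=doc["response_factors"],
        noise_sd=float(doc.get("noise_sd", 0.0)),
        baseline_drift_slope=float(doc.get("baseline_drift_slope", 0.0)),
        seed=int(doc.get("seed", 0)),
    )
    return Scenario(
        peaks=peaks,
        model=model,
        detectors=tuple(_detector_from_label(d) for d in doc["detectors"]),
        analytes=tuple(doc["analytes"]),
        calibration_concentrations={
            a: tuple(float(x) for x in c)
            for a, c in doc["calibration_concentrations"].items()
        },
        window=IntegrationWindow(
            float(doc["window"]["start"]), float(doc["window"]["end"])
        ),
        mixtures={
            name: MixtureSpec({k: float(v) for k, v in m.items()})
            for name, m in doc["mixtures"].items()
        },
    )
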