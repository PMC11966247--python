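"""Zero-intercept calibration and response-matrix assembly.

For each (analyte, detector) pair, calibration standards give (concentration,
integrated area) points.  Because no analyte means no peak, the calibration
line is constrained through the origin: ``a = m · c`` with the single slope

    m = Σ aᵢcᵢ / Σ cᵢ²

(the through-origin least-squares estimator).  Stacking slopes by detector
row and analyte column yields the response matrix M that links the area
vector A of an unknown mixture to its concentration vector C via A = M·C.
Unique recovery of C requires rank(M) equal to the number of analytes;
diagnostics here report rank and condition number so near-collinear detector
responses are flagged before a solve goes numerically bad.

Slopes may legitimately be negative (an analyte absorbing less than the
mobile phase) or nearly zero; near-zero slopes are kept as fitted, and the
matrix diagnostics — not the individual fit — decide usability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import yaml

from .chromio import RID, DetectorChannel, vwd
from .exceptions import CalibrationError

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "ResponseMatrix",
    "SolvabilityReport",
    "fit_zero_intercept",
    "build_response_matrix",
    "assess_solvability",
    "save_calibration",
    "load_calibration",
]

#: Relative singular-value tolerance for deciding rank.
RANK_RTOL = 1e-10
#: Condition number above which a solvable matrix is still flagged.
ILL_CONDITION_THRESHOLD = 1e6


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration point: concentration (mM) and integrated area
    (signal·minutes).  The area may be negative for negative-response
    analytes; the concentration may not."""

    concentration: float
    area: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("standard concentration must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted through-origin calibration line for one (analyte, detector).

    ``slope`` is in signal·minutes per mM and may be negative or ~0.
    ``r_squared`` is computed against the through-origin model
    (1 − SS_res / Σa²) and ``residual_sd`` is the standard deviation of the
    area residuals about the fitted line.
    """

    analyte: str
    detector: DetectorChannel
    slope: float
    n_points: int
    r_squared: float
    residual_sd: float


def fit_zero_intercept(
    standards: Sequence[CalibrationStandard],
    analyte: str = "",
    detector: DetectorChannel | None = None,
) -> CalibrationCurve:
    """Fit ``a = m·c`` by least squares through the origin.

    Raises :class:`CalibrationError` when no standard has positive
    concentration (the slope would be 0/0).
    """
    if len(standards) == 0:
        raise CalibrationError("no calibration standards supplied")
    c = np.array([s.concentration for s in standards], dtype=float)
    a = np.array([s.area for s in standards], dtype=float)
    scc = float(np.dot(c, c))
    if scc == 0.0:
        raise CalibrationError(
            "all standard concentrations are zero: through-origin fit is degenerate"
        )
    m = float(np.dot(a, c)) / scc
    resid = a - m * c
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(a, a))  # through-origin total sum of squares
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    n = len(standards)
    residual_sd = math.sqrt(ss_res / (n - 1)) if n > 1 else 0.0
    return CalibrationCurve(
        analyte=analyte,
        detector=detector if detector is not None else RID,
        slope=m,
        n_points=n,
        r_squared=r2,
        residual_sd=residual_sd,
    )


@dataclass(frozen=True)
class ResponseMatrix:
    """Detector-by-analyte matrix of calibration slopes.

    Rows follow ``detectors``, columns follow ``analytes``.  Must be square
    or tall (at least as many detectors as analytes).  ``rank`` uses singular
    values with relative tolerance :data:`RANK_RTOL`; ``condition_number`` is
    the 2-norm ratio of extreme singular values (``inf`` when rank-deficient).
    """

    detectors: tuple[DetectorChannel, ...]
    analytes: tuple[str, ...]
    entries: np.ndarray
    rank: int = field(init=False)
    condition_number: float = field(init=False)

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        n_det, n_an = len(self.detectors), len(self.analytes)
        if entries.shape != (n_det, n_an):
            raise ValueError(
                f"entries shape {entries.shape} does not match "
                f"{n_det} detectors x {n_an} analytes"
            )
        if n_det < n_an:
            raise ValueError(
                f"need at least as many detectors ({n_det}) as analytes ({n_an})"
            )
        sv = np.linalg.svd(entries, compute_uv=False)
        tol = RANK_RTOL * (sv[0] if sv.size else 0.0)
        rank = int(np.sum(sv > tol))
        cond = float(sv[0] / sv[-1]) if rank == n_an and sv[-1] > 0 else math.inf
        object.__setattr__(self, "rank", rank)
        object.__setattr__(self, "condition_number", cond)

    @property
    def is_solvable(self) -> bool:
        """True when rank equals the number of analytes, i.e. the linear
        system A = M·C has a unique solution."""
        return self.rank == len(self.analytes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


def build_response_matrix(
    curves: Iterable[CalibrationCurve],
    analyte_order: Sequence[str],
    detector_order: Sequence[DetectorChannel],
) -> ResponseMatrix:
    """Place each curve's slope at (detector row, analyte column).

    Exactly one curve per pair is required: a missing pair raises an
    incomplete-calibration error, a duplicate an ambiguity error.
    """
    by_pair: dict[tuple[str, DetectorChannel], float] = {}
    for curve in curves:
        key = (curve.analyte, curve.detector)
        if key in by_pair:
            raise CalibrationError(
                f"duplicate calibration for analyte {curve.analyte!r} on "
                f"detector {curve.detector.label}"
            )
        by_pair[key] = curve.slope

    n_det, n_an = len(detector_order), len(analyte_order)
    entries = np.empty((n_det, n_an), dtype=float)
    for i, det in enumerate(detector_order):
        for j, an in enumerate(analyte_order):
            try:
                entries[i, j] = by_pair[(an, det)]
            except KeyError:
                raise CalibrationError(
                    f"missing calibration for analyte {an!r} on detector "
                    f"{det.label}"
                ) from None
    extra = set(by_pair) - {
        (an, det) for det in detector_order for an in analyte_order
    }
    if extra:
        an, det = next(iter(extra))
        raise CalibrationError(
            f"curve for ({an!r}, {det.label}) not covered by the requested orders"
        )
    return ResponseMatrix(tuple(detector_order), tuple(analyte_order), entries)


@dataclass(frozen=True)
class SolvabilityReport:
    """Human-readable verdict on whether a response matrix supports a unique
    concentration solve, with conditioning warnings."""

    solvable: bool
    rank: int
    n_analytes: int
    condition_number: float
    warnings: tuple[str, ...]

    def __str__(self) -> str:
        lines = [
            f"solvable: {'yes' if self.solvable else 'NO'}",
            f"rank: {self.rank} of {self.n_analytes} required",
            f"condition number: {self.condition_number:.6g}",
        ]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def assess_solvability(matrix: ResponseMatrix) -> SolvabilityReport:
    """Report rank/conditioning diagnostics for ``matrix``.

    A matrix is unsolvable when its rank falls short of the analyte count
    (two detectors responding proportionally, say); it is solvable-but-warned
    when the condition number exceeds :data:`ILL_CONDITION_THRESHOLD`, since
    area noise is then amplified by that factor in the solved concentrations.
    """
    warns: list[str] = []
    if not matrix.is_solvable:
        warns.append(
            "rank-deficient response matrix: detector responses are linearly "
            "dependent, concentrations are not uniquely determined"
        )
    elif matrix.condition_number > ILL_CONDITION_THRESHOLD:
        warns.append(
            f"ill-conditioned response matrix (condition number "
            f"{matrix.condition_number:.3g} > {ILL_CONDITION_THRESHOLD:g}): "
            "small area errors will be strongly amplified"
        )
    return SolvabilityReport(
        solvable=matrix.is_solvable,
        rank=matrix.rank,
        n_analytes=len(matrix.analytes),
        condition_number=matrix.condition_number,
        warnings=tuple(warns),
    )


# ---------------------------------------------------------------------------
# Calibration persistence: one YAML record per (analyte, detector).

def _detector_to_record(det: DetectorChannel) -> dict:
    rec = {"detector_kind": det.kind}
    if det.wavelength_nm is not None:
        rec["wavelength_nm"] = float(det.wavelength_nm)
    return rec


def _detector_from_record(rec: dict) -> DetectorChannel:
    kind = rec["detector_kind"]
    if kind == "refractive-index":
        return RID
    return vwd(rec["wavelength_nm"])


def save_calibration(curves: Iterable[CalibrationCurve], dest: str | IO[str]) -> None:
    """Write calibration curves as a YAML list of flat records."""
    records = []
    for c in curves:
        rec = {"analyte": c.analyte, **_detector_to_record(c.detector),
               "slope": float(c.slope), "n_points": int(c.n_points),
               "r_squared": float(c.r_squared),
               "residual_sd": float(c.residual_sd)}
        records.append(rec)
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            yaml.safe_dump(records, fh, sort_keys=False)
    else:
        yaml.safe_dump(records, dest, sort_keys=False)


def load_calibration(source: str | IO[str]) -> list[CalibrationCurve]:
    """Read calibration curves written by :func:`save_calibration`."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            records = yaml.safe_load(fh)
    else:
        records = yaml.safe_load(source)
    if not isinstance(records, list):
        raise CalibrationError("calibration file must contain a list of records")
    curves = []
    for rec in records:
        curves.append(
            CalibrationCurve(
                analyte=rec["analyte"],
                detector=_detector_from_record(rec),
                slope=float(rec["slope"]),
                n_points=int(rec.get("n_points", 0)),
                r_squared=float(rec.get("r_squared", float("nan"))),
                residual_sd=float(rec.get("residual_sd", float("nan"))),
            )
        )
    return curves
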