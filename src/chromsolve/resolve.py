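"""Solving the multi-detector linear system for concentrations.

With k analytes whose peaks overlap, one chromatogram cannot separate them —
but k detector channels can.  Each channel's integrated area over a shared
retention window is a known linear combination of the analyte concentrations
(area = Σ m·c), so the area vector A and the calibration response matrix M
satisfy A = M·C.  A square well-conditioned M is solved directly; extra
detectors (tall M) are reconciled by least squares.

Negative solved concentrations are physically impossible and signal a
calibration or integration fault; they are reported and flagged, never
clipped, because truncation would hide the fault.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import scipy.linalg

from .calibrate import ILL_CONDITION_THRESHOLD, ResponseMatrix
from .chromio import DetectorChannel, IntegrationWindow
from .exceptions import ContractError, DomainError, UnsolvableSystemError

__all__ = [
    "AreaVector",
    "ConcentrationEstimate",
    "solve_concentrations",
    "percent_error",
    "additivity_check",
    "round_sig",
    "format_estimate_report",
]


@dataclass(frozen=True)
class AreaVector:
    """Integrated areas (signal·minutes), one per detector, over a shared
    retention window.  Detector order must match the response matrix the
    vector is solved against."""

    detectors: tuple[DetectorChannel, ...]
    areas: np.ndarray
    window: IntegrationWindow | None = None

    def __post_init__(self) -> None:
        areas = np.asarray(self.areas, dtype=float)
        object.__setattr__(self, "areas", areas)
        if areas.ndim != 1 or len(areas) != len(self.detectors):
            raise ValueError("one area per detector required")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Solved analyte concentrations (mM) with solve diagnostics.

    ``negative_flags`` marks analytes whose solved concentration came out
    below zero.  ``residual_norm`` is ``||M·C − A||₂`` (zero up to roundoff
    for a square solve).
    """

    analytes: tuple[str, ...]
    concentrations: np.ndarray
    residual_norm: float
    condition_number: float
    negative_flags: tuple[bool, ...]

    def as_dict(self) -> dict[str, float]:
        return {a: float(c) for a, c in zip(self.analytes, self.concentrations)}


def solve_concentrations(
    matrix: ResponseMatrix, areas: AreaVector
) -> ConcentrationEstimate:
    """Solve A = M·C for the concentration vector C.

    Square systems go through an LU factorization (numerically safer than
    forming M⁻¹ explicitly); tall systems are solved in the least-squares
    sense.  Raises :class:`UnsolvableSystemError` for rank-deficient M and
    :class:`ContractError` when the detector orders disagree.
    """
    if areas.detectors != matrix.detectors:
        raise ContractError(
            "area vector detector order "
            f"{[d.label for d in areas.detectors]} does not match response "
            f"matrix order {[d.label for d in matrix.detectors]}"
        )
    if not matrix.is_solvable:
        raise UnsolvableSystemError(
            f"response matrix rank {matrix.rank} < {len(matrix.analytes)} "
            "analytes: concentrations are not uniquely determined"
        )
    m = matrix.entries
    a = areas.areas
    if m.shape[0] == m.shape[1]:
        conc = scipy.linalg.solve(m, a)
    else:
        conc, *_ = scipy.linalg.lstsq(m, a)
    residual = float(np.linalg.norm(m @ conc - a))
    return ConcentrationEstimate(
        analytes=matrix.analytes,
        concentrations=conc,
        residual_norm=residual,
        condition_number=matrix.condition_number,
        negative_flags=tuple(bool(c < 0) for c in conc),
    )


def percent_error(estimated: float, true: float) -> float:
    """Absolute percent error ``100·|estimated − true| / true``.

    The denominator is the true (nominal) concentration; ``true`` must be
    positive.
    """
    if true <= 0:
        raise DomainError("true value must be positive for a percent error")
    return 100.0 * abs(estimated - true) / true


def round_sig(x: float, sig_figs: int = 3) -> float:
    """Round ``x`` to ``sig_figs`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig_figs - 1 - math.floor(math.log10(abs(x))))


def additivity_check(
    mixture_area: float,
    component_areas: Sequence[float],
    sig_figs: int | None = None,
) -> float:
    """Percent discrepancy between a mixture's integrated area and the sum
    of its components' individually measured areas.

    Peak-area additivity is one of the two linearity assumptions the whole
    method rests on; this is its empirical check.  With ``sig_figs`` set, the
    component sum is rounded to that many significant figures before the
    comparison — the convention used when areas are quoted to 3 s.f.
    """
    total = float(sum(component_areas))
    if total == 0:
        raise DomainError("component areas sum to zero")
    if sig_figs is not None:
        total = round_sig(total, sig_figs)
    return 100.0 * abs(mixture_area - total) / abs(total)


def format_estimate_report(
    estimate: ConcentrationEstimate,
    true_concentrations: dict[str, float] | None = None,
) -> str:
    """Plain-text quantification report: per-analyte concentration (3 s.f.),
    negative flags, residual norm, condition number, and percent errors when
    nominal concentrations are supplied."""
    lines = ["quantification report", "---------------------"]
    for analyte, conc, neg in zip(
        estimate.analytes, estimate.concentrations, estimate.negative_flags
    ):
        line = f"{analyte}: {round_sig(float(conc), 3):g} mM"
        if true_concentrations and analyte in true_concentrations:
            err = percent_error(float(conc), true_concentrations[analyte])
            line += f" (error {round_sig(err, 3):g}%)"
        if neg:
            line += "  ** NEGATIVE — check calibration/integration **"
        lines.append(line)
    lines.append(f"residual norm: {estimate.residual_norm:.3g}")
    lines.append(f"condition number: {estimate.condition_number:.6g}")
    if estimate.condition_number > ILL_CONDITION_THRESHOLD:
        lines.append("warning: ill-conditioned system; treat results with caution")
    return "\n".join(lines)
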