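"""Chromatogram data model, delimited-text I/O, and windowed integration.

A chromatogram here is one detector channel's signal sampled on a strictly
increasing retention-time grid (minutes).  Signals are allowed to be negative:
an analyte that absorbs less UV light than the mobile phase produces a
genuine below-baseline excursion, and the quantification method integrates
that negative lobe as-is.

The interchange format is deliberately plain: two-column delimited text
(``time_min,signal``), UTF-8, ``.`` decimal separator.  Vendor binary formats
are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    ChromatogramParseError,
    DomainError,
    EmptyDataError,
    WindowError,
)

__all__ = [
    "DetectorChannel",
    "Chromatogram",
    "IntegrationWindow",
    "RID",
    "vwd",
    "read_chromatogram",
    "write_chromatogram",
    "integrate_window",
    "subtract_linear_baseline",
    "absorbance_from_transmittance",
]


@dataclass(frozen=True)
class DetectorChannel:
    """One HPLC detector channel.

    ``kind`` is either ``"refractive-index"`` (a bulk-property detector,
    signal in counts) or ``"variable-wavelength"`` (a UV absorbance detector,
    signal in absorbance units).  A variable-wavelength detector read at two
    different wavelengths counts as two distinct channels — each wavelength
    is an independent measurement for the linear system.
    """

    kind: str
    wavelength_nm: float | None = None

    _KINDS = ("refractive-index", "variable-wavelength")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(
                f"detector kind must be one of {self._KINDS}, got {self.kind!r}"
            )
        if self.kind == "variable-wavelength" and self.wavelength_nm is None:
            raise ValueError("variable-wavelength channel requires wavelength_nm")
        if self.kind == "refractive-index" and self.wavelength_nm is not None:
            raise ValueError("refractive-index channel takes no wavelength")

    @property
    def label(self) -> str:
        """Short identifier, e.g. ``RID`` or ``VWD210``."""
        if self.kind == "refractive-index":
            return "RID"
        wl = self.wavelength_nm
        return f"VWD{wl:g}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The refractive-index detector channel (there is only one).
RID = DetectorChannel("refractive-index")


def vwd(wavelength_nm: float) -> DetectorChannel:
    """Variable-wavelength (UV) detector channel at ``wavelength_nm``."""
    return DetectorChannel("variable-wavelength", float(wavelength_nm))


@dataclass
class Chromatogram:
    """One channel's signal trace over retention time.

    Parameters
    ----------
    detector
        The channel this trace was recorded on.
    times
        Retention times in minutes, strictly increasing, length >= 2.
    signals
        Detector response at each time.  Counts for the refractive-index
        channel, absorbance units for UV channels.  May be negative.
    metadata
        Free-form annotations (sample id, instrument, ...).
    """

    detector: DetectorChannel
    times: np.ndarray
    signals: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.ndim != 1 or self.signals.ndim != 1:
            raise ValueError("times and signals must be one-dimensional")
        if len(self.times) != len(self.signals):
            raise ValueError(
                f"times (n={len(self.times)}) and signals (n={len(self.signals)}) "
                "must have the same length"
            )
        if len(self.times) < 2:
            raise EmptyDataError("a chromatogram needs at least 2 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("retention times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.signals))):
            raise ValueError("times and signals must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) retention time in minutes."""
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class IntegrationWindow:
    """Retention-time interval ``[start, end]`` (minutes) shared by all
    detectors when assembling an area vector."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise WindowError(
                f"window start ({self.start}) must be before end ({self.end})"
            )


def read_chromatogram(
    source: str | IO[str],
    detector: DetectorChannel,
    metadata: Mapping | None = None,
) -> Chromatogram:
    """Read a two-column (time_min, signal) delimited text table.

    A header row is optional and detected by its non-numeric first field.
    The delimiter may be a comma, tab, or run of whitespace.  Malformed rows
    raise :class:`ChromatogramParseError` with the 1-based line number.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_chromatogram(fh, detector, metadata)

    times: list[float] = []
    signals: list[float] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f for f in line.replace(",", " ").replace("\t", " ").split() if f]
        if len(fields) != 2:
            raise ChromatogramParseError(
                f"expected 2 columns, got {len(fields)}: {line!r}", line=lineno
            )
        try:
            t, s = float(fields[0]), float(fields[1])
        except ValueError:
            if lineno == 1 and not times:
                continue  # header row
            raise ChromatogramParseError(
                f"non-numeric value in {line!r}", line=lineno
            ) from None
        times.append(t)
        signals.append(s)

    if len(times) < 2:
        raise EmptyDataError(f"only {len(times)} data row(s) found; need at least 2")
    try:
        return Chromatogram(detector, np.array(times), np.array(signals),
                            dict(metadata or {}))
    except ValueError as exc:
        raise ChromatogramParseError(str(exc)) from exc


def write_chromatogram(chrom: Chromatogram, dest: str | IO[str]) -> None:
    """Write the ``time_min,signal`` CSV; values at 6 significant digits.

    The formatting is the declared interchange contract: a write/read/write
    cycle reproduces the file byte-for-byte.
    """
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8") as fh:
            write_chromatogram(chrom, fh)
        return
    dest.write("time_min,signal\n")
    for t, s in zip(chrom.times, chrom.signals):
        dest.write(f"{t:.6g},{s:.6g}\n")


def chromatogram_to_frame(chrom: Chromatogram) -> pd.DataFrame:
    """The trace as a two-column DataFrame (``time_min``, ``signal``)."""
    return pd.DataFrame({"time_min": chrom.times, "signal": chrom.signals})


def _interp_signal(chrom: Chromatogram, t: float) -> float:
    return float(np.interp(t, chrom.times, chrom.signals))


def integrate_window(chrom: Chromatogram, window: IntegrationWindow) -> float:
    """Signed mathematical area of the signal over the window, in
    signal·minutes.

    Trapezoidal integration on the native grid; window endpoints that fall
    between samples are handled by linear interpolation, so the result is
    continuous in the window bounds and exactly linear in the signal.
    Negative lobes subtract from the area — no baseline correction and no
    clipping is applied.
    """
    t0, t1 = chrom.span
    if window.start < t0 or window.end > t1:
        raise WindowError(
            f"window [{window.start}, {window.end}] min outside the sampled "
            f"span [{t0:g}, {t1:g}] min"
        )
    inside = (chrom.times > window.start) & (chrom.times < window.end)
    ts = np.concatenate(([window.start], chrom.times[inside], [window.end]))
    ss = np.concatenate(
        (
            [_interp_signal(chrom, window.start)],
            chrom.signals[inside],
            [_interp_signal(chrom, window.end)],
        )
    )
    return float(np.trapezoid(ss, ts))


def subtract_linear_baseline(
    chrom: Chromatogram, window: IntegrationWindow
) -> Chromatogram:
    """Return a copy with the chord through the window's endpoint signals
    subtracted over the whole trace.

    Off by default everywhere in the package: the quantification method
    integrates the raw signal, negative lobes included.  Provided for users
    whose instruments drift.
    """
    y0 = _interp_signal(chrom, window.start)
    y1 = _interp_signal(chrom, window.end)
    slope = (y1 - y0) / (window.end - window.start)
    baseline = y0 + slope * (chrom.times - window.start)
    return Chromatogram(
        chrom.detector,
        chrom.times.copy(),
        chrom.signals - baseline,
        dict(chrom.metadata, baseline="linear"),
    )


def absorbance_from_transmittance(percent_t: float | np.ndarray):
    """Absorbance (AU) from percent transmittance: ``A = log10(100 / %T)``.

    100 %T maps to 0 AU, 10 %T to 1 AU.  Values above 100 %T are accepted
    with a warning and yield negative absorbance (the sample transmitting
    more than the blank — physically odd but measurable).  %T <= 0 has no
    finite absorbance and raises :class:`DomainError`.
    """
    arr = np.asarray(percent_t, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("percent transmittance must be positive")
    if np.any(arr > 100):
        warnings.warn(
            "transmittance above 100% yields negative absorbance", stacklevel=2
        )
    out = np.log10(100.0 / arr)
    if np.isscalar(percent_t) or arr.ndim == 0:
        return float(out)
    return out
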