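"""Readers and writers for beat-annotation and segmented-HR data.

All public functions normalise units to the package's canonical conventions:
timestamps in seconds from record start, NN intervals in milliseconds, heart
rate in beats per minute. Input files are plain text: either a two-column
``(timestamp, nn)`` table or a single-column RR interval list (timestamps
reconstructed by cumulative sum, as is common for PhysioNet RR exports).
Delimiters are auto-detected among comma, tab and whitespace.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np

__all__ = [
    "BeatSeries",
    "SubjectRecord",
    "ValidationError",
    "ParseError",
    "read_rr_csv",
    "write_rr_csv",
    "read_hr_segments",
    "write_hr_segments",
]

#: Quality flag values carried per beat.
FLAG_NORMAL = "normal"
FLAG_OUTLIER = "outlier"
FLAG_ECTOPIC = "ectopic"
FLAG_INTERPOLATED = "interpolated"

_SPLIT_RE = re.compile(r"[,\t ;]+")


class ValidationError(ValueError):
    """Raised when data violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a text file cannot be parsed; names the offending line."""


@dataclass
class BeatSeries:
    """A timestamped sequence of NN (normal-to-normal) inter-beat intervals.

    Parameters
    ----------
    subject_id : str
        Identifier carried through all downstream tables.
    t : ndarray
        Beat timestamps in seconds from record start, strictly increasing.
    nn : ndarray
        NN intervals in milliseconds; ``nn[i]`` is the interval ending at
        ``t[i]``. All values must be positive.
    quality_flags : ndarray of str, optional
        Per-beat flag, one of ``normal | outlier | ectopic | interpolated``.
    start_time : str, optional
        ISO-8601 wall-clock time of record start, used only for reporting
        the cosinor acrophase as time of day.
    """

    subject_id: str
    t: np.ndarray
    nn: np.ndarray
    quality_flags: Optional[np.ndarray] = None
    start_time: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.nn = np.asarray(self.nn, dtype=float)
        if self.t.ndim != 1 or self.nn.ndim != 1 or self.t.size != self.nn.size:
            raise ValidationError("t and nn must be 1-D arrays of equal length")
        if self.t.size == 0:
            raise ValidationError("empty beat series")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.any(self.nn <= 0) or not np.all(np.isfinite(self.nn)):
            raise ValidationError("NN intervals must be positive and finite")
        if self.quality_flags is None:
            self.quality_flags = np.full(self.t.size, FLAG_NORMAL, dtype="U12")
        else:
            self.quality_flags = np.asarray(self.quality_flags, dtype="U12")
            if self.quality_flags.size != self.t.size:
                raise ValidationError("quality_flags length mismatch")

    @property
    def n_beats(self) -> int:
        return int(self.t.size)

    @property
    def span_s(self) -> float:
        """Record span in seconds, counting the interval ending at the first beat."""
        return float(self.t[-1] - self.t[0] + self.nn[0] / 1000.0)

    def check_span(self, min_hours: float = 20.0) -> None:
        """Raise if the record is too short for 24-h estimator semantics."""
        if self.span_s < min_hours * 3600.0:
            raise ValidationError(
                f"record spans {self.span_s / 3600.0:.2f} h; "
                f"at least {min_hours:g} h required"
            )

    def check_consistency(self, tol_ms: float = 1.0) -> None:
        """Verify the timestamp/interval invariant for consecutive beats.

        For contiguous beats, the elapsed time between successive timestamps
        must match the NN interval to within ``tol_ms``. Records with true
        gaps (missing data) legitimately violate the two-sided check, so this
        is an opt-in verification rather than a constructor invariant.
        """
        dt_ms = np.diff(self.t) * 1000.0
        if np.any(np.abs(dt_ms - self.nn[1:]) > tol_ms):
            raise ValidationError("timestamp/interval mismatch exceeds tolerance")

    def copy(self) -> "BeatSeries":
        return BeatSeries(
            subject_id=self.subject_id,
            t=self.t.copy(),
            nn=self.nn.copy(),
            quality_flags=self.quality_flags.copy(),
            start_time=self.start_time,
        )


@dataclass
class SubjectRecord:
    """A subject's beat series plus optional risk metadata.

    ``risk_label``, when present, must follow the NYHA mapping implemented in
    :func:`wearhrv.risk_models.label_risk` (classes 0-1 -> low, 2-4 -> high).
    ``truth`` optionally carries the artefact-free series when the record was
    produced by the synthetic generator.
    """

    beat_series: BeatSeries
    risk_label: Optional[Literal["low", "high"]] = None
    nyha_class: Optional[int] = None
    truth: Optional[BeatSeries] = None

    def __post_init__(self) -> None:
        if self.nyha_class is not None and self.nyha_class not in range(5):
            raise ValidationError("nyha_class must be an integer in 0..4")
        if self.risk_label is not None and self.risk_label not in ("low", "high"):
            raise ValidationError("risk_label must be 'low' or 'high'")


def _parse_numeric_rows(path: Path) -> tuple[list[list[float]], int]:
    """Parse whitespace/comma/tab-delimited numeric rows; skip one header line."""
    rows: list[list[float]] = []
    ncols = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in _SPLIT_RE.split(line) if f]
            try:
                values = [float(f) for f in fields]
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ParseError(f"{path}: malformed row at line {lineno}: {line!r}")
            if not values:
                continue
            if ncols == 0:
                ncols = len(values)
            elif len(values) != ncols:
                raise ParseError(
                    f"{path}: expected {ncols} columns at line {lineno}, "
                    f"got {len(values)}"
                )
            rows.append(values)
    return rows, ncols


def read_rr_csv(
    path: str | Path,
    time_unit: Literal["seconds", "milliseconds"] = "seconds",
    nn_unit: Literal["seconds", "milliseconds"] = "milliseconds",
    subject_id: Optional[str] = None,
) -> BeatSeries:
    """Read a beat series from a two-column (t, nn) or one-column RR file.

    Single-column files are interval-only exports: timestamps are
    reconstructed by cumulative sum, ``t[i] = sum(nn[:i+1]) / 1000``.
    """
    path = Path(path)
    rows, ncols = _parse_numeric_rows(path)
    if not rows:
        raise ParseError(f"{path}: no numeric data rows")
    data = np.asarray(rows, dtype=float)
    nn_scale = 1000.0 if nn_unit == "seconds" else 1.0
    if ncols == 1:
        nn = data[:, 0] * nn_scale
        t = np.cumsum(nn) / 1000.0
    elif ncols == 2:
        t_scale = 0.001 if time_unit == "milliseconds" else 1.0
        t = data[:, 0] * t_scale
        nn = data[:, 1] * nn_scale
    else:
        raise ParseError(f"{path}: expected 1 or 2 columns, found {ncols}")
    if subject_id is None:
        subject_id = path.stem
    return BeatSeries(subject_id=subject_id, t=t, nn=nn)


def write_rr_csv(path: str | Path, series: BeatSeries) -> None:
    """Write a beat series as a two-column CSV with header (t_s, nn_ms)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("t_s,nn_ms\n")
        for t, nn in zip(series.t, series.nn):
            fh.write(f"{t:.6f},{nn:.6f}\n")


_SEGMENT_HEADER = "segment_start_s,window_min,mean_hr_bpm,ann_ms,n_beats,coverage"


def write_hr_segments(path: str | Path, segments) -> None:
    """Write a :class:`~wearhrv.time_domain.SegmentedHR` to CSV.

    Values are printed with 6 decimal places so that a read/write round trip
    reproduces the structure to that precision.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_SEGMENT_HEADER + "\n")
        for start, hr, ann, n, cov in zip(
            segments.start_s,
            segments.hr_bpm,
            segments.ann_ms,
            segments.n_beats,
            segments.coverage,
        ):
            fh.write(
                f"{start:.6f},{segments.window_min:g},{hr:.6f},"
                f"{ann:.6f},{int(n)},{cov:.6f}\n"
            )


def read_hr_segments(path: str | Path):
    """Read a segmented-HR CSV written by :func:`write_hr_segments`."""
    from .time_domain import SegmentedHR  # local import: avoids a module cycle

    path = Path(path)
    rows, ncols = _parse_numeric_rows(path)
    if rows and ncols != 6:
        raise ParseError(f"{path}: expected 6 columns, found {ncols}")
    data = np.asarray(rows, dtype=float).reshape(-1, 6)
    window_min = float(data[0, 1]) if len(data) else 5.0
    if len(data) and not np.all(data[:, 1] == window_min):
        raise ValidationError(f"{path}: inconsistent window_min column")
    return SegmentedHR(
        window_min=window_min,
        start_s=data[:, 0],
        n_beats=data[:, 4].astype(int),
        ann_ms=data[:, 3],
        hr_bpm=data[:, 2],
        coverage=data[:, 5],
    )
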