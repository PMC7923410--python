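"""Window segmentation, wearable HR noise model and time-domain SDNN estimators.

The four 24-h estimators:

* ``sdnn24``   — population SD of all NN intervals (the gold standard; equals
  the square root of the total spectral power).
* ``sdnni24``  — mean over windows of the per-window NN standard deviation;
  captures short-term power only.
* ``sdann24``  — SD of per-window mean NN (ANN); a low-pass-filtered SDNN.
* ``sdannhr24``— SD of ANN reconstructed from segment heart rate, optionally
  with the calibrated PPG measurement error injected on HR.

All standard deviations use the population convention (divisor N); pass
``sample=True`` for the n-1 convention.

The PPG error model is a lookup of the empirically calibrated per-window HR
error (mean bias and SD, in bpm) for 1/5/10/30/60-min windows, with
log-linear interpolation at other window lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .io_formats import BeatSeries, ValidationError

__all__ = [
    "SegmentedHR",
    "SdnnEstimates",
    "segment",
    "ppg_noise_sigma",
    "ppg_noise_bias",
    "inject_hr_noise",
    "sdnn24",
    "sdnni24",
    "sdann24",
    "sdannhr24",
    "sdnn_estimates",
    "classify_sdnn",
]

# Calibrated wearable HR error vs ECG per averaging window (bpm).
# Keys are window lengths in minutes; values are (mean bias, SD).
PPG_HR_ERROR_BPM: dict[float, tuple[float, float]] = {
    1: (0.03, 5.91),
    5: (0.33, 5.09),
    10: (-0.16, 4.71),
    30: (-0.60, 4.01),
    60: (-0.35, 3.95),
}

STANDARD_WINDOWS_MIN = (1, 5, 10, 30, 60)


@dataclass
class SegmentedHR:
    """Per-window mean-HR view of a beat series — what a wearable reports.

    Windows tile the record from the first beat timestamp as half-open
    intervals ``[start, start + 60*window_min)``. ANN is the mean NN of the
    beats falling in a window; HR = 60000/ANN. ``coverage`` is the summed NN
    duration in the window divided by the window length; windows below the
    minimum coverage are excluded (their count is kept in ``n_excluded``).

    When HR noise has been injected, ``ann_ms`` holds 60000/(noisy HR) and
    the noiseless ANN is retained in ``ann_noiseless_ms``.
    """

    window_min: float
    start_s: np.ndarray
    n_beats: np.ndarray
    ann_ms: np.ndarray
    hr_bpm: np.ndarray
    coverage: np.ndarray
    noise_sigma_bpm: float = 0.0
    seed: Optional[int] = None
    n_excluded: int = 0
    ann_noiseless_ms: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.window_min <= 0:
            raise ValidationError("window_min must be positive")
        for name in ("start_s", "n_beats", "ann_ms", "hr_bpm", "coverage"):
            setattr(self, name, np.asarray(getattr(self, name)))
        if self.ann_noiseless_ms is None:
            self.ann_noiseless_ms = self.ann_ms.copy()

    @property
    def n_segments(self) -> int:
        return int(self.start_s.size)


@dataclass(frozen=True)
class SdnnEstimates:
    """The four estimators for one subject at one window length (ms)."""

    sdnn24_ms: float
    sdnni24_ms: float
    sdann24_ms: float
    sdannhr24_ms: float
    window_min: float
    n_segments: int


def _pop_std(x: np.ndarray, sample: bool = False) -> float:
    return float(np.std(x, ddof=1 if sample else 0))


def segment(
    series: BeatSeries, window_min: float, min_coverage: float = 0.5
) -> SegmentedHR:
    """Tile the record into fixed windows and average NN per window.

    Windows start at the first beat timestamp (making every estimator
    invariant to a constant timestamp offset). A beat belongs to the window
    containing its timestamp.
    """
    if window_min <= 0:
        raise ValidationError("window_min must be positive")
    w_s = 60.0 * window_min
    if series.span_s < 2 * w_s:
        raise ValidationError("record shorter than two windows")
    idx = np.floor((series.t - series.t[0]) / w_s).astype(int)
    n_win = idx[-1] + 1
    counts = np.bincount(idx, minlength=n_win)
    nn_sums = np.bincount(idx, weights=series.nn, minlength=n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        ann = nn_sums / counts
    coverage = nn_sums / 1000.0 / w_s
    keep = (counts > 0) & (coverage >= min_coverage)
    ann = ann[keep]
    return SegmentedHR(
        window_min=window_min,
        start_s=series.t[0] + w_s * np.flatnonzero(keep),
        n_beats=counts[keep],
        ann_ms=ann,
        hr_bpm=60000.0 / ann,
        coverage=coverage[keep],
        n_excluded=int(n_win - keep.sum()),
    )


def _log_interp(window_min: float, table: dict[float, tuple[float, float]], col: int) -> float:
    if window_min <= 0:
        raise ValidationError("window_min must be positive")
    wins = np.array(sorted(table))
    vals = np.array([table[w][col] for w in wins])
    if window_min in table:
        return float(table[window_min][col])
    # log-linear in window length; flat beyond the calibrated range
    return float(np.interp(np.log(window_min), np.log(wins), vals))


def ppg_noise_sigma(window_min: float) -> float:
    """SD of the wearable HR error (bpm) for an averaging window (minutes)."""
    return _log_interp(window_min, PPG_HR_ERROR_BPM, 1)


def ppg_noise_bias(window_min: float) -> float:
    """Mean bias of the wearable HR error (bpm); not injected by default."""
    return _log_interp(window_min, PPG_HR_ERROR_BPM, 0)


def inject_hr_noise(
    segments: SegmentedHR,
    sigma_bpm: float,
    seed: int,
    bias_bpm: float = 0.0,
) -> SegmentedHR:
    """Add zero-mean Gaussian error to each segment's HR (deterministic per seed).

    The noisy ANN is recomputed as 60000/(HR + eps); the noiseless ANN is
    retained for validation. A zero-mean error is the default; the calibrated
    mean bias can be added via ``bias_bpm``.
    """
    if sigma_bpm < 0:
        raise ValidationError("sigma_bpm must be non-negative")
    if sigma_bpm == 0 and bias_bpm == 0:
        return segments
    rng = np.random.default_rng(seed)
    eps = rng.normal(bias_bpm, sigma_bpm, size=segments.n_segments)
    hr_noisy = np.maximum(segments.hr_bpm + eps, 5.0)  # keep HR physical
    return SegmentedHR(
        window_min=segments.window_min,
        start_s=segments.start_s,
        n_beats=segments.n_beats,
        ann_ms=60000.0 / hr_noisy,
        hr_bpm=hr_noisy,
        coverage=segments.coverage,
        noise_sigma_bpm=sigma_bpm,
        seed=seed,
        n_excluded=segments.n_excluded,
        ann_noiseless_ms=segments.ann_noiseless_ms.copy(),
    )


def sdnn24(series: BeatSeries, sample: bool = False) -> float:
    """Standard deviation of all NN intervals over the record (ms)."""
    if series.n_beats < 2:
        raise ValidationError("need at least 2 beats")
    return _pop_std(series.nn, sample)


def sdnni24(
    series: BeatSeries,
    window_min: float,
    min_coverage: float = 0.5,
    sample: bool = False,
) -> float:
    """Mean over windows of the per-window SD of NN intervals (ms).

    Windows follow the same tiling and coverage rule as :func:`segment`;
    windows with fewer than 2 beats are excluded.
    """
    seg = segment(series, window_min, min_coverage)
    w_s = 60.0 * window_min
    idx = np.floor((series.t - series.t[0]) / w_s).astype(int)
    kept_windows = np.round((seg.start_s - series.t[0]) / w_s).astype(int)
    sds = []
    for w in kept_windows:
        nn_w = series.nn[idx == w]
        if nn_w.size >= 2:
            sds.append(_pop_std(nn_w, sample))
    if len(sds) < 2:
        raise ValidationError("need at least 2 windows with >= 2 beats")
    return float(np.mean(sds))


def sdann24(segments: SegmentedHR, sample: bool = False) -> float:
    """SD of per-window mean NN values (noiseless ANN), in ms."""
    if segments.n_segments < 2:
        raise ValidationError("need at least 2 segments")
    return _pop_std(segments.ann_noiseless_ms, sample)


def sdannhr24(segments: SegmentedHR, sample: bool = False) -> float:
    """SD of ANN values derived from segment HR (ms).

    With zero injected noise this equals :func:`sdann24` exactly, since
    60000/(60000/ANN) = ANN.
    """
    if segments.n_segments < 2:
        raise ValidationError("need at least 2 segments")
    return _pop_std(60000.0 / segments.hr_bpm, sample)


def sdnn_estimates(
    series: BeatSeries,
    window_min: float,
    min_coverage: float = 0.5,
    noise: Literal["none", "table"] | float = "none",
    seed: int = 0,
) -> SdnnEstimates:
    """All four estimators for one subject at one window length.

    ``noise`` selects the HR error SD: ``"none"``, ``"table"`` (the
    calibrated PPG error for this window) or an explicit SD in bpm.
    """
    seg = segment(series, window_min, min_coverage)
    if noise == "table":
        sigma = ppg_noise_sigma(window_min)
    elif noise == "none":
        sigma = 0.0
    else:
        sigma = float(noise)
    noisy = inject_hr_noise(seg, sigma, seed)
    return SdnnEstimates(
        sdnn24_ms=sdnn24(series),
        sdnni24_ms=sdnni24(series, window_min, min_coverage),
        sdann24_ms=sdann24(seg),
        sdannhr24_ms=sdannhr24(noisy),
        window_min=window_min,
        n_segments=seg.n_segments,
    )


def classify_sdnn(sdnn_ms: float) -> str:
    """Kleiger interpretation bands for 24-h SDNN.

    Below 50 ms -> ``"unhealthy"``; 50-100 ms -> ``"compromised"``;
    above 100 ms -> ``"healthy"``.
    """
    if sdnn_ms < 0:
        raise ValidationError("SDNN must be non-negative")
    if sdnn_ms < 50.0:
        return "unhealthy"
    if sdnn_ms <= 100.0:
        return "compromised"
    return "healthy"
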