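"""Outlier/ectopic beat detection and quadratic reconstruction.

Artefact handling follows the de-facto HRV standard: a plausibility range
filter on NN intervals ([300, 2000] ms by default) plus the Malik rule for
ectopic beats (an interval differing from the previous accepted interval by
more than 20%). Flagged beats strictly inside the record are reconstructed by
a least-squares quadratic of NN against beat timestamp fitted through the two
clean beats on each side of the gap; gaps longer than ``max_gap_s`` are
dropped rather than fabricated. After reconstruction, timestamps of retained
beats are recomputed by cumulative sum so the timestamp/interval invariant
holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    FLAG_ECTOPIC,
    FLAG_INTERPOLATED,
    FLAG_OUTLIER,
    BeatSeries,
    ValidationError,
)

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "flag_outliers",
    "flag_ectopic",
    "interpolate_flagged",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the artefact-removal pipeline.

    Attributes
    ----------
    nn_min_ms, nn_max_ms : float
        Physiological plausibility bounds on NN intervals (ms).
    ectopic_rule : str
        Only ``"malik"`` (relative difference to the previous clean beat) is
        implemented.
    ectopic_threshold : float
        Relative-difference threshold of the Malik rule (fraction).
    interpolation : str
        Reconstruction method; fixed to ``"quadratic"``.
    max_gap_s : float
        Flagged runs spanning more than this many seconds are dropped as true
        gaps instead of being interpolated.
    """

    nn_min_ms: float = 300.0
    nn_max_ms: float = 2000.0
    ectopic_rule: str = "malik"
    ectopic_threshold: float = 0.20
    interpolation: str = "quadratic"
    max_gap_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.nn_min_ms < self.nn_max_ms):
            raise ValidationError("require 0 < nn_min_ms < nn_max_ms")
        if not (0 < self.ectopic_threshold < 1):
            raise ValidationError("ectopic_threshold must be in (0, 1)")
        if self.ectopic_rule != "malik":
            raise ValidationError(f"unknown ectopic rule {self.ectopic_rule!r}")
        if self.interpolation != "quadratic":
            raise ValidationError("only quadratic interpolation is supported")


@dataclass
class PreprocessReport:
    """Counts of beats flagged by each rule.

    ``pct_flagged`` is the percentage of beats in the union of the outlier
    and ectopic masks.
    """

    n_total: int
    n_outlier: int
    n_ectopic: int
    n_dropped: int = 0
    pct_flagged: float = field(init=False, default=0.0)
    _n_union: int = 0

    def __post_init__(self) -> None:
        self.pct_flagged = 100.0 * self._n_union / self.n_total if self.n_total else 0.0


def flag_outliers(series: BeatSeries, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Boolean mask, true where nn is outside [nn_min_ms, nn_max_ms]."""
    return (series.nn < cfg.nn_min_ms) | (series.nn > cfg.nn_max_ms)


def flag_ectopic(
    series: BeatSeries,
    cfg: PreprocessConfig = PreprocessConfig(),
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Malik-rule ectopic mask: |nn[i] - ref| > threshold * ref.

    The reference is the previous *clean* beat: beats already flagged (by
    this rule or by the ``exclude`` mask, typically the outlier mask) do not
    serve as reference, which prevents one ectopic beat from cascading flags
    over its normal successors. Beat 0 is never flagged.
    """
    nn = series.nn
    if nn.size < 2:
        raise ValidationError("ectopic rule needs at least 2 beats")
    if exclude is None:
        exclude = np.zeros(nn.size, dtype=bool)
    mask = np.zeros(nn.size, dtype=bool)
    ref = nn[0] if not exclude[0] else np.nan
    for i in range(1, nn.size):
        if exclude[i]:
            continue
        if np.isnan(ref):
            ref = nn[i]
            continue
        if abs(nn[i] - ref) > cfg.ectopic_threshold * ref:
            mask[i] = True
        else:
            ref = nn[i]
    return mask


def _flagged_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous flagged index runs as (start, stop) half-open pairs."""
    runs = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def interpolate_flagged(
    series: BeatSeries,
    mask: np.ndarray,
    max_gap_s: float = 10.0,
    flag_value: str = FLAG_INTERPOLATED,
) -> BeatSeries:
    """Replace flagged beats by a quadratic interpolant of nn over time.

    Per flagged run, a least-squares quadratic is fitted through the two
    clean beats on each side (4 support points) and evaluated at the flagged
    timestamps. Leading/trailing flagged beats and runs spanning more than
    ``max_gap_s`` seconds are dropped. Timestamps of retained beats are then
    recomputed by cumulative sum of nn so that consecutive-beat consistency
    holds exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != series.n_beats:
        raise ValidationError("mask length mismatch")
    if (~mask).sum() < 3:
        raise ValidationError("need at least 3 unflagged beats")
    if not mask.any():
        return series.copy()

    t = series.t
    nn = series.nn.copy()
    flags = series.quality_flags.copy()
    drop = np.zeros(mask.size, dtype=bool)
    clean_idx = np.flatnonzero(~mask)

    for start, stop in _flagged_runs(mask):
        interior = start > clean_idx[0] and stop - 1 < clean_idx[-1]
        gap_span = t[min(stop, mask.size - 1)] - t[max(start - 1, 0)]
        if not interior or gap_span > max_gap_s:
            drop[start:stop] = True
            continue
        left = clean_idx[clean_idx < start][-2:]
        right = clean_idx[clean_idx >= stop][:2]
        support = np.concatenate([left, right])
        if support.size < 3:
            drop[start:stop] = True
            continue
        # fit in a shifted frame for conditioning
        t0 = t[support].mean()
        coeffs = np.polyfit(t[support] - t0, nn[support], deg=2)
        nn[start:stop] = np.polyval(coeffs, t[start:stop] - t0)
        flags[start:stop] = flag_value

    keep = ~drop
    nn = nn[keep]
    flags = flags[keep]
    if nn.size < 3 or np.any(nn <= 0):
        raise ValidationError("too few valid beats after interpolation")
    t_first = t[keep][0]
    t_new = t_first + np.concatenate([[0.0], np.cumsum(nn[1:]) / 1000.0])
    return BeatSeries(
        subject_id=series.subject_id,
        t=t_new,
        nn=nn,
        quality_flags=flags,
        start_time=series.start_time,
    )


def preprocess(
    series: BeatSeries, cfg: PreprocessConfig = PreprocessConfig()
) -> tuple[BeatSeries, PreprocessReport]:
    """Full artefact pipeline: range filter, Malik rule, quadratic repair."""
    outlier = flag_outliers(series, cfg)
    ectopic = flag_ectopic(series, cfg, exclude=outlier)
    union = outlier | ectopic

    flags = series.quality_flags.copy()
    flags[outlier] = FLAG_OUTLIER
    flags[ectopic & ~outlier] = FLAG_ECTOPIC
    marked = BeatSeries(
        subject_id=series.subject_id,
        t=series.t,
        nn=series.nn,
        quality_flags=flags,
        start_time=series.start_time,
    )
    cleaned = interpolate_flagged(marked, union, max_gap_s=cfg.max_gap_s)
    report = PreprocessReport(
        n_total=series.n_beats,
        n_outlier=int(outlier.sum()),
        n_ectopic=int(ectopic.sum()),
        n_dropped=series.n_beats - cleaned.n_beats,
        _n_union=int(union.sum()),
    )
    return cleaned, report
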