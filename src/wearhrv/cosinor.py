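"""Single-component cosinor fit of the 24-h heart-rate circadian rhythm.

The model is HR(t) = M + A cos(2 pi (t/T + phi)) + e, with the period T
fixed (24 h by default). M is the MESOR (rhythm-adjusted mean, bpm), A >= 0
the amplitude (half the predictable within-cycle swing, bpm) and phi the
acrophase in cycles. The fit is the exact linear least-squares solution via
the cos/sin linearisation HR = M + b cos(2 pi t/T) + g sin(2 pi t/T), so it
is deterministic and needs no starting values.

An optional list of harmonic periods (e.g. 12 h) can be fitted jointly;
their amplitudes are reported but not used by the downstream risk features,
which consume only MESOR and the 24-h amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import ValidationError

__all__ = ["CosinorFit", "fit_cosinor"]


@dataclass(frozen=True)
class CosinorFit:
    """Fitted circadian parameters.

    ``acrophase_cycles`` is in [0, 1) cycles of the period;
    ``acrophase_h`` is the time (hours after t=0) at which the fitted
    rhythm peaks.
    """

    mesor_bpm: float
    amplitude_bpm: float
    acrophase_cycles: float
    period_h: float
    residual_sd_bpm: float
    harmonic_amplitudes_bpm: tuple[float, ...] = ()

    @property
    def acrophase_h(self) -> float:
        return float((-self.acrophase_cycles) % 1.0 * self.period_h)

    def predict(self, times_s: np.ndarray) -> np.ndarray:
        t = np.asarray(times_s, dtype=float)
        period_s = self.period_h * 3600.0
        return self.mesor_bpm + self.amplitude_bpm * np.cos(
            2.0 * np.pi * (t / period_s + self.acrophase_cycles)
        )


def fit_cosinor(
    times_s: np.ndarray,
    hr_bpm: np.ndarray,
    period_h: float = 24.0,
    harmonics_h: Sequence[float] = (),
) -> CosinorFit:
    """Least-squares cosinor fit at a fixed period.

    Requires at least 4 samples spanning at least half a period, and a
    non-degenerate phase design.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(hr_bpm, dtype=float)
    if t.ndim != 1 or t.size != y.size:
        raise ValidationError("times and HR must be 1-D arrays of equal length")
    if t.size < 4:
        raise ValidationError("need at least 4 samples")
    if period_h <= 0:
        raise ValidationError("period must be positive")
    span_h = (t.max() - t.min()) / 3600.0
    if span_h < period_h / 2.0:
        raise ValidationError("samples must span at least half a period")

    period_s = period_h * 3600.0
    cols = [np.ones_like(t)]
    for p_h in (period_h, *harmonics_h):
        w = 2.0 * np.pi / (p_h * 3600.0)
        cols.extend([np.cos(w * t), np.sin(w * t)])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("rank-deficient cosinor design (degenerate phases)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)

    mesor = beta[0]
    b, g = beta[1], beta[2]
    amplitude = float(np.hypot(b, g))
    acrophase = float(np.arctan2(-g, b) / (2.0 * np.pi) % 1.0)
    residuals = y - X @ beta
    harm_amps = tuple(
        float(np.hypot(beta[1 + 2 * k], beta[2 + 2 * k]))
        for k in range(1, 1 + len(harmonics_h))
    )
    return CosinorFit(
        mesor_bpm=float(mesor),
        amplitude_bpm=amplitude,
        acrophase_cycles=acrophase,
        period_h=float(period_h),
        residual_sd_bpm=float(np.std(residuals)),
        harmonic_amplitudes_bpm=harm_amps,
    )
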