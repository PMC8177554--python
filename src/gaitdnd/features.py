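"""Statistical amplitude descriptors and 1×8 feature-vector assembly.

Each analysis window is summarized, per signal family (raw VGRF or one of
the stride/stance/swing duration series) and per foot, by four amplitude
statistics: root mean square, variance, skewness, and kurtosis.  The
window's feature vector concatenates the left-foot block with the
right-foot block: ``[rms_L, var_L, skew_L, kurt_L, rms_R, var_R, skew_R,
kurt_R]``.

Moment conventions
------------------
The variance uses the unbiased 1/(N−1) divisor.  Skewness and kurtosis
use 1/N central moments in the numerator but normalize by powers of that
*sample* variance::

    Sk = (1/N) Σ (x_i − μ)³ / Var^(3/2)
    Ku = (1/N) Σ (x_i − μ)⁴ / Var²        (non-excess)

This hybrid population/sample composition is deliberate and is NOT what
``scipy.stats.skew``/``kurtosis`` compute by default (they normalize by
the 1/N variance); the difference is O(1/N) but nonzero, so library
defaults are not substituted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import FEATURE_NAMES, SIGNAL_TYPES

logger = logging.getLogger(__name__)

#: Minimum series length for a full descriptor set (kurtosis needs N ≥ 4).
MIN_SAMPLES = 4


def rms(x: np.ndarray) -> float:
    """Root mean square: sqrt((1/N) Σ x_i²)."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("rms requires at least one sample")
    return float(np.sqrt(np.mean(np.square(x))))


def variance(x: np.ndarray) -> float:
    """Unbiased sample variance: (1/(N−1)) Σ (x_i − μ)²."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("variance requires at least two samples")
    return float(np.var(x, ddof=1))


def skewness(x: np.ndarray) -> float:
    """(1/N) Σ (x_i − μ)³ / Var^(3/2), with Var the N−1 sample variance."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires at least three samples")
    var = variance(x)
    if var == 0.0:
        raise ValueError("degenerate (constant) signal: zero variance")
    mu = np.mean(x)
    return float(np.mean((x - mu) ** 3) / var**1.5)


def kurtosis(x: np.ndarray) -> float:
    """(1/N) Σ (x_i − μ)⁴ / Var², non-excess, Var the N−1 sample variance."""
    x = np.asarray(x, dtype=float)
    if x.size < MIN_SAMPLES:
        raise ValueError("kurtosis requires at least four samples")
    var = variance(x)
    if var == 0.0:
        raise ValueError("degenerate (constant) signal: zero variance")
    mu = np.mean(x)
    return float(np.mean((x - mu) ** 4) / var**2)


#: Descriptor callables in canonical order.
DESCRIPTORS = (rms, variance, skewness, kurtosis)


@dataclass
class FeatureVector:
    """The 1×8 statistical descriptor vector for one window and signal type."""

    subject_id: str
    window_index: int
    condition: str
    signal_type: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (8,):
            raise ValueError("feature vector must hold exactly 8 values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")
        if self.signal_type not in SIGNAL_TYPES:
            raise ValueError(f"unknown signal type {self.signal_type!r}")


def channel_features(x: np.ndarray) -> np.ndarray:
    """[rms, var, skew, kurt] for one channel."""
    return np.asarray([f(x) for f in DESCRIPTORS])


def feature_vector(
    left: np.ndarray,
    right: np.ndarray,
    subject_id: str = "",
    window_index: int = 0,
    condition: str = "CON",
    signal_type: str = "vgrf",
) -> FeatureVector:
    """Assemble the channel-major 8-vector; descriptor errors identify the
    offending foot."""
    blocks = []
    for foot, series in (("left", left), ("right", right)):
        try:
            blocks.append(channel_features(series))
        except ValueError as exc:
            raise ValueError(f"{foot} channel: {exc}") from exc
    return FeatureVector(
        subject_id=subject_id,
        window_index=window_index,
        condition=condition,
        signal_type=signal_type,
        values=np.concatenate(blocks),
    )


def window_features(signals, signal_types=SIGNAL_TYPES) -> dict:
    """Feature vectors for one window's extracted signals, keyed by signal
    type; duration families too short for the descriptors are skipped
    (logged), raw VGRF is always produced."""
    out = {}
    window = signals.window
    for signal_type in signal_types:
        left = signals.series(signal_type, "left")
        right = signals.series(signal_type, "right")
        if signal_type != "vgrf" and (
            left.size < MIN_SAMPLES or right.size < MIN_SAMPLES
        ):
            logger.info(
                "window %s: %s series too short (%d/%d cycles) for features",
                window.window_id, signal_type, left.size, right.size,
            )
            continue
        try:
            out[signal_type] = feature_vector(
                left,
                right,
                subject_id=window.subject_id,
                window_index=window.window_index,
                condition=window.condition,
                signal_type=signal_type,
            )
        except ValueError as exc:
            logger.info("window %s: %s features skipped: %s",
                        window.window_id, signal_type, exc)
    return out
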