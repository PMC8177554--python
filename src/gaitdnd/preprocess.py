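"""Record conditioning: edge trimming, despiking, windowing, rejection.

The preparation recipe for continuous hallway-walking VGRF records is:
drop the first and last 15 s (gait initiation/termination artifacts),
median-filter turn-back force spikes, cut the remainder into 30-s
non-overlapping windows, and drop windows that are still dominated by
artifacts.  Each surviving window is treated as an independent sample.

Manual noisy-window screening is replaced by a reproducible surrogate: a
window is rejected when more than ``max_spike_fraction`` of its samples
exceed three times its upper state level, or when its id appears on an
explicit exclude list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import GaitRecord

logger = logging.getLogger(__name__)


@dataclass
class SignalWindow:
    """One fixed-length analysis window cut from a record."""

    subject_id: str
    condition: str
    window_index: int
    fs_hz: float
    left: np.ndarray
    right: np.ndarray

    @property
    def duration_s(self) -> float:
        return self.left.size / self.fs_hz

    @property
    def window_id(self) -> str:
        return f"{self.subject_id}:{self.window_index}"


def trim_edges(record: GaitRecord, trim_s: float = 15.0) -> GaitRecord:
    """Remove ``round(trim_s × fs)`` samples from both ends of both channels."""
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    k = int(round(trim_s * record.fs_hz))
    if k == 0:
        return record
    if record.n_samples <= 2 * k:
        raise ValueError(
            f"record {record.subject_id} too short to trim {trim_s} s "
            f"from each end ({record.duration_s:.1f} s total)"
        )
    return replace(record, left=record.left[k:-k], right=record.right[k:-k])


def despike_median(signal: np.ndarray, kernel_samples: int = 5) -> np.ndarray:
    """Running median of odd width; edge windows shrink rather than pad.

    A centered window of ``kernel_samples`` is used where it fits; near the
    edges the window is truncated to the available samples, so output
    length always equals input length and a kernel of 1 is the identity.
    """
    if kernel_samples % 2 == 0 or kernel_samples < 1:
        raise ValueError("kernel_samples must be odd and >= 1")
    if kernel_samples == 1:
        return np.asarray(signal, dtype=float).copy()
    out = (
        pd.Series(np.asarray(signal, dtype=float))
        .rolling(window=kernel_samples, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return out


def despike_record(record: GaitRecord, kernel_samples: int = 5) -> GaitRecord:
    return replace(
        record,
        left=despike_median(record.left, kernel_samples),
        right=despike_median(record.right, kernel_samples),
    )


def segment_windows(record: GaitRecord, win_s: float = 30.0) -> list[SignalWindow]:
    """Cut a record into non-overlapping complete windows of ``win_s`` seconds.

    The trailing remainder shorter than one window is discarded.  Returns
    an empty list (with a warning) for records shorter than one window.
    """
    if win_s <= 0:
        raise ValueError("win_s must be positive")
    n_win_samples = int(round(win_s * record.fs_hz))
    n_windows = record.n_samples // n_win_samples
    if n_windows == 0:
        logger.warning(
            "record %s (%.1f s) shorter than one %.0f-s window; no windows",
            record.subject_id, record.duration_s, win_s,
        )
        return []
    windows = []
    for i in range(n_windows):
        sl = slice(i * n_win_samples, (i + 1) * n_win_samples)
        windows.append(
            SignalWindow(
                subject_id=record.subject_id,
                condition=record.condition,
                window_index=i,
                fs_hz=record.fs_hz,
                left=record.left[sl],
                right=record.right[sl],
            )
        )
    return windows


def spike_fraction(window: SignalWindow, max_spike_fraction: float = 0.05) -> float:
    """Fraction of samples (either foot) above 3× the window's upper state
    level — the automated surrogate for visual artifact screening.

    The upper state level is estimated with the top ``2 × max_spike_fraction``
    amplitude quantile excluded (never more than the top half), so that the
    artifact being screened for cannot inflate the level it is tested
    against: a long saturated segment would otherwise become the upper
    histogram mode itself.
    """
    from .events import estimate_bilevels

    q = max(1.0 - 2.0 * max_spike_fraction, 0.5)
    fracs = []
    for channel in (window.left, window.right):
        trimmed = channel[channel <= np.quantile(channel, q)]
        try:
            est = estimate_bilevels(trimmed)
        except ValueError:
            fracs.append(0.0)
            continue
        fracs.append(float(np.mean(channel > 3.0 * est.upper)))
    return max(fracs)


def reject_noisy_windows(
    windows: list[SignalWindow],
    max_spike_fraction: float = 0.05,
    exclude_ids: set[str] | None = None,
) -> tuple[list[SignalWindow], list[dict]]:
    """Drop artifact-dominated or explicitly excluded windows.

    Returns ``(kept, dropped)`` where each dropped entry records the window
    id and the reason, for the run manifest.
    """
    if not 0.0 <= max_spike_fraction <= 1.0:
        raise ValueError("max_spike_fraction must lie in [0, 1]")
    exclude_ids = exclude_ids or set()
    kept, dropped = [], []
    for window in windows:
        if window.window_id in exclude_ids:
            reason = "on exclude list"
        else:
            frac = spike_fraction(window, max_spike_fraction)
            if frac > max_spike_fraction:
                reason = f"spike fraction {frac:.3f} > {max_spike_fraction}"
            else:
                kept.append(window)
                continue
        logger.info("rejecting window %s: %s", window.window_id, reason)
        dropped.append({"window_id": window.window_id, "reason": reason})
    return kept, dropped


def load_exclude_list(path) -> set[str]:
    """One window id (``subject:index``) per line; blank lines and # comments
    ignored."""
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
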