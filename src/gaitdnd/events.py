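"""Gait-event detection from VGRF windows via bilevel waveform estimation.

A walking VGRF trace alternates between two amplitude states — loaded
(stance) and unloaded (swing) — so it can be idealized as a bilevel
waveform.  The two state levels are estimated non-parametrically from the
amplitude histogram of the window:

1. histogram range ``A_R = A_max − A_min``;
2. bin width from Scott's normal reference rule ``3.49 · σ̂ · n^(−1/3)``
   (σ̂ the sample standard deviation, n the sample count);
3. bin count ``M = ceil(A_R / bin_width)``, at least 2;
4. the occupied bin range ``[i_low, i_high]`` is split at the midpoint
   index into a lower and an upper sub-histogram; each state level is the
   center of the most populated bin of its sub-histogram (lowest index on
   ties).

A reference level is then set 10% of the state separation above the lower
level; upward crossings of this reference are heel strikes, downward
crossings are toe-offs.  Crossing times are refined by linear
interpolation between the straddling samples, so event timing is not
quantized to the sampling grid.  From the alternating event sequence the
per-cycle stance (heel-strike → toe-off), swing (toe-off → next
heel-strike) and stride (heel-strike → heel-strike) duration series
follow, with stride = stance + swing by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import SignalWindow

logger = logging.getLogger(__name__)

#: Reference level position within the state separation.
REFERENCE_FRACTION = 0.10

#: Default debounce interval: candidate crossings closer than this to the
#: previous accepted event are treated as noise chatter.  Shorter than any
#: physiological stance or swing phase at normal pace.
DEFAULT_MIN_PHASE_S = 0.1


@dataclass
class BilevelEstimate:
    """Histogram-derived state levels of one signal window."""

    lower: float            # lower state level S_L
    upper: float            # upper state level S_U
    reference: float        # S_L + 0.10 (S_U − S_L)
    amp_range: float        # A_R = A_max − A_min
    bin_width: float        # Scott's rule width
    n_bins: int             # M
    i_low: int              # lowest occupied bin index
    i_high: int             # highest occupied bin index


@dataclass
class EventSequence:
    """Alternating heel-strike / toe-off times (seconds) for one foot."""

    foot: str
    heel_strikes: np.ndarray
    toe_offs: np.ndarray

    def __len__(self) -> int:
        return self.heel_strikes.size + self.toe_offs.size


@dataclass
class DurationSeries:
    """Per-cycle stride/stance/swing durations (seconds) for one foot."""

    foot: str
    stride_s: np.ndarray
    stance_s: np.ndarray
    swing_s: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.stride_s.size


def estimate_bilevels(signal: np.ndarray) -> BilevelEstimate:
    """Estimate lower/upper state levels of a bilevel-like signal.

    Raises ``ValueError`` for signals without bilevel structure (constant,
    or collapsing into fewer than two occupied histogram bins).
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"signal too short for histogram state levels (n={n})")
    a_min, a_max = float(np.min(x)), float(np.max(x))
    amp_range = a_max - a_min
    sd = float(np.std(x, ddof=1))
    if amp_range == 0.0 or sd == 0.0:
        raise ValueError("no bilevel structure: constant signal")
    bin_width = scott_bin_width(sd, n)
    n_bins = max(2, math.ceil(amp_range / bin_width))
    counts, edges = np.histogram(x, bins=n_bins, range=(a_min, a_max))
    occupied = np.flatnonzero(counts)
    if occupied.size < 2:
        raise ValueError("no bilevel structure: fewer than 2 occupied bins")
    i_low, i_high = int(occupied[0]), int(occupied[-1])
    split = i_low + (i_high - i_low) // 2
    centers = 0.5 * (edges[:-1] + edges[1:])
    lower_slice = slice(i_low, split + 1)
    upper_slice = slice(split + 1, i_high + 1)
    s_low = float(centers[lower_slice][np.argmax(counts[lower_slice])])
    s_high = float(centers[upper_slice][np.argmax(counts[upper_slice])])
    reference = s_low + REFERENCE_FRACTION * (s_high - s_low)
    return BilevelEstimate(
        lower=s_low,
        upper=s_high,
        reference=reference,
        amp_range=amp_range,
        bin_width=bin_width,
        n_bins=n_bins,
        i_low=i_low,
        i_high=i_high,
    )


def scott_bin_width(sd: float, n: int) -> float:
    """Scott's normal reference rule: 3.49 · σ̂ · n^(−1/3)."""
    return 3.49 * sd * n ** (-1.0 / 3.0)


def _crossings(x: np.ndarray, level: float, fs_hz: float):
    """All reference crossings as (time, kind) with linear interpolation;
    kind is +1 for upward (heel strike), −1 for downward (toe-off)."""
    above = x > level
    idx = np.flatnonzero(above[1:] != above[:-1])
    events = []
    for i in idx:
        frac = (level - x[i]) / (x[i + 1] - x[i])
        t = (i + frac) / fs_hz
        events.append((t, +1 if above[i + 1] else -1))
    return events


def detect_events(
    signal: np.ndarray,
    bilevels: BilevelEstimate,
    fs_hz: float,
    min_phase_s: float = DEFAULT_MIN_PHASE_S,
    foot: str = "left",
) -> EventSequence:
    """Locate heel strikes (upward 10%-reference crossings) and toe-offs
    (downward crossings), debounced and trimmed to start at a heel strike.

    Debounce: an opposite-kind candidate closer than ``min_phase_s`` to
    the last accepted event is discarded; a same-kind candidate supersedes
    the previous one (noise chatter around the reference emits runs of
    same-direction crossings, and the last crossing before the state
    actually switches is the genuine event).
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if min_phase_s < 0:
        raise ValueError("min_phase_s must be non-negative")
    x = np.asarray(signal, dtype=float)
    accepted: list[tuple[float, int]] = []
    for t, kind in _crossings(x, bilevels.reference, fs_hz):
        if accepted:
            last_t, last_kind = accepted[-1]
            if kind == last_kind:
                accepted[-1] = (t, kind)
                continue
            if t - last_t < min_phase_s:
                continue
        accepted.append((t, kind))
    # trim leading toe-offs so the sequence starts with a heel strike
    while accepted and accepted[0][1] == -1:
        accepted.pop(0)
    hs = np.asarray([t for t, kind in accepted if kind == +1])
    to = np.asarray([t for t, kind in accepted if kind == -1])
    if hs.size == 0:
        logger.warning("no gait events detected on %s foot", foot)
    return EventSequence(foot=foot, heel_strikes=hs, toe_offs=to)


def durations_from_events(events: EventSequence) -> DurationSeries:
    """Derive stride/stance/swing series from alternating events.

    For cycle k: stance = TO_k − HS_k, swing = HS_{k+1} − TO_k, stride =
    HS_{k+1} − HS_k.  The trailing incomplete cycle is dropped.
    """
    hs, to = events.heel_strikes, events.toe_offs
    n = min(hs.size - 1, to.size)
    if n < 1:
        logger.warning(
            "fewer than 2 heel strikes on %s foot; empty duration series",
            events.foot,
        )
        n = 0
    stance = to[:n] - hs[:n]
    swing = hs[1 : n + 1] - to[:n]
    stride = hs[1 : n + 1] - hs[:n]
    if n and (np.any(stance <= 0) or np.any(swing <= 0)):
        raise ValueError(
            f"non-positive phase duration on {events.foot} foot; "
            "event sequence violates alternation"
        )
    return DurationSeries(
        foot=events.foot, stride_s=stride, stance_s=stance, swing_s=swing
    )


@dataclass
class WindowSignals:
    """All four signal families extracted from one window."""

    window: SignalWindow
    vgrf: dict          # foot -> raw force samples
    events: dict        # foot -> EventSequence
    durations: dict     # foot -> DurationSeries
    bilevels: dict      # foot -> BilevelEstimate | None

    def series(self, signal_type: str, foot: str) -> np.ndarray:
        """The per-foot sample series for one of vgrf/stride/stance/swing."""
        if signal_type == "vgrf":
            return self.vgrf[foot]
        return getattr(self.durations[foot], f"{signal_type}_s")


def extract_all_signals(
    window: SignalWindow,
    min_phase_s: float = DEFAULT_MIN_PHASE_S,
    min_cycles: int = 3,
) -> WindowSignals:
    """Run bilevel estimation, event detection, and duration derivation on
    both feet of one window.

    Feet are processed independently.  A foot yielding fewer than
    ``min_cycles`` complete cycles keeps its (short) duration series but is
    logged as unusable for duration features.
    """
    vgrf, events, durations, bilevels = {}, {}, {}, {}
    empty = lambda foot: EventSequence(foot, np.empty(0), np.empty(0))
    for foot in ("left", "right"):
        channel = np.asarray(getattr(window, foot), dtype=float)
        vgrf[foot] = channel
        try:
            est = estimate_bilevels(channel)
        except ValueError as exc:
            logger.warning(
                "window %s %s foot: %s; no events", window.window_id, foot, exc
            )
            bilevels[foot] = None
            events[foot] = empty(foot)
            durations[foot] = durations_from_events(events[foot])
            continue
        bilevels[foot] = est
        events[foot] = detect_events(
            channel, est, window.fs_hz, min_phase_s=min_phase_s, foot=foot
        )
        durations[foot] = durations_from_events(events[foot])
        if durations[foot].n_cycles < min_cycles:
            logger.warning(
                "window %s %s foot: only %d complete cycles (<%d); "
                "unusable for duration features",
                window.window_id, foot, durations[foot].n_cycles, min_cycles,
            )
    return WindowSignals(
        window=window, vgrf=vgrf, events=events,
        durations=durations, bilevels=bilevels,
    )
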