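"""Descriptive follow-up after rejection: relevant frames and channels.

Both thresholds (top 5% of frames, top 25% of channels) are descriptive
conventions, not inference; they are exposed as parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .similarity import ClosenessSeries, GroupDataset, closeness_series

__all__ = [
    "FrameSet",
    "ChannelRelevance",
    "top_frames",
    "frame_timestamps",
    "format_mmss",
    "channel_relevance",
]


def _ceil_fraction(fraction: float, total: int) -> int:
    """ceil(fraction * total) guarded against float round-up (0.05*100 -> 5)."""
    return math.ceil(fraction * total - 1e-9)


@dataclass
class FrameSet:
    """The highest-closeness frames of a recording."""

    frames: np.ndarray
    threshold_quantile: float
    closeness_at_threshold: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)


@dataclass
class ChannelRelevance:
    """Leave-one-channel-out relevance summary.

    ``relevance_frequency[c]`` is the fraction of frames in which channel c
    ranks in the per-frame top-``top_fraction`` set of closeness drops;
    ``membership_counts`` holds the underlying integer counts.
    """

    channel_ids: list[str]
    loo_series: list[ClosenessSeries]
    relevance_frequency: np.ndarray
    membership_counts: np.ndarray
    top_fraction: float

    def __post_init__(self):
        self.relevance_frequency = np.asarray(self.relevance_frequency, dtype=float)
        self.membership_counts = np.asarray(self.membership_counts, dtype=int)


def top_frames(series: ClosenessSeries, threshold_quantile: float = 0.95) -> FrameSet:
    """Select the k = ceil((1 - quantile) * T) frames with highest closeness.

    Ties are broken in favor of the earlier frame index; the returned frames
    are sorted ascending.
    """
    if not 0 < threshold_quantile < 1:
        raise ValueError(
            f"threshold_quantile must be in (0, 1), got {threshold_quantile}"
        )
    t = len(series)
    if t == 0:
        raise ValueError("empty closeness series")
    k = max(1, _ceil_fraction(1.0 - threshold_quantile, t))
    # stable argsort on negated values: highest first, ties earliest-first
    order = np.argsort(-series.values, kind="stable")[:k]
    selected = series.frame_indices[order]
    return FrameSet(
        frames=np.sort(selected),
        threshold_quantile=threshold_quantile,
        closeness_at_threshold=float(series.values[order].min()),
    )


def frame_timestamps(
    frames: FrameSet | np.ndarray,
    fs: float,
    hrf_delay: float = 5.0,
    t0: float = 0.0,
) -> np.ndarray:
    """Map frame indices to the stimulus times their hemodynamics reflect.

    Each frame t maps to ``t0 + t/fs - hrf_delay`` seconds (clipped at 0):
    the moment in the stimulus whose delayed vascular response the frame
    captures.
    """
    if not fs > 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if hrf_delay < 0:
        raise ValueError(f"hrf_delay must be >= 0, got {hrf_delay}")
    idx = frames.frames if isinstance(frames, FrameSet) else np.asarray(frames)
    return np.maximum(t0 + idx / fs - hrf_delay, 0.0)


def format_mmss(seconds: float) -> str:
    """Render seconds as a minutes:seconds string ('01:35')."""
    total = int(round(seconds))
    return f"{total // 60:02d}:{total % 60:02d}"


def channel_relevance(
    group: GroupDataset, top_fraction: float = 0.25
) -> ChannelRelevance:
    """Leave-one-channel-out importance of every channel.

    For each channel c the whole closeness series is recomputed with c
    removed.  Per frame, channels are ranked by the closeness DROP
    (full - leave-one-out; a large drop means the channel carries the
    intersubject similarity); the top ceil(top_fraction * C) are marked
    relevant, with ties broken by channel order.  The relevance frequency of
    a channel is the fraction of frames where it is marked.
    """
    if not 0 < top_fraction < 1:
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    c = group.n_channels
    if c < 2:
        raise DataError("channel relevance needs at least 2 channels")

    full = closeness_series(group)
    loo = [closeness_series(group, exclude_channel=ch) for ch in group.channel_ids]
    drops = full.values[None, :] - np.stack([s.values for s in loo])  # (C, T)

    k = max(1, _ceil_fraction(top_fraction, c))
    # stable sort over channels per frame: largest drop first, ties by channel order
    order = np.argsort(-drops, axis=0, kind="stable")  # (C, T)
    top = order[:k, :]  # (k, T)
    counts = np.zeros(c, dtype=int)
    np.add.at(counts, top.ravel(), 1)
    t = group.n_frames
    return ChannelRelevance(
        channel_ids=list(group.channel_ids),
        loo_series=loo,
        relevance_frequency=counts / t,
        membership_counts=counts,
        top_fraction=top_fraction,
    )
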