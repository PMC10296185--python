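"""Per-frame between-participant distance graphs and their closeness summaries.

At every time frame each participant contributes a multivariate hemodynamic
state (the vector of long-channel values).  Pairwise Euclidean distances
between those states define a complete weighted graph whose mean node
closeness quantifies how similar the group is at that frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DegenerateFrameError

__all__ = [
    "GroupDataset",
    "FrameDistanceMatrix",
    "ClosenessSeries",
    "frame_distance_matrix",
    "mean_closeness",
    "closeness_series",
]


@dataclass
class GroupDataset:
    """Frame-aligned multi-participant recording: the unit of analysis.

    Parameters
    ----------
    participants : list of str
        Ordered participant identifiers.
    data : ndarray, shape (N, T, C)
        Hemodynamic values per participant, frame and channel (arbitrary
        concentration units after normalization).
    fs : float
        Sampling rate in Hz.
    channel_ids : list of str
        Ordered long-channel labels, length C.
    t0 : float
        Acquisition start offset in seconds.
    """

    participants: list[str]
    data: np.ndarray
    fs: float
    channel_ids: list[str]
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError(f"data must be (N, T, C), got shape {self.data.shape}")
        n, t, c = self.data.shape
        if len(self.participants) != n:
            raise DataError(
                f"{len(self.participants)} participant ids for {n} data matrices"
            )
        if len(self.channel_ids) != c:
            raise DataError(f"{len(self.channel_ids)} channel ids for {c} channels")
        if n < 3:
            raise DataError(f"need at least 3 participants, got {n}")
        if t < 2:
            raise DataError(f"need at least 2 frames, got {t}")
        if c < 1:
            raise DataError("need at least 1 channel")
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            p, fr, ch = np.argwhere(~np.isfinite(self.data))[0]
            raise DataError(
                f"non-finite value for participant {self.participants[p]!r}, "
                f"channel {self.channel_ids[ch]!r}, frame {fr}"
            )

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def channel_index(self, channel_id: str) -> int:
        try:
            return self.channel_ids.index(channel_id)
        except ValueError:
            raise DataError(f"unknown channel {channel_id!r}") from None


@dataclass
class FrameDistanceMatrix:
    """Symmetric participant-by-participant Euclidean distance matrix at one frame."""

    values: np.ndarray
    frame: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ClosenessSeries:
    """Mean node closeness per frame over a whole recording."""

    values: np.ndarray
    frame_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.frame_indices is None:
            self.frame_indices = np.arange(len(self.values))
        else:
            self.frame_indices = np.asarray(self.frame_indices, dtype=int)

    def __len__(self) -> int:
        return len(self.values)


def _state_matrix(group: GroupDataset, exclude_channel: str | None) -> np.ndarray:
    """Return the (N, T, C') data tensor, optionally dropping one channel."""
    if exclude_channel is None:
        return group.data
    if group.n_channels < 2:
        raise DataError("cannot exclude a channel from a single-channel dataset")
    idx = group.channel_index(exclude_channel)
    keep = [c for c in range(group.n_channels) if c != idx]
    return group.data[:, :, keep]


def frame_distance_matrix(
    group: GroupDataset, frame: int, exclude_channel: str | None = None
) -> FrameDistanceMatrix:
    """Pairwise Euclidean distances between participant states at one frame.

    Entry (i, j) is the Euclidean norm of the difference between participant
    i's and participant j's channel vectors at ``frame``.
    """
    if not 0 <= frame < group.n_frames:
        raise IndexError(
            f"frame {frame} out of range for {group.n_frames}-frame recording"
        )
    states = _state_matrix(group, exclude_channel)[:, frame, :]  # (N, C')
    diff = states[:, None, :] - states[None, :, :]
    values = np.sqrt(np.einsum("ijc,ijc->ij", diff, diff))
    return FrameDistanceMatrix(values=values, frame=frame)


def _closeness_from_rowsums(rowsums: np.ndarray, frame: int) -> np.ndarray:
    n = rowsums.shape[0]
    if np.any(rowsums <= 0):
        raise DegenerateFrameError(frame)
    return (n - 1) / rowsums


def mean_closeness(dist: FrameDistanceMatrix) -> float:
    """Arithmetic mean of node closeness over the complete weighted graph.

    Node closeness is (N-1) / (sum of that node's distances to all others).
    Distances are Euclidean, hence metric, so the direct edge is always the
    shortest path and the row-sum form equals a full shortest-path
    computation.
    """
    values = dist.values
    n = values.shape[0]
    if n < 3:
        raise DataError(f"closeness needs at least 3 nodes, got {n}")
    rowsums = values.sum(axis=1)
    return float(_closeness_from_rowsums(rowsums, dist.frame).mean())


def _closeness_values_tensor(data: np.ndarray) -> np.ndarray:
    """Mean closeness per frame for an (N, T, C) tensor (vectorized core).

    Uses the Gram-matrix identity for squared distances; clips tiny negative
    round-off before the square root.
    """
    n = data.shape[0]
    gram = np.einsum("itc,jtc->ijt", data, data)
    sq = np.einsum("itc,itc->it", data, data)
    d2 = sq[:, None, :] + sq[None, :, :] - 2.0 * gram
    np.clip(d2, 0.0, None, out=d2)
    dist = np.sqrt(d2)  # (N, N, T)
    rowsums = dist.sum(axis=1)  # (N, T)
    bad = np.any(rowsums <= 0, axis=0)
    if np.any(bad):
        raise DegenerateFrameError(int(np.argmax(bad)))
    return ((n - 1) / rowsums).mean(axis=0)


def closeness_series(
    group: GroupDataset, exclude_channel: str | None = None
) -> ClosenessSeries:
    """Mean closeness of the between-participant graph at every frame.

    With ``exclude_channel`` the named channel is dropped from every state
    vector first (leave-one-channel-out support).
    """
    data = _state_matrix(group, exclude_channel)
    return ClosenessSeries(values=_closeness_values_tensor(data))
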