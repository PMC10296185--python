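"""Single-model hypothesis test: mean closeness vs a circular-permutation null.

The test statistic is the mean, across all frames, of the per-frame mean
graph closeness.  The null distribution is built by circularly shifting each
participant's whole multichannel recording by an independent random offset —
which exactly preserves every within-subject autocorrelation and
cross-channel correlation while breaking the across-subject alignment — and
recomputing the statistic.  One p-value for the whole recording; no
per-channel or per-frame multiple testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import ClosenessSeries, GroupDataset, _closeness_values_tensor

__all__ = [
    "TestResult",
    "circular_shift",
    "mean_statistic",
    "intersubject_similarity_test",
]


@dataclass
class TestResult:
    """Observed statistic, permutation null sample and Monte-Carlo p-value."""

    observed: float
    null_sample: np.ndarray
    p_value: float
    n_permutations: int
    seed: int
    per_frame: ClosenessSeries

    def __post_init__(self):
        self.null_sample = np.asarray(self.null_sample, dtype=float)


def circular_shift(matrix: np.ndarray, offset: int) -> np.ndarray:
    """Rotate a (T, C) matrix along time with wrap-around.

    Row t of the output is row (t - offset) mod T of the input; all channels
    shift together, so within-subject cross-channel correlation is untouched.
    """
    matrix = np.asarray(matrix)
    t = matrix.shape[0]
    if not 0 <= offset < t:
        raise ValueError(f"offset must be in [0, {t}), got {offset}")
    return np.roll(matrix, offset, axis=0)


def mean_statistic(series: ClosenessSeries) -> float:
    """Mean closeness across all frames — the scalar test statistic."""
    if len(series) == 0:
        raise ValueError("empty closeness series")
    return float(np.mean(series.values))


def intersubject_similarity_test(
    group: GroupDataset, n_permutations: int = 1000, seed: int | None = None
) -> TestResult:
    """Permutation test for stimulus-driven intersubject similarity.

    For each of ``n_permutations`` permutations every participant receives an
    independent uniform offset from {1, ..., T-1} (0 excluded so each permuted
    dataset differs from the observed one) applied to all channels at once.
    One-sided upper tail: similarity means HIGH closeness.  The p-value is
    (b + 1) / (B + 1) with b the number of permuted statistics >= observed;
    the observed dataset itself is not part of the null sample.

    Deterministic given ``seed``; offsets are drawn from a single generator
    in permutation-major, participant-minor order.
    """
    if n_permutations < 1:
        raise ValueError(f"need at least 1 permutation, got {n_permutations}")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")

    data = group.data
    n, t, _ = data.shape
    per_frame = ClosenessSeries(values=_closeness_values_tensor(data))
    observed = mean_statistic(per_frame)

    rng = np.random.default_rng(seed)
    offsets = rng.integers(1, t, size=(n_permutations, n))

    null_sample = np.empty(n_permutations)
    shifted = np.empty_like(data)
    for b in range(n_permutations):
        for i in range(n):
            shifted[i] = np.roll(data[i], offsets[b, i], axis=0)
        null_sample[b] = _closeness_values_tensor(shifted).mean()

    b_ge = int(np.sum(null_sample >= observed))
    p_value = (b_ge + 1) / (n_permutations + 1)
    return TestResult(
        observed=observed,
        null_sample=null_sample,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        per_frame=per_frame,
    )
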