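"""Synthetic multi-participant fNIRS-like data with known ground truth.

The generative model is the simplest one exhibiting exactly the two
properties circular permutation preserves: AR(1) temporal autocorrelation
and equicorrelated cross-channel noise, both at unit stationary variance so
effect sizes read in noise-SD units.  A shared stimulus-locked component
(boxcar convolved with a double-gamma hemodynamic response) is added to a
chosen subset of channels, with per-participant gain jitter so responses are
shared but not identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .preprocess import ChannelGeometry, RawRecording
from .similarity import GroupDataset

__all__ = ["SimulationConfig", "GroundTruth", "canonical_hrf", "simulate_group", "simulate_raw"]


@dataclass
class SimulationConfig:
    n_participants: int = 19
    n_long_channels: int = 20
    n_short_channels: int = 8
    n_frames: int = 2100
    fs: float = 7.81
    ar_coefficient: float = 0.95
    spatial_rho: float = 0.3
    event_onsets: tuple[float, ...] = ()
    event_duration: float = 10.0
    responsive_channels: tuple[int, ...] = ()
    effect_size: float = 0.0
    gain_jitter: float = 0.1
    superficial_amplitude: float = 0.0
    noise_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must be in [0, 1)")
        if not 0 <= self.spatial_rho < 1:
            raise ValueError("spatial_rho must be in [0, 1)")
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants")
        duration_s = self.n_frames / self.fs
        for onset in self.event_onsets:
            if not 0 <= onset < duration_s:
                raise ValueError(
                    f"event onset {onset}s outside recording [0, {duration_s:.1f}s)"
                )
        bad = [c for c in self.responsive_channels if not 0 <= c < self.n_long_channels]
        if bad:
            raise ValueError(f"responsive channels {bad} outside long-channel range")

    @property
    def channel_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_long_channels)]


@dataclass
class GroundTruth:
    """What was injected: where the shared response lives in time and space."""

    response_frames: np.ndarray
    responsive_channels: tuple[int, ...]
    clean_signals: np.ndarray  # (T, C) noiseless shared component per channel

    def __post_init__(self):
        self.response_frames = np.asarray(self.response_frames, dtype=int)
        self.clean_signals = np.asarray(self.clean_signals, dtype=float)


def canonical_hrf(fs: float, duration: float = 30.0) -> np.ndarray:
    """Double-gamma hemodynamic impulse response, peak-normalized to 1.

    Standard parameters: response gamma with shape 6, undershoot with shape
    16, undershoot ratio 1/6; peak around 5 s, undershoot near 15 s.
    Finite support of ``duration`` seconds; kernel[0] = 0.
    """
    if not fs > 0:
        raise ValueError("fs must be positive")
    t = np.arange(int(round(duration * fs))) / fs
    h = _stats.gamma.pdf(t, a=6, scale=1.0) - _stats.gamma.pdf(t, a=16, scale=1.0) / 6.0
    return h / h.max()


def _ar1_noise(rng: np.random.Generator, n: int, t: int, c: int, phi: float, rho: float) -> np.ndarray:
    """(n, t, c) stationary AR(1) noise with equicorrelated innovations, unit variance."""
    cov = np.full((c, c), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    e = rng.standard_normal((n, t, c)) @ chol.T
    if phi == 0:
        return e
    e *= np.sqrt(1.0 - phi * phi)
    e[:, 0, :] /= np.sqrt(1.0 - phi * phi)  # stationary start
    return _signal.lfilter([1.0], [1.0, -phi], e, axis=1)


def _shared_response(config: SimulationConfig) -> np.ndarray:
    """Noiseless stimulus-locked component, common shape across participants (T,)."""
    t = config.n_frames
    box = np.zeros(t)
    for onset in config.event_onsets:
        i0 = int(round(onset * config.fs))
        i1 = min(t, i0 + int(round(config.event_duration * config.fs)))
        box[i0:i1] = 1.0
    if not box.any():
        return box
    s = np.convolve(box, canonical_hrf(config.fs))[:t]
    peak = np.abs(s).max()
    return s / peak if peak > 0 else s


def _simulate_core(config: SimulationConfig, displace: bool):
    rng = np.random.default_rng(config.seed)
    n, t, c = config.n_participants, config.n_frames, config.n_long_channels
    sigma = config.noise_amplitude
    if sigma > 0:
        data = sigma * _ar1_noise(
            rng, n, t, c, config.ar_coefficient, config.spatial_rho
        )
    else:
        data = np.zeros((n, t, c))

    shape = _shared_response(config)
    clean = np.zeros((t, c))
    if config.effect_size != 0 and shape.any() and config.responsive_channels:
        w = config.effect_size * shape  # (T,) stimulus-locked amplitude in SD units
        gains = 1.0 + config.gain_jitter * rng.standard_normal(n)
        if displace and sigma > 0:
            # For the statistical-analysis path the stimulus-driven component
            # DISPLACES ongoing activity rather than merely adding to it: at
            # each frame total variance stays ~sigma^2 while the noise share
            # shrinks, so participants' states genuinely converge during the
            # response.  A purely additive common signal would shift every
            # participant's state by the same vector and leave
            # between-participant distances — hence closeness — untouched.
            scale = np.sqrt(1.0 + (w / sigma) ** 2)
            for ch in config.responsive_channels:
                clean[:, ch] = w / scale  # the component actually in the data
                data[:, :, ch] = (
                    data[:, :, ch] + gains[:, None] * w[None, :]
                ) / scale[None, :]
        else:
            for ch in config.responsive_channels:
                clean[:, ch] = w
                data[:, :, ch] += gains[:, None] * w[None, :]

    superficial = None
    if config.superficial_amplitude != 0:
        superficial = _ar1_noise(rng, n, t, 1, 0.9, 0.0)[:, :, 0]
        data += config.superficial_amplitude * superficial[:, :, None]

    response_frames = (
        np.flatnonzero(shape > 0.5 * shape.max())
        if shape.any() and config.effect_size != 0 and config.responsive_channels
        else np.array([], dtype=int)
    )
    truth = GroundTruth(
        response_frames=response_frames,
        responsive_channels=tuple(config.responsive_channels),
        clean_signals=clean,
    )
    return data, truth, superficial, rng


def simulate_group(config: SimulationConfig) -> tuple[GroupDataset, GroundTruth]:
    """Generate an analysis-ready synthetic group dataset plus its ground truth."""
    data, truth, _, _ = _simulate_core(config, displace=True)
    group = GroupDataset(
        participants=[f"P{i + 1:02d}" for i in range(config.n_participants)],
        data=data,
        fs=config.fs,
        channel_ids=config.channel_ids,
    )
    return group, truth


#: Forward-model constants for :func:`simulate_raw`.
_BASELINE_INTENSITY = 1.0
_HBO_SCALE_MM = 1e-3  # unit-variance signal -> 1 uM concentration swing
_HBR_RATIO = -0.3  # dHbR tracks dHbO with opposite sign, smaller amplitude
_LONG_SEPARATION_CM = 3.0
_SHORT_SEPARATION_CM = 0.8


def simulate_raw(config: SimulationConfig) -> tuple[list[RawRecording], GroundTruth]:
    """Dual-wavelength intensity recordings via the inverse Beer-Lambert forward model.

    Long channels carry the simulated cortical dynamics (plus any superficial
    component); short channels carry only the superficial component plus a
    little independent noise.  The shared response is injected additively
    here — concentration changes add optically — unlike the
    variance-preserving displacement used for analysis-ready group data.
    Intensities are strictly positive by construction at the packaged
    amplitude scale.
    """
    from .preprocess import DEFAULT_EXTINCTION  # avoid cycle at import time

    data, truth, superficial, rng = _simulate_core(config, displace=False)
    n, t = config.n_participants, config.n_frames
    dpf = 6.0

    channels = [
        ChannelGeometry(cid, _LONG_SEPARATION_CM, "long") for cid in config.channel_ids
    ] + [
        ChannelGeometry(f"S{i + 1:02d}", _SHORT_SEPARATION_CM, "short")
        for i in range(config.n_short_channels)
    ]

    recordings = []
    for p in range(n):
        cols = []
        for ch_idx in range(config.n_long_channels):
            hbo = _HBO_SCALE_MM * data[p, :, ch_idx]
            cols.append(_forward_intensity(hbo, _LONG_SEPARATION_CM, dpf, DEFAULT_EXTINCTION))
        for _ in range(config.n_short_channels):
            base = superficial[p] if superficial is not None else 0.0
            hbo = _HBO_SCALE_MM * (
                config.superficial_amplitude * base
                + 0.1 * config.noise_amplitude * rng.standard_normal(t)
            )
            cols.append(_forward_intensity(hbo, _SHORT_SEPARATION_CM, dpf, DEFAULT_EXTINCTION))
        intensities = np.concatenate(cols, axis=1)
        if np.any(intensities <= 0):
            raise ValueError(
                "forward model produced nonpositive intensities; "
                "reduce effect or confound amplitudes"
            )
        recordings.append(
            RawRecording(
                intensities=intensities,
                channels=[
                    ChannelGeometry(c.channel_id, c.separation_cm, c.role)
                    for c in channels
                ],
                fs=config.fs,
                participant=f"P{p + 1:02d}",
            )
        )
    return recordings, truth


def _forward_intensity(
    hbo: np.ndarray, separation: float, dpf: float, extinction: np.ndarray
) -> np.ndarray:
    """(T, 2) intensities at both wavelengths from a dHbO series (mM)."""
    conc = np.column_stack([hbo, _HBR_RATIO * hbo])  # (T, 2): HbO, HbR
    a = extinction * separation * dpf  # (2, 2) wavelength x chromophore
    od = conc @ a.T  # (T, 2)
    return _BASELINE_INTENSITY * np.power(10.0, -od)
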