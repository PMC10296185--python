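"""Signal conditioning from raw dual-wavelength intensities to analysis-ready HbO.

Stage order: optical density -> modified Beer-Lambert -> z-score -> wavelet
spike suppression -> zero-phase band-pass -> short-channel regression ->
rescale to variance one.  Every stage preserves series length.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from . import _wavelet
from .errors import ConfigError, DataError
from .similarity import GroupDataset

__all__ = [
    "ChannelGeometry",
    "RawRecording",
    "PreprocessConfig",
    "DEFAULT_EXTINCTION",
    "optical_density",
    "beer_lambert",
    "zscore",
    "wavelet_despike",
    "bandpass",
    "short_channel_regress",
    "preprocess_pipeline",
]

#: Molar extinction coefficients in 1/(mM*cm), rows = wavelengths (760, 850 nm),
#: columns = chromophores (HbO, HbR).  Packaged defaults; replace with the
#: values your acquisition software uses if they differ.
DEFAULT_EXTINCTION = np.array(
    [
        [0.5865, 1.5485],  # 760 nm
        [1.0580, 0.6913],  # 850 nm
    ]
)

WAVELENGTHS_NM = (760.0, 850.0)


@dataclass
class ChannelGeometry:
    """Source-detector pair: label, separation and long/short role."""

    channel_id: str
    separation_cm: float
    role: str  # "long" | "short"

    def __post_init__(self):
        if self.role not in ("long", "short"):
            raise DataError(f"channel {self.channel_id!r}: bad role {self.role!r}")
        if not self.separation_cm > 0:
            raise DataError(f"channel {self.channel_id!r}: nonpositive separation")


@dataclass
class RawRecording:
    """Raw dual-wavelength light intensities for one participant.

    ``intensities`` has shape (T, 2K): two adjacent columns per channel,
    ordered (760 nm, 850 nm), channels in ``channels`` order.
    """

    intensities: np.ndarray
    channels: list[ChannelGeometry]
    fs: float
    participant: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise DataError("intensities must be a 2-D (T, 2K) matrix")
        if self.intensities.shape[1] != 2 * len(self.channels):
            raise DataError(
                f"{self.intensities.shape[1]} intensity columns for "
                f"{len(self.channels)} channels (expected 2 per channel)"
            )
        if not self.fs > 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if np.any(self.intensities <= 0):
            t, col = np.argwhere(self.intensities <= 0)[0]
            ch = self.channels[col // 2].channel_id
            raise DataError(
                f"nonpositive intensity at frame {t}, channel {ch!r} "
                "(logarithm undefined)"
            )
        roles = {c.role for c in self.channels}
        if "long" in roles and "short" not in roles:
            raise DataError("long channels present but no short channel for regression")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    def channel_intensities(self, index: int) -> np.ndarray:
        """(T, 2) intensity pair for channel ``index``."""
        return self.intensities[:, 2 * index : 2 * index + 2]


@dataclass
class PreprocessConfig:
    """Parameters of the conditioning chain (field-standard defaults)."""

    band: tuple[float, float] = (0.01, 0.08)
    wavelet_lambda: float = 0.1
    dpf: tuple[float, float] = (6.0, 6.0)
    extinction: np.ndarray = field(default_factory=lambda: DEFAULT_EXTINCTION.copy())
    filter_order: int = 3
    chromophore: str = "HbO"
    short_regression: bool = True
    wavelet_levels: int | None = None

    def __post_init__(self):
        self.extinction = np.asarray(self.extinction, dtype=float)
        low, high = self.band
        if not 0 < low < high:
            raise ConfigError(f"band must satisfy 0 < low < high, got {self.band}")
        if not self.wavelet_lambda > 0:
            raise ConfigError("wavelet_lambda must be positive")
        if self.extinction.shape != (2, 2) or abs(np.linalg.det(self.extinction)) < 1e-12:
            raise ConfigError("extinction matrix must be an invertible 2x2 matrix")
        if self.chromophore not in ("HbO", "HbR", "both"):
            raise ConfigError(f"unknown chromophore {self.chromophore!r}")


def optical_density(intensities: np.ndarray) -> np.ndarray:
    """Change in optical density relative to the temporal mean intensity.

    dOD(t) = -log10(I(t) / mean(I)); works column-wise on 2-D input.
    """
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities <= 0):
        idx = np.argwhere(intensities <= 0)[0]
        raise DataError(f"nonpositive intensity at index {tuple(idx)}")
    mean = intensities.mean(axis=0, keepdims=True) if intensities.ndim > 1 else intensities.mean()
    return -np.log10(intensities / mean)


def beer_lambert(
    od: np.ndarray,
    separation_cm: float,
    dpf: tuple[float, float] | float = (6.0, 6.0),
    extinction: np.ndarray | None = None,
) -> np.ndarray:
    """Invert the modified Beer-Lambert relation for one channel.

    ``od`` is (T, 2): optical-density change at 760 and 850 nm.  Solves
    dOD_l = (eps_l,HbO * dHbO + eps_l,HbR * dHbR) * separation * dpf_l
    per frame; returns (T, 2) concentration changes (dHbO, dHbR) in mM.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 2 or od.shape[1] != 2:
        raise DataError(f"od must be (T, 2), got shape {od.shape}")
    if not separation_cm > 0:
        raise ConfigError("separation must be positive")
    ext = DEFAULT_EXTINCTION if extinction is None else np.asarray(extinction, float)
    if np.isscalar(dpf):
        dpf = (float(dpf), float(dpf))
    # forward matrix: od = conc @ A.T with A[l, k] = ext[l, k] * d * dpf[l]
    a = ext * separation_cm * np.asarray(dpf)[:, None]
    if abs(np.linalg.det(a)) < 1e-15:
        raise ConfigError("singular extinction matrix")
    return np.linalg.solve(a, od.T).T


def zscore(series: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to sample variance 1 (ddof=1)."""
    series = np.asarray(series, dtype=float)
    sd = series.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataError("constant series cannot be z-scored")
    return (series - series.mean()) / sd


def _despike_levels(t: int, requested: int | None) -> int:
    # padded length is a power of two >= t; depth floor(log2 t) - 2 by default
    depth = max(1, int(math.floor(math.log2(t))) - 2) if requested is None else requested
    return max(1, depth)


def wavelet_despike(
    series: np.ndarray, lam: float = 0.1, levels: int | None = None
) -> np.ndarray:
    """Suppress isolated spikes by clipping outlying wavelet detail coefficients.

    The series is reflection-padded to a power-of-two length and decomposed
    with a periodized Daubechies-4 pyramid.  Per detail level the noise scale
    is estimated robustly (median absolute deviation / 0.6745) and detail
    coefficients are clipped to +/- sigma_level * sqrt(2 ln T) / lam.
    Smaller ``lam`` raises the threshold, so only larger excursions — spikes —
    are touched, while smooth physiology passes unchanged.
    """
    series = np.asarray(series, dtype=float)
    t = series.shape[0]
    if t < 8:
        raise ValueError(f"need at least 8 samples, got {t}")
    if not lam > 0:
        raise ValueError("lam must be positive")

    # Mirror-pad on BOTH sides to the next power of two >= 2T.  The
    # periodized transform wraps around; without padding the wrap junction is
    # a jump discontinuity right at the data edges whose spurious fine-scale
    # coefficients would be clipped as "spikes", distorting the output.  With
    # two-sided padding every junction (mirror kinks and the circular wrap)
    # sits well inside the padding, where clipping artifacts stay localized.
    n = max(1 << math.ceil(math.log2(2 * t)), 16)
    pad_left = (n - t) // 2
    pad_right = n - t - pad_left
    padded = np.pad(series, (pad_left, pad_right), mode="symmetric")

    depth = min(_despike_levels(t, levels), int(math.log2(n)) - 1)
    approx, details = _wavelet.wavedec(padded, depth)
    scale = math.sqrt(2.0 * math.log(t)) / lam
    out_details = []
    for d in details:
        if d.shape[0] >= 8:  # MAD is meaningless on a handful of coefficients
            mad = np.median(np.abs(d - np.median(d)))
            sigma = mad / 0.6745
            if sigma > 0:
                d = np.clip(d, -sigma * scale, sigma * scale)
        out_details.append(d)
    return _wavelet.waverec(approx, out_details)[pad_left : pad_left + t]


def bandpass(
    series: np.ndarray,
    band: tuple[float, float] = (0.01, 0.08),
    fs: float = 7.81,
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band must satisfy 0 < low < high < fs/2, got {band} at fs={fs}")
    sos = _signal.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, np.asarray(series, dtype=float))


def short_channel_regress(long: np.ndarray, shorts: np.ndarray) -> np.ndarray:
    """Residual of the long channel after OLS on all short channels + intercept.

    The residual is orthogonal to every short-channel regressor; superficial
    and systemic dynamics common to both are removed.
    """
    long = np.asarray(long, dtype=float)
    shorts = np.asarray(shorts, dtype=float)
    if shorts.ndim == 1:
        shorts = shorts[:, None]
    t, s = shorts.shape
    if s < 1:
        raise DataError("need at least one short channel")
    if t <= s + 1:
        raise DataError(f"need more than {s + 1} frames for {s} regressors")
    design = np.column_stack([np.ones(t), shorts])
    coef, _, rank, _ = np.linalg.lstsq(design, long, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "rank-deficient short-channel regressors; using minimum-norm fit",
            RuntimeWarning,
            stacklevel=2,
        )
    return long - design @ coef


def _condition_series(x: np.ndarray, fs: float, config: PreprocessConfig) -> np.ndarray:
    """z-score -> despike -> band-pass for one concentration series."""
    x = zscore(x)
    x = wavelet_despike(x, lam=config.wavelet_lambda, levels=config.wavelet_levels)
    return bandpass(x, band=config.band, fs=fs, order=config.filter_order)


def preprocess_pipeline(
    recordings: list[RawRecording], config: PreprocessConfig | None = None
) -> GroupDataset:
    """Run the full conditioning chain and assemble a group dataset.

    Recordings of unequal length are truncated to the common minimum T.
    Only long channels (and the chromophore named in the config) enter the
    output; channels end with sample variance exactly 1.
    """
    if config is None:
        config = PreprocessConfig()
    if not recordings:
        raise DataError("no recordings given")
    fs = recordings[0].fs
    geometry = [(c.channel_id, c.role) for c in recordings[0].channels]
    for rec in recordings[1:]:
        if rec.fs != fs:
            raise DataError(
                f"participant {rec.participant!r}: fs {rec.fs} != {fs}"
            )
        if [(c.channel_id, c.role) for c in rec.channels] != geometry:
            raise DataError(
                f"participant {rec.participant!r}: channel geometry differs"
            )
    if config.chromophore == "both":
        raise ConfigError(
            "group assembly requires a single chromophore ('HbO' or 'HbR')"
        )
    chrom_col = 0 if config.chromophore == "HbO" else 1

    t_common = min(rec.n_frames for rec in recordings)
    long_idx = [i for i, c in enumerate(recordings[0].channels) if c.role == "long"]
    short_idx = [i for i, c in enumerate(recordings[0].channels) if c.role == "short"]
    if not long_idx:
        raise DataError("no long channels in geometry")

    matrices = []
    participants = []
    for p, rec in enumerate(recordings):
        pid = rec.participant or f"P{p + 1:02d}"
        participants.append(pid)

        def conc(idx: int) -> np.ndarray:
            ch = rec.channels[idx]
            od = optical_density(rec.channel_intensities(idx)[:t_common])
            hb = beer_lambert(od, ch.separation_cm, config.dpf, config.extinction)
            return hb[:, chrom_col]

        try:
            shorts = np.column_stack(
                [_condition_series(conc(i), fs, config) for i in short_idx]
            ) if short_idx else None
            cols = []
            for i in long_idx:
                x = _condition_series(conc(i), fs, config)
                if config.short_regression and shorts is not None:
                    x = short_channel_regress(x, shorts)
                sd = x.std(ddof=1)
                if sd == 0:
                    raise DataError(
                        f"channel {rec.channels[i].channel_id!r} is constant "
                        "after preprocessing"
                    )
                cols.append(x / sd)
            matrices.append(np.column_stack(cols))
        except DataError as exc:
            raise DataError(f"participant {pid!r}: {exc}") from exc

    return GroupDataset(
        participants=participants,
        data=np.stack(matrices),
        fs=fs,
        channel_ids=[recordings[0].channels[i].channel_id for i in long_idx],
    )
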