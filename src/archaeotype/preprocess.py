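"""Profile-spectrum preprocessing: smoothing, baseline, noise, peak picking.

The chain mirrors standard linear-mode MALDI fingerprint processing:
Savitzky–Golay smoothing (width 5 m/z, 1 cycle, order 2), morphological
top-hat baseline correction, a robust noise estimate, and centroid peak
detection with a signal-to-noise threshold of 3, a 5 m/z peak width, and at
most 100 peaks kept.  The whole chain is deterministic: identical input and
configuration give a bit-identical peak list.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterator

import numpy as np
from scipy.ndimage import grey_opening
from scipy.signal import savgol_filter

from .errors import ConfigError, InputError
from .io import RawSpectrum

#: Relative height floor used instead of the S/N gate when the noise
#: estimate is exactly 0 (idealized noiseless input).
_NOISELESS_REL_FLOOR = 1e-3


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``sg_width_mz`` is the full span of the smoothing window in m/z units;
    it is converted to the nearest odd point count from the local sampling
    density.  ``tophat_width_mz`` is the flat structuring-element span for
    baseline opening: much wider than a peak (5 m/z) and much narrower than
    the baseline's variation scale over the 18 kDa window.  ``peak_width_mz``
    sets both the minimum half-height span a peak must cover and the merge
    distance between neighbouring maxima.
    """

    sg_width_mz: float = 5.0
    sg_cycles: int = 1
    sg_polyorder: int = 2
    tophat_width_mz: float = 150.0
    snr_threshold: float = 3.0
    max_peaks: int = 100
    peak_width_mz: float = 5.0
    noise_method: str = "mad"

    def __post_init__(self) -> None:
        for name in ("sg_width_mz", "tophat_width_mz", "peak_width_mz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.sg_cycles < 1:
            raise ConfigError("sg_cycles must be >= 1")
        if self.sg_polyorder < 0:
            raise ConfigError("sg_polyorder must be >= 0")
        if self.snr_threshold <= 0:
            raise ConfigError("snr_threshold must be > 0")
        if self.max_peaks < 1:
            raise ConfigError("max_peaks must be >= 1")
        if self.noise_method not in ("mad",):
            raise ConfigError(f"unknown noise_method {self.noise_method!r}")


@dataclass(frozen=True)
class Peak:
    """A centroided peak: intensity-weighted mean m/z, height, and S/N."""

    mz: float
    intensity: float
    snr: float

    def __post_init__(self) -> None:
        if not self.intensity > 0:
            raise InputError("peak intensity must be > 0")
        if not self.snr > 0:
            raise InputError("peak snr must be > 0")


@dataclass(frozen=True)
class PeakList:
    """Centroided peaks from one spectrum, sorted by m/z."""

    peaks: tuple
    strain_id: str = "unknown"
    replicate_id: str = "r1"
    params: PreprocessConfig | None = None

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks)
        object.__setattr__(self, "peaks", peaks)
        mzs = [p.mz for p in peaks]
        if mzs != sorted(mzs):
            raise InputError("peaks must be sorted by m/z")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


def _grid_step(spectrum: RawSpectrum, max_drift: float = 0.2) -> float:
    """Median sampling step; errors if the grid drifts more than *max_drift*."""
    steps = np.diff(spectrum.mz)
    step = float(np.median(steps))
    if np.any(np.abs(steps - step) > max_drift * step):
        raise InputError(
            "spectrum grid is not approximately uniform "
            f"(sampling step varies more than {max_drift:.0%} from {step:g})"
        )
    return step


def _odd_points(span_mz: float, step: float) -> int:
    n = max(int(round(span_mz / step)), 1)
    return n if n % 2 == 1 else n + 1


def smooth(spectrum: RawSpectrum, cfg: PreprocessConfig | None = None) -> RawSpectrum:
    """Savitzky–Golay smoothing applied ``sg_cycles`` times.

    The window span in m/z is converted to an odd point count from the
    sampling step; endpoints are handled by fitting the polynomial on the
    truncated window.  An order-2 filter reproduces constants and
    quadratics exactly.
    """
    cfg = cfg or PreprocessConfig()
    step = _grid_step(spectrum)
    window = _odd_points(cfg.sg_width_mz, step)
    if window < cfg.sg_polyorder + 2:
        raise ConfigError(
            f"smoothing window of {window} points (from {cfg.sg_width_mz} m/z at "
            f"step {step:g}) is smaller than polyorder+2 = {cfg.sg_polyorder + 2}"
        )
    y = spectrum.intensity
    for _ in range(cfg.sg_cycles):
        y = savgol_filter(y, window, cfg.sg_polyorder, mode="interp")
    return spectrum.with_intensity(y)


def subtract_baseline(
    spectrum: RawSpectrum, cfg: PreprocessConfig | None = None
) -> RawSpectrum:
    """Morphological top-hat baseline correction.

    The baseline is the grayscale opening (erosion then dilation) of the
    signal with a flat structuring element spanning ``tophat_width_mz``.
    The signal is padded by linear extrapolation of its edges before the
    opening (and cropped after): with edge-value or reflective padding a
    flat element systematically under-removes a sloping baseline inside
    the first and last half-window.  Opening is anti-extensive, so the
    corrected signal is >= 0 pointwise.
    """
    cfg = cfg or PreprocessConfig()
    step = _grid_step(spectrum)
    size = _odd_points(cfg.tophat_width_mz, step)
    if size > len(spectrum):
        raise InputError(
            f"structuring element of {size} points is wider than the "
            f"spectrum ({len(spectrum)} points)"
        )
    y = spectrum.intensity
    pad = size
    k = np.arange(1, pad + 1, dtype=float)
    slope_l = (y[pad] - y[0]) / pad
    slope_r = (y[-1] - y[-1 - pad]) / pad
    padded = np.concatenate([y[0] - slope_l * k[::-1], y, y[-1] + slope_r * k])
    baseline = grey_opening(padded, size=size)[pad:-pad]
    return spectrum.with_intensity(y - np.minimum(baseline, y))


def estimate_noise(spectrum: RawSpectrum) -> float:
    """Robust noise level from the first difference of the signal.

    Scale = MAD(diff) x 1.4826 / sqrt(2), the Gaussian-consistent estimate
    of the pointwise noise sigma.  Differencing removes slowly varying
    structure; the median absolute deviation ignores the sparse peaks, so
    the estimate reflects the signal-free background.
    """
    if len(spectrum) < 16:
        raise InputError("noise estimate undefined for spectra shorter than 16 points")
    d = np.diff(spectrum.intensity)
    mad = float(np.median(np.abs(d - np.median(d))))
    return mad * 1.4826 / np.sqrt(2.0)


def _half_height_region(y: np.ndarray, i: int, offset: float) -> tuple[int, int]:
    """Indices [lo, hi] of the contiguous region around *i* above half height.

    Heights are measured from *offset*, the residual background level.
    """
    half = offset + (y[i] - offset) / 2.0
    lo = i
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = i
    while hi < y.size - 1 and y[hi + 1] >= half:
        hi += 1
    return lo, hi


def detect_peaks(
    spectrum: RawSpectrum,
    cfg: PreprocessConfig | None = None,
    noise: float | None = None,
) -> PeakList:
    """Centroid peak detection on a smoothed, baseline-corrected spectrum.

    Peak heights are measured above the residual background level (the
    median of the corrected signal — morphological opening of a noisy
    trace sits at the noise's lower envelope, leaving a positive pedestal
    that would otherwise inflate every height).  Local maxima with
    height/noise >= ``snr_threshold`` are kept; maxima closer than
    ``peak_width_mz`` are merged keeping the taller.  Each peak is
    centroided as the intensity-weighted mean m/z over the contiguous
    region above half height, which must span at least half of
    ``peak_width_mz`` (rejects single-sample noise spikes).  If more than
    ``max_peaks`` survive, the most intense are kept, ties broken by
    ascending m/z.
    """
    cfg = cfg or PreprocessConfig()
    if noise is None:
        noise = estimate_noise(spectrum)
    step = _grid_step(spectrum)
    y = spectrum.intensity
    mz = spectrum.mz
    offset = float(np.median(y))

    # interior local maxima (plateaus take their left edge)
    left = np.r_[True, y[1:] > y[:-1]]
    right = np.r_[y[:-1] >= y[1:], True]
    idx = np.flatnonzero(left & right & (y - offset > 0))
    if noise > 0:
        idx = idx[(y[idx] - offset) / noise >= cfg.snr_threshold]
    elif idx.size:
        # zero estimated noise: a dynamic-range floor stands in for the
        # S/N gate, rejecting numerical residue far below the tallest peak
        floor = _NOISELESS_REL_FLOOR * float(np.max(y[idx] - offset))
        idx = idx[(y[idx] - offset) >= floor]
    if idx.size == 0:
        return PeakList(
            peaks=(), strain_id=spectrum.strain_id,
            replicate_id=spectrum.replicate_id, params=cfg,
        )

    # merge maxima closer than peak_width_mz, keeping the taller
    order = sorted(idx, key=lambda i: (-y[i], mz[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(mz[i] - mz[j]) >= cfg.peak_width_mz for j in kept):
            kept.append(i)

    min_span = cfg.peak_width_mz / 2.0
    peaks: list[Peak] = []
    for i in kept:
        lo, hi = _half_height_region(y, i, offset)
        span = (mz[hi] - mz[lo]) + step
        if span < min_span:
            continue
        w = np.clip(y[lo : hi + 1] - offset, 0.0, None)
        centroid = float(np.sum(mz[lo : hi + 1] * w) / np.sum(w))
        height = float(y[i] - offset)
        snr = height / noise if noise > 0 else float("inf")
        peaks.append(Peak(mz=centroid, intensity=height, snr=snr))

    peaks.sort(key=lambda p: (-p.intensity, p.mz))
    peaks = peaks[: cfg.max_peaks]
    peaks.sort(key=lambda p: p.mz)
    return PeakList(
        peaks=tuple(peaks), strain_id=spectrum.strain_id,
        replicate_id=spectrum.replicate_id, params=cfg,
    )


def preprocess(
    spectrum: RawSpectrum, cfg: PreprocessConfig | None = None
) -> PeakList:
    """Run the full chain: smooth, baseline-correct, estimate noise, pick peaks.

    The noise level is estimated on the baseline-corrected but *unsmoothed*
    signal: smoothing shrinks and correlates the background, which would
    bias the difference-MAD estimate low and admit near-threshold noise
    maxima.  Peak heights and centroids are then measured on the smoothed,
    baseline-corrected signal.
    """
    cfg = cfg or PreprocessConfig()
    noise = estimate_noise(subtract_baseline(spectrum, cfg))
    s = subtract_baseline(smooth(spectrum, cfg), cfg)
    return detect_peaks(s, cfg, noise=noise)


def normalize_intensities(peaks: PeakList, mode: str = "max") -> PeakList:
    """Rescale intensities: ``max`` puts the base peak at 100, ``tic`` makes
    the intensities sum to 100.  m/z values are untouched."""
    if len(peaks) == 0:
        raise InputError("cannot normalize an empty peak list")
    if mode == "max":
        scale = 100.0 / max(p.intensity for p in peaks)
    elif mode == "tic":
        scale = 100.0 / sum(p.intensity for p in peaks)
    else:
        raise ConfigError(f"unknown normalization mode {mode!r}")
    new = tuple(
        Peak(mz=p.mz, intensity=p.intensity * scale, snr=p.snr) for p in peaks
    )
    return PeakList(
        peaks=new, strain_id=peaks.strain_id,
        replicate_id=peaks.replicate_id, params=peaks.params,
    )


def config_snapshot(cfg: PreprocessConfig) -> dict:
    """Plain-dict snapshot of a config, for provenance blocks."""
    return asdict(cfg)
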