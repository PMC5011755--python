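"""SELDI-TOF spectrum preprocessing chain.

Raw spectra from different runs sit on heterogeneous m/z axes, carry a
slowly varying chemical/matrix background, high-frequency detector noise,
and small rigid m/z miscalibrations.  The chain here turns them into a
fixed-dimension matrix ready for dimensionality reduction:

    resample -> correct_baseline -> denoise -> align_peaks -> normalize

The stage order is part of the contract.  Each stage is independently
switchable through :class:`PreprocessConfig` so other preprocessing
dialects can be configured.

Defaults follow the conventions of ovarian-cancer SELDI studies: a uniform
15,000-point grid over the informative band m/z 2000-10000, running-minimum
baseline estimation, wavelet soft-threshold denoising (moving-average
fallback), a bounded rigid-shift alignment against known reference peaks,
and total-ion-current (TIC) normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage

from .msio import Spectrum, SpectrumSet, assemble_set

__all__ = [
    "PreprocessConfig",
    "resample",
    "correct_baseline",
    "denoise",
    "align_peaks",
    "normalize",
    "preprocess_pipeline",
]

log = logging.getLogger(__name__)

#: Reference peak positions (m/z) of the two prominent serum-protein peaks
#: used for alignment in the ovarian-cancer SELDI band.
DEFAULT_ALIGN_REFERENCE = (3883.321, 7766.159)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    All windows and shifts are in physical m/z units, not grid indices.
    """

    grid_lo: float = 2000.0
    grid_hi: float = 10000.0
    grid_n: int = 15000
    baseline_window: float = 200.0      # m/z width of the running-minimum window
    denoise_method: str = "wavelet"     # {"wavelet", "moving-average", "none"}
    denoise_level: int = 4              # wavelet depth / half-window in points
    align_reference: tuple[float, ...] = DEFAULT_ALIGN_REFERENCE
    align_max_shift: float = 10.0       # maximum rigid m/z shift
    normalization: str = "total-ion-current"  # {"total-ion-current", "max-peak", "none"}
    baseline_enabled: bool = True
    align_enabled: bool = True

    def __post_init__(self) -> None:
        if not self.grid_lo < self.grid_hi:
            raise ValueError("grid_lo must be < grid_hi")
        if self.grid_n < 2:
            raise ValueError("grid_n must be >= 2")
        if self.align_max_shift < 0:
            raise ValueError("align_max_shift must be >= 0")
        if self.normalization not in ("total-ion-current", "max-peak", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.denoise_method not in ("wavelet", "moving-average", "none"):
            raise ValueError(f"unknown denoise_method {self.denoise_method!r}")

    @property
    def grid(self) -> np.ndarray:
        """The uniform target m/z grid (both endpoints included)."""
        return np.linspace(self.grid_lo, self.grid_hi, self.grid_n)

    @property
    def grid_step(self) -> float:
        return (self.grid_hi - self.grid_lo) / (self.grid_n - 1)


def resample(spec: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Linear-interpolation resampling onto the uniform target grid.

    Grid regions outside the input's m/z support are set to 0.
    """
    if spec.mz[-1] < cfg.grid_lo or spec.mz[0] > cfg.grid_hi:
        raise ValueError(
            f"spectrum {spec.sample_id!r} (m/z {spec.mz[0]:g}-{spec.mz[-1]:g}) "
            f"does not overlap the target grid [{cfg.grid_lo:g}, {cfg.grid_hi:g}]"
        )
    grid = cfg.grid
    y = np.interp(grid, spec.mz, spec.intensity, left=0.0, right=0.0)
    return spec.replace(mz=grid, intensity=y)


def _window_points(window_mz: float, cfg: PreprocessConfig) -> int:
    n = int(round(window_mz / cfg.grid_step))
    return max(n, 1)


def correct_baseline(spec: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Subtract a slowly varying baseline.

    The baseline is a windowed running minimum (window ``baseline_window``
    m/z units) smoothed by a uniform filter of the same width; negative
    residuals are clipped to 0 so downstream normalization sees
    nonnegative intensities.
    """
    span = spec.mz[-1] - spec.mz[0]
    if cfg.baseline_window > span:
        raise ValueError(
            f"baseline_window {cfg.baseline_window:g} exceeds the spectrum span {span:g}"
        )
    w = _window_points(cfg.baseline_window, cfg)
    base = ndimage.minimum_filter1d(spec.intensity, size=w, mode="nearest")
    base = ndimage.uniform_filter1d(base, size=w, mode="nearest")
    out = np.clip(spec.intensity - base, 0.0, None)
    return spec.replace(intensity=out)


def _wavelet_denoise(y: np.ndarray, level: int) -> np.ndarray:
    """Soft-threshold wavelet shrinkage with a MAD-estimated universal threshold."""
    wavelet = "sym8"
    level = min(level, pywt.dwt_max_level(y.size, pywt.Wavelet(wavelet).dec_len))
    if level < 1:
        return y.copy()
    coeffs = pywt.wavedec(y, wavelet, level=level, mode="symmetric")
    detail = coeffs[-1]
    sigma = np.median(np.abs(detail)) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(max(y.size, 2)))
    if thr == 0.0:
        return y.copy()
    coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet, mode="symmetric")
    return out[: y.size]


def denoise(spec: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Suppress high-frequency noise.

    ``"wavelet"`` applies soft-threshold shrinkage at depth
    ``denoise_level``; ``"moving-average"`` applies a uniform filter of
    half-window ``denoise_level`` points.  Negative excursions introduced
    by the filter are clipped to 0.
    """
    if cfg.denoise_method == "none":
        return spec
    if cfg.denoise_method == "wavelet":
        out = _wavelet_denoise(spec.intensity, cfg.denoise_level)
    else:
        out = ndimage.uniform_filter1d(
            spec.intensity, size=2 * cfg.denoise_level + 1, mode="nearest"
        )
    return spec.replace(intensity=np.clip(out, 0.0, None))


def _reference_signal(grid: np.ndarray, positions: tuple[float, ...],
                      width: float) -> np.ndarray:
    ref = np.zeros_like(grid)
    for p in positions:
        ref += np.exp(-0.5 * ((grid - p) / width) ** 2)
    return ref


def align_peaks(spec: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Rigid-shift peak alignment against the configured reference peaks.

    A synthetic reference of unit Gaussians at ``align_reference`` is
    cross-correlated with the spectrum over integer grid shifts; the
    optimum is refined to a sub-grid shift by parabolic interpolation of
    the correlation scores, clamped to ``align_max_shift`` (with a
    warning when the optimum sits beyond the bound), and applied by
    interpolation.  A single rigid shift per spectrum is estimated (no
    warping).
    """
    if not cfg.align_reference:
        raise ValueError("align_reference must be non-empty")
    grid = spec.mz
    for p in cfg.align_reference:
        if not (grid[0] <= p <= grid[-1]):
            raise ValueError(f"reference peak m/z {p:g} is outside the grid")
    if cfg.align_max_shift == 0:
        return spec
    step = grid[1] - grid[0]
    max_steps = int(np.floor(cfg.align_max_shift / step))
    # reference width ~ a few grid steps: narrow enough to localize, wide
    # enough that the correlation surface is smooth
    ref = _reference_signal(grid, cfg.align_reference, width=5 * step)
    y = spec.intensity

    def score(k: int) -> float:
        # correlation after moving the spectrum right by k grid steps
        if k == 0:
            return float(np.dot(y, ref))
        if k > 0:
            return float(np.dot(y[: y.size - k], ref[k:]))
        return float(np.dot(y[-k:], ref[: y.size + k]))

    # evaluate one step past the bound so clamping is detectable
    shifts = np.arange(-max_steps - 1, max_steps + 2)
    scores = np.array([score(k) for k in shifts])
    in_range = np.abs(shifts) <= max_steps
    best_i = int(np.argmax(np.where(in_range, scores, -np.inf)))
    if scores.max() > scores[best_i]:
        warnings.warn(
            f"alignment shift clamped at +/-{cfg.align_max_shift:g} m/z "
            f"for sample {spec.sample_id!r}",
            stacklevel=2,
        )
        shift_mz = float(np.sign(shifts[int(np.argmax(scores))])
                         * cfg.align_max_shift)
    else:
        # parabolic sub-grid refinement around the integer optimum
        sm, s0, sp = scores[best_i - 1], scores[best_i], scores[best_i + 1]
        denom = sm - 2 * s0 + sp
        frac = 0.5 * (sm - sp) / denom if denom < 0 else 0.0
        shift_mz = (shifts[best_i] + frac) * step
        shift_mz = float(np.clip(shift_mz, -cfg.align_max_shift,
                                 cfg.align_max_shift))
    if abs(shift_mz) < 0.02 * step:   # below meaningful m/z resolution
        return spec
    out = np.interp(grid, grid + shift_mz, y, left=0.0, right=0.0)
    return spec.replace(intensity=out)


def normalize(spec: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Scale intensities: TIC mode sums to 1, max-peak mode has apex 1."""
    if cfg.normalization == "none":
        return spec
    y = spec.intensity
    if cfg.normalization == "total-ion-current":
        s = float(np.sum(y))
    else:
        s = float(np.max(y))
    if s <= 0:
        raise ValueError(f"cannot normalize all-zero spectrum {spec.sample_id!r}")
    return spec.replace(intensity=y / s)


def preprocess_pipeline(spectra: list[Spectrum], cfg: PreprocessConfig) -> SpectrumSet:
    """Run the full chain on each spectrum and assemble a SpectrumSet."""
    if not spectra:
        raise ValueError("preprocess_pipeline needs at least one spectrum")
    out = []
    for spec in spectra:
        try:
            s = resample(spec, cfg)
            if cfg.baseline_enabled:
                s = correct_baseline(s, cfg)
            s = denoise(s, cfg)
            if cfg.align_enabled:
                s = align_peaks(s, cfg)
            s = normalize(s, cfg)
        except Exception as e:
            raise type(e)(f"sample {spec.sample_id!r}: {e}") from e
        out.append(s)
    sset = assemble_set(out)
    log.info(
        "preprocessed %d spectra -> %d x %d matrix on [%g, %g]",
        len(spectra), sset.n_samples, sset.n_points, cfg.grid_lo, cfg.grid_hi,
    )
    return sset
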