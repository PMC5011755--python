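"""Synthetic SELDI-TOF-like case/control serum spectra.

The generator emulates the statistical structure the pipeline assumes for
an ovarian-cancer serum cohort: a cohort of 121 cancer and 95 healthy
samples, a raw m/z axis spanning 700-12000, Gaussian protein peaks whose
amplitudes differ by class, a decaying-exponential matrix background,
additive white detector noise, per-spectrum multiplicative amplitude
variability (lognormal), and a small per-spectrum rigid m/z
miscalibration that exercises the alignment stage.

The two hallmark serum peaks sit at m/z 3883.321 and 7766.159 with
noise-free apex intensities 126/719 in healthy samples and 130/608 in
cancer samples — the 7766 peak is lower in cancer, the 3883 peak nearly
equal, so these two peaks alone carry a deliberately weak class signal.
Additional differential peaks (configurable) set the separability of the
default cohort.

:func:`generate_latent_gaussian` samples directly from the PPCA
generative model S = W x + mu + eps and returns the true parameters, for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msio import Spectrum

__all__ = ["SimConfig", "Peak", "generate", "generate_latent_gaussian"]


@dataclass(frozen=True)
class Peak:
    """A Gaussian peak: position (m/z), class amplitudes, width sigma (m/z)."""

    position: float
    amplitude_healthy: float
    amplitude_cancer: float
    width: float


def _default_peaks() -> tuple[Peak, ...]:
    # hallmark pair (weak signal by design) + differential peaks that give
    # the cohort a clearly separable low-rank class signature
    return (
        Peak(3883.321, 126.0, 130.0, 10.0),
        Peak(7766.159, 719.0, 608.0, 20.0),
        Peak(4500.0, 220.0, 300.0, 12.0),
        Peak(6200.0, 180.0, 120.0, 16.0),
        Peak(8900.0, 90.0, 140.0, 22.0),
    )


def _default_shared_peaks() -> tuple[tuple[float, float, float], ...]:
    # class-invariant peaks: (position, amplitude, width)
    return ((2500.0, 150.0, 8.0), (5000.0, 260.0, 14.0), (9500.0, 120.0, 25.0))


@dataclass
class SimConfig:
    """Cohort and spectrum-shape parameters of the simulator.

    ``raw_n`` defaults to 36,000 points so a full cohort simulates in
    seconds; a full-fidelity 360,000-point axis is just a config change.
    """

    n_cancer: int = 121
    n_healthy: int = 95
    raw_n: int = 36000
    mz_range: tuple[float, float] = (700.0, 12000.0)
    peaks: tuple[Peak, ...] = field(default_factory=_default_peaks)
    shared_peaks: tuple[tuple[float, float, float], ...] = field(
        default_factory=_default_shared_peaks)
    jitter_sd: float = 1.5          # per-spectrum rigid m/z shift sd
    baseline: tuple[float, float] = (80.0, 2500.0)  # (amplitude, decay const)
    noise_sd: float = 8.0           # additive white-noise sd
    amp_cv: float = 0.15            # lognormal per-spectrum amplitude CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cancer < 1 or self.n_healthy < 1:
            raise ValueError("sample counts must be >= 1")
        if self.raw_n < 2:
            raise ValueError("raw_n must be >= 2")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must be increasing")
        if self.jitter_sd < 0 or self.noise_sd < 0 or self.amp_cv < 0:
            raise ValueError("sds and CV must be >= 0")
        for p in self.peaks:
            if not (lo <= p.position <= hi):
                raise ValueError(f"peak position {p.position:g} outside mz_range")
            if p.width <= 0:
                raise ValueError("peak widths must be > 0")
        for pos, _, w in self.shared_peaks:
            if not (lo <= pos <= hi):
                raise ValueError(f"shared peak position {pos:g} outside mz_range")
            if w <= 0:
                raise ValueError("peak widths must be > 0")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplicative factor with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    s2 = np.log(1.0 + cv ** 2)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2)))


def generate(cfg: SimConfig) -> list[Spectrum]:
    """Simulate the labeled cohort; deterministic under ``cfg.seed``.

    Each spectrum is the sum of class-appropriate Gaussian peaks (scaled
    by one per-spectrum lognormal amplitude factor, positions offset by
    one per-spectrum Normal(0, jitter_sd) shift), the shared peaks, an
    exponential baseline, and white noise, truncated at 0.  Cancer
    samples come first, then healthy.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mz_range
    mz = np.linspace(lo, hi, cfg.raw_n)
    amp0, decay = cfg.baseline
    base = amp0 * np.exp(-(mz - lo) / decay) if amp0 else np.zeros_like(mz)
    spectra: list[Spectrum] = []
    plan = [(1, i, cfg.n_cancer) for i in range(cfg.n_cancer)] + \
           [(0, i, cfg.n_healthy) for i in range(cfg.n_healthy)]
    for label, i, _n in plan:
        shift = rng.normal(0.0, cfg.jitter_sd) if cfg.jitter_sd else 0.0
        factor = _lognormal_factor(rng, cfg.amp_cv)
        y = base.copy()
        for p in cfg.peaks:
            amp = p.amplitude_cancer if label == 1 else p.amplitude_healthy
            y += factor * amp * np.exp(-0.5 * ((mz - p.position - shift) / p.width) ** 2)
        for pos, amp, w in cfg.shared_peaks:
            y += factor * amp * np.exp(-0.5 * ((mz - pos - shift) / w) ** 2)
        if cfg.noise_sd:
            y += rng.normal(0.0, cfg.noise_sd, size=mz.size)
        np.clip(y, 0.0, None, out=y)
        tag = "cancer" if label == 1 else "healthy"
        spectra.append(Spectrum(mz=mz, intensity=y, label=label,
                                sample_id=f"{tag}{i:03d}"))
    return spectra


def generate_latent_gaussian(n: int, d: int, q: int, *, W_norm: float = 1.0,
                             sigma2: float = 1.0, seed: int = 0
                             ) -> tuple[np.ndarray, dict]:
    """Sample S = W x + mu + eps from the PPCA generative model.

    Returns the (n, d) sample matrix and a dict with the true
    ``W`` (d x q, random orthogonal directions scaled by ``W_norm``),
    ``mu`` and ``sigma2`` for comparison against fitted estimates.  The
    true parameters depend only on (d, q, W_norm), not on ``seed``, so
    replicate draws share one ground truth.
    """
    if not 1 <= q < d:
        raise ValueError("need 1 <= q < d")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    param_rng = np.random.default_rng(abs(hash((d, q))) % (2 ** 31))
    A = param_rng.standard_normal((d, q))
    Q, _ = np.linalg.qr(A)
    W = Q * W_norm
    mu = param_rng.standard_normal(d)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, q))
    S = X @ W.T + mu
    if sigma2 > 0:
        S = S + rng.normal(0.0, np.sqrt(sigma2), size=(n, d))
    return S, {"W": W, "mu": mu, "sigma2": float(sigma2)}
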