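"""Photoacoustic signal formation, noise model, CNR and ROI definition.

Signal model: S(v) = k * mu_a(v) * Gamma(v) * phi(v), clipped to the
[0, 255] a.u. dynamic range and stored unquantized. The global scale k is
calibrated once per hardware setup so the homogeneous background slice has
a mean signal of ~4 a.u.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec
from .mclight import FluenceMap, SourceSpec, simulate_fluence

SIGNAL_MAX = 255.0
BACKGROUND_TARGET_MEAN = 4.0
CNR_ROI_THRESHOLD = 2.0


@dataclass(frozen=True)
class NoiseLevel:
    """One of the four signal noise settings.

    Level 0 is intrinsic (Monte Carlo) noise only. Levels 1-3 add a Gaussian
    additive term followed by a zero-mean multiplicative term:
    S' = (S + A) * (1 + M).
    """

    level: int
    multiplicative_sd: float
    additive_mean: float
    additive_sd: float


NOISE_LEVELS = {
    0: NoiseLevel(0, 0.0, 0.0, 0.0),
    1: NoiseLevel(1, 0.02, 0.125, 0.125),
    2: NoiseLevel(2, 0.10, 0.625, 0.625),
    3: NoiseLevel(3, 0.20, 1.25, 1.25),
}


@dataclass(frozen=True)
class BackgroundStats:
    """Mean/sd of the signal over a structure-free background slice."""

    avg: float
    std: float
    n_photons: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.std > 0:
            raise ValueError("background std must be > 0")


def calibrate_scale(phi_h: FluenceMap | np.ndarray,
                    mu_a_background: float = 0.1,
                    gamma: float = 1.0,
                    target_mean: float = BACKGROUND_TARGET_MEAN) -> float:
    """Global proportionality constant k anchoring the [0, 255] range."""
    phi = phi_h.phi if isinstance(phi_h, FluenceMap) else np.asarray(phi_h)
    mean_h = float(np.mean(mu_a_background * gamma * phi))
    if mean_h <= 0:
        raise ValueError("cannot calibrate k on a zero fluence map")
    return target_mean / mean_h


def forward_signal(mu_a: np.ndarray, phi: np.ndarray, scale_k: float,
                   gamma: float = 1.0) -> np.ndarray:
    """S = clip(k * mu_a * Gamma * phi, 0, 255), continuous-valued."""
    mu_a = np.asarray(mu_a)
    phi = np.asarray(phi)
    if mu_a.shape != phi.shape:
        raise ValueError(
            f"grid mismatch: mu_a {mu_a.shape} vs phi {phi.shape}")
    if not scale_k > 0:
        raise ValueError("scale_k must be > 0")
    return np.clip(scale_k * mu_a * gamma * phi, 0.0, SIGNAL_MAX)


def apply_noise(signal: np.ndarray, noise_level: int | NoiseLevel,
                seed: int) -> np.ndarray:
    """Additive-then-multiplicative Gaussian noise, result clipped to >= 0."""
    if isinstance(noise_level, int):
        noise_level = NOISE_LEVELS[noise_level]
    if noise_level.level == 0:
        return np.array(signal, copy=True)
    rng = np.random.default_rng(seed)
    a = rng.normal(noise_level.additive_mean, noise_level.additive_sd,
                   size=signal.shape)
    m = rng.normal(0.0, noise_level.multiplicative_sd, size=signal.shape)
    return np.clip((signal + a) * (1.0 + m), 0.0, SIGNAL_MAX)


def background_stats(grid: GridSpec, source: SourceSpec, scale_k: float,
                     mu_a_background: float = 0.1, mu_s_prime: float = 1.5,
                     gamma: float = 1.0, n_photons: int = 200_000,
                     seed: int = 0, estimator: str = "auto") -> BackgroundStats:
    """Signal statistics of a homogeneous slice, intrinsic MC noise only.

    The background standard deviation reflects Monte Carlo shot noise at the
    given photon count; no noise model is applied.
    """
    fm = simulate_fluence(np.full(grid.plane_shape, float(mu_a_background)),
                          mu_s_prime, grid.spacing_mm, source, n_photons,
                          seed, estimator=estimator)
    s = forward_signal(np.full(grid.plane_shape, float(mu_a_background)),
                       fm.phi, scale_k, gamma)
    std = float(s.std())
    if std == 0:
        raise ValueError(
            "degenerate background: zero signal variance (infinite-photon "
            "limit); CNR is undefined")
    return BackgroundStats(avg=float(s.mean()), std=std,
                           n_photons=n_photons, seed=seed)


def compute_cnr(signal, stats: BackgroundStats):
    """Contrast-to-noise ratio (S - avg(b)) / std(b), signed."""
    if not stats.std > 0:
        raise ValueError("std(b) must be > 0")
    return (np.asarray(signal, dtype=float) - stats.avg) / stats.std


def roi_mask(vessel_labels: np.ndarray, signal: np.ndarray,
             stats: BackgroundStats) -> np.ndarray:
    """Vessel voxels with CNR strictly greater than 2."""
    vessel_labels = np.asarray(vessel_labels)
    signal = np.asarray(signal)
    if vessel_labels.shape != signal.shape:
        raise ValueError("labels and signal must share the grid")
    return (vessel_labels > 0) & (compute_cnr(signal, stats)
                                  > CNR_ROI_THRESHOLD)
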