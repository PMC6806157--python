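"""Spectral (Fourier) texture features.

A 32x32 patch is transformed with the unnormalized 2D DFT, the
zero-frequency bin is shifted to the center, and the magnitude spectrum is
reduced to two profiles:

* ``Srad`` — for each radius r in 1..16, the sum of magnitudes over the
  upper semicircle of (rounded) radius r around the center.  Dominant
  spatial frequencies show up as bursts at the matching radius.
* ``Sang`` — for each of 180 one-degree-spaced lines through the center,
  the sum of 16 integer-radius magnitude samples along the line.  Oriented
  periodic patterns (vibrations, streaks) concentrate energy on few lines.

Each profile is summarized by five statistics (mean, maximum, 0-based
location of the first maximum, population variance, max - min), giving the
canonical 10-entry spectral feature vector.

Only one half-plane is profiled: a real image has a conjugate-symmetric
spectrum, so the lower half duplicates the upper.  Angular samples are
indexed modulo N — the DFT grid is periodic, and the radius-16 sample of
near-zero-degree lines would otherwise fall one pixel off the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .patch_io import Patch

N_ANGLES = 180
MAX_RADIUS = 16

SPECTRAL_FEATURE_NAMES = [
    "srad_mean", "srad_max", "srad_argmax", "srad_var", "srad_range",
    "sang_mean", "sang_max", "sang_argmax", "sang_var", "sang_range",
]


@dataclass(frozen=True)
class Spectrum:
    """Complex DFT coefficients; ``coefficients[l, k]`` follows
    F(l,k) = sum_{px,py} I(px,py) exp(-2*pi*i*(k*px + l*py)/N)."""

    coefficients: np.ndarray

    @property
    def n(self) -> int:
        return self.coefficients.shape[0]


@dataclass(frozen=True)
class MagnitudeSpectrum:
    """Non-negative magnitudes of a center-shifted spectrum."""

    magnitudes: np.ndarray

    @property
    def center(self) -> tuple[int, int]:
        n = self.magnitudes.shape[0]
        return (n // 2, n // 2)


@dataclass(frozen=True)
class SpectralProfiles:
    srad: np.ndarray  # length 16, index r-1 holds radius r
    sang: np.ndarray  # length 180, index k holds angle k degrees


@dataclass(frozen=True)
class ProfileStats:
    mean: float
    maximum: float
    argmax_index: int
    variance: float
    range: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean, self.maximum, float(self.argmax_index),
             self.variance, self.range]
        )


def dft2(patch: Patch) -> Spectrum:
    """Unnormalized forward 2D DFT of a square, even-sided patch."""
    h, w = patch.height, patch.width
    if h != w or h % 2 != 0:
        raise ValueError(f"patch must be square with even side, got {h}x{w}")
    # fft2(I)[k, l] sums I[px, py] e^{-2pi i (k px + l py)/N}; transpose to [l, k]
    return Spectrum(np.fft.fft2(patch.pixels).T)


def shift_center(spectrum: Spectrum) -> Spectrum:
    """Swap quadrants so bin (0,0) sits at (N/2, N/2)."""
    if spectrum.n % 2 != 0:
        raise ValueError("center shift requires an even transform size")
    return Spectrum(np.fft.fftshift(spectrum.coefficients))


def magnitude(spectrum: Spectrum) -> MagnitudeSpectrum:
    """Elementwise complex modulus; no logarithmic scaling."""
    return MagnitudeSpectrum(np.abs(spectrum.coefficients))


@lru_cache(maxsize=4)
def _radial_bins(n: int) -> np.ndarray:
    """Map each upper-half-plane pixel to its rounded radius (0 = unused)."""
    c = n // 2
    rows, cols = np.mgrid[0:n, 0:n]
    dist = np.hypot(rows - c, cols - c)
    radius = np.rint(dist).astype(np.int64)
    mask = (rows <= c) & ~((rows == c) & (cols == c)) & (radius >= 1) & (radius <= c)
    return np.where(mask, radius, 0)


def radial_sums(mag: MagnitudeSpectrum) -> np.ndarray:
    """Srad: per-radius magnitude sums over the upper semicircle.

    The input must already be center-shifted.  The DC bin is excluded;
    pixels whose rounded distance exceeds N/2 (the grid corners) are
    discarded.
    """
    m = mag.magnitudes
    n = m.shape[0]
    bins = _radial_bins(n)
    sums = np.bincount(bins.ravel(), weights=m.ravel(), minlength=n // 2 + 1)
    return sums[1 : n // 2 + 1]


@lru_cache(maxsize=4)
def _angular_samples(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of shape (180, N/2): sample pixel of each (angle, radius)."""
    c = n // 2
    theta = np.arange(N_ANGLES) * np.pi / N_ANGLES
    r = np.arange(1, c + 1)
    rows = (c - np.rint(np.outer(np.sin(theta), r))).astype(np.int64) % n
    cols = (c + np.rint(np.outer(np.cos(theta), r))).astype(np.int64) % n
    return rows, cols


def angular_sums(mag: MagnitudeSpectrum) -> np.ndarray:
    """Sang: per-angle sums of 16 integer-radius samples along each of 180
    one-degree-spaced lines from the center into the upper half-plane.

    Each (angle, radius) pair contributes exactly one nearest-pixel sample;
    samples are not deduplicated across angles.  Indices wrap modulo N.
    """
    m = mag.magnitudes
    rows, cols = _angular_samples(m.shape[0])
    return m[rows, cols].sum(axis=1)


def spectral_profiles(mag: MagnitudeSpectrum) -> SpectralProfiles:
    return SpectralProfiles(radial_sums(mag), angular_sums(mag))


def profile_stats(profile: np.ndarray) -> ProfileStats:
    """Five summary statistics of a profile.

    Variance is the population variance; argmax is the smallest index
    attaining the maximum.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("profile must be a non-empty 1D array")
    return ProfileStats(
        mean=float(p.mean()),
        maximum=float(p.max()),
        argmax_index=int(p.argmax()),
        variance=float(p.var()),
        range=float(p.max() - p.min()),
    )


def spectral_features(patch: Patch) -> np.ndarray:
    """The 10 spectral features: stats(Srad) then stats(Sang), each in order
    (mean, max, argmax, variance, range)."""
    mag = magnitude(shift_center(dft2(patch)))
    prof = spectral_profiles(mag)
    return np.concatenate(
        [profile_stats(prof.srad).as_array(), profile_stats(prof.sang).as_array()]
    )
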