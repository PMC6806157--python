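"""Haar wavelet energy features.

A 32x32 patch is decomposed with a 3-level separable 2D Haar transform:
at each level every row is filtered into (approximation, detail) halves,
then every column of the row result, yielding four channels — approximation
A plus horizontal (H), vertical (V) and diagonal (D) detail — and the
approximation is recursed.  Three levels give ten channels:
A3 and (H, V, D) at levels 3, 2, 1 with sizes 4x4, 4x4/8x8/16x16.

The orthonormal filter pair (1/sqrt(2) scaling) is used so that the total
squared sum over all ten channels equals the input's squared sum exactly —
a testable conservation law.  Any fixed rescaling would only scale features
uniformly, which an axis-aligned decision tree is invariant to.

The per-channel feature is the mean absolute coefficient value
E = (1/(N*M)) * sum |W(p)| over the channel's own N x M grid; blob-like
binding excitations deposit energy in the low and middle detail channels,
while smooth negatives keep it in the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patch_io import Patch

_SQRT2 = np.sqrt(2.0)

# Canonical channel order: approximation first, then coarse-to-fine details.
CHANNEL_NAMES = ["A3", "H3", "V3", "D3", "H2", "V2", "D2", "H1", "V1", "D1"]
WAVELET_FEATURE_NAMES = [f"E_{c}" for c in CHANNEL_NAMES]


@dataclass(frozen=True)
class WaveletDecomposition:
    """Ten channels of the 3-level Haar transform, keyed by CHANNEL_NAMES."""

    channels: dict[str, np.ndarray]
    levels: int

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def squared_sum(self) -> float:
        return float(sum(np.sum(ch**2) for ch in self.channels.values()))


def haar_step_1d(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One orthonormal Haar analysis step on a 1D signal of even length.

    approx[i] = (v[2i] + v[2i+1]) / sqrt(2)
    detail[i] = (v[2i] - v[2i+1]) / sqrt(2)
    """
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or v.size < 2 or v.size % 2 != 0:
        raise ValueError("haar step needs a 1D array of even length >= 2")
    even, odd = v[0::2], v[1::2]
    return (even + odd) / _SQRT2, (even - odd) / _SQRT2


def _haar_level_2d(image: np.ndarray) -> tuple[np.ndarray, ...]:
    """One 2D level: rows first, then columns of the row result.

    Returns (A, H, V, D) where H pairs row-approximation with column-detail,
    V the reverse, and D is detail in both directions.
    """
    # rows
    ra = (image[:, 0::2] + image[:, 1::2]) / _SQRT2
    rd = (image[:, 0::2] - image[:, 1::2]) / _SQRT2
    # columns
    a = (ra[0::2, :] + ra[1::2, :]) / _SQRT2
    h = (ra[0::2, :] - ra[1::2, :]) / _SQRT2
    v = (rd[0::2, :] + rd[1::2, :]) / _SQRT2
    d = (rd[0::2, :] - rd[1::2, :]) / _SQRT2
    return a, h, v, d


def haar_fwt2(patch: Patch, levels: int = 3) -> WaveletDecomposition:
    """Multi-level separable 2D Haar decomposition of a square patch.

    Row and column filtering complete within each level before the
    approximation channel is recursed; interleaving the levels differently
    would produce a different (non-standard) transform.
    """
    side = patch.height
    if patch.width != side or side % (2**levels) != 0:
        raise ValueError(
            f"patch side {patch.height}x{patch.width} must be square and "
            f"divisible by 2^{levels}"
        )
    channels: dict[str, np.ndarray] = {}
    approx = patch.pixels
    for level in range(1, levels + 1):
        approx, h, v, d = _haar_level_2d(approx)
        channels[f"H{level}"] = h
        channels[f"V{level}"] = v
        channels[f"D{level}"] = d
    channels[f"A{levels}"] = approx
    ordered = {name: channels[name] for name in _channel_names(levels)}
    return WaveletDecomposition(ordered, levels)


def _channel_names(levels: int) -> list[str]:
    names = [f"A{levels}"]
    for level in range(levels, 0, -1):
        names += [f"H{level}", f"V{level}", f"D{level}"]
    return names


def channel_energy(channel: np.ndarray) -> float:
    """Mean absolute coefficient value of one channel."""
    ch = np.asarray(channel, dtype=np.float64)
    if ch.size == 0:
        raise ValueError("channel must be non-empty")
    return float(np.abs(ch).mean())


def wavelet_features(patch: Patch) -> np.ndarray:
    """The 10 wavelet energies in canonical order
    [A3, H3, V3, D3, H2, V2, D2, H1, V1, D1]."""
    dec = haar_fwt2(patch, levels=3)
    return np.array([channel_energy(dec[name]) for name in CHANNEL_NAMES])
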