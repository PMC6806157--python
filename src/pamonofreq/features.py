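"""Canonical 20-entry feature vector: 10 spectral + 10 wavelet features.

The fixed ordering is the contract between extraction, stored feature
tables, trained models and exported code; models are only valid for the
exact feature layout they were trained on.
"""

from __future__ import annotations

import numpy as np

from .fft_features import SPECTRAL_FEATURE_NAMES, spectral_features
from .fwt_features import WAVELET_FEATURE_NAMES, wavelet_features
from .patch_io import FeatureTable, Patch

CANONICAL_FEATURE_NAMES: list[str] = SPECTRAL_FEATURE_NAMES + WAVELET_FEATURE_NAMES

FEATURE_SETS = {
    "fft": list(range(0, 10)),
    "fwt": list(range(10, 20)),
    "both": list(range(0, 20)),
}


def feature_set_indices(feature_set: str) -> list[int]:
    try:
        return list(FEATURE_SETS[feature_set])
    except KeyError:
        raise ValueError(
            f"unknown feature set {feature_set!r}; choose from {sorted(FEATURE_SETS)}"
        ) from None


def extract_features(patch: Patch, feature_set: str = "both") -> np.ndarray:
    """Extract the canonical features of one 32x32 patch.

    ``feature_set`` selects the spectral half ('fft'), the wavelet half
    ('fwt'), or the full 20-vector ('both').
    """
    idx = feature_set_indices(feature_set)
    parts = []
    if any(i < 10 for i in idx):
        parts.append(spectral_features(patch))
    else:
        parts.append(np.full(10, np.nan))
    if any(i >= 10 for i in idx):
        parts.append(wavelet_features(patch))
    else:
        parts.append(np.full(10, np.nan))
    return np.concatenate(parts)[idx]


def extract_table(
    patches: list[Patch],
    labels: np.ndarray | None = None,
    feature_set: str = "both",
) -> FeatureTable:
    """Extract a FeatureTable for a list of patches (one row per patch)."""
    idx = feature_set_indices(feature_set)
    values = np.stack([extract_features(p, feature_set) for p in patches])
    names = [CANONICAL_FEATURE_NAMES[i] for i in idx]
    return FeatureTable(values, names, labels)
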