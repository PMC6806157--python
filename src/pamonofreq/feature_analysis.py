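"""PCA feature ranking, incremental-subset accuracy curves, and extraction
planning for reduced feature subsets.

Exhaustively scoring all 2^20 - 1 feature subsets is infeasible; instead
features are ranked once by the variance they account for in a principal
component analysis of the standardized training features, and a classifier
is retrained on the top-k subsets for k = 1..d.  The ranking score is the
explained-variance-ratio-weighted sum of squared loadings,

    score(f) = sum_j EVR_j * loading(f, j)^2,

a standard operationalization of "variance accounted for": it distributes
each component's share of the total variance over the features by their
squared contribution to that component's direction.

An ExtractionPlan maps a chosen subset of the canonical 20 features back
to the minimal set of pipeline stages needed to compute it — e.g. a model
using only radial-profile statistics never needs the 180-line angular
profile, which is the most expensive part of the spectral extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .classifier import TrainConfig, train_tree
from .fft_features import (
    angular_sums,
    dft2,
    magnitude,
    profile_stats,
    radial_sums,
    shift_center,
)
from .fwt_features import CHANNEL_NAMES, channel_energy, haar_fwt2
from .metrics import accuracy, confusion
from .patch_io import FeatureTable, Patch

ALL_STAGES = (
    "dft2",
    "shift",
    "magnitude",
    "radial_sums",
    "angular_sums",
    "haar_fwt2",
    "energies",
)

_STAGE_DEPS = {
    "dft2": set(),
    "shift": {"dft2"},
    "magnitude": {"shift", "dft2"},
    "radial_sums": {"magnitude", "shift", "dft2"},
    "angular_sums": {"magnitude", "shift", "dft2"},
    "haar_fwt2": set(),
    "energies": {"haar_fwt2"},
}

# terminal stage -> canonical feature indices it yields
_STAGE_FEATURES = {
    "radial_sums": tuple(range(0, 5)),
    "angular_sums": tuple(range(5, 10)),
    "energies": tuple(range(10, 20)),
}


@dataclass(frozen=True)
class FeatureRanking:
    """Permutation of feature indices, most important first, with scores."""

    order: tuple[int, ...]
    scores: tuple[float, ...]  # aligned with order, non-increasing

    @property
    def d(self) -> int:
        return len(self.order)


@dataclass(frozen=True)
class AccuracyCurve:
    """Test accuracy of a classifier retrained on the top-k features."""

    points: tuple[tuple[int, float], ...]  # (k, accuracy), k = 1..d

    def as_dict(self) -> dict[int, float]:
        return dict(self.points)


@dataclass(frozen=True)
class ExtractionPlan:
    """Dependency-closed set of extraction stages."""

    stages: frozenset[str]

    def __post_init__(self) -> None:
        unknown = self.stages - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            if not _STAGE_DEPS[stage] <= self.stages:
                raise ValueError(f"plan not closed under dependencies at {stage!r}")

    @property
    def feature_indices(self) -> tuple[int, ...]:
        """Canonical indices of the features this plan produces, ascending."""
        out: list[int] = []
        for stage, idx in _STAGE_FEATURES.items():
            if stage in self.stages:
                out.extend(idx)
        return tuple(sorted(out))

    def ordered_stages(self) -> tuple[str, ...]:
        return tuple(s for s in ALL_STAGES if s in self.stages)


def rank_features_pca(table: FeatureTable) -> FeatureRanking:
    """Rank features by PCA variance accounted for, descending.

    Features are standardized to zero mean and unit deviation first
    (constant columns become all-zero and score 0).  Ties break toward the
    smaller feature index.
    """
    X = np.asarray(table.values, dtype=np.float64)
    if X.size == 0:
        raise ValueError("empty feature table")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    nonconst = sd > 0
    Z = np.zeros_like(X)
    Z[:, nonconst] = (X[:, nonconst] - mu[nonconst]) / sd[nonconst]
    n_comp = min(Z.shape[0], int(nonconst.sum()))
    scores = np.zeros(X.shape[1])
    if n_comp > 0:
        pca = PCA(n_components=n_comp, svd_solver="full")
        pca.fit(Z)
        # EVR-weighted squared loadings; rows of components_ are unit vectors
        scores = pca.explained_variance_ratio_ @ pca.components_**2
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(tuple(int(i) for i in order),
                          tuple(float(scores[i]) for i in order))


def accuracy_curve(
    train: FeatureTable,
    test: FeatureTable,
    ranking: FeatureRanking,
    config: TrainConfig = TrainConfig(),
) -> AccuracyCurve:
    """Retrain on the top-k ranked features for k = 1..d; record test accuracy."""
    if ranking.d != train.d or train.d != test.d:
        raise ValueError("ranking and tables must share one feature space")
    points = []
    for k in range(1, ranking.d + 1):
        idx = list(ranking.order[:k])
        model = train_tree(train.select(idx), config)
        preds = [model.predict(row) for row in test.select(idx).values]
        points.append((k, accuracy(confusion(preds, test.labels))))
    return AccuracyCurve(tuple(points))


def extraction_plan(selected: set[int]) -> ExtractionPlan:
    """Minimal dependency-closed stage set producing the selected features.

    ``selected`` holds canonical feature indices (0..19); e.g. a model
    restricted to radial-profile statistics {0..4} needs no angular sums
    and no wavelet transform at all.
    """
    sel = set(selected)
    if not sel:
        raise ValueError("selection must be non-empty")
    if not sel <= set(range(20)):
        raise ValueError("feature indices must lie in 0..19")
    stages: set[str] = set()
    for stage, idx in _STAGE_FEATURES.items():
        if sel & set(idx):
            stages.add(stage)
            stages |= _STAGE_DEPS[stage]
    return ExtractionPlan(frozenset(stages))


def extract_with_plan(patch: Patch, plan: ExtractionPlan) -> np.ndarray:
    """Run only the plan's stages; return its features in canonical order."""
    values = np.full(20, np.nan)
    if {"radial_sums", "angular_sums"} & plan.stages:
        mag = magnitude(shift_center(dft2(patch)))
        if "radial_sums" in plan.stages:
            values[0:5] = profile_stats(radial_sums(mag)).as_array()
        if "angular_sums" in plan.stages:
            values[5:10] = profile_stats(angular_sums(mag)).as_array()
    if "energies" in plan.stages:
        dec = haar_fwt2(patch, levels=3)
        values[10:20] = [channel_energy(dec[c]) for c in CHANNEL_NAMES]
    return values[list(plan.feature_indices)]
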