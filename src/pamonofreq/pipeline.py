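"""End-to-end pipeline operations: single-patch classification, the timing
benchmark, and the one-seed synthesize/extract/train/evaluate run.

The benchmark mirrors an embedded deployment protocol: batches of random
grayscale images are generated up front, then features are extracted and
classified per image under a monotonic nanosecond clock, with the time
split into transform (FFT/FWT), post-transform (shift + magnitude),
summing (profiles/energies + statistics) and tree stages.  Defaults (25
images per batch, 40 batches = 1000 runs) keep the protocol portable
across platforms.  Reported times are informational: they characterize the
machine the benchmark ran on, and trees must be retrained on features
extracted on the platform where they will run.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .classifier import (
    DecisionTreeModel,
    ForestModel,
    TrainConfig,
    train_forest,
    train_tree,
)
from .feature_analysis import ExtractionPlan, extract_with_plan, extraction_plan
from .features import extract_table, feature_set_indices
from .fft_features import (
    angular_sums,
    dft2,
    magnitude,
    profile_stats,
    radial_sums,
    shift_center,
)
from .fwt_features import CHANNEL_NAMES, channel_energy, haar_fwt2
from .metrics import confusion, report
from .patch_io import Patch, center_crop
from .synthetic_data import SynthConfig, generate_patches

logger = logging.getLogger("pamonofreq")

BENCHMARK_STAGES = ("Transf.", "PT", "Sum", "DT", "Total")


class PlanModelMismatchError(ValueError):
    """The model's feature dimensionality differs from what the plan yields."""


@dataclass(frozen=True)
class BenchmarkReport:
    """Per-image timing decomposition in nanoseconds."""

    mean_ns: dict[str, float]  # keyed by BENCHMARK_STAGES
    std_ns: dict[str, float]
    runs: int

    def format_table(self) -> str:
        header = "  ".join(f"{s:>12}" for s in BENCHMARK_STAGES)
        means = "  ".join(f"{self.mean_ns[s]:12.0f}" for s in BENCHMARK_STAGES)
        stds = "  ".join(f"{self.std_ns[s]:12.0f}" for s in BENCHMARK_STAGES)
        return (
            f"runs: {self.runs}\n{header}\nmean  {means}\nstd   {stds}"
        )


def classify_patch(
    patch: Patch,
    model: DecisionTreeModel | ForestModel,
    plan: ExtractionPlan | None = None,
) -> int:
    """Crop, extract the planned features, and classify one patch.

    The model must have been trained on exactly the features the plan
    produces, in canonical order.  48x48 detection patches are handled
    identically to their pre-cropped 32x32 centers.
    """
    if plan is None:
        plan = extraction_plan(set(range(20)))
    if len(plan.feature_indices) != model.n_features:
        raise PlanModelMismatchError(
            f"plan yields {len(plan.feature_indices)} features but model "
            f"expects {model.n_features}"
        )
    cropped = center_crop(patch, 32)
    return model.predict(extract_with_plan(cropped, plan))


def _timed_extract(patch: Patch, plan: ExtractionPlan) -> tuple[np.ndarray, dict]:
    """Planned extraction with a per-stage nanosecond breakdown."""
    times = {"Transf.": 0, "PT": 0, "Sum": 0}
    values = np.full(20, np.nan)
    spectral = bool({"radial_sums", "angular_sums"} & plan.stages)
    if spectral:
        t0 = time.perf_counter_ns()
        spec = dft2(patch)
        t1 = time.perf_counter_ns()
        mag = magnitude(shift_center(spec))
        t2 = time.perf_counter_ns()
        if "radial_sums" in plan.stages:
            values[0:5] = profile_stats(radial_sums(mag)).as_array()
        if "angular_sums" in plan.stages:
            values[5:10] = profile_stats(angular_sums(mag)).as_array()
        t3 = time.perf_counter_ns()
        times["Transf."] += t1 - t0
        times["PT"] += t2 - t1
        times["Sum"] += t3 - t2
    if "energies" in plan.stages:
        t0 = time.perf_counter_ns()
        dec = haar_fwt2(patch, levels=3)
        t1 = time.perf_counter_ns()
        values[10:20] = [channel_energy(dec[c]) for c in CHANNEL_NAMES]
        t2 = time.perf_counter_ns()
        times["Transf."] += t1 - t0
        times["Sum"] += t2 - t1
    return values[list(plan.feature_indices)], times


def run_benchmark(
    plan: ExtractionPlan | None = None,
    batch_size: int = 25,
    batches: int = 40,
    model: DecisionTreeModel | ForestModel | None = None,
    seed: int = 0,
    image_size: int = 32,
) -> BenchmarkReport:
    """Time planned extraction + classification on random grayscale images.

    Images are uniform in [0, 1]; runs = batch_size * batches.  If no model
    is given, a trivial depth-0 tree stands in so the tree stage is timed.
    """
    if batch_size < 1 or batches < 1:
        raise ValueError("batch_size and batches must be >= 1")
    if plan is None:
        plan = extraction_plan(set(range(20)))
    if model is None:
        from .classifier import TreeNode

        model = DecisionTreeModel(
            (TreeNode(klass=0),), n_features=len(plan.feature_indices)
        )
    rng = np.random.default_rng(seed)
    rows: list[dict[str, float]] = []
    for _ in range(batches):
        batch = [
            Patch(rng.uniform(0.0, 1.0, size=(image_size, image_size)))
            for _ in range(batch_size)
        ]
        for patch in batch:
            t0 = time.perf_counter_ns()
            features, stage_ns = _timed_extract(patch, plan)
            t1 = time.perf_counter_ns()
            model.predict(features)
            t2 = time.perf_counter_ns()
            stage_ns["DT"] = t2 - t1
            stage_ns["Total"] = t2 - t0
            rows.append(stage_ns)
    arr = {s: np.array([r[s] for r in rows], dtype=np.float64) for s in BENCHMARK_STAGES}
    return BenchmarkReport(
        mean_ns={s: float(v.mean()) for s, v in arr.items()},
        std_ns={s: float(v.std()) for s, v in arr.items()},
        runs=len(rows),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """One-seed configuration of the full synthetic evaluation run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    n: int = 4000
    train_fraction: float = 0.7
    feature_set: str = "both"  # fft | fwt | both
    train: TrainConfig = field(default_factory=TrainConfig)


def end_to_end(config: PipelineConfig = PipelineConfig()) -> dict:
    """Synthesize, split, extract, train, and evaluate in one seeded run.

    Returns the evaluation report (confusion counts, precision, recall,
    accuracy) plus the split sizes and the trained model.  Bit-identical
    across repeated runs with the same config.
    """
    logger.info("synth: n=%d seed=%d balance=%.2f",
                config.n, config.synth.seed, config.synth.balance)
    patches, labels = generate_patches(config.synth, config.n)
    patches = [center_crop(p, 32) for p in patches]
    n_train = int(round(config.train_fraction * config.n))
    logger.info("split: %d train / %d test", n_train, config.n - n_train)

    t_start = time.perf_counter()
    train_table = extract_table(patches[:n_train], labels[:n_train], config.feature_set)
    test_table = extract_table(patches[n_train:], labels[n_train:], config.feature_set)
    logger.info("extract: %d features (%s) in %.1fs",
                train_table.d, config.feature_set, time.perf_counter() - t_start)

    if config.train.n_trees > 1:
        model = train_forest(train_table, config.train)
    else:
        model = train_tree(train_table, config.train)
    logger.info("train: max_depth=%d n_trees=%d seed=%d",
                config.train.max_depth, config.train.n_trees, config.train.seed)

    preds = [model.predict(row) for row in test_table.values]
    result = report(confusion(preds, test_table.labels))
    result.update(
        n_train=n_train,
        n_test=config.n - n_train,
        feature_set=config.feature_set,
        feature_names=list(train_table.feature_names),
    )
    logger.info("evaluate: accuracy=%.4f precision=%.4f recall=%.4f",
                result["accuracy"], result["precision"], result["recall"])
    return {"report": result, "model": model,
            "train_table": train_table, "test_table": test_table}
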