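"""Patch, manifest and feature-table I/O.

Patches are small single-channel grayscale images cut from PAMONO sensor
frames around candidate particle detections.  The detection stage emits
48x48 patches; the classifier consumes the 32x32 center crop.  Intensities
are normalized to [0, 1] by the integer dtype maximum so that 8- and
16-bit sources land on the same scale — the spectral and wavelet features
are scale-dependent, so training and inference must share this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
import tifffile


class PatchIOError(Exception):
    """Base class for patch/manifest/feature-table I/O failures."""


class MissingFileError(PatchIOError):
    """The requested file does not exist."""


class MultiChannelImageError(PatchIOError):
    """The image has more than one channel; patches must be grayscale."""


class UnsupportedBitDepthError(PatchIOError):
    """The image dtype is neither 8- nor 16-bit unsigned integer."""


class PatchSizeError(PatchIOError, ValueError):
    """A patch is too small for the requested crop (padding is never done)."""


class ManifestError(PatchIOError):
    """A dataset manifest row is malformed or carries a non-binary label."""


class FeatureTableError(PatchIOError):
    """A feature-table file is inconsistent (duplicate or mismatched columns)."""


@dataclass(frozen=True)
class Patch:
    """A 2D grid of grayscale intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("patch must be a non-empty 2D array")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("patch intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: int


@dataclass(frozen=True)
class DatasetManifest:
    """Ordered list of (patch path, binary label) records; label 1 = 'virus'."""

    records: tuple[ManifestRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def paths(self) -> list[str]:
        return [r.path for r in self.records]

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)


@dataclass
class FeatureTable:
    """n x d table of feature values with named columns and optional labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("feature table must be a non-empty 2D array")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature name count must match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (self.values.shape[0],):
                raise ValueError("labels length must match row count")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select(self, indices: list[int] | np.ndarray) -> "FeatureTable":
        """Column subset in the given order, keeping labels."""
        idx = list(indices)
        return FeatureTable(
            self.values[:, idx],
            [self.feature_names[i] for i in idx],
            None if self.labels is None else self.labels.copy(),
        )


def read_patch(path: str | Path) -> Patch:
    """Load a single-channel 8- or 16-bit grayscale image as a Patch.

    Intensities are divided by the dtype maximum (255 or 65535).
    """
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such patch file: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        with Image.open(path) as img:
            arr = np.asarray(img)
    if arr.ndim != 2:
        raise MultiChannelImageError(
            f"{path}: expected a single-channel image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        maxval = 255.0
    elif arr.dtype == np.uint16:
        maxval = 65535.0
    else:
        raise UnsupportedBitDepthError(
            f"{path}: unsupported dtype {arr.dtype}; need uint8 or uint16"
        )
    return Patch(arr.astype(np.float64) / maxval)


def write_patch(patch: Patch, path: str | Path, bit_depth: int = 8) -> None:
    """Quantize a Patch to the given bit depth and write it as PNG/TIFF."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.rint(patch.pixels * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.rint(patch.pixels * 65535.0).astype(np.uint16)
    else:
        raise UnsupportedBitDepthError(f"bit_depth must be 8 or 16, got {bit_depth}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), arr)
    else:
        Image.fromarray(arr).save(path)


def center_crop(patch: Patch, size: int = 32) -> Patch:
    """Cut the size x size center region of a patch.

    The top-left corner sits at (floor((H-size)/2), floor((W-size)/2)).
    Patches smaller than the target size raise; zero-padding is forbidden
    because padded spectra interpolate and degrade spectral features.
    """
    if patch.height < size or patch.width < size:
        raise PatchSizeError(
            f"cannot crop {size}x{size} from {patch.height}x{patch.width}; "
            "padding is not allowed"
        )
    r0 = (patch.height - size) // 2
    c0 = (patch.width - size) // 2
    return Patch(patch.pixels[r0 : r0 + size, c0 : c0 + size].copy())


def load_manifest(path: str | Path) -> DatasetManifest:
    """Read a 'path,label' CSV manifest; labels must be 0 or 1."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such manifest: {path}")
    try:
        df = pd.read_csv(path, dtype={"path": str})
    except Exception as exc:  # malformed CSV
        raise ManifestError(f"cannot parse manifest {path}: {exc}") from exc
    if list(df.columns) != ["path", "label"]:
        raise ManifestError(
            f"manifest header must be 'path,label', got {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        if not isinstance(row["path"], str) or not row["path"]:
            raise ManifestError(f"empty path in manifest {path}")
        try:
            label = int(row["label"])
        except (TypeError, ValueError) as exc:
            raise ManifestError(f"non-integer label {row['label']!r}") from exc
        if label not in (0, 1):
            raise ManifestError(f"label must be 0 or 1, got {label}")
        records.append(ManifestRecord(row["path"], label))
    return DatasetManifest(tuple(records))


def save_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    df = pd.DataFrame(
        {"path": [r.path for r in manifest.records],
         "label": [r.label for r in manifest.records]}
    )
    df.to_csv(path, index=False)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write the table as CSV at 17 significant digits (lossless for float64)."""
    data = {name: table.values[:, j] for j, name in enumerate(table.feature_names)}
    df = pd.DataFrame(data)
    if table.labels is not None:
        df["label"] = table.labels
    df.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"no such feature table: {path}")
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh), [])
    if len(set(header)) != len(header):
        raise FeatureTableError(f"duplicate column names in {path}")
    df = pd.read_csv(path)
    labels = None
    names = header
    if "label" in header:
        labels = df["label"].to_numpy(dtype=np.int64)
        names = [c for c in header if c != "label"]
        df = df[names]
    return FeatureTable(df.to_numpy(dtype=np.float64), list(names), labels)
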