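"""Seeded generator of PAMONO-like sensor patches.

On a PAMONO (surface-plasmon-resonance) sensor, a nanoparticle binding
appears as a localized intensity step: a blob-like excitation surrounded by
decaying wave-like rings.  Positive patches are modeled as

    background + A*exp(-d^2 / 2 sigma^2)                    (blob core)
               + B*exp(-d / tau) * sin(2 pi d / lambda + phi)  (rings)
               + Gaussian noise,

with d the distance to a jittered center and per-patch parameters drawn
from configured ranges.  Negative patches contain the confounders that
cause false positives in practice: pure sensor noise, low-frequency plane
sinusoids (mechanical vibration), or an oriented linear streak (artifact),
mixed in configurable proportions.

This generative model is a stand-in emulating the described appearance of
real sensor patches; it makes no claim to match the real data distribution
(amplitude/SNR ranges for specific particle sizes are exposed as
parameters, not asserted).  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patch_io import DatasetManifest, ManifestRecord, Patch, save_manifest, write_patch


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic patch generator.

    Amplitudes are intensity fractions on the [0, 1] scale; lengths are in
    pixels.  Defaults keep every pixel clampable to [0, 1] around the 0.5
    background.
    """

    patch_size: int = 48
    blob_amplitude: tuple[float, float] = (0.05, 0.25)
    blob_sigma: tuple[float, float] = (2.0, 5.0)
    ring_amplitude_fraction: float = 0.4
    ring_wavelength: tuple[float, float] = (4.0, 10.0)
    ring_decay: float = 8.0
    background: float = 0.5
    noise_sd: float = 0.02
    negative_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # noise/vibration/streak
    center_jitter: float = 3.0
    balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.balance <= 1.0:
            raise ValueError("balance must be in [0, 1]")
        if abs(sum(self.negative_mix) - 1.0) > 1e-9:
            raise ValueError("negative_mix fractions must sum to 1")
        if self.patch_size < 32:
            raise ValueError("patch_size must be >= 32")
        if self.noise_sd < 0 or self.ring_decay <= 0:
            raise ValueError("noise_sd must be >= 0 and ring_decay > 0")


def _distance_grid(size: int, center: tuple[float, float]) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size]
    return np.hypot(rows - center[0], cols - center[1])


def _finish(image: np.ndarray, config: SynthConfig, rng: np.random.Generator) -> Patch:
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    return Patch(np.clip(image, 0.0, 1.0))


def make_positive(config: SynthConfig, rng: np.random.Generator) -> Patch:
    """One particle-binding patch: Gaussian blob plus decaying radial waves."""
    size = config.patch_size
    c = (size - 1) / 2.0
    jitter = rng.uniform(-config.center_jitter, config.center_jitter, size=2)
    d = _distance_grid(size, (c + jitter[0], c + jitter[1]))
    amp = rng.uniform(*config.blob_amplitude)
    sigma = rng.uniform(*config.blob_sigma)
    wavelength = rng.uniform(*config.ring_wavelength)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    blob = amp * np.exp(-(d**2) / (2.0 * sigma**2))
    rings = (
        config.ring_amplitude_fraction
        * amp
        * np.exp(-d / config.ring_decay)
        * np.sin(2.0 * np.pi * d / wavelength + phase)
    )
    return _finish(config.background + blob + rings, config, rng)


def make_negative(config: SynthConfig, rng: np.random.Generator) -> Patch:
    """One non-binding patch: noise, a vibration sinusoid, or a streak."""
    size = config.patch_size
    kind = rng.choice(3, p=np.asarray(config.negative_mix, dtype=np.float64))
    base = np.full((size, size), config.background)
    if kind == 1:  # plane sinusoid from mechanical vibration
        amp = rng.uniform(0.02, 0.08)
        wavelength = rng.uniform(*config.ring_wavelength)
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        rows, cols = np.mgrid[0:size, 0:size]
        proj = rows * np.sin(theta) + cols * np.cos(theta)
        base = base + amp * np.sin(2.0 * np.pi * proj / wavelength + phase)
    elif kind == 2:  # oriented linear streak artifact (Gaussian ridge)
        amp = rng.uniform(0.05, 0.2) * rng.choice((-1.0, 1.0))
        width = rng.uniform(1.0, 3.0)
        theta = rng.uniform(0.0, np.pi)
        offset = rng.uniform(-size / 4.0, size / 4.0)
        rows, cols = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2.0
        dist = (rows - c) * np.cos(theta) - (cols - c) * np.sin(theta) - offset
        base = base + amp * np.exp(-(dist**2) / (2.0 * width**2))
    return _finish(base, config, rng)


def generate_patches(
    config: SynthConfig, n: int
) -> tuple[list[Patch], np.ndarray]:
    """Generate n patches in memory with shuffled labels (1 = binding).

    The positive count is round(n * balance); ordering is a seeded shuffle.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(config.seed)
    n_pos = round(n * config.balance)
    labels = np.array([1] * n_pos + [0] * (n - n_pos), dtype=np.int64)
    rng.shuffle(labels)
    patches = [
        make_positive(config, rng) if y == 1 else make_negative(config, rng)
        for y in labels
    ]
    return patches, labels


def generate_dataset(config: SynthConfig, n: int, out_dir: str | Path) -> DatasetManifest:
    """Write n synthetic patches as 8-bit PNGs plus a 'path,label' manifest.

    Fully reproducible: the same config and seed yield byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patches, labels = generate_patches(config, n)
    records = []
    for i, (patch, label) in enumerate(zip(patches, labels)):
        name = f"patch_{i:05d}.png"
        write_patch(patch, out_dir / name, bit_depth=8)
        records.append(ManifestRecord(str(out_dir / name), int(label)))
    manifest = DatasetManifest(tuple(records))
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest
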