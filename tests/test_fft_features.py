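"""Spectral feature extraction against independent brute-force oracles."""

import numpy as np
import pytest

from pamonofreq.fft_features import (
    MagnitudeSpectrum,
    Spectrum,
    angular_sums,
    dft2,
    magnitude,
    profile_stats,
    radial_sums,
    shift_center,
    spectral_features,
)
from pamonofreq.patch_io import Patch

# ---------------------------------------------------------------------------
# oracles: direct scalar evaluations, independent of the numpy-vectorized path


def dft2_oracle(image):
    """Direct O(N^4) double-sum DFT, indexed [l, k]."""
    n = image.shape[0]
    F = np.zeros((n, n), dtype=complex)
    for l in range(n):
        for k in range(n):
            acc = 0.0j
            for px in range(n):
                for py in range(n):
                    acc += image[px, py] * np.exp(-2j * np.pi * (k * px + l * py) / n)
            F[l, k] = acc
    return F


def radial_sums_oracle(mag):
    """Brute-force pixel enumeration and radius binning."""
    n = mag.shape[0]
    c = n // 2
    sums = np.zeros(c)
    for row in range(n):
        for col in range(n):
            if row > c or (row == c and col == c):
                continue
            r = round(np.hypot(row - c, col - c))
            if 1 <= r <= c:
                sums[r - 1] += mag[row, col]
    return sums


def angular_sums_oracle(mag):
    """Enumerate all 180 x 16 (angle, radius) samples one by one."""
    n = mag.shape[0]
    c = n // 2
    sums = np.zeros(180)
    for k in range(180):
        theta = k * np.pi / 180.0
        for r in range(1, c + 1):
            row = (c - round(r * np.sin(theta))) % n
            col = (c + round(r * np.cos(theta))) % n
            sums[k] += mag[row, col]
    return sums


def _shifted_mag(pixels):
    return magnitude(shift_center(dft2(Patch(pixels))))


# ---------------------------------------------------------------------------
# dft2


def test_dft2_constant_patch_concentrates_at_dc():
    spec = dft2(Patch(np.ones((32, 32))))
    assert spec.coefficients[0, 0] == pytest.approx(1024.0)
    rest = np.abs(spec.coefficients).copy()
    rest[0, 0] = 0.0
    assert rest.max() < 1e-9


def test_dft2_impulse_has_flat_spectrum():
    px = np.zeros((32, 32))
    px[0, 0] = 1.0
    spec = dft2(Patch(px))
    assert np.allclose(np.abs(spec.coefficients), 1.0, atol=1e-12)


def test_dft2_matches_bruteforce_double_sum(rng):
    for _ in range(10):
        image = rng.uniform(size=(8, 8))
        got = dft2(Patch(image)).coefficients
        want = dft2_oracle(image)
        assert np.max(np.abs(got - want)) / np.max(np.abs(want)) < 1e-9


def test_dft2_rejects_nonsquare_and_odd():
    with pytest.raises(ValueError):
        dft2(Patch(np.zeros((32, 16))))
    with pytest.raises(ValueError):
        dft2(Patch(np.zeros((31, 31))))


def test_parseval_unnormalized(rng):
    image = rng.uniform(size=(32, 32))
    spec = dft2(Patch(image))
    lhs = np.sum(np.abs(spec.coefficients) ** 2)
    rhs = 32 * 32 * np.sum(image**2)
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_conjugate_symmetry_for_real_input(rng):
    image = rng.uniform(size=(32, 32))
    F = dft2(Patch(image)).coefficients
    n = 32
    for l in range(n):
        for k in range(n):
            assert F[l, k] == pytest.approx(
                np.conj(F[(-l) % n, (-k) % n]), rel=1e-9, abs=1e-9
            )


# ---------------------------------------------------------------------------
# shift / magnitude


def test_shift_moves_dc_to_center():
    F = np.zeros((32, 32), dtype=complex)
    F[0, 0] = 7.0
    shifted = shift_center(Spectrum(F))
    assert shifted.coefficients[16, 16] == 7.0


def test_shift_is_involution_on_even_sizes(rng):
    F = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
    twice = shift_center(shift_center(Spectrum(F)))
    assert np.array_equal(twice.coefficients, F)


def test_shift_quadrant_swap_4x4():
    F = np.arange(16, dtype=complex).reshape(4, 4)
    shifted = shift_center(Spectrum(F))
    assert shifted.coefficients[2, 2] == 0


def test_magnitude_values():
    F = np.array([[3 + 4j, 0.0], [0 - 2j, 1.0]])
    mag = magnitude(Spectrum(F))
    assert np.allclose(mag.magnitudes, [[5.0, 0.0], [2.0, 1.0]])


# ---------------------------------------------------------------------------
# profiles


def test_radial_sums_zero_and_single_pixel():
    assert np.array_equal(radial_sums(MagnitudeSpectrum(np.zeros((32, 32)))), np.zeros(16))
    m = np.zeros((32, 32))
    m[13, 16] = 5.0  # distance 3, upper half
    sums = radial_sums(MagnitudeSpectrum(m))
    assert sums[2] == 5.0
    assert sums.sum() == 5.0


def test_radial_sums_all_ones_matches_enumeration():
    m = np.ones((32, 32))
    assert np.array_equal(radial_sums(MagnitudeSpectrum(m)), radial_sums_oracle(m))


def test_radial_sums_random_matches_enumeration(rng):
    m = rng.uniform(size=(32, 32))
    assert np.allclose(radial_sums(MagnitudeSpectrum(m)), radial_sums_oracle(m), rtol=1e-12)


def test_angular_sums_zero_and_all_ones():
    assert np.array_equal(angular_sums(MagnitudeSpectrum(np.zeros((32, 32)))), np.zeros(180))
    sums = angular_sums(MagnitudeSpectrum(np.ones((32, 32))))
    assert np.array_equal(sums, np.full(180, 16.0))


def test_angular_sums_single_pixel_matches_enumeration():
    m = np.zeros((32, 32))
    m[16, 20] = 2.0  # on the zero-degree axis at radius 4
    got = angular_sums(MagnitudeSpectrum(m))
    want = angular_sums_oracle(m)
    assert np.array_equal(got, want)
    assert got[0] == 2.0  # the zero-degree line passes through (16, 20)


def test_angular_sums_random_matches_enumeration(rng):
    m = rng.uniform(size=(32, 32))
    assert np.allclose(angular_sums(MagnitudeSpectrum(m)), angular_sums_oracle(m), rtol=1e-12)


def test_profiles_are_linear(rng):
    m1 = rng.uniform(size=(32, 32))
    m2 = rng.uniform(size=(32, 32))
    a, b = 2.5, -1.25
    combo = MagnitudeSpectrum(a * m1 + b * m2)
    assert np.allclose(
        radial_sums(combo),
        a * radial_sums(MagnitudeSpectrum(m1)) + b * radial_sums(MagnitudeSpectrum(m2)),
    )
    assert np.allclose(
        angular_sums(combo),
        a * angular_sums(MagnitudeSpectrum(m1)) + b * angular_sums(MagnitudeSpectrum(m2)),
    )


@pytest.mark.parametrize("freq", [2, 4, 8])
def test_vertical_sinusoid_peaks_at_its_frequency(freq):
    rows = np.arange(32)
    pixels = np.tile(0.5 + 0.4 * np.sin(2 * np.pi * freq * rows / 32), (32, 1)).T
    srad = radial_sums(_shifted_mag(pixels))
    assert int(np.argmax(srad)) == freq - 1


# ---------------------------------------------------------------------------
# statistics and composition


@pytest.mark.parametrize(
    "profile, expected",
    [
        ([1, 2, 3], (2.0, 3.0, 2, 2.0 / 3.0, 2.0)),
        ([4, 4, 4], (4.0, 4.0, 0, 0.0, 0.0)),
        ([5, 1, 5], (11.0 / 3.0, 5.0, 0, None, 4.0)),
    ],
)
def test_profile_stats_worked_examples(profile, expected):
    stats = profile_stats(np.array(profile, dtype=float))
    mean, maximum, argmax, variance, rng_ = expected
    assert stats.mean == pytest.approx(mean)
    assert stats.maximum == pytest.approx(maximum)
    assert stats.argmax_index == argmax
    if variance is not None:
        assert stats.variance == pytest.approx(variance)
    assert stats.range == pytest.approx(rng_)


def test_profile_stats_rejects_empty():
    with pytest.raises(ValueError):
        profile_stats(np.array([]))


def test_spectral_features_all_zero_patch():
    feats = spectral_features(Patch(np.zeros((32, 32))))
    assert feats.shape == (10,)
    assert np.array_equal(feats, np.zeros(10))


def test_spectral_features_matches_scalar_composition(rng):
    """Full chain against an independent scalar step-by-step evaluation."""
    image = rng.uniform(size=(32, 32))
    F = dft2_oracle(image)
    shifted = np.roll(np.roll(F, 16, axis=0), 16, axis=1)
    mag = np.abs(shifted)
    srad = radial_sums_oracle(mag)
    sang = angular_sums_oracle(mag)

    def stats(p):
        return [
            float(np.mean(p)),
            float(np.max(p)),
            float(np.argmax(p)),
            float(np.mean((p - np.mean(p)) ** 2)),
            float(np.max(p) - np.min(p)),
        ]

    want = np.array(stats(srad) + stats(sang))
    got = spectral_features(Patch(image))
    assert np.allclose(got, want, rtol=1e-9, atol=1e-9)
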