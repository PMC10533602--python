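"""Beamline decimation and cubic-convolution up-sampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echosr.image import USImage
from echosr.sampling import (
    SamplingScheme,
    cubic_kernel,
    downsample_beamlines,
    upsample_beamlines,
    make_training_pair,
    _extend_lateral,
)


# ---------------------------------------------------------------------------
# cubic kernel
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, expected",
    [
        (0.0, 1.0),  # interpolating node
        (1.0, 0.0),
        (2.0, 0.0),
        (-1.0, 0.0),
        (0.5, 0.5625),  # piecewise polynomial, near branch
        (1.5, -0.0625),  # far branch
        (2.5, 0.0),  # outside support
    ],
)
def test_cubic_kernel_values(x, expected):
    assert cubic_kernel(x, a=-0.5) == pytest.approx(expected, abs=1e-14)


def test_cubic_kernel_vectorised_and_even():
    xs = np.linspace(-3, 3, 301)
    vals = cubic_kernel(xs)
    assert np.allclose(vals, cubic_kernel(-xs), atol=1e-14)
    assert np.all(vals[np.abs(xs) >= 2] == 0)


@given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
@settings(deadline=None, max_examples=200)
def test_partition_of_unity(u):
    """The four weights covering any fractional offset sum to one."""
    w = sum(cubic_kernel(u - j, -0.5) for j in (-1, 0, 1, 2))
    assert w == pytest.approx(1.0, abs=1e-12)


def test_two_x_weight_vector():
    """Midpoint interpolation uses (-1/16, 9/16, 9/16, -1/16)."""
    w = [cubic_kernel(0.5 - j, -0.5) for j in (-1, 0, 1, 2)]
    assert np.allclose(w, [-1 / 16, 9 / 16, 9 / 16, -1 / 16], atol=1e-15)


def test_four_x_quarter_offset_weights():
    w = np.array([cubic_kernel(0.25 - j, -0.5) for j in (-1, 0, 1, 2)])
    assert np.allclose(
        w, [-0.0703125, 0.8671875, 0.2265625, -0.0234375], atol=1e-15
    )
    assert w.sum() == pytest.approx(1.0, abs=1e-15)


# ---------------------------------------------------------------------------
# scheme validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        {"factor": 0},
        {"factor": 2, "phase": 2},
        {"factor": 2, "phase": -1},
        {"kernel_a": 0.0},
        {"kernel_a": 0.5},
        {"boundary_mode": "wrap"},
    ],
)
def test_invalid_scheme_rejected(kwargs):
    with pytest.raises(ValueError):
        SamplingScheme(**kwargs)


# ---------------------------------------------------------------------------
# decimation
# ---------------------------------------------------------------------------

def test_downsample_keeps_expected_lines(random_image):
    img = random_image(L=8, D=5)
    low2 = downsample_beamlines(img, SamplingScheme(factor=2))
    assert low2.L == 4
    assert np.array_equal(low2.pixels, img.pixels[[0, 2, 4, 6]])
    low4 = downsample_beamlines(img, SamplingScheme(factor=4))
    assert low4.L == 2
    assert np.array_equal(low4.pixels, img.pixels[[0, 4]])
    assert low4.acquired_mask.all()


def test_downsample_phase_and_identity(random_image):
    img = random_image(L=8, D=3)
    low = downsample_beamlines(img, SamplingScheme(factor=2, phase=1))
    assert np.array_equal(low.pixels, img.pixels[[1, 3, 5, 7]])
    same = downsample_beamlines(img, SamplingScheme(factor=1))
    assert same == img


def test_downsample_crops_to_multiple(random_image):
    img = random_image(L=10, D=4)
    low = downsample_beamlines(img, SamplingScheme(factor=4))
    assert low.L == 2  # 10 -> crop to 8 -> keep {0, 4}
    assert np.array_equal(low.pixels, img.pixels[[0, 4]])


def test_downsample_too_narrow_raises(random_image):
    img = random_image(L=6, D=4)
    with pytest.raises(ValueError, match="too narrow"):
        downsample_beamlines(img, SamplingScheme(factor=4))


# ---------------------------------------------------------------------------
# up-sampling
# ---------------------------------------------------------------------------

def brute_force_upsample(low: np.ndarray, s: int, phase: int, a: float,
                         mode: str = "quadratic") -> np.ndarray:
    """Per-pixel loop oracle for the kernel-weighted line sum."""
    ext = _extend_lateral(low, mode)

    def f(i):  # low-res line i with 2-line extension each side
        return ext[i + 2]

    L = s * low.shape[0]
    out = np.empty((L, low.shape[1]))
    for l in range(L):
        x = (l - phase) / s
        if x == int(x) and (l - phase) % s == 0:
            out[l] = low[int(x)]
            continue
        i = int(np.floor(x))
        u = x - i
        for d in range(low.shape[1]):
            out[l, d] = sum(
                cubic_kernel(u - j, a) * f(i + j)[d] for j in (-1, 0, 1, 2)
            )
    return np.clip(out, 0.0, 1.0)


@pytest.mark.parametrize("s", [2, 4])
@pytest.mark.parametrize("phase", [0, 1])
def test_upsample_matches_brute_force(random_image, s, phase):
    img = random_image(L=16, D=6)
    scheme = SamplingScheme(factor=s, phase=phase)
    low = downsample_beamlines(img, scheme)
    up = upsample_beamlines(low, scheme, s * low.L)
    oracle = brute_force_upsample(low.pixels, s, phase, -0.5)
    assert np.abs(up.pixels - oracle).max() < 1e-10
    acq = (np.arange(up.L) - phase) % s == 0
    assert np.array_equal(up.acquired_mask, acq)
    assert np.array_equal(up.pixels[acq], low.pixels)  # bit-identical copies


def test_upsample_constant_image_exact():
    const = USImage(np.full((6, 4), 0.37))
    up = upsample_beamlines(const, SamplingScheme(factor=2), 12)
    assert np.allclose(up.pixels, 0.37, atol=1e-14)


def test_upsample_linear_ramp_exact():
    """a = -0.5 reproduces linear lateral ramps, borders included."""
    ramp = np.tile(np.linspace(0.1, 0.9, 8)[:, None], (1, 3))
    up = upsample_beamlines(USImage(ramp), SamplingScheme(factor=2), 16)
    # quadratic boundary extension continues the ramp past the last
    # acquired line, so the whole output is the exact (unclamped) line
    expect = np.tile((0.1 + (0.8 / 7) * (np.arange(16) / 2))[:, None], (1, 3))
    assert np.abs(up.pixels - expect).max() < 1e-12


def test_upsample_wrong_target_raises():
    low = USImage(np.random.default_rng(0).random((4, 3)))
    with pytest.raises(ValueError, match="target_L"):
        upsample_beamlines(low, SamplingScheme(factor=2), 10)


def test_upsample_rejects_fewer_than_four_lines():
    # fewer than 4 lines cannot define the boundary extension
    class Tiny:
        L, D = 3, 4
        pixels = np.random.default_rng(1).random((3, 4))
        value_range = (0.0, 1.0)

    with pytest.raises(ValueError, match="insufficient support"):
        upsample_beamlines(Tiny(), SamplingScheme(factor=2), 6)


# ---------------------------------------------------------------------------
# training pairs
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("s", [2, 4])
def test_training_pair_acquired_fidelity(random_image, s):
    hr = random_image(L=64, D=8)
    inp, tgt = make_training_pair(hr, SamplingScheme(factor=s))
    assert inp.pixels.shape == tgt.pixels.shape
    acq = inp.acquired_mask
    assert acq.sum() == 64 // s
    assert np.array_equal(inp.pixels[acq], tgt.pixels[acq])


def test_training_pair_crop_rule(random_image):
    hr = random_image(L=19, D=5)
    inp, tgt = make_training_pair(hr, SamplingScheme(factor=4))
    assert inp.L == tgt.L == 16


def test_training_pair_constant_roundtrip():
    hr = USImage(np.full((8, 6), 0.42))
    inp, tgt = make_training_pair(hr, SamplingScheme(factor=2))
    assert np.allclose(inp.pixels, tgt.pixels, atol=1e-14)
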