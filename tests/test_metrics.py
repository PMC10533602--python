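"""Quality metrics against hand values and raw-moment oracles."""

import numpy as np
import pytest

from echosr.metrics import (
    mse,
    psnr,
    ssim,
    mae,
    abs_error_image,
    error_histogram,
    cohort_summary,
    brightness,
    MetricsReport,
)

A22 = np.array([[255.0, 0.0], [0.0, 0.0]])
B22 = np.array([[255.0, 10.0], [0.0, 0.0]])


# ---------------------------------------------------------------------------
# oracles: plain double loops over raw moments
# ---------------------------------------------------------------------------

def mse_oracle(A, B):
    total = 0.0
    m, n = A.shape
    for i in range(m):
        for j in range(n):
            total += (A[i, j] - B[i, j]) ** 2
    return total / (m * n)


def mae_oracle(A, B):
    total = 0.0
    m, n = A.shape
    for i in range(m):
        for j in range(n):
            total += abs(A[i, j] - B[i, j])
    return total / (m * n)


def ssim_oracle(A, B, R=255.0):
    C1, C2 = (0.01 * R) ** 2, (0.03 * R) ** 2
    C3 = C2 / 2
    n = A.size
    mu_a = sum(A.flat) / n
    mu_b = sum(B.flat) / n
    var_a = sum((v - mu_a) ** 2 for v in A.flat) / n
    var_b = sum((v - mu_b) ** 2 for v in B.flat) / n
    cov = sum((a - mu_a) * (b - mu_b) for a, b in zip(A.flat, B.flat)) / n
    sa, sb = np.sqrt(var_a), np.sqrt(var_b)
    lum = (2 * mu_a * mu_b + C1) / (mu_a**2 + mu_b**2 + C1)
    con = (2 * sa * sb + C2) / (sa**2 + sb**2 + C2)
    struct = (cov + C3) / (sa * sb + C3)
    return lum * con * struct


# ---------------------------------------------------------------------------
# hand values
# ---------------------------------------------------------------------------

def test_mse_hand_values():
    assert mse(A22, A22) == 0.0
    assert mse(A22, B22) == pytest.approx(25.0)
    assert mse(B22, A22) == pytest.approx(25.0)  # symmetry


def test_psnr_hand_value_and_identity():
    assert psnr(A22, B22) == pytest.approx(10 * np.log10(65025 / 25), abs=1e-12)
    assert psnr(A22, A22) == np.inf


def test_psnr_scale_invariance():
    assert psnr(0.5 * A22, 0.5 * B22) == pytest.approx(psnr(A22, B22), abs=1e-12)


def test_psnr_degenerate_target_raises():
    zero = np.zeros((2, 2))
    with pytest.raises(ValueError, match="degenerate"):
        psnr(zero, B22)


def test_mae_hand_values():
    assert mae(A22, A22) == 0.0
    assert mae(A22, B22) == pytest.approx(2.5)


def test_ssim_self_similarity(rng):
    A = rng.uniform(0, 255, (7, 9))
    assert ssim(A, A) == pytest.approx(1.0, abs=1e-12)


def test_ssim_constant_images_reduce_to_luminance():
    c1, c2 = 100.0, 150.0
    A = np.full((4, 4), c1)
    B = np.full((4, 4), c2)
    C1 = (0.01 * 255) ** 2
    expect = (2 * c1 * c2 + C1) / (c1**2 + c2**2 + C1)
    assert ssim(A, B) == pytest.approx(expect, abs=1e-12)


def test_metric_dimension_mismatch():
    with pytest.raises(ValueError, match="shape"):
        mse(A22, np.zeros((3, 2)))


# ---------------------------------------------------------------------------
# oracle agreement on random images
# ---------------------------------------------------------------------------

def test_metrics_agree_with_oracles(rng):
    for _ in range(30):
        A = rng.uniform(0, 255, (5, 5))
        B = rng.uniform(0, 255, (5, 5))
        assert mse(A, B) == pytest.approx(mse_oracle(A, B), abs=1e-10)
        assert mae(A, B) == pytest.approx(mae_oracle(A, B), abs=1e-10)
        assert ssim(A, B) == pytest.approx(ssim_oracle(A, B), abs=1e-10)
        expected_psnr = 10 * np.log10(A.max() ** 2 / mse_oracle(A, B))
        assert psnr(A, B) == pytest.approx(expected_psnr, abs=1e-10)


def test_ssim_symmetry_and_bound(rng):
    A = rng.uniform(0, 255, (6, 6))
    B = rng.uniform(0, 255, (6, 6))
    assert ssim(A, B) == pytest.approx(ssim(B, A), abs=1e-12)
    assert ssim(A, B) <= 1.0 + 1e-12


def test_psnr_decreasing_in_mse(rng):
    A = rng.uniform(50, 255, (8, 8))
    noisy1 = A + rng.normal(0, 1, A.shape)
    noisy2 = A + rng.normal(0, 5, A.shape)
    if mse(A, noisy1) < mse(A, noisy2):
        assert psnr(A, noisy1) > psnr(A, noisy2)


def test_mae_bounded_by_rmse(rng):
    A = rng.uniform(0, 255, (5, 5))
    B = rng.uniform(0, 255, (5, 5))
    assert mae(A, B) <= np.sqrt(mse(A, B)) + 1e-12


def test_windowed_ssim_variant_runs(rng):
    A = rng.uniform(0, 255, (16, 16))
    B = np.clip(A + rng.normal(0, 5, A.shape), 0, 255)
    global_val = ssim(A, B)
    windowed = ssim(A, B, window=7)
    assert -1.0 <= windowed <= 1.0
    assert windowed != pytest.approx(global_val)  # genuinely different estimator


# ---------------------------------------------------------------------------
# error image and histogram
# ---------------------------------------------------------------------------

def test_abs_error_image():
    err, emax = abs_error_image(A22, B22)
    assert np.array_equal(err, [[0, 10], [0, 0]])
    assert emax == 10.0
    # max equals the Chebyshev distance
    assert emax == np.abs(A22 - B22).max()


def test_error_histogram_buckets():
    A = np.array([[0.0, 0.0, 0.0, 0.0]])
    B = np.array([[0.0, 3.0, 5.0, 7.0]])
    counts = error_histogram(A, B, bin_width=5.0)
    assert counts.tolist() == [2, 2]  # half-open bins: 5 goes to the second


def test_error_histogram_conservation(rng):
    A = rng.uniform(0, 255, (13, 7))
    B = rng.uniform(0, 255, (13, 7))
    counts = error_histogram(A, B)
    assert counts.sum() == A.size


def test_error_histogram_identical_images():
    counts = error_histogram(A22, A22)
    assert counts.tolist() == [4]


def test_error_histogram_invalid_width():
    with pytest.raises(ValueError):
        error_histogram(A22, B22, bin_width=0)


# ---------------------------------------------------------------------------
# cohort summary and brightness
# ---------------------------------------------------------------------------

def test_cohort_summary_order_statistics():
    stats = cohort_summary([1, 2, 3, 4, 5])
    assert stats["median"] == 3
    assert stats["q1"] == 2  # linear interpolation convention
    assert stats["q3"] == 4
    assert stats["whisker_low"] == 1
    assert stats["whisker_high"] == 5


def test_cohort_summary_single_value_and_permutation(rng):
    stats = cohort_summary([7.0])
    assert all(v == 7.0 for v in stats.values())
    vals = list(rng.uniform(0, 10, 20))
    shuffled = list(vals)
    rng.shuffle(shuffled)
    assert cohort_summary(vals) == cohort_summary(shuffled)


def test_cohort_summary_tukey_whiskers_exclude_outlier():
    vals = [1, 2, 3, 4, 100]  # 100 is far outside q3 + 1.5 IQR
    stats = cohort_summary(vals)
    assert stats["whisker_high"] == 4


def test_cohort_summary_empty_raises():
    with pytest.raises(ValueError):
        cohort_summary([])


def test_brightness():
    assert brightness(np.zeros((3, 3))) == 0.0
    assert brightness(np.array([[0, 255], [0, 255]])) == 127.5
    A = np.random.default_rng(0).uniform(0, 1, (4, 4))
    assert brightness(2 * A) == pytest.approx(2 * brightness(A))


# ---------------------------------------------------------------------------
# report writer
# ---------------------------------------------------------------------------

def test_metrics_report_writers(tmp_path):
    rep = MetricsReport(
        per_image=[{"image": 0, "psnr": 30.0}, {"image": 1, "psnr": 32.0}],
        cohort={"psnr": cohort_summary([30.0, 32.0])},
        m=8,
        n=8,
    )
    rep.to_csv(tmp_path / "per_image.csv")
    rep.to_json(tmp_path / "cohort.json")
    import pandas as pd, json

    df = pd.read_csv(tmp_path / "per_image.csv")
    assert len(df) == 2
    payload = json.loads((tmp_path / "cohort.json").read_text())
    assert payload["cohort"]["psnr"]["median"] == 31.0
    assert rep.summarise("psnr")["median"] == 31.0
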