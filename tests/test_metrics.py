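"""Dice / HD95 metrics against brute-force oracles, aggregation, and the
paired statistics (Wilcoxon signed-rank, bootstrap CI)."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from egunet.errors import ShapeError
from egunet.metrics import (EvalRecord, aggregate, bootstrap_ci, boundary_points,
                            dsc, evaluate_case, hd95, paired_wilcoxon)


# -- DSC ---------------------------------------------------------------------

def pixel_dsc_oracle(pred, gt):
    inter = sum(1 for p, g in zip(pred.ravel(), gt.ravel()) if p and g)
    total = int(pred.sum()) + int(gt.sum())
    return 1.0 if total == 0 else 2 * inter / total


def test_dsc_identity_and_disjoint():
    a = np.zeros((5, 5), bool)
    a[1:3, 1:3] = True
    assert dsc(a, a) == 1.0
    b = np.zeros((5, 5), bool)
    b[4, 4] = True
    assert dsc(a, b) == 0.0


def test_dsc_counting_example():
    # |Mp| = 4, |Mg| = 6, overlap 3 -> 2*3/10 = 0.6
    pred = np.zeros((4, 4), bool)
    gt = np.zeros((4, 4), bool)
    pred.ravel()[[0, 1, 2, 3]] = True
    gt.ravel()[[1, 2, 3, 8, 9, 10]] = True
    assert dsc(pred, gt) == pytest.approx(0.6)
    assert dsc(pred, gt) == pytest.approx(pixel_dsc_oracle(pred, gt))


def test_dsc_symmetric_and_bounded(rng):
    for _ in range(25):
        a = rng.random((6, 6)) < 0.4
        b = rng.random((6, 6)) < 0.4
        v = dsc(a, b)
        assert v == dsc(b, a)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(pixel_dsc_oracle(a, b))


def test_dsc_empty_conventions():
    e = np.zeros((3, 3), bool)
    f = np.zeros((3, 3), bool)
    f[0, 0] = True
    assert dsc(e, e) == 1.0
    assert dsc(e, f) == 0.0
    assert dsc(f, e) == 0.0


def test_dsc_shape_mismatch():
    with pytest.raises(ShapeError):
        dsc(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


# -- HD95 --------------------------------------------------------------------

def hd95_bruteforce(pred, gt, spacing=None, percentile=95.0):
    """All-pairs boundary distances + percentile; O(n^2) oracle."""
    bp = boundary_points(pred).astype(float)
    bg = boundary_points(gt).astype(float)
    if spacing is not None:
        bp = bp * np.asarray(spacing)
        bg = bg * np.asarray(spacing)
    d = cdist(bp, bg)
    d_pg = np.percentile(d.min(axis=1), percentile)
    d_gp = np.percentile(d.min(axis=0), percentile)
    return max(d_pg, d_gp)


def test_hd95_identical_masks_zero(rng):
    m = rng.random((8, 8)) < 0.5
    m[0, 0] = True
    assert hd95(m, m) == 0.0


def test_hd95_two_single_voxels():
    a = np.zeros((9, 9), bool)
    b = np.zeros((9, 9), bool)
    a[2, 2] = True
    b[2, 7] = True
    assert hd95(a, b) == pytest.approx(5.0)


def test_hd95_spacing_aware():
    a = np.zeros((5, 5), bool)
    b = np.zeros((5, 5), bool)
    a[2, 1] = True
    b[2, 3] = True
    assert hd95(a, b, spacing=(1.0, 2.5)) == pytest.approx(5.0)


def test_hd95_matches_bruteforce_oracle(rng):
    for _ in range(200):
        h, w = rng.integers(4, 16), rng.integers(4, 16)
        a = rng.random((h, w)) < 0.35
        b = rng.random((h, w)) < 0.35
        if not a.any() or not b.any():
            continue
        np.testing.assert_allclose(hd95(a, b), hd95_bruteforce(a, b), rtol=1e-10)


def test_hd95_le_classical_hausdorff(rng):
    for _ in range(50):
        a = rng.random((10, 10)) < 0.3
        b = rng.random((10, 10)) < 0.3
        if not a.any() or not b.any():
            continue
        assert hd95(a, b) <= hd95(a, b, percentile=100.0) + 1e-12


def test_hd95_empty_mask_undefined():
    m = np.zeros((4, 4), bool)
    f = m.copy()
    f[1, 1] = True
    assert np.isnan(hd95(m, f))
    assert np.isnan(hd95(m, m))


def test_boundary_points_subset_of_mask(rng):
    m = rng.random((7, 7)) < 0.5
    pts = boundary_points(m)
    assert all(m[tuple(p)] for p in pts)
    assert boundary_points(np.zeros((4, 4), bool)).size == 0


# -- aggregation -------------------------------------------------------------

def test_aggregate_grand_mean_of_class_means():
    recs = [EvalRecord("c1", 1, 0.8, 2.0), EvalRecord("c1", 2, 0.6, 4.0)]
    agg = aggregate(recs)
    assert agg["mean_dsc"] == pytest.approx(0.7)
    assert agg["mean_hd95"] == pytest.approx(3.0)


def test_aggregate_duplicates_against_hand_sum():
    recs = [EvalRecord("a", 1, 0.5, 1.0), EvalRecord("b", 1, 0.9, 3.0),
            EvalRecord("a", 2, 1.0, 0.0)]
    agg = aggregate(recs)
    assert agg["per_class"][1]["dsc"] == pytest.approx((0.5 + 0.9) / 2)
    assert agg["mean_dsc"] == pytest.approx(((0.5 + 0.9) / 2 + 1.0) / 2)


def test_aggregate_perfect_scores():
    recs = [EvalRecord(f"c{i}", k, 1.0, 0.0) for i in range(3) for k in (1, 2)]
    assert aggregate(recs)["mean_dsc"] == 1.0


def test_aggregate_excludes_undefined_hd95():
    recs = [EvalRecord("a", 1, 0.5, 2.0), EvalRecord("b", 1, 0.0, float("nan"))]
    agg = aggregate(recs)
    assert agg["per_class"][1]["hd95"] == pytest.approx(2.0)
    assert agg["n_hd95_undefined"] == 1
    assert agg["per_class"][1]["dsc"] == pytest.approx(0.25)


def test_aggregate_empty_rejected():
    with pytest.raises(ValueError):
        aggregate([])


def test_evaluate_case_per_class_records(rng):
    gt = rng.integers(0, 3, size=(12, 12))
    recs = evaluate_case(gt, gt, num_classes=3, case_id="x")
    assert [r.class_id for r in recs] == [1, 2]
    assert all(r.dsc == 1.0 and r.hd95 == 0.0 for r in recs)


# -- Wilcoxon ----------------------------------------------------------------

def wilcoxon_exact_oracle(diffs):
    """Two-sided exact p by enumerating all sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = [ranks[list(signs)].sum() for signs in
          (np.array(bits, bool) for bits in itertools.product([0, 1], repeat=n))]
    ws = np.asarray(ws)
    p = 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean())
    return min(p, 1.0)


def test_wilcoxon_all_positive_n12():
    diffs = np.arange(1, 13, dtype=float)
    res = paired_wilcoxon(diffs)
    assert res["p_value"] == pytest.approx(2 / 4096, rel=1e-9)
    assert res["mean_diff"] == pytest.approx(diffs.mean())


@pytest.mark.parametrize("n", [5, 6, 8, 10])
def test_wilcoxon_matches_exact_enumeration(n, rng):
    for _ in range(5):
        mags = rng.choice(np.arange(1, 40), size=n, replace=False).astype(float)
        diffs = mags * rng.choice([-1, 1], size=n)
        res = paired_wilcoxon(diffs)
        assert res["p_value"] == pytest.approx(wilcoxon_exact_oracle(diffs), rel=1e-9)


def test_wilcoxon_symmetric_pairs_near_null_center():
    diffs = np.array([3.0, -3.0, 7.0, -7.0, 11.0, -11.0])
    assert paired_wilcoxon(diffs)["p_value"] > 0.9


def test_wilcoxon_outlier_shifts_rank_statistic():
    """One large opposite-sign difference outranks several small ones; the
    hand-computed rank sum fixes the exact p-value (n=6, no ties)."""
    diffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -60.0])
    res = paired_wilcoxon(diffs)
    assert res["p_value"] == pytest.approx(wilcoxon_exact_oracle(diffs), rel=1e-9)
    # W+ = 1+2+3+4+5 = 15, W- = 6: not significant despite 5/6 positive signs
    assert res["p_value"] > 0.4


def test_wilcoxon_zero_handling():
    res = paired_wilcoxon([0.0, 0.0, 1.0, -2.0, 3.0])
    assert res["n_zeros_dropped"] == 2
    allz = paired_wilcoxon([0.0, 0.0, 0.0])
    assert allz["p_value"] == 1.0 and allz["all_zero"]


# -- bootstrap ---------------------------------------------------------------

def test_bootstrap_degenerate_constant():
    lo, hi = bootstrap_ci([2.5] * 10, seed=0)
    assert lo == hi == 2.5


def test_bootstrap_seed_deterministic(rng):
    vals = rng.normal(size=30)
    assert bootstrap_ci(vals, seed=42) == bootstrap_ci(vals, seed=42)
    assert bootstrap_ci(vals, seed=42) != bootstrap_ci(vals, seed=43)


def test_bootstrap_interval_covers_sample_mean(rng):
    for _ in range(100):
        vals = rng.normal(size=rng.integers(5, 30))
        lo, hi = bootstrap_ci(vals, n_boot=1000, seed=int(rng.integers(2**31)))
        assert lo <= vals.mean() <= hi
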