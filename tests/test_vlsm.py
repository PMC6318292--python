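"""Brunner-Munzel statistic, voxelwise mapping, and residualization."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from wcstmap.vlsm import (
    DegenerateStatisticError,
    brunner_munzel,
    conjunction,
    density_map,
    residualize,
    run_vlsm,
)


# ---------------------------------------------------------------------------
# independent oracle: exhaustive permutation of the relative effect

def oracle_permutation_p(x, y):
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    ranks = scipy.stats.rankdata(pooled)
    obs = abs((ranks[: n1].mean() - (n1 + 1) / 2) / (n - n1) - 0.5)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        eff = (ranks[list(combo)].mean() - (n1 + 1) / 2) / (n - n1)
        total += 1
        if abs(eff - 0.5) >= obs - 1e-12:
            count += 1
    return count / total


class TestBrunnerMunzel:
    def test_identical_multisets_give_null_statistic(self):
        res = brunner_munzel([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.z == 0.0
        assert res.relative_effect == 0.5
        assert res.p == 1.0

    def test_complete_separation(self):
        res = brunner_munzel([1, 2, 3], [4, 5, 6])
        assert res.relative_effect == 0.0
        assert res.z == -np.inf and res.p == 0.0

    def test_all_tied_raises(self):
        with pytest.raises(DegenerateStatisticError):
            brunner_munzel([2, 2, 2], [2, 2, 2])

    def test_matches_scipy_statistic_and_t_pvalue(self):
        x = [1, 2, 1, 1, 1, 1, 1, 1, 2, 4, 1, 1]
        y = [3, 3, 4, 3, 1, 2, 3, 1, 1, 5, 4]
        mine = brunner_munzel(x, y)
        ref = scipy.stats.brunnermunzel(x, y)
        # scipy's statistic is ours with the opposite sign convention
        assert mine.z == pytest.approx(-ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)

    def test_sign_convention_lesioned_larger_is_positive(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 1.0, 20)
        y = rng.normal(0.0, 1.0, 20)
        res = brunner_munzel(x, y)
        assert res.z > 0
        assert res.relative_effect > 0.5
        assert brunner_munzel(x, y, alternative="greater").p < brunner_munzel(x, y, alternative="less").p

    def test_permutation_reference_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.integers(0, 5, 6).astype(float)
            y = rng.integers(0, 5, 7).astype(float)
            try:
                res = brunner_munzel(x, y, reference="permutation")
            except DegenerateStatisticError:
                continue
            assert res.p == pytest.approx(oracle_permutation_p(x, y), abs=1e-12)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            brunner_munzel([1], [2, 3])


@pytest.fixture(scope="module")
def toy_masks():
    """Two disjoint 6x6x1 blocks lesioned by two participant groups."""
    rng = np.random.default_rng(2)
    shape = (16, 8, 4)
    masks = np.zeros((40, *shape), dtype=bool)
    for i in range(20):  # group A: low-value participants, left block
        masks[i, 2:8, 1:7, 1:3] = True
    for i in range(20, 40):  # group B, right block
        masks[i, 9:15, 1:7, 1:3] = True
    y = np.concatenate([rng.normal(-2.0, 0.5, 20), rng.normal(0.0, 0.5, 20)])
    return masks, y


class TestRunVlsm:
    def test_deficit_block_detected_and_other_block_clean(self, toy_masks):
        masks, y = toy_masks
        sm = run_vlsm(masks, y, min_overlap=12, alternative="less")
        left = np.zeros(masks.shape[1:], dtype=bool)
        left[2:8, 1:7, 1:3] = True
        assert sm.significant[left].all()
        assert not sm.significant[~left].any()
        assert sm.analyzed.sum() == 2 * left.sum()

    def test_fdr_pass_set_monotone_in_q(self, toy_masks):
        masks, y = toy_masks
        strict = run_vlsm(masks, y, fdr_q=0.001, alternative="less").significant
        loose = run_vlsm(masks, y, fdr_q=0.01, alternative="less").significant
        assert not (strict & ~loose).any()

    def test_min_overlap_above_n_gives_empty_map(self, toy_masks):
        masks, y = toy_masks
        sm = run_vlsm(masks, y, min_overlap=len(y) + 1)
        assert not sm.analyzed.any()
        assert not sm.significant.any()

    def test_deterministic(self, toy_masks):
        masks, y = toy_masks
        a = run_vlsm(masks, y, alternative="less")
        b = run_vlsm(masks, y, alternative="less")
        assert np.array_equal(a.z, b.z, equal_nan=True)
        assert np.array_equal(a.significant, b.significant)

    def test_shape_mismatch_rejected(self, toy_masks):
        masks, y = toy_masks
        with pytest.raises(ValueError):
            run_vlsm(masks, y[:-1])

    def test_peak_table_has_world_coordinates(self, toy_masks):
        masks, y = toy_masks
        affine = np.diag([4.0, 4.0, 4.0, 1.0])
        sm = run_vlsm(masks, y, affine=affine, alternative="less")
        peaks = sm.peak_table(5)
        assert len(peaks) == 5
        assert (peaks.x == peaks.i * 4.0).all()


class TestConjunction:
    def test_identity_overlap(self, toy_masks):
        masks, y = toy_masks
        sm = run_vlsm(masks, y, alternative="less")
        overlay = conjunction(sm, sm)
        assert ((overlay == 3) == sm.significant).all()
        assert not np.isin(overlay, [1, 2]).any()

    def test_disjoint_maps_have_no_both_label(self, toy_masks):
        masks, y = toy_masks
        a = run_vlsm(masks, y, alternative="less")
        b = run_vlsm(masks, -y, alternative="less")  # flips the deficit block
        overlay = conjunction(a, b)
        assert not (overlay == 3).any()
        assert (overlay == 1).sum() == a.significant.sum()


class TestDensityMap:
    def test_single_mask_counts_equal_mask(self, toy_masks):
        masks, _ = toy_masks
        dm = density_map(masks[:1], threshold=0)
        assert np.array_equal(dm.counts, masks[0].astype(int))

    def test_identical_masks_stack(self, toy_masks):
        masks, _ = toy_masks
        stack = np.repeat(masks[:1], 9, axis=0)
        dm = density_map(stack, threshold=8)
        assert dm.counts.max() == 9
        assert np.array_equal(dm.mask, masks[0])  # 9 > 8 inside, 0 outside

    def test_centroid_count_matches_hand_count(self, toy_masks):
        masks, _ = toy_masks
        dm = density_map(masks)
        assert dm.counts[4, 3, 1] == int(masks[:, 4, 3, 1].sum())


class TestResidualize:
    def test_orthogonal_covariate_keeps_variable(self):
        rng = np.random.default_rng(0)
        n = 200
        y = pd.Series(rng.normal(size=n))
        cov = pd.DataFrame({"c": rng.normal(size=n)}, index=y.index)
        res = residualize(y, cov)
        assert res.correlation > 0.98
        assert res.residuals.mean() == pytest.approx(0.0, abs=1e-10)

    def test_variable_linear_in_covariate_vanishes(self):
        x = pd.Series(np.linspace(0, 1, 50))
        cov = pd.DataFrame({"c": 2 * x + 1})
        res = residualize(x, cov)
        assert np.abs(res.residuals).max() < 1e-8

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        cov = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="collinear"):
            residualize(pd.Series(rng.normal(size=30)), cov)

    def test_missing_rows_dropped_with_flag(self):
        rng = np.random.default_rng(2)
        y = pd.Series(rng.normal(size=10), index=[f"s{i}" for i in range(10)])
        cov = pd.DataFrame({"c": rng.normal(size=10)}, index=y.index)
        cov.loc["s3", "c"] = np.nan
        res = residualize(y, cov)
        assert res.dropped == ["s3"]
        assert np.isnan(res.residuals["s3"])
        assert res.residuals.drop("s3").notna().all()
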