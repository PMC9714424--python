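"""Trait-accuracy regression, TFCE against brute force, and permutation FWE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import affectlight as al
from affectlight.trait import T_SENTINEL, TfceParams


class TestDemean:
    def test_arithmetic(self):
        np.testing.assert_allclose(al.demean([10, 20, 30]), [-10, 0, 10])

    def test_idempotent_on_centred_input(self):
        x = np.array([-3.0, 1.0, 2.0])
        np.testing.assert_allclose(al.demean(x), x)

    def test_mean_is_numerically_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 29, 57)
        assert abs(al.demean(x).mean()) < 1e-12

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            al.demean([5, 5, 5, 5])
        with pytest.raises(ValueError):
            al.demean([1, 2])


class TestVoxelwiseStatistic:
    def test_matches_closed_form_ols_on_five_subjects(self):
        scores = np.array([8.0, 12.0, 14.0, 19.0, 25.0])
        acc = np.array([[0.21], [0.30], [0.28], [0.36], [0.45]])
        t = al.voxelwise_statistic(acc, scores)
        lr = stats.linregress(scores, acc[:, 0])
        assert t[0] == pytest.approx(lr.slope / lr.stderr, rel=1e-10)

    def test_orthogonal_regressor_gives_zero(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        acc = np.array([[0.3], [0.5], [0.3], [0.1]])  # covariance with x is 0
        assert al.voxelwise_statistic(acc, x)[0] == pytest.approx(0.0, abs=1e-10)

    def test_perfect_linear_fit_hits_sentinel_cap(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        acc = (0.1 + 0.05 * x)[:, None]
        assert al.voxelwise_statistic(acc, x)[0] == T_SENTINEL

    def test_constant_accuracy_voxels_are_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        acc = np.full((4, 3), 0.25)
        np.testing.assert_array_equal(al.voxelwise_statistic(acc, x), 0.0)

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            al.voxelwise_statistic(np.zeros((4, 2)), np.arange(5))


def brute_force_tfce(stat, mask, E, H, heights, dh):
    """Flood-fill component labelling at every height step; no ndimage."""
    stat = np.where(mask, stat, 0.0)
    out = np.zeros_like(stat)
    shape = stat.shape
    for h in heights:
        supra = stat >= h
        seen = np.zeros(shape, bool)
        for start in np.argwhere(supra):
            start = tuple(start)
            if seen[start]:
                continue
            component, queue = [], [start]
            seen[start] = True
            while queue:
                v = queue.pop()
                component.append(v)
                for axis in range(3):
                    for step in (-1, 1):
                        w = list(v)
                        w[axis] += step
                        w = tuple(w)
                        if (
                            0 <= w[axis] < shape[axis]
                            and supra[w]
                            and not seen[w]
                        ):
                            seen[w] = True
                            queue.append(w)
            for v in component:
                out[v] += len(component) ** E * h**H * dh
    return out


class TestTfce:
    def test_zero_map_stays_zero(self):
        mask = np.ones((4, 4, 4), bool)
        assert not al.tfce(np.zeros(mask.shape), mask).any()

    def test_isolated_voxel_hand_integration(self):
        # heights 1 and 2: 1^0.5*1^2*1 + 1^0.5*2^2*1 = 5
        mask = np.ones((5, 5, 5), bool)
        stat = np.zeros(mask.shape)
        stat[2, 2, 2] = 2.0
        enhanced = al.tfce(stat, mask, TfceParams(E=0.5, H=2.0, dh=1.0))
        assert enhanced[2, 2, 2] == pytest.approx(5.0)
        assert enhanced.sum() == pytest.approx(5.0)

    def test_disjoint_clusters_do_not_interact(self):
        mask = np.ones((6, 6, 6), bool)
        a = np.zeros(mask.shape)
        a[1, 1, 1] = 1.0
        both = a.copy()
        both[4, 4, 4] = 3.0
        alone = al.tfce(a, mask)
        # heights are set by the map max, so fix dh to compare like for like
        params = TfceParams(dh=0.03)
        alone = al.tfce(a, mask, params)
        joint = al.tfce(both, mask, params)
        assert joint[1, 1, 1] == pytest.approx(alone[1, 1, 1])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_component_labelling(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((6, 6, 6)) > 0.2
        stat = np.clip(rng.normal(0.5, 1.0, mask.shape), 0, None)
        params = TfceParams(E=0.5, H=2.0, n_steps=20)
        mine = al.tfce(stat, mask, params)
        hmax = np.where(mask, stat, 0).max()
        dh = hmax / params.n_steps
        heights = dh * np.arange(1, params.n_steps + 1)
        oracle = brute_force_tfce(stat, mask, 0.5, 2.0, heights, dh)
        np.testing.assert_allclose(mine, oracle, atol=1e-10)

    def test_pointwise_monotonicity(self):
        rng = np.random.default_rng(3)
        mask = np.ones((5, 5, 5), bool)
        stat = np.clip(rng.normal(0.3, 1.0, mask.shape), 0, None)
        bigger = stat + rng.uniform(0, 0.5, mask.shape)
        params = TfceParams(dh=0.05)  # shared heights for a fair comparison
        assert (al.tfce(bigger, mask, params) >= al.tfce(stat, mask, params) - 1e-12).all()


@pytest.fixture(scope="module")
def planted_stack():
    """Accuracy stack with a PT-linked ROI column block."""
    rng = np.random.default_rng(10)
    mask = np.ones((5, 5, 5), bool)
    n_subj, n_vox = 20, 125
    scores = rng.normal(14, 3.7, n_subj)
    stack = 0.25 + rng.normal(0, 0.05, (n_subj, n_vox))
    roi = np.zeros(mask.shape, bool)
    roi[1:4, 1:4, 1:4] = True
    roi_cols = np.flatnonzero(roi[mask])
    link = 0.02 * (scores - scores.mean())
    stack[:, roi_cols] += link[:, None]
    return mask, roi, scores, np.clip(stack, 0, 1)


class TestPermutationFwe:
    def test_seed_determinism(self, planted_stack):
        mask, _, scores, stack = planted_stack
        kw = dict(params=TfceParams(n_steps=25), n_perms=150, seed=5)
        a = al.permutation_fwe(stack, scores, mask, **kw)
        b = al.permutation_fwe(stack, scores, mask, **kw)
        np.testing.assert_array_equal(a.one_minus_p, b.one_minus_p)

    def test_planted_linkage_recovered(self, planted_stack):
        mask, roi, scores, stack = planted_stack
        pm = al.permutation_fwe(stack, scores, mask,
                                params=TfceParams(n_steps=25),
                                n_perms=400, seed=6)
        sig = pm.significance_mask
        assert (sig & roi).sum() / roi.sum() >= 0.8
        outside = pm.one_minus_p[mask & ~roi]
        assert np.median(outside) < 0.95

    def test_p_values_use_small_sample_convention(self, planted_stack):
        mask, _, scores, stack = planted_stack
        pm = al.permutation_fwe(stack, scores, mask,
                                params=TfceParams(n_steps=25),
                                n_perms=150, seed=7)
        omp = pm.one_minus_p[mask]
        assert (omp <= 1 - 1 / 151).all()  # p never reaches 0
        assert (omp >= 0).all()

    def test_constant_regressor_rejected(self, planted_stack):
        mask, _, _, stack = planted_stack
        with pytest.raises(ValueError):
            al.permutation_fwe(stack, np.full(20, 14.0), mask, n_perms=10, seed=0)


class TestConjunction:
    def test_empty_and_idempotent(self):
        a = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = True
        assert not al.conjunction(a, np.zeros_like(a)).any()
        np.testing.assert_array_equal(al.conjunction(a, a), a)

    def test_counts_constructed_overlap(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, :] = True  # 4 voxels
        b[0, :, 0] = True  # 4 voxels, overlap at (0,0,0)
        a[1, 1, :3] = True
        b[1, 1, :] = True  # overlap adds 3
        a[2, 2, 2] = b[2, 2, 2] = True
        a[3, 3, :] = True
        b[3, 3, 2:] = True  # overlap adds 2
        assert al.conjunction(a, b).sum() == 1 + 3 + 1 + 2

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            al.conjunction(np.ones((3, 3, 3), bool), np.ones((4, 4, 4), bool))


class TestTraitCorrelationModel:
    def test_only_planted_subscale_detects(self):
        """The same machinery runs all four sub-scales; only the PT-linked
        stack yields detections when only PT is planted."""
        rng = np.random.default_rng(20)
        mask = np.ones((4, 4, 4), bool)
        n_subj = 18
        traits = al.generate_trait_table(n_subj, seed=21)
        stack = 0.25 + rng.normal(0, 0.04, (n_subj, 64))
        pt = traits["PT"].to_numpy(float)
        roi_cols = np.arange(10)
        stack[:, roi_cols] += 0.02 * (pt - pt.mean())[:, None]

        maps = []
        for row in stack:
            vol = np.full(mask.shape, np.nan)
            vol[mask] = row
            maps.append(al.AccuracyMap(data=vol, mask=mask, affine=np.eye(4)))

        hits = {}
        for sub in ("PT", "FS", "EC", "PD"):
            res = al.TraitCorrelation(
                maps, traits, subscale=sub, params=TfceParams(n_steps=25)
            ).fit(n_perms=300, seed=22)
            hits[sub] = int(res.significance_mask.sum())
        assert hits["PT"] > 0
        assert hits["FS"] == hits["EC"] == hits["PD"] == 0

    def test_cluster_table_and_summary(self):
        rng = np.random.default_rng(30)
        mask = np.ones((4, 4, 4), bool)
        scores = np.arange(12, dtype=float)
        stack = 0.25 + rng.normal(0, 0.03, (12, 64))
        stack[:, :6] += 0.03 * (scores - scores.mean())[:, None]
        maps = []
        for row in stack:
            vol = np.zeros(mask.shape)
            vol[mask] = row
            maps.append(al.AccuracyMap(data=vol, mask=mask, affine=2 * np.eye(4)))
        traits = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(12)], "PT": scores,
             "FS": scores, "EC": scores, "PD": scores}
        )
        res = al.TraitCorrelation(maps, traits, params=TfceParams(n_steps=25)).fit(
            n_perms=200, seed=31
        )
        table = res.cluster_table()
        if len(table):
            # world coordinates follow the affine (voxel * 2)
            assert (table["peak_x"] == 2 * table["peak_i"]).all()
            assert table["size"].sum() == int(res.significance_mask.sum())
        text = res.summary()
        assert "PT" in text and "permutations" in text
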