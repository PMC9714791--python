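import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenorev.drfa import (
    Cloud,
    FeatureMatrix,
    discrimination_index,
    fit_cloud,
    fit_drf_space,
    permutation_pvalue,
    project_group,
    rescue_score,
)
from phenorev.simulate import BehaviorSimConfig, simulate_behavior


def _matrix(rng, n_a=20, n_b=20, p=5, shift=0.0):
    a = rng.standard_normal((n_a, p))
    b = rng.standard_normal((n_b, p)) + shift
    return FeatureMatrix(
        np.vstack([a, b]),
        np.array(["a"] * n_a + ["b"] * n_b),
        tuple(f"f{i}" for i in range(p)),
    )


class TestFitSpace:
    def test_whitening_contract(self, two_group_behavior):
        data = FeatureMatrix.from_dataframe(two_group_behavior)
        space = fit_drf_space(data)
        T = space.apply(data.values)
        resid = T.copy()
        for g in data.groups:
            mask = data.group_labels == g
            resid[mask] -= resid[mask].mean(axis=0)
        pooled = resid.T @ resid / (len(data.values) - len(data.groups))
        assert np.abs(pooled - np.eye(space.k)).max() < 1e-6

    def test_separating_axis_ranked_first(self, rng):
        # groups differ only on feature 1; the top component must carry
        # essentially all of the between-group separation
        a = rng.standard_normal((40, 4))
        b = rng.standard_normal((40, 4))
        b[:, 0] += 8.0
        data = FeatureMatrix(
            np.vstack([a, b]), np.array(["a"] * 40 + ["b"] * 40), ("f0", "f1", "f2", "f3")
        )
        space = fit_drf_space(data)
        T = space.apply(data.values)
        diffs = np.abs(
            T[data.group_labels == "a"].mean(axis=0) - T[data.group_labels == "b"].mean(axis=0)
        )
        assert diffs[0] == diffs.max()
        assert diffs[0] > 5 * diffs[1:].max()

    def test_ranking_matches_brute_force_ordering(self, rng):
        # oracle: per-component between-group sum of squares computed
        # directly on the transformed 5-feature toy data
        data = _matrix(rng, p=5, shift=0.8)
        space = fit_drf_space(data)
        T = space.apply(data.values)
        overall = T.mean(axis=0)
        bss = np.zeros(space.k)
        for g in data.groups:
            mask = data.group_labels == g
            bss += mask.sum() * (T[mask].mean(axis=0) - overall) ** 2
        assert np.all(np.diff(bss) <= 1e-9)  # ranked columns are nonincreasing

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_drf_space(_matrix(rng), k=99)

    def test_singular_covariance_without_regularization(self, rng):
        data = _matrix(rng, n_a=3, n_b=3, p=10)
        with pytest.raises(ValueError):
            fit_drf_space(data, shrinkage=0.0)
        fit_drf_space(data)  # auto regularization succeeds

    def test_missing_values_rejected(self):
        values = np.array([[1.0, np.nan]] * 6)
        with pytest.raises(ValueError):
            FeatureMatrix(values, np.array(["a"] * 3 + ["b"] * 3), ("x", "y"))


def _spherical(label, mean, dim=3):
    return Cloud(label=label, mean=np.asarray(mean, dtype=float), cov=np.eye(dim))


class TestDiscriminationIndex:
    def test_identical_clouds_give_exactly_50(self):
        c = _spherical("a", [0, 0, 0])
        assert discrimination_index(c, c) == 50.0

    def test_far_separation_saturates_at_100(self):
        a = _spherical("a", [0, 0, 0])
        b = _spherical("b", [50, 0, 0])
        assert discrimination_index(a, b) == pytest.approx(100.0, abs=0.5)

    @pytest.mark.parametrize("d", [0.5, 1.0, 2.0, 4.0])
    def test_equal_spherical_closed_form(self, d):
        a = _spherical("a", [0, 0, 0])
        b = _spherical("b", [d, 0, 0])
        expected = 50.0 + 50.0 * (1.0 - np.exp(-(d**2) / 8.0))
        assert discrimination_index(a, b) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_separation(self):
        seps = np.linspace(0, 6, 13)
        idx = [
            discrimination_index(_spherical("a", [0, 0, 0]), _spherical("b", [d, 0, 0]))
            for d in seps
        ]
        assert np.all(np.diff(idx) >= 0)

    @given(
        st.integers(1, 4),
        st.floats(-3, 3),
        st.floats(0.2, 3.0),
        st.floats(0.2, 3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_range(self, dim, sep, sa, sb):
        a = Cloud("a", np.zeros(dim), sa * np.eye(dim))
        mean_b = np.full(dim, sep)
        b = Cloud("b", mean_b, sb * np.eye(dim))
        iab = discrimination_index(a, b)
        iba = discrimination_index(b, a)
        assert iab == pytest.approx(iba, abs=1e-9)
        assert 50.0 <= iab <= 100.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            discrimination_index(_spherical("a", [0, 0]), _spherical("b", [0, 0, 0]))


class TestPermutation:
    def test_identical_groups_large_p(self):
        cfg = BehaviorSimConfig(
            groups=[("a", 12), ("b", 12)], n_features=4, mean_shift={}, seed=0
        )
        pvals = []
        for seed in range(9):
            df = simulate_behavior(
                BehaviorSimConfig(
                    groups=[("a", 12), ("b", 12)], n_features=4, mean_shift={}, seed=seed
                )
            )
            data = FeatureMatrix.from_dataframe(df)
            pvals.append(permutation_pvalue(data, ("a", "b"), n_perm=49, seed=seed).pvalue)
        assert np.median(pvals) > 0.3

    def test_separated_groups_minimum_p(self):
        df = simulate_behavior(
            BehaviorSimConfig(
                groups=[("a", 30), ("b", 30)], n_features=5, mean_shift={"b": 50.0}, seed=1
            )
        )
        data = FeatureMatrix.from_dataframe(df)
        disc = permutation_pvalue(data, ("a", "b"), n_perm=99, seed=2)
        assert disc.pvalue == pytest.approx(1 / 100)
        assert disc.index == pytest.approx(100.0, abs=0.5)

    def test_1000_vs_10000_permutations_agree(self):
        # binomial resampling oracle: both estimates target the same
        # exceedance probability
        df = simulate_behavior(
            BehaviorSimConfig(
                groups=[("a", 10), ("b", 10)], n_features=3, mean_shift={"b": 0.9}, seed=4
            )
        )
        data = FeatureMatrix.from_dataframe(df)
        p_small = permutation_pvalue(data, ("a", "b"), n_perm=1000, seed=0).pvalue
        p_big = permutation_pvalue(data, ("a", "b"), n_perm=10000, seed=1).pvalue
        sd = np.sqrt(p_big * (1 - p_big) / 1000)
        assert abs(p_small - p_big) <= 3 * sd + 2 / 1000

    def test_null_pvalues_super_uniform(self):
        # P(p <= t) must not exceed t under the null (add-one estimator)
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(200):
            values = rng.standard_normal((16, 3))
            data = FeatureMatrix(
                values, np.array(["a"] * 8 + ["b"] * 8), ("f0", "f1", "f2")
            )
            pvals.append(
                permutation_pvalue(
                    data, ("a", "b"), n_perm=39, seed=int(rng.integers(2**31))
                ).pvalue
            )
        pvals = np.asarray(pvals)
        for t in (0.05, 0.1, 0.25, 0.5):
            bound = t + 3 * np.sqrt(t * (1 - t) / 200)
            assert (pvals <= t).mean() <= bound

    def test_invalid_n_perm(self, rng):
        with pytest.raises(ValueError):
            permutation_pvalue(_matrix(rng), ("a", "b"), n_perm=0)


class TestProjectionAndRescue:
    def _reference(self, seed=0):
        rng = np.random.default_rng(seed)
        groups = []
        labels = []
        for i, (label, shift) in enumerate(
            [("wt6", 0), ("dis6", 4), ("wt9", 1), ("dis9", 5), ("wt12", 2), ("dis12", 6)]
        ):
            g = rng.standard_normal((12, 4))
            g[:, 0] += shift
            groups.append(g)
            labels += [label] * 12
        data = FeatureMatrix(np.vstack(groups), np.array(labels), ("f0", "f1", "f2", "f3"))
        space = fit_drf_space(data)
        clouds = [
            fit_cloud(space, data.values[data.group_labels == g], g) for g in data.groups
        ]
        return rng, data, space, clouds

    def test_lowered_group_matching_disease(self):
        rng, data, space, clouds = self._reference()
        lowered_values = rng.standard_normal((15, 4))
        lowered_values[:, 0] += 4  # drawn from the dis6 distribution
        lowered = FeatureMatrix(
            lowered_values, np.array(["low"] * 15), ("f0", "f1", "f2", "f3")
        )
        proj = project_group(space, clouds, lowered)
        assert proj.indices["dis6"] < 65.0
        assert proj.distances["dis6"] == min(proj.distances.values())

    def test_lowered_group_matching_control(self):
        rng, data, space, clouds = self._reference(seed=1)
        lowered_values = rng.standard_normal((15, 4))  # wt6 distribution
        lowered = FeatureMatrix(
            lowered_values, np.array(["low"] * 15), ("f0", "f1", "f2", "f3")
        )
        proj = project_group(space, clouds, lowered)
        assert proj.indices["wt6"] < 65.0

    def test_feature_mismatch_rejected(self):
        _, data, space, clouds = self._reference()
        bad = FeatureMatrix(
            np.zeros((5, 3)) + np.arange(3), np.array(["x"] * 5), ("a", "b", "c")
        )
        with pytest.raises(ValueError):
            project_group(space, clouds, bad)

    def test_rescue_anchors_and_midpoint(self):
        _, data, space, clouds = self._reference()
        by_label = {c.label: c for c in clouds}
        dis, wt = by_label["dis6"], by_label["wt6"]
        # reconstruct feature-space points that map onto the cloud means
        inv = np.linalg.pinv(space.transform)
        to_features = lambda t: t @ inv * space.scale + space.center
        mid = 0.5 * (dis.mean + wt.mean)
        pts = to_features(np.vstack([dis.mean, wt.mean, mid]))
        scores = rescue_score(space, dis, wt, pts)
        assert scores == pytest.approx([0.0, 100.0, 50.0], abs=1e-6)

    def test_intermediate_mixture_between_anchors(self):
        rng, data, space, clouds = self._reference(seed=2)
        by_label = {c.label: c for c in clouds}
        dis, wt = by_label["dis6"], by_label["wt6"]
        w = 0.3  # mixing weight toward control
        lowered = rng.standard_normal((200, 4))
        lowered[:, 0] += (1 - w) * 4  # between dis6 (+4) and wt6 (0)
        scores = rescue_score(space, dis, wt, lowered)
        assert 0.0 < scores.mean() < 100.0
        assert scores.mean() == pytest.approx(100 * w, abs=12.0)

    def test_coincident_means_rejected(self):
        _, data, space, clouds = self._reference()
        c = clouds[0]
        with pytest.raises(ValueError):
            rescue_score(space, c, c, np.zeros((3, 4)))
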