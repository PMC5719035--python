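"""Superimposition, ordination, regression, disparity, and permutation tests."""

import itertools

import numpy as np
import pytest

from gpmap.morphometrics import (
    LandmarkConfiguration,
    disparity_permutation_test,
    generalized_procrustes,
    mean_shape_permutation_test,
    procrustes_variance,
    remove_lab_offset,
    shape_pca,
    shape_regression,
    standardize_shapes,
    variance_power_simulation,
)
from gpmap.synthetic import default_series, sample_landmarks


def _rigid(coords, rng, scale=None):
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    s = scale if scale is not None else np.exp(rng.uniform(-0.7, 0.7))
    return s * (coords @ q.T) + rng.normal(0, 3, size=3)


def _tetra():
    return np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0.2, 0.3, 1.0]], dtype=float
    )


class TestGeneralizedProcrustes:
    def test_identical_up_to_similarity_gives_zero_distance(self, rng):
        a = _tetra()
        rot90 = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        b = 2.0 * (a @ rot90.T) + np.array([5.0, -3.0, 1.0])
        out = generalized_procrustes(
            [
                LandmarkConfiguration("a", a),
                LandmarkConfiguration("b", b),
            ]
        )
        assert np.linalg.norm(out.shapes[0] - out.shapes[1]) < 1e-10

    def test_pairwise_distance_matches_rotation_grid_search(self):
        """Planar toy vs brute-force minimum over a fine rotation grid."""
        tri_a = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        th = np.deg2rad(10.0)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        tri_b = 1.5 * (tri_a @ rot.T)

        def unit(x):
            c = x - x.mean(axis=0)
            return c / np.sqrt(np.sum(c * c))

        ua, ub = unit(tri_a), unit(tri_b)
        best = np.inf
        for ang in np.arange(0, 2 * np.pi, 1e-4):
            r = np.array(
                [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
            )
            best = min(best, np.linalg.norm(ua - ub @ r.T))
        out = generalized_procrustes(
            [LandmarkConfiguration("a", tri_a), LandmarkConfiguration("b", tri_b)]
        )
        got = np.linalg.norm(out.shapes[0] - out.shapes[1])
        assert got == pytest.approx(best, abs=1e-4)

    def test_output_invariant_under_input_similarity_transforms(self, rng):
        series = default_series(seed=11, n_scale=0.2)
        configs, _ = sample_landmarks(series)
        base = generalized_procrustes(configs)
        moved = [
            LandmarkConfiguration(c.specimen_id, _rigid(c.coords, rng), c.genotype)
            for c in configs
        ]
        again = generalized_procrustes(moved)
        assert np.max(np.abs(base.shapes - again.shapes)) < 1e-8

    def test_noise_free_generator_collapses_to_single_point(self):
        series = default_series(seed=3, n_scale=0.2, landmark_noise_sd=1e-13)
        series.stage_allometry = None
        series.lab_offset = None
        only_wt = [g for g in series.genotypes if g.is_wild_type]
        object.__setattr__(only_wt[0], "expression_sd", 1e-13)
        series.genotypes = only_wt
        configs, _ = sample_landmarks(series)
        out = generalized_procrustes(configs)
        d = out.shapes - out.shapes[0]
        assert np.max(np.abs(d)) < 1e-8

    def test_centroid_properties(self, small_series):
        _, configs, _ = small_series
        out = generalized_procrustes(configs)
        per_spec = out.shapes.reshape(out.n, out.k, 3)
        assert np.max(np.abs(per_spec.mean(axis=1))) < 1e-10
        assert np.allclose(out.consensus, out.shapes.mean(axis=0), atol=1e-8)

    def test_degenerate_configuration_named_in_error(self):
        bad = np.zeros((4, 3))
        with pytest.raises(ValueError, match="spec_x"):
            generalized_procrustes(
                [
                    LandmarkConfiguration("ok", _tetra()),
                    LandmarkConfiguration("spec_x", bad),
                ]
            )

    def test_mismatched_landmark_counts_rejected(self):
        with pytest.raises(ValueError):
            generalized_procrustes(
                [
                    LandmarkConfiguration("a", _tetra()),
                    LandmarkConfiguration("b", _tetra()[:3]),
                ]
            )


class TestShapePCA:
    def test_single_direction_gives_full_first_component(self, rng):
        d = rng.standard_normal(12)
        d /= np.linalg.norm(d)
        x = np.outer(rng.standard_normal(30), d)
        _, _, props = shape_pca(x)
        assert props[0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_constructed_two_component_toy(self):
        # points ±√3·u1 ± 1·u2 (all four sign combinations):
        # eigenvalues 4 and 4/3 → proportions 0.75 / 0.25
        u1 = np.array([1.0, 1.0]) / np.sqrt(2)
        u2 = np.array([1.0, -1.0]) / np.sqrt(2)
        x = np.array(
            [s1 * np.sqrt(3) * u1 + s2 * u2 for s1 in (1, -1) for s2 in (1, -1)]
        )
        _, eigvals, props = shape_pca(x)
        assert eigvals[0] == pytest.approx(4.0, abs=1e-12)
        assert eigvals[1] == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert props[0] == pytest.approx(0.75, abs=1e-12)

    def test_proportions_sum_to_one_and_scores_keep_variance(self, rng):
        x = rng.standard_normal((40, 9))
        scores, eigvals, props = shape_pca(x)
        assert props.sum() == pytest.approx(1.0, abs=1e-12)
        assert scores.var(axis=0, ddof=1).sum() == pytest.approx(
            x.var(axis=0, ddof=1).sum(), rel=1e-10
        )

    def test_sign_convention_is_deterministic(self, rng):
        x = rng.standard_normal((25, 6))
        s1, *_ = shape_pca(x)
        s2, *_ = shape_pca(x.copy())
        assert np.array_equal(s1, s2)

    def test_series_orders_along_first_component(self, small_series):
        """Genotype rank along PC1 tracks rank of mean expression."""
        from scipy.stats import spearmanr

        _, configs, truth = small_series
        out = generalized_procrustes(configs)
        scores, _, _ = shape_pca(out.shapes)
        df = truth.assign(pc1=scores[:, 0]).groupby("genotype").mean(numeric_only=True)
        rho = spearmanr(df["pc1"], df["true_expression"]).statistic
        assert abs(rho) > 0.9


class TestStandardize:
    def test_orthogonal_covariate_is_noop(self, rng):
        from gpmap.morphometrics import AlignedShapeSet
        import pandas as pd

        x = rng.standard_normal((20, 6))
        cov = rng.standard_normal(20)
        # make shape variation exactly orthogonal to the covariate
        cc = cov - cov.mean()
        x = x - np.outer(cc, cc @ x) / (cc @ cc)
        aset = AlignedShapeSet(
            shapes=x,
            centroid_sizes=np.ones(20),
            consensus=x.mean(axis=0),
            metadata=pd.DataFrame({"stage": cov}),
        )
        out = standardize_shapes(aset, "stage")
        assert np.max(np.abs(out.shapes - x)) < 1e-10

    def test_constructed_stage_effect_removed(self, rng):
        from gpmap.morphometrics import AlignedShapeSet
        import pandas as pd

        a = rng.standard_normal(6)
        stage = rng.uniform(8, 14, 30)
        x = np.outer(stage, a) + 0.5
        aset = AlignedShapeSet(
            shapes=x,
            centroid_sizes=np.ones(30),
            consensus=x.mean(axis=0),
            metadata=pd.DataFrame({"stage": stage}),
        )
        out = standardize_shapes(aset, "stage")
        # no variance left along the stage direction
        assert np.ptp(out.shapes @ a) < 1e-9
        cc = stage - stage.mean()
        assert np.max(np.abs(cc @ (out.shapes - out.shapes.mean(0)))) < 1e-8

    def test_constant_covariate_fails(self, rng):
        from gpmap.morphometrics import AlignedShapeSet
        import pandas as pd

        x = rng.standard_normal((5, 6))
        aset = AlignedShapeSet(
            shapes=x, centroid_sizes=np.ones(5), consensus=x.mean(0),
            metadata=pd.DataFrame({"stage": np.ones(5)}),
        )
        with pytest.raises(ValueError):
            standardize_shapes(aset, "stage")


class TestLabOffset:
    def _make(self, shapes, labs, genos):
        import pandas as pd
        from gpmap.morphometrics import AlignedShapeSet

        return AlignedShapeSet(
            shapes=shapes,
            centroid_sizes=np.ones(len(shapes)),
            consensus=shapes.mean(axis=0),
            metadata=pd.DataFrame({"lab": labs, "genotype": genos}),
        )

    def test_identical_labs_noop(self, rng):
        x = rng.standard_normal((8, 6))
        aset = self._make(x, ["lab1"] * 8, ["WT"] * 4 + ["mut"] * 4)
        out = remove_lab_offset(aset, "WT")
        assert np.array_equal(out.shapes, x)

    def test_configured_offset_recovered_exactly_without_noise(self, rng):
        base = rng.standard_normal((4, 6))
        v = rng.standard_normal(6)
        shapes = np.vstack([base, base + v])
        labs = ["lab1"] * 4 + ["lab2"] * 4
        genos = ["WT", "WT", "m", "m"] * 2
        out = remove_lab_offset(self._make(shapes, labs, genos), "WT")
        assert np.max(np.abs(out.shapes[4:] - base)) < 1e-10

    def test_residual_offset_shrinks_with_wild_type_sample_size(self):
        """The estimated offset (from noisy wild types) misaligns the
        mutant groups by an error that shrinks as 1/sqrt(n_WT)."""
        rng = np.random.default_rng(17)
        v = np.ones(6)
        n_mut = 400  # large so mutant-mean noise is negligible
        resid = {}
        for n_wt in (8, 128):
            reps = []
            for _ in range(25):
                wt1 = rng.standard_normal((n_wt, 6))
                wt2 = rng.standard_normal((n_wt, 6)) + v
                m1 = rng.standard_normal((n_mut, 6))
                m2 = rng.standard_normal((n_mut, 6)) + v
                shapes = np.vstack([wt1, m1, wt2, m2])
                labs = ["lab1"] * (n_wt + n_mut) + ["lab2"] * (n_wt + n_mut)
                genos = (["WT"] * n_wt + ["m"] * n_mut) * 2
                out = remove_lab_offset(self._make(shapes, labs, genos), "WT")
                g = np.array(genos)
                l = np.array(labs)
                d = (
                    out.shapes[(g == "m") & (l == "lab1")].mean(0)
                    - out.shapes[(g == "m") & (l == "lab2")].mean(0)
                )
                reps.append(np.linalg.norm(d))
            resid[n_wt] = np.mean(reps)
        # 16x more wild types -> ~4x smaller residual misalignment
        assert resid[128] < resid[8] / 2.5

    def test_lab_without_wild_type_fails(self, rng):
        x = rng.standard_normal((4, 6))
        aset = self._make(x, ["lab1", "lab1", "lab2", "lab2"], ["WT", "m", "m", "m"])
        with pytest.raises(ValueError, match="lab2"):
            remove_lab_offset(aset, "WT")


class TestShapeRegression:
    def test_exact_linear_relationship(self, rng):
        d = rng.standard_normal(9)
        x = rng.uniform(0, 1, 25)
        shapes = 0.3 + np.outer(x, d)
        res = shape_regression(shapes, x)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        # scores reproduce the covariate up to an affine map
        r = np.corrcoef(res.regression_scores, x)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        shapes = rng.standard_normal((100, 6))
        x = rng.standard_normal(100)
        res = shape_regression(shapes, x)
        xc = x - x.mean()
        beta = (xc @ (shapes - shapes.mean(0))) / (xc @ xc)
        fitted = np.outer(xc, beta)
        yc = shapes - shapes.mean(0)
        r2 = np.sum(fitted**2) / np.sum(yc**2)
        assert res.r_squared == pytest.approx(r2, abs=1e-12)
        assert np.max(np.abs(res.coefficients - beta)) < 1e-10

    def test_r_squared_plus_residual_fraction_is_one(self, rng):
        shapes = rng.standard_normal((50, 8))
        x = rng.standard_normal(50)
        res = shape_regression(shapes, x)
        yc = shapes - shapes.mean(0)
        resid = res.residual_shapes - res.residual_shapes.mean(0)
        frac = np.sum(resid**2) / np.sum(yc**2)
        assert res.r_squared + frac == pytest.approx(1.0, abs=1e-12)


class TestDisparity:
    def test_identical_shapes_zero(self):
        x = np.tile(np.arange(6.0), (5, 1))
        pv = procrustes_variance(x, ["g"] * 5)
        assert pv["g"] == 0.0

    def test_two_point_group_value(self):
        # deviations from the midpoint are d/2 each: SS = d²/2, so the
        # population form (divisor n = 2) gives d²/4 and ddof=1 gives d²/2
        a, b = np.zeros(6), np.ones(6)
        d2 = np.sum((a - b) ** 2)
        pv = procrustes_variance(np.vstack([a, b]), ["g", "g"])
        assert pv["g"] == pytest.approx(d2 / 4.0, abs=1e-12)
        pv1 = procrustes_variance(np.vstack([a, b]), ["g", "g"], ddof=1)
        assert pv1["g"] == pytest.approx(d2 / 2.0, abs=1e-12)

    def test_invariant_under_group_translation(self, rng):
        x = rng.standard_normal((10, 6))
        g = ["a"] * 5 + ["b"] * 5
        pv = procrustes_variance(x, g)
        x2 = x.copy()
        x2[5:] += 7.3
        pv2 = procrustes_variance(x2, g)
        assert pv["b"] == pytest.approx(pv2["b"], abs=1e-10)

    def test_singleton_group_flagged_nan(self, rng):
        x = rng.standard_normal((3, 6))
        pv = procrustes_variance(x, ["a", "a", "b"])
        assert np.isnan(pv["b"])


class TestPermutationTests:
    def test_fixed_seed_reproducible(self, rng):
        x = rng.standard_normal((20, 6))
        g = ["a"] * 10 + ["b"] * 10
        p1 = disparity_permutation_test(x, g, n_perm=199, seed=5)
        p2 = disparity_permutation_test(x, g, n_perm=199, seed=5)
        assert p1.equals(p2)
        m1 = mean_shape_permutation_test(x, g, n_perm=199, seed=5)
        m2 = mean_shape_permutation_test(x, g, n_perm=199, seed=5)
        assert m1.equals(m2)

    def test_pvalues_in_unit_interval(self, rng):
        x = rng.standard_normal((24, 6))
        g = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        p = disparity_permutation_test(x, g, n_perm=99, seed=1)
        off = p.values[~np.eye(3, dtype=bool)]
        assert np.all(off > 0) and np.all(off <= 1)

    def test_strong_variance_difference_detected(self, rng):
        x = np.vstack(
            [rng.standard_normal((20, 6)), 4.0 * rng.standard_normal((20, 6))]
        )
        g = ["a"] * 20 + ["b"] * 20
        p = disparity_permutation_test(x, g, n_perm=199, seed=2)
        assert p.loc["a", "b"] == pytest.approx(1 / 200, abs=1e-12)

    def test_saturated_mean_difference_hits_floor(self, rng):
        x = np.vstack(
            [rng.standard_normal((15, 6)), rng.standard_normal((15, 6)) + 10.0]
        )
        g = ["a"] * 15 + ["b"] * 15
        p = mean_shape_permutation_test(x, g, n_perm=199, seed=3)
        assert p.loc["a", "b"] == pytest.approx(1 / 200, abs=1e-12)

    def test_mean_test_matches_exhaustive_enumeration(self):
        """Small two-group toy vs full enumeration of label assignments."""
        x = np.array(
            [[0.0, 0.1], [0.2, -0.1], [-0.1, 0.0],
             [0.8, 0.9], [1.1, 0.7], [0.9, 1.2]]
        )
        g = np.array(["a"] * 3 + ["b"] * 3)
        obs = np.linalg.norm(x[:3].mean(0) - x[3:].mean(0))
        count = 0
        total = 0
        for idx in itertools.permutations(range(6)):
            pa = x[list(idx[:3])].mean(0)
            pb = x[list(idx[3:])].mean(0)
            total += 1
            if np.linalg.norm(pa - pb) >= obs - 1e-12:
                count += 1
        exact = count / total
        p = mean_shape_permutation_test(x, g, n_perm=9999, seed=0).loc["a", "b"]
        assert p == pytest.approx(exact, abs=0.02)


class TestPowerSimulation:
    def test_null_power_near_alpha(self):
        out = variance_power_simulation(10, 1.0, reps=300, n_perm=99, seed=1)
        assert abs(out["power"] - 0.05) < 0.04

    def test_large_effect_high_power(self):
        out = variance_power_simulation(20, 4.0, reps=100, n_perm=99, seed=2)
        assert out["power"] > 0.9

    def test_template_route_runs(self):
        series = default_series(seed=5)
        out = variance_power_simulation(
            5, 4.0, reps=100, n_perm=99, seed=3, template=series
        )
        assert 0.0 <= out["power"] <= 1.0
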