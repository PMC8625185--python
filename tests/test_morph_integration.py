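"""Parity replication, principal coordinates, density surfaces,
Procrustes/PROTEST, character weights, association tests."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial import procrustes as scipy_procrustes
from scipy.stats import spearmanr

import ppl
from ppl.morph_integration import Ordination
from ppl.tree_ops import DistanceMatrix

from conftest import random_additive_dm


def ordination(labels, coords):
    return Ordination(list(labels), np.asarray(coords, dtype=float),
                      np.array([]))


class TestReplicateToParity:
    def matrix(self, n_taxa=4, n_chars=6, seed=0):
        rng = np.random.default_rng(seed)
        states = (rng.random((n_taxa, n_chars)) < 0.5).astype(float)
        return ppl.BinaryCharacterMatrix(
            [f"t{i}" for i in range(n_taxa)],
            [f"c{j}" for j in range(n_chars)], states)

    def test_equal_counts_leave_matrix_unchanged(self):
        m = self.matrix(n_chars=6)
        out = ppl.replicate_to_parity(m, 6)
        assert out.n_characters == 6
        np.testing.assert_array_equal(out.states, m.states)

    def test_study_scale_counts(self):
        # 114 morphological characters vs 2062 molecular sites -> r = 18
        m = self.matrix(n_taxa=3, n_chars=114)
        out = ppl.replicate_to_parity(m, 2062)
        assert out.n_characters == 114 * 18 == 2052

    def test_rounding_bound(self):
        for n_morph, n_mol in [(10, 95), (7, 100), (5, 11)]:
            m = self.matrix(n_chars=n_morph)
            out = ppl.replicate_to_parity(m, n_mol)
            r = out.n_characters // n_morph
            # r = round(n_mol / n_morph) implies the exact parity bound
            assert abs(r * n_morph - n_mol) <= 0.5 * n_morph + 1e-12

    def test_distances_unchanged_by_replication(self):
        m = self.matrix(n_taxa=6, n_chars=10, seed=3)
        m.states[0, 0] = np.nan
        base = ppl.character_distance_matrix(m)
        rep = ppl.character_distance_matrix(ppl.replicate_to_parity(m, 70))
        np.testing.assert_allclose(rep.values, base.values, equal_nan=True)


class TestClassicalMDS:
    def test_planar_points_reconstructed(self):
        pts = np.array([[0.0, 0], [3, 0], [0, 4]])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        ord_ = ppl.classical_mds(DistanceMatrix(["a", "b", "c"], d), dims=2)
        out = np.linalg.norm(
            ord_.coordinates[:, None] - ord_.coordinates[None], axis=-1)
        np.testing.assert_allclose(sorted(out[np.triu_indices(3, 1)]),
                                   [3, 4, 5], atol=1e-9)

    def test_coordinates_are_centered(self):
        dm = random_additive_dm(10, 2)
        ord_ = ppl.classical_mds(dm, dims=2)
        np.testing.assert_allclose(ord_.coordinates.mean(axis=0), 0,
                                   atol=1e-9)

    def test_equilateral_from_equal_distances(self):
        d = np.ones((3, 3)) - np.eye(3)
        ord_ = ppl.classical_mds(DistanceMatrix(["a", "b", "c"], d), dims=2)
        sides = np.linalg.norm(
            ord_.coordinates[[0, 1, 2]] - ord_.coordinates[[1, 2, 0]], axis=1)
        np.testing.assert_allclose(sides, sides[0], rtol=1e-9)
        assert ord_.eigenvalues[0] == pytest.approx(ord_.eigenvalues[1])

    def test_duplicate_point_coincides(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [0, 1]])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        ord_ = ppl.classical_mds(DistanceMatrix(list("abcd"), d), dims=2)
        np.testing.assert_allclose(ord_.coordinates[2], ord_.coordinates[3],
                                   atol=1e-9)

    def test_too_many_dims_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError, match="positive"):
            ppl.classical_mds(DistanceMatrix(["a", "b", "c"], d), dims=3)

    def test_matches_scikit_bio_pcoa(self):
        import warnings

        from skbio.stats.ordination import pcoa
        dm = random_additive_dm(12, 9)
        ord_ = ppl.classical_mds(dm, dims=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = pcoa(dm.values, number_of_dimensions=2)
        # same embedding up to per-axis sign
        ours = ord_.coordinates
        theirs = ref.samples.to_numpy()
        for ax in range(2):
            assert min(
                np.abs(ours[:, ax] - theirs[:, ax]).max(),
                np.abs(ours[:, ax] + theirs[:, ax]).max(),
            ) < 1e-6


class TestDensitySurface:
    def test_single_cluster_peak_location(self, rng):
        pts = rng.normal([2.0, -1.0], 0.05, size=(60, 2))
        surf = ppl.density_surface(
            ordination(range(60), pts), grid_size=64)
        i, j = np.unravel_index(surf.density.argmax(), surf.density.shape)
        assert abs(surf.grid_x[i] - 2.0) < 0.15
        assert abs(surf.grid_y[j] + 1.0) < 0.15

    def test_two_separated_clusters_have_equal_peaks(self, rng):
        a = rng.normal([0, 0], 0.1, size=(100, 2))
        b = rng.normal([10, 0], 0.1, size=(100, 2))
        pts = np.vstack([a, b])
        surf = ppl.density_surface(ordination(range(200), pts),
                                   grid_size=128, bandwidth=(0.3, 0.3))
        mid = np.searchsorted(surf.grid_x, 5.0)
        left = surf.density[:mid].max()
        right = surf.density[mid:].max()
        assert 0.9 <= left / right <= 1.1

    def test_unit_integral(self, rng):
        pts = rng.normal(size=(40, 2))
        surf = ppl.density_surface(ordination(range(40), pts), grid_size=96)
        assert surf.integral() == pytest.approx(1.0, abs=0.01)

    def test_zero_variance_axis_suggests_jitter(self):
        pts = np.array([[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
        with pytest.raises(ValueError, match="jitter"):
            ppl.density_surface(ordination("abc", pts))


def brute_force_m12sq(X, Y, allow_reflection=True):
    """Direct optimization over rotation angle (and scale, analytic) for
    2-D configurations: grid over theta then local refinement."""
    def normalize(c):
        c = c - c.mean(axis=0)
        return c / np.sqrt((c**2).sum())

    xn, yn = normalize(X), normalize(Y)

    def neg_trace(theta, flip):
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        F = np.diag([1.0, -1.0 if flip else 1.0])
        return -np.trace(xn.T @ yn @ F @ R)

    best = -np.inf
    flips = (False, True) if allow_reflection else (False,)
    for flip in flips:
        grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        vals = np.array([-neg_trace(t, flip) for t in grid])
        t0 = grid[vals.argmax()]
        res = minimize_scalar(neg_trace, args=(flip,),
                              bounds=(t0 - 0.02, t0 + 0.02),
                              method="bounded",
                              options={"xatol": 1e-12})
        best = max(best, -res.fun)
    return 1.0 - best**2


class TestProcrustes:
    def test_rigid_motion_gives_perfect_fit(self, rng):
        X = rng.normal(size=(20, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        Y = 3.2 * X @ R + np.array([5.0, -2.0])
        labels = [f"t{i}" for i in range(20)]
        res = ppl.procrustes_superimpose(ordination(labels, X),
                                         ordination(labels, Y))
        assert res.correlation == pytest.approx(1.0, abs=1e-9)
        assert res.m12_squared == pytest.approx(0.0, abs=1e-9)
        assert res.residuals.max() < 1e-9

    def test_matched_by_label_not_order(self, rng):
        X = rng.normal(size=(10, 2))
        labels = [f"t{i}" for i in range(10)]
        perm = rng.permutation(10)
        res = ppl.procrustes_superimpose(
            ordination(labels, X),
            ordination([labels[i] for i in perm], X[perm]))
        assert res.correlation == pytest.approx(1.0, abs=1e-9)

    def test_correlation_is_sqrt_one_minus_m12sq(self, rng):
        labels = [f"t{i}" for i in range(30)]
        res = ppl.procrustes_superimpose(
            ordination(labels, rng.normal(size=(30, 2))),
            ordination(labels, rng.normal(size=(30, 2))))
        assert res.correlation == pytest.approx(
            np.sqrt(1 - res.m12_squared), abs=1e-12)

    def test_symmetry_of_m12sq(self, rng):
        labels = [f"t{i}" for i in range(15)]
        A = ordination(labels, rng.normal(size=(15, 2)))
        B = ordination(labels, rng.normal(size=(15, 2)))
        ab = ppl.procrustes_superimpose(A, B).m12_squared
        ba = ppl.procrustes_superimpose(B, A).m12_squared
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_against_grid_refinement_oracle(self, rng):
        X = rng.normal(size=(100, 2))
        Y = rng.normal(size=(100, 2))
        labels = [f"t{i}" for i in range(100)]
        res = ppl.procrustes_superimpose(ordination(labels, X),
                                         ordination(labels, Y))
        assert res.correlation < 1.0
        oracle = brute_force_m12sq(X, Y)
        assert res.m12_squared == pytest.approx(oracle, abs=1e-6)

    def test_against_scipy_disparity(self, rng):
        X = rng.normal(size=(25, 2))
        Y = rng.normal(size=(25, 2))
        labels = [f"t{i}" for i in range(25)]
        res = ppl.procrustes_superimpose(ordination(labels, X),
                                         ordination(labels, Y))
        _, _, disparity = scipy_procrustes(X, Y)
        assert res.m12_squared == pytest.approx(disparity, abs=1e-9)

    def test_label_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ppl.procrustes_superimpose(
                ordination(["a", "b", "c"], rng.normal(size=(3, 2))),
                ordination(["a", "b", "x"], rng.normal(size=(3, 2))))


class TestProtest:
    def test_perfect_match_hits_the_floor_at_999(self, rng):
        X = rng.normal(size=(12, 2))
        labels = [f"t{i}" for i in range(12)]
        res = ppl.protest(ordination(labels, X),
                          ordination(labels, 2 * X + 1.0),
                          n_permutations=999, seed=3)
        assert res.p_value == pytest.approx(0.001)

    def test_exhaustive_three_taxa_enumeration(self, rng):
        import itertools
        labels = ["a", "b", "c"]
        X = rng.normal(size=(3, 2))
        Y = rng.normal(size=(3, 2))
        obs = ppl.procrustes_superimpose(ordination(labels, X),
                                         ordination(labels, Y)).correlation
        corrs = []
        for perm in itertools.permutations(range(3)):
            c = ppl.procrustes_superimpose(
                ordination(labels, X),
                ordination([labels[i] for i in perm], Y)).correlation
            corrs.append(c)
        exact = np.mean([c >= obs - 1e-12 for c in corrs])
        # estimate with many permutations; the add-one estimator converges
        # to the exact enumeration fraction over the 3! = 6 distinct orders
        res = ppl.protest(ordination(labels, X), ordination(labels, Y),
                          n_permutations=6000, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.03)

    def test_seed_determinism(self, rng):
        labels = [f"t{i}" for i in range(9)]
        X = ordination(labels, rng.normal(size=(9, 2)))
        Y = ordination(labels, rng.normal(size=(9, 2)))
        assert (ppl.protest(X, Y, 99, seed=5).p_value
                == ppl.protest(X, Y, 99, seed=5).p_value)

    def test_matches_vegan_protest_statistic(self, tmp_path, rng):
        X = rng.normal(size=(14, 2))
        Y = rng.normal(size=(14, 2))
        np.savetxt(tmp_path / "x.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", Y, delimiter=",")
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            x <- as.matrix(read.csv("x.csv", header = FALSE))
            y <- as.matrix(read.csv("y.csv", header = FALSE))
            res <- protest(x, y, permutations = 29)
            cat(sprintf("%.12f\\n", res$t0))
        """)
        (tmp_path / "protest.R").write_text(script)
        out = subprocess.run(["Rscript", "protest.R"], cwd=tmp_path,
                             capture_output=True, text=True, check=True)
        t0 = float(out.stdout.strip().splitlines()[-1])
        labels = [f"t{i}" for i in range(14)]
        res = ppl.procrustes_superimpose(ordination(labels, X),
                                         ordination(labels, Y))
        assert res.correlation == pytest.approx(t0, abs=1e-9)


class TestCharacterWeights:
    def test_self_reference_gives_rho_near_one(self, rng):
        states = (rng.random((12, 1)) < 0.5).astype(float)
        while len(np.unique(states)) < 2:
            states = (rng.random((12, 1)) < 0.5).astype(float)
        taxa = [f"t{i}" for i in range(12)]
        mat = ppl.BinaryCharacterMatrix(taxa, ["c1"], states)
        mism = (states != states.T).astype(float)
        ref = DistanceMatrix(taxa, mism + rng.random((12, 12)) * 1e-9
                             * (1 - np.eye(12)) * 0)
        res = ppl.character_weights(mat, ref, n_bootstrap=50, seed=1)
        assert res.table.loc["c1", "median_rho"] > 0.99

    def test_clade_marker_outranks_noise_character(self):
        hits = 0
        n_runs = 40
        for seed in range(n_runs):
            tree = ppl.simulate_yule_tree(16, seed=seed)
            ref = ppl.cophenetic_distances(tree)
            labels = ppl.assign_sections(tree, 2)
            taxa = ref.labels
            clade_char = np.array(
                [1.0 if labels[t] == "S01" else 0.0 for t in taxa])
            rng = np.random.default_rng(1000 + seed)
            noise_char = (rng.random(len(taxa)) < 0.5).astype(float)
            if len(np.unique(noise_char)) < 2:
                noise_char[0] = 1 - noise_char[0]
            mat = ppl.BinaryCharacterMatrix(
                list(taxa), ["clade", "noise"],
                np.column_stack([clade_char, noise_char]))
            res = ppl.character_weights(mat, ref, n_bootstrap=60,
                                        seed=seed)
            if (res.table.loc["clade", "median_rho"]
                    > res.table.loc["noise", "median_rho"]):
                hits += 1
        assert hits >= 0.9 * n_runs

    def test_invariant_characters_reported_nan_with_warning(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        states = np.column_stack([
            np.zeros(8),
            (rng.random(8) < 0.5).astype(float),
        ])
        states[0, 1] = 1.0
        states[1, 1] = 0.0
        mat = ppl.BinaryCharacterMatrix(taxa, ["flat", "var"], states)
        ref = random_additive_dm(8, 3)
        ref = DistanceMatrix(taxa, ref.values)
        with pytest.warns(UserWarning, match="distinct"):
            res = ppl.character_weights(mat, ref, n_bootstrap=20, seed=2)
        assert np.isnan(res.table.loc["flat", "median_rho"])
        assert not np.isnan(res.table.loc["var", "median_rho"])

    def test_max_rho_at_least_median_rho(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        states = (rng.random((10, 5)) < 0.5).astype(float)
        states[0] = 1 - states[1]  # ensure variation
        mat = ppl.BinaryCharacterMatrix(taxa, [f"c{j}" for j in range(5)],
                                        states)
        ref = DistanceMatrix(taxa, random_additive_dm(10, 4).values)
        res = ppl.character_weights(mat, ref, n_bootstrap=100, seed=3)
        ok = res.table.dropna()
        assert (ok["max_rho"] >= ok["median_rho"] - 1e-12).all()

    def test_monotone_reference_invariance(self, rng):
        taxa = [f"t{i}" for i in range(10)]
        states = (rng.random((10, 4)) < 0.5).astype(float)
        mat = ppl.BinaryCharacterMatrix(taxa, list("wxyz"), states)
        ref = DistanceMatrix(taxa, random_additive_dm(10, 5).values)
        ref_sq = DistanceMatrix(taxa, ref.values**2)
        a = ppl.character_weights(mat, ref, n_bootstrap=30, seed=6)
        b = ppl.character_weights(mat, ref_sq, n_bootstrap=30, seed=6)
        np.testing.assert_allclose(a.table.to_numpy(), b.table.to_numpy(),
                                   equal_nan=True, atol=1e-12)


class TestAssociation:
    def test_independence_gives_zero(self):
        a = ["x"] * 10 + ["y"] * 10
        b = (["u", "v"] * 10)
        res = ppl.association_test(a, b)
        assert res.chi2 == pytest.approx(0.0)
        assert res.cramers_v_corrected == pytest.approx(0.0)

    def test_perfect_association_hand_computed_bergsma(self):
        a = ["x"] * 10 + ["y"] * 10
        b = ["u"] * 10 + ["v"] * 10
        res = ppl.association_test(a, b)
        # chi2 = 20, n = 20, phi2 = 1; bias term (1*1)/19
        # phi2_corr = 18/19; r' = c' = 2 - 1/19; denom = 18/19 -> V = 1
        assert res.chi2 == pytest.approx(20.0)
        assert res.cramers_v_corrected == pytest.approx(1.0, abs=1e-12)

    def test_partial_association_hand_computed(self):
        # 2x2 table [[8,2],[3,7]]: chi2 via scipy, Bergsma by hand
        a = ["x"] * 10 + ["y"] * 10
        b = ["u"] * 8 + ["v"] * 2 + ["u"] * 3 + ["v"] * 7
        res = ppl.association_test(a, b)
        n = 20
        phi2 = res.chi2 / n
        phi2_corr = max(0.0, phi2 - 1 / 19)
        expected_v = np.sqrt(phi2_corr / (1 - 1 / 19))
        assert res.cramers_v_corrected == pytest.approx(expected_v, abs=1e-12)

    def test_invariant_to_category_permutation(self, rng):
        a = rng.choice(list("abc"), size=60)
        b = rng.choice(list("uv"), size=60)
        res1 = ppl.association_test(a, b)
        swap = {"a": "c", "b": "a", "c": "b"}
        res2 = ppl.association_test([swap[v] for v in a], b)
        assert res1.cramers_v_corrected == pytest.approx(
            res2.cramers_v_corrected)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ppl.association_test(["x"] * 5, ["u", "v", "u", "v", "u"])
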