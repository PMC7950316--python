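"""Entropy weighting, weighted distances, NMDS, knee selection, DBSCAN."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from ligandscape import landscape as ls
from ligandscape import synth
from ligandscape.alphabet import AMINO_ACIDS

LOG2_20 = math.log2(20)


class TestPositionalEntropy:
    def test_hand_values(self):
        peps = ["AY", "AY", "CW", "DF"]  # P1 freq (.5,.25,.25), P2 all distinct+dup
        prof = ls.positional_entropy(["AA", "AA"])
        assert prof.entropies[0] == pytest.approx(0.0)
        prof = ls.positional_entropy(["AA", "CA"])
        assert prof.entropies[0] == pytest.approx(1.0)
        prof = ls.positional_entropy(peps)
        assert prof.entropies[0] == pytest.approx(1.5)

    def test_needs_two_peptides(self):
        with pytest.raises(ValueError):
            ls.positional_entropy(["AAAA"])


class TestEntropyWeights:
    @pytest.mark.parametrize(
        "entropy,weight",
        [(0.0, 1.0), (LOG2_20, 0.0), (LOG2_20 / 2, 0.5)],
    )
    def test_linear_form(self, entropy, weight):
        assert ls.entropy_weights(np.array([entropy]))[0] == pytest.approx(weight)


def _distance_oracle(a, b, weights, R):
    """Position-by-position brute-force computation."""
    total = 0.0
    for p, (ra, rb) in enumerate(zip(a, b)):
        total += weights[p] * R[AMINO_ACIDS.index(ra), AMINO_ACIDS.index(rb)]
    return total


class TestPeptideDistance:
    def test_identity(self):
        w = np.ones(4)
        assert ls.peptide_distance("ACDE", "ACDE", w) == 0.0

    def test_single_mismatch_unit_weight(self):
        R = np.ones((20, 20)) - np.eye(20)
        w = np.array([1.0, 0.0, 0.0])
        assert ls.peptide_distance("AAA", "CAA", w, R) == pytest.approx(1.0)

    def test_toy_three_peptide_matrix_vs_oracle(self):
        rng = np.random.default_rng(0)
        R = rng.uniform(0.1, 1.0, size=(20, 20))
        R = (R + R.T) / 2
        np.fill_diagonal(R, 0.0)
        w = np.array([0.9, 0.4, 0.1])
        peps = ["ACD", "AYD", "WCD"]
        for a in peps:
            for b in peps:
                assert ls.peptide_distance(a, b, w, R) == pytest.approx(
                    _distance_oracle(a, b, w, R), abs=1e-12
                )

    def test_random_pairs_vs_oracle_exact(self):
        rng = np.random.default_rng(1)
        R = ls.residue_distance_matrix()
        w = rng.uniform(0, 1, size=9)
        for _ in range(50):
            a = "".join(rng.choice(list(AMINO_ACIDS), size=9))
            b = "".join(rng.choice(list(AMINO_ACIDS), size=9))
            assert ls.peptide_distance(a, b, w, R) == pytest.approx(
                _distance_oracle(a, b, w, R), abs=1e-12
            )

    def test_condensed_matrix_matches_pairwise_calls(self):
        spec = synth.make_allele("uni", 9)
        peps = synth.sample_ligands(spec, 20, seed=2)
        prof = ls.positional_entropy(peps)
        d = squareform(ls.pairwise_distances(peps, prof.weights))
        R = ls.residue_distance_matrix()
        for i in range(20):
            for j in range(20):
                assert d[i, j] == pytest.approx(
                    ls.peptide_distance(peps[i], peps[j], prof.weights, R), abs=1e-12
                )

    def test_symmetry_and_triangle_with_default_matrix(self):
        rng = np.random.default_rng(3)
        R = ls.residue_distance_matrix()
        w = ls.entropy_weights(rng.uniform(0, LOG2_20, size=9))
        peps = ["".join(rng.choice(list(AMINO_ACIDS), size=9)) for _ in range(15)]
        for a in peps:
            for b in peps:
                dab = ls.peptide_distance(a, b, w, R)
                assert dab == pytest.approx(ls.peptide_distance(b, a, w, R))
                for c in peps:
                    assert dab <= (
                        ls.peptide_distance(a, c, w, R)
                        + ls.peptide_distance(c, b, w, R)
                        + 1e-12
                    )


class TestResidueMatrix:
    def test_basic_properties(self):
        R = ls.residue_distance_matrix()
        assert R.shape == (20, 20)
        assert np.allclose(np.diag(R), 0.0)
        assert np.allclose(R, R.T)
        assert R.min() >= 0.0 and R.max() <= 1.0
        # conservative pairs are closer than radical ones
        i = AMINO_ACIDS.index
        assert R[i("L"), i("V")] < R[i("L"), i("D")]


class TestNmds:
    def test_planar_distances_embed_with_tiny_stress(self, rng):
        pts = rng.normal(size=(10, 2))
        emb = ls.nmds(pdist(pts), seed=1)
        assert emb.stress < 0.01

    def test_invariance_under_monotone_transform(self, rng):
        pts = rng.normal(size=(12, 2))
        d = pdist(pts)
        s1 = ls.nmds(d, seed=2).stress
        s2 = ls.nmds(d**2, seed=2).stress  # strictly monotone transform
        assert abs(s1 - s2) < 0.02

    def test_returns_least_stress_restart(self, rng):
        pts = rng.normal(size=(15, 3))
        emb = ls.nmds(pdist(pts), seed=3)
        assert emb.stress == pytest.approx(min(emb.all_stresses))

    def test_stress_trajectory_non_increasing(self, rng):
        pts = rng.normal(size=(20, 4))
        emb = ls.nmds(pdist(pts), seed=4)
        assert np.all(np.diff(emb.trajectory) <= 1e-12)

    def test_agrees_with_sklearn_nonmetric_mds(self, rng):
        # independent implementation embeds the same planar data as well
        pts = rng.normal(size=(10, 2))
        d = pdist(pts)
        ours = ls.nmds(d, seed=5)
        _, sk_stress = smacof(
            squareform(d),
            metric=False,
            n_components=2,
            n_init=4,
            random_state=0,
            normalized_stress=True,
        )
        assert ours.stress < 0.01 and sk_stress < 0.05

    def test_all_zero_distances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ls.nmds(np.zeros(6), seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            ls.nmds(np.array([1.0, 2.0, 3.0]), seed=0)


class TestKneeAndDbscan:
    def test_two_blobs_recovered(self, rng):
        blob = np.vstack(
            [rng.normal(0, 0.05, (100, 2)), rng.normal(1, 0.05, (100, 2))]
        )
        eps, curve = ls.knee_eps(blob, 5)
        assert curve.shape == (200,)
        clust = ls.dbscan(blob, eps, 5)
        assert clust.labels.max() == 2
        assert (clust.labels == 0).mean() <= 0.05

    def test_uniform_grid_single_cluster(self):
        grid = np.array([[i, j] for i in range(10) for j in range(10)], dtype=float)
        eps, _ = ls.knee_eps(grid, 5)
        assert 0.9 <= eps <= 2.1  # near the grid spacing
        clust = ls.dbscan(grid, eps, 5)
        assert clust.labels.max() == 1
        assert (clust.labels == 0).sum() == 0

    def test_knee_needs_more_points_than_min_pts(self):
        with pytest.raises(ValueError):
            ls.knee_eps(np.zeros((5, 2)), 5)

    def test_tiny_eps_marks_all_noise(self, rng):
        pts = rng.normal(size=(30, 2))
        clust = ls.dbscan(pts, 1e-9, 3)
        assert np.all(clust.labels == 0)

    def test_identical_points_one_cluster_no_noise(self):
        pts = np.zeros((20, 2))
        clust = ls.dbscan(pts, 0.5, 5)
        assert clust.labels.max() == 1
        assert (clust.labels == 0).sum() == 0

    def test_invalid_parameters_rejected(self, rng):
        pts = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            ls.dbscan(pts, 0.0, 5)
        with pytest.raises(ValueError):
            ls.dbscan(pts, 0.5, 1)


class TestLandscapeRecovery:
    def test_planted_submotifs_form_pure_clusters(self):
        peps, ids = synth.planted_submotif_ligands(seed=1)
        ids = np.array(ids)
        scape = ls.build_landscape(peps, seed=101)
        lab = scape.clustering.labels
        for sub in ("P2FY", "P7L"):
            purities = [
                (ids[lab == c] == sub).mean()
                for c in range(1, lab.max() + 1)
                if (lab == c).sum() >= scape.clustering.min_pts
            ]
            assert max(purities) >= 0.8

    def test_distance_mode_clustering_runs(self):
        peps, _ = synth.planted_submotif_ligands(
            n_submotif_a=60, n_submotif_b=60, n_background=80, seed=2
        )
        scape = ls.build_landscape(peps, seed=3, cluster_on="distances", n_restarts=3)
        assert scape.clustering.labels.shape == (200,)

    def test_unknown_cluster_mode_rejected(self):
        peps, _ = synth.planted_submotif_ligands(
            n_submotif_a=20, n_submotif_b=20, n_background=20, seed=4
        )
        with pytest.raises(ValueError, match="cluster_on"):
            ls.build_landscape(peps, cluster_on="volume")
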