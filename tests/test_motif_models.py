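"""PSSM training, percentile scores, deconvolution, proteome scanning."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ligandscape import motif_models as mm
from ligandscape import synth
from ligandscape.alphabet import AMINO_ACIDS
from ligandscape.peptide_io import ProteinRecord


class TestTrainPssm:
    def test_conserved_terminal_column(self):
        rng = np.random.default_rng(0)
        peps = [
            "".join(rng.choice(list(AMINO_ACIDS), size=8)) + "Y" for _ in range(100)
        ]
        pssm = mm.train_pssm(peps)
        assert AMINO_ACIDS[np.argmax(pssm.log_odds[:, 8])] == "Y"

    def test_generator_round_trip_recovers_anchors(self, a29_spec, a29_ligands):
        pssm = mm.train_pssm(a29_ligands)
        for pos in range(a29_spec.length):
            w = a29_spec.position_weights[pos]
            if w.max() >= 0.5:  # anchor positions only
                assert np.argmax(pssm.log_odds[:, pos]) == np.argmax(w)

    def test_huge_pseudocount_flattens_to_zero(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands[:100], beta=1e12)
        assert np.max(np.abs(pssm.log_odds)) < 1e-6

    def test_uniform_counts_give_zero_log_odds(self):
        peps = [aa * 9 for aa in AMINO_ACIDS]  # each residue once per column
        pssm = mm.train_pssm(peps)
        assert np.max(np.abs(pssm.log_odds)) < 1e-9

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mm.train_pssm(["AAAAAAAAA"] * 20 + ["AAAA"])

    def test_too_few_peptides_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            mm.train_pssm(["AAAAAAAAA"] * 10)


class TestMsiLikeScore:
    def test_consensus_scores_near_one(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands)
        assert mm.msi_like_score(pssm, mm.consensus_peptide(pssm)) >= 0.99

    def test_uniform_pssm_ties_at_midrank(self):
        pssm = mm.train_pssm([aa * 9 for aa in AMINO_ACIDS])
        assert mm.msi_like_score(pssm, "AAAAAAAAA") == pytest.approx(0.5)

    def test_background_scores_probability_integral_transform(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands)
        rng = np.random.default_rng(77)
        bg = [
            "".join(rng.choice(list(AMINO_ACIDS), size=9)) for _ in range(10_000)
        ]
        scores = mm.msi_like_scores(pssm, bg)
        assert stats.kstest(scores, "uniform").statistic < 0.02

    def test_monotone_in_raw_score(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands)
        rng = np.random.default_rng(5)
        peps = ["".join(rng.choice(list(AMINO_ACIDS), size=9)) for _ in range(200)]
        raw = mm.raw_scores(pssm, peps)
        msi = mm.msi_like_scores(pssm, peps)
        order = np.argsort(raw)
        assert np.all(np.diff(msi[order]) >= 0)

    def test_length_mismatch_rejected(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands)
        with pytest.raises(ValueError, match="length"):
            mm.msi_like_score(pssm, "AAAA")


class TestAssignBestAllele:
    def test_single_model(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands, name="A29")
        allele, score, scores = mm.assign_best_allele("AAAAAAAAY", [pssm])
        assert allele == "A29" and set(scores) == {"A29"}

    def test_tie_breaks_lexicographically(self, a29_ligands):
        m1 = mm.train_pssm(a29_ligands, name="B")
        m2 = mm.train_pssm(a29_ligands, name="A")
        allele, _, _ = mm.assign_best_allele("AAAAAAAAY", [m1, m2])
        assert allele == "A"

    def test_generator_round_trip_assignment(self, disjoint_anchor_families):
        fam_a, fam_b = disjoint_anchor_families
        model_a = mm.train_pssm(synth.sample_ligands(fam_a, 1000, 1), name="A")
        model_b = mm.train_pssm(synth.sample_ligands(fam_b, 1000, 2), name="B")
        test_peps = synth.sample_ligands(fam_a, 500, 3)
        hits = 0
        for p in test_peps:
            allele, score, _ = mm.assign_best_allele(p, [model_a, model_b])
            hits += allele == "A" and score > 0.8
        assert hits / 500 >= 0.95


class TestGibbsCluster:
    def test_planted_partition_recovery(self, disjoint_anchor_families):
        fam_a, fam_b = disjoint_anchor_families
        peps = synth.sample_ligands(fam_a, 200, 10) + synth.sample_ligands(
            fam_b, 200, 11
        )
        truth = np.array([0] * 200 + [1] * 200)
        sol = mm.gibbs_cluster(peps, mm.GibbsParams(), seed=3)
        assigned = sol.labels >= 0
        ari = adjusted_rand_score(truth[assigned], sol.labels[assigned])
        assert ari >= 0.95
        assert sol.n_clusters == 2  # third cluster empty

    def test_single_cluster_objective_is_self_likelihood(self, a29_ligands):
        peps = a29_ligands[:100]
        sol = mm.gibbs_cluster(peps, mm.GibbsParams(max_clusters=1), seed=1)
        from ligandscape.alphabet import encode_peptides
        from ligandscape.motif_models import (
            _cluster_scores,
            _counts_from_assign,
            uniform_background,
        )

        codes = encode_peptides(peps)
        assign = np.zeros(len(peps), dtype=int)
        counts, sizes = _counts_from_assign(codes, assign, 1)
        scores = _cluster_scores(codes, assign, counts, sizes, 20.0, uniform_background())
        assert sol.objective == pytest.approx(float(scores.sum()))
        assert set(sol.labels.tolist()) <= {0, -1}

    def test_same_master_seed_is_deterministic(self, disjoint_anchor_families):
        fam_a, fam_b = disjoint_anchor_families
        peps = synth.sample_ligands(fam_a, 100, 20) + synth.sample_ligands(
            fam_b, 100, 21
        )
        s1 = mm.gibbs_cluster(peps, mm.GibbsParams(), seed=9)
        s2 = mm.gibbs_cluster(peps, mm.GibbsParams(), seed=9)
        assert np.array_equal(s1.labels, s2.labels)
        assert s1.objective == s2.objective

    def test_single_motif_not_split(self, disjoint_anchor_families):
        fam_a, _ = disjoint_anchor_families
        peps = synth.sample_ligands(fam_a, 200, 30)
        sol = mm.gibbs_cluster(peps, mm.GibbsParams(), seed=2)
        sizes = [(sol.labels == c).sum() for c in range(3)]
        assert max(sizes) >= 0.9 * (sol.labels >= 0).sum()

    def test_final_sweep_never_decreases_objective(self, disjoint_anchor_families):
        fam_a, fam_b = disjoint_anchor_families
        peps = synth.sample_ligands(fam_a, 60, 40) + synth.sample_ligands(
            fam_b, 60, 41
        )
        sol = mm.gibbs_cluster(peps, mm.GibbsParams(seeds=2, iterations=20), seed=4)
        assert sol.trajectory[-1] >= sol.trajectory[-2] - 1e-9

    def test_too_few_peptides_rejected(self):
        with pytest.raises(ValueError, match="need >="):
            mm.gibbs_cluster(["AAAAAAAAA"] * 30, mm.GibbsParams(max_clusters=3))


class TestScanProteome:
    def test_consensus_kmer_found(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands, name="A29")
        consensus = mm.consensus_peptide(pssm)
        prot = ProteinRecord("prot1", "MMMM" + consensus + "GGGG")
        found = mm.scan_proteome([prot], pssm, [], k=9)
        assert consensus in set(found["peptide"])
        row = found[found["peptide"] == consensus].iloc[0]
        assert row["occurrences"] == [("prot1", 5)]

    def test_short_protein_yields_nothing(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands, name="A29")
        found = mm.scan_proteome([ProteinRecord("p", "MKY")], pssm, [], k=9)
        assert found.empty

    def test_self_as_other_model_excludes_everything(self, a29_ligands):
        pssm = mm.train_pssm(a29_ligands, name="A29")
        prot = ProteinRecord("p", "MMMM" + mm.consensus_peptide(pssm) + "GGGG")
        found = mm.scan_proteome([prot], pssm, [pssm], k=9)
        assert found.empty


class TestSerialization:
    def test_pssm_tsv_round_trip(self, a29_ligands, tmp_path):
        pssm = mm.train_pssm(a29_ligands, name="A29")
        mm.write_pssm(pssm, tmp_path / "p.tsv", tmp_path / "p.json")
        back = mm.read_pssm(tmp_path / "p.tsv", name="A29")
        assert np.allclose(back.log_odds, pssm.log_odds)
        assert back.length == pssm.length
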