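"""Self-validation measurements on synthetic experiments with known truth.

Each function runs a complete planted-truth simulation through the package
and returns the operating characteristic it measures (realized false
discovery, familywise error, recovery rates). These are the quantities a
user would check before trusting the pipeline on real data; they are also
what the repository's acceptance script reports.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ligandscape import diff_abundance as da
from ligandscape import enrichment as en
from ligandscape import motif_models as mm
from ligandscape import peptide_io, pipeline, synth


def realized_fdp(
    n_peptides: int = 5000,
    delta: float = 1.5,
    noise_sd: float = 0.4,
    n_replicates: int = 2,
    frac_sensitive: float = 0.1,
    frac_dependent: float = 0.1,
    q_threshold: float = 0.01,
    n_seeds: int = 20,
    seed: int = 0,
) -> float:
    """Mean realized false-discovery proportion at the q-value threshold.

    Runs ``n_seeds`` independent synthetic SILAC experiments, calls
    peptides at q < threshold, and averages the per-seed fraction of
    calls whose planted effect is zero (0 when nothing is called).
    """
    master = np.random.default_rng(seed)
    child = master.integers(0, 2**31 - 1, size=(n_seeds, 2))
    spec = synth.hla_a29_like()
    fdps = []
    for lig_seed, exp_seed in child:
        peps = synth.sample_ligands(spec, n_peptides, int(lig_seed))
        design = synth.EffectDesign(
            frac_sensitive=frac_sensitive,
            frac_dependent=frac_dependent,
            delta=delta,
            noise_sd=noise_sd,
            n_replicates=n_replicates,
            seed=int(exp_seed),
        )
        records, truth = synth.build_silac_experiment(peps, design)
        filtered, _ = peptide_io.apply_quality_filters(records)
        matrix = da.median_normalize(da.build_log_ratio_matrix(filtered))
        results, _ = da.moderate(matrix, q_threshold)
        merged = results.join(
            truth.drop_duplicates("peptide").set_index("peptide"), how="left"
        )
        calls = merged[merged["q"] < q_threshold]
        fdps.append(
            0.0 if calls.empty else float((calls["true_class"] == "unaffected").mean())
        )
    return float(np.mean(fdps))


def familywise_error_rate(
    n_per_group: int = 500,
    n_replicates: int = 200,
    position: int = 1,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Familywise type-I error of the Bonferroni-corrected positional
    Fisher procedure under the null (both groups from the same motif)."""
    master = np.random.default_rng(seed)
    child = master.integers(0, 2**31 - 1, size=(n_replicates, 2))
    spec = synth.hla_a29_like()
    flagged = 0
    for sa, sb in child:
        group_a = synth.sample_ligands(spec, n_per_group, int(sa))
        group_b = synth.sample_ligands(spec, n_per_group, int(sb))
        results = en.fisher_positional(group_a, group_b, position)
        if any(r.p_adj < alpha for r in results):
            flagged += 1
    return flagged / n_replicates


def submotif_recovery(
    n_seeds: int = 10,
    purity_threshold: float = 0.8,
    alpha: float = 0.05,
    seed: int = 0,
    outdir: Optional[str] = None,
) -> dict:
    """End-to-end planted-submotif recovery rate over seeded pipeline runs.

    A seed succeeds when, for each planted submotif, some DBSCAN cluster
    reaches the purity threshold AND the largest such cluster shows a
    Bonferroni-significant χ² class imbalance in the planted direction
    (P2-F/Y peptides are planted dependent, P7-L peptides sensitive).
    """
    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=n_seeds)
    wanted = {"P2FY": "dependent", "P7L": "sensitive"}
    successes, details = 0, []
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(outdir) if outdir else Path(tmp)
        for i, rs in enumerate(run_seeds):
            cfg, errors = pipeline.normalize_config(
                {
                    "seed": int(rs),
                    "outdir": str(base / f"seed{i}"),
                    "synthetic": {"mode": "submotif"},
                }
            )
            assert not errors
            pipeline.run_pipeline(cfg)
            emb = pd.read_csv(base / f"seed{i}" / "embedding.tsv", sep="\t")
            truth = (
                pd.read_csv(base / f"seed{i}" / "truth.tsv", sep="\t")
                .drop_duplicates("peptide")
                .set_index("peptide")
            )
            emb["sub"] = (
                truth.loc[emb["peptide"], "submotif"].fillna("").to_numpy()
            )
            n_clusters = int(emb["cluster"].max())
            ok = True
            record = {}
            for sub, direction in wanted.items():
                pure = []
                for c in range(1, n_clusters + 1):
                    members = emb[emb["cluster"] == c]
                    if len(members) == 0:
                        continue
                    purity = float((members["sub"] == sub).mean())
                    if purity >= purity_threshold:
                        pure.append((len(members), purity, c))
                if not pure:
                    ok = False
                    record[sub] = {"purity": 0.0}
                    continue
                size, purity, c = max(pure)
                try:
                    ce = en.cluster_class_chisq(
                        emb["cluster"], emb["class"], c, n_clusters
                    )
                except ValueError:
                    ok = False
                    record[sub] = {"purity": purity, "chisq": None}
                    continue
                (in_s, in_d), (out_s, out_d) = ce.table
                frac_in = {"sensitive": in_s, "dependent": in_d}[direction] / max(
                    1, in_s + in_d
                )
                frac_out = {"sensitive": out_s, "dependent": out_d}[direction] / max(
                    1, out_s + out_d
                )
                sig = ce.p_adj < alpha and frac_in > frac_out
                record[sub] = {"purity": purity, "p_adj": ce.p_adj, "correct": sig}
                ok = ok and sig
            successes += ok
            details.append(record)
    return {"rate": successes / n_seeds, "n_seeds": n_seeds, "details": details}


def deconvolution_ari(seed: int = 0, n_per_family: int = 200) -> float:
    """Adjusted Rand index of Gibbs deconvolution on two disjoint-anchor
    motif families (anchors at P2 and PΩ), over the assigned (non-trash)
    peptides."""
    from sklearn.metrics import adjusted_rand_score

    fam_a = synth.make_allele(
        "famA", 9, anchors={2: {"L": 0.5, "V": 0.5}, 9: {"Y": 0.5, "F": 0.5}}
    )
    fam_b = synth.make_allele(
        "famB", 9, anchors={2: {"S": 0.5, "T": 0.5}, 9: {"K": 0.5, "R": 0.5}}
    )
    master = np.random.default_rng(seed)
    s1, s2, s3 = master.integers(0, 2**31 - 1, size=3)
    peps = synth.sample_ligands(fam_a, n_per_family, int(s1)) + synth.sample_ligands(
        fam_b, n_per_family, int(s2)
    )
    truth = np.array([0] * n_per_family + [1] * n_per_family)
    sol = mm.gibbs_cluster(peps, mm.GibbsParams(), seed=int(s3))
    assigned = sol.labels >= 0
    return float(adjusted_rand_score(truth[assigned], sol.labels[assigned]))


def variance_prior_recovery(
    d0_true: float = 4.0,
    s0sq_true: float = 0.09,
    n_peptides: int = 5000,
    d: float = 1.0,
    seed: int = 0,
):
    """Recover (d0, s0²) from scaled-F sample variances drawn at truth."""
    rng = np.random.default_rng(seed)
    s2 = s0sq_true * rng.f(d, d0_true, size=n_peptides)
    return da.fit_variance_prior(s2, d)
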