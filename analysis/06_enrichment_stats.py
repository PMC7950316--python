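#!/usr/bin/env python
"""Positional and cluster-level enrichment statistics on the landscape.

Runs the full submotif pipeline (simulate → filter → moderate → landscape)
once, then: per-residue Fisher tests comparing sensitive and dependent
peptides against unaffected ones at the non-anchor positions, χ² tests of
class balance per DBSCAN cluster, and GRAVY hydrophobicity compared across
classes with Kruskal-Wallis/Dunn.
"""

from pathlib import Path

import pandas as pd

from ligandscape import enrichment as en
from ligandscape import pipeline

OUT = Path("results/analysis")
SEED = 20251006

cfg, errors = pipeline.normalize_config(
    {
        "seed": SEED,
        "outdir": str(OUT / "submotif_run"),
        "synthetic": {"mode": "submotif"},
        "anchor_positions": [9],  # PΩ is fixed; P2/P7 carry the planted signal
    }
)
assert not errors
summary = pipeline.run_pipeline(cfg)

enr = pd.read_csv(OUT / "submotif_run" / "positional_enrichment.tsv", sep="\t")
hits = enr[enr["p_adj"] < 0.05].sort_values("p_adj")
print("Bonferroni-significant positional residues (Padj < 0.05):")
for row in hits.itertuples():
    print(
        f"  {row.comparison} P{row.position} {row.residue}: "
        f"OR {row.odds_ratio:.2f}, Padj {row.p_adj:.2e}"
    )

clusters = pd.read_csv(OUT / "submotif_run" / "cluster_enrichment.tsv", sep="\t")
sig = clusters[clusters["p_adj"] < 0.05]
print(f"{len(sig)} of {len(clusters)} clusters with class imbalance at Padj < 0.05")

emb = pd.read_csv(OUT / "submotif_run" / "embedding.tsv", sep="\t")
groups = {
    cls: [en.gravy(p) for p in emb.loc[emb["class"] == cls, "peptide"]]
    for cls in ("sensitive", "dependent", "unaffected")
}
kw_p, pairs = en.kruskal_dunn(groups)
print(f"GRAVY across classes: Kruskal-Wallis p = {kw_p:.3g}")
for row in pairs.itertuples():
    print(f"  Dunn {row.group1} vs {row.group2}: z = {row.z:.2f}, Padj = {row.p_adj:.3g}")
pairs.to_csv(OUT / "gravy_dunn.tsv", sep="\t", index=False)
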