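"""Pipeline orchestration: one config drives all analysis stages.

Stage order: simulate/load → filter → differential abundance →
deconvolution → landscape → enrichment → proteome scan. Every stage
persists its inputs/outputs as plain TSV/JSON in the output directory so
any stage can be inspected, re-run or replaced. All stochastic stages
draw child seeds derived by hashing (master seed, stage name), so a
single master seed fully determines the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from ligandscape import diff_abundance, enrichment, landscape, motif_models, peptide_io, synth

logger = logging.getLogger("ligandscape")

_ALLELE_BUILDERS = {
    "a29": synth.hla_a29_like,
    "a03": synth.hla_a03_like,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "ligandscape_out"
    q_threshold: float = 0.01
    min_len: int = 8
    max_len: int = 11
    anchor_positions: list = field(default_factory=lambda: [2, 9])
    synthetic: Optional[dict] = None
    inputs: Optional[dict] = None
    gibbs: dict = field(default_factory=dict)
    landscape: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)


_SYNTH_DEFAULTS = {
    "mode": "motif",  # "motif" or "submotif"
    "allele": "a29",
    "n_peptides": 1000,
    "length": 9,
    "frac_sensitive": 0.1,
    "frac_dependent": 0.1,
    "n_submotif_a": 150,
    "n_submotif_b": 150,
    "n_background": 200,
    "delta": 1.5,
    "noise_sd": 0.4,
    "n_replicates": 2,
    "flag_rate": 0.05,
}

_GIBBS_DEFAULTS = {
    "max_clusters": 3,
    "seeds": 5,
    "lam": 0.7,
    "sigma": 5.0,
    "trash_threshold": 3.0,
    "iterations": 60,
}

_LANDSCAPE_DEFAULTS = {
    "n_restarts": 10,
    "max_iter": 500,
    "min_pts": None,
    "cluster_on": "embedding",
}

_SCAN_DEFAULTS = {"k": 9, "thr_target": 0.9, "thr_other": 0.6}


def normalize_config(raw: dict):
    """Fill defaults and collect validation errors (field, reason)."""
    errors = []
    if not isinstance(raw, dict):
        return None, [("config", "must be a mapping with at least one of "
                       "'synthetic' or 'inputs'")]
    known = {
        "seed", "outdir", "q_threshold", "min_len", "max_len",
        "anchor_positions", "synthetic", "inputs", "gibbs", "landscape", "scan",
    }
    for key in raw:
        if key not in known:
            errors.append((key, "unknown field"))
    has_synth = raw.get("synthetic") is not None
    has_inputs = raw.get("inputs") is not None
    if has_synth and has_inputs:
        errors.append(("synthetic/inputs", "exactly one of 'synthetic' and "
                       "'inputs' must be present, not both"))
    if not has_synth and not has_inputs:
        errors.append(("synthetic/inputs", "one of 'synthetic' or 'inputs' "
                       "is required"))
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        outdir=str(raw.get("outdir", "ligandscape_out")),
        q_threshold=float(raw.get("q_threshold", 0.01)),
        min_len=int(raw.get("min_len", 8)),
        max_len=int(raw.get("max_len", 11)),
        anchor_positions=list(raw.get("anchor_positions", [2, 9])),
        synthetic={**_SYNTH_DEFAULTS, **raw["synthetic"]} if has_synth else None,
        inputs=dict(raw["inputs"]) if has_inputs else None,
        gibbs={**_GIBBS_DEFAULTS, **raw.get("gibbs", {})},
        landscape={**_LANDSCAPE_DEFAULTS, **raw.get("landscape", {})},
        scan={**_SCAN_DEFAULTS, **raw.get("scan", {})},
    )
    if not 0 < cfg.q_threshold < 1:
        errors.append(("q_threshold", "must be in (0, 1)"))
    if cfg.min_len > cfg.max_len:
        errors.append(("min_len/max_len", "min_len must be <= max_len"))
    if has_synth:
        mode = cfg.synthetic["mode"]
        if mode not in ("motif", "submotif"):
            errors.append(("synthetic.mode", "must be 'motif' or 'submotif'"))
        if mode == "motif" and cfg.synthetic["allele"] not in _ALLELE_BUILDERS:
            errors.append(
                ("synthetic.allele", f"unknown allele preset {cfg.synthetic['allele']!r}")
            )
    if has_inputs and "quant_table" not in cfg.inputs:
        errors.append(("inputs.quant_table", "required for non-synthetic runs"))
    if not 0 <= cfg.gibbs["lam"] <= 1:
        errors.append(("gibbs.lam", "must be in [0, 1]"))
    return cfg, errors


def validate_config(path):
    """Load a YAML config, fill defaults, return (config, errors)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return None, [("config", "empty file; required: one of 'synthetic' "
                       "or 'inputs', plus 'seed' and 'outdir'")]
    return normalize_config(raw)


def simulate_stage(cfg: PipelineConfig, outdir: Path):
    s = cfg.synthetic
    seed = child_seed(cfg.seed, "simulate")
    if s["mode"] == "submotif":
        peptides, submotifs = synth.planted_submotif_ligands(
            n_submotif_a=s["n_submotif_a"],
            n_submotif_b=s["n_submotif_b"],
            n_background=s["n_background"],
            length=s["length"],
            seed=seed,
        )
        n = len(peptides)
        design = synth.EffectDesign(
            frac_sensitive=s["n_submotif_b"] / n,
            frac_dependent=s["n_submotif_a"] / n,
            delta=s["delta"],
            noise_sd=s["noise_sd"],
            n_replicates=s["n_replicates"],
            sensitive_rule=lambda p: p[6] == "L",
            dependent_rule=lambda p: p[1] in "FY",
            flag_rate=s["flag_rate"],
            seed=seed + 1,
        )
        allele_names = ["A29-like"] * n
    else:
        spec = _ALLELE_BUILDERS[s["allele"]](s["length"])
        peptides = synth.sample_ligands(spec, s["n_peptides"], seed)
        design = synth.EffectDesign(
            frac_sensitive=s["frac_sensitive"],
            frac_dependent=s["frac_dependent"],
            delta=s["delta"],
            noise_sd=s["noise_sd"],
            n_replicates=s["n_replicates"],
            flag_rate=s["flag_rate"],
            seed=seed + 1,
        )
        allele_names = [spec.name] * len(peptides)
        submotifs = None
    records, truth = synth.build_silac_experiment(
        peptides, design, allele_names=allele_names, submotif_ids=submotifs
    )
    synth.write_quant_table(records, outdir / "records.tsv")
    synth.write_truth(truth, outdir / "truth.tsv")
    return records, truth


def enrichment_stage(peps, cls_arr, labels, anchor_positions, outdir: Path) -> dict:
    """Positional Fisher tests (non-anchor positions, each class vs the
    unaffected group) and per-cluster χ² class-imbalance tests; persists
    both tables and returns the summary block."""
    length = len(peps[0]) if len(peps) else 0
    test_positions = [p for p in range(1, length + 1) if p not in anchor_positions]
    enr_rows = []
    for group in ("sensitive", "dependent"):
        ga = [p for p, c in zip(peps, cls_arr) if c == group]
        gb = [p for p, c in zip(peps, cls_arr) if c == "unaffected"]
        if not ga or not gb:
            continue
        for pos in test_positions:
            for res in enrichment.fisher_positional(ga, gb, pos):
                enr_rows.append(
                    {
                        "comparison": f"{group}_vs_unaffected",
                        "position": res.position,
                        "residue": res.residue,
                        "odds_ratio": res.odds_ratio,
                        "p": res.p,
                        "p_adj": res.p_adj,
                    }
                )
    enr = pd.DataFrame(
        enr_rows,
        columns=["comparison", "position", "residue", "odds_ratio", "p", "p_adj"],
    )
    enr.to_csv(outdir / "positional_enrichment.tsv", sep="\t", index=False)
    hits = enr[enr["p_adj"] < 0.05]

    labels = np.asarray(labels)
    cluster_rows = []
    n_clusters = int(labels.max()) if labels.size else 0
    for cid in range(1, n_clusters + 1):
        try:
            ce = enrichment.cluster_class_chisq(labels, cls_arr, cid, n_clusters)
        except ValueError:
            continue
        cluster_rows.append(
            {
                "cluster": ce.cluster,
                "sens_in": ce.table[0][0],
                "dep_in": ce.table[0][1],
                "sens_out": ce.table[1][0],
                "dep_out": ce.table[1][1],
                "chi2": ce.chi2,
                "p": ce.p,
                "p_adj": ce.p_adj,
            }
        )
    pd.DataFrame(
        cluster_rows,
        columns=["cluster", "sens_in", "dep_in", "sens_out", "dep_out", "chi2", "p", "p_adj"],
    ).to_csv(outdir / "cluster_enrichment.tsv", sep="\t", index=False)
    return {
        "n_positional_tests": int(len(enr)),
        "significant_positional": [
            f"{r.comparison}:P{r.position}:{r.residue}" for r in hits.itertuples()
        ],
        "significant_clusters": [
            r["cluster"] for r in cluster_rows if r["p_adj"] < 0.05
        ],
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and persists) the summary bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    # --- stage 1: simulate or load ------------------------------------
    stage = "simulate" if config.synthetic else "load"
    try:
        if config.synthetic:
            records, truth = simulate_stage(config, outdir)
        else:
            records = peptide_io.read_quant_table(config.inputs["quant_table"])
            truth = None
        summary["stages"][stage] = {"n_records": int(len(records))}
        logger.info("%s: %d records", stage, len(records))
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- stage 2: filter ----------------------------------------------
    try:
        filtered, report = peptide_io.apply_quality_filters(
            records, min_len=config.min_len, max_len=config.max_len
        )
        n_reps = filtered["replicate"].nunique()
        jaccard = {}
        if n_reps >= 2:
            _, jac = peptide_io.replicate_consensus(filtered)
            jaccard = {f"{a}|{b}": round(v, 6) for (a, b), v in jac.items()}
        peptide_io.write_quant_table(filtered, outdir / "filtered.tsv")
        peptide_io.write_filter_report(report, outdir / "filter_report.json")
        summary["stages"]["filter"] = {
            "n_in": int(len(records)),
            "n_kept": int(len(filtered)),
            "removed": report,
            "jaccard": jaccard,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'filter' failed: {exc}") from exc

    # --- stage 3: differential abundance ------------------------------
    try:
        matrix = diff_abundance.build_log_ratio_matrix(filtered)
        matrix = diff_abundance.median_normalize(matrix)
        results, mod_summary = diff_abundance.moderate(matrix, config.q_threshold)
        results.to_csv(outdir / "diffabund.tsv", sep="\t")
        summary["stages"]["diff_abundance"] = {
            "n_tested": mod_summary["n_tested"],
            "pi0": round(mod_summary["pi0"], 6),
            "d0": (
                mod_summary["d0"] if np.isinf(mod_summary["d0"])
                else round(mod_summary["d0"], 6)
            ),
            "s0sq": round(mod_summary["s0sq"], 6),
            "class_counts": mod_summary["class_counts"],
            "n_single_replicate": len(mod_summary["single_replicate_peptides"]),
            "n_single_channel": len(mod_summary["single_channel_peptides"]),
        }
        if np.isinf(summary["stages"]["diff_abundance"]["d0"]):
            summary["stages"]["diff_abundance"]["d0"] = "inf"
    except Exception as exc:
        raise RuntimeError(f"stage 'diff_abundance' failed: {exc}") from exc

    classes = results["class"]
    target_len = config.synthetic["length"] if config.synthetic else 9
    peps = [p for p in results.index if len(p) == target_len]

    # --- stage 4: deconvolution ---------------------------------------
    try:
        params = motif_models.GibbsParams(
            max_clusters=config.gibbs["max_clusters"],
            seeds=config.gibbs["seeds"],
            lam=config.gibbs["lam"],
            sigma=config.gibbs["sigma"],
            trash_threshold=config.gibbs["trash_threshold"],
            iterations=config.gibbs["iterations"],
        )
        solution = motif_models.gibbs_cluster(
            peps, params, seed=child_seed(config.seed, "deconvolute")
        )
        pd.DataFrame({"peptide": peps, "gibbs_cluster": solution.labels}).to_csv(
            outdir / "gibbs_clusters.tsv", sep="\t", index=False
        )
        sizes = {
            str(c): int((solution.labels == c).sum())
            for c in sorted(set(solution.labels.tolist()))
        }
        summary["stages"]["deconvolute"] = {
            "n_clusters": solution.n_clusters,
            "cluster_sizes": sizes,
            "objective": round(solution.objective, 4),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'deconvolute' failed: {exc}") from exc

    # --- stage 5: landscape -------------------------------------------
    try:
        scape = landscape.build_landscape(
            peps,
            seed=child_seed(config.seed, "landscape"),
            n_restarts=config.landscape["n_restarts"],
            max_iter=config.landscape["max_iter"],
            min_pts=config.landscape["min_pts"],
            cluster_on=config.landscape["cluster_on"],
        )
        emb = pd.DataFrame(
            {
                "peptide": peps,
                "x": scape.embedding.coords[:, 0],
                "y": scape.embedding.coords[:, 1],
                "cluster": scape.clustering.labels,
                "class": classes.loc[peps].to_numpy(),
            }
        )
        emb.to_csv(outdir / "embedding.tsv", sep="\t", index=False)
        n_clusters = int(scape.clustering.labels.max())
        summary["stages"]["landscape"] = {
            "n_peptides": len(peps),
            "stress": round(scape.embedding.stress, 6),
            "eps": round(scape.clustering.eps, 6),
            "min_pts": scape.clustering.min_pts,
            "n_clusters": n_clusters,
            "n_noise": int((scape.clustering.labels == 0).sum()),
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'landscape' failed: {exc}") from exc

    # --- stage 6: enrichment ------------------------------------------
    try:
        cls_arr = classes.loc[peps].to_numpy()
        summary["stages"]["enrichment"] = enrichment_stage(
            peps,
            cls_arr,
            scape.clustering.labels,
            config.anchor_positions,
            outdir,
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    # --- stage 7: proteome scan (only with a proteome + trained models)
    if config.inputs and config.inputs.get("fasta"):
        try:
            proteins = peptide_io.read_fasta(config.inputs["fasta"])
            training = config.inputs.get("training_sets", {})
            models = []
            for allele, path in sorted(training.items()):
                ligands = [
                    line.strip()
                    for line in Path(path).read_text().splitlines()
                    if line.strip()
                ]
                models.append(motif_models.train_pssm(ligands, name=allele))
            if models:
                target, others = models[0], models[1:]
                found = motif_models.scan_proteome(
                    proteins,
                    target,
                    others,
                    k=config.scan["k"],
                    thr_target=config.scan["thr_target"],
                    thr_other=config.scan["thr_other"],
                )
                found.to_csv(outdir / "proteome_scan.tsv", sep="\t", index=False)
                summary["stages"]["scan"] = {"n_candidates": int(len(found))}
        except Exception as exc:
            raise RuntimeError(f"stage 'scan' failed: {exc}") from exc

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
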