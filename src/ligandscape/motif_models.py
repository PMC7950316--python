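"""PSSM allele models, percentile binding scores, and motif deconvolution.

The allele model is a position-specific scoring matrix (PSSM) of log-odds
log2((c + β·b)/(n + β)/b) from residue counts c with pseudocount β against
a background b. Its binding score is a percentile rank in [0, 1] of the
peptide's summed log-odds within a fixed seeded population of background-
sampled reference peptides — a rank-scale surrogate for neural-network
presentation scores, carrying over the conventional thresholds (> 0.6
good, > 0.8 strong binder). It is a percentile, not a presentation
probability.

Deconvolution of mixed ligand sets uses annealed Gibbs sampling over
cluster assignments with leave-one-out PSSM likelihoods, an inter-cluster
similarity penalty λ, a geometric annealing schedule starting at
temperature σ, a zero-temperature greedy final sweep, and a trash
threshold of t bits on the per-peptide best cluster score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ligandscape.alphabet import AMINO_ACIDS, N_RESIDUES, encode_peptides

#: Seed of the shared background reference population used by percentile
#: scoring; fixed so that scores are reproducible across processes.
REFERENCE_SEED = 402908
REFERENCE_SIZE = 10_000


def uniform_background() -> np.ndarray:
    return np.full(N_RESIDUES, 1.0 / N_RESIDUES)


@dataclass
class PSSM:
    """Position-specific scoring matrix: (20, L) log-odds in bits."""

    name: str
    length: int
    log_odds: np.ndarray  # (20, L)
    background: np.ndarray  # (20,)
    _ref_sorted: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def reference_scores(self) -> np.ndarray:
        """Sorted summed log-odds of the seeded background population."""
        if self._ref_sorted is None:
            rng = np.random.default_rng(REFERENCE_SEED)
            codes = rng.choice(
                N_RESIDUES, size=(REFERENCE_SIZE, self.length), p=self.background
            )
            scores = self.log_odds[codes, np.arange(self.length)].sum(axis=1)
            self._ref_sorted = np.sort(scores)
        return self._ref_sorted


def train_pssm(
    peptides: Sequence[str],
    beta: float = 20.0,
    background: Optional[np.ndarray] = None,
    name: str = "",
) -> PSSM:
    """Train a PSSM from equal-length peptides.

    log-odds = log2((c + β·b)/(n + β)/b); β is the total pseudocount
    mass, distributed over residues by the background — the default of 20
    is one pseudocount per residue (Laplace) under a uniform background.
    Deterministic; requires at least 20 peptides.
    """
    if len(peptides) < 20:
        raise ValueError(f"need >= 20 training peptides, got {len(peptides)}")
    codes = encode_peptides(peptides)  # raises on mixed lengths
    n, length = codes.shape
    background = uniform_background() if background is None else np.asarray(background)
    counts = np.zeros((N_RESIDUES, length))
    for p in range(length):
        counts[:, p] = np.bincount(codes[:, p], minlength=N_RESIDUES)
    freq = (counts + beta * background[:, None]) / (n + beta)
    log_odds = np.log2(freq / background[:, None])
    return PSSM(name=name, length=length, log_odds=log_odds, background=background)


def raw_scores(pssm: PSSM, peptides: Sequence[str]) -> np.ndarray:
    """Summed log-odds of each peptide under the PSSM."""
    codes = encode_peptides(peptides)
    if codes.shape[1] != pssm.length:
        raise ValueError(
            f"peptide length {codes.shape[1]} does not match PSSM length "
            f"{pssm.length}"
        )
    return pssm.log_odds[codes, np.arange(pssm.length)].sum(axis=1)


def msi_like_scores(pssm: PSSM, peptides: Sequence[str]) -> np.ndarray:
    """Percentile-rank scores in [0, 1] for many peptides (mid-rank ties)."""
    scores = raw_scores(pssm, peptides)
    ref = pssm.reference_scores()
    lo = np.searchsorted(ref, scores, side="left")
    hi = np.searchsorted(ref, scores, side="right")
    return (lo + 0.5 * (hi - lo)) / ref.size


def msi_like_score(pssm: PSSM, peptide: str) -> float:
    """Percentile rank of one peptide's summed log-odds; 1.0 means above
    every reference peptide, 0.5 the mid-rank of an exact tie with all."""
    return float(msi_like_scores(pssm, [peptide])[0])


def consensus_peptide(pssm: PSSM) -> str:
    """The per-position argmax peptide of the PSSM."""
    return "".join(AMINO_ACIDS[i] for i in np.argmax(pssm.log_odds, axis=0))


def assign_best_allele(peptide: str, models: Sequence[PSSM]):
    """Best-scoring allele for a peptide; ties break lexicographically.

    Returns (allele_name, best_score, {allele: score}).
    """
    if not models:
        raise ValueError("need at least one allele model")
    scores = {m.name: msi_like_score(m, peptide) for m in models}
    best = sorted(scores, key=lambda a: (-scores[a], a))[0]
    return best, scores[best], scores


@dataclass
class GibbsParams:
    """Parameters of the annealed Gibbs deconvolution."""

    max_clusters: int = 3
    seeds: int = 5  # random restarts
    lam: float = 0.7  # inter-cluster score penalty
    sigma: float = 5.0  # initial annealing temperature
    trash_threshold: float = 3.0  # bits
    iterations: int = 60
    beta: float = 20.0

    def __post_init__(self):
        if self.max_clusters < 1:
            raise ValueError("max_clusters must be >= 1")
        if self.seeds < 1:
            raise ValueError("seeds must be >= 1")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if self.trash_threshold < 0:
            raise ValueError("trash threshold must be >= 0")


@dataclass
class GibbsSolution:
    """Result of one deconvolution: labels are 0..g−1, or −1 for trash."""

    labels: np.ndarray
    cluster_pssms: list
    objective: float
    trajectory: list
    n_clusters: int
    restart: int


def _cluster_scores(codes, assign, counts, sizes, beta, background):
    """(n, g) matrix of per-peptide log-odds under every cluster PSSM,
    leave-one-out for the peptide's own cluster."""
    n, length = codes.shape
    g = counts.shape[0]
    pos = np.arange(length)
    scores = np.empty((n, g))
    bg = background[:, None]
    for c in range(g):
        freq_in = (counts[c] + beta * bg) / (sizes[c] + beta)
        mat_in = np.log2(freq_in / bg)
        scores[:, c] = mat_in[codes, pos].sum(axis=1)
        members = np.flatnonzero(assign == c)
        if members.size:
            # leave-one-out: remove each member's own residues before scoring
            cnt = counts[c][codes[members], pos] - 1.0
            freq_loo = (cnt + beta * background[codes[members]]) / (sizes[c] - 1 + beta)
            loo = np.log2(freq_loo / background[codes[members]]).sum(axis=1)
            scores[members, c] = loo
    return scores


def _objective(scores, assign, lam):
    n, g = scores.shape
    own = scores[np.arange(n), assign]
    if g == 1:
        return float(own.sum())
    masked = scores.copy()
    masked[np.arange(n), assign] = -np.inf
    other_best = masked.max(axis=1)
    return float((own - lam * other_best).sum())


def _counts_from_assign(codes, assign, g):
    n, length = codes.shape
    counts = np.zeros((g, N_RESIDUES, length))
    for c in range(g):
        members = codes[assign == c]
        for p in range(length):
            counts[c, :, p] = np.bincount(members[:, p], minlength=N_RESIDUES)
    sizes = np.array([(assign == c).sum() for c in range(g)], dtype=float)
    return counts, sizes


def _move_scores(scores, lam):
    """Per-peptide, per-candidate-cluster move score: the candidate's
    log-odds minus λ times the best log-odds among the other clusters."""
    n, g = scores.shape
    if g == 1:
        return scores.copy()
    move = np.empty_like(scores)
    for c in range(g):
        others = np.delete(scores, c, axis=1).max(axis=1)
        move[:, c] = scores[:, c] - lam * others
    return move


def _greedy_sweep(codes, assign, g, beta, background, lam, start_obj):
    """One zero-temperature pass: accept single-peptide moves only when
    they do not decrease the global objective."""
    n = codes.shape[0]
    obj = start_obj
    for i in range(n):
        c_old = assign[i]
        best_move, best_obj = c_old, obj
        for c in range(g):
            if c == c_old:
                continue
            assign[i] = c
            counts_c, sizes_c = _counts_from_assign(codes, assign, g)
            sc = _cluster_scores(codes, assign, counts_c, sizes_c, beta, background)
            cand_obj = _objective(sc, assign, lam)
            if cand_obj > best_obj:
                best_move, best_obj = c, cand_obj
        assign[i] = best_move
        obj = best_obj
    return obj


def gibbs_cluster(
    peptides: Sequence[str],
    params: GibbsParams = GibbsParams(),
    seed: int = 0,
    background: Optional[np.ndarray] = None,
) -> GibbsSolution:
    """Deconvolute a mixed ligand set into up to g motif clusters.

    For every cluster number g' = 1..g, ``seeds`` annealed Gibbs restarts
    are run: each iteration rescores all peptides against the current
    cluster PSSMs (leave-one-out for the own cluster), forms the move
    score (candidate log-odds − λ · best log-odds under any other
    cluster) and resamples every assignment with probability
    ∝ exp(move/T), with T following a geometric schedule from σ down to
    0.1. Each restart ends with a zero-temperature greedy sweep that
    never decreases the objective. The overall solution is the best
    objective across all g' and restarts (ties prefer fewer clusters), so
    a single-motif set collapses to one cluster rather than splitting.
    Peptides whose best cluster log-odds is below the trash threshold
    (bits) are labelled −1. Fully reproducible under a fixed seed.
    """
    codes = encode_peptides(peptides)
    n, length = codes.shape
    g_max = params.max_clusters
    if n < g_max * 20:
        raise ValueError(f"need >= {g_max * 20} peptides for {g_max} clusters, got {n}")
    background = uniform_background() if background is None else np.asarray(background)
    beta = params.beta
    master = np.random.default_rng(seed)

    temps = params.sigma * (0.1 / params.sigma) ** (
        np.arange(params.iterations) / max(1, params.iterations - 1)
    )
    best = None
    for g in range(1, g_max + 1):
        restart_seeds = master.integers(0, 2**31 - 1, size=params.seeds)
        n_restarts = 1 if g == 1 else params.seeds  # g=1 is deterministic
        for restart, rs in enumerate(restart_seeds[:n_restarts]):
            rng = np.random.default_rng(rs)
            assign = rng.integers(0, g, size=n)
            trajectory = []
            if g > 1:
                for temp in temps:
                    counts, sizes = _counts_from_assign(codes, assign, g)
                    scores = _cluster_scores(codes, assign, counts, sizes, beta, background)
                    move = _move_scores(scores, params.lam)
                    gumbel = rng.gumbel(size=move.shape)
                    assign = np.argmax(move / temp + gumbel, axis=1)
                    counts, sizes = _counts_from_assign(codes, assign, g)
                    scores = _cluster_scores(codes, assign, counts, sizes, beta, background)
                    trajectory.append(_objective(scores, assign, params.lam))
            else:
                assign = np.zeros(n, dtype=int)
                counts, sizes = _counts_from_assign(codes, assign, g)
                scores = _cluster_scores(codes, assign, counts, sizes, beta, background)
                trajectory.append(_objective(scores, assign, params.lam))
            obj = _greedy_sweep(
                codes, assign, g, beta, background, params.lam, trajectory[-1]
            )
            trajectory.append(obj)
            if best is None or obj > best[0] + 1e-9:
                best = (obj, assign.copy(), trajectory, restart, g)

    obj, assign, trajectory, restart, g = best
    counts, sizes = _counts_from_assign(codes, assign, g)
    scores = _cluster_scores(codes, assign, counts, sizes, beta, background)
    best_bits = scores.max(axis=1)
    labels = assign.copy()
    labels[best_bits < params.trash_threshold] = -1

    peptide_list = list(peptides)
    cluster_pssms = []
    for c in range(g):
        members = [peptide_list[i] for i in np.flatnonzero(labels == c)]
        if len(members) >= 20:
            cluster_pssms.append(
                train_pssm(members, beta=beta, background=background, name=f"cluster{c + 1}")
            )
        else:
            cluster_pssms.append(None)
    n_clusters = int(np.sum([(labels == c).any() for c in range(g)]))
    return GibbsSolution(
        labels=labels,
        cluster_pssms=cluster_pssms,
        objective=obj,
        trajectory=trajectory,
        n_clusters=n_clusters,
        restart=restart,
    )


def scan_proteome(
    proteins,
    target_model: PSSM,
    other_models: Sequence[PSSM] = (),
    k: int = 9,
    thr_target: float = 0.9,
    thr_other: float = 0.6,
) -> pd.DataFrame:
    """Find k-mers restricted to the target allele's motif.

    Returns unique k-mers scoring above ``thr_target`` on the target model
    and below ``thr_other`` on *every* other model, with provenance
    (protein identifier, 1-based start) retained for all occurrences.
    """
    if target_model.length != k or any(m.length != k for m in other_models):
        raise ValueError("all models must have length k")
    valid = set(AMINO_ACIDS)
    occurrences: dict = {}
    for prot in proteins:
        seq = prot.sequence
        for start in range(len(seq) - k + 1):
            kmer = seq[start : start + k]
            if set(kmer) <= valid:
                occurrences.setdefault(kmer, []).append((prot.identifier, start + 1))
    if not occurrences:
        return pd.DataFrame(
            columns=["peptide", "target_score", "max_other_score", "occurrences"]
        )
    kmers = sorted(occurrences)
    tscores = msi_like_scores(target_model, kmers)
    keep = tscores > thr_target
    rows = []
    kept = [km for km, ok in zip(kmers, keep) if ok]
    if kept:
        other = np.zeros(len(kept))
        for m in other_models:
            other = np.maximum(other, msi_like_scores(m, kept))
        for km, ts, os_ in zip(kept, tscores[keep], other):
            if not other_models or os_ < thr_other:
                rows.append(
                    {
                        "peptide": km,
                        "target_score": float(ts),
                        "max_other_score": float(os_) if len(other_models) else np.nan,
                        "occurrences": occurrences[km],
                    }
                )
    return pd.DataFrame(rows, columns=["peptide", "target_score", "max_other_score", "occurrences"])


def write_pssm(pssm: PSSM, tsv_path, meta_path=None) -> None:
    """Serialize a PSSM as TSV (rows = residues, cols = positions 1..L)."""
    df = pd.DataFrame(
        pssm.log_odds,
        index=list(AMINO_ACIDS),
        columns=[f"P{i + 1}" for i in range(pssm.length)],
    )
    df.to_csv(tsv_path, sep="\t")
    if meta_path is not None:
        meta = {
            "name": pssm.name,
            "length": pssm.length,
            "background": [float(x) for x in pssm.background],
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def read_pssm(tsv_path, name: str = "", background: Optional[np.ndarray] = None) -> PSSM:
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    df = df.loc[list(AMINO_ACIDS)]
    bg = uniform_background() if background is None else np.asarray(background)
    return PSSM(
        name=name, length=df.shape[1], log_odds=df.to_numpy(dtype=float), background=bg
    )
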