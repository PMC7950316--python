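"""Positional enrichment statistics, hydrophobicity and logo matrices.

Per-position per-residue two-sided Fisher exact tests (Bonferroni over the
20 residues), Pearson χ² tests for the balance of peptidase-sensitive vs
-dependent peptides inside vs outside a submotif cluster (Bonferroni over
clusters), GRAVY hydrophobicity on the Kyte–Doolittle scale, Kruskal–
Wallis with Dunn's post-hoc comparisons, and information-content logo
matrices.

The Fisher p-value is computed by exact hypergeometric enumeration: the
sum of probabilities of all tables (with the observed margins) no more
likely than the observed one. Probabilities are compared with a relative
tie tolerance of 1e-9 — for table totals in the useful range, distinct
table probabilities share a common denominator and differ by far more
than that, so the tolerance only absorbs floating-point noise in exact
ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ligandscape.alphabet import AMINO_ACIDS, N_RESIDUES, encode_peptides
from ligandscape.landscape import LOG2_20, positional_entropy

#: Kyte–Doolittle hydropathy scale (published values); injectable where a
#: different scale is wanted.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

_TIE_RTOL = 1e-9


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    ``table`` is 2×2: [[a, b], [c, d]]. The p-value sums P(k) over all k
    in the support of Hypergeom(N=a+b+c+d, K=a+b, n=a+c) with
    P(k) ≤ P(a)·(1 + 1e-9).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0:
        return 1.0
    kmin = max(0, col1 - (c + d))
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


@dataclass
class EnrichmentResult:
    position: int  # 1-based
    residue: str
    table: tuple  # ((present_A, absent_A), (present_B, absent_B))
    odds_ratio: float
    p: float
    p_adj: float  # Bonferroni × 20, capped at 1


def positional_counts(peptides: Sequence[str]) -> np.ndarray:
    """(20, L) residue counts; column sums equal the group size."""
    codes = encode_peptides(peptides)
    n, length = codes.shape
    counts = np.zeros((N_RESIDUES, length), dtype=int)
    for p in range(length):
        counts[:, p] = np.bincount(codes[:, p], minlength=N_RESIDUES)
    return counts


def fisher_positional(
    group_a: Sequence[str],
    group_b: Sequence[str],
    position: int,
) -> list:
    """Per-residue 2×2 Fisher tests at one 1-based position.

    The table for residue r is [[#A with r, #A without r],
    [#B with r, #B without r]]. Odds ratios use a Haldane 0.5 correction
    when a cell is zero (display only; the p-value is exact). Bonferroni
    adjustment is ×20 residues, capped at 1.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ca = positional_counts(group_a)
    cb = positional_counts(group_b)
    if ca.shape[1] != cb.shape[1]:
        raise ValueError("groups must have equal peptide lengths")
    if not 1 <= position <= ca.shape[1]:
        raise ValueError(f"position {position} outside 1..{ca.shape[1]}")
    na, nb = len(group_a), len(group_b)
    col_a = ca[:, position - 1]
    col_b = cb[:, position - 1]
    out = []
    for i, residue in enumerate(AMINO_ACIDS):
        a, b = int(col_a[i]), na - int(col_a[i])
        c, d = int(col_b[i]), nb - int(col_b[i])
        p = fisher_exact_two_sided([[a, b], [c, d]])
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        out.append(
            EnrichmentResult(
                position=position,
                residue=residue,
                table=((a, b), (c, d)),
                odds_ratio=float(orr),
                p=p,
                p_adj=min(1.0, p * N_RESIDUES),
            )
        )
    return out


@dataclass
class ClusterEnrichment:
    cluster: int
    table: tuple  # ((sens_in, dep_in), (sens_out, dep_out))
    chi2: float
    p: float
    p_adj: float  # Bonferroni × n_clusters


def cluster_class_chisq(
    cluster_labels: Sequence[int],
    class_labels: Sequence[str],
    cluster_id: int,
    n_clusters: int,
    yates: bool = False,
) -> ClusterEnrichment:
    """Pearson χ² (df=1) on sensitive/dependent balance in vs out of a
    cluster; no continuity correction unless ``yates``. Bonferroni over
    ``n_clusters``. Degenerate margins (an all-zero row or column) raise.
    """
    cl = np.asarray(cluster_labels)
    cls = np.asarray(class_labels, dtype=object)
    keep = np.isin(cls, ("sensitive", "dependent"))
    cl, cls = cl[keep], cls[keep]
    inside = cl == cluster_id
    table = np.array(
        [
            [np.sum(inside & (cls == "sensitive")), np.sum(inside & (cls == "dependent"))],
            [np.sum(~inside & (cls == "sensitive")), np.sum(~inside & (cls == "dependent"))],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"degenerate margins for cluster {cluster_id}: {table.tolist()}")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
    return ClusterEnrichment(
        cluster=int(cluster_id),
        table=tuple(map(tuple, table.astype(int))),
        chi2=float(chi2),
        p=float(p),
        p_adj=min(1.0, float(p) * n_clusters),
    )


def gravy(peptide: str, scale: Optional[Dict[str, float]] = None) -> float:
    """Grand average of hydropathicity: mean Kyte–Doolittle value."""
    if not peptide:
        raise ValueError("empty peptide")
    scale = KYTE_DOOLITTLE if scale is None else scale
    try:
        return float(np.mean([scale[aa] for aa in peptide]))
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in hydropathy scale") from None


def kruskal_dunn(groups: Dict[str, Sequence[float]]):
    """Kruskal–Wallis across named groups plus Dunn's pairwise post-hoc.

    Dunn's z uses pooled mid-ranks with tie correction; pairwise p-values
    are two-sided normal, Bonferroni-adjusted over all pairs. Returns
    ``(kw_p, pairs)`` where pairs is a DataFrame (group1, group2, z, p,
    p_adj).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    try:
        kw_p = float(stats.kruskal(*arrays).pvalue)
    except ValueError:
        # all values identical in every group: no evidence of difference
        kw_p = 1.0
    pooled = np.concatenate(arrays)
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    # tie correction sum(t^3 - t) over tied groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks = {}
    start = 0
    for g, arr in zip(names, arrays):
        mean_ranks[g] = float(ranks[start : start + arr.size].mean())
        start += arr.size
    sizes = {g: arr.size for g, arr in zip(names, arrays)}
    pairs = list(combinations(names, 2))
    rows = []
    for g1, g2 in pairs:
        se = np.sqrt(var_factor * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "z": float(z),
                "p": float(p),
                "p_adj": min(1.0, float(p) * len(pairs)),
            }
        )
    return kw_p, pd.DataFrame(rows)


def logo_matrix(peptides: Sequence[str]) -> pd.DataFrame:
    """Residue-frequency × information-content matrix for logo plotting.

    IC_p = log2(20) − H_p (no small-sample correction); cell(r, p) =
    f_p(r) · IC_p. Rows are residues, columns positions P1..PL.
    """
    if len(peptides) < 2:
        raise ValueError("need >= 2 peptides")
    counts = positional_counts(peptides)
    freq = counts / len(peptides)
    ic = LOG2_20 - positional_entropy(peptides).entropies
    mat = freq * ic[None, :]
    return pd.DataFrame(
        mat,
        index=list(AMINO_ACIDS),
        columns=[f"P{i + 1}" for i in range(mat.shape[1])],
    )
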