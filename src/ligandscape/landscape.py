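"""Entropy-weighted peptide landscapes: distances, NMDS, density clustering.

A set of equal-length peptides is mapped to a pairwise dissimilarity
d(a, b) = Σ_p w_p · R[a_p, b_p], where R is a 20×20 residue dissimilarity
(by default 1 − min-max-normalized BLOSUM62 similarity, diagonal forced to
0) and w_p = 1 − H_p/log2(20) weights each position inversely to its
Shannon entropy — conserved (anchor-like) positions dominate the
geometry. The dissimilarities are embedded in 2-D by non-metric
multidimensional scaling (SMACOF with isotonic regression, Kruskal
stress-1, several random ordinations keeping the least-stress one), and
submotifs are extracted with DBSCAN, with eps chosen at the elbow of the
sorted k-nearest-neighbor distance curve.

Peptides of different lengths belong in separate landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN as _SkDBSCAN
from sklearn.neighbors import NearestNeighbors

from ligandscape.alphabet import AMINO_ACIDS, N_RESIDUES, encode_peptides

LOG2_20 = np.log2(20.0)


@dataclass
class PositionalProfile:
    length: int
    entropies: np.ndarray  # bits, per position
    weights: np.ndarray


@dataclass
class Embedding:
    coords: np.ndarray  # (n, 2)
    stress: float  # Kruskal stress-1 of the chosen ordination
    restart: int
    all_stresses: list
    trajectory: list  # stress per accepted iteration of the chosen ordination


@dataclass
class DensityClustering:
    labels: np.ndarray  # 0 = noise, 1..K = clusters
    eps: float
    min_pts: int
    knn_curve: Optional[np.ndarray] = field(default=None)


def positional_entropy(peptides: Sequence[str]) -> PositionalProfile:
    """Shannon entropy (bits) of observed residue frequencies per position."""
    if len(peptides) < 2:
        raise ValueError("need >= 2 peptides")
    codes = encode_peptides(peptides)
    n, length = codes.shape
    ent = np.empty(length)
    for p in range(length):
        freq = np.bincount(codes[:, p], minlength=N_RESIDUES) / n
        nz = freq[freq > 0]
        ent[p] = float(-(nz * np.log2(nz)).sum())
    return PositionalProfile(length=length, entropies=ent, weights=entropy_weights(ent))


def entropy_weights(entropies: np.ndarray) -> np.ndarray:
    """w_p = 1 − H_p/log2(20): bounded, 1 at full conservation, 0 at a
    uniform position."""
    entropies = np.asarray(entropies, dtype=float)
    return 1.0 - entropies / LOG2_20


_DEFAULT_R: Optional[np.ndarray] = None


def residue_distance_matrix() -> np.ndarray:
    """Default 20×20 residue dissimilarity in [0, 1] from BLOSUM62.

    Similarity is min-max normalized over the 20 canonical residues; the
    dissimilarity is 1 − normalized similarity with the diagonal forced
    to 0 (identity of indiscernibles).
    """
    global _DEFAULT_R
    if _DEFAULT_R is None:
        blosum = substitution_matrices.load("BLOSUM62")
        sub = np.array(
            [[blosum[a][b] for b in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
        )
        lo, hi = sub.min(), sub.max()
        dist = 1.0 - (sub - lo) / (hi - lo)
        np.fill_diagonal(dist, 0.0)
        _DEFAULT_R = (dist + dist.T) / 2.0
    return _DEFAULT_R


def peptide_distance(
    a: str,
    b: str,
    weights: np.ndarray,
    residue_matrix: Optional[np.ndarray] = None,
) -> float:
    """Entropy-weighted residue dissimilarity between two peptides."""
    if len(a) != len(b) or len(a) != len(weights):
        raise ValueError("peptides and weights must have matching lengths")
    R = residue_distance_matrix() if residue_matrix is None else residue_matrix
    codes = encode_peptides([a, b])
    return float(np.sum(np.asarray(weights) * R[codes[0], codes[1]]))


def pairwise_distances(
    peptides: Sequence[str],
    weights: Optional[np.ndarray] = None,
    residue_matrix: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Condensed entropy-weighted distance matrix over a peptide set.

    Weights default to the entropy weights of the set itself.
    """
    codes = encode_peptides(peptides)
    if weights is None:
        weights = positional_entropy(peptides).weights
    R = residue_distance_matrix() if residue_matrix is None else residue_matrix
    n, length = codes.shape
    sq = np.zeros((n, n))
    for p in range(length):
        sq += weights[p] * R[codes[:, p][:, None], codes[:, p][None, :]]
    np.fill_diagonal(sq, 0.0)
    return squareform((sq + sq.T) / 2.0, checks=False)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d**2))
    if denom == 0:
        return np.inf
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _nmds_single(delta: np.ndarray, n: int, dims: int, max_iter: int, tol: float, rng):
    order = np.argsort(delta, kind="mergesort")
    x = rng.normal(size=(n, dims))
    w_sum = float(n)
    rms_delta = float(np.sqrt(np.mean(delta**2)))
    best_stress = np.inf
    best_x = x.copy()
    trajectory = []
    for _ in range(max_iter):
        d = pdist(x)
        # stress-1 is scale-invariant; pin the configuration scale to the
        # data scale so coordinates stay numerically meaningful
        rms_d = float(np.sqrt(np.mean(d**2)))
        if rms_d > 0:
            scale = rms_delta / rms_d
            x *= scale
            d *= scale
        # monotone (isotonic) disparities in the rank order of delta
        dhat = np.empty_like(d)
        dhat[order] = isotonic_regression(d[order]).x
        # scale so that Σ dhat² = Σ d² (Kruskal's normalization)
        ssd = np.sum(d**2)
        ssdh = np.sum(dhat**2)
        if ssdh > 0:
            dhat *= np.sqrt(ssd / ssdh)
        stress = _stress1(d, dhat)
        if stress > best_stress:
            # descent safeguard: stress failed to improve — keep the best
            # configuration found so far and stop this ordination
            break
        trajectory.append(stress)
        improvement = best_stress - stress
        best_stress, best_x = stress, x.copy()
        if improvement < tol and len(trajectory) > 1:
            break
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = -squareform(ratio, checks=False)
        np.fill_diagonal(B, -B.sum(axis=1))
        x = B @ x / w_sum
    return best_x, best_stress, trajectory


def nmds(
    distances: np.ndarray,
    dims: int = 2,
    n_restarts: int = 10,
    max_iter: int = 500,
    seed: int = 0,
    tol: float = 1e-6,
) -> Embedding:
    """Non-metric MDS of a condensed distance matrix (Kruskal stress-1).

    Runs ``n_restarts`` independent random ordinations of up to
    ``max_iter`` SMACOF iterations each (isotonic disparities + Guttman
    transform) and returns the least-stress configuration. Each
    ordination stops early at convergence or if stress fails to decrease
    (descent safeguard), so the recorded stress trajectory is
    non-increasing. Deterministic under a fixed seed.
    """
    delta = np.asarray(distances, dtype=float)
    m = delta.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError("distances must be a condensed pairwise matrix")
    if n < 4:
        raise ValueError("need >= 4 points for an NMDS ordination")
    if np.all(delta == 0):
        raise ValueError("degenerate input: all distances are zero")
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=n_restarts)
    results = []
    for rs in seeds:
        rng = np.random.default_rng(rs)
        results.append(_nmds_single(delta, n, dims, max_iter, tol, rng))
    stresses = [r[1] for r in results]
    best = int(np.argmin(stresses))
    x, stress, trajectory = results[best]
    x = x - x.mean(axis=0)
    return Embedding(
        coords=x,
        stress=stress,
        restart=best,
        all_stresses=stresses,
        trajectory=trajectory,
    )


def default_min_pts(n: int) -> int:
    """minPts default: max(5, 1% of n)."""
    return max(5, int(round(0.01 * n)))


def _knee_from_curve(curve: np.ndarray, window=None) -> float:
    """eps at the maximum discrete curvature (second difference) of a
    sorted k-distance curve.

    With ``window=(lo, hi)`` (fractions of the curve length), the search
    is restricted to that index range of a lightly smoothed curve. This
    suits landscapes of discrete sequence data, whose curves have a
    duplicate-stack floor at the start and an outlier tail at the end
    that both carry spuriously large curvature.
    """
    n = len(curve)
    if n < 3:
        return float(curve[-1])
    if window is None:
        sm = curve
        lo, hi = 1, n - 1
    else:
        w = max(3, n // 100)
        sm = np.convolve(curve, np.ones(w) / w, mode="same") if n >= 20 else curve
        lo = max(1, int(n * window[0]))
        hi = min(n - 1, int(n * window[1]))
        if hi - lo < 3:
            lo, hi = 1, n - 1
    second_diff = sm[lo + 1 : hi + 1] - 2 * sm[lo:hi] + sm[lo - 1 : hi - 1]
    eps = float(curve[lo + int(np.argmax(second_diff))])
    if eps <= 0:
        eps = float(curve[curve > 0][0]) if np.any(curve > 0) else 1e-12
    return eps


def knee_eps(points: np.ndarray, min_pts: int, window=None):
    """eps at the elbow (max second difference) of the sorted k-distance
    curve, k = minPts. Returns (eps, curve) for inspection."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n <= min_pts:
        raise ValueError(f"need more than minPts={min_pts} points, got {n}")
    nn = NearestNeighbors(n_neighbors=min_pts + 1).fit(points)
    dist, _ = nn.kneighbors(points)
    curve = np.sort(dist[:, -1])
    return _knee_from_curve(curve, window), curve


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> DensityClustering:
    """Density-based clustering with the standard core/border/noise
    semantics; noise is labelled 0 and clusters 1..K in order of first
    appearance in the input."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 2:
        raise ValueError("minPts must be >= 2")
    raw = _SkDBSCAN(eps=eps, min_samples=min_pts).fit_predict(np.asarray(points, float))
    labels = np.zeros(raw.shape, dtype=int)
    mapping: dict = {}
    for i, lab in enumerate(raw):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[i] = mapping[lab]
    return DensityClustering(labels=labels, eps=float(eps), min_pts=int(min_pts))


@dataclass
class PeptideLandscape:
    peptides: list
    profile: PositionalProfile
    distances: np.ndarray  # condensed
    embedding: Embedding
    clustering: DensityClustering


def build_landscape(
    peptides: Sequence[str],
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    min_pts: Optional[int] = None,
    residue_matrix: Optional[np.ndarray] = None,
    cluster_on: str = "embedding",
    knee_window=(0.25, 0.95),
) -> PeptideLandscape:
    """Full landscape of one equal-length peptide set.

    ``cluster_on`` selects whether DBSCAN runs on the 2-D embedding
    (default, matching how submotif clusters are usually depicted) or on
    the raw distance matrix ("distances"). ``knee_window`` restricts the
    eps elbow search to the bulk of the k-distance curve (see
    :func:`_knee_from_curve`); pass None for the plain full-curve elbow.
    """
    peptides = list(peptides)
    profile = positional_entropy(peptides)
    dist = pairwise_distances(peptides, profile.weights, residue_matrix)
    emb = nmds(dist, n_restarts=n_restarts, max_iter=max_iter, seed=seed)
    k = default_min_pts(len(peptides)) if min_pts is None else min_pts
    if cluster_on == "embedding":
        eps, curve = knee_eps(emb.coords, k, window=knee_window)
        clust = dbscan(emb.coords, eps, k)
    elif cluster_on == "distances":
        sq = squareform(dist)
        kdist = np.sort(np.sort(sq, axis=1)[:, k])
        eps = _knee_from_curve(kdist, window=knee_window)
        raw = _SkDBSCAN(eps=max(eps, 1e-12), min_samples=k, metric="precomputed").fit_predict(sq)
        labels = np.zeros(raw.shape, dtype=int)
        mapping: dict = {}
        for i, lab in enumerate(raw):
            if lab != -1:
                if lab not in mapping:
                    mapping[lab] = len(mapping) + 1
                labels[i] = mapping[lab]
        clust = DensityClustering(labels=labels, eps=eps, min_pts=k)
        curve = kdist
    else:
        raise ValueError("cluster_on must be 'embedding' or 'distances'")
    clust.knn_curve = curve
    return PeptideLandscape(
        peptides=peptides,
        profile=profile,
        distances=dist,
        embedding=emb,
        clustering=clust,
    )
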