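"""Empirical-Bayes moderated differential abundance of SILAC log-ratios.

One-sample moderation of per-peptide log2(light/heavy) = log2(KO/WT)
replicate ratios: the per-peptide sample variance s² (d residual df) is
shrunk toward an empirical-Bayes prior (d0, s0²) estimated from all
peptides by the moments-on-log-variances method, giving the posterior
variance s̃² = (d0·s0² + d·s²)/(d0 + d) and a moderated t on d + d0 df.
False-discovery calibration uses Storey q-values with a smoothed π0
estimate; peptides with q below threshold are classified "sensitive"
(logFC > 0, destroyed by the peptidase — more abundant in KO) or
"dependent" (logFC < 0, generated by the peptidase).

Sign convention: logFC = log2(KO/WT) throughout, so a peptide normally
destroyed by the peptidase has a *positive* logFC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import interpolate, special, stats


@dataclass
class QuantMatrix:
    """Peptides × replicates matrix of log2(light/heavy) ratios.

    ``single_channel`` lists peptides seen in only one channel (no ratio
    anywhere), reported separately rather than analyzed.
    """

    data: pd.DataFrame
    offsets: dict = field(default_factory=dict)
    single_channel: list = field(default_factory=list)


def build_log_ratio_matrix(records: pd.DataFrame) -> QuantMatrix:
    """Pivot a record table into a log-ratio matrix.

    A cell is log2(light/heavy) where both channels are present, NaN
    otherwise; rows (peptides) need a complete pair in at least one
    replicate to enter the matrix. Raises on non-positive intensities.
    """
    heavy = records["heavy_intensity"].to_numpy(dtype=float)
    light = records["light_intensity"].to_numpy(dtype=float)
    if np.any(heavy[np.isfinite(heavy)] <= 0) or np.any(light[np.isfinite(light)] <= 0):
        raise ValueError("intensities must be positive where present")
    ratio = np.where(
        np.isfinite(heavy) & np.isfinite(light), np.log2(light / heavy), np.nan
    )
    tmp = records[["peptide", "replicate"]].copy()
    tmp["log_ratio"] = ratio
    mat = tmp.pivot_table(
        index="peptide",
        columns="replicate",
        values="log_ratio",
        aggfunc="mean",
        dropna=False,
    )
    has_ratio = mat.notna().any(axis=1)
    single = sorted(mat.index[~has_ratio])
    return QuantMatrix(data=mat.loc[has_ratio], single_channel=single)


def median_normalize(matrix: QuantMatrix) -> QuantMatrix:
    """Center each replicate column at median 0; offsets are recorded."""
    offsets = matrix.data.median(axis=0, skipna=True)
    data = matrix.data.sub(offsets, axis=1)
    return QuantMatrix(
        data=data,
        offsets={c: float(offsets[c]) for c in matrix.data.columns},
        single_channel=list(matrix.single_channel),
    )


def _trigamma(x):
    return special.polygamma(1, x)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = _trigamma(y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, d) -> Tuple[float, float]:
    """Estimate the variance prior (d0, s0²) from sample variances.

    Moments method on log variances: with z = log s², the excess of
    var(z) over trigamma(d/2) equals trigamma(d0/2), and the mean of z
    (bias-corrected) gives s0². Returns d0 = inf when sample variances are
    numerically constant (no excess dispersion).
    """
    s2 = np.asarray(s2, dtype=float)
    d = np.broadcast_to(np.asarray(d, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (d >= 1)
    if np.all(s2[ok] == 0):
        raise ValueError("all sample variances are zero: degenerate input")
    # guard against exact zeros from duplicate measurements
    s2 = np.where(s2[ok] > 0, s2[ok], np.min(s2[ok][s2[ok] > 0]) * 1e-3)
    d = d[ok]
    if s2.size < 10:
        warnings.warn(
            f"variance prior fitted on only {s2.size} peptides (< 10); "
            "estimates will be unstable",
            stacklevel=2,
        )
    if np.ptp(s2) < 1e-12 * np.max(s2):
        # numerically constant variances: no dispersion to shrink against
        return np.inf, float(s2[0])
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    evar = float(np.var(e, ddof=1))
    excess = evar - float(np.mean(_trigamma(d / 2.0)))
    if excess <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0sq


def moderated_test(mean_logfc, s2, d, d0: float, s0sq: float, n_eff):
    """Moderated one-sample t-test.

    s̃² = (d0·s0² + d·s²)/(d0 + d); t = mean / √(s̃²/n_eff); two-sided p
    on d + d0 df. d0 = 0 reduces to the ordinary t; d0 = inf to a pooled
    z-like statistic with variance s0².
    """
    mean_logfc = np.asarray(mean_logfc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    d = np.asarray(d, dtype=float)
    n_eff = np.asarray(n_eff, dtype=float)
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_tilde = (d0 * s0sq + d * s2) / (d0 + d)
        df_total = d + d0
    t = mean_logfc / np.sqrt(s2_tilde / n_eff)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return s2_tilde, t, df_total, p


def storey_qvalues(
    p: np.ndarray,
    pi0: Optional[float] = None,
    lambdas: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float]:
    """Storey q-values with smoothed π0 estimation.

    π0(λ) = #{p > λ}/(m(1−λ)) on the grid λ = 0.05..0.95 is smoothed with
    a cubic spline and evaluated at the largest λ, clamped to (0, 1];
    with fewer than 100 p-values π0 falls back to 1 (the Benjamini–
    Hochberg limit). q_i = π0 · min_{p_j ≥ p_i} m·p_j/rank_j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            pi0 = 1.0
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.951, 0.05)
            pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
            spline = interpolate.UnivariateSpline(lambdas, pi0_l, k=3)
            pi0 = float(spline(lambdas[-1]))
            pi0 = min(max(pi0, 1e-8), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def classify(q, mean_logfc, q_threshold: float = 0.01) -> np.ndarray:
    """Three-way call: q < threshold splits by the sign of log2(KO/WT)."""
    q = np.asarray(q, dtype=float)
    mean_logfc = np.asarray(mean_logfc, dtype=float)
    out = np.full(q.shape, "unaffected", dtype=object)
    out[(q < q_threshold) & (mean_logfc > 0)] = "sensitive"
    out[(q < q_threshold) & (mean_logfc < 0)] = "dependent"
    return out


def moderate(matrix: QuantMatrix, q_threshold: float = 0.01):
    """Full moderated analysis of a (normalized) log-ratio matrix.

    Peptides quantified in a single replicate (d = 0) cannot contribute a
    variance and are reported separately, not moderated. Returns
    ``(results, summary)``: a per-peptide DataFrame (mean_logFC, s2,
    s2_tilde, t, df, p, q, class) and a summary dict with π0, the prior,
    class counts, and the d = 0 peptide list.
    """
    data = matrix.data
    values = data.to_numpy(dtype=float)
    n_eff = np.isfinite(values).sum(axis=1)
    mean_lfc = np.nanmean(values, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s2 = np.nanvar(values, axis=1, ddof=1)
    d = n_eff - 1.0

    usable = d >= 1
    single_rep = sorted(data.index[~usable])
    if usable.sum() < 10:
        raise ValueError(
            f"only {int(usable.sum())} peptides with >= 2 replicate ratios; "
            "cannot fit a variance prior"
        )
    d0, s0sq = fit_variance_prior(s2[usable], d[usable])
    s2_tilde, t, df_total, p = moderated_test(
        mean_lfc[usable], s2[usable], d[usable], d0, s0sq, n_eff[usable]
    )
    q, pi0 = storey_qvalues(p)
    cls = classify(q, mean_lfc[usable], q_threshold)

    results = pd.DataFrame(
        {
            "peptide": data.index[usable],
            "mean_logFC": mean_lfc[usable],
            "s2": s2[usable],
            "s2_tilde": s2_tilde,
            "t": t,
            "df": df_total,
            "p": p,
            "q": q,
            "class": cls,
        }
    ).set_index("peptide")
    counts = results["class"].value_counts().to_dict()
    summary = {
        "n_tested": int(usable.sum()),
        "pi0": pi0,
        "d0": float(d0),
        "s0sq": s0sq,
        "q_threshold": q_threshold,
        "class_counts": {
            k: int(counts.get(k, 0)) for k in ("sensitive", "dependent", "unaffected")
        },
        "single_replicate_peptides": [str(x) for x in single_rep],
        "single_channel_peptides": [str(x) for x in matrix.single_channel],
    }
    return results, summary
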