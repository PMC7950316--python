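"""Synthetic peptidomes and SILAC experiments with planted ground truth.

Emulates the structure of a heavy/light (SILAC) immunopeptidome comparison
between aminopeptidase-proficient (WT, heavy) and -deficient (KO, light)
cells: allele-specific anchor motifs, within-allele submotifs, per-replicate
Gaussian log-ratio noise, planted "sensitive" (destroyed by the peptidase,
higher in KO) and "dependent" (generated by the peptidase, lower in KO)
peptide classes, missing channels and disqualifying quality flags.

The generator draws intensities on a log-normal scale so that only the
heavy/light *ratio* carries signal; absolute intensity is nuisance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ligandscape.alphabet import AMINO_ACIDS, AA_INDEX, N_RESIDUES, decode_peptides

#: Quality flags that disqualify a record from quantitative analysis.
DISQUALIFYING_FLAGS = (
    "InconsistentlyLabeled",
    "NoQuanValues",
    "Redundant",
    "IndistinguishableChannels",
)

BASE_INTENSITY = 1e6
LOGNORMAL_SD = 1.0


@dataclass(frozen=True)
class AlleleSpec:
    """Positional residue distribution of an HLA allele's ligand motif.

    ``position_weights`` is an (L, 20) row-stochastic matrix over the
    canonical alphabet; anchor positions carry concentrated rows,
    non-anchors near-uniform rows.
    """

    name: str
    length: int
    position_weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.position_weights, dtype=float)
        if not (8 <= self.length <= 11):
            raise ValueError(f"peptide length must be in [8, 11], got {self.length}")
        if w.shape != (self.length, N_RESIDUES):
            raise ValueError(
                f"position_weights must be ({self.length}, {N_RESIDUES}), "
                f"got {w.shape}"
            )
        if np.any(w < 0):
            raise ValueError("position weights must be non-negative")
        if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each positional weight vector must sum to 1")
        object.__setattr__(self, "position_weights", w)


def make_allele(
    name: str,
    length: int = 9,
    anchors: Optional[dict] = None,
) -> AlleleSpec:
    """Build an :class:`AlleleSpec` from anchor definitions.

    ``anchors`` maps 1-based positions to ``{residue: weight}`` dicts whose
    weights must sum to ≤ 1; remaining mass at an anchor, and all mass at
    non-anchor positions, is spread uniformly over the unnamed residues.
    """
    anchors = anchors or {}
    weights = np.full((length, N_RESIDUES), 1.0 / N_RESIDUES)
    for pos, residues in anchors.items():
        if not 1 <= pos <= length:
            raise ValueError(f"anchor position {pos} outside 1..{length}")
        row = np.zeros(N_RESIDUES)
        total = 0.0
        for aa, w in residues.items():
            if aa not in AA_INDEX:
                raise ValueError(f"invalid residue {aa!r} in anchor at P{pos}")
            row[AA_INDEX[aa]] = w
            total += w
        if total > 1.0 + 1e-9:
            raise ValueError(f"anchor weights at P{pos} sum to {total} > 1")
        rest = np.flatnonzero(row == 0)
        if rest.size:
            row[rest] = (1.0 - total) / rest.size
        weights[pos - 1] = row / row.sum()
    return AlleleSpec(name=name, length=length, position_weights=weights)


def hla_a29_like(length: int = 9) -> AlleleSpec:
    """A canonical PΩ-Y/F motif (aromatic C-terminal anchor) with a mild
    aromatic preference at P2 — the motif family of HLA-A*29:02 ligands."""
    return make_allele(
        "A29-like",
        length,
        anchors={2: {"F": 0.18, "Y": 0.18}, length: {"Y": 0.7, "F": 0.3}},
    )


def hla_a03_like(length: int = 9) -> AlleleSpec:
    """A canonical PΩ-K/R motif (basic C-terminal anchor), as for
    HLA-A*03:01 ligands."""
    return make_allele("A03-like", length, anchors={length: {"K": 0.5, "R": 0.5}})


def sample_ligands(spec: AlleleSpec, n: int, seed: int) -> list:
    """Draw ``n`` peptides position-independently from ``spec``.

    Reproducible under a fixed seed; positions are sampled independently
    from the spec's positional weight vectors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    codes = np.empty((n, spec.length), dtype=np.int64)
    for p in range(spec.length):
        codes[:, p] = rng.choice(N_RESIDUES, size=n, p=spec.position_weights[p])
    return decode_peptides(codes)


def _p1_in_akr(peptide: str) -> bool:
    return peptide[0] in "AKR"


def _p2_in_fy(peptide: str) -> bool:
    return peptide[1] in "FY"


@dataclass
class EffectDesign:
    """Design of a planted two-channel (heavy=WT, light=KO) experiment.

    ``delta`` is the planted |log2(KO/WT)| effect; sensitive peptides get
    +delta (enriched in KO because the peptidase normally destroys them),
    dependent peptides get −delta. Class eligibility is gated by sequence
    predicates so that planted effects co-occur with sequence features, as
    they do in real trimming data.
    """

    frac_sensitive: float = 0.1
    frac_dependent: float = 0.1
    delta: float = 1.5
    noise_sd: float = 0.4
    n_replicates: int = 2
    sensitive_rule: Callable[[str], bool] = field(default=_p1_in_akr)
    dependent_rule: Callable[[str], bool] = field(default=_p2_in_fy)
    flag_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.frac_sensitive < 0 or self.frac_dependent < 0:
            raise ValueError("class fractions must be non-negative")
        if self.frac_sensitive + self.frac_dependent > 1.0 + 1e-12:
            raise ValueError("frac_sensitive + frac_dependent must be <= 1")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 <= self.flag_rate <= 1.0:
            raise ValueError("flag_rate must be in [0, 1]")


def build_silac_experiment(
    peptides: Sequence[str],
    design: EffectDesign,
    allele_names: Optional[Sequence[str]] = None,
    submotif_ids: Optional[Sequence[Optional[str]]] = None,
):
    """Plant effects on ``peptides`` and emit a quantification table.

    Returns ``(records, truth)``: ``records`` is a long-format DataFrame
    with columns peptide / replicate / heavy_intensity / light_intensity /
    flags (semicolon-joined string), one row per peptide × replicate;
    ``truth`` has one row per peptide with the planted class, true
    log2(KO/WT), source allele and submotif id.

    Class counts are ``floor(frac * n)`` per class, remainder unaffected.
    A class is only planted on sequences satisfying its eligibility rule;
    a deficit of eligible sequences raises a ValueError naming the deficit.
    ``flag_rate`` of the records receive one random disqualifying flag;
    records flagged "NoQuanValues" get their light channel blanked.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("peptides must be non-empty")
    n = len(peptides)
    if allele_names is None:
        allele_names = ["synthetic"] * n
    if submotif_ids is None:
        submotif_ids = [None] * n

    rng = np.random.default_rng(design.seed)
    n_sens = math.floor(design.frac_sensitive * n)
    n_dep = math.floor(design.frac_dependent * n)

    eligible_s = [i for i, p in enumerate(peptides) if design.sensitive_rule(p)]
    if len(eligible_s) < n_sens:
        raise ValueError(
            f"not enough sensitive-eligible peptides: need {n_sens}, have "
            f"{len(eligible_s)} (deficit {n_sens - len(eligible_s)})"
        )
    rng.shuffle(eligible_s)
    sensitive = set(eligible_s[:n_sens])

    eligible_d = [
        i
        for i, p in enumerate(peptides)
        if design.dependent_rule(p) and i not in sensitive
    ]
    if len(eligible_d) < n_dep:
        raise ValueError(
            f"not enough dependent-eligible peptides: need {n_dep}, have "
            f"{len(eligible_d)} (deficit {n_dep - len(eligible_d)})"
        )
    rng.shuffle(eligible_d)
    dependent = set(eligible_d[:n_dep])

    classes = np.array(["unaffected"] * n, dtype=object)
    true_lfc = np.zeros(n)
    for i in sensitive:
        classes[i] = "sensitive"
        true_lfc[i] = design.delta
    for i in dependent:
        classes[i] = "dependent"
        true_lfc[i] = -design.delta

    rows = []
    for i, pep in enumerate(peptides):
        for r in range(1, design.n_replicates + 1):
            heavy = BASE_INTENSITY * math.exp(rng.normal(0.0, LOGNORMAL_SD))
            log_ratio = true_lfc[i] + rng.normal(0.0, design.noise_sd)
            light = heavy * 2.0 ** log_ratio
            flags = ""
            if rng.random() < design.flag_rate:
                flags = DISQUALIFYING_FLAGS[rng.integers(len(DISQUALIFYING_FLAGS))]
                if flags == "NoQuanValues":
                    light = np.nan
            rows.append((pep, f"R{r}", heavy, light, flags))

    records = pd.DataFrame(
        rows,
        columns=["peptide", "replicate", "heavy_intensity", "light_intensity", "flags"],
    )
    truth = pd.DataFrame(
        {
            "peptide": peptides,
            "source_allele": list(allele_names),
            "true_class": classes,
            "true_log2fc": true_lfc,
            "submotif": [s if s is not None else "" for s in submotif_ids],
        }
    )
    return records, truth


def planted_submotif_ligands(
    n_submotif_a: int = 150,
    n_submotif_b: int = 150,
    n_background: int = 200,
    length: int = 9,
    seed: int = 0,
):
    """Ligands of one PΩ-Y allele carrying two planted submotifs.

    Submotif "P2FY" fixes P2 ∈ {F, Y}; submotif "P7L" fixes P7 = L;
    background peptides avoid both features. Returns
    ``(peptides, submotif_ids)`` with ids in {"P2FY", "P7L", ""}.
    """
    if length < 8:
        raise ValueError("length must be >= 8 so that P7 exists")
    # base motif with concentrated preferences at the planted positions
    # (acidic P2, small P7) and a fixed PΩ-Y anchor; remaining positions
    # near-uniform so the planted features carry the entropy weight, as
    # anchor/submotif positions do in a real single-allele ligand set
    base = make_allele(
        "A29-like",
        length,
        anchors={
            2: {"E": 0.55, "D": 0.15},
            7: {"S": 0.35, "A": 0.2, "V": 0.15},
            length: {"Y": 1.0},
        },
    )
    rng = np.random.default_rng(seed)
    ss = rng.integers(0, 2**31 - 1, size=3)

    def resample(peps, pos, allowed, rs):
        # redraw one position from the base motif restricted to `allowed`
        r = np.random.default_rng(rs)
        idx = [AA_INDEX[aa] for aa in allowed]
        w = base.position_weights[pos - 1][idx]
        w = w / w.sum()
        out = []
        for p in peps:
            aa = allowed[r.choice(len(allowed), p=w)]
            out.append(p[: pos - 1] + aa + p[pos:])
        return out

    not_fy = [aa for aa in AMINO_ACIDS if aa not in "FY"]
    not_l = [aa for aa in AMINO_ACIDS if aa != "L"]

    pep_a = sample_ligands(base, n_submotif_a, int(ss[0]))
    pep_a = resample(pep_a, 2, ["F", "Y"], int(ss[0]) + 1)
    pep_a = resample(pep_a, 7, not_l, int(ss[0]) + 2)

    pep_b = sample_ligands(base, n_submotif_b, int(ss[1]))
    pep_b = resample(pep_b, 7, ["L"], int(ss[1]) + 1)
    pep_b = resample(pep_b, 2, not_fy, int(ss[1]) + 2)

    pep_bg = sample_ligands(base, n_background, int(ss[2]))
    pep_bg = resample(pep_bg, 2, not_fy, int(ss[2]) + 1)
    pep_bg = resample(pep_bg, 7, not_l, int(ss[2]) + 2)

    peptides = pep_a + pep_b + pep_bg
    ids = ["P2FY"] * n_submotif_a + ["P7L"] * n_submotif_b + [""] * n_background
    return peptides, ids


def write_quant_table(records: pd.DataFrame, path) -> None:
    """Write a quantification table as TSV (flags semicolon-joined)."""
    records.to_csv(path, sep="\t", index=False)


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the planted-truth sidecar as TSV."""
    truth.to_csv(path, sep="\t", index=False)
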