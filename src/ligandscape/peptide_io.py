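"""Reading, writing and filtering peptide quantification tables and FASTA.

The quantification table is the generic long-format TSV produced downstream
of an MS search engine: one row per peptide × replicate with heavy/light
intensities and a semicolon-joined quality-flag column. Flags such as
"Redundant" or "NoQuanValues" are treated as opaque disqualifying labels.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from ligandscape.synth import DISQUALIFYING_FLAGS

_VALID_PEPTIDE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
#: Default regex stripping bracketed modification annotations, e.g.
#: "M[Oxidation]" or "M(ox)".
DEFAULT_MOD_REGEX = r"\[[^\]]*\]|\([^)]*\)"

REQUIRED_COLUMNS = ("peptide", "replicate", "heavy_intensity", "light_intensity", "flags")


@dataclass(frozen=True)
class QuantRecord:
    """One quantified peptide observation in one replicate."""

    peptide: str
    replicate: str
    heavy_intensity: Optional[float]
    light_intensity: Optional[float]
    flags: frozenset


@dataclass(frozen=True)
class ProteinRecord:
    identifier: str
    sequence: str


def read_quant_table(path, mod_regex: str = DEFAULT_MOD_REGEX) -> pd.DataFrame:
    """Read a quantification TSV into a validated DataFrame.

    Peptides are uppercased and modification annotations matching
    ``mod_regex`` are stripped. Missing intensity cells become NaN (never
    zero). Raises ValueError naming the line for malformed residues and
    naming the column when a required column is absent.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "replicate": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    peptides = (
        df["peptide"].astype(str).str.replace(mod_regex, "", regex=True).str.upper()
    )
    for idx, pep in peptides.items():
        if not _VALID_PEPTIDE.match(pep):
            # +2: one for the header, one for 0-based indexing
            raise ValueError(
                f"{path}: invalid peptide {pep!r} at line {idx + 2}"
            )
    df = df.copy()
    df["peptide"] = peptides
    for col in ("heavy_intensity", "light_intensity"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df[col] <= 0
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise ValueError(f"{path}: non-positive {col} at line {line}")
    df["flags"] = df["flags"].fillna("").astype(str)
    return df


def record_flags(flag_cell: str) -> frozenset:
    """Parse a semicolon-joined flag cell into a set of flags."""
    return frozenset(f for f in str(flag_cell).split(";") if f)


def apply_quality_filters(
    records: pd.DataFrame,
    disqualifying_flags: Sequence[str] = DISQUALIFYING_FLAGS,
    min_len: int = 8,
    max_len: int = 11,
) -> Tuple[pd.DataFrame, dict]:
    """Drop flagged records and out-of-window peptide lengths.

    Returns the retained records and a report of counts removed per reason.
    A record matching several reasons is counted once, under the first
    matching flag in ``disqualifying_flags`` order; flag reasons take
    priority over the length reason.
    """
    report = {flag: 0 for flag in disqualifying_flags}
    report["length"] = 0
    keep = np.ones(len(records), dtype=bool)
    flag_sets = records["flags"].map(record_flags)
    lengths = records["peptide"].str.len()
    for i, (fs, ln) in enumerate(zip(flag_sets, lengths)):
        reason = next((f for f in disqualifying_flags if f in fs), None)
        if reason is not None:
            report[reason] += 1
            keep[i] = False
        elif not (min_len <= ln <= max_len):
            report["length"] += 1
            keep[i] = False
    report = {k: v for k, v in report.items() if v > 0}
    return records.loc[keep].reset_index(drop=True), report


def write_filter_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def replicate_consensus(records: pd.DataFrame):
    """Peptides present in every replicate, plus pairwise Jaccard overlap.

    Jaccard(A, B) = |A∩B| / |A∪B| over unique peptide sequences; charge
    states and modifications play no role (sequences are already
    normalized on read). Raises on a single replicate and advises the
    bypass (a single replicate has no overlap to compute).
    """
    sets = {
        rep: set(group["peptide"]) for rep, group in records.groupby("replicate")
    }
    if len(sets) < 2:
        raise ValueError(
            "replicate consensus needs >= 2 replicates; pass the records "
            "through unchanged (bypass) for single-replicate designs"
        )
    reps = sorted(sets)
    consensus = set.intersection(*sets.values())
    jaccard = {}
    for i, a in enumerate(reps):
        for b in reps[i + 1 :]:
            union = sets[a] | sets[b]
            jaccard[(a, b)] = len(sets[a] & sets[b]) / len(union) if union else 1.0
    return consensus, jaccard


def read_fasta(path) -> list:
    """Read a (multi-record) FASTA file into ProteinRecords, file order."""
    out = [
        ProteinRecord(identifier=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not out:
        raise ValueError(f"{path}: empty or unparseable FASTA")
    return out


def kmerize(protein, k: int):
    """All k-mers of a protein with 1-based inclusive start positions."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = protein.sequence if isinstance(protein, ProteinRecord) else str(protein)
    return [(seq[i : i + k], i + 1) for i in range(len(seq) - k + 1)]


def write_quant_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)
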