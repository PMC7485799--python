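"""Protein database handling.

FASTA I/O, in-silico endopeptidase digestion, N-terminal peptide indexing for
reference-based protein identification, and a synthetic proteome generator so
that the whole pipeline is testable without downloading a real database.
Protein identification rests on N-terminal peptides that occur in exactly one
protein of the reference; proteins whose N-terminal peptide is shared can
never be identified and are counted as failures downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import CANONICAL_RESIDUES

__all__ = [
    "ProteinRecord",
    "ReferenceIndex",
    "read_fasta",
    "write_fasta",
    "digest",
    "n_terminal_peptides",
    "uniqueness_under_clustering",
    "generate_synthetic_proteome",
]

logger = logging.getLogger(__name__)

#: Residues after which each enzyme cleaves the backbone.
CLEAVAGE_AFTER = {
    "trypsin": frozenset("KR"),
    "glu-c": frozenset("E"),
    "cnbr": frozenset("M"),
}

RESIDUE_ORDER = sorted(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty protein sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"noncanonical residues: {sorted(bad)}")


@dataclass(frozen=True)
class ReferenceIndex:
    """Digested peptide reference with the N-terminal uniqueness map.

    ``nterm`` maps protein id -> its N-terminal peptide (omitted when the
    peptide exceeded the length cutoff); ``unique_nterm`` maps each peptide
    occurring in exactly one protein back to that protein.
    """

    nterm: dict[str, str]
    unique_nterm: dict[str, str]
    enzyme: str = "trypsin"
    max_length: int | None = None

    @property
    def peptides(self) -> list[str]:
        return list(self.nterm.values())

    def peptides_of_length(self, length: int) -> list[str]:
        return sorted({p for p in self.nterm.values() if len(p) == length})

    def non_identifiable_proteins(self, all_ids: list[str] | None = None) -> set[str]:
        """Proteins whose N-terminal peptide is shared (or was discarded)."""
        ids = set(all_ids) if all_ids is not None else set(self.nterm)
        identifiable = set(self.unique_nterm.values())
        return ids - identifiable


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records, skipping (with a warning) any record containing
    noncanonical residue codes such as U, X, B or Z."""
    records: list[ProteinRecord] = []
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq or set(seq) - CANONICAL_RESIDUES:
            n_skipped += 1
            logger.warning("skipping record %s: noncanonical residues", rec.id)
            continue
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if n_skipped:
        logger.warning("skipped %d records with noncanonical residues", n_skipped)
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def digest(
    seq: str, enzyme: str = "trypsin", max_length: int | None = None
) -> list[str]:
    """Cleave a sequence after every site residue of the enzyme
    (trypsin: K/R; Glu-C: E; CNBr: M) and drop peptides longer than
    ``max_length`` when set."""
    try:
        sites = CLEAVAGE_AFTER[enzyme]
    except KeyError:
        raise ValueError(f"unknown enzyme: {enzyme!r}") from None
    peptides: list[str] = []
    start = 0
    for i, residue in enumerate(seq):
        if residue in sites:
            peptides.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    if max_length is not None:
        peptides = [p for p in peptides if len(p) <= max_length]
    return peptides


def n_terminal_peptides(
    db: list[ProteinRecord],
    enzyme: str = "trypsin",
    max_length: int | None = None,
) -> ReferenceIndex:
    """Index the first digestion product of every protein and mark which of
    those peptides identify their protein uniquely."""
    if not db:
        raise ValueError("empty protein database")
    nterm: dict[str, str] = {}
    counts: dict[str, int] = {}
    for rec in db:
        products = digest(rec.sequence, enzyme, max_length=None)
        peptide = products[0]
        if max_length is not None and len(peptide) > max_length:
            continue
        nterm[rec.id] = peptide
        counts[peptide] = counts.get(peptide, 0) + 1
    unique = {p: pid for pid, p in nterm.items() if counts[p] == 1}
    return ReferenceIndex(
        nterm=nterm, unique_nterm=unique, enzyme=enzyme, max_length=max_length
    )


def uniqueness_under_clustering(index: ReferenceIndex, clusters) -> int:
    """Number of proteins that cannot be identified when residues within a
    cluster are treated as indistinguishable.

    Each N-terminal peptide is mapped to its cluster-symbol string; proteins
    whose cluster-string is shared by two or more proteins are not
    identifiable.
    """
    symbol = {}
    for gi, group in enumerate(clusters.groups):
        for code in group:
            symbol[code] = gi
    counts: dict[tuple, int] = {}
    strings: dict[str, tuple] = {}
    for pid, peptide in index.nterm.items():
        s = tuple(symbol[c] for c in peptide)
        strings[pid] = s
        counts[s] = counts.get(s, 0) + 1
    return sum(1 for pid, s in strings.items() if counts[s] > 1)


def generate_synthetic_proteome(
    n_proteins: int,
    median_length: float = 350.0,
    sigma_log: float = 0.5,
    composition: dict[str, float] | None = None,
    rng_seed: np.random.Generator | int | None = None,
    min_length: int = 5,
) -> list[ProteinRecord]:
    """Generate i.i.d. random protein sequences emulating a reference
    database.

    Lengths are log-normal (median ``median_length``, log-sd ``sigma_log``,
    floored at ``min_length``); residues are drawn i.i.d. from ``composition``
    (a residue -> weight map, uniform over the 20 codes by default).
    Deterministic under a fixed seed.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not (median_length > 0) or sigma_log < 0:
        raise ValueError("degenerate length distribution")
    rng = np.random.default_rng(rng_seed)
    if composition is None:
        codes = RESIDUE_ORDER
        probs = np.full(len(codes), 1.0 / len(codes))
    else:
        codes = sorted(composition)
        if set(codes) - CANONICAL_RESIDUES:
            raise ValueError("composition contains noncanonical residues")
        weights = np.array([composition[c] for c in codes], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("degenerate composition")
        probs = weights / weights.sum()
    code_arr = np.array(list(codes))
    records = []
    width = max(4, len(str(n_proteins)))
    for i in range(n_proteins):
        if sigma_log == 0:
            length = int(round(median_length))
        else:
            length = int(round(np.exp(rng.normal(np.log(median_length), sigma_log))))
        length = max(length, min_length)
        seq = "".join(rng.choice(code_arr, size=length, p=probs))
        records.append(ProteinRecord(id=f"SYN{i + 1:0{width}d}", sequence=seq))
    return records
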