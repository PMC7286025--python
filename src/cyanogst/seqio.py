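"""Sequence records and file I/O (FASTA, order-metadata TSV, Newick, edge lists).

Order metadata travels in a sidecar TSV (``id<TAB>order``) rather than in
FASTA headers, so records exported from public databases pass through
unmodified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue alphabet accepted in records; X is the catch-all unknown
ALPHABET = frozenset(AMINO_ACIDS + "X")
#: taxonomic orders recognised for cyanobacteria in this analysis
ORDERS = (
    "Pleurocapsales",
    "Chroococcales",
    "Oscillatoriales",
    "Nostocales",
    "Stigonematales",
)
_AMBIGUOUS = set("BZJUO*")


class FastaParseError(ValueError):
    """Raised when a FASTA file is structurally malformed."""


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


def _clean_residues(raw: str, record_id: str) -> str:
    seq = raw.upper()
    cleaned = []
    for ch in seq:
        if ch in ALPHABET:
            cleaned.append(ch)
        elif ch in _AMBIGUOUS:
            warnings.warn(
                f"{record_id}: ambiguous residue code {ch!r} mapped to X",
                stacklevel=3,
            )
            cleaned.append("X")
        else:
            raise ValidationError(
                f"{record_id}: invalid residue {ch!r} (allowed: 20 amino acids + X)"
            )
    return "".join(cleaned)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its cyanobacterial order label."""

    id: str
    residues: str
    order_label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.residues:
            raise ValidationError(f"{self.id}: empty sequence")
        object.__setattr__(self, "residues", _clean_residues(self.residues, self.id))
        if self.order_label not in ORDERS and self.order_label != "unknown":
            raise ValidationError(
                f"{self.id}: unknown order label {self.order_label!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`ProteinRecord` with pairwise-distinct ids."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValidationError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, key: int | str) -> ProteinRecord:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def orders(self) -> dict[str, str]:
        """Map id -> order label."""
        return {rec.id: rec.order_label for rec in self.records}


def read_order_table(path: str | Path) -> dict[str, str]:
    """Read an ``id<TAB>order`` TSV (header row required)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValidationError(
                f"{path}: order table must start with header 'id\\torder'"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(f"{path}:{lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


def read_fasta(path: str | Path, metadata: str | Path | None = None) -> SequenceSet:
    """Read a protein FASTA, optionally joining order labels from a sidecar TSV.

    TSV ids absent from the FASTA produce a warning; FASTA ids absent from the
    TSV are labelled ``unknown``.
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected '>' header before sequence data"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")

    orders = read_order_table(metadata) if metadata is not None else {}
    records = []
    seen_ids = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaParseError(f"{path}: FASTA entry with empty id")
        records.append(
            ProteinRecord(
                id=entry.id,
                residues=str(entry.seq),
                order_label=orders.get(entry.id, "unknown"),
            )
        )
        seen_ids.add(entry.id)
    missing = sorted(set(orders) - seen_ids)
    if missing:
        warnings.warn(
            f"{len(missing)} order-table ids absent from FASTA: {missing[:5]}...",
            stacklevel=2,
        )
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA (60 columns)."""
    bio = [SeqRecord(Seq(rec.residues), id=rec.id, description="") for rec in seqs]
    SeqIO.write(bio, str(path), "fasta")


def write_order_table(seqs: SequenceSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id\torder\n")
        for rec in seqs:
            fh.write(f"{rec.id}\t{rec.order_label}\n")


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (``phylo.PhyloTree`` or dendropy ``Tree``) as Newick."""
    nwk = tree.newick() if hasattr(tree, "newick") else tree.as_string(schema="newick")
    with Path(path).open("w") as fh:
        fh.write(nwk.strip() + "\n")


def write_edgelist(network, path: str | Path) -> None:
    """Write a similarity network as a 3-column TSV (node, node, bit score)."""
    with Path(path).open("w") as fh:
        fh.write("source\ttarget\tbit_score\n")
        for a, b, bits in network.sorted_edges():
            fh.write(f"{a}\t{b}\t{bits:.4f}\n")
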