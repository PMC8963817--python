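"""Sequence and interaction-pair I/O.

Reads multi-record FASTA files for RNA and protein sequences and a
three-column tab-separated pair table (``rna_id<TAB>protein_id<TAB>label``),
producing the validated :class:`InteractionDataset` consumed by every
downstream stage.

Alphabet policy: input is normalized (uppercased; for RNA, ``T`` mapped to
``U`` so DNA-convention files are accepted), but residues outside the
canonical alphabets are *not* rejected here — they are flagged as ambiguous
and skipped later at tokenization.  I/O stays permissive, the feature layer
stays strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
#: the 20 standard one-letter amino-acid codes
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

KINDS = ("rna", "protein")


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA or protein sequence with a validated, normalized alphabet."""

    id: str
    residues: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    @property
    def alphabet(self) -> frozenset:
        return RNA_ALPHABET if self.kind == "rna" else PROTEIN_ALPHABET

    @property
    def ambiguous_positions(self) -> tuple:
        """0-based positions of residues outside the canonical alphabet."""
        alpha = self.alphabet
        return tuple(i for i, c in enumerate(self.residues) if c not in alpha)

    @property
    def n_ambiguous(self) -> int:
        return len(self.ambiguous_positions)

    def __len__(self) -> int:
        return len(self.residues)


def normalize_residues(residues: str, kind: str) -> str:
    residues = residues.upper()
    if kind == "rna":
        residues = residues.replace("T", "U")
    return residues


def read_fasta(path, kind: str) -> list:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased; for ``kind='rna'`` every ``T`` becomes ``U``.
    Duplicate identifiers and empty records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list = []
    seen: set = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = normalize_residues(str(rec.seq), kind)
        if not residues:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, residues=residues, kind=kind))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    n_amb = sum(1 for r in records if r.n_ambiguous)
    if n_amb:
        logger.warning("%d/%d %s records contain ambiguous residues", n_amb, len(records), kind)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    path = Path(path)
    bio = [_BioRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


@dataclass
class InteractionDataset:
    """RNA records, protein records and labelled (rna_id, protein_id) pairs."""

    rnas: dict
    proteins: dict
    pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rid, pid, label in self.pairs:
            if rid not in self.rnas:
                raise ValueError(f"pair references unknown rna id {rid!r}")
            if pid not in self.proteins:
                raise ValueError(f"pair references unknown protein id {pid!r}")
            if label not in (0, 1):
                raise ValueError(f"label for pair ({rid}, {pid}) must be 0 or 1, got {label!r}")
            key = (rid, pid)
            if key in seen:
                raise ValueError(f"duplicate pair ({rid}, {pid})")
            seen.add(key)

    @classmethod
    def from_records(cls, rnas: Sequence[SequenceRecord], proteins: Sequence[SequenceRecord], pairs) -> "InteractionDataset":
        return cls(rnas={r.id: r for r in rnas}, proteins={p.id: p for p in proteins}, pairs=list(pairs))

    @property
    def labels(self) -> list:
        return [label for _, _, label in self.pairs]

    @property
    def n_positive(self) -> int:
        return sum(self.labels)

    @property
    def n_negative(self) -> int:
        return len(self.pairs) - self.n_positive

    def __len__(self) -> int:
        return len(self.pairs)


def read_pairs(path, rnas: Sequence[SequenceRecord], proteins: Sequence[SequenceRecord],
               skip_header: bool = False) -> InteractionDataset:
    """Parse a tab-separated ``rna_id, protein_id, label`` table.

    Parsing is order-preserving; every id must resolve against the supplied
    records and labels must be 0/1.  ``skip_header`` drops the first line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pair table not found: {path}")
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if skip_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}")
            rid, pid, raw = (f.strip() for f in fields)
            if raw not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {raw!r}")
            pairs.append((rid, pid, int(raw)))
    ds = InteractionDataset.from_records(rnas, proteins, pairs)
    logger.info("read %d pairs (%d positive, %d negative) from %s",
                len(ds), ds.n_positive, ds.n_negative, path)
    return ds


def write_pairs(dataset: InteractionDataset, path) -> None:
    with open(path, "w") as fh:
        for rid, pid, label in dataset.pairs:
            fh.write(f"{rid}\t{pid}\t{label}\n")
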