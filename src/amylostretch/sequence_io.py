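"""Protein sequence and label I/O, and fixed-length residue window extraction.

Sequences live on the 21-symbol alphabet: the 20 canonical one-letter amino
acid codes plus ``X`` for unknown/padding. All residue coordinates exposed by
this package are 1-based and inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical 20 amino acids, in the fixed internal order used for all tables.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Unknown / terminal-padding symbol.
UNKNOWN = "X"
#: Full 21-symbol alphabet.
ALPHABET = AMINO_ACIDS + UNKNOWN
#: Symbol -> integer code (0..20, X = 20).
AA_CODE = {a: i for i, a in enumerate(ALPHABET)}


def normalize_sequence(sequence: str) -> str:
    """Uppercase a raw sequence and map non-alphabet characters to ``X``.

    A single warning is logged per sequence listing the replaced characters.
    """
    seq = sequence.upper()
    bad = sorted({c for c in seq if c not in AA_CODE})
    if bad:
        logger.warning(
            "replacing %d non-standard symbol(s) %s with '%s'",
            sum(seq.count(c) for c in bad), "".join(bad), UNKNOWN,
        )
        seq = "".join(c if c in AA_CODE else UNKNOWN for c in seq)
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with optional per-residue binary labels.

    ``labels[i] == 1`` marks residue ``i+1`` (1-based) as an experimentally
    verified fibril-forming site.
    """

    id: str
    sequence: str
    labels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = {c for c in self.sequence if c not in AA_CODE}
        if bad:
            raise ValueError(
                f"record {self.id!r}: symbols {sorted(bad)} outside alphabet "
                f"(normalize with normalize_sequence first)"
            )
        if self.labels is not None:
            if len(self.labels) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: {len(self.labels)} labels for "
                    f"{len(self.sequence)} residues"
                )
            if not set(self.labels) <= {0, 1}:
                raise ValueError(f"record {self.id!r}: labels must be 0/1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueWindow:
    """A ``2*flank_j + 1`` segment centered on one residue of a protein.

    Positions beyond either terminus are padded with ``X`` so that every
    residue of the protein owns exactly one window. ``center`` is 1-based.
    """

    protein_id: str
    center: int
    flank_j: int
    segment: str
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.segment) != 2 * self.flank_j + 1:
            raise ValueError(
                f"segment length {len(self.segment)} != 2*{self.flank_j}+1"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased; characters outside the 21-symbol alphabet are
    replaced by ``X`` with a logged warning. An empty file yields an empty
    list with a warning.
    """
    path = Path(path)
    records = [
        ProteinRecord(id=rec.id, sequence=normalize_sequence(str(rec.seq)))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        logger.warning("no FASTA entries found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> Path:
    """Write records as FASTA (60-column wrapping)."""
    path = Path(path)
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")
    return path


def read_labels(path: str | Path) -> dict[str, set[int]]:
    """Read a two-column TSV ``protein_id <TAB> 1-based-position`` of positives.

    All unlisted residues of listed proteins are negatives; proteins absent
    from the file remain unlabeled. A row with position ``0`` lists a protein
    that has no positive site at all (every residue negative).
    """
    positives: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pid, pos_s = parts
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad position {pos_s!r}") from exc
            if pos < 0:
                raise ValueError(f"{path}:{lineno}: position must be >= 0")
            positives.setdefault(pid, set())
            if pos > 0:
                positives[pid].add(pos)
    return positives


def write_labels(records: Iterable[ProteinRecord], path: str | Path) -> Path:
    """Write the positive positions of labeled records as a two-column TSV.

    A labeled record with no positive site is listed as ``<id>\\t0`` so it
    round-trips as all-negative rather than unlabeled.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            if rec.labels is None:
                continue
            if not any(rec.labels):
                fh.write(f"{rec.id}\t0\n")
                continue
            for pos, lab in enumerate(rec.labels, 1):
                if lab:
                    fh.write(f"{rec.id}\t{pos}\n")
    return path


def label_records(
    records: Iterable[ProteinRecord], positives: Mapping[str, set[int]]
) -> list[ProteinRecord]:
    """Attach 0/1 label vectors to the records listed in ``positives``.

    Raises if a listed position exceeds its protein's length. Records not
    listed are returned unchanged (labels stay ``None``).
    """
    out = []
    for rec in records:
        if rec.id in positives:
            pos = positives[rec.id]
            over = [p for p in pos if p > len(rec)]
            if over:
                raise ValueError(
                    f"record {rec.id!r}: positions {sorted(over)} beyond length {len(rec)}"
                )
            labels = tuple(1 if (i + 1) in pos else 0 for i in range(len(rec)))
            out.append(ProteinRecord(rec.id, rec.sequence, labels))
        else:
            out.append(rec)
    return out


def extract_windows(record: ProteinRecord, flank_j: int) -> list[ResidueWindow]:
    """Extract one centered ``2*flank_j+1`` window per residue of ``record``.

    Terminal positions are padded with ``X`` (never truncated), so the number
    of windows always equals the sequence length. Labels are copied from the
    center residue.
    """
    if flank_j < 0:
        raise ValueError("flank_j must be >= 0")
    pad = UNKNOWN * flank_j
    padded = pad + record.sequence + pad
    width = 2 * flank_j + 1
    return [
        ResidueWindow(
            protein_id=record.id,
            center=i + 1,
            flank_j=flank_j,
            segment=padded[i : i + width],
            label=None if record.labels is None else record.labels[i],
        )
        for i in range(len(record))
    ]


def write_windows_tsv(windows: Iterable[ResidueWindow], path: str | Path) -> Path:
    """Debug dump: TSV with columns protein_id, center, segment, label."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("protein_id\tcenter\tsegment\tlabel\n")
        for w in windows:
            lab = "" if w.label is None else str(w.label)
            fh.write(f"{w.protein_id}\t{w.center}\t{w.segment}\t{lab}\n")
    return path
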