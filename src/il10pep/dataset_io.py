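"""Reading, validation and bookkeeping of labelled peptide datasets.

Datasets are pairs of peptide lists — positives (IL-10 inducing) and
negatives (non-inducing MHC II binders, or MHC II non-binders for the
alternate dataset). Input formats are FASTA and plain one-sequence-per-line
text (optionally ``id<TAB>sequence``); outputs are FASTA and TSV.

All sequences are validated against the 20 canonical one-letter amino-acid
codes and a minimum length of 8 residues, and deduplicated within each
class. Duplicates shared across classes carry contradictory labels; they
are reported as a warning by default and rejected in strict mode.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical residues in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Shortest peptide accepted anywhere in the toolkit.
MIN_PEPTIDE_LENGTH = 8


class PeptideError(ValueError):
    """Base class for peptide validation failures."""


class AlphabetError(PeptideError):
    """Sequence contains characters outside the 20 canonical codes."""


class LengthError(PeptideError):
    """Sequence is shorter than the required minimum."""


class ParseError(ValueError):
    """Input file is not in the expected format."""


def clean_sequence(raw: str) -> str:
    """Strip whitespace and digits (common in hand-edited files) and uppercase."""
    return "".join(ch for ch in raw if not ch.isspace() and not ch.isdigit()).upper()


def validate_peptide(seq: str, min_len: int = MIN_PEPTIDE_LENGTH) -> str:
    """Return the uppercased sequence iff alphabet-valid and long enough.

    Raises
    ------
    AlphabetError
        If any character is not one of the 20 canonical one-letter codes.
    LengthError
        If the sequence is shorter than ``min_len`` residues.
    """
    s = seq.strip().upper()
    bad = sorted(set(s) - _AA_SET)
    if bad:
        raise AlphabetError(
            f"non-canonical residue(s) {','.join(bad)} in sequence {s!r}"
        )
    if len(s) < min_len:
        raise LengthError(
            f"sequence {s!r} has {len(s)} residues; minimum is {min_len}"
        )
    return s


@dataclass
class Peptide:
    """A validated amino-acid sequence with an identifier and optional label."""

    id: str
    sequence: str
    label: Optional[str] = None  # "positive" | "negative" | None

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: Union[str, Path], min_len: int = MIN_PEPTIDE_LENGTH) -> list[Peptide]:
    """Read peptides from a FASTA file.

    Whitespace and digits inside sequence lines are stripped before
    validation; lowercase input is uppercased. Ids come from the headers.
    """
    path = Path(path)
    text = path.read_text()
    first = next((ln for ln in text.splitlines() if ln.strip()), None)
    if first is None:
        raise ParseError(f"{path}: file is empty")
    if not first.startswith(">"):
        raise ParseError(f"{path}: not FASTA — first non-blank line {first!r} lacks '>'")
    peptides = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = clean_sequence(str(record.seq))
        if not seq:
            raise ParseError(f"{path}: record {record.id!r} has an empty sequence")
        peptides.append(Peptide(id=record.id, sequence=validate_peptide(seq, min_len)))
    if not peptides:
        raise ParseError(f"{path}: no FASTA records found")
    return peptides


def read_plain(path: Union[str, Path], min_len: int = MIN_PEPTIDE_LENGTH) -> list[Peptide]:
    """Read peptides from one-sequence-per-line text (optional ``id<TAB>seq``)."""
    path = Path(path)
    peptides = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if "\t" in line:
            pid, seq = line.split("\t", 1)
        else:
            pid, seq = f"seq{i}", line
        seq = clean_sequence(seq)
        try:
            peptides.append(Peptide(id=pid.strip(), sequence=validate_peptide(seq, min_len)))
        except PeptideError as exc:
            raise type(exc)(f"{path} line {i}: {exc}") from exc
    if not peptides:
        raise ParseError(f"{path}: no sequences found")
    return peptides


def read_peptides(path: Union[str, Path], min_len: int = MIN_PEPTIDE_LENGTH) -> list[Peptide]:
    """Read peptides, sniffing FASTA vs plain-list format from the first line."""
    path = Path(path)
    first = next((ln for ln in path.read_text().splitlines() if ln.strip()), "")
    if first.startswith(">"):
        return read_fasta(path, min_len)
    return read_plain(path, min_len)


def write_fasta(peptides: Sequence[Peptide], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in peptides:
            fh.write(f">{p.id}\n{p.sequence}\n")


def deduplicate(peptides: Sequence[Peptide]) -> list[Peptide]:
    """Keep the first occurrence of each distinct sequence, preserving order."""
    seen: set[str] = set()
    kept = []
    for p in peptides:
        if p.sequence not in seen:
            seen.add(p.sequence)
            kept.append(p)
    removed = len(peptides) - len(kept)
    if removed:
        logger.info("deduplicate: removed %d duplicate sequence(s)", removed)
    return kept


@dataclass
class PeptideDataset:
    """A labelled two-class peptide dataset (positives vs negatives)."""

    positives: list[Peptide] = field(default_factory=list)
    negatives: list[Peptide] = field(default_factory=list)
    name: str = "dataset"

    @classmethod
    def from_files(
        cls,
        pos_path: Union[str, Path],
        neg_path: Union[str, Path],
        name: str = "dataset",
        min_len: int = MIN_PEPTIDE_LENGTH,
        strict: bool = False,
    ) -> "PeptideDataset":
        """Load, label and deduplicate a dataset from two peptide files.

        Cross-class duplicates (identical sequence in both files) are kept
        but reported with a warning; with ``strict=True`` they raise.
        """
        pos = deduplicate(read_peptides(pos_path, min_len))
        neg = deduplicate(read_peptides(neg_path, min_len))
        for p in pos:
            p.label = "positive"
        for p in neg:
            p.label = "negative"
        shared = sorted({p.sequence for p in pos} & {p.sequence for p in neg})
        if shared:
            msg = (
                f"{len(shared)} sequence(s) appear in both classes "
                f"(contradictory labels): {', '.join(shared[:10])}"
            )
            if strict:
                raise PeptideError(msg)
            warnings.warn(msg, stacklevel=2)
        return cls(positives=pos, negatives=neg, name=name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": p.id, "sequence": p.sequence, "label": lbl}
            for lst, lbl in ((self.positives, "positive"), (self.negatives, "negative"))
            for p in lst
        ]
        return pd.DataFrame(rows, columns=["id", "sequence", "label"])


def dataset_summary(ds: PeptideDataset) -> dict:
    """Counts and per-class length extrema, recomputed from the contents."""
    if not ds.positives or not ds.negatives:
        raise ValueError("dataset_summary requires both classes to be non-empty")
    pos_lens = [len(p) for p in ds.positives]
    neg_lens = [len(p) for p in ds.negatives]
    return {
        "n_pos": len(ds.positives),
        "n_neg": len(ds.negatives),
        "min_len_pos": min(pos_lens),
        "max_len_pos": max(pos_lens),
        "min_len_neg": min(neg_lens),
        "max_len_neg": max(neg_lens),
    }
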