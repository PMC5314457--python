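"""Fixed-length numeric encodings of peptides.

Implemented encodings
---------------------
AAC
    Amino-acid composition: 20 values, percent of each residue,
    ``AAC(i) = 100 * R(i) / N`` with R(i) the count of residue type i and
    N the peptide length.
DPC
    Dipeptide composition: 400 values, percent of each overlapping residue
    pair, ``DPC(i) = 100 * D(i) / (N - 1)``.
SPLIT_AAC / SPLIT_DPC
    The peptide is split into two (near-)equal halves — the N-half gets
    floor(N/2) residues — and the composition of each half is concatenated.
NT_* / CT_* / NTCT_*
    Compositions of the first / last ``terminal_len`` residues, or of both
    terminal fragments concatenated block-wise (NT block then CT block).
BINARY_NT / BINARY_CT / BINARY_NTCT
    Per-position one-hot profiles (20 bits per position, alphabetical
    residue order, Ala first) of the terminal fragment, or of the derived
    2*terminal_len-mer obtained by concatenating the N- and C-terminal
    fragments.

Feature order is fixed: residues alphabetically (A, C, D, ..., Y) and
dipeptides row-major alphabetically (AA, AC, ..., YY), so vectors are
portable across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from il10pep.dataset_io import AMINO_ACIDS, AlphabetError, PeptideDataset

AAC_NAMES: list[str] = list(AMINO_ACIDS)
DPC_NAMES: list[str] = [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_DP_INDEX = {d: i for i, d in enumerate(DPC_NAMES)}

ENCODER_KINDS = (
    "AAC",
    "DPC",
    "SPLIT_AAC",
    "SPLIT_DPC",
    "NT_AAC",
    "NT_DPC",
    "CT_AAC",
    "CT_DPC",
    "NTCT_AAC",
    "NTCT_DPC",
    "BINARY_NT",
    "BINARY_CT",
    "BINARY_NTCT",
)


def _check_alphabet(seq: str) -> None:
    bad = sorted(set(seq) - set(AMINO_ACIDS))
    if bad:
        raise AlphabetError(f"non-canonical residue(s) {','.join(bad)} in {seq!r}")


def aac(seq: str) -> np.ndarray:
    """Percent amino-acid composition (20 values, alphabetical order)."""
    if len(seq) < 1:
        raise ValueError("AAC requires at least 1 residue")
    _check_alphabet(seq)
    counts = np.zeros(20)
    for ch in seq:
        counts[_AA_INDEX[ch]] += 1
    return 100.0 * counts / len(seq)


def dpc(seq: str) -> np.ndarray:
    """Percent dipeptide composition over the N-1 overlapping pairs (400 values)."""
    if len(seq) < 2:
        raise ValueError("DPC requires at least 2 residues")
    _check_alphabet(seq)
    counts = np.zeros(400)
    for i in range(len(seq) - 1):
        counts[_DP_INDEX[seq[i : i + 2]]] += 1
    return 100.0 * counts / (len(seq) - 1)


def split_composition(seq: str, level: str = "AAC") -> np.ndarray:
    """Composition of the two peptide halves, N-half block then C-half block.

    The split point is floor(N/2), so for odd lengths the C-half carries the
    extra residue.
    """
    fn, min_half = {"AAC": (aac, 1), "DPC": (dpc, 2)}[level.upper()]
    half = len(seq) // 2
    if half < min_half or len(seq) - half < min_half:
        raise ValueError(
            f"split {level} needs each half to have >= {min_half} residues; "
            f"got length {len(seq)}"
        )
    return np.concatenate([fn(seq[:half]), fn(seq[half:])])


def terminal_fragment(seq: str, end: str, n: int = 8) -> str:
    """First (``end='N'``) or last (``end='C'``) ``n`` residues."""
    if len(seq) < n:
        raise ValueError(f"sequence of length {len(seq)} shorter than terminal length {n}")
    if end.upper() == "N":
        return seq[:n]
    if end.upper() == "C":
        return seq[-n:]
    raise ValueError(f"end must be 'N' or 'C', got {end!r}")


def derived_16mer(seq: str, n: int = 8) -> str:
    """NT fragment + CT fragment: a fixed-length 2n-mer (16 for n=8).

    For peptides of exactly n residues the two fragments coincide and the
    derived sequence duplicates the peptide.
    """
    return terminal_fragment(seq, "N", n) + terminal_fragment(seq, "C", n)


def binary_profile(seq: str) -> np.ndarray:
    """Per-position one-hot encoding: 20 bits per residue, Ala first.

    A length-L input yields 20*L values with exactly L ones.
    """
    _check_alphabet(seq)
    out = np.zeros(20 * len(seq))
    for i, ch in enumerate(seq):
        out[20 * i + _AA_INDEX[ch]] = 1.0
    return out


@dataclass(frozen=True)
class EncoderSpec:
    """An encoder kind plus its parameters; determines dimensionality.

    ``feature_subset``, when given, restricts the output to the named
    features (used with correlation-based feature selection).
    """

    kind: str
    terminal_len: int = 8
    feature_subset: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.kind not in ENCODER_KINDS:
            raise ValueError(f"unknown encoder kind {self.kind!r}; valid: {ENCODER_KINDS}")
        if self.terminal_len < 2:
            raise ValueError("terminal_len must be >= 2")
        if self.feature_subset is not None:
            object.__setattr__(self, "feature_subset", tuple(self.feature_subset))


def min_length(spec: EncoderSpec) -> int:
    """Shortest peptide encodable under ``spec``."""
    return {
        "AAC": 1,
        "DPC": 2,
        "SPLIT_AAC": 2,
        "SPLIT_DPC": 4,
    }.get(spec.kind, spec.terminal_len)


def _prefixed(prefix: str, names: Sequence[str]) -> list[str]:
    return [f"{prefix}{n}" for n in names]


def feature_names(spec: EncoderSpec) -> list[str]:
    """Ordered feature labels for ``spec`` (ignoring any subset)."""
    t = spec.terminal_len
    base = {
        "AAC": AAC_NAMES,
        "DPC": DPC_NAMES,
        "SPLIT_AAC": _prefixed("N_", AAC_NAMES) + _prefixed("C_", AAC_NAMES),
        "SPLIT_DPC": _prefixed("N_", DPC_NAMES) + _prefixed("C_", DPC_NAMES),
        "NT_AAC": _prefixed("NT_", AAC_NAMES),
        "NT_DPC": _prefixed("NT_", DPC_NAMES),
        "CT_AAC": _prefixed("CT_", AAC_NAMES),
        "CT_DPC": _prefixed("CT_", DPC_NAMES),
        "NTCT_AAC": _prefixed("NT_", AAC_NAMES) + _prefixed("CT_", AAC_NAMES),
        "NTCT_DPC": _prefixed("NT_", DPC_NAMES) + _prefixed("CT_", DPC_NAMES),
        "BINARY_NT": [f"P{i+1}_{a}" for i in range(t) for a in AMINO_ACIDS],
        "BINARY_CT": [f"P{i+1}_{a}" for i in range(t) for a in AMINO_ACIDS],
        "BINARY_NTCT": [f"P{i+1}_{a}" for i in range(2 * t) for a in AMINO_ACIDS],
    }[spec.kind]
    return list(base)


def encode_peptide(seq: str, spec: EncoderSpec) -> np.ndarray:
    """Full (un-subsetted) feature vector of one validated sequence."""
    t = spec.terminal_len
    if len(seq) < min_length(spec):
        raise ValueError(
            f"sequence of length {len(seq)} too short for encoder {spec.kind} "
            f"(minimum {min_length(spec)})"
        )
    if spec.kind == "AAC":
        return aac(seq)
    if spec.kind == "DPC":
        return dpc(seq)
    if spec.kind == "SPLIT_AAC":
        return split_composition(seq, "AAC")
    if spec.kind == "SPLIT_DPC":
        return split_composition(seq, "DPC")
    if spec.kind == "NT_AAC":
        return aac(terminal_fragment(seq, "N", t))
    if spec.kind == "NT_DPC":
        return dpc(terminal_fragment(seq, "N", t))
    if spec.kind == "CT_AAC":
        return aac(terminal_fragment(seq, "C", t))
    if spec.kind == "CT_DPC":
        return dpc(terminal_fragment(seq, "C", t))
    if spec.kind == "NTCT_AAC":
        return np.concatenate(
            [aac(terminal_fragment(seq, "N", t)), aac(terminal_fragment(seq, "C", t))]
        )
    if spec.kind == "NTCT_DPC":
        return np.concatenate(
            [dpc(terminal_fragment(seq, "N", t)), dpc(terminal_fragment(seq, "C", t))]
        )
    if spec.kind == "BINARY_NT":
        return binary_profile(terminal_fragment(seq, "N", t))
    if spec.kind == "BINARY_CT":
        return binary_profile(terminal_fragment(seq, "C", t))
    if spec.kind == "BINARY_NTCT":
        return binary_profile(derived_16mer(seq, t))
    raise AssertionError(f"unhandled encoder kind {spec.kind}")  # pragma: no cover


def encode_sequences(
    seqs: Sequence[str], spec: EncoderSpec
) -> tuple[np.ndarray, list[str]]:
    """Encode sequences into a matrix, applying any feature subset."""
    names = feature_names(spec)
    rows = []
    for s in seqs:
        try:
            rows.append(encode_peptide(s, spec))
        except ValueError as exc:
            raise ValueError(f"cannot encode peptide {s!r}: {exc}") from exc
    X = np.vstack(rows) if rows else np.empty((0, len(names)))
    if spec.feature_subset is not None:
        index = {n: i for i, n in enumerate(names)}
        missing = [n for n in spec.feature_subset if n not in index]
        if missing:
            raise ValueError(f"unknown feature name(s) in subset: {missing}")
        cols = [index[n] for n in spec.feature_subset]
        X = X[:, cols]
        names = list(spec.feature_subset)
    return X, names


def encode_dataset(
    ds: PeptideDataset, spec: EncoderSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix (positives first), 1/0 label vector and feature names."""
    seqs = [p.sequence for p in ds.positives] + [p.sequence for p in ds.negatives]
    X, names = encode_sequences(seqs, spec)
    y = np.concatenate(
        [np.ones(len(ds.positives), dtype=int), np.zeros(len(ds.negatives), dtype=int)]
    )
    return X, y, names


def write_feature_matrix(ds: PeptideDataset, spec: EncoderSpec, path) -> None:
    """Write the encoded dataset as TSV: id, label, then one column per feature."""
    import pandas as pd

    X, y, names = encode_dataset(ds, spec)
    ids = [p.id for p in ds.positives] + [p.id for p in ds.negatives]
    frame = pd.DataFrame(X, columns=names)
    frame.insert(0, "label", y)
    frame.insert(0, "id", ids)
    frame.to_csv(path, sep="\t", index=False)
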