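"""Mining of class-exclusive contiguous residue motifs.

A motif here is a plain contiguous substring (length 2-6 by default) over
the 20-letter alphabet. A motif is *exclusive* to the target class when it
occurs in at least ``min_support`` target sequences and in zero contrast
sequences. Hyphenated motif notation ("R-D-H") is accepted and normalised
by stripping hyphens.

Ranked motif lists report, per motif, its support, the number of target
sequences it newly covers, and the running cumulative coverage — motifs
with identical support are ordered shorter-first then lexicographically,
and any motif whose single-residue extension has identical support is
dropped as non-maximal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from il10pep.dataset_io import AMINO_ACIDS, Peptide

_AA_SET = frozenset(AMINO_ACIDS)


def normalize_motif(token: str) -> str:
    """Strip hyphens/whitespace and validate a motif pattern (length >= 2)."""
    pattern = token.replace("-", "").replace(" ", "").upper()
    if len(pattern) < 2:
        raise ValueError(f"motif {token!r} must have at least 2 residues")
    bad = sorted(set(pattern) - _AA_SET)
    if bad:
        raise ValueError(f"motif {token!r} contains non-canonical residue(s) {bad}")
    return pattern


def _sequences(items: Sequence) -> list[str]:
    return [p.sequence if isinstance(p, Peptide) else str(p) for p in items]


def count_matches(motif: str, peptides: Sequence) -> int:
    """Number of peptides containing the motif as a contiguous substring.

    Each peptide counts once regardless of internal repeats.
    """
    pattern = normalize_motif(motif)
    return sum(pattern in s for s in _sequences(peptides))


@dataclass(frozen=True)
class MotifRecord:
    pattern: str
    support: int
    contrast_support: int
    unique_new: int
    cumulative_coverage: int


def _substring_supports(
    seqs: list[str], length_range: tuple[int, int]
) -> dict[str, set[int]]:
    lo, hi = length_range
    supports: dict[str, set[int]] = {}
    for idx, s in enumerate(seqs):
        for L in range(lo, hi + 1):
            for i in range(len(s) - L + 1):
                supports.setdefault(s[i : i + L], set()).add(idx)
    return supports


def mine_exclusive_motifs(
    target: Sequence,
    contrast: Sequence,
    min_support: Optional[int] = None,
    length_range: tuple[int, int] = (2, 6),
) -> list[MotifRecord]:
    """Ranked exclusive motifs of the target class against the contrast class.

    All substrings of the target sequences within ``length_range`` are
    enumerated; a motif is kept iff its unique-sequence support reaches
    ``min_support`` (default: ceil(2% of target size)) and it never occurs
    in the contrast class. Ranking is by support descending, ties broken
    toward shorter then lexicographically smaller patterns, with greedy
    cumulative-coverage bookkeeping down the ranking.
    """
    tgt = _sequences(target)
    ctr = _sequences(contrast)
    if not tgt or not ctr:
        raise ValueError("both target and contrast sets must be non-empty")
    if min_support is None:
        min_support = math.ceil(0.02 * len(tgt))
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    lo, hi = length_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid motif length range {length_range}")

    supports = _substring_supports(tgt, (lo, hi))
    contrast_patterns = set(_substring_supports(ctr, (lo, hi)))

    kept = {
        p: s
        for p, s in supports.items()
        if len(s) >= min_support and p not in contrast_patterns
    }
    # Maximality: an extension with identical support covers the same
    # sequences (its occurrences are a subset), so the shorter motif is
    # redundant.
    maximal = {}
    for p, s in kept.items():
        if len(p) < hi:
            extended = any(
                len(supports.get(p + a, ())) == len(s)
                or len(supports.get(a + p, ())) == len(s)
                for a in AMINO_ACIDS
            )
            if extended:
                continue
        maximal[p] = s

    ranked = sorted(maximal.items(), key=lambda kv: (-len(kv[1]), len(kv[0]), kv[0]))
    covered: set[int] = set()
    records = []
    for pattern, supp in ranked:
        new = supp - covered
        covered |= supp
        records.append(
            MotifRecord(
                pattern=pattern,
                support=len(supp),
                contrast_support=0,
                unique_new=len(new),
                cumulative_coverage=len(covered),
            )
        )
    return records


def coverage_table(records: Sequence[MotifRecord]) -> pd.DataFrame:
    """Tabular view of a ranked motif list: support, cumulative coverage,
    newly covered unique sequences."""
    return pd.DataFrame(
        [
            {
                "Motif": r.pattern,
                "n_sequences": r.support,
                "cumulative_coverage": r.cumulative_coverage,
                "n_unique_new": r.unique_new,
            }
            for r in records
        ],
        columns=["Motif", "n_sequences", "cumulative_coverage", "n_unique_new"],
    )
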