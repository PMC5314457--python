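"""Per-position and whole-sequence residue preferences between classes.

Variable-length peptides are aligned by their termini: each peptide is
reduced to its derived 2*terminal_len-mer (first 8 + last 8 residues by
default), giving a fixed 16-position profile. Class differences are tested
per (position, residue) with a two-proportion z-test (pooled variance),
falling back to Fisher's exact test whenever any expected cell count drops
below 5. No multiple-testing correction is applied by default; Bonferroni
is available via a flag.

Whole-sequence composition differences compare the per-peptide amino-acid
composition means between classes with Welch's t-test per residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from il10pep.dataset_io import AMINO_ACIDS, PeptideDataset
from il10pep.encoders import aac, derived_16mer
from il10pep.motif_miner import _sequences

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class PositionProfile:
    """Per-position residue percentages over terminally aligned peptides."""

    freq: np.ndarray    # (2*terminal_len, 20) percentages, rows sum to 100
    counts: np.ndarray  # (2*terminal_len, 20) integer counts
    n: int
    terminal_len: int


def position_profile(peptides: Sequence, terminal_len: int = 8) -> PositionProfile:
    """Residue frequency profile on the derived 2n-mers of the peptides."""
    seqs = _sequences(peptides)
    if not seqs:
        raise ValueError("position_profile requires at least one peptide")
    width = 2 * terminal_len
    counts = np.zeros((width, 20), dtype=int)
    for s in seqs:
        for pos, ch in enumerate(derived_16mer(s, terminal_len)):
            counts[pos, _AA_INDEX[ch]] += 1
    freq = 100.0 * counts / len(seqs)
    return PositionProfile(freq=freq, counts=counts, n=len(seqs), terminal_len=terminal_len)


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """p-value for H0: equal residue frequency in the two classes.

    Pooled-variance z-test; Fisher's exact test when any expected count
    under the pooled rate falls below 5.
    """
    if k1 == k2 == 0 or (k1 == n1 and k2 == n2):
        return 1.0
    pooled = (k1 + k2) / (n1 + n2)
    expected = [n1 * pooled, n1 * (1 - pooled), n2 * pooled, n2 * (1 - pooled)]
    if min(expected) < 5:
        _, p = stats.fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        return float(p)
    _, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(p)


def two_sample_enrichment(
    pos_peptides: Sequence,
    neg_peptides: Sequence,
    terminal_len: int = 8,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Significantly enriched/depleted residues per derived position.

    Returns one row per (position, residue) call with columns position
    (1-based), residue, pos_freq, neg_freq, delta (percentage points,
    positive = enriched in the positive class), p_value and direction.
    """
    prof_pos = position_profile(pos_peptides, terminal_len)
    prof_neg = position_profile(neg_peptides, terminal_len)
    n_tests = 2 * terminal_len * 20
    cutoff = alpha / n_tests if bonferroni else alpha
    rows = []
    for pos in range(2 * terminal_len):
        for ai, residue in enumerate(AMINO_ACIDS):
            k1, k2 = int(prof_pos.counts[pos, ai]), int(prof_neg.counts[pos, ai])
            if k1 == 0 and k2 == 0:
                continue
            p = _two_proportion_p(k1, prof_pos.n, k2, prof_neg.n)
            if p < cutoff:
                delta = prof_pos.freq[pos, ai] - prof_neg.freq[pos, ai]
                rows.append(
                    {
                        "position": pos + 1,
                        "residue": residue,
                        "pos_freq": prof_pos.freq[pos, ai],
                        "neg_freq": prof_neg.freq[pos, ai],
                        "delta": delta,
                        "p_value": p,
                        "direction": "enriched" if delta > 0 else "depleted",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["position", "residue", "pos_freq", "neg_freq", "delta",
                 "p_value", "direction"],
    )


def composition_comparison(ds: PeptideDataset) -> pd.DataFrame:
    """Mean amino-acid composition per class, difference and Welch-t p-value."""
    if not ds.positives or not ds.negatives:
        raise ValueError("both classes must be non-empty")
    pos = np.vstack([aac(p.sequence) for p in ds.positives])
    neg = np.vstack([aac(p.sequence) for p in ds.negatives])
    rows = []
    for ai, residue in enumerate(AMINO_ACIDS):
        a, b = pos[:, ai], neg[:, ai]
        if a.std() == 0 and b.std() == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "residue": residue,
                "mean_pos": float(a.mean()),
                "mean_neg": float(b.mean()),
                "delta": float(a.mean() - b.mean()),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows, columns=["residue", "mean_pos", "mean_neg", "delta", "p_value"])
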