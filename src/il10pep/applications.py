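"""Predict, Design and Protein-Scan applications.

All three modes score peptides with a main model (IL-10 inducing vs
non-inducing MHC II binders) and, optionally, an alternate model (IL-10
inducing vs MHC II non-binders). With two models the decision rule is AND:
a peptide is called an inducer only when *both* scores reach their model's
threshold, so the two-model call set is never more permissive than either
single model.

Models are duck-typed: anything with ``score_peptides(seqs) -> array`` and
a ``threshold`` attribute works (normally a
:class:`il10pep.model_suite.TrainedModel`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from il10pep.dataset_io import AMINO_ACIDS, Peptide, PeptideError, validate_peptide

VERDICT_POS = "inducer"
VERDICT_NEG = "non-inducer"


@dataclass
class Prediction:
    id: str
    sequence: str
    score_main: Optional[float] = None
    score_alt: Optional[float] = None
    verdict: Optional[str] = None
    error: Optional[str] = None


def _verdict(score_main, thr_main, score_alt, thr_alt) -> str:
    ok = score_main >= thr_main
    if thr_alt is not None:
        ok = ok and score_alt >= thr_alt
    return VERDICT_POS if ok else VERDICT_NEG


def _as_peptides(peptides: Sequence) -> list[Peptide]:
    out = []
    for i, p in enumerate(peptides):
        if isinstance(p, Peptide):
            out.append(p)
        else:
            out.append(Peptide(id=f"pep{i+1}", sequence=str(p)))
    return out


def predict_batch(
    peptides: Sequence, model_main, model_alt=None
) -> list[Prediction]:
    """Score a peptide library; per-peptide failures become error rows.

    A peptide that cannot be scored (too short for the encoder, bad
    residue) yields a Prediction with ``error`` set; the batch continues.
    """
    items = _as_peptides(peptides)
    preds: list[Prediction] = [Prediction(id=p.id, sequence=p.sequence) for p in items]
    valid_idx = []
    for i, p in enumerate(items):
        try:
            validate_peptide(p.sequence, min_len=1)
            model_main.score_peptides([p.sequence])  # probe encodability
            if model_alt is not None:
                model_alt.score_peptides([p.sequence])
            valid_idx.append(i)
        except (PeptideError, ValueError) as exc:
            preds[i].error = str(exc)
    if valid_idx:
        seqs = [items[i].sequence for i in valid_idx]
        s_main = np.asarray(model_main.score_peptides(seqs), dtype=float)
        s_alt = (
            np.asarray(model_alt.score_peptides(seqs), dtype=float)
            if model_alt is not None
            else None
        )
        for j, i in enumerate(valid_idx):
            preds[i].score_main = float(s_main[j])
            if s_alt is not None:
                preds[i].score_alt = float(s_alt[j])
            preds[i].verdict = _verdict(
                s_main[j],
                model_main.threshold,
                None if s_alt is None else s_alt[j],
                None if model_alt is None else model_alt.threshold,
            )
    return preds


def predictions_to_frame(preds: Sequence[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "sequence": p.sequence,
                "score_main": p.score_main,
                "score_alt": p.score_alt,
                "verdict": p.verdict,
                "error": p.error,
            }
            for p in preds
        ]
    )


def design_analogs(peptide, model_main, model_alt=None) -> pd.DataFrame:
    """All single-position substitution analogs of a peptide, ranked by score.

    For a length-L peptide this is the L*19 substitution neighbourhood plus
    the original, sorted descending by main-model score. The ``mutation``
    column encodes each analog as ``<orig><1-based position><new>``.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else validate_peptide(str(peptide))
    rows = [("original", seq)]
    for pos, orig in enumerate(seq):
        for alt in AMINO_ACIDS:
            if alt == orig:
                continue
            rows.append((f"{orig}{pos+1}{alt}", seq[:pos] + alt + seq[pos + 1 :]))
    seqs = [s for _, s in rows]
    s_main = np.asarray(model_main.score_peptides(seqs), dtype=float)
    s_alt = (
        np.asarray(model_alt.score_peptides(seqs), dtype=float)
        if model_alt is not None
        else np.full(len(seqs), np.nan)
    )
    table = pd.DataFrame(
        {
            "mutation": [m for m, _ in rows],
            "sequence": seqs,
            "score_main": s_main,
            "score_alt": s_alt,
            "verdict": [
                _verdict(
                    s_main[i],
                    model_main.threshold,
                    s_alt[i] if model_alt is not None else None,
                    model_alt.threshold if model_alt is not None else None,
                )
                for i in range(len(seqs))
            ],
        }
    )
    table = table.sort_values("score_main", ascending=False, kind="mergesort")
    table.insert(0, "rank", range(1, len(table) + 1))
    return table.reset_index(drop=True)


def protein_scan(
    protein: str, model_main, model_alt=None, window: int = 15
) -> pd.DataFrame:
    """Score every overlapping window (step 1) of a protein sequence.

    Coordinates are 1-based inclusive; a length-N protein gives
    N - window + 1 rows.
    """
    if window < 8:
        raise ValueError("scan window must be >= 8 residues")
    seq = validate_peptide(protein, min_len=window)
    windows = [seq[i : i + window] for i in range(len(seq) - window + 1)]
    s_main = np.asarray(model_main.score_peptides(windows), dtype=float)
    s_alt = (
        np.asarray(model_alt.score_peptides(windows), dtype=float)
        if model_alt is not None
        else np.full(len(windows), np.nan)
    )
    return pd.DataFrame(
        {
            "start": np.arange(1, len(windows) + 1),
            "end": np.arange(window, len(seq) + 1),
            "sequence": windows,
            "score_main": s_main,
            "score_alt": s_alt,
            "verdict": [
                _verdict(
                    s_main[i],
                    model_main.threshold,
                    s_alt[i] if model_alt is not None else None,
                    model_alt.threshold if model_alt is not None else None,
                )
                for i in range(len(windows))
            ],
        }
    )
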