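"""Training, cross-validation, feature selection and persistence of the
classifier families used for IL-10 inducer prediction.

Five algorithm families are supported, each behind a common score
orientation contract (higher score = more likely IL-10 inducing):

=================  ===============================  =======================
algorithm          score                            threshold grid
=================  ===============================  =======================
svm_rbf            signed RBF-SVM margin            margins (-2 ... 2)
smo_svm            signed RBF-SVM margin            margins (-2 ... 2)
random_forest      fraction of positive trees       probabilities (0 ... 1)
knn                fraction of positive neighbours  probabilities (0 ... 1)
decision_tree      leaf positive fraction           probabilities (0 ... 1)
=================  ===============================  =======================

Hyperparameter names mirror the knobs the published models tuned:
``trees`` (forest size), ``neighbors`` (k), ``cost``/``gamma`` (SVM), and
``pruning_confidence``/``min_leaf`` (tree). Compositions feed the forest,
tree and k-NN learners as raw percentages; the SVM families min-max scale
features to [0, 1] with the scaler fitted on training folds only.

Thresholds are selected on pooled out-of-fold scores (a single reportable
operating point per model), by maximum MCC unless another criterion is
requested.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from il10pep import metrics
from il10pep.dataset_io import Peptide, PeptideDataset
from il10pep.encoders import EncoderSpec, encode_dataset, encode_sequences

MODEL_FORMAT_VERSION = "il10pep-model-1"

#: Per-algorithm hyperparameter schema with defaults.
ALGORITHM_SCHEMAS: dict[str, dict] = {
    "svm_rbf": {"cost": 5.0, "gamma": "scale"},
    "smo_svm": {"cost": 5.0, "gamma": 0.001},
    "random_forest": {"trees": 600},
    "knn": {"neighbors": 3},
    "decision_tree": {"pruning_confidence": 0.4, "min_leaf": 2},
}

#: Families whose scores are signed margins rather than probabilities.
MARGIN_FAMILIES = frozenset({"svm_rbf", "smo_svm"})


class ModelFormatError(ValueError):
    """Persisted model artifact is unreadable or has a wrong format version."""


@dataclass(frozen=True)
class ModelConfig:
    """An algorithm choice plus hyperparameters and a reproducibility seed."""

    algorithm: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self):
        if self.algorithm not in ALGORITHM_SCHEMAS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; "
                f"valid: {sorted(ALGORITHM_SCHEMAS)}"
            )
        unknown = set(self.hyperparams) - set(ALGORITHM_SCHEMAS[self.algorithm])
        if unknown:
            raise ValueError(
                f"unknown hyperparameter(s) {sorted(unknown)} for {self.algorithm}"
            )

    def resolved(self) -> dict:
        """Hyperparameters with schema defaults filled in."""
        return {**ALGORITHM_SCHEMAS[self.algorithm], **self.hyperparams}


def build_estimator(config: ModelConfig):
    """A fresh (unfitted) scikit-learn estimator for ``config``."""
    hp = config.resolved()
    if config.algorithm in MARGIN_FAMILIES:
        return Pipeline(
            [
                ("scale", MinMaxScaler()),
                ("svm", SVC(C=hp["cost"], gamma=hp["gamma"], kernel="rbf")),
            ]
        )
    if config.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp["trees"]), random_state=config.seed, n_jobs=1
        )
    if config.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=int(hp["neighbors"]))
    if config.algorithm == "decision_tree":
        # WEKA-style pruning confidence ~0.5 means essentially no pruning;
        # lower confidence prunes harder -> larger complexity penalty.
        conf = float(hp["pruning_confidence"])
        return DecisionTreeClassifier(
            min_samples_leaf=int(hp["min_leaf"]),
            ccp_alpha=max(0.0, 0.01 * (0.5 - conf)),
            random_state=config.seed,
        )
    raise AssertionError  # pragma: no cover


def _score_estimator(estimator, algorithm: str, X: np.ndarray) -> np.ndarray:
    if algorithm in MARGIN_FAMILIES:
        return np.asarray(estimator.decision_function(X), dtype=float)
    proba = estimator.predict_proba(X)
    pos_col = int(np.where(estimator.classes_ == 1)[0][0])
    return np.asarray(proba[:, pos_col], dtype=float)


def default_grid(config: ModelConfig) -> np.ndarray:
    return metrics.MARGIN_GRID if config.algorithm in MARGIN_FAMILIES else metrics.PROB_GRID


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its encoder and decision threshold."""

    config: ModelConfig
    estimator: object
    feature_names: list[str]
    encoder: Optional[EncoderSpec] = None
    threshold: Optional[float] = None

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        return _score_estimator(self.estimator, self.config.algorithm, np.asarray(X))

    def score_peptides(self, seqs: Sequence[str]) -> np.ndarray:
        if self.encoder is None:
            raise ValueError("model has no encoder spec; use score_matrix")
        X, _ = encode_sequences(list(seqs), self.encoder)
        return self.score_matrix(X)

    def predict_peptides(self, seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """(scores, boolean predicted-positive) at the stored threshold."""
        if self.threshold is None:
            raise ValueError("model has no decision threshold")
        scores = self.score_peptides(seqs)
        return scores, scores >= self.threshold


def train(
    config: ModelConfig,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    encoder: Optional[EncoderSpec] = None,
) -> TrainedModel:
    """Fit one estimator; the returned model carries no threshold yet."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y length")
    if np.any(np.isnan(X)):
        raise ValueError("X contains missing values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class")
    est = build_estimator(config)
    est.fit(X, y)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])
    ]
    return TrainedModel(config=config, estimator=est, feature_names=names, encoder=encoder)


def stratified_kfold(
    n_pos: int, n_neg: int, k: int = 5, seed: int = 42
) -> list[np.ndarray]:
    """k disjoint test-index folds over positives-then-negatives ordering.

    Per-class fold sizes differ by at most one; deterministic given seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if min(n_pos, n_neg) < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros((len(y), 1)), y)]


@dataclass
class CVResult:
    """Pooled out-of-fold evaluation of one (algorithm, encoder) pair."""

    config: ModelConfig
    encoder: EncoderSpec
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    auc: float
    fold_table: pd.DataFrame
    scores: np.ndarray
    labels: np.ndarray

    def summary_row(self) -> dict:
        return {
            "Algorithm": self.config.algorithm,
            "Encoder": self.encoder.kind,
            "Threshold": self.threshold,
            "Sensitivity": round(self.sensitivity, 2),
            "Specificity": round(self.specificity, 2),
            "Accuracy": round(self.accuracy, 2),
            "MCC": round(self.mcc, 2),
            "AUC": round(self.auc, 3),
        }


def cross_validate(
    config: ModelConfig,
    spec: EncoderSpec,
    ds: PeptideDataset,
    k: int = 5,
    seed: int = 42,
    grid=None,
    criterion: str = "mcc",
) -> CVResult:
    """Stratified k-fold CV with threshold selection on pooled scores.

    Each fold is scored by a model trained on the other k-1 folds; the
    single decision threshold is then chosen on the pooled out-of-fold
    scores, and per-fold plus pooled Sn/Sp/Acc/MCC are reported at it.
    """
    X, y, names = encode_dataset(ds, spec)
    folds = stratified_kfold(len(ds.positives), len(ds.negatives), k=k, seed=seed)
    oof = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        model = train(config, X[train_mask], y[train_mask], feature_names=names)
        oof[test_idx] = model.score_matrix(X[test_idx])
        fold_of[test_idx] = fi
    assert not np.any(np.isnan(oof))
    if grid is None:
        grid = default_grid(config)
    _, thr = metrics.threshold_sweep(oof, y, grid, criterion=criterion)
    sn, sp, acc, mcc = metrics.sens_spec_acc_mcc(
        metrics.confusion_at_threshold(oof, y, thr)
    )
    auc, _, _ = metrics.roc_auc(oof, y)
    fold_rows = []
    for fi in range(k):
        m = fold_of == fi
        fsn, fsp, facc, fmcc = metrics.sens_spec_acc_mcc(
            metrics.confusion_at_threshold(oof[m], y[m], thr)
        )
        fold_rows.append(
            {"Fold": fi + 1, "Sensitivity": fsn, "Specificity": fsp,
             "Accuracy": facc, "MCC": fmcc}
        )
    return CVResult(
        config=config,
        encoder=spec,
        threshold=thr,
        sensitivity=sn,
        specificity=sp,
        accuracy=acc,
        mcc=mcc,
        auc=auc,
        fold_table=pd.DataFrame(fold_rows),
        scores=oof,
        labels=y,
    )


def stratified_split(
    ds: PeptideDataset, test_fraction: float = 0.2, seed: int = 42
) -> tuple[PeptideDataset, PeptideDataset]:
    """Seeded stratified train/test split (default 80/20) of a dataset."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    def split(items: list[Peptide]) -> tuple[list[Peptide], list[Peptide]]:
        order = rng.permutation(len(items))
        n_test = int(round(test_fraction * len(items)))
        test_set = set(order[:n_test].tolist())
        tr = [p for i, p in enumerate(items) if i not in test_set]
        te = [p for i, p in enumerate(items) if i in test_set]
        return tr, te

    pos_tr, pos_te = split(ds.positives)
    neg_tr, neg_te = split(ds.negatives)
    return (
        PeptideDataset(pos_tr, neg_tr, name=f"{ds.name}-train"),
        PeptideDataset(pos_te, neg_te, name=f"{ds.name}-test"),
    )


# ---------------------------------------------------------------------------
# Correlation-based feature selection (CFS)
# ---------------------------------------------------------------------------

def _abs_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0  # constant feature: correlation defined as 0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def cfs_merit(
    subset: Sequence[int], r_cf: np.ndarray, ff_corr
) -> float:
    """CFS merit k*r_cf / sqrt(k + k(k-1)*r_ff) of a feature subset.

    r_cf is the mean absolute feature-class correlation over the subset and
    r_ff the mean absolute pairwise feature-feature correlation.
    """
    k = len(subset)
    if k == 0:
        return -np.inf
    mean_cf = float(np.mean(r_cf[list(subset)]))
    if k == 1:
        return mean_cf
    pairs = list(itertools.combinations(sorted(subset), 2))
    mean_ff = float(np.mean([ff_corr(i, j) for i, j in pairs]))
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
    max_stale: int = 5,
) -> list[str]:
    """Correlation-based feature subset selection via best-first search.

    Starting from the empty set, subsets are expanded one feature at a
    time; the open list is ordered by merit and the search stops after
    ``max_stale`` consecutive expansions that fail to improve the best
    merit seen. Returns the selected feature names in input order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n_features = X.shape[1]
    if n_features < 2:
        raise ValueError("cfs_select requires at least 2 features")
    if len(np.unique(y)) != 2:
        raise ValueError("cfs_select requires binary labels")
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(n_features)
    ]
    r_cf = np.array([_abs_corr(X[:, i], y) for i in range(n_features)])
    ff_cache: dict[tuple[int, int], float] = {}

    def ff_corr(i: int, j: int) -> float:
        key = (i, j) if i < j else (j, i)
        if key not in ff_cache:
            ff_cache[key] = _abs_corr(X[:, key[0]], X[:, key[1]])
        return ff_cache[key]

    counter = itertools.count()
    open_heap: list[tuple[float, int, frozenset]] = []
    seen: set[frozenset] = set()

    def push(subset: frozenset, merit: float) -> None:
        if subset not in seen:
            seen.add(subset)
            heapq.heappush(open_heap, (-merit, next(counter), subset))

    best_subset: frozenset = frozenset()
    best_merit = -np.inf
    push(frozenset(), 0.0)
    stale = 0
    while open_heap and stale < max_stale:
        _, _, current = heapq.heappop(open_heap)
        improved = False
        for f in range(n_features):
            if f in current:
                continue
            child = current | {f}
            if child in seen:
                continue
            merit = cfs_merit(child, r_cf, ff_corr)
            push(child, merit)
            if merit > best_merit + 1e-12:
                best_merit, best_subset = merit, child
                improved = True
        stale = 0 if improved else stale + 1
    return [names[i] for i in sorted(best_subset)]


# ---------------------------------------------------------------------------
# Persistence and external validation
# ---------------------------------------------------------------------------

def persist(model: TrainedModel, path: Union[str, Path]) -> None:
    """Write a single-file model bundle (estimator + encoder + threshold)."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "config": model.config,
            "encoder": model.encoder,
            "threshold": model.threshold,
            "feature_names": model.feature_names,
            "estimator": model.estimator,
        },
        path,
    )


def load(path: Union[str, Path]) -> TrainedModel:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"cannot read model artifact {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model format "
            f"{payload.get('format_version') if isinstance(payload, dict) else type(payload)}"
        )
    return TrainedModel(
        config=payload["config"],
        estimator=payload["estimator"],
        feature_names=payload["feature_names"],
        encoder=payload["encoder"],
        threshold=payload["threshold"],
    )


def external_validate(
    model: TrainedModel, peptides: Sequence
) -> tuple[pd.DataFrame, int]:
    """Score an assumed-positive held-out peptide list; count the hits.

    Returns the per-peptide table (id, sequence, score, predicted) and the
    number predicted positive at the model's threshold.
    """
    if model.threshold is None:
        raise ValueError("external validation requires a thresholded model")
    items = [
        (p.id, p.sequence) if isinstance(p, Peptide) else (f"pep{i+1}", str(p))
        for i, p in enumerate(peptides)
    ]
    if not items:
        return pd.DataFrame(columns=["id", "sequence", "score", "predicted"]), 0
    scores = model.score_peptides([s for _, s in items])
    predicted = scores >= model.threshold
    table = pd.DataFrame(
        {
            "id": [i for i, _ in items],
            "sequence": [s for _, s in items],
            "score": scores,
            "predicted": np.where(predicted, "inducer", "non-inducer"),
        }
    )
    return table, int(predicted.sum())
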