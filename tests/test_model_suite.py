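import itertools

import numpy as np
import pytest

from il10pep.dataset_io import Peptide, PeptideDataset
from il10pep.encoders import EncoderSpec, encode_dataset
from il10pep.metrics import threshold_sweep
from il10pep.model_suite import (
    ModelConfig,
    ModelFormatError,
    _abs_corr,
    cfs_merit,
    cfs_select,
    cross_validate,
    external_validate,
    load,
    persist,
    stratified_kfold,
    stratified_split,
    train,
)
from il10pep.synthetic_data import GeneratorConfig, biased_weights, generate


def exhaustive_cfs(X, y):
    """Powerset brute-force oracle for the CFS merit maximiser."""
    n = X.shape[1]
    r_cf = np.array([_abs_corr(X[:, i], y) for i in range(n)])
    cache = {}

    def ff(i, j):
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = _abs_corr(X[:, key[0]], X[:, key[1]])
        return cache[key]

    best_merit, best_subset = -np.inf, ()
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            merit = cfs_merit(subset, r_cf, ff)
            if merit > best_merit + 1e-12:
                best_merit, best_subset = merit, subset
    return set(best_subset)


class TestStratifiedKFold:
    @pytest.mark.parametrize("n_pos,n_neg,k", [(10, 10, 5), (394, 848, 5), (23, 57, 4)])
    def test_partition_law_and_balanced_class_sizes(self, n_pos, n_neg, k):
        folds = stratified_kfold(n_pos, n_neg, k=k, seed=9)
        joined = np.sort(np.concatenate(folds))
        assert np.array_equal(joined, np.arange(n_pos + n_neg))  # exact partition
        pos_sizes = [(f < n_pos).sum() for f in folds]
        neg_sizes = [(f >= n_pos).sum() for f in folds]
        assert max(pos_sizes) - min(pos_sizes) <= 1
        assert max(neg_sizes) - min(neg_sizes) <= 1

    def test_main_dataset_fold_sizes(self):
        folds = stratified_kfold(394, 848, k=5, seed=0)
        assert sorted((f < 394).sum() for f in folds) == [78, 79, 79, 79, 79]
        assert sorted((f >= 394).sum() for f in folds) == [169, 169, 170, 170, 170]

    def test_deterministic_given_seed(self):
        a = stratified_kfold(20, 30, seed=5)
        b = stratified_kfold(20, 30, seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(4, 100, k=5)


class TestTrain:
    def test_separable_toy_reaches_mcc_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(3, 0.2, (20, 2)), rng.normal(-3, 0.2, (20, 2))])
        y = np.array([1] * 20 + [0] * 20)
        model = train(ModelConfig(algorithm="svm_rbf"), X, y)
        table, _ = threshold_sweep(model.score_matrix(X), y, np.arange(-2, 2.01, 0.1))
        assert table["MCC"].max() == pytest.approx(1.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            train(ModelConfig(algorithm="knn"), np.zeros((5, 3)), np.ones(5))

    def test_unknown_algorithm_and_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(algorithm="deep_net")
        with pytest.raises(ValueError):
            ModelConfig(algorithm="random_forest", hyperparams={"neighbors": 3})


class TestCrossValidate:
    def test_uninformative_data_gives_near_zero_mcc(self):
        ds, _ = generate(
            GeneratorConfig(
                n_pos=80, n_neg=80,
                pos_weights=biased_weights({}), neg_weights=biased_weights({}),
                seed=21,
            )
        )
        r = cross_validate(
            ModelConfig(algorithm="random_forest", hyperparams={"trees": 100}),
            EncoderSpec(kind="AAC"), ds, seed=2,
        )
        assert abs(r.mcc) < 0.3

    def test_deterministic_repeat(self, small_ds):
        ds, _ = small_ds
        config = ModelConfig(algorithm="random_forest", hyperparams={"trees": 60})
        r1 = cross_validate(config, EncoderSpec(kind="AAC"), ds, seed=3)
        r2 = cross_validate(config, EncoderSpec(kind="AAC"), ds, seed=3)
        assert np.array_equal(r1.scores, r2.scores)
        assert r1.threshold == r2.threshold and r1.mcc == r2.mcc

    def test_every_peptide_scored_once_out_of_fold(self):
        ds = PeptideDataset(
            positives=[Peptide(f"p{i}", s) for i, s in enumerate(
                ["RRRRRRRL", "RLRLRLRL", "RRRLLLRR", "LRLRLRLR"])],
            negatives=[Peptide(f"n{i}", s) for i, s in enumerate(
                ["AAAAGGGG", "GGGGAAAA", "APAPAPAP", "PAPAGAGA"])],
        )
        r = cross_validate(
            ModelConfig(algorithm="knn", hyperparams={"neighbors": 1}),
            EncoderSpec(kind="AAC"), ds, k=2, seed=1,
        )
        assert len(r.scores) == 8 and not np.any(np.isnan(r.scores))
        assert len(r.fold_table) == 2
        # pooled confusion counts cover the whole dataset
        assert len(r.labels) == 8

    def test_accuracy_stable_across_seeds(self, small_ds):
        ds, _ = small_ds
        config = ModelConfig(algorithm="random_forest", hyperparams={"trees": 100})
        accs = [
            cross_validate(config, EncoderSpec(kind="AAC"), ds, seed=s).accuracy
            for s in (1, 2, 3)
        ]
        assert max(accs) - min(accs) <= 6.0  # small-n fold noise only


class TestCFS:
    def test_perfect_feature_selected_among_noise(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 60).astype(float)
        X = rng.normal(size=(60, 6))
        X[:, 2] = y  # perfectly correlated
        assert cfs_select(X, y) == ["f2"]

    def test_duplicated_informative_feature_not_selected_twice(self):
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 80).astype(float)
        X = rng.normal(size=(80, 4)) * 0.05
        X[:, 0] = y + rng.normal(scale=0.1, size=80)
        X[:, 1] = X[:, 0]  # exact duplicate: redundancy penalty halves merit
        selected = cfs_select(X, y)
        assert len([f for f in selected if f in ("f0", "f1")]) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 5])
    def test_best_first_matches_powerset_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 70, 7
        y = rng.integers(0, 2, n).astype(float)
        X = rng.normal(size=(n, p))
        X[:, 0] += 1.4 * y
        X[:, 1] += 0.7 * y
        X[:, 2] = X[:, 0] + rng.normal(scale=0.4, size=n)
        selected = {int(f[1:]) for f in cfs_select(X, y)}
        assert selected == exhaustive_cfs(X, y)

    def test_constant_feature_treated_as_uninformative(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 50).astype(float)
        X = rng.normal(size=(50, 3))
        X[:, 1] = 5.0  # constant
        X[:, 0] += 2 * y
        assert "f1" not in cfs_select(X, y)


class TestPersistence:
    @pytest.fixture()
    def fitted(self, small_ds):
        ds, _ = small_ds
        spec = EncoderSpec(kind="AAC")
        X, y, names = encode_dataset(ds, spec)
        config = ModelConfig(algorithm="random_forest", hyperparams={"trees": 50})
        model = train(config, X, y, feature_names=names, encoder=spec)
        model.threshold = 0.5
        return model

    def test_roundtrip_scores_identically(self, fitted, tmp_path):
        rng = np.random.default_rng(10)
        seqs = [
            "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=12))
            for _ in range(100)
        ]
        path = tmp_path / "model.joblib"
        persist(fitted, path)
        back = load(path)
        np.testing.assert_array_equal(back.score_peptides(seqs), fitted.score_peptides(seqs))
        assert back.encoder == fitted.encoder
        assert back.threshold == fitted.threshold
        assert back.feature_names == fitted.feature_names

    def test_truncated_artifact_rejected(self, fitted, tmp_path):
        path = tmp_path / "model.joblib"
        persist(fitted, path)
        path.write_bytes(path.read_bytes()[:40])
        with pytest.raises(ModelFormatError):
            load(path)

    def test_wrong_payload_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "weird.joblib"
        joblib.dump({"format_version": "something-else"}, path)
        with pytest.raises(ModelFormatError):
            load(path)


class TestExternalValidation:
    def test_threshold_below_all_scores_hits_everything(self, small_ds):
        ds, _ = small_ds
        spec = EncoderSpec(kind="AAC")
        X, y, names = encode_dataset(ds, spec)
        model = train(
            ModelConfig(algorithm="knn"), X, y, feature_names=names, encoder=spec
        )
        model.threshold = -1.0
        peptides = ds.positives[:10]
        table, hits = external_validate(model, peptides)
        assert hits == 10 and len(table) == 10

    def test_empty_list(self, small_ds):
        ds, _ = small_ds
        spec = EncoderSpec(kind="AAC")
        X, y, names = encode_dataset(ds, spec)
        model = train(
            ModelConfig(algorithm="knn"), X, y, feature_names=names, encoder=spec
        )
        model.threshold = 0.5
        table, hits = external_validate(model, [])
        assert hits == 0 and table.empty

    def test_planted_signal_positives_mostly_recovered(self, small_ds):
        ds, _ = small_ds
        spec = EncoderSpec(kind="AAC")
        X, y, names = encode_dataset(ds, spec)
        config = ModelConfig(algorithm="random_forest", hyperparams={"trees": 100})
        model = train(config, X, y, feature_names=names, encoder=spec)
        table, thr = threshold_sweep(model.score_matrix(X), y, np.arange(0, 1.01, 0.05))
        model.threshold = thr
        # fresh positives from the same class distribution
        fresh, _ = generate(GeneratorConfig(n_pos=10, n_neg=10, seed=77))
        _, hits = external_validate(model, fresh.positives)
        assert hits >= 8


class TestBiasRecoveryAndMonotonicity:
    def test_forest_importances_recover_biased_residues(self, benchmark):
        ds, _ = benchmark
        spec = EncoderSpec(kind="AAC")
        X, y, names = encode_dataset(ds, spec)
        config = ModelConfig(algorithm="random_forest", hyperparams={"trees": 200})
        model = train(config, X, y, feature_names=names)
        order = np.argsort(model.estimator.feature_importances_)[::-1]
        top5 = {names[i] for i in order[:5]}
        assert top5 <= set("ACDEFGHIKLMNPQRSTVWY")
        assert top5 & {"R", "L", "A", "G", "P"}

    def test_cv_mcc_monotone_in_composition_bias(self):
        levels = [1.0, 2.0, 4.0]
        config = ModelConfig(algorithm="random_forest", hyperparams={"trees": 80})
        means = []
        for f in levels:
            mccs = []
            for seed in (31, 32, 33):
                ds, _ = generate(
                    GeneratorConfig(
                        n_pos=80, n_neg=80,
                        pos_weights=biased_weights({"R": f, "L": f}),
                        neg_weights=biased_weights({"A": f, "G": f, "P": f}),
                        seed=seed,
                    )
                )
                mccs.append(
                    cross_validate(config, EncoderSpec(kind="AAC"), ds, seed=seed).mcc
                )
            means.append(np.mean(mccs))
        assert means[1] >= means[0] - 0.05
        assert means[2] >= means[1] - 0.05


def test_stratified_split_sizes_and_disjointness(benchmark):
    ds, _ = benchmark
    tr, te = stratified_split(ds, test_fraction=0.2, seed=4)
    assert len(te.positives) == round(0.2 * 394)
    assert len(te.negatives) == round(0.2 * 848)
    assert len(tr.positives) + len(te.positives) == 394
    assert not ({p.sequence for p in tr.positives} & {p.sequence for p in te.positives})
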