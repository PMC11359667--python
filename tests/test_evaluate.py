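"""Cross-validation laws, metric oracles, AUC pair-counting equivalence,
benchmark determinism and table emission."""

import numpy as np
import pytest

from emgpipe.evaluate import (
    MODEL_NAMES,
    ModelSpec,
    confusion_matrix,
    default_model_specs,
    emit_tables,
    overall_accuracy,
    precision_recall_f1_acc,
    roc_auc_ovr,
    run_benchmark,
    stratified_kfold,
)
from emgpipe.exceptions import ConfigurationError, UndefinedMetricError

# ---------------------------------------------------------------------------
# stratified folds
# ---------------------------------------------------------------------------


def test_folds_partition_balanced_classes():
    labels = np.repeat(np.arange(1, 8), 10)
    folds = stratified_kfold(labels, k=5, seed=0)
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test) == list(range(70))
    for _, te in folds:
        assert te.size == 14
        vals, counts = np.unique(labels[te], return_counts=True)
        assert list(vals) == list(range(1, 8))
        assert all(c == 2 for c in counts)


def test_folds_proportions_within_one_sample():
    rng = np.random.default_rng(0)
    labels = rng.choice([1, 2, 3, 4, 5, 6, 7], size=400, p=[0.3, 0.2, 0.15, 0.1, 0.1, 0.1, 0.05])
    k = 5
    folds = stratified_kfold(labels, k=k, seed=1)
    total = labels.size
    for _, te in folds:
        for cls in range(1, 8):
            global_share = np.sum(labels == cls) * te.size / total
            assert abs(np.sum(labels[te] == cls) - global_share) <= 1.0


def test_folds_deterministic():
    labels = np.repeat(np.arange(1, 8), 12)
    a = stratified_kfold(labels, k=5, seed=9)
    b = stratified_kfold(labels, k=5, seed=9)
    for (tr1, te1), (tr2, te2) in zip(a, b):
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(te1, te2)


def test_folds_small_class_rejected():
    labels = np.array([1] * 20 + [2] * 3)
    with pytest.raises(ConfigurationError):
        stratified_kfold(labels, k=5, seed=0)


# ---------------------------------------------------------------------------
# confusion-matrix metrics vs hand computation
# ---------------------------------------------------------------------------


def _oracle_prf(cm, ci):
    """Hand transcription: TP over column/row sums."""
    tp = cm[ci][ci]
    fp = sum(cm[r][ci] for r in range(len(cm))) - tp
    fn = sum(cm[ci][c] for c in range(len(cm))) - tp
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def test_binary_cm_example():
    cm = np.array([[8, 2], [1, 9]])
    prec, rec, f1, acc = precision_recall_f1_acc(cm, 0)
    assert prec == pytest.approx(8 / 9)
    assert rec == pytest.approx(0.8)
    assert f1 == pytest.approx(0.8421, abs=1e-4)
    assert acc == rec  # per-class accuracy reported as recall
    assert overall_accuracy(cm) == pytest.approx(0.85)


def test_diagonal_cm_perfect():
    cm = np.diag([5, 3, 7])
    for ci in range(3):
        assert precision_recall_f1_acc(cm, ci) == (1.0, 1.0, 1.0, 1.0)
    assert overall_accuracy(cm) == 1.0


def test_absent_class_zero_with_warning():
    cm = np.array([[5, 0, 0], [0, 4, 0], [0, 0, 0]])
    with pytest.warns(UserWarning):
        prec, rec, f1, acc = precision_recall_f1_acc(cm, 2)
    assert (prec, rec, f1, acc) == (0.0, 0.0, 0.0, 0.0)


def test_exhaustive_2x2_matches_oracle():
    for a in range(5):
        for b in range(5):
            for c in range(5):
                for d in range(5):
                    cm = np.array([[a, b], [c, d]])
                    if cm.sum() == 0:
                        continue
                    for ci in range(2):
                        import warnings as _w

                        with _w.catch_warnings():
                            _w.simplefilter("ignore")
                            prec, rec, f1, _ = precision_recall_f1_acc(cm, ci)
                        o_prec, o_rec, o_f1 = _oracle_prf(cm.tolist(), ci)
                        assert prec == pytest.approx(o_prec)
                        assert rec == pytest.approx(o_rec)
                        assert f1 == pytest.approx(o_f1)


def test_random_7x7_matches_oracle():
    rng = np.random.default_rng(2)
    import warnings as _w

    for _ in range(200):
        cm = rng.integers(0, 30, size=(7, 7))
        for ci in range(7):
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                prec, rec, f1, acc = precision_recall_f1_acc(cm, ci)
            o_prec, o_rec, o_f1 = _oracle_prf(cm.tolist(), ci)
            assert prec == pytest.approx(o_prec)
            assert rec == pytest.approx(o_rec)
            assert f1 == pytest.approx(o_f1)
            assert acc == rec
        assert overall_accuracy(cm) == pytest.approx(np.trace(cm) / cm.sum())


def test_f1_harmonic_mean_identity_random():
    rng = np.random.default_rng(3)
    import warnings as _w

    for _ in range(100):
        cm = rng.integers(0, 25, size=(7, 7))
        for ci in range(7):
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                prec, rec, f1, _ = precision_recall_f1_acc(cm, ci)
            if prec + rec > 0:
                assert f1 == pytest.approx(2 * prec * rec / (prec + rec), rel=1e-12)


def test_micro_accuracy_permutation_invariant():
    rng = np.random.default_rng(4)
    cm = rng.integers(0, 20, size=(7, 7))
    perm = rng.permutation(7)
    assert overall_accuracy(cm[np.ix_(perm, perm)]) == pytest.approx(overall_accuracy(cm))


# ---------------------------------------------------------------------------
# AUC vs pair-counting oracle
# ---------------------------------------------------------------------------


def _oracle_auc(scores, positives):
    wins = ties = 0
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def test_auc_perfect_separation():
    scores = np.array([[0.9], [0.8], [0.2], [0.1]])
    labels = np.array([1, 1, 2, 2])
    assert roc_auc_ovr(scores, labels, 1, classes=[1]) == 1.0


def test_auc_all_ties():
    scores = np.full((10, 1), 0.3)
    labels = np.array([1] * 5 + [2] * 5)
    assert roc_auc_ovr(scores, labels, 1, classes=[1]) == 0.5


def test_auc_hand_example():
    scores = np.array([[0.9], [0.8], [0.7], [0.1]])
    labels = np.array([1, 2, 1, 2])
    assert roc_auc_ovr(scores, labels, 1, classes=[1]) == pytest.approx(0.75)


def test_auc_single_class_undefined():
    with pytest.raises(UndefinedMetricError):
        roc_auc_ovr(np.zeros((3, 1)), np.array([1, 1, 1]), 1, classes=[1])


def test_auc_matches_pair_counting_up_to_200():
    rng = np.random.default_rng(5)
    for n in [2, 3, 5, 10, 50, 121, 200]:
        for _ in range(20):
            # quantized scores force ties
            scores = np.round(rng.standard_normal(n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            got = roc_auc_ovr(scores[:, None], labels, 1, classes=[1])
            want = _oracle_auc(list(scores), list(labels == 1))
            assert got == pytest.approx(want, rel=1e-12)


# ---------------------------------------------------------------------------
# benchmark behaviour
# ---------------------------------------------------------------------------


def test_benchmark_deterministic(separable_features):
    fm = separable_features
    specs = [ModelSpec("RF"), ModelSpec("kNN")]
    a = run_benchmark(fm.values, fm.labels, models=specs, k=5, seed=3, retention=0.999)
    b = run_benchmark(fm.values, fm.labels, models=specs, k=5, seed=3, retention=0.999)
    for r1, r2 in zip(a, b):
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.overall == r2.overall


def test_benchmark_pooled_cm_total(separable_features):
    fm = separable_features
    reports = run_benchmark(fm.values, fm.labels, models=[ModelSpec("kNN")], k=5, seed=0, retention=0.999)
    assert reports[0].confusion.sum() == fm.n_segments


def test_benchmark_model_failure_isolated(separable_features):
    fm = separable_features
    bad = ModelSpec("LR", hyperparams={"C": -1.0})  # invalid C: training fails
    reports = run_benchmark(fm.values, fm.labels, models=[bad, ModelSpec("kNN")], k=5, seed=0, retention=0.999)
    assert reports[0].error is not None
    assert reports[1].error is None
    assert reports[1].overall["accuracy"] > 0.5


def test_benchmark_f1_identity_on_reports(separable_features):
    fm = separable_features
    reports = run_benchmark(fm.values, fm.labels, models=[ModelSpec("kNN")], k=5, seed=1, retention=0.999)
    rep = reports[0]
    for p, r, f in zip(rep.per_class["precision"], rep.per_class["recall"], rep.per_class["f1"]):
        if p + r > 0:
            assert f == pytest.approx(2 * p * r / (p + r), rel=1e-12)


def test_ranking_sanity_soft_ordering():
    """Distinct profiles + moderate noise: RF and kNN >= LR on a majority of seeds."""
    from emgpipe.preprocess import PreprocessConfig, segment_recording
    from emgpipe.features import extract_features
    from emgpipe.synth import SynthConfig, default_activation_profile, generate_recording

    n_seeds = 12
    rf_wins = knn_wins = 0
    for seed in range(n_seeds):
        cfg = SynthConfig(
            class_counts={c: 40 for c in range(1, 8)},
            activation_profile=default_activation_profile(gain=1.0),
            baseline_sd=0.6,
            seed=seed,
        )
        fm = extract_features(segment_recording(generate_recording(cfg), PreprocessConfig()))
        reports = run_benchmark(
            fm.values,
            fm.labels,
            models=[ModelSpec("LR"), ModelSpec("kNN"), ModelSpec("RF")],
            k=5,
            seed=seed,
            retention=0.999,
        )
        acc = {r.model: r.overall["accuracy"] for r in reports}
        rf_wins += acc["RF"] >= acc["LR"]
        knn_wins += acc["kNN"] >= acc["LR"]
    assert rf_wins > n_seeds // 2
    assert knn_wins > n_seeds // 2


# ---------------------------------------------------------------------------
# table emission
# ---------------------------------------------------------------------------


def _perfect_report():
    fm_labels = np.repeat(np.arange(1, 8), 10)
    cm = confusion_matrix(fm_labels, fm_labels, np.arange(1, 8))
    from emgpipe.evaluate import MetricsReport

    ones = np.ones(7)
    return MetricsReport(
        model="RF",
        classes=np.arange(1, 8),
        confusion=cm,
        per_class={"precision": ones, "recall": ones, "f1": ones, "accuracy": ones, "auc": ones},
        overall={"precision": 1.0, "recall": 1.0, "f1": 1.0, "accuracy": 1.0, "auc": 1.0},
        fold_accuracy=[1.0] * 5,
        fold_auc=[ones] * 5,
    )


def test_emit_tables_perfect(tmp_path):
    tables = emit_tables([_perfect_report()], tmp_path)
    frame = tables["RF"]
    assert list(frame.columns) == [f"Class {c}" for c in range(1, 8)]
    assert (frame.to_numpy() == 100.0).all()
    assert (tmp_path / "table_rf.csv").exists()
    assert (tmp_path / "table_overall.csv").exists()
    assert (tmp_path / "table_rf.txt").exists()


def test_emit_tables_round_half_even(tmp_path):
    rep = _perfect_report()
    rep.per_class = {k: np.full(7, 0.98125) for k in rep.per_class}
    tables = emit_tables([rep], tmp_path)
    # 98.125 rounds half-even to 98.12
    assert tables["RF"].iloc[0, 0] == 98.12


def test_default_model_specs_cover_all_names():
    assert [s.name for s in default_model_specs()] == list(MODEL_NAMES)
    with pytest.raises(ConfigurationError):
        ModelSpec("XGB")
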