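"""RBF-SVM training/tuning, ROC/AUC construction, and model round-trips."""

import numpy as np
import pandas as pd
import pytest

from noduleomics import (
    FeatureTable,
    MetricsReport,
    SvmModel,
    compare_models,
    evaluate,
    metrics_from_scores,
    roc_curve_points,
    auc_trapezoid,
    train_svm,
)

import oracles


def table_from_array(x, y, prefix="f"):
    df = pd.DataFrame(x, columns=[f"{prefix}{i}" for i in range(x.shape[1])])
    df.insert(0, "case_id", [f"c{i}" for i in range(len(x))])
    df.insert(1, "label", np.where(y == 1, "LC", "LM"))
    df.insert(2, "split", "train")
    return FeatureTable(df)


def separable_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    x = rng.normal(size=(n, 2)) * 0.3
    x[y == 1] += 3.0
    return table_from_array(x, y)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def test_separable_table_trains_to_perfect_accuracy():
    t = separable_table()
    model = train_svm(t, ["f0", "f1"], reps=10, seed=0)
    report = evaluate(model, t)
    assert report.accuracy == 1.0
    assert report.auc == 1.0


def test_fixed_seed_reproduces_hyperparameters():
    t = separable_table(seed=3)
    m1 = train_svm(t, ["f0", "f1"], reps=15, seed=9)
    m2 = train_svm(t, ["f0", "f1"], reps=15, seed=9)
    assert (m1.C, m1.gamma) == (m2.C, m2.gamma)
    np.testing.assert_array_equal(m1.dual_coef, m2.dual_coef)


def test_permuted_labels_give_chance_level_validation_accuracy():
    """Label-permutation null: tuned bootstrap validation accuracy stays
    near 0.5."""
    rng = np.random.default_rng(0)
    accs = []
    grid = (0.1, 1.0, 10.0)
    gammas = (0.01, 0.1, 1.0)
    for seed in range(10):
        x = rng.normal(size=(60, 3))
        y = rng.permutation(np.repeat([1, 0], 30))
        t = table_from_array(x, y)
        model = train_svm(t, ["f0", "f1", "f2"], reps=20, seed=seed,
                          C_grid=grid, gamma_grid=gammas)
        accs.append(model.bootstrap_accuracy)
    assert 0.4 <= np.mean(accs) <= 0.6


def test_zero_variance_feature_dropped_with_warning(caplog):
    t = separable_table()
    df = t.data.copy()
    df["f2"] = 1.0
    t2 = FeatureTable(df)
    with caplog.at_level("WARNING", logger="noduleomics"):
        model = train_svm(t2, ["f0", "f1", "f2"], reps=5, seed=0)
    assert model.features == ["f0", "f1"]
    assert any("zero-variance" in rec.message for rec in caplog.records)


# ---------------------------------------------------------------------------
# Metrics and ROC
# ---------------------------------------------------------------------------

def test_all_correct_predictions_give_unit_metrics():
    y = np.array([1, 1, 0, 0, 0])
    prob = np.array([0.9, 0.8, 0.1, 0.2, 0.3])
    rep = metrics_from_scores(y, prob)
    assert (rep.sensitivity, rep.specificity, rep.accuracy, rep.auc) == (1, 1, 1, 1)


def test_constant_probabilities_give_auc_half():
    y = np.array([1, 0, 1, 0])
    rep = metrics_from_scores(y, np.full(4, 0.5))
    assert rep.auc == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(5))
def test_auc_equals_mann_whitney_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 40
    y = rng.integers(0, 2, size=n)
    y[:2] = [0, 1]  # both classes present
    scores = np.round(rng.random(n), 1)  # coarse grid forces ties
    points = roc_curve_points(y, scores)
    assert auc_trapezoid(points) == pytest.approx(oracles.bf_auc(y, scores), abs=1e-12)


def test_roc_contract_endpoints_and_monotonicity(rng):
    y = rng.integers(0, 2, size=30)
    y[:2] = [0, 1]
    points = roc_curve_points(y, rng.random(30))
    assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)
    xs, ys = zip(*points)
    assert all(b >= a for a, b in zip(xs, xs[1:]))
    assert all(b >= a for a, b in zip(ys, ys[1:]))


def test_single_class_test_set_rejected_naming_class():
    t = separable_table()
    model = train_svm(t, ["f0", "f1"], reps=5, seed=0)
    only_lm = t.subset(t.labels == "LM")
    with pytest.raises(ValueError, match="LC"):
        evaluate(model, only_lm)


def test_metrics_invariant_to_case_order(rng):
    t = separable_table(seed=5)
    model = train_svm(t, ["f0", "f1"], reps=5, seed=1)
    rep1 = evaluate(model, t)
    shuffled = FeatureTable(t.data.sample(frac=1, random_state=4).reset_index(drop=True))
    rep2 = evaluate(model, shuffled)
    assert rep1.to_dict() == rep2.to_dict()


# ---------------------------------------------------------------------------
# Serialization and model comparison
# ---------------------------------------------------------------------------

def test_model_json_round_trip(tmp_path):
    t = separable_table(seed=7)
    model = train_svm(t, ["f0", "f1"], reps=5, seed=2)
    model.save(tmp_path / "model.json")
    back = SvmModel.load(tmp_path / "model.json")
    x = t.features(["f0", "f1"])
    np.testing.assert_allclose(back.predict_proba(x), model.predict_proba(x), atol=1e-15)


def test_report_json_round_trip():
    t = separable_table(seed=8)
    model = train_svm(t, ["f0", "f1"], reps=5, seed=3)
    rep = evaluate(model, t)
    assert MetricsReport.from_dict(rep.to_dict()) == rep


def test_identical_models_compare_identically():
    t = separable_table(seed=9)
    model = train_svm(t, ["f0", "f1"], reps=5, seed=4)
    out = compare_models(model, model, t)
    assert out["intranodular"].to_dict() == out["combined"].to_dict()


def test_combined_model_beats_intra_when_signal_is_perinodular():
    """With the only informative feature tagged peri, the combined model's
    held-out AUC should on average exceed the intra-only model's."""
    deltas = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        y = np.tile([1, 0], 60)  # interleaved so both splits hold both classes
        x = rng.normal(size=(120, 2))
        x[y == 1, 1] += 1.5  # feature 1 = perinodular signal
        df = pd.DataFrame(x, columns=["tex_intra", "tex_peri"])
        df.insert(0, "case_id", [f"c{i}" for i in range(120)])
        df.insert(1, "label", np.where(y == 1, "LC", "LM"))
        df.insert(2, "split", ["train"] * 80 + ["test"] * 40)
        table = FeatureTable(df)
        tr, te = table.split("train"), table.split("test")
        intra = train_svm(tr, ["tex_intra"], reps=10, seed=seed)
        comb = train_svm(tr, ["tex_intra", "tex_peri"], reps=10, seed=seed)
        out = compare_models(intra, comb, te)
        deltas.append(out["combined"].auc - out["intranodular"].auc)
    assert np.mean(deltas) > 0
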