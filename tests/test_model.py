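"""Classification protocol: feature screen against a closed-form t-test
oracle, training determinism, ensembles, the random control, and planted
signal recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutwave.datasets import LearningDataset
from gutwave.errors import (
    AlgorithmIncompatibleError,
    DegenerateLabelsError,
    InvalidArgumentError,
    NoSignificantFeaturesError,
)
from gutwave.model import (
    AEClassifier,
    ensemble_predict,
    evaluate,
    make_random_control,
    permute_labels,
    predict,
    run_protocol,
    select_features,
    train,
    validate_against_control,
)


def gaussian_dataset(
    n_per_class=50,
    n_features=8,
    n_informative=3,
    d=2.0,
    seed=0,
    kind="tissue_split",
    n_drugs=None,
):
    """Synthetic Gaussian dataset with `n_informative` mean-shifted features."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.normal(size=(n, n_features))
    y = np.array([1] * n_per_class + [0] * n_per_class)
    X[y == 1, :n_informative] += d
    cols = [f"f{i}" for i in range(n_features)]
    n_drugs = n_drugs or n
    meta = pd.DataFrame(
        {
            "drug_id": [f"drug{i % n_drugs:03d}" for i in range(n)],
            "dose": 1e-5,
            "dose_rank": 1,
            "tissue": "colon",
            "repeat": 0,
        }
    )
    return LearningDataset(
        X=pd.DataFrame(X, columns=cols),
        y=pd.Series(y, name="label"),
        meta=meta,
        ae="nausea",
        kind=kind,
        ratio=0.5,
    )


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def ttest_oracle(a, b):
    """Closed-form pooled-variance two-sample t-test p-value."""
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    t = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2.0 * stats.t.sf(abs(t), na + nb - 2)


def test_pvalues_match_closed_form_oracle():
    ds = gaussian_dataset(d=2.0, seed=1)
    sel = select_features(ds)
    for col in ds.X.columns:
        a = ds.X[col][ds.y == 1].values
        b = ds.X[col][ds.y == 0].values
        assert sel.pvalues[col] == pytest.approx(ttest_oracle(a, b), abs=1e-10)
    for i in range(3):
        assert f"f{i}" in sel.selected
        assert sel.pvalues[f"f{i}"] < 1e-6


def test_identical_groups_not_selected():
    ds = gaussian_dataset(d=0.0, seed=2)
    ds.X["f0"] = 1.0  # constant in both groups
    sel = select_features(ds)
    assert sel.pvalues["f0"] == 1.0
    assert "f0" not in sel.selected


def test_single_class_degenerate():
    ds = gaussian_dataset()
    ds.y[:] = 1
    with pytest.raises(DegenerateLabelsError):
        select_features(ds)


def test_no_selected_features_aborts_protocol():
    rng = np.random.default_rng(0)
    ds = gaussian_dataset(d=0.0, n_features=2, seed=3)
    # Force clearly non-significant columns.
    ds.X.iloc[:, 0] = rng.normal(size=ds.n_rows)
    ds.X.iloc[:, 1] = ds.y.values * 0.0 + rng.normal(size=ds.n_rows) * 1e-3
    tries = 0
    while select_features(ds).selected and tries < 20:
        ds.X.iloc[:] = rng.normal(size=ds.X.shape)
        tries += 1
    with pytest.raises(NoSignificantFeaturesError):
        run_protocol(ds, master_seed=0)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


def test_training_deterministic():
    ds = gaussian_dataset(seed=4)
    sel = select_features(ds)
    m1 = train(ds, sel, "knn", seed=5)
    m2 = train(ds, sel, "knn", seed=5)
    assert np.array_equal(m1.train_idx, m2.train_idx)
    s1, c1 = predict(m1, ds.X)
    s2, c2 = predict(m2, ds.X)
    assert np.array_equal(s1, s2) and np.array_equal(c1, c2)


@pytest.mark.parametrize("algorithm", ["tree", "knn"])
def test_separable_data_training_accuracy(algorithm):
    ds = gaussian_dataset(d=8.0, seed=6)  # essentially separable
    sel = select_features(ds)
    model = train(ds, sel, algorithm, seed=1)
    _, pred = predict(model, ds.X.iloc[model.train_idx])
    acc = evaluate(ds.y.iloc[model.train_idx].values, pred).accuracy
    assert acc == 1.0


def test_discriminant_incompatible_with_missing():
    ds = gaussian_dataset(kind="averaged", seed=7)
    ds.X.iloc[0, 0] = np.nan
    sel = select_features(ds)
    with pytest.raises(AlgorithmIncompatibleError):
        train(ds, sel, "discriminant", seed=0)


def test_nan_tolerant_naive_bayes_on_missing():
    ds = gaussian_dataset(kind="averaged", d=3.0, seed=8)
    ds.X.iloc[::7, 2] = np.nan
    sel = select_features(ds)
    model = train(ds, sel, "naive_bayes", seed=0)
    _, pred = predict(model, ds.X.iloc[model.test_idx])
    acc = evaluate(ds.y.iloc[model.test_idx].values, pred).accuracy
    assert acc > 0.8


def test_score_half_is_negative_class():
    ds = gaussian_dataset(seed=9)
    sel = select_features(ds)
    models = [train(ds, sel, a, seed=0) for a in ("naive_bayes", "tree", "knn", "svm")]
    # Force a 2-2 vote by duplicating two models' votes.
    scores, classes = ensemble_predict(models[:4], ds.X)
    tied = np.isclose(scores, 0.5)
    assert np.all(classes[tied] == 0)


def test_ensemble_vote_arithmetic():
    class Const:
        def __init__(self, c):
            self.c = c

        def predict_proba(self, Z):
            p = np.full((len(Z), 2), [1 - self.c, self.c], dtype=float)
            return p

        classes_ = np.array([0, 1])

    from gutwave.model import TrainedModel

    def const_model(c):
        return TrainedModel(
            algorithm="naive_bayes",
            estimator=Const(c),
            features=["f0"],
            mean_=np.zeros(1),
            scale_=np.ones(1),
            seed=0,
            train_idx=np.array([0]),
            test_idx=np.array([0]),
        )

    rows = pd.DataFrame({"f0": [0.0]})
    s, c = ensemble_predict([const_model(1), const_model(1), const_model(0)], rows)
    assert s[0] == pytest.approx(2 / 3) and c[0] == 1
    s, c = ensemble_predict(
        [const_model(1), const_model(1), const_model(0), const_model(0)], rows
    )
    assert s[0] == 0.5 and c[0] == 0  # strict > 0.5
    with pytest.raises(InvalidArgumentError):
        ensemble_predict([], rows)


def test_evaluation_confusion_rates():
    ev = evaluate([1, 1, 0, 0], [1, 0, 0, 0])
    assert (ev.accuracy, ev.tpr, ev.tnr) == (0.75, 0.5, 1.0)
    assert evaluate([1, 0], [1, 0]).accuracy == 1.0
    assert evaluate([1, 0], [0, 1]).accuracy == 0.0
    with pytest.raises(InvalidArgumentError):
        evaluate([], [])


# ---------------------------------------------------------------------------
# Random control and validation rule
# ---------------------------------------------------------------------------


def test_random_control_moments_and_labels():
    ds = gaussian_dataset(n_per_class=100, seed=10)
    ctrl = make_random_control(ds, seed=1)
    assert ctrl.y.equals(ds.y)
    n = ds.n_rows
    for col in ds.X.columns:
        mu, sd = ds.X[col].mean(), ds.X[col].std(ddof=1)
        se_mean = sd / np.sqrt(n)
        assert abs(ctrl.X[col].mean() - mu) < 3 * se_mean
        se_sd = sd / np.sqrt(2 * (n - 1))
        assert abs(ctrl.X[col].std(ddof=1) - sd) < 3 * se_sd


def test_control_destroys_planted_separation():
    hits = 0
    for seed in range(20):
        ds = gaussian_dataset(d=1.5, seed=100 + seed)
        n_actual = len(select_features(ds).selected)
        ctrl = make_random_control(ds, seed=seed)
        try:
            n_ctrl = len(select_features(ctrl).selected)
        except DegenerateLabelsError:  # pragma: no cover
            n_ctrl = 0
        hits += n_ctrl < n_actual
    assert hits >= 18  # >= 90% of seeds


def test_validation_margin_rule():
    assert validate_against_control(0.670, 0.70, 0.660, 0.70).passed
    assert not validate_against_control(0.662, 0.700, 0.660, 0.698).passed
    assert validate_against_control(0.5, 0.5, None, None).control_aborted


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------


def test_protocol_counts_and_determinism():
    ds = gaussian_dataset(d=1.0, seed=11)
    table, models, sel, seeds = run_protocol(ds, master_seed=3)
    assert len(seeds) == 7
    for alg in ds.applicable_algorithms() + ("ensemble",):
        assert (table.algorithm == alg).sum() == 7
    table2, *_ = run_protocol(ds, master_seed=3)
    pd.testing.assert_frame_equal(table, table2)


def test_row_permutation_invariance():
    ds = gaussian_dataset(d=1.0, seed=12)
    rng = np.random.default_rng(0)
    perm = rng.permutation(ds.n_rows)
    ds_perm = LearningDataset(
        X=ds.X.iloc[perm].reset_index(drop=True),
        y=ds.y.iloc[perm].reset_index(drop=True),
        meta=ds.meta.iloc[perm].reset_index(drop=True),
        ae=ds.ae,
        kind=ds.kind,
        ratio=ds.ratio,
    )
    t1, *_ = run_protocol(ds, algorithms=("naive_bayes", "knn"), master_seed=5)
    t2, *_ = run_protocol(ds_perm, algorithms=("naive_bayes", "knn"), master_seed=5)
    assert np.allclose(t1["accuracy"].values, t2["accuracy"].values)


def test_permuted_labels_accuracy_near_chance():
    ds = gaussian_dataset(n_per_class=100, d=1.5, seed=13)
    accs = []
    for s in range(5):
        null = permute_labels(ds, seed=s)
        try:
            table, *_ = run_protocol(null, master_seed=s)
        except NoSignificantFeaturesError:
            continue
        accs.append(table["accuracy"].mean())
    if accs:  # abort at selection is an acceptable null outcome
        n_test = ds.n_rows // 2
        se = np.sqrt(0.25 / n_test) / np.sqrt(len(accs) * 7)
        assert abs(np.mean(accs) - 0.5) < 3 * np.sqrt(0.25 / n_test)


def test_accuracy_monotone_in_planted_effect_size():
    means = []
    for d in (0.25, 0.5, 1.0, 2.0):
        accs = []
        for seed in range(10):
            ds = gaussian_dataset(n_per_class=60, d=d, seed=200 + seed)
            try:
                table, *_ = run_protocol(
                    ds, algorithms=("naive_bayes", "discriminant"), master_seed=seed
                )
                accs.append(table["accuracy"].mean())
            except NoSignificantFeaturesError:
                accs.append(0.5)
        means.append(np.mean(accs))
    assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
    assert means[-1] > means[0]


def test_model_results_surface():
    ds = gaussian_dataset(d=1.5, seed=14)
    results = AEClassifier(ds).fit(seed=2)
    assert results.best_accuracy >= results.table["accuracy"].mean() - 1e-12
    assert 0 <= results.mean_accuracy <= 1
    assert len(results.best_models_per_randomization()) == 7
    validation = results.validate(seed=3)
    text = results.summary()
    assert "mean accuracy" in text and ds.ae in text
    assert validation.passed  # strong planted signal beats the control


def test_drug_split_mode_keeps_drugs_on_one_side():
    ds = gaussian_dataset(d=1.0, seed=15, n_drugs=20)
    from gutwave.model import split_rows

    tr, te = split_rows(ds, seed=0, mode="drug")
    tr_drugs = set(ds.meta["drug_id"].iloc[tr])
    te_drugs = set(ds.meta["drug_id"].iloc[te])
    assert tr_drugs.isdisjoint(te_drugs)
    assert len(tr) + len(te) == ds.n_rows
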