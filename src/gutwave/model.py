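"""The classification protocol: t-test feature refinement, five classifier
families plus an ensemble, seven randomized half/half splits, and the
random-dataset validation control.

The public surface follows the statsmodels convention: build an
:class:`AEClassifier` from a :class:`~gutwave.datasets.LearningDataset`,
call :meth:`AEClassifier.fit` to obtain :class:`AEClassifierResults` with
per-randomization evaluations, a best model, and a ``summary()`` table;
``results.validate()`` re-runs the protocol on a Gaussian-resampled control
dataset and applies the >0.5-point margin rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datasets import LearningDataset
from .errors import (
    AlgorithmIncompatibleError,
    DegenerateLabelsError,
    InvalidArgumentError,
    NoSignificantFeaturesError,
)

ALGORITHMS = ("naive_bayes", "discriminant", "tree", "knn", "svm")


# ---------------------------------------------------------------------------
# Feature refinement
# ---------------------------------------------------------------------------


@dataclass
class FeatureSelection:
    ae: str
    selected: list
    pvalues: pd.Series

    def __post_init__(self):
        sel = set(self.pvalues.index[self.pvalues < 0.05])
        if set(self.selected) != sel:
            raise InvalidArgumentError("selected features must be exactly p < 0.05")


def select_features(ds: LearningDataset, alpha: float = 0.05) -> FeatureSelection:
    """Two-sample pooled-variance t-test per feature; keep p < alpha.

    Missing values are dropped pairwise; features constant in both groups
    get p = 1. Raises :class:`DegenerateLabelsError` when only one class is
    present.
    """
    y = ds.y.values
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(ds.ae)
    pos = ds.X.values[y == 1]
    neg = ds.X.values[y == 0]
    res = stats.ttest_ind(pos, neg, axis=0, equal_var=True, nan_policy="omit")
    pvals = np.asarray(res.pvalue, dtype=float)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    pseries = pd.Series(pvals, index=ds.X.columns)
    selected = list(pseries.index[pseries < alpha])
    return FeatureSelection(ae=ds.ae, selected=selected, pvalues=pseries)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class NaNGaussianNB:
    """Gaussian naive Bayes that ignores missing features per row.

    Used for averaged datasets with untested tissues; matches sklearn's
    GaussianNB on complete data up to variance smoothing.
    """

    def fit(self, X, y):
        X, y = np.asarray(X, float), np.asarray(y, int)
        self.classes_ = np.unique(y)
        self.theta_, self.var_, self.prior_ = [], [], []
        vmax = np.nanvar(X) if np.isfinite(np.nanvar(X)) else 1.0
        self.eps_ = 1e-9 * max(vmax, 1e-12)
        for c in self.classes_:
            sub = X[y == c]
            self.theta_.append(np.nanmean(sub, axis=0))
            self.var_.append(np.nanvar(sub, axis=0) + self.eps_)
            self.prior_.append(len(sub) / len(X))
        self.theta_, self.var_ = np.array(self.theta_), np.array(self.var_)
        self.prior_ = np.array(self.prior_)
        return self

    def predict_proba(self, X):
        X = np.asarray(X, float)
        logp = np.zeros((len(X), len(self.classes_)))
        for k in range(len(self.classes_)):
            ll = -0.5 * (
                np.log(2 * np.pi * self.var_[k]) + (X - self.theta_[k]) ** 2 / self.var_[k]
            )
            logp[:, k] = np.nansum(ll, axis=1) + np.log(self.prior_[k])
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "discriminant":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
    if algorithm == "tree":
        return DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=3, random_state=seed
        )
    if algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if algorithm == "svm":
        return SVC(kernel="linear", C=1.0)
    raise InvalidArgumentError(f"unknown algorithm {algorithm!r}")


@dataclass
class TrainedModel:
    """One fitted classifier with its split, scaling and selected features."""

    algorithm: str
    estimator: object
    features: list
    mean_: np.ndarray
    scale_: np.ndarray
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise InvalidArgumentError(f"rows missing model features: {missing}")
        Z = X[self.features].values.astype(float)
        return (Z - self.mean_) / self.scale_


def split_rows(ds: LearningDataset, seed: int, mode: str = "row"):
    """Stratified half/half split of dataset rows.

    ``row`` mode splits rows directly (repeats of one drug may land on both
    sides); ``drug`` mode splits whole drugs so no drug crosses the split.
    """
    idx = np.arange(ds.n_rows)
    # Canonical condition order: the split then depends only on which
    # conditions exist, not on the storage order of the rows.
    m = ds.meta
    order = np.lexsort(
        (
            m["repeat"].to_numpy(),
            m["tissue"].astype(str).to_numpy(),
            m["dose_rank"].to_numpy(),
            m["drug_id"].astype(str).to_numpy(),
        )
    )
    if mode == "row":
        train, test = train_test_split(
            idx[order], test_size=0.5, stratify=ds.y.values[order], random_state=seed
        )
    elif mode == "drug":
        drugs = ds.drug_ids.values
        uniq = np.sort(pd.unique(drugs))
        drug_label = pd.Series(ds.y.values, index=drugs).groupby(level=0).max()
        tr_drugs, te_drugs = train_test_split(
            uniq, test_size=0.5, stratify=drug_label[uniq].values, random_state=seed
        )
        train = idx[np.isin(drugs, tr_drugs)]
        test = idx[np.isin(drugs, te_drugs)]
    else:
        raise InvalidArgumentError(f"unknown split mode {mode!r}")
    return np.sort(train), np.sort(test)


def train(
    ds: LearningDataset,
    selection: FeatureSelection,
    algorithm: str,
    seed: int,
    split_mode: str = "row",
) -> TrainedModel:
    """Fit one algorithm on a stratified half split with standardized
    selected features."""
    if algorithm not in ds.applicable_algorithms():
        raise AlgorithmIncompatibleError(
            f"{algorithm} not applicable to {ds.kind} dataset"
            + (" with missing features" if ds.has_missing else "")
        )
    if not selection.selected:
        raise NoSignificantFeaturesError(ds.ae)
    train_idx, test_idx = split_rows(ds, seed, split_mode)
    Xtr = ds.X.iloc[train_idx][selection.selected].values.astype(float)
    mean = np.nanmean(Xtr, axis=0)
    scale = np.nanstd(Xtr, axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Ztr = (Xtr - mean) / scale
    est = _make_estimator(algorithm, seed)
    if algorithm == "naive_bayes" and np.isnan(Ztr).any():
        est = NaNGaussianNB()
    est.fit(Ztr, ds.y.iloc[train_idx].values)
    return TrainedModel(
        algorithm=algorithm,
        estimator=est,
        features=list(selection.selected),
        mean_=mean,
        scale_=scale,
        seed=seed,
        train_idx=train_idx,
        test_idx=test_idx,
    )


def predict(model: TrainedModel, rows: pd.DataFrame):
    """Per-row positive-class score in [0, 1] and binary class (score > 0.5)."""
    Z = model.transform(rows)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(Z)
        classes = getattr(est, "classes_", np.array([0, 1]))
        col = int(np.argmax(classes == 1)) if 1 in classes else proba.shape[1] - 1
        scores = proba[:, col]
        if 1 not in classes:
            scores = np.zeros(len(Z))
    else:
        margin = est.decision_function(Z)
        scores = 1.0 / (1.0 + np.exp(-margin))
    scores = np.asarray(scores, dtype=float)
    return scores, (scores > 0.5).astype(int)


def ensemble_predict(models: list, rows: pd.DataFrame):
    """Unweighted mean of member binary votes; class = score > 0.5."""
    if not models:
        raise InvalidArgumentError("empty model list")
    votes = np.stack([predict(m, rows)[1] for m in models])
    scores = votes.mean(axis=0)
    return scores, (scores > 0.5).astype(int)


@dataclass
class Evaluation:
    accuracy: float
    tpr: float
    tnr: float


def evaluate(y_true, y_pred) -> Evaluation:
    """Confusion-matrix rates on a labelled test set."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.size == 0:
        raise InvalidArgumentError("empty test set")
    acc = float(np.mean(y_true == y_pred))
    pos, neg = y_true == 1, y_true == 0
    tpr = float(np.mean(y_pred[pos] == 1)) if pos.any() else float("nan")
    tnr = float(np.mean(y_pred[neg] == 0)) if neg.any() else float("nan")
    return Evaluation(accuracy=acc, tpr=tpr, tnr=tnr)


# ---------------------------------------------------------------------------
# Random-dataset control and validation
# ---------------------------------------------------------------------------


def make_random_control(ds: LearningDataset, seed: int) -> LearningDataset:
    """Same shape and labels, each feature resampled independently from
    Normal(column mean, column sample SD)."""
    rng = np.random.default_rng(seed)
    X = ds.X.values.astype(float)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        ok = np.isfinite(col)
        mu = col[ok].mean() if ok.any() else 0.0
        sd = col[ok].std(ddof=1) if ok.sum() > 1 else 0.0
        out[:, j] = rng.normal(mu, sd, size=len(col))
        out[~ok, j] = np.nan
    return LearningDataset(
        X=pd.DataFrame(out, columns=ds.X.columns, index=ds.X.index),
        y=ds.y.copy(),
        meta=ds.meta.copy(),
        ae=ds.ae,
        kind=ds.kind,
        ratio=ds.ratio,
        tissue=ds.tissue,
    )


def permute_labels(ds: LearningDataset, seed: int) -> LearningDataset:
    """Row-level label permutation (breaks the drug-label link so that
    repeat leakage across the half split cannot recover the labels)."""
    rng = np.random.default_rng(seed)
    y = ds.y.values.copy()
    rng.shuffle(y)
    return LearningDataset(
        X=ds.X.copy(),
        y=pd.Series(y, index=ds.y.index, name="label"),
        meta=ds.meta.copy(),
        ae=ds.ae,
        kind=ds.kind,
        ratio=ds.ratio,
        tissue=ds.tissue,
    )


@dataclass
class ValidationResult:
    passed: bool
    margin_points: float
    actual_mean: float
    actual_best: float
    control_mean: float = float("nan")
    control_best: float = float("nan")
    control_aborted: bool = False


def validate_against_control(
    actual_mean: float,
    actual_best: float,
    control_mean: float | None,
    control_best: float | None,
    margin_points: float = 0.5,
) -> ValidationResult:
    """Pass iff the actual model beats the control by more than the margin
    (in accuracy points) in either mean or best accuracy, or the control
    failed to select any feature. Accuracies are fractions in [0, 1]."""
    if control_mean is None or control_best is None:
        return ValidationResult(
            passed=True,
            margin_points=margin_points,
            actual_mean=actual_mean,
            actual_best=actual_best,
            control_aborted=True,
        )
    mean_margin = (actual_mean - control_mean) * 100.0
    best_margin = (actual_best - control_best) * 100.0
    return ValidationResult(
        passed=mean_margin > margin_points or best_margin > margin_points,
        margin_points=margin_points,
        actual_mean=actual_mean,
        actual_best=actual_best,
        control_mean=control_mean,
        control_best=control_best,
    )


# ---------------------------------------------------------------------------
# Protocol
# ---------------------------------------------------------------------------


def _protocol_seeds(master_seed: int, n: int) -> list:
    return [int(s % (2**31)) for s in np.random.SeedSequence(int(master_seed)).generate_state(n)]


def run_protocol(
    ds: LearningDataset,
    algorithms=None,
    n_randomizations: int = 7,
    master_seed: int = 0,
    split_mode: str = "row",
    coverage_threshold: float = 0.8,
):
    """Randomize, train and evaluate ``n_randomizations`` times.

    Returns ``(table, models, selection, seeds)`` where ``table`` has one
    row per (randomization, algorithm or ensemble) with accuracy, TPR, TNR
    and training-half drug coverage, and ``models`` maps
    (randomization, algorithm) to the fitted :class:`TrainedModel`.
    """
    selection = select_features(ds)
    if not selection.selected:
        raise NoSignificantFeaturesError(ds.ae)
    if algorithms is None:
        algorithms = ds.applicable_algorithms()
    else:
        bad = [a for a in algorithms if a not in ds.applicable_algorithms()]
        if bad:
            raise AlgorithmIncompatibleError(f"{bad} not applicable to {ds.kind}")
    seeds = _protocol_seeds(master_seed, n_randomizations)
    n_drugs = ds.drug_ids.nunique()
    rows, models = [], {}
    for i, seed in enumerate(seeds):
        fitted = []
        for alg in algorithms:
            model = train(ds, selection, alg, seed, split_mode)
            models[(i, alg)] = model
            fitted.append(model)
            y_te = ds.y.iloc[model.test_idx].values
            _, pred = predict(model, ds.X.iloc[model.test_idx])
            ev = evaluate(y_te, pred)
            coverage = ds.drug_ids.iloc[model.train_idx].nunique() / n_drugs
            rows.append(
                dict(
                    randomization=i,
                    seed=seed,
                    algorithm=alg,
                    accuracy=ev.accuracy,
                    tpr=ev.tpr,
                    tnr=ev.tnr,
                    coverage=coverage,
                    covered=coverage > coverage_threshold,
                )
            )
        # Ensemble over this randomization's members (same split for all).
        ref = fitted[0]
        _, pred = ensemble_predict(fitted, ds.X.iloc[ref.test_idx])
        ev = evaluate(ds.y.iloc[ref.test_idx].values, pred)
        coverage = ds.drug_ids.iloc[ref.train_idx].nunique() / n_drugs
        rows.append(
            dict(
                randomization=i,
                seed=seed,
                algorithm="ensemble",
                accuracy=ev.accuracy,
                tpr=ev.tpr,
                tnr=ev.tnr,
                coverage=coverage,
                covered=coverage > coverage_threshold,
            )
        )
    table = pd.DataFrame(rows)
    return table, models, selection, seeds


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class AEClassifier:
    """Adverse-effect classification model for one learning dataset.

    Parameters
    ----------
    dataset : LearningDataset
        Features, labels and metadata for one AE.
    algorithms : sequence of str, optional
        Subset of the five classifier families; defaults to the families
        applicable to the dataset kind.
    n_randomizations : int
        Number of randomized half/half splits (7 by default; odd to avoid
        tied ensemble votes downstream).
    split_mode : str
        'row' (default) or 'drug'.
    """

    def __init__(
        self,
        dataset: LearningDataset,
        algorithms=None,
        n_randomizations: int = 7,
        split_mode: str = "row",
        coverage_threshold: float = 0.8,
        validation_margin_points: float = 0.5,
    ):
        self.dataset = dataset
        self.algorithms = tuple(algorithms) if algorithms else None
        self.n_randomizations = int(n_randomizations)
        self.split_mode = split_mode
        self.coverage_threshold = coverage_threshold
        self.validation_margin_points = validation_margin_points

    @classmethod
    def from_dataframe(
        cls, features: pd.DataFrame, labels: pd.Series, ae: str = "ae", **kwargs
    ) -> "AEClassifier":
        """Build from a plain feature frame and aligned binary labels.

        A ``drug_id`` column, if present, is moved to the metadata.
        """
        features = features.reset_index(drop=True)
        labels = pd.Series(np.asarray(labels, int), name="label")
        drug = features.pop("drug_id") if "drug_id" in features else pd.Series(
            [f"row{i}" for i in range(len(features))]
        )
        meta = pd.DataFrame(
            {
                "drug_id": drug,
                "dose": np.nan,
                "dose_rank": -1,
                "tissue": "all",
                "repeat": -1,
            }
        )
        ds = LearningDataset(
            X=features,
            y=labels,
            meta=meta,
            ae=ae,
            kind="averaged",
            ratio=float(labels.mean()),
        )
        return cls(ds, **kwargs)

    def fit(self, seed: int = 0) -> "AEClassifierResults":
        table, models, selection, seeds = run_protocol(
            self.dataset,
            algorithms=self.algorithms,
            n_randomizations=self.n_randomizations,
            master_seed=seed,
            split_mode=self.split_mode,
            coverage_threshold=self.coverage_threshold,
        )
        return AEClassifierResults(self, table, models, selection, seeds, seed)


@dataclass
class AEClassifierResults:
    """Fitted protocol: per-randomization evaluations and the best model."""

    model: AEClassifier
    table: pd.DataFrame
    models: dict
    selection: FeatureSelection
    seeds: list
    master_seed: int
    _validation: ValidationResult | None = field(default=None, repr=False)

    @property
    def mean_accuracy(self) -> float:
        return float(self.table["accuracy"].mean())

    @property
    def best_accuracy(self) -> float:
        t = self._covered()
        return float(t["accuracy"].max())

    def _covered(self) -> pd.DataFrame:
        t = self.table[self.table["covered"]]
        return t if len(t) else self.table

    @property
    def coverage_ok(self) -> bool:
        return bool(self.table["covered"].all())

    @property
    def best_row(self) -> pd.Series:
        t = self._covered().copy()
        t = t.sort_values(
            ["accuracy", "tpr", "randomization"], ascending=[False, False, True]
        )
        return t.iloc[0]

    def best_model(self) -> TrainedModel | None:
        row = self.best_row
        if row["algorithm"] == "ensemble":
            i = int(row["randomization"])
            members = [m for (j, _), m in self.models.items() if j == i]
            return members[0] if len(members) == 1 else None
        return self.models[(int(row["randomization"]), row["algorithm"])]

    def best_models_per_randomization(self) -> list:
        """For each randomization, the single member model with the highest
        test accuracy (ties: higher TPR, then algorithm order)."""
        out = []
        t = self.table[self.table["algorithm"] != "ensemble"]
        for i in sorted(t["randomization"].unique()):
            sub = t[t["randomization"] == i].sort_values(
                ["accuracy", "tpr"], ascending=False
            )
            out.append(self.models[(int(i), sub.iloc[0]["algorithm"])])
        return out

    def validate(self, seed: int | None = None) -> ValidationResult:
        """Re-run the protocol on the Gaussian random control and apply the
        margin rule; a control that selects no feature counts as a pass."""
        if seed is None:
            seed = self.master_seed + 104729
        control = make_random_control(self.model.dataset, seed)
        try:
            table, *_ = run_protocol(
                control,
                algorithms=self.model.algorithms,
                n_randomizations=self.model.n_randomizations,
                master_seed=self.master_seed,
                split_mode=self.model.split_mode,
                coverage_threshold=self.model.coverage_threshold,
            )
        except NoSignificantFeaturesError:
            result = validate_against_control(
                self.mean_accuracy,
                self.best_accuracy,
                None,
                None,
                self.model.validation_margin_points,
            )
            self._validation = result
            return result
        c_mean = float(table["accuracy"].mean())
        c_best = float(table[table["covered"]]["accuracy"].max() if table["covered"].any() else table["accuracy"].max())
        result = validate_against_control(
            self.mean_accuracy,
            self.best_accuracy,
            c_mean,
            c_best,
            self.model.validation_margin_points,
        )
        self._validation = result
        return result

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "AE classification protocol results",
            "=" * 50,
            f"AE:                 {ds.ae}",
            f"dataset kind:       {ds.kind}" + (f" ({ds.tissue})" if ds.tissue else ""),
            f"rows / drugs:       {ds.n_rows} / {ds.drug_ids.nunique()}",
            f"balance ratio:      {ds.ratio:.3f}",
            f"selected features:  {len(self.selection.selected)}",
            f"randomizations:     {self.model.n_randomizations}",
            f"mean accuracy:      {self.mean_accuracy:.3f}",
            f"best accuracy:      {self.best_accuracy:.3f}",
            f"coverage > {self.model.coverage_threshold:.0%}:     {self.coverage_ok}",
        ]
        if self._validation is not None:
            v = self._validation
            status = "PASS" if v.passed else "FAIL"
            extra = " (control aborted at selection)" if v.control_aborted else ""
            lines.append(f"validation:         {status}{extra}")
        lines.append("-" * 50)
        per_alg = (
            self.table.groupby("algorithm")["accuracy"]
            .agg(["mean", "max"])
            .sort_values("mean", ascending=False)
        )
        lines.append(f"{'algorithm':<14}{'mean acc':>10}{'best acc':>10}")
        for alg, row in per_alg.iterrows():
            lines.append(f"{alg:<14}{row['mean']:>10.3f}{row['max']:>10.3f}")
        return "\n".join(lines)
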