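"""Learning-dataset assembly: percentage-change normalization, label merge
with the indication override, balance-ratio filtering, and the three dataset
kinds (averaged, full, tissue-split).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateBaselineError,
    InvalidArgumentError,
)
from .recording import DIFFERENCE_FEATURES, FEATURE_NAMES, TISSUES

log = logging.getLogger(__name__)

META_COLUMNS = ("drug_id", "dose", "dose_rank", "tissue", "repeat")

PROVENANCE = ("absent", "sider_positive", "indication_override")


def normalize_features(baseline: pd.Series, post: pd.Series) -> pd.Series:
    """Percentage-change normalization of one baseline/post feature pair.

    Unit-bearing features map to ``(post - baseline) / baseline * 100``;
    features already expressed as percentages (and the bounded pattern-change
    index) map to the plain difference ``post - baseline``.
    """
    out = {}
    for name in FEATURE_NAMES:
        b, p = float(baseline[name]), float(post[name])
        if name in DIFFERENCE_FEATURES:
            out[name] = p - b
        else:
            if abs(b) < 1e-12:
                raise DegenerateBaselineError(f"zero baseline for {name}")
            out[name] = (p - b) / b * 100.0
    return pd.Series([out[k] for k in FEATURE_NAMES], index=list(FEATURE_NAMES))


@dataclass
class AELabelTable:
    """Binary drug x adverse-effect labels with per-cell provenance."""

    labels: pd.DataFrame  # int {0,1}, index=drugs, columns=AEs
    provenance: pd.DataFrame  # str, same shape

    def __post_init__(self):
        if self.labels.shape != self.provenance.shape:
            raise InvalidArgumentError("labels/provenance shape mismatch")
        override = self.provenance.values == "indication_override"
        if np.any(self.labels.values[override] != 0):
            raise InvalidArgumentError("indication override must force label 0")

    @property
    def drugs(self) -> list:
        return list(self.labels.index)

    @property
    def aes(self) -> list:
        return list(self.labels.columns)

    def ratio(self, ae: str) -> float:
        return balance_ratio(self.labels[ae])


def assign_labels(raw_rows: pd.DataFrame, drugs, aes) -> AELabelTable:
    """Merge raw (drug, AE, role) rows into a binary label table.

    A drug is labelled 1 for an AE iff a side-effect row exists and no
    indication row exists for the pair; an indication row forces 0
    regardless (override). AE names are matched exactly on canonical
    lower-cased names. Rows for unknown drugs are logged and skipped.
    """
    drugs, aes = list(drugs), [a.lower() for a in aes]
    labels = pd.DataFrame(0, index=drugs, columns=aes, dtype=int)
    prov = pd.DataFrame("absent", index=drugs, columns=aes)
    if len(raw_rows):
        rows = raw_rows.copy()
        rows["ae_name"] = rows["ae_name"].str.lower()
        unknown = ~rows["drug_id"].isin(drugs)
        if unknown.any():
            log.warning(
                "skipping %d label rows for unknown drugs: %s",
                int(unknown.sum()),
                sorted(rows.loc[unknown, "drug_id"].unique()),
            )
            rows = rows[~unknown]
        rows = rows[rows["ae_name"].isin(aes)]
        for (drug, ae), grp in rows.groupby(["drug_id", "ae_name"], sort=False):
            roles = set(grp["role"])
            if "indication" in roles:
                prov.loc[drug, ae] = "indication_override"
            elif "side_effect" in roles:
                labels.loc[drug, ae] = 1
                prov.loc[drug, ae] = "sider_positive"
    return AELabelTable(labels=labels, provenance=prov)


def balance_ratio(labels: pd.Series) -> float:
    """Positive drugs / total drugs for one AE."""
    if len(labels) == 0:
        raise InvalidArgumentError("no drugs")
    return float(np.asarray(labels).sum() / len(labels))


def filter_balanced(table: AELabelTable, low: float = 0.25, high: float = 0.75) -> list:
    """AEs whose balance ratio lies inside [low, high] (strict exclusion
    outside: ratios < low or > high are imbalanced)."""
    return [ae for ae in table.aes if low <= table.ratio(ae) <= high]


@dataclass
class LearningDataset:
    """Feature matrix + binary labels for one AE, in one of three kinds."""

    X: pd.DataFrame
    y: pd.Series
    meta: pd.DataFrame
    ae: str
    kind: str  # 'averaged' | 'full' | 'tissue_split'
    ratio: float
    tissue: str | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.X.index.equals(self.y.index) and self.X.index.equals(self.meta.index)):
            raise InvalidArgumentError("rows of X, y and meta must align")
        if self.kind not in ("averaged", "full", "tissue_split"):
            raise InvalidArgumentError(f"unknown dataset kind {self.kind!r}")

    @property
    def has_missing(self) -> bool:
        return bool(self.X.isna().any().any())

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def drug_ids(self) -> pd.Series:
        return self.meta["drug_id"]

    def applicable_algorithms(self) -> tuple:
        """Algorithm families usable on this dataset.

        Full (single-row) datasets use the three NaN-tolerant families;
        averaged and tissue-split datasets use all five unless missing
        values exclude discriminant analysis and the SVM.
        """
        if self.kind == "full":
            return ("naive_bayes", "tree", "knn")
        if self.has_missing:
            return ("naive_bayes", "tree", "knn")
        return ("naive_bayes", "discriminant", "tree", "knn", "svm")


def _check_norm_rows(rows: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in rows.columns]
    missing += [c for c in FEATURE_NAMES if c not in rows.columns]
    if missing:
        raise InvalidArgumentError(f"normalized rows missing columns: {missing}")
    if len(rows) == 0:
        raise InvalidArgumentError("no normalized rows")


def build_full_dataset(
    rows: pd.DataFrame, table: AELabelTable, ae: str
) -> LearningDataset:
    """One row per (drug, dose, tissue, repeat) with the 24 feature columns;
    every row inherits its drug's AE label."""
    _check_norm_rows(rows)
    rows = rows.reset_index(drop=True)
    y = rows["drug_id"].map(table.labels[ae]).astype(int)
    return LearningDataset(
        X=rows[list(FEATURE_NAMES)].copy(),
        y=y.rename("label"),
        meta=rows[list(META_COLUMNS)].copy(),
        ae=ae,
        kind="full",
        ratio=table.ratio(ae),
    )


def averaged_feature_columns() -> list:
    return [f"{t}__{f}" for t in TISSUES for f in FEATURE_NAMES]


def build_averaged_rows(rows: pd.DataFrame) -> pd.DataFrame:
    """Average normalized rows over repeats and align the four tissues into
    96 tissue-prefixed columns, one row per (drug, dose). Tissues a drug was
    not tested on yield missing values."""
    _check_norm_rows(rows)
    means = (
        rows.groupby(["drug_id", "dose", "dose_rank", "tissue"], sort=False)[
            list(FEATURE_NAMES)
        ]
        .mean()
        .reset_index()
    )
    wide = means.pivot_table(
        index=["drug_id", "dose", "dose_rank"],
        columns="tissue",
        values=list(FEATURE_NAMES),
        aggfunc="first",
    )
    wide.columns = [f"{tissue}__{feat}" for feat, tissue in wide.columns]
    wide = wide.reindex(columns=averaged_feature_columns()).reset_index()
    return wide


def build_averaged_dataset(
    rows: pd.DataFrame, table: AELabelTable, ae: str
) -> LearningDataset:
    """One row per (drug, dose); per-tissue repeat means in 96 columns."""
    wide = build_averaged_rows(rows)
    y = wide["drug_id"].map(table.labels[ae]).astype(int)
    meta = wide[["drug_id", "dose", "dose_rank"]].copy()
    meta["tissue"] = "all"
    meta["repeat"] = -1
    X = wide[averaged_feature_columns()].copy()
    ds = LearningDataset(
        X=X,
        y=y.rename("label"),
        meta=meta,
        ae=ae,
        kind="averaged",
        ratio=table.ratio(ae),
    )
    if ds.has_missing:
        ds.flags["nan_incompatible_algorithms"] = ("discriminant", "svm")
    return ds


def split_by_tissue(ds: LearningDataset) -> dict:
    """Partition a full dataset by tissue; row counts sum to the original."""
    if ds.kind != "full":
        raise InvalidArgumentError("tissue split applies to full datasets")
    out = {}
    for tissue in TISSUES:
        mask = (ds.meta["tissue"] == tissue).values
        out[tissue] = LearningDataset(
            X=ds.X.loc[mask].reset_index(drop=True),
            y=ds.y.loc[mask].reset_index(drop=True),
            meta=ds.meta.loc[mask].reset_index(drop=True),
            ae=ds.ae,
            kind="tissue_split",
            ratio=ds.ratio,
            tissue=tissue,
        )
    return out


def intestine_view(ds: LearningDataset) -> LearningDataset:
    """Derived view pooling the three intestinal segments (all but stomach)."""
    if ds.kind != "full":
        raise InvalidArgumentError("intestine view derives from a full dataset")
    mask = (ds.meta["tissue"] != "stomach").values
    return LearningDataset(
        X=ds.X.loc[mask].reset_index(drop=True),
        y=ds.y.loc[mask].reset_index(drop=True),
        meta=ds.meta.loc[mask].reset_index(drop=True),
        ae=ds.ae,
        kind="tissue_split",
        ratio=ds.ratio,
        tissue="intestine",
    )
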