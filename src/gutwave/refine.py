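"""Post-prediction refinement and per-drug AE probability reports.

Refinement order is fixed: binary predictions are first averaged over
experimental repeats within each (drug, dose), then combined across doses
with descending weights (1, 0.5, 0.3, 0.1, 0.05 from the highest dose).
Both steps use a strict > 0.5 threshold. Swapping the order changes results
on constructed inputs, so the order is part of the contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import LearningDataset
from .errors import InvalidArgumentError
from .model import TrainedModel, predict

log = logging.getLogger(__name__)

#: Approximately twofold-decreasing dose weights, highest dose first.
DOSE_WEIGHTS = (1.0, 0.5, 0.3, 0.1, 0.05)


def average_repeats(predictions) -> int:
    """Mean of member binary predictions; strictly > 0.5 counts positive."""
    p = np.asarray(predictions, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("empty prediction group")
    return int(p.mean() > 0.5)


def dose_weight_adjust(predictions, weights=DOSE_WEIGHTS) -> int:
    """Weighted vote across doses (descending dose order), strict > 0.5.

    Fewer than five doses use the first k weights so the highest dose always
    carries weight 1; more doses than weights is an error.
    """
    p = np.asarray(predictions, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("empty prediction list")
    if p.size > len(weights):
        raise InvalidArgumentError(
            f"{p.size} doses exceed the {len(weights)} available weights"
        )
    w = np.asarray(weights[: p.size], dtype=float)
    return int((w @ p) / w.sum() > 0.5)


def _refined_binary(
    rows_X: pd.DataFrame,
    rows_meta: pd.DataFrame,
    model: TrainedModel,
    average: bool = True,
    dose_adjust: bool = True,
) -> int:
    """One model's refined binary for one drug across its rows."""
    _, classes = predict(model, rows_X)
    frame = rows_meta[["dose_rank"]].copy()
    frame["pred"] = classes
    per_dose = (
        frame.groupby("dose_rank")["pred"]
        .apply(lambda g: average_repeats(g.values) if average else int(g.values.mean() > 0.5))
        .sort_index()  # rank 1 = highest dose first
    )
    if dose_adjust:
        return dose_weight_adjust(per_dose.values)
    return average_repeats(per_dose.values)


def predict_probability(
    rows_X: pd.DataFrame,
    rows_meta: pd.DataFrame,
    models: list,
    average: bool = True,
    dose_adjust: bool = True,
) -> float:
    """Probability (%) that a drug induces the AE.

    Each of the (typically seven) randomized models contributes one refined
    binary; the probability is 100 x positives / n_models, so reported
    values are multiples of 100/n.
    """
    if not models:
        raise InvalidArgumentError("no models")
    votes = [
        _refined_binary(rows_X, rows_meta, m, average=average, dose_adjust=dose_adjust)
        for m in models
    ]
    return 100.0 * float(np.mean(votes))


@dataclass
class ReportEntry:
    drug_id: str
    ae_name: str
    probability_pct_exact: float
    probability_pct_rounded: int
    refined: bool
    dose_adjusted: bool
    known_label: float  # nan when the drug has no label row
    hit: float  # 1 hit / 0 miss / nan unknown


def generate_report(
    datasets_by_ae: dict,
    models_by_ae: dict,
    label_table=None,
    average: bool = True,
    dose_adjust: bool = True,
) -> pd.DataFrame:
    """Per-drug AE probability report over the validated models.

    Parameters
    ----------
    datasets_by_ae : dict
        ae -> :class:`LearningDataset` providing the rows to predict on
        (typically the dataset kind the AE's best validated model was
        trained on).
    models_by_ae : dict
        ae -> list of trained per-randomization models; AEs that failed
        validation are simply absent from this mapping.
    label_table : AELabelTable, optional
        Known labels for hit/miss annotation; drugs without labels get NaN.
    """
    if not models_by_ae:
        raise InvalidArgumentError("no validated models")
    entries = []
    for ae, models in models_by_ae.items():
        ds: LearningDataset = datasets_by_ae[ae]
        for drug in pd.unique(ds.drug_ids):
            mask = (ds.drug_ids == drug).values
            prob = predict_probability(
                ds.X.loc[mask],
                ds.meta.loc[mask],
                models,
                average=average,
                dose_adjust=dose_adjust,
            )
            known = float("nan")
            if label_table is not None and drug in label_table.labels.index and ae in label_table.labels.columns:
                known = float(label_table.labels.loc[drug, ae])
            hit = float("nan")
            if np.isfinite(known):
                hit = float(int(prob > 50.0) == int(known))
            entries.append(
                ReportEntry(
                    drug_id=drug,
                    ae_name=ae,
                    probability_pct_exact=prob,
                    probability_pct_rounded=int(round(prob)),
                    refined=average,
                    dose_adjusted=dose_adjust,
                    known_label=known,
                    hit=hit,
                )
            )
    return pd.DataFrame([e.__dict__ for e in entries])


def format_report(report: pd.DataFrame) -> str:
    """Human-readable text summary of a probability report."""
    lines = [
        f"{'drug':<12}{'adverse effect':<24}{'probability':>12}{'known':>8}{'hit':>6}"
    ]
    for _, r in report.iterrows():
        known = "-" if not np.isfinite(r.known_label) else str(int(r.known_label))
        hit = "-" if not np.isfinite(r.hit) else ("yes" if r.hit else "no")
        lines.append(
            f"{r.drug_id:<12}{r.ae_name:<24}{r.probability_pct_rounded:>11}%{known:>8}{hit:>6}"
        )
    return "\n".join(lines)
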