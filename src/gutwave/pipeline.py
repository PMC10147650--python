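"""End-to-end orchestration: synthetic study -> feature extraction ->
learning datasets -> fitted and validated classifiers -> reports.

These helpers wire the stage modules together with derived seeds so that a
whole study is a pure function of its design and master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import ExtractorConfig, ProtocolConfig
from .datasets import (
    AELabelTable,
    assign_labels,
    build_averaged_dataset,
    build_full_dataset,
    filter_balanced,
    normalize_features,
    split_by_tissue,
)
from .errors import DegenerateLabelsError, GutwaveError, NoSignificantFeaturesError
from .features import extract_features
from .model import AEClassifier, AEClassifierResults, ValidationResult
from .recording import FEATURE_NAMES
from .synth import (
    StudyBundle,
    StudyDesign,
    _stable_seed,
    default_ae_rules,
    generate_study,
    make_drug_library,
)

log = logging.getLogger(__name__)


def make_planted_study(
    n_drugs: int = 40,
    n_classes: int = 4,
    effect_size: float = 1.0,
    prevalence: float = 0.5,
    master_seed: int = 0,
    design_kwargs: dict | None = None,
    rules=None,
) -> StudyBundle:
    """A study with the canonical planted rules (excitatory + inhibitory)."""
    design = StudyDesign(
        n_drugs=n_drugs, master_seed=master_seed, **(design_kwargs or {})
    )
    library = make_drug_library(
        n_drugs, n_classes, seed=_stable_seed(master_seed, "library")
    )
    if rules is None:
        rules = default_ae_rules(effect_size=effect_size, prevalence=prevalence)
    return generate_study(design, library, rules)


def make_network_study(
    n_drugs: int = 20,
    effect_size: float = 3.0,
    master_seed: int = 5,
    design_kwargs: dict | None = None,
) -> StudyBundle:
    """Two-receptor-class demo study for the drug-AE network.

    AE positivity is coupled to receptor class (drugs acting on similar
    receptors share adverse effects), and the planted effect is large, so
    the refined-feature geometry cleanly separates the two correlation
    poles while drugs cluster by class.
    """
    from .synth import PlantedAERule

    exc = (
        ("colon", "frequency", 1),
        ("colon", "amplitude", 1),
        ("stomach", "amplitude", -1),
    )
    rules = [
        PlantedAERule(
            "vomiting",
            "excitatory",
            exc,
            effect_size=effect_size,
            prevalence=0.5,
            class_prevalence={"class0": 0.9, "class1": 0.1},
        )
    ]
    design = StudyDesign(
        n_drugs=n_drugs, master_seed=master_seed, **(design_kwargs or {})
    )
    library = make_drug_library(n_drugs, 2, seed=_stable_seed(master_seed, "library"))
    return generate_study(design, library, rules)


def extract_study_features(
    bundle: StudyBundle, config: ExtractorConfig | None = None
):
    """Extract and normalize features for every study condition.

    Returns ``(norm_df, ef_df, rejected)``: normalized percentage-change
    rows (one per condition), raw per-recording feature rows, and a list of
    (condition, reason) for conditions dropped by quality control or
    degenerate baselines.
    """
    config = config or ExtractorConfig()
    norm_rows, ef_rows, rejected = [], [], []
    for row, base, post in bundle.iter_recordings():
        meta = dict(
            drug_id=row.drug_id,
            dose=row.dose,
            dose_rank=int(row.dose_rank),
            tissue=row.tissue,
            repeat=int(row["repeat"]),
        )
        try:
            ef_base = extract_features(base, config)
            ef_post = extract_features(post, config)
            norm = normalize_features(ef_base, ef_post)
        except GutwaveError as err:
            rejected.append((meta, repr(err)))
            log.info("condition dropped (%s): %r", meta, err)
            continue
        for phase, ef in (("baseline", ef_base), ("post_drug", ef_post)):
            ef_rows.append({**meta, "phase": phase, **ef.to_dict()})
        norm_rows.append({**meta, **norm.to_dict()})
    norm_df = pd.DataFrame(norm_rows)
    ef_df = pd.DataFrame(ef_rows)
    return norm_df, ef_df, rejected


def study_label_table(bundle: StudyBundle) -> AELabelTable:
    return assign_labels(bundle.raw_label_rows, bundle.drug_ids, bundle.ae_names)


@dataclass
class AEOutcome:
    """Per-AE result across dataset kinds."""

    ae: str
    ratio: float
    candidates: dict = field(default_factory=dict)  # kind -> AEClassifierResults
    validations: dict = field(default_factory=dict)  # kind -> ValidationResult
    aborted: dict = field(default_factory=dict)  # kind -> reason string

    def validated_kinds(self) -> list:
        return [k for k, v in self.validations.items() if v.passed]

    def best_validated(self):
        """(kind, results) with the highest mean accuracy among validated
        candidates, or None."""
        kinds = self.validated_kinds()
        if not kinds:
            return None
        best = max(kinds, key=lambda k: self.candidates[k].mean_accuracy)
        return best, self.candidates[best]


@dataclass
class StudyFit:
    label_table: AELabelTable
    retained_aes: list
    outcomes: dict  # ae -> AEOutcome
    datasets: dict  # (ae, kind) -> LearningDataset

    def report_inputs(self, dose_adjust: bool = True):
        """(datasets_by_ae, models_by_ae) over best validated models."""
        ds_by_ae, models_by_ae = {}, {}
        for ae, outcome in self.outcomes.items():
            best = outcome.best_validated()
            if best is None:
                continue
            kind, results = best
            ds_by_ae[ae] = self.datasets[(ae, kind)]
            models_by_ae[ae] = results.best_models_per_randomization()
        return ds_by_ae, models_by_ae


def _dataset_kinds(norm_df, table, ae, kinds):
    full = build_full_dataset(norm_df, table, ae)
    out = {}
    for kind in kinds:
        if kind == "full":
            out["full"] = full
        elif kind == "averaged":
            out["averaged"] = build_averaged_dataset(norm_df, table, ae)
        elif kind == "tissue_split":
            for tissue, ds in split_by_tissue(full).items():
                out[f"tissue:{tissue}"] = ds
        else:
            raise ValueError(f"unknown dataset kind {kind!r}")
    return out


def analyze_study(
    norm_df: pd.DataFrame,
    table: AELabelTable,
    kinds=("averaged", "full", "tissue_split"),
    protocol: ProtocolConfig | None = None,
    master_seed: int = 0,
) -> StudyFit:
    """Fit and validate the classification protocol for every retained AE.

    AEs outside the balance band are skipped; for each retained AE every
    requested dataset kind is fitted with its applicable algorithms,
    evaluated over the randomized splits, and validated against the Gaussian
    random control.
    """
    protocol = protocol or ProtocolConfig()
    retained = filter_balanced(table)
    if not retained:
        log.warning("no trainable AE: all balance ratios outside the band")
    outcomes, datasets = {}, {}
    for ae in retained:
        outcome = AEOutcome(ae=ae, ratio=table.ratio(ae))
        for kind, ds in _dataset_kinds(norm_df, table, ae, kinds).items():
            datasets[(ae, kind)] = ds
            seed = _stable_seed(master_seed, "protocol", ae, kind)
            clf = AEClassifier(
                ds,
                n_randomizations=protocol.n_randomizations,
                split_mode=protocol.split_mode,
                coverage_threshold=protocol.coverage_threshold,
                validation_margin_points=protocol.validation_margin_points,
            )
            try:
                results = clf.fit(seed=seed)
            except (NoSignificantFeaturesError, DegenerateLabelsError) as err:
                outcome.aborted[kind] = type(err).__name__
                continue
            outcome.candidates[kind] = results
            outcome.validations[kind] = results.validate(
                seed=_stable_seed(master_seed, "control", ae, kind)
            )
        outcomes[ae] = outcome
    return StudyFit(
        label_table=table,
        retained_aes=retained,
        outcomes=outcomes,
        datasets=datasets,
    )
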