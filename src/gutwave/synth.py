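"""Seeded synthetic studies: drug libraries with receptor-class structure,
grid slow-wave recordings under drug effects, and side-effect-style label
tables with planted feature-to-adverse-effect rules.

The generator emulates the shape of a multi-electrode drug-screening study:
each (drug, dose, tissue, repeat) condition has a baseline and a post-drug
recording of a travelling periodic wave on an electrode grid. Drug effects
are per-tissue multiplicative changes on frequency, amplitude, upstroke
slope and propagation velocity, plus an additive increase in cycle-period
irregularity; effects grow monotonically with dose rank. Adverse-effect
rules perturb the effect maps of "positive" drugs in stated directions so
downstream feature extraction and classification have a recoverable signal.
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .recording import MEARecording, PHASES, TISSUE_BASE_CPM, TISSUES

#: Standard deviation of log-multipliers across receptor-class centroids.
CLASS_LOG_SD = 0.35
#: Within-class spread of log-multipliers around the class centroid.
WITHIN_CLASS_LOG_SD = 0.08
#: Scale of irregularity perturbations (additive jitter SD fraction).
IRREGULARITY_SCALE = 0.05

#: Drug-effect parameters a planted rule may target.
EFFECT_PARAMS = ("frequency", "amplitude", "slope", "velocity", "irregularity")
_PARAM_ATTR = {
    "frequency": "freq_mult",
    "amplitude": "amp_mult",
    "slope": "slope_mult",
    "velocity": "velocity_mult",
}


@dataclass(frozen=True)
class TissueEffect:
    """Multiplicative drug effect on one tissue (dimensionless)."""

    freq_mult: float = 1.0
    amp_mult: float = 1.0
    slope_mult: float = 1.0
    velocity_mult: float = 1.0
    irregularity_add: float = 0.0

    def __post_init__(self):
        for name in ("freq_mult", "amp_mult", "slope_mult", "velocity_mult"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.irregularity_add < 0:
            raise InvalidArgumentError("irregularity_add must be >= 0")

    def as_log_vector(self) -> np.ndarray:
        return np.array(
            [
                np.log(self.freq_mult),
                np.log(self.amp_mult),
                np.log(self.slope_mult),
                np.log(self.velocity_mult),
                self.irregularity_add / IRREGULARITY_SCALE,
            ]
        )


@dataclass
class DrugEffectProfile:
    """Per-tissue effect map of one drug."""

    drug_id: str
    receptor_class: str
    effects: dict  # tissue -> TissueEffect
    dose_scaling: float = 1.0

    def __post_init__(self):
        if set(self.effects) != set(TISSUES):
            raise InvalidArgumentError("effect map must cover exactly the four tissues")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.effects[t].as_log_vector() for t in TISSUES])


def effect_distance(a: DrugEffectProfile, b: DrugEffectProfile) -> float:
    """Euclidean distance between two effect maps in log-multiplier space."""
    return float(np.linalg.norm(a.as_vector() - b.as_vector()))


@dataclass
class PlantedAERule:
    """A planted adverse-effect rule.

    ``affected`` lists (tissue, parameter, direction) triples; positives get
    the named parameter shifted by ``direction * effect_size`` population
    standard deviations (log scale for multipliers).
    """

    ae_name: str
    polarity: str  # 'excitatory' or 'inhibitory'
    affected: tuple  # of (tissue, parameter, direction)
    effect_size: float = 1.0
    prevalence: float = 0.5
    indication_fraction: float = 0.0
    #: Optional receptor_class -> prevalence overrides. Drugs acting on the
    #: same receptors tend to share adverse effects; setting per-class
    #: prevalences plants that coupling.
    class_prevalence: dict | None = None

    def drug_prevalence(self, receptor_class: str) -> float:
        if self.class_prevalence and receptor_class in self.class_prevalence:
            return float(self.class_prevalence[receptor_class])
        return self.prevalence

    def __post_init__(self):
        if not 0.0 <= self.prevalence < 1.0:
            raise InvalidArgumentError("prevalence must be in [0, 1)")
        for p in (self.class_prevalence or {}).values():
            if not 0.0 <= p <= 1.0:
                raise InvalidArgumentError("class prevalence must be in [0, 1]")
        if self.effect_size <= 0:
            raise InvalidArgumentError("effect size must be > 0")
        if self.polarity not in ("excitatory", "inhibitory"):
            raise InvalidArgumentError("polarity must be excitatory or inhibitory")
        for tissue, param, direction in self.affected:
            if tissue not in TISSUES:
                raise InvalidArgumentError(f"unknown tissue {tissue!r}")
            if param not in EFFECT_PARAMS:
                raise InvalidArgumentError(f"unknown parameter {param!r}")
            if direction not in (-1, 1):
                raise InvalidArgumentError("direction must be +1 or -1")


def default_ae_rules(
    effect_size: float = 1.0,
    prevalence: float = 0.5,
    indication_fraction: float = 0.0,
) -> list:
    """The study's canonical planted rules.

    Excitatory rules raise colonic frequency and power while depressing
    gastric power; inhibitory rules depress duodenal slope, amplitude and
    frequency (hence lengthen the period).
    """
    exc = (("colon", "frequency", 1), ("colon", "amplitude", 1), ("stomach", "amplitude", -1))
    inh = (
        ("duodenum", "slope", -1),
        ("duodenum", "amplitude", -1),
        ("duodenum", "frequency", -1),
    )
    kw = dict(
        effect_size=effect_size,
        prevalence=prevalence,
        indication_fraction=indication_fraction,
    )
    return [
        PlantedAERule("vomiting", "excitatory", exc, **kw),
        PlantedAERule("diarrhea", "excitatory", exc, **kw),
        PlantedAERule("anxiety", "excitatory", exc + (("stomach", "frequency", 1),), **kw),
        PlantedAERule("constipation", "inhibitory", inh, **kw),
        PlantedAERule("gastrointestinal_pain", "inhibitory", inh, **kw),
    ]


@dataclass
class StudyDesign:
    """Sizes, acquisition settings and master seed of one synthetic study."""

    n_drugs: int = 10
    doses: tuple = (1e-5, 1e-6, 1e-7)  # mol/L, descending
    n_repeats: int = 3
    tissues: tuple = TISSUES
    duration_s: float = 300.0
    fs: float = 10.0
    grid_rows: int = 8
    grid_cols: int = 8
    pitch_um: float = 300.0
    master_seed: int = 0
    # Waveform parameters.
    base_amplitude_uv: float = 100.0
    base_velocity_um_s: float = 600.0
    base_jitter: float = 0.02  # cycle-period CV at baseline
    noise_uv: float = 10.0
    harmonic: float = 0.25

    def __post_init__(self):
        self.doses = tuple(float(d) for d in self.doses)
        if len(self.doses) < 3:
            raise InvalidArgumentError("at least 3 doses per drug required")
        if list(self.doses) != sorted(set(self.doses), reverse=True):
            raise InvalidArgumentError("doses must be distinct and descending")
        if not 3 <= self.n_repeats <= 10:
            raise InvalidArgumentError("n_repeats must be within [3, 10]")
        if self.n_drugs < 1:
            raise InvalidArgumentError("n_drugs must be positive")
        # The analysis band tops out at 60 cpm = 1 Hz; sampling must resolve it.
        if self.fs <= 2.0:
            raise InvalidArgumentError("fs must exceed twice the highest analyzed frequency")

    @property
    def n_doses(self) -> int:
        return len(self.doses)

    def dose_rank(self, dose: float) -> int:
        """1 = highest dose."""
        try:
            return self.doses.index(float(dose)) + 1
        except ValueError:
            raise InvalidArgumentError(f"dose {dose} not in design") from None


def make_drug_library(n_drugs: int, n_classes: int, seed: int) -> list:
    """Draw a drug library with receptor-class structure.

    Each class has a centroid effect map; drugs scatter tightly around their
    class centroid, so within-class effect distances are smaller than
    between-class distances in expectation.
    """
    if n_drugs < 1 or n_classes < 1:
        raise InvalidArgumentError("counts must be positive")
    if n_classes > n_drugs:
        raise InvalidArgumentError("more classes than drugs")
    rng = np.random.default_rng(seed)
    centroids = []
    for _ in range(n_classes):
        cent = {}
        for tissue in TISSUES:
            logs = rng.normal(0.0, CLASS_LOG_SD, size=4)
            irr = abs(rng.normal(0.0, 0.6 * IRREGULARITY_SCALE))
            cent[tissue] = (logs, irr)
        centroids.append(cent)
    library = []
    for i in range(n_drugs):
        c = i % n_classes  # round-robin: every class gets >= 1 drug
        effects = {}
        for tissue in TISSUES:
            logs, irr = centroids[c][tissue]
            logs_i = logs + rng.normal(0.0, WITHIN_CLASS_LOG_SD, size=4)
            irr_i = max(0.0, irr + rng.normal(0.0, 0.2 * IRREGULARITY_SCALE))
            effects[tissue] = TissueEffect(
                freq_mult=float(np.exp(logs_i[0])),
                amp_mult=float(np.exp(logs_i[1])),
                slope_mult=float(np.exp(logs_i[2])),
                velocity_mult=float(np.exp(logs_i[3])),
                irregularity_add=irr_i,
            )
        library.append(
            DrugEffectProfile(
                drug_id=f"drug{i:03d}",
                receptor_class=f"class{c}",
                effects=effects,
            )
        )
    return library


def _dose_effect_exponent(design: StudyDesign, dose: float, dose_scaling: float) -> float:
    """Fraction of the full effect expressed at this dose (1 at the highest)."""
    rank = design.dose_rank(dose)  # 1 = highest
    s = (design.n_doses - rank + 1) / design.n_doses
    return s**dose_scaling


def simulate_recording(
    profile,
    tissue: str,
    dose: float,
    phase: str,
    design: StudyDesign,
    seed: int,
    repeat: int = 0,
) -> MEARecording:
    """Simulate one grid recording of a travelling slow wave.

    The wave is a fundamental plus one harmonic with per-cycle period
    jitter, propagating along the grid's column (longitudinal) axis with an
    integer-sample delay per column; Gaussian noise is added per channel.
    ``post_drug`` applies the profile's effect map scaled by dose rank.
    """
    if tissue not in TISSUES:
        raise InvalidArgumentError(f"unknown tissue {tissue!r}")
    if phase not in PHASES:
        raise InvalidArgumentError(f"unknown phase {phase!r}")
    if phase == "post_drug" and profile is None:
        raise InvalidArgumentError("post_drug requires a drug-effect profile")

    f0_hz = TISSUE_BASE_CPM[tissue] / 60.0
    if design.fs <= 4.0 * f0_hz:
        raise InvalidArgumentError("fs too low for the tissue base frequency")

    rng = np.random.default_rng(seed)
    # Preparation-level biological variability, drawn per recording.
    freq_jit = float(np.exp(rng.normal(0.0, 0.02)))
    amp_jit = float(np.exp(rng.normal(0.0, 0.05)))

    fm = am = sm = vm = 1.0
    irr_add = 0.0
    if phase == "post_drug":
        e = _dose_effect_exponent(design, dose, profile.dose_scaling)
        eff = profile.effects[tissue]
        fm, am = eff.freq_mult**e, eff.amp_mult**e
        sm, vm = eff.slope_mult**e, eff.velocity_mult**e
        irr_add = eff.irregularity_add * e

    f = f0_hz * freq_jit * fm
    amp = design.base_amplitude_uv * amp_jit * am
    velocity = design.base_velocity_um_s * vm
    jitter_sd = design.base_jitter + irr_add

    n = int(round(design.duration_s * design.fs))
    n_ch = design.grid_rows * design.grid_cols
    col_of = np.arange(n_ch) % design.grid_cols
    delays = np.round(design.fs * col_of * design.pitch_um / velocity).astype(int)
    max_delay = int(delays.max())

    # Master waveform covering [-max_delay, n) samples.
    n_master = n + max_delay
    t_master = (np.arange(n_master) - max_delay) / design.fs
    mean_period = 1.0 / f
    n_cycles = int(np.ceil((t_master[-1] - t_master[0]) * f)) + 4
    periods = mean_period * (1.0 + rng.normal(0.0, jitter_sd, size=n_cycles))
    periods = np.clip(periods, 0.2 * mean_period, None)
    start = t_master[0] - rng.uniform(0.0, mean_period)
    boundaries = start + np.concatenate([[0.0], np.cumsum(periods)])
    phase_of_t = 2.0 * np.pi * np.interp(t_master, boundaries, np.arange(n_cycles + 1))
    master = amp * (
        np.sin(phase_of_t) + design.harmonic * sm * np.sin(2.0 * phase_of_t)
    )

    idx = (np.arange(n)[None, :] + (max_delay - delays)[:, None])
    signals = master[idx]
    if design.noise_uv > 0:
        signals = signals + rng.normal(0.0, design.noise_uv, size=(n_ch, n))

    return MEARecording(
        signals=signals,
        fs=design.fs,
        grid_rows=design.grid_rows,
        grid_cols=design.grid_cols,
        pitch_um=design.pitch_um,
        tissue=tissue,
        drug_id=profile.drug_id if profile is not None else "none",
        dose=float(dose) if dose is not None else float("nan"),
        phase=phase,
        repeat=repeat,
    )


def make_ae_label_table(library: list, rules: list, seed: int):
    """Plant adverse-effect rules into a drug library.

    Returns ``(raw_rows, perturbed_library)`` where ``raw_rows`` is a
    DataFrame of side-effect-resource-style rows (drug_id, ae_name, role)
    and ``perturbed_library`` is a deep copy of the library with positive
    drugs' effect maps shifted in each rule's stated directions. A
    configurable fraction of positives additionally carries an indication
    row, which downstream labelling overrides to 0.
    """
    if not library:
        raise InvalidArgumentError("empty drug library")
    names = [r.ae_name for r in rules]
    if len(set(names)) != len(names):
        raise InvalidArgumentError("rule AE names must be unique")
    rng = np.random.default_rng(seed)
    new_library = copy.deepcopy(library)
    by_id = {p.drug_id: p for p in new_library}
    rows = []
    for rule in rules:
        thresholds = np.array(
            [rule.drug_prevalence(p.receptor_class) for p in new_library]
        )
        positive = rng.random(len(new_library)) < thresholds
        indicated = rng.random(len(new_library)) < rule.indication_fraction
        for prof, pos, ind in zip(new_library, positive, indicated):
            if not pos:
                continue
            _apply_rule(prof, rule)
            rows.append((prof.drug_id, rule.ae_name, "side_effect"))
            if ind:
                rows.append((prof.drug_id, rule.ae_name, "indication"))
    raw = pd.DataFrame(rows, columns=["drug_id", "ae_name", "role"])
    return raw, new_library


def _apply_rule(profile: DrugEffectProfile, rule: PlantedAERule) -> None:
    for tissue, param, direction in rule.affected:
        eff = profile.effects[tissue]
        if param == "irregularity":
            newval = max(
                0.0,
                eff.irregularity_add
                + direction * rule.effect_size * IRREGULARITY_SCALE,
            )
            profile.effects[tissue] = replace(eff, irregularity_add=newval)
        else:
            attr = _PARAM_ATTR[param]
            factor = float(np.exp(direction * rule.effect_size * CLASS_LOG_SD))
            profile.effects[tissue] = replace(
                eff, **{attr: getattr(eff, attr) * factor}
            )


def _stable_seed(master_seed: int, *parts) -> int:
    key = "|".join(str(p) for p in parts)
    return int(
        np.random.SeedSequence(
            (int(master_seed), zlib.crc32(key.encode()))
        ).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class StudyBundle:
    """A full synthetic study: design, perturbed library, labels, manifest.

    The manifest has one row per (drug, dose, tissue, repeat) condition;
    each condition owns a baseline and a post-drug recording, generated
    lazily from per-recording seed streams derived from the master seed.
    """

    design: StudyDesign
    library: list
    raw_label_rows: pd.DataFrame
    manifest: pd.DataFrame
    rules: list = field(default_factory=list)

    @property
    def drug_ids(self) -> list:
        return [p.drug_id for p in self.library]

    @property
    def ae_names(self) -> list:
        return [r.ae_name for r in self.rules]

    def _profile(self, drug_id: str) -> DrugEffectProfile:
        for p in self.library:
            if p.drug_id == drug_id:
                return p
        raise InvalidArgumentError(f"unknown drug {drug_id!r}")

    def recording_seed(self, drug_id, dose, tissue, repeat, phase) -> int:
        return _stable_seed(
            self.design.master_seed, drug_id, f"{dose:.6e}", tissue, repeat, phase
        )

    def get_recording(self, drug_id, dose, tissue, repeat, phase) -> MEARecording:
        profile = self._profile(drug_id) if phase == "post_drug" else None
        rec = simulate_recording(
            profile,
            tissue,
            dose,
            phase,
            self.design,
            seed=self.recording_seed(drug_id, dose, tissue, repeat, phase),
            repeat=repeat,
        )
        rec.drug_id = str(drug_id)  # the condition's drug owns its baseline too
        return rec

    def iter_recordings(self):
        """Yield (manifest_row, baseline, post_drug) for every condition."""
        for _, row in self.manifest.iterrows():
            base = self.get_recording(
                row.drug_id, row.dose, row.tissue, row["repeat"], "baseline"
            )
            post = self.get_recording(
                row.drug_id, row.dose, row.tissue, row["repeat"], "post_drug"
            )
            yield row, base, post


def generate_study(design: StudyDesign, library: list, rules: list) -> StudyBundle:
    """Assemble a full study bundle from a design, library and rule set."""
    if len(library) != design.n_drugs:
        raise InvalidArgumentError("library size must match design.n_drugs")
    raw_rows, perturbed = make_ae_label_table(
        library, rules, seed=_stable_seed(design.master_seed, "labels")
    )
    records = [
        {
            "drug_id": p.drug_id,
            "dose": dose,
            "dose_rank": design.dose_rank(dose),
            "tissue": tissue,
            "repeat": rep,
        }
        for p in perturbed
        for dose in design.doses
        for tissue in design.tissues
        for rep in range(design.n_repeats)
    ]
    manifest = pd.DataFrame.from_records(records)
    return StudyBundle(
        design=design,
        library=perturbed,
        raw_label_rows=raw_rows,
        manifest=manifest,
        rules=list(rules),
    )
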