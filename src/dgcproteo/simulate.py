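"""Synthetic paired tumor/nearby cohorts with planted ground truth.

The generator emulates the structure of an 84-patient paired-tissue
label-free proteomics study: per-protein log-normal baseline abundance,
abundance-dependent missingness (logistic in log10 abundance around the
10^-5 FOT quantification floor), three latent subtypes carrying
signature programs (a cell-cycle, an EMT and an immune block, one per
subtype by default; multi-subtype sharing is configurable),
globally differential proteins, driver-gene mutation profiles with
planted downstream protein effects, druggability annotation, and
right-censored Weibull survival with subtype-ordered hazards plus
planted per-protein prognostic effects.  Every random choice flows from
a single mandatory seed, so identical configurations reproduce
byte-identical tables, and the emitted :class:`SyntheticTruth` records
exactly what was planted so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    AbundanceMatrix,
    AnnotationTable,
    ClinicalTable,
    MutationTable,
    NEARBY,
    TUMOR,
)

LOG10_3 = float(np.log10(3.0))

_DRUG_CATEGORIES = ("enzyme", "gpcr", "kinase", "ion channel", "transmembrane", "extracellular")

_SITES = ("cardia", "body", "antrum")
_STAGES = ("Ib", "II", "III", "IV")

_VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "inframe", "silent")
_VARIANT_PROBS = (0.55, 0.12, 0.12, 0.06, 0.05, 0.10)


@dataclass(frozen=True)
class SignatureBlock:
    """A subtype-specific protein program (count, log10 effect, carriers)."""

    n_proteins: int
    effect: float
    subtypes: tuple[int, ...]


@dataclass(frozen=True)
class MutationSpec:
    """Per-gene mutation model: cohort frequency, subtype skew, protein targets."""

    base_frequency: float
    subtype_multipliers: tuple[float, float, float] = (0.7, 1.0, 1.3)
    n_up_targets: int = 0
    up_fold: float = 2.0
    n_down_targets: int = 0
    down_fold: float = 0.25


@dataclass(frozen=True)
class SurvivalSpec:
    """Weibull survival with subtype-ordered hazards and censoring window."""

    weibull_shape: float = 1.2
    baseline_scale: float = 40.0  # months
    subtype_trend_ln_hr: float = 0.7  # per subtype step
    censor_window: tuple[float, float] = (8.0, 50.0)  # months
    target_ln_hr: float = 1.1  # planted harmful targets (high vs low)
    protective_ln_hr: float = -1.1  # planted protective genomic targets


def _default_blocks() -> dict[str, SignatureBlock]:
    # Disjoint subtype programs keep the three subtypes near-equidistant,
    # so the 2-cluster solution is genuinely ambiguous under resampling
    # while the 3-cluster solution is stable; shared programs (e.g. a
    # cell-cycle block carried by two subtypes) can be configured via
    # SignatureBlock.subtypes.
    return {
        "cell_cycle": SignatureBlock(50, 1.0, (1,)),
        "emt": SignatureBlock(50, 1.0, (2,)),
        "immune": SignatureBlock(50, 1.0, (3,)),
    }


def _default_mutations() -> dict[str, MutationSpec]:
    return {
        "TP53": MutationSpec(0.45),
        "CDH1": MutationSpec(0.25, n_up_targets=20, n_down_targets=10),
        "KMT2D": MutationSpec(0.20),
        "ARID1A": MutationSpec(0.15),
        "RHOA": MutationSpec(0.15),
        "FAT4": MutationSpec(0.12),
        "APC": MutationSpec(0.12),
        "PIK3CA": MutationSpec(0.12),
        "SPTA1": MutationSpec(0.10),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Abundances are on the FOT x 10^5 presentation scale (log10 units);
    the detection floor of 10^-5 FOT sits at log10 = 0.
    """

    seed: int
    n_patients: int = 84
    n_proteins: int = 500
    subtype_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    signature_blocks: dict[str, SignatureBlock] = field(default_factory=_default_blocks)
    dep_fraction: float = 0.10
    dep_effect: float = 0.6  # log10 units
    dep_up_prob: float = 0.7
    n_strict_deps: int = 20
    strict_dep_effect: float = 1.0
    baseline_mean: float = 1.7  # log10(FOT x 1e5) across proteins
    baseline_sd: float = 1.0
    noise_sd: float = 0.25  # within-protein log10 noise per sample
    detection_center: float = 0.0  # log10 abundance of 50% detection
    detection_steepness: float = 1.5
    mutation_spec: dict[str, MutationSpec] = field(default_factory=_default_mutations)
    vaf_pass_fraction: float = 0.9
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    n_planted_targets: int = 5
    target_effect: float = 1.2  # mean log10 overexpression of planted targets
    target_contrast: float = 1.5  # extra log10 overexpression in the high-risk half
    druggable_fraction: float = 0.3
    n_genomic_targets: int = 40
    n_protective_targets: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        n_special = (
            sum(b.n_proteins for b in self.signature_blocks.values())
            + int(self.dep_fraction * self.n_proteins)
            + self.n_planted_targets
            + self.n_protective_targets
            + sum(
                m.n_up_targets + m.n_down_targets for m in self.mutation_spec.values()
            )
            + len(self.mutation_spec)
        )
        if n_special > self.n_proteins:
            raise ValueError(
                f"planted structure needs {n_special} proteins but only "
                f"{self.n_proteins} are configured"
            )


@dataclass
class SyntheticTruth:
    """Everything the generator planted, keyed the way pipelines report it."""

    subtypes: pd.Series  # patient -> 1..3
    protein_status: pd.DataFrame  # per protein: role, tumor effect, block
    dep_set: pd.Index
    dep_directions: pd.Series
    strict_dep_set: pd.Index
    mutation_carriers: dict[str, frozenset]
    mutation_altered: dict[str, dict[str, frozenset]]  # gene -> {"up": .., "down": ..}
    subtype_trend_ln_hr: float
    target_set: pd.Index
    protective_set: pd.Index
    protein_ln_hr: pd.Series

    @property
    def shifted_set(self) -> frozenset:
        """All proteins planted with any tumor-vs-nearby shift (global DEPs,
        signature blocks, survival targets, mutation targets)."""
        status = self.protein_status
        return frozenset(status.index[status["role"] != "null"])


@dataclass
class SyntheticCohort:
    """A generated cohort: the four analysis tables plus annotation."""

    abundance: AbundanceMatrix
    mutations: MutationTable
    clinical: ClinicalTable
    annotation: AnnotationTable
    truth: SyntheticTruth
    config: CohortConfig


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort under *config* (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    P = config.n_proteins

    patients = [f"P{i + 1:03d}" for i in range(n)]
    # exact (largest-remainder) allocation of the subtype proportions,
    # shuffled: the proportions are study conditions, not expectations
    props = np.asarray(config.subtype_proportions, dtype=float)
    counts = np.floor(props * n).astype(int)
    remainder = props * n - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    subtype_draw = rng.permutation(np.repeat([1, 2, 3], counts))
    subtypes = pd.Series(subtype_draw, index=patients, name="subtype")

    # --- protein roles -----------------------------------------------------
    genes = list(config.mutation_spec)
    proteins = genes + [f"G{i + 1:04d}" for i in range(P - len(genes))]
    status = pd.DataFrame(
        {"role": "null", "effect": 0.0, "block": ""},
        index=pd.Index(proteins, name="protein"),
    )
    free = [p for p in proteins if p not in genes]
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = free[cursor : cursor + k]
        cursor += k
        return out

    block_members: dict[str, list[str]] = {}
    for name, block in config.signature_blocks.items():
        members = take(block.n_proteins)
        block_members[name] = members
        status.loc[members, ["role", "effect", "block"]] = ["signature", block.effect, name]

    n_dep = int(round(config.dep_fraction * P))
    dep_proteins = take(n_dep)
    dep_dirs = np.where(rng.random(n_dep) < config.dep_up_prob, 1, -1)
    dep_effects = dep_dirs * config.dep_effect
    strict = dep_proteins[: min(config.n_strict_deps, n_dep)]
    dep_effects[: len(strict)] = dep_dirs[: len(strict)] * config.strict_dep_effect
    status.loc[dep_proteins, "role"] = "dep"
    status.loc[dep_proteins, "effect"] = dep_effects
    status.loc[strict, "role"] = "strict_dep"

    targets = take(config.n_planted_targets)
    status.loc[targets, ["role", "effect"]] = ["target", config.target_effect]
    protective = take(config.n_protective_targets)
    status.loc[protective, ["role", "effect"]] = ["protective_target", config.target_effect]

    mutation_targets: dict[str, dict[str, list[str]]] = {}
    for gene, spec in config.mutation_spec.items():
        up = take(spec.n_up_targets)
        down = take(spec.n_down_targets)
        mutation_targets[gene] = {"up": up, "down": down}
        if up:
            status.loc[up, ["role", "block"]] = ["mutation_up", gene]
        if down:
            status.loc[down, ["role", "block"]] = ["mutation_down", gene]

    # --- mutations (decided before abundance so carriers shape tumors) ----
    mult = {1: 0, 2: 1, 3: 2}
    records = []
    carriers: dict[str, frozenset] = {}
    for gene, spec in config.mutation_spec.items():
        freq = np.clip(
            spec.base_frequency
            * np.array([spec.subtype_multipliers[mult[s]] for s in subtype_draw]),
            0.0,
            0.95,
        )
        mutated = rng.random(n) < freq
        gene_carriers = []
        for i, is_mut in enumerate(mutated):
            if not is_mut:
                continue
            vclass = rng.choice(_VARIANT_CLASSES, p=_VARIANT_PROBS)
            passes = rng.random() < config.vaf_pass_fraction
            if passes:
                vaf_t = rng.uniform(0.10, 0.60)
                vaf_n = rng.uniform(0.0, 0.02)
            elif rng.random() < 0.5:
                vaf_t = rng.uniform(0.005, 0.05)
                vaf_n = rng.uniform(0.0, 0.02)
            else:
                vaf_t = rng.uniform(0.10, 0.60)
                vaf_n = rng.uniform(0.04, 0.15)
            records.append(
                {
                    "patient": patients[i],
                    "gene": gene,
                    "variant_class": vclass,
                    "vaf_tumor": round(float(vaf_t), 4),
                    "vaf_normal": round(float(vaf_n), 4),
                }
            )
            nonsyn = vclass != "silent"
            if passes and nonsyn:
                gene_carriers.append(patients[i])
        carriers[gene] = frozenset(gene_carriers)
    mutation_table = MutationTable(pd.DataFrame.from_records(records))

    # --- abundance ---------------------------------------------------------
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=P)
    nearby_log = base[:, None] + rng.normal(0.0, config.noise_sd, size=(P, n))

    effect = np.zeros((P, n))
    p_idx = {p: i for i, p in enumerate(proteins)}
    for name, block in config.signature_blocks.items():
        rows = [p_idx[p] for p in block_members[name]]
        cols = np.isin(subtype_draw, block.subtypes)
        effect[np.ix_(rows, cols)] += block.effect
    rows = [p_idx[p] for p in dep_proteins]
    effect[rows, :] += dep_effects[:, None]
    # planted prognostic targets: an "aggressive" half of the cohort
    # co-overexpresses all harmful targets (and carries their hazard);
    # an independent half does the same for the protective ones
    aggressive = np.zeros(n, dtype=bool)
    aggressive[rng.permutation(n)[: n // 2]] = True
    protected_high = np.zeros(n, dtype=bool)
    protected_high[rng.permutation(n)[: n // 2]] = True
    for p in targets:
        effect[p_idx[p], :] += config.target_effect + config.target_contrast * (
            aggressive.astype(float) - 0.5
        )
    for p in protective:
        effect[p_idx[p], :] += config.target_effect + config.target_contrast * (
            protected_high.astype(float) - 0.5
        )
    for gene, tg in mutation_targets.items():
        carrier_cols = np.array([pt in carriers[gene] for pt in patients])
        if not carrier_cols.any():
            continue
        for p in tg["up"]:
            effect[p_idx[p], carrier_cols] += np.log10(
                config.mutation_spec[gene].up_fold
            )
        for p in tg["down"]:
            effect[p_idx[p], carrier_cols] += np.log10(
                config.mutation_spec[gene].down_fold
            )

    tumor_log = (
        base[:, None] + effect + rng.normal(0.0, config.noise_sd, size=(P, n))
    )

    def _with_missingness(log_vals: np.ndarray) -> np.ndarray:
        p_detect = 1.0 / (
            1.0
            + np.exp(
                -config.detection_steepness * (log_vals - config.detection_center)
            )
        )
        detected = rng.random(log_vals.shape) < p_detect
        out = np.power(10.0, log_vals)
        out[~detected] = np.nan
        return out

    tumor_vals = _with_missingness(tumor_log)
    nearby_vals = _with_missingness(nearby_log)

    columns, data = [], []
    for j, pt in enumerate(patients):
        columns += [f"{pt}_T", f"{pt}_N"]
        data += [tumor_vals[:, j], nearby_vals[:, j]]
    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(proteins, name="protein"), columns=columns
    )
    samples = pd.DataFrame(
        {
            "patient": [c.rsplit("_", 1)[0] for c in columns],
            "tissue": [TUMOR if c.endswith("_T") else NEARBY for c in columns],
        },
        index=pd.Index(columns, name="sample"),
    )
    abundance = AbundanceMatrix(values=values, samples=samples)

    # --- survival ----------------------------------------------------------
    sv = config.survival
    lp = sv.subtype_trend_ln_hr * (subtype_draw - 1).astype(float)
    ln_hr = pd.Series(0.0, index=pd.Index(proteins, name="protein"))
    for p in targets:
        ln_hr[p] = sv.target_ln_hr
    for p in protective:
        ln_hr[p] = sv.protective_ln_hr
    if len(targets):
        lp += sv.target_ln_hr * (aggressive.astype(float) - 0.5)
    if len(protective):
        lp += sv.protective_ln_hr * (protected_high.astype(float) - 0.5)
    u = rng.random(n)
    t_event = sv.baseline_scale * np.power(
        -np.log(u) / np.exp(lp), 1.0 / sv.weibull_shape
    )
    censor = rng.uniform(*sv.censor_window, size=n)
    os_months = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "age": np.round(rng.normal(60, 10, size=n)).clip(28, 88),
                "gender": rng.choice(["male", "female"], size=n, p=[0.6, 0.4]),
                "site": rng.choice(_SITES, size=n, p=[0.25, 0.4, 0.35]),
                "stage": rng.choice(_STAGES, size=n, p=[0.1, 0.2, 0.35, 0.35]),
                "chemo": rng.choice([0, 1], size=n, p=[0.3, 0.7]),
                "os_months": np.maximum(np.round(os_months, 2), 0.01),
                "event": event,
                "subtype": subtype_draw,
            },
            index=pd.Index(patients, name="patient"),
        )
    )

    # --- annotation --------------------------------------------------------
    druggable = rng.random(P) < config.druggable_fraction
    for p in list(targets) + list(protective):
        druggable[p_idx[p]] = True
    categories = np.where(
        druggable, rng.choice(_DRUG_CATEGORIES, size=P), ""
    )
    genomic = np.zeros(P, dtype=bool)
    for p in protective:
        genomic[p_idx[p]] = True
    # the fixed druggable-driver list mixes overexpressed proteins (like
    # the planted up-DEPs) with drivers that are not overexpressed
    n_extra = max(0, config.n_genomic_targets - int(genomic.sum()))
    up_pool = [
        p_idx[p]
        for p in dep_proteins
        if status.loc[p, "effect"] > 0 and not genomic[p_idx[p]]
    ]
    null_pool = [
        i
        for i, p in enumerate(proteins)
        if not genomic[i] and status.loc[p, "role"] == "null"
    ]
    n_up = min(len(up_pool), n_extra // 3)
    if n_up:
        genomic[rng.choice(up_pool, size=n_up, replace=False)] = True
    if n_extra - n_up:
        genomic[rng.choice(null_pool, size=n_extra - n_up, replace=False)] = True
    annotation = AnnotationTable(
        pd.DataFrame(
            {
                "druggable": druggable,
                "category": categories,
                "stomach_specific": rng.random(P) < 0.05,
                "genomic_target": genomic,
            },
            index=pd.Index(proteins, name="protein"),
        )
    )

    truth = SyntheticTruth(
        subtypes=subtypes,
        protein_status=status,
        dep_set=pd.Index(dep_proteins),
        dep_directions=pd.Series(np.sign(dep_effects).astype(int), index=dep_proteins),
        strict_dep_set=pd.Index(strict),
        mutation_carriers=carriers,
        mutation_altered={
            g: {"up": frozenset(t["up"]), "down": frozenset(t["down"])}
            for g, t in mutation_targets.items()
        },
        subtype_trend_ln_hr=sv.subtype_trend_ln_hr,
        target_set=pd.Index(targets),
        protective_set=pd.Index(protective),
        protein_ln_hr=ln_hr,
    )
    return SyntheticCohort(abundance, mutation_table, clinical, annotation, truth, config)


def null_config(seed: int, **overrides) -> CohortConfig:
    """A cohort with no planted effects of any kind (calibration baseline)."""
    cfg = CohortConfig(
        seed=seed,
        signature_blocks={},
        dep_fraction=0.0,
        n_strict_deps=0,
        n_planted_targets=0,
        n_protective_targets=0,
        mutation_spec={
            g: replace(s, n_up_targets=0, n_down_targets=0)
            for g, s in _default_mutations().items()
        },
        survival=SurvivalSpec(subtype_trend_ln_hr=0.0, target_ln_hr=0.0, protective_ln_hr=0.0),
    )
    return replace(cfg, **overrides) if overrides else cfg


def de_calibration_config(seed: int, dep_fraction: float = 0.10, dep_effect: float = 0.6, **overrides) -> CohortConfig:
    """A cohort whose only planted structure is the global DEP set.

    This is the differential-expression calibration condition: 84 paired
    patients, *dep_fraction* of proteins shifted by *dep_effect* log10
    units, no subtype programs, survival targets or mutation effects.
    """
    cfg = null_config(seed)
    cfg = replace(
        cfg, dep_fraction=dep_fraction, dep_effect=dep_effect,
        n_strict_deps=0, strict_dep_effect=dep_effect,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# truth scorecard
# ---------------------------------------------------------------------------


def truth_scorecard(
    truth: SyntheticTruth,
    *,
    subtype_labels: pd.Series | None = None,
    called_deps: pd.Index | None = None,
    trend_ln_hr_estimate: float | None = None,
    nominated: pd.Index | None = None,
) -> dict:
    """Score pipeline outputs against the planted truth.

    Returns a flat dict of recovery metrics; only the supplied outputs
    are scored.  Patient-id mismatches between labels and truth raise.
    """
    from sklearn.metrics import adjusted_rand_score

    metrics: dict[str, float] = {}
    if subtype_labels is not None:
        if set(subtype_labels.index) != set(truth.subtypes.index):
            raise ValueError("patient ids of labels and truth differ")
        aligned = subtype_labels.loc[truth.subtypes.index]
        metrics["ari"] = float(adjusted_rand_score(truth.subtypes, aligned))
    if called_deps is not None:
        called = set(called_deps)
        planted = set(truth.dep_set)
        tp = len(called & planted)
        metrics["dep_sensitivity"] = tp / len(planted) if planted else float("nan")
        # a call is false only if the protein carries no planted tumor shift
        # of any kind (signature blocks etc. are genuinely differential)
        false_calls = len(called - truth.shifted_set)
        metrics["dep_fdr"] = false_calls / len(called) if called else 0.0
        metrics["dep_called"] = float(len(called))
    if trend_ln_hr_estimate is not None:
        metrics["ln_hr_bias"] = float(trend_ln_hr_estimate - truth.subtype_trend_ln_hr)
    if nominated is not None:
        nom = set(nominated)
        planted = set(truth.target_set)
        tp = len(nom & planted)
        metrics["nomination_recall"] = tp / len(planted) if planted else float("nan")
        metrics["nomination_precision"] = tp / len(nom) if nom else 1.0
        metrics["nomination_false_positives"] = float(len(nom) - tp)
    return metrics
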