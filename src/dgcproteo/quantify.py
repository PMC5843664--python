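"""Label-free quantification and the nested D1-D6 filter cascade.

iBAQ divides a protein's summed peptide intensity by its count of
theoretically observable fully tryptic peptides; FOT (fraction of total)
normalizes iBAQ to the sample's total and is presented x 10^5, so the
10^-5 FOT quantification-reliability floor equals 1.0 on the working
scale.  The cascade then narrows the protein universe: D2 keeps
high-confidence identifications (>= 2 unique peptides, ion score > 20),
D3 drops keratins and proteins never quantified above the floor, D4 keeps
proteins detected in at least one-sixth of samples, D5 additionally
requires quantification above the floor in that many samples and floors
the remaining small values before taking per-patient log10 tumor/nearby
ratios, and D6 keeps proteins changed more than threefold in at least a
tenth of the patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import parser as _pt_parser

from .io import AbundanceMatrix, ProteinEvidence, TUMOR, NEARBY

logger = logging.getLogger(__name__)

#: 10^-5 FOT on the x 10^5 presentation scale
FLOOR_PRESENTATION = 1.0

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_CASCADE_CONFIG = {
    "floor": FLOOR_PRESENTATION,
    "detect_fraction": 1.0 / 6.0,
    "ratio_fold": 3.0,
    "ratio_fraction": 1.0 / 10.0,
    "keratin_prefixes": ("KRT",),
}


def count_theoretical_peptides(sequence: str, min_len: int = 6, max_len: int = 30) -> int:
    """Count fully tryptic peptides of a protein sequence.

    Cleaves after K/R except before P, zero missed cleavages, and keeps
    peptides whose length lies in ``[min_len, max_len]``.
    """
    if not sequence:
        logger.warning("empty protein sequence; theoretical peptide count is 0")
        return 0
    seq = sequence.upper()
    bad = set(seq) - AA20
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    peptides = _pt_parser.cleave(
        seq, _pt_parser.expasy_rules["trypsin"], missed_cleavages=0
    )
    return sum(1 for p in peptides if min_len <= len(p) <= max_len)


def compute_ibaq(summed_intensity, theoretical_peptides):
    """iBAQ = summed intensity / theoretical peptide count (vectorized)."""
    intensity = np.asarray(summed_intensity, dtype=float)
    npep = np.asarray(theoretical_peptides, dtype=float)
    if np.any(npep < 1):
        raise ValueError("theoretical peptide count must be >= 1")
    if np.any(intensity < 0):
        raise ValueError("intensities must be non-negative")
    out = intensity / npep
    return float(out) if out.ndim == 0 else out


def normalize_fot(ibaq, scale: float = 1e5):
    """Normalize per-sample iBAQ values to FOT x *scale*.

    ``ibaq`` is a Series (one sample) or DataFrame (proteins x samples);
    NaN means not detected and is excluded from the denominator, so the
    detected values of every sample sum to *scale*.
    """
    if isinstance(ibaq, pd.DataFrame):
        return ibaq.apply(lambda col: normalize_fot(col, scale=scale))
    vals = pd.Series(ibaq, dtype=float)
    total = vals.sum(skipna=True)
    if not np.isfinite(total) or total <= 0:
        raise ValueError("sample has no detected protein with positive iBAQ")
    return vals / total * scale


def gate_d2(
    evidence: ProteinEvidence,
    *,
    min_unique_peptides: int = 2,
    min_ion_score: float = 20.0,
) -> pd.Index:
    """High-confidence identification gate.

    Keeps proteins with >= *min_unique_peptides* unique peptides and a
    Mascot ion score strictly greater than *min_ion_score* in at least
    one sample (peptide-level FDR control happens upstream).
    """
    peptide_ok = evidence.unique_peptides.max(axis=1) >= min_unique_peptides
    score_ok = evidence.ion_score.max(axis=1) > min_ion_score
    keep = peptide_ok & score_ok
    return evidence.unique_peptides.index[keep.fillna(False)]


@dataclass
class RatioMatrix:
    """Per-(protein, patient) log10 tumor/nearby ratios after floor imputation.

    ``log_ratios`` is proteins x patients; a value of 0 arises when both
    sides were at or below the floor.  ``detected_tumor`` /
    ``detected_nearby`` record pre-imputation detection, and
    ``floored_tumor`` / ``floored_nearby`` record where the floor replaced
    the observed (or missing) value.
    """

    log_ratios: pd.DataFrame
    detected_tumor: pd.DataFrame
    detected_nearby: pd.DataFrame
    floored_tumor: pd.DataFrame
    floored_nearby: pd.DataFrame
    floor: float = FLOOR_PRESENTATION

    @property
    def proteins(self) -> pd.Index:
        return self.log_ratios.index

    @property
    def patients(self) -> pd.Index:
        return self.log_ratios.columns

    def detected_either(self) -> pd.DataFrame:
        return self.detected_tumor | self.detected_nearby

    def detected_both(self) -> pd.DataFrame:
        return self.detected_tumor & self.detected_nearby

    def restrict(self, proteins) -> "RatioMatrix":
        idx = self.log_ratios.index.intersection(pd.Index(proteins))
        return RatioMatrix(
            self.log_ratios.loc[idx],
            self.detected_tumor.loc[idx],
            self.detected_nearby.loc[idx],
            self.floored_tumor.loc[idx],
            self.floored_nearby.loc[idx],
            self.floor,
        )


def compute_ratios(matrix: AbundanceMatrix, floor: float = FLOOR_PRESENTATION) -> RatioMatrix:
    """Per-patient log10(T/N) with both sides floored at *floor*.

    Patients missing either tissue are omitted with a warning.  Undetected
    values count as below the floor, so every paired patient has a defined
    ratio for every protein (0 when both sides sit at the floor).
    """
    paired = matrix.patients
    all_patients = set(matrix.samples["patient"])
    dropped = all_patients - set(paired)
    if dropped:
        logger.warning("omitting %d unpaired patients: %s", len(dropped), sorted(dropped))
    tum = matrix.tissue_matrix(TUMOR)[paired]
    nea = matrix.tissue_matrix(NEARBY)[paired]
    det_t = tum.notna()
    det_n = nea.notna()
    t_vals = tum.fillna(0.0).clip(lower=floor)
    n_vals = nea.fillna(0.0).clip(lower=floor)
    log_ratios = np.log10(t_vals / n_vals)
    return RatioMatrix(
        log_ratios=log_ratios,
        detected_tumor=det_t,
        detected_nearby=det_n,
        floored_tumor=tum.isna() | (tum <= floor),
        floored_nearby=nea.isna() | (nea <= floor),
        floor=floor,
    )


@dataclass
class FilterCascadeResult:
    """Nested protein sets D2 through D6 with the config that produced them."""

    stages: dict[str, pd.Index]
    config: dict = field(default_factory=dict)
    ratios: RatioMatrix | None = None

    @property
    def cardinalities(self) -> dict[str, int]:
        return {name: len(idx) for name, idx in self.stages.items()}

    def __getitem__(self, stage: str) -> pd.Index:
        return self.stages[stage]


def prevalence_count(n: int, fraction: float) -> int:
    """Half-up-rounded count threshold for a prevalence fraction (min 1).

    Reproduces the study's cut-offs: one-sixth of 168 samples -> 28 and
    one-tenth of 84 patients -> 8.
    """
    return max(1, int(np.floor(n * fraction + 0.5)))


def filter_cascade(
    matrix: AbundanceMatrix,
    evidence: ProteinEvidence | None = None,
    config: dict | None = None,
) -> FilterCascadeResult:
    """Apply the nested D2 -> D6 protein filters to an FOT matrix.

    D2: evidence gate (all proteins when no evidence is supplied).
    D3: D2 minus keratins and proteins whose maximum FOT never exceeds
    the floor (equality excluded).  D4: D3 proteins detected in at least
    the prevalence count of samples (either tissue).  D5: D4 proteins
    quantified strictly above the floor in at least that many samples;
    values are then floor-imputed and per-patient log10 T/N ratios taken.
    D6: D5 proteins with |T/N| fold change strictly above ``ratio_fold``
    in at least the ratio-prevalence count of patients.
    """
    cfg = dict(DEFAULT_CASCADE_CONFIG)
    if config:
        cfg.update(config)
    floor = cfg["floor"]

    if evidence is not None:
        d2 = gate_d2(evidence).intersection(matrix.proteins)
    else:
        d2 = matrix.proteins
    d2 = pd.Index([p for p in matrix.proteins if p in set(d2)])  # keep input order

    values = matrix.values.loc[d2]
    prefixes = tuple(cfg.get("keratin_prefixes") or ())
    if prefixes:
        keratin = values.index.str.upper().str.startswith(prefixes)
    else:
        logger.warning("keratin prefix list empty; skipping keratin exclusion")
        keratin = np.zeros(len(values), dtype=bool)
    above_floor_ever = (values.max(axis=1, skipna=True) > floor).fillna(False)
    d3 = values.index[~keratin & above_floor_ever.to_numpy()]

    n_samples = matrix.n_samples()
    min_detect = prevalence_count(n_samples, cfg["detect_fraction"])
    detected_counts = matrix.values.loc[d3].notna().sum(axis=1)
    d4 = d3[(detected_counts >= min_detect).to_numpy()]

    above_floor_counts = (matrix.values.loc[d4] > floor).sum(axis=1)
    d5 = d4[(above_floor_counts >= min_detect).to_numpy()]

    ratios = compute_ratios(matrix, floor=floor).restrict(d5)
    log_bound = np.log10(cfg["ratio_fold"])
    n_patients = ratios.log_ratios.shape[1]
    min_changed = prevalence_count(n_patients, cfg["ratio_fraction"])
    changed = (ratios.log_ratios.abs() > log_bound).sum(axis=1)
    d6 = d5[(changed.loc[d5] >= min_changed).to_numpy()]

    cfg_snapshot = dict(cfg, min_detect=min_detect, min_changed=min_changed)
    stages = {"D2": d2, "D3": d3, "D4": d4, "D5": d5, "D6": d6}
    return FilterCascadeResult(stages=stages, config=cfg_snapshot, ratios=ratios)
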