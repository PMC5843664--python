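"""Mutation filtering, summaries, and mutation-proteome association.

Somatic variants are gated on allele frequency (tumor VAF strictly above
0.05 and matched-normal VAF strictly below 0.03), summarized per gene
(a patient counts once per gene), and related to the tumor proteome two
ways: the mutated gene's own protein abundance (mutant vs. wild-type
Wilcoxon, with a detection-status classification), and the gene's
"mutation-altered proteome" — every protein that is both nominally
different (P < 0.05) and shifted more than the fold gate (mutant/wild
mean ratio > 1.6 up or < 0.33 down) across mutant tumors.  Jaccard
similarity compares altered proteomes between genes; gene-level profiles
lift to pathway-level mutation profiles, and Fisher's exact test relates
mutation profiles to proteomic subtypes one-vs-rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSetCollection, MutationTable
from .quantify import FLOOR_PRESENTATION
from .stats import TestResult, fisher_exact, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


def filter_variants(
    table: MutationTable,
    vaf_t_min: float = 0.05,
    vaf_n_max: float = 0.03,
) -> MutationTable:
    """Keep variants with tumor VAF > *vaf_t_min* and normal VAF < *vaf_n_max*.

    Both comparisons are strict, so a variant exactly at either bound is
    dropped.
    """
    rec = table.records
    keep = (rec["vaf_tumor"] > vaf_t_min) & (rec["vaf_normal"] < vaf_n_max)
    return MutationTable(rec[keep].copy())


def mutation_frequency(
    table: MutationTable,
    n_patients: int,
    *,
    nonsynonymous_only: bool = True,
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-gene mutated-patient counts and cohort fractions.

    A patient counts once per gene regardless of variant multiplicity.
    ``above_cutoff`` flags genes mutated in at least *cutoff* of the
    *n_patients*-patient cohort (>= comparison, so 5% means 5 of 84
    patients qualifies at 5/84 = 0.0595).
    """
    rec = table.records
    if nonsynonymous_only:
        rec = rec[rec["nonsynonymous"]]
    counts = rec.groupby("gene")["patient"].nunique().sort_values(ascending=False)
    out = pd.DataFrame({"n_mutated": counts})
    out["fraction"] = out["n_mutated"] / n_patients
    out["above_cutoff"] = out["fraction"] >= cutoff
    return out


def mutant_patients(
    table: MutationTable,
    gene: str,
    *,
    truncating_only: bool = False,
) -> set:
    """Patients carrying a qualifying (nonsynonymous) variant in *gene*."""
    rec = table.records
    mask = (rec["gene"] == gene) & rec["nonsynonymous"]
    if truncating_only:
        mask &= rec["truncating"]
    return set(rec.loc[mask, "patient"])


def mutation_protein_effect(
    gene: str,
    tumor_fot: pd.DataFrame,
    mutations: MutationTable,
    *,
    nearby_fot: pd.DataFrame | None = None,
    truncating_only: bool = False,
    min_detect: int = 3,
) -> dict:
    """Effect of a gene's mutations on its own tumor protein abundance.

    Tests detected tumor FOT values of the gene's protein, mutant vs.
    wild-type patients (Wilcoxon rank-sum), after classifying the
    detection status: ``"detected-in-tumor"``, ``"undetected-in-tumor"``
    (detected only in nearby tissue), ``"never-detected"``, or
    ``"insufficient"`` when either group has fewer than *min_detect*
    detected tumors.
    """
    patients = list(tumor_fot.columns)
    mut = mutant_patients(mutations, gene, truncating_only=truncating_only)
    mut &= set(patients)
    wt = [p for p in patients if p not in mut]
    if gene not in tumor_fot.index:
        if nearby_fot is not None and gene in nearby_fot.index and nearby_fot.loc[gene].notna().any():
            status = "undetected-in-tumor"
        else:
            status = "never-detected"
        return {"gene": gene, "status": status, "test": None,
                "n_mutant": len(mut), "n_wildtype": len(wt)}
    row = tumor_fot.loc[gene]
    if not row.notna().any():
        detected_nearby = (
            nearby_fot is not None
            and gene in nearby_fot.index
            and nearby_fot.loc[gene].notna().any()
        )
        status = "undetected-in-tumor" if detected_nearby else "never-detected"
        return {"gene": gene, "status": status, "test": None,
                "n_mutant": len(mut), "n_wildtype": len(wt)}
    x = row[list(mut)].dropna() if mut else pd.Series(dtype=float)
    y = row[wt].dropna()
    if len(x) < min_detect or len(y) < min_detect:
        return {"gene": gene, "status": "insufficient", "test": None,
                "n_mutant": len(mut), "n_wildtype": len(wt)}
    test = wilcoxon_rank_sum(x.to_numpy(), y.to_numpy())
    return {
        "gene": gene,
        "status": "detected-in-tumor",
        "test": test,
        "n_mutant": len(mut),
        "n_wildtype": len(wt),
        "mean_mutant": float(x.mean()),
        "mean_wildtype": float(y.mean()),
    }


@dataclass
class MutationAlteredProteome:
    """Proteins shifted in tumors carrying a given gene's mutations."""

    gene: str
    table: pd.DataFrame  # per protein: p, mean_mutant, mean_wildtype, mean_ratio
    p_max: float
    up_fold: float
    down_fold: float

    @property
    def up(self) -> pd.Index:
        t = self.table
        return t.index[(t["p"] < self.p_max) & (t["mean_ratio"] > self.up_fold)]

    @property
    def down(self) -> pd.Index:
        t = self.table
        return t.index[(t["p"] < self.p_max) & (t["mean_ratio"] < self.down_fold)]

    @property
    def altered(self) -> frozenset:
        return frozenset(self.up) | frozenset(self.down)


def _vectorized_wilcoxon(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p (tie-corrected normal approximation)."""
    res = sps.mannwhitneyu(
        x, y, axis=-1, alternative="two-sided", method="asymptotic",
        use_continuity=True,
    )
    p = np.asarray(res.pvalue, dtype=float)
    # constant rows carry no information
    both = np.concatenate([x, y], axis=-1)
    degenerate = np.all(both == both[..., :1], axis=-1)
    p[degenerate] = 1.0
    return np.minimum(p, 1.0)


def mutation_altered_proteome(
    gene: str,
    tumor_fot: pd.DataFrame,
    mutations: MutationTable,
    *,
    p_max: float = 0.05,
    up_fold: float = 1.6,
    down_fold: float = 0.33,
    floor: float = FLOOR_PRESENTATION,
    min_group: int = 3,
) -> MutationAlteredProteome:
    """Scan all proteins for association with *gene*'s mutation status.

    Abundances are floored at the quantification floor (undetected ->
    floor) before both the rank-sum test and the mutant/wild-type mean
    ratio; both fold gates are strict.
    """
    patients = list(tumor_fot.columns)
    mut = sorted(mutant_patients(mutations, gene) & set(patients))
    wt = [p for p in patients if p not in set(mut)]
    if len(mut) < min_group or len(wt) < min_group:
        raise ValueError(
            f"gene {gene!r}: need >= {min_group} mutant and wild-type tumors "
            f"(have {len(mut)} and {len(wt)})"
        )
    floored = tumor_fot.fillna(0.0).clip(lower=floor)
    x = floored[mut].to_numpy(dtype=float)
    y = floored[wt].to_numpy(dtype=float)
    p = _vectorized_wilcoxon(x, y)
    mean_mut = x.mean(axis=1)
    mean_wt = y.mean(axis=1)
    table = pd.DataFrame(
        {
            "p": p,
            "mean_mutant": mean_mut,
            "mean_wildtype": mean_wt,
            "mean_ratio": mean_mut / mean_wt,
        },
        index=tumor_fot.index,
    )
    return MutationAlteredProteome(gene, table, p_max, up_fold, down_fold)


def jaccard(set_a, set_b) -> float:
    """Intersection over union; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def pathway_mutation_profile(
    table: MutationTable,
    sets: GeneSetCollection,
    patients=None,
) -> pd.DataFrame:
    """Patient x pathway binary matrix: 1 iff any member gene carries a
    qualifying (nonsynonymous) variant in that patient."""
    rec = table.records[table.records["nonsynonymous"]]
    if patients is None:
        patients = sorted(rec["patient"].unique())
    by_patient = rec.groupby("patient")["gene"].agg(set)
    data = {}
    for name, members in sets.items():
        data[name] = [
            int(bool(by_patient.get(p, set()) & members)) for p in patients
        ]
    return pd.DataFrame(data, index=pd.Index(patients, name="patient"))


def gene_mutation_profile(table: MutationTable, patients=None, genes=None) -> pd.DataFrame:
    """Patient x gene binary nonsynonymous-mutation matrix."""
    rec = table.records[table.records["nonsynonymous"]]
    if patients is None:
        patients = sorted(rec["patient"].unique())
    if genes is None:
        genes = sorted(rec["gene"].unique())
    profile = pd.DataFrame(0, index=pd.Index(patients, name="patient"), columns=genes)
    for _, row in rec.iterrows():
        if row["patient"] in profile.index and row["gene"] in profile.columns:
            profile.loc[row["patient"], row["gene"]] = 1
    return profile


def subtype_mutation_enrichment(
    labels: pd.Series,
    profile: pd.DataFrame,
) -> pd.DataFrame:
    """One-vs-rest Fisher's exact test per (feature, subtype).

    *labels* maps patients to subtypes; *profile* is a patient x feature
    binary matrix (gene- or pathway-level).  Returns one row per feature
    and subtype with the 2x2 counts, odds ratio and p-value.
    """
    common = labels.index.intersection(profile.index)
    labels = labels.loc[common]
    profile = profile.loc[common]
    rows = []
    for subtype in sorted(labels.unique()):
        in_grp = labels == subtype
        for feature in profile.columns:
            mutated = profile[feature].astype(bool)
            a = int((in_grp & mutated).sum())
            b = int((in_grp & ~mutated).sum())
            c = int((~in_grp & mutated).sum())
            d = int((~in_grp & ~mutated).sum())
            res = fisher_exact([[a, b], [c, d]])
            rows.append(
                {
                    "feature": feature,
                    "subtype": subtype,
                    "mutated_in": a,
                    "total_in": a + b,
                    "mutated_out": c,
                    "total_out": c + d,
                    "odds_ratio": res.effect,
                    "p": res.p_value,
                }
            )
    return pd.DataFrame(rows)
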