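"""Domain types and tabular readers/writers.

All on-disk formats are plain text: TSV for the protein abundance matrix
and mutation table, CSV for clinical and annotation tables, and standard
GMT for gene sets.  Abundance values live on the FOT x 10^5 presentation
scale; a missing cell means "not detected", which is distinct from an
observed zero (a literal 0 is treated as missing only when the dialect
flag ``zero_is_missing`` is set).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TUMOR = "tumor"
NEARBY = "nearby"

#: sample-id suffix -> tissue
_TISSUE_CODES = {"T": TUMOR, "N": NEARBY}

#: variant class -> (nonsynonymous, truncating); truncating = nonsense,
#: frameshift and canonical splice-site changes
VARIANT_CLASS_FLAGS: dict[str, tuple[bool, bool]] = {
    "missense": (True, False),
    "nonsense": (True, True),
    "frameshift": (True, True),
    "splice": (True, True),
    "inframe": (True, False),
    "silent": (False, False),
    "synonymous": (False, False),
    "intronic": (False, False),
    "utr": (False, False),
}

DRUGGABLE_CATEGORIES = frozenset(
    {
        "enzyme",
        "gpcr",
        "kinase",
        "ion channel",
        "transmembrane",
        "extracellular",
    }
)

#: ordinal coding of clinical stage (AJCC Ib through IV)
STAGE_ORDER: dict[str, int] = {"Ib": 1, "II": 2, "III": 3, "IV": 4}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AbundanceMatrix:
    """Protein x sample FOT abundance matrix with tumor/nearby pairing.

    Parameters
    ----------
    values : pandas.DataFrame
        Proteins (rows, gene symbols) by samples (columns, sample ids);
        NaN encodes "not detected".  Values are on the FOT x 10^5 scale,
        so the 10^-5 FOT quantification floor sits at 1.0.
    samples : pandas.DataFrame
        Indexed by sample id with columns ``patient`` and ``tissue``
        (``"tumor"`` or ``"nearby"``).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate protein row: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample column: {dup!r}")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        bad = set(self.samples["tissue"]) - {TUMOR, NEARBY}
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")
        counts = self.samples.groupby(["patient", "tissue"]).size()
        if (counts > 1).any():
            pat, tis = counts[counts > 1].index[0]
            raise ValueError(f"patient {pat!r} has more than one {tis} sample")
        neg = self.values.lt(0).any().any()
        if neg:
            raise ValueError("abundance values must be non-negative")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def patients(self) -> list:
        """Patients with both a tumor and a nearby sample, in first-seen order."""
        by_patient = self.samples.groupby("patient")["tissue"].agg(set)
        paired = [p for p, t in by_patient.items() if {TUMOR, NEARBY} <= t]
        order = {p: i for i, p in enumerate(self.samples["patient"])}
        return sorted(paired, key=order.get)

    def tissue_matrix(self, tissue: str) -> pd.DataFrame:
        """Proteins x patients matrix for one tissue (columns renamed to patients)."""
        meta = self.samples[self.samples["tissue"] == tissue]
        sub = self.values[meta.index]
        sub.columns = meta["patient"].to_list()
        return sub

    def detected(self) -> pd.DataFrame:
        return self.values.notna()

    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ProteinEvidence:
    """Per-(protein, sample) identification evidence feeding iBAQ and the
    high-confidence (D2) gate.

    ``intensity``, ``unique_peptides`` and ``ion_score`` are proteins x
    samples frames; ``theoretical_peptides`` is a per-protein Series of
    observable fully tryptic peptide counts (>= 1 wherever iBAQ is taken).
    """

    intensity: pd.DataFrame
    unique_peptides: pd.DataFrame
    ion_score: pd.DataFrame
    theoretical_peptides: pd.Series

    def __post_init__(self) -> None:
        if (self.intensity.fillna(0) < 0).any().any():
            raise ValueError("intensities must be non-negative")
        known = self.theoretical_peptides.dropna()
        if (known < 1).any():
            bad = known[known < 1].index[0]
            raise ValueError(f"theoretical peptide count < 1 for {bad!r}")


@dataclass
class MutationTable:
    """Somatic variant records (one row per distinct variant per patient)."""

    records: pd.DataFrame

    REQUIRED = ("patient", "gene", "variant_class", "vaf_tumor", "vaf_normal")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.records.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        for col in ("vaf_tumor", "vaf_normal"):
            vals = self.records[col].astype(float)
            bad = vals[(vals < 0) | (vals > 1)]
            if len(bad):
                raise ValueError(
                    f"{col} outside [0, 1] at record index {bad.index[0]}"
                )
        if "nonsynonymous" not in self.records.columns:
            flags = self.records["variant_class"].map(_class_flags)
            self.records = self.records.assign(
                nonsynonymous=[f[0] for f in flags],
                truncating=[f[1] for f in flags],
            )

    @property
    def patients(self) -> list:
        return sorted(self.records["patient"].unique())

    def nonsynonymous(self) -> "MutationTable":
        return MutationTable(self.records[self.records["nonsynonymous"]].copy())


def _class_flags(variant_class: str) -> tuple[bool, bool]:
    key = str(variant_class).strip().lower()
    if key not in VARIANT_CLASS_FLAGS:
        raise ValueError(f"unknown variant class {variant_class!r}")
    return VARIANT_CLASS_FLAGS[key]


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates and right-censored overall survival."""

    data: pd.DataFrame

    REQUIRED = ("age", "gender", "site", "stage", "chemo", "os_months", "event")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        os_m = self.data["os_months"].astype(float)
        if (os_m <= 0).any():
            pat = self.data.index[os_m <= 0][0]
            raise ValueError(f"non-positive OS time for patient {pat!r}")
        ev = set(self.data["event"].astype(int).unique())
        if not ev <= {0, 1}:
            raise ValueError(f"event flags must be 0/1, got {sorted(ev)}")

    @property
    def patients(self) -> pd.Index:
        return self.data.index

    def stage_ordinal(self) -> pd.Series:
        """Stage coded 1 (Ib) through 4 (IV) as an ordered numeric covariate."""
        stage = self.data["stage"]
        if pd.api.types.is_numeric_dtype(stage):
            return stage.astype(float)
        mapped = stage.map(STAGE_ORDER)
        if mapped.isna().any():
            bad = stage[mapped.isna()].iloc[0]
            raise ValueError(f"unknown clinical stage {bad!r}")
        return mapped.astype(float)


@dataclass
class GeneSetCollection:
    """Named gene sets (KEGG/Reactome/Biocarta/PID/hallmark/custom)."""

    sets: dict[str, frozenset]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"empty gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def restrict(self, background) -> "GeneSetCollection":
        """Intersect every set with *background*, dropping emptied sets."""
        bg = set(background)
        kept, dropped = {}, []
        for name, members in self.sets.items():
            inter = frozenset(members & bg)
            if inter:
                kept[name] = inter
            else:
                dropped.append(name)
        if dropped:
            logger.info("dropped %d gene sets with no background overlap", len(dropped))
        return GeneSetCollection(kept, {n: self.sources.get(n, "") for n in kept})


@dataclass
class AnnotationTable:
    """Per-protein druggability and tissue-specificity annotation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("druggable", "stomach_specific", "genomic_target"):
            if col not in self.data.columns:
                raise ValueError(f"annotation table missing column {col!r}")
            self.data[col] = self.data[col].astype(bool)
        if "category" in self.data.columns:
            cats = set(self.data.loc[self.data["druggable"], "category"].str.lower())
            bad = cats - DRUGGABLE_CATEGORIES
            if bad:
                raise ValueError(f"unknown druggable categories: {sorted(bad)}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SAMPLE_ID_RE = re.compile(r"^(?P<patient>.+)_(?P<code>[TN])$")


def parse_sample_id(sample_id: str, pattern: re.Pattern = _SAMPLE_ID_RE):
    m = pattern.match(sample_id)
    if m is None:
        raise ValueError(f"unparseable sample id in column {sample_id!r}")
    return m.group("patient"), _TISSUE_CODES[m.group("code")]


def read_abundance_matrix(
    path,
    *,
    zero_is_missing: bool = False,
    sample_pattern: str | re.Pattern = _SAMPLE_ID_RE,
) -> AbundanceMatrix:
    """Read a proteins x samples FOT TSV into an :class:`AbundanceMatrix`.

    The first column holds gene symbols; remaining column headers encode
    patient and tissue as ``<patient>_<T|N>`` (override via
    *sample_pattern*).  Empty/NA cells map to "not detected"; literal
    zeros do too when *zero_is_missing* is set.
    """
    if isinstance(sample_pattern, str):
        sample_pattern = re.compile(sample_pattern)
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise ValueError(f"duplicate protein row: {dup!r}")
    if zero_is_missing:
        values = values.where(values != 0)
    meta = {}
    for col in values.columns:
        patient, tissue = parse_sample_id(str(col), sample_pattern)
        meta[col] = {"patient": patient, "tissue": tissue}
    samples = pd.DataFrame.from_dict(meta, orient="index")
    samples.index.name = "sample"
    _warn_case_conflicts(values.index)
    return AbundanceMatrix(values=values.astype(float), samples=samples)


def write_abundance_matrix(matrix: AbundanceMatrix, path) -> None:
    """Write the matrix back to TSV (empty cell = not detected)."""
    out = matrix.values.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.10g")


def _warn_case_conflicts(symbols: pd.Index) -> None:
    lowered = pd.Index([s.lower() for s in symbols])
    if lowered.duplicated().any():
        logger.warning("gene symbols differing only by case are present")


def read_mutation_table(path) -> MutationTable:
    """Read a MAF-like TSV with patient/gene/class/VAF columns.

    Nonsynonymous and truncating flags are derived deterministically from
    the variant class via :data:`VARIANT_CLASS_FLAGS`; silent variants are
    retained with ``nonsynonymous=False``.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    return MutationTable(df)


def read_clinical(path) -> ClinicalTable:
    """Read a per-patient clinical CSV (first column patient id)."""
    df = pd.read_csv(path, index_col=0)
    df.columns = [c.strip().lower() for c in df.columns]
    return ClinicalTable(df)


def read_annotation(path) -> AnnotationTable:
    """Read a per-protein annotation CSV (first column protein symbol)."""
    df = pd.read_csv(path, index_col=0)
    df.columns = [c.strip().lower() for c in df.columns]
    return AnnotationTable(df)


def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file (set name, description, then members)."""
    sets: dict[str, frozenset] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: no gene members")
            name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            if not members:
                raise ValueError(f"empty gene set {name!r}")
            sets[name] = frozenset(members)
            sources[name] = desc
    return GeneSetCollection(sets, sources)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = collection.sources.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
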