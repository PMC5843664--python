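"""Variant filtering, summaries, and mutation-proteome association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dgcproteo.io import GeneSetCollection, MutationTable
from dgcproteo.proteogenomics import (
    filter_variants,
    gene_mutation_profile,
    jaccard,
    mutation_altered_proteome,
    mutation_frequency,
    mutation_protein_effect,
    pathway_mutation_profile,
    subtype_mutation_enrichment,
)


def mut_table(rows):
    return MutationTable(
        pd.DataFrame(
            rows,
            columns=["patient", "gene", "variant_class", "vaf_tumor", "vaf_normal"],
        )
    )


class TestVafFilter:
    @pytest.mark.parametrize(
        "vaf_t,vaf_n,kept",
        [
            (0.5, 0.0, True),
            (0.04, 0.0, False),
            (0.5, 0.03, False),  # strict < on the normal side
            (0.05, 0.0, False),  # strict > on the tumor side
        ],
    )
    def test_boundaries(self, vaf_t, vaf_n, kept):
        t = mut_table([("P1", "G", "missense", vaf_t, vaf_n)])
        assert (len(filter_variants(t).records) == 1) is kept


class TestFrequency:
    def test_patient_counts_once_per_gene(self):
        t = mut_table(
            [
                ("P1", "TP53", "missense", 0.4, 0.0),
                ("P1", "TP53", "nonsense", 0.2, 0.0),
            ]
        )
        out = mutation_frequency(t, n_patients=10)
        assert out.loc["TP53", "n_mutated"] == 1

    def test_five_percent_cutoff_is_inclusive(self):
        rows = [(f"P{i}", "G", "missense", 0.4, 0.0) for i in range(5)]
        out = mutation_frequency(mut_table(rows), n_patients=84)
        assert out.loc["G", "fraction"] == pytest.approx(5 / 84)
        assert bool(out.loc["G", "above_cutoff"])

    def test_silent_only_gene_not_counted(self):
        t = mut_table([("P1", "G", "silent", 0.4, 0.0)])
        out = mutation_frequency(t, n_patients=10)
        assert "G" not in out.index or out.loc["G", "n_mutated"] == 0


class TestJaccard:
    def test_examples(self):
        assert jaccard({"A", "B"}, {"B", "C"}) == pytest.approx(1 / 3)
        assert jaccard({"A"}, {"A"}) == 1.0
        assert jaccard({"A"}, {"B"}) == 0.0
        assert jaccard(set(), set()) == 0.0

    def test_symmetry(self):
        a, b = {"x", "y", "z"}, {"y", "q"}
        assert jaccard(a, b) == jaccard(b, a)


class TestAlteredProteome:
    def _cohort(self, seed=0, n_mut=10, n_wt=20, n_prot=60):
        rng = np.random.default_rng(seed)
        patients = [f"P{i}" for i in range(n_mut + n_wt)]
        tumor = pd.DataFrame(
            10 ** rng.normal(1.5, 0.3, size=(n_prot, len(patients))),
            index=[f"G{i}" for i in range(n_prot)],
            columns=patients,
        )
        rows = [(p, "MUT", "missense", 0.4, 0.0) for p in patients[:n_mut]]
        return tumor, mut_table(rows), patients

    def test_planted_program_recovered(self):
        tumor, muts, patients = self._cohort(seed=1)
        mut_cols = patients[:10]
        tumor.loc[[f"G{i}" for i in range(10)], mut_cols] *= 2.5
        tumor.loc[[f"G{i}" for i in range(10, 16)], mut_cols] *= 0.2
        result = mutation_altered_proteome("MUT", tumor, muts)
        up_truth = {f"G{i}" for i in range(10)}
        down_truth = {f"G{i}" for i in range(10, 16)}
        assert len(up_truth & set(result.up)) >= 8
        assert len(down_truth & set(result.down)) >= 5
        spurious = (set(result.up) | set(result.down)) - up_truth - down_truth
        assert len(spurious) <= 3

    def test_label_swap_maps_up_to_down(self):
        tumor, muts, patients = self._cohort(seed=2)
        tumor.loc["G0", patients[:10]] *= 3.0
        res = mutation_altered_proteome("MUT", tumor, muts)
        # swap: everyone not mutated is "mutated"
        swapped = mut_table([(p, "MUT", "missense", 0.4, 0.0) for p in patients[10:]])
        res_swapped = mutation_altered_proteome(
            "MUT", tumor, swapped, up_fold=1 / 0.33, down_fold=1 / 1.6
        )
        assert "G0" in set(res.up)
        assert "G0" in set(res_swapped.down)

    def test_fold_gate_is_strict(self):
        # mean mutant/wild ratio exactly at the gate -> excluded
        tumor = pd.DataFrame(
            [[2.0, 2.0, 2.0, 1.0, 1.0, 1.0]],
            index=["G0"],
            columns=[f"P{i}" for i in range(6)],
        )
        muts = mut_table([(f"P{i}", "MUT", "missense", 0.4, 0.0) for i in range(3)])
        res = mutation_altered_proteome("MUT", tumor, muts, up_fold=2.0, floor=0.0001)
        assert res.table.loc["G0", "mean_ratio"] == 2.0
        assert "G0" not in set(res.up)

    def test_too_few_mutants_rejected(self):
        tumor, _, patients = self._cohort()
        muts = mut_table([("P0", "MUT", "missense", 0.4, 0.0)])
        with pytest.raises(ValueError, match="MUT"):
            mutation_altered_proteome("MUT", tumor, muts)

    def test_null_cohort_false_calls_bounded(self):
        counts = []
        for seed in range(5):
            tumor, muts, _ = self._cohort(seed=seed + 10)
            res = mutation_altered_proteome("MUT", tumor, muts)
            counts.append(len(res.up) + len(res.down))
        # 5% nominal level and >1.6-fold gate: expect nearly none of 60
        assert np.median(counts) <= 3


class TestProteinEffect:
    def test_planted_knockdown_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            patients = [f"P{i}" for i in range(30)]
            tumor = pd.DataFrame(
                10 ** rng.normal(1.5, 0.3, size=(1, 30)), index=["MUT"], columns=patients
            )
            tumor.loc["MUT", patients[:10]] /= 4.0
            muts = mut_table([(p, "MUT", "missense", 0.4, 0.0) for p in patients[:10]])
            out = mutation_protein_effect("MUT", tumor, muts)
            hits += out["test"].p_value < 0.05
        assert hits >= 8

    def test_detection_status_classification(self):
        patients = ["P1", "P2", "P3"]
        tumor = pd.DataFrame(
            [[np.nan] * 3], index=["MUT"], columns=patients, dtype=float
        )
        nearby = pd.DataFrame([[5.0, 6.0, 7.0]], index=["MUT"], columns=patients)
        muts = mut_table([("P1", "MUT", "missense", 0.4, 0.0)])
        out = mutation_protein_effect("MUT", tumor, muts, nearby_fot=nearby)
        assert out["status"] == "undetected-in-tumor"
        out2 = mutation_protein_effect("OTHER", tumor, muts)
        assert out2["status"] == "never-detected"

    def test_insufficient_detection(self):
        patients = [f"P{i}" for i in range(6)]
        tumor = pd.DataFrame(
            [[1.0, np.nan, np.nan, 2.0, 3.0, 4.0]], index=["MUT"], columns=patients
        )
        muts = mut_table([(p, "MUT", "missense", 0.4, 0.0) for p in patients[:3]])
        assert mutation_protein_effect("MUT", tumor, muts)["status"] == "insufficient"


class TestProfilesAndEnrichment:
    def test_pathway_profile(self, small_mutations):
        sets = GeneSetCollection({"PATH": frozenset({"TP53", "NRAS"})})
        prof = pathway_mutation_profile(
            small_mutations, sets, patients=["P1", "P2", "P3", "P9"]
        )
        assert prof.loc["P1", "PATH"] == 1
        assert prof.loc["P2", "PATH"] == 0  # only a silent TP53 variant
        assert prof.loc["P9", "PATH"] == 0  # no variants at all

    def test_exclusive_feature_p_matches_hypergeometric(self):
        patients = [f"P{i}" for i in range(28)]
        labels = pd.Series([1] * 8 + [2] * 20, index=patients)
        profile = pd.DataFrame({"G": [1] * 8 + [0] * 20}, index=patients)
        out = subtype_mutation_enrichment(labels, profile)
        row = out[(out["feature"] == "G") & (out["subtype"] == 1)].iloc[0]
        # all 8 mutated patients land in the 8-patient subtype; no other
        # table with these margins has probability <= the observed one
        expected = sps.hypergeom.pmf(8, 28, 8, 8)
        assert row["p"] == pytest.approx(expected, rel=1e-6)

    def test_ubiquitous_feature_p_one(self):
        patients = [f"P{i}" for i in range(10)]
        labels = pd.Series([1] * 5 + [2] * 5, index=patients)
        profile = pd.DataFrame({"G": [1] * 10}, index=patients)
        out = subtype_mutation_enrichment(labels, profile)
        assert (out["p"] == 1.0).all()

    def test_gene_profile_counts(self, small_mutations):
        prof = gene_mutation_profile(small_mutations)
        assert prof.loc["P1", "TP53"] == 1
        assert prof.loc["P2", "TP53"] == 0  # silent only
        assert prof.loc["P2", "CDH1"] == 1
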