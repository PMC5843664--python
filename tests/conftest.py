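"""Shared fixtures: hand-built matrices and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dgcproteo.io import AbundanceMatrix, MutationTable


def make_abundance(values: dict[str, list], patients: list[str]) -> AbundanceMatrix:
    """Build an AbundanceMatrix from per-protein [T1, N1, T2, N2, ...] lists."""
    columns = []
    for p in patients:
        columns += [f"{p}_T", f"{p}_N"]
    frame = pd.DataFrame.from_dict(values, orient="index", columns=columns, dtype=float)
    frame.index.name = "protein"
    samples = pd.DataFrame(
        {
            "patient": [c.rsplit("_", 1)[0] for c in columns],
            "tissue": ["tumor" if c.endswith("T") else "nearby" for c in columns],
        },
        index=pd.Index(columns, name="sample"),
    )
    return AbundanceMatrix(values=frame, samples=samples)


NA = np.nan


@pytest.fixture
def cascade_fixture() -> tuple[AbundanceMatrix, dict]:
    """Six proteins, four patients (8 samples), engineered so that exactly
    5, 4, 3, 2 proteins survive D3, D4, D5, D6.

    Uses detect_fraction = 1/2 (threshold 4 of 8 samples) and
    ratio_fraction = 1/2 (threshold 2 of 4 patients) so every stage can
    discriminate at this size.  Values are FOT x 1e5; the floor is 1.0.

    - KRT1: abundant everywhere -> removed at D3 (keratin exclusion).
    - P_RARE: far above the floor but detected in only 2 samples ->
      passes D3, dropped at D4.
    - P_DIM: detected in 6 samples but above the floor in only 2 ->
      passes D4, dropped at D5.
    - P_FLAT: abundant, all T/N ratios exactly 3 (strict boundary) ->
      passes D5, dropped at D6.
    - P_DE / P_DOWN: abundant, T/N = 10 (up) and 0.1 (down) for every
      patient -> survive D6.
    """
    values = {
        #         P1_T   P1_N   P2_T   P2_N   P3_T   P3_N   P4_T   P4_N
        "KRT1": [50.0, 50.0, 50.0, 50.0, 50.0, 50.0, 50.0, 50.0],
        "P_RARE": [90.0, NA, NA, NA, NA, 80.0, NA, NA],
        "P_DIM": [9.0, 0.5, 0.6, 0.7, 6.0, 0.4, NA, NA],
        "P_FLAT": [30.0, 10.0, 30.0, 10.0, 30.0, 10.0, 30.0, 10.0],
        "P_DE": [100.0, 10.0, 100.0, 10.0, 100.0, 10.0, 100.0, 10.0],
        "P_DOWN": [10.0, 100.0, 10.0, 100.0, 10.0, 100.0, 10.0, 100.0],
    }
    matrix = make_abundance(values, ["P1", "P2", "P3", "P4"])
    config = {"detect_fraction": 0.5, "ratio_fraction": 0.5}
    return matrix, config


@pytest.fixture
def small_mutations() -> MutationTable:
    records = pd.DataFrame(
        [
            ("P1", "TP53", "missense", 0.4, 0.0),
            ("P1", "TP53", "nonsense", 0.3, 0.01),
            ("P2", "TP53", "silent", 0.5, 0.0),
            ("P2", "CDH1", "frameshift", 0.2, 0.0),
            ("P3", "CDH1", "splice", 0.3, 0.02),
            ("P4", "APC", "inframe", 0.25, 0.0),
        ],
        columns=["patient", "gene", "variant_class", "vaf_tumor", "vaf_normal"],
    )
    return MutationTable(records)
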