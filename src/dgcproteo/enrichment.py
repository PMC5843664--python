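"""Gene-set over-representation against a detected-protein background.

One Fisher's exact test per gene set on the 2x2 table (in-set & DE,
in-set & not-DE, out-of-set & DE, out-of-set & not-DE).  Sets are
intersected with the background before testing (the detected D2 proteins
in the cohort analysis), genes outside the background are dropped from
the DE set with a log message, and rows come back sorted by p-value.
The default is one-sided over-representation; a two-sided flag and an
optional BH q-value column are available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .stats import bh_adjust, fisher_exact

logger = logging.getLogger(__name__)


def enrich(
    de_set,
    sets: GeneSetCollection,
    background,
    *,
    two_sided: bool = False,
    adjust: bool = False,
) -> pd.DataFrame:
    """Over-representation of *de_set* in each gene set given *background*.

    Returns one row per (restricted) set: overlap, set size in the
    background, DE and background sizes, odds ratio and Fisher p, sorted
    ascending by p.  With ``adjust=True`` a BH ``q`` column is added.
    """
    background = set(background)
    de = set(de_set)
    outside = de - background
    if outside:
        logger.info("dropping %d DE genes absent from the background", len(outside))
        de &= background
    if not de:
        logger.warning("empty DE set; returning empty enrichment table")
        return pd.DataFrame(
            columns=[
                "set",
                "overlap",
                "set_size",
                "de_size",
                "background_size",
                "odds_ratio",
                "p",
            ]
        ).set_index("set")
    restricted = sets.restrict(background)
    n_bg = len(background)
    n_de = len(de)
    rows = []
    alternative = "two-sided" if two_sided else "greater"
    for name, members in restricted.items():
        overlap = len(members & de)
        in_set_not_de = len(members) - overlap
        out_de = n_de - overlap
        out_not = n_bg - len(members) - out_de
        res = fisher_exact(
            [[overlap, in_set_not_de], [out_de, out_not]], alternative=alternative
        )
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(members),
                "de_size": n_de,
                "background_size": n_bg,
                "odds_ratio": res.extra["odds_ratio_continuity"]
                if not np.isfinite(res.effect)
                else res.effect,
                "p": res.p_value,
            }
        )
    table = pd.DataFrame(rows).set_index("set").sort_values("p")
    if adjust:
        table["q"] = bh_adjust(table["p"].to_numpy())
    return table
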