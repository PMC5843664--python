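"""Paired permutation differential expression (SAM) and DEP calling.

The model follows the significance-analysis-of-microarrays recipe for
two-class paired data applied to per-patient log10 tumor/nearby ratios
z_k: the regularized statistic is d = z_bar / (s + s0) with
s = sqrt(sum (z_k - z_bar)^2 / (n (n - 1))), the fudge factor s0 chosen
by the percentile procedure that minimizes the coefficient of variation
of d's spread across windows of s, and the null distribution built from
sign flips of the paired differences (exhaustive for n <= 12, random
otherwise).  For each threshold delta, asymmetric cut-points on the
observed-versus-expected order plot yield a called set, a median false
count across permutations, and an estimated FDR; a protein's q-value is
the smallest FDR at which it is called.

On top of the permutation machinery sit the cohort-level calls used for
the tumor/nearby comparison: the differentially-expressed percentage
|N_up - N_down| / N_detected, the joint (q < 0.01, percentage > 50%)
call, the stricter consistency-based call (detected in > 75% of
patients, > 3-fold change in > 60% of detected cases), and per-protein
overexpression fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import RatioMatrix

logger = logging.getLogger(__name__)

LOG10_3 = float(np.log10(3.0))


def _as_frame(ratios) -> pd.DataFrame:
    if isinstance(ratios, RatioMatrix):
        return ratios.log_ratios
    return pd.DataFrame(ratios)


# ---------------------------------------------------------------------------
# SAM model
# ---------------------------------------------------------------------------


class PairedSAM:
    """Two-class paired SAM on a proteins x patients log-ratio matrix.

    Parameters
    ----------
    ratios : RatioMatrix or DataFrame
        Per-patient paired differences (log10 T/N), no missing entries.
    n_permutations : int
        Random sign-flip permutations when n > ``exhaustive_max_n``;
        below that all 2^n flips are enumerated and this is ignored.
    seed : int
        Seed for the permutation draw (mandatory for reproducibility
        when random permutations are used).
    s0 : float, optional
        Fix the fudge factor instead of selecting it (0 recovers the
        one-sample t statistic).
    """

    def __init__(
        self,
        ratios,
        *,
        n_permutations: int = 1000,
        seed: int | None = None,
        s0: float | None = None,
        exhaustive_max_n: int = 12,
        n_delta: int = 200,
    ) -> None:
        self.ratios = _as_frame(ratios)
        if self.ratios.isna().any().any():
            raise ValueError("ratio matrix must have no undefined entries")
        if self.ratios.shape[1] < 3:
            raise ValueError("paired SAM needs >= 3 patients")
        self.n_permutations = int(n_permutations)
        self.seed = seed
        self.fixed_s0 = s0
        self.exhaustive_max_n = int(exhaustive_max_n)
        self.n_delta = int(n_delta)

    # -- statistic ---------------------------------------------------------

    @staticmethod
    def _zbar_s(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = z.shape[1]
        zbar = z.mean(axis=1)
        ss = ((z - zbar[:, None]) ** 2).sum(axis=1)
        s = np.sqrt(ss / (n * (n - 1)))
        return zbar, s

    @staticmethod
    def _select_s0(zbar: np.ndarray, s: np.ndarray) -> float:
        """Tusher percentile procedure for the exchangeability factor s0."""
        if np.allclose(s, 0):
            return 0.0
        alphas = np.arange(0, 101, 5)
        candidates = np.percentile(s, alphas)
        n_windows = min(100, max(2, s.size // 5))
        # quantile windows of s shared across candidates
        edges = np.percentile(s, np.linspace(0, 100, n_windows + 1))
        window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
        best_cv, best_s0 = np.inf, float(candidates[0])
        for s0 in candidates:
            d = zbar / (s + s0) if s0 > 0 else _safe_div(zbar, s)
            mads = []
            for w in range(n_windows):
                dw = d[window == w]
                if dw.size:
                    mads.append(np.median(np.abs(dw - np.median(dw))) * 1.4826)
            mads = np.asarray(mads)
            if mads.size < 2 or np.mean(mads) == 0:
                continue
            cv = np.std(mads) / np.mean(mads)
            if cv < best_cv:
                best_cv, best_s0 = cv, float(s0)
        return best_s0

    def _sign_matrix(self, n: int) -> np.ndarray:
        if n <= self.exhaustive_max_n:
            bits = np.arange(2**n)[:, None] >> np.arange(n) & 1
            return (2 * bits - 1).astype(float).T  # n x 2^n
        if self.n_permutations < 100:
            logger.warning(
                "only %d random permutations for n=%d patients; FDR estimates "
                "will be unstable",
                self.n_permutations,
                n,
            )
        if self.seed is None:
            raise ValueError("seed is required for random permutations")
        rng = np.random.default_rng(self.seed)
        return rng.choice([-1.0, 1.0], size=(n, self.n_permutations))

    def fit(self) -> "SAMResults":
        z = self.ratios.to_numpy(dtype=float)
        n = z.shape[1]
        zbar, s = self._zbar_s(z)
        s0 = self.fixed_s0 if self.fixed_s0 is not None else self._select_s0(zbar, s)
        d = _safe_div(zbar, s + s0) if s0 == 0 else zbar / (s + s0)

        signs = self._sign_matrix(n)  # n x B
        sum_sq = (z**2).sum(axis=1)  # sign-invariant
        zbar_null = z @ signs / n  # P x B
        ss_null = np.clip(sum_sq[:, None] - n * zbar_null**2, 0.0, None)
        s_null = np.sqrt(ss_null / (n * (n - 1)))
        denom = s_null + s0
        d_null = np.where(denom > 0, zbar_null / np.where(denom > 0, denom, 1.0), 0.0)

        order = np.argsort(d)
        d_sorted = d[order]
        dbar = np.sort(d_null, axis=0).mean(axis=1)

        gaps = np.abs(d_sorted - dbar)
        deltas = np.unique(np.concatenate([[0.0], gaps]))
        if deltas.size > self.n_delta:
            take = np.unique(
                np.quantile(deltas, np.linspace(0, 1, self.n_delta))
            )
            deltas = take

        rows = []
        cuts = []
        for delta in deltas:
            cut_up, cut_low = _cut_points(d_sorted, dbar, delta)
            called_mask = (d >= cut_up) | (d <= cut_low)
            n_called = int(called_mask.sum())
            false_counts = ((d_null >= cut_up) | (d_null <= cut_low)).sum(axis=0)
            median_false = float(np.median(false_counts))
            fdr = min(median_false / n_called, 1.0) if n_called else 0.0
            rows.append((float(delta), n_called, median_false, fdr))
            cuts.append((cut_up, cut_low))
        table = pd.DataFrame(
            rows, columns=["delta", "n_called", "median_false", "fdr"]
        )

        # q-value: smallest FDR over deltas at which the protein is called
        q = np.ones(d.size)
        for (cut_up, cut_low), fdr in zip(cuts, table["fdr"]):
            mask = (d >= cut_up) | (d <= cut_low)
            q = np.where(mask, np.minimum(q, fdr), q)

        return SAMResults(
            proteins=self.ratios.index,
            d=pd.Series(d, index=self.ratios.index, name="d"),
            zbar=pd.Series(zbar, index=self.ratios.index, name="zbar"),
            s=pd.Series(s, index=self.ratios.index, name="s"),
            q_values=pd.Series(q, index=self.ratios.index, name="q"),
            s0=float(s0),
            delta_table=table,
            cut_points=cuts,
            expected_order=dbar,
            n_permutations=signs.shape[1],
            exhaustive=n <= self.exhaustive_max_n,
            seed=self.seed,
        )


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    nz = den != 0
    out[nz] = num[nz] / den[nz]
    return out


def _cut_points(d_sorted: np.ndarray, dbar: np.ndarray, delta: float):
    """Asymmetric SAM cut-points from the observed-vs-expected plot."""
    above = d_sorted - dbar >= delta
    upper = above & (d_sorted >= 0)
    cut_up = d_sorted[upper].min() if upper.any() else np.inf
    below = dbar - d_sorted >= delta
    lower = below & (d_sorted <= 0)
    cut_low = d_sorted[lower].max() if lower.any() else -np.inf
    return float(cut_up), float(cut_low)


@dataclass
class SAMResults:
    """Fitted paired SAM: per-protein statistics and the per-delta FDR table."""

    proteins: pd.Index
    d: pd.Series
    zbar: pd.Series
    s: pd.Series
    q_values: pd.Series
    s0: float
    delta_table: pd.DataFrame
    cut_points: list
    expected_order: np.ndarray
    n_permutations: int
    exhaustive: bool
    seed: int | None = None

    def select_delta(self, fdr_target: float = 0.01) -> float:
        """Smallest delta whose estimated FDR is below *fdr_target*.

        Returns +inf (nothing called) when no delta with at least one
        called protein attains the target.
        """
        tab = self.delta_table
        ok = (tab["fdr"] < fdr_target) & (tab["n_called"] > 0)
        if not ok.any():
            return float("inf")
        return float(tab.loc[ok, "delta"].min())

    def called_at(self, delta: float) -> pd.Series:
        """Direction (+1/-1/0) per protein at threshold *delta*."""
        if np.isinf(delta):
            return pd.Series(0, index=self.proteins, name="direction")
        tab = self.delta_table
        idx = int(np.searchsorted(tab["delta"].to_numpy(), delta, side="right") - 1)
        idx = max(idx, 0)
        cut_up, cut_low = self.cut_points[idx]
        direction = np.where(
            self.d >= cut_up, 1, np.where(self.d <= cut_low, -1, 0)
        )
        return pd.Series(direction, index=self.proteins, name="direction")

    def summary(self) -> pd.DataFrame:
        """Per-protein table: d, z_bar, s, q-value."""
        return pd.DataFrame(
            {"d": self.d, "zbar": self.zbar, "s": self.s, "q": self.q_values}
        )


# ---------------------------------------------------------------------------
# cohort-level DEP calls
# ---------------------------------------------------------------------------


@dataclass
class DepCall:
    """Per-protein patient counts behind the differentially-expressed percentage."""

    table: pd.DataFrame  # n_up, n_down, n_detected, dep_percentage

    def __post_init__(self) -> None:
        t = self.table
        if ((t["n_up"] + t["n_down"]) > t["n_detected"]).any():
            raise ValueError("n_up + n_down exceeds n_detected")


def dep_percentage(n_up: int, n_down: int, n_detected: int) -> float:
    """|N_up - N_down| / N_detected for one protein."""
    if n_detected <= 0:
        raise ValueError("dep_percentage undefined with no detected patients")
    if n_up + n_down > n_detected:
        raise ValueError("n_up + n_down exceeds n_detected")
    return abs(n_up - n_down) / n_detected


def compute_dep_calls(ratios: RatioMatrix, fold: float = 3.0) -> DepCall:
    """Patient counts of >fold up/down change and the DEP percentage.

    N_detected counts patients in which the protein was detected in
    either tissue; proteins never detected get percentage NaN.
    """
    bound = np.log10(fold)
    lr = ratios.log_ratios
    detected = ratios.detected_either()
    n_up = ((lr > bound) & detected).sum(axis=1)
    n_down = ((lr < -bound) & detected).sum(axis=1)
    n_det = detected.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = (n_up - n_down).abs() / n_det.replace(0, np.nan)
    table = pd.DataFrame(
        {
            "n_up": n_up,
            "n_down": n_down,
            "n_detected": n_det,
            "dep_percentage": pct,
        }
    )
    return DepCall(table)


def call_significant_deps(
    sam: SAMResults,
    dep_calls: DepCall,
    q_max: float = 0.01,
    pct_min: float = 0.5,
) -> pd.DataFrame:
    """Proteins with SAM q-value < *q_max* and DEP percentage strictly > *pct_min*.

    Returns a frame indexed by called proteins with the q-value, the DEP
    percentage and direction (+1 when more patients go up than down).
    """
    common = sam.proteins.intersection(dep_calls.table.index)
    q = sam.q_values.loc[common]
    tab = dep_calls.table.loc[common]
    mask = (q < q_max) & (tab["dep_percentage"] > pct_min)
    called = tab.loc[mask.fillna(False)].copy()
    called["q"] = q.loc[called.index]
    called["direction"] = np.sign(called["n_up"] - called["n_down"]).astype(int)
    return called


def call_strict_deps(
    ratios: RatioMatrix,
    fold: float = 3.0,
    detect_min: float = 0.75,
    direction_min: float = 0.60,
) -> pd.DataFrame:
    """Consistency-based DEP call independent of the permutation test.

    A protein qualifies when it is detected (either tissue) in strictly
    more than *detect_min* of the patients and changed more than
    *fold*-fold in one consistent direction in strictly more than
    *direction_min* of the detected cases.
    """
    bound = np.log10(fold)
    lr = ratios.log_ratios
    detected = ratios.detected_either()
    n_patients = lr.shape[1]
    n_det = detected.sum(axis=1)
    frac_det = n_det / n_patients
    n_up = ((lr > bound) & detected).sum(axis=1)
    n_down = ((lr < -bound) & detected).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        up_frac = n_up / n_det.replace(0, np.nan)
        down_frac = n_down / n_det.replace(0, np.nan)
    up = (frac_det > detect_min) & (up_frac > direction_min)
    down = (frac_det > detect_min) & (down_frac > direction_min)
    out = pd.DataFrame(
        {
            "detected_fraction": frac_det,
            "up_fraction": up_frac,
            "down_fraction": down_frac,
            "direction": np.where(up, 1, np.where(down, -1, 0)),
        }
    )
    return out[out["direction"] != 0]


def overexpression_fraction(ratios: RatioMatrix, fold: float = 3.0) -> pd.DataFrame:
    """Fraction of patients with T/N strictly above *fold* per protein.

    ``fraction_all`` uses the whole cohort as denominator (the headline
    reporting style); ``fraction_detected`` restricts the denominator to
    patients in which the protein was detected.
    """
    bound = np.log10(fold)
    lr = ratios.log_ratios
    detected = ratios.detected_either()
    over = (lr > bound) & detected
    n_patients = lr.shape[1]
    n_det = detected.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_det = over.sum(axis=1) / n_det.replace(0, np.nan)
    return pd.DataFrame(
        {
            "fraction_all": over.sum(axis=1) / n_patients,
            "fraction_detected": frac_det.fillna(0.0),
        }
    )
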