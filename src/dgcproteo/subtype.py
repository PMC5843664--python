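"""Consensus resampled k-means subtyping with PAC-based model selection.

Patients are repeatedly subsampled (items only; features kept whole) and
partitioned by k-means for each candidate k; the consensus matrix M holds
the fraction of co-sampling draws in which two patients landed in the
same cluster.  Cluster-number selection follows the consensus-clustering
playbook: the empirical CDF of M's upper triangle and its area, the
relative delta-area between successive k, the proportion of ambiguous
clustering (PAC: entries strictly between two confidence bounds), and
the average silhouette width on the 1 - M distance.  The chosen k is the
PAC minimizer (ties toward smaller k), with the other metrics reported
so a human can override.  Final labels come from average-linkage
hierarchical clustering of 1 - M cut at k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# internal k-means (vectorized Lloyd with k-means++ seeding)
# ---------------------------------------------------------------------------


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def kmeans(
    X: np.ndarray,
    k: int,
    *,
    n_restarts: int = 10,
    rng: np.random.Generator | None = None,
    max_iter: int = 100,
) -> tuple[np.ndarray, float]:
    """Euclidean k-means with k-means++ seeding and multiple restarts.

    Returns the best (labels, inertia) over restarts.  Written for many
    small problems (tens of items); empty clusters are re-seeded with the
    point farthest from its center.
    """
    rng = rng or np.random.default_rng()
    X = np.ascontiguousarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of items {n}")
    x_sq = (X**2).sum(axis=1)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        centers = _kmeans_pp_init(X, k, rng)
        labels = np.full(n, -1)
        for _ in range(max_iter):
            d2 = x_sq[:, None] - 2 * X @ centers.T + (centers**2).sum(axis=1)
            new_labels = d2.argmin(axis=1)
            point_d2 = d2[np.arange(n), new_labels]
            for j in range(k):
                mask = new_labels == j
                if mask.any():
                    centers[j] = X[mask].mean(axis=0)
                else:  # re-seed empty cluster at the worst-fit point
                    far = point_d2.argmax()
                    centers[j] = X[far]
                    new_labels[far] = j
                    point_d2[far] = 0.0
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
        d2 = x_sq[:, None] - 2 * X @ centers.T + (centers**2).sum(axis=1)
        inertia = float(d2[np.arange(n), labels].sum())
        if inertia < best_inertia:
            best_inertia, best_labels = inertia, labels.copy()
    return best_labels, best_inertia


# ---------------------------------------------------------------------------
# consensus metrics
# ---------------------------------------------------------------------------


def _upper_triangle(M: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def compute_cdf_area(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical CDF of the upper-triangle consensus entries and its area.

    Returns (support, cdf, area) where the area is the step integral of
    the CDF over [0, 1] (histogram convention of the consensus-clustering
    literature).
    """
    vals = np.sort(_upper_triangle(M))
    support = np.unique(np.concatenate([[0.0], vals, [1.0]]))
    cdf = np.searchsorted(vals, support, side="right") / vals.size
    area = float(np.sum(np.diff(support) * cdf[:-1]))
    return support, cdf, area


def compute_pac(M: np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguous clustering: entries strictly inside (u1, u2)."""
    vals = _upper_triangle(M)
    return float(np.mean((vals > u1) & (vals < u2)))


def compute_delta_area(areas: dict[int, float]) -> dict[int, float]:
    """Relative change in CDF area per k (first k keeps its raw area)."""
    ks = sorted(areas)
    out = {ks[0]: areas[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        out[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 else np.inf
    return out


def silhouette_on_consensus(M: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width using 1 - M as the distance."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    D = 1.0 - np.asarray(M, dtype=float)
    np.fill_diagonal(D, 0.0)
    return float(silhouette_score(D, labels, metric="precomputed"))


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class ConsensusClustering:
    """Consensus k-means over patient resamples.

    Parameters
    ----------
    data : DataFrame
        Patients (rows) x features (columns); typically per-patient log10
        T/N ratios restricted to the differential (D6) proteins.  No
        missing entries (floor-imputed upstream).
    k_range : (int, int)
        Inclusive candidate range of cluster numbers, default (2, 6).
    resample_fraction : float
        Fraction of patients drawn (without replacement) per resample.
    n_resamples : int
        Number of resampling iterations.
    n_restarts : int
        k-means restarts per subsample.
    seed : int
        Seed controlling subsampling and k-means seeding; identical seeds
        give identical results.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        k_range: tuple[int, int] = (2, 6),
        resample_fraction: float = 0.8,
        n_resamples: int = 1000,
        n_restarts: int = 10,
        seed: int | None = None,
        pac_bounds: tuple[float, float] = (0.1, 0.9),
    ) -> None:
        self.data = pd.DataFrame(data)
        if self.data.isna().any().any():
            raise ValueError("input matrix must have no undefined entries")
        n = self.data.shape[0]
        self.k_min, self.k_max = k_range
        if self.k_max >= n:
            raise ValueError(f"k_max={self.k_max} must be below n={n}")
        if not 0 < resample_fraction <= 1:
            raise ValueError("resample_fraction must be in (0, 1]")
        self.resample_fraction = resample_fraction
        self.n_resamples = int(n_resamples)
        self.n_restarts = int(n_restarts)
        self.seed = seed
        self.pac_bounds = pac_bounds

    def fit(self) -> "ConsensusResults":
        X = self.data.to_numpy(dtype=float)
        n = X.shape[0]
        m = int(np.ceil(self.resample_fraction * n))
        rng = np.random.default_rng(self.seed)
        ks = list(range(self.k_min, self.k_max + 1))
        co_cluster = {k: np.zeros((n, n)) for k in ks}
        co_sample = np.zeros((n, n))
        for _ in range(self.n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            sel = np.ix_(idx, idx)
            co_sample[sel] += 1.0
            Xs = X[idx]
            for k in ks:
                labels, _ = kmeans(Xs, k, n_restarts=self.n_restarts, rng=rng)
                same = labels[:, None] == labels[None, :]
                co_cluster[k][sel] += same
        if np.any(_upper_triangle(co_sample) == 0):
            raise ValueError(
                "some patient pairs were never co-sampled; increase n_resamples"
            )
        matrices: dict[int, np.ndarray] = {}
        labels_by_k: dict[int, pd.Series] = {}
        rows = []
        areas: dict[int, float] = {}
        for k in ks:
            M = co_cluster[k] / co_sample
            np.fill_diagonal(M, 1.0)
            M = (M + M.T) / 2.0
            matrices[k] = M
            link = linkage(squareform(1.0 - M, checks=False), method="average")
            lab = fcluster(link, t=k, criterion="maxclust")
            labels_by_k[k] = pd.Series(lab, index=self.data.index, name="subtype")
            _, _, area = compute_cdf_area(M)
            areas[k] = area
            pac = compute_pac(M, *self.pac_bounds)
            try:
                sil = silhouette_on_consensus(M, lab)
            except ValueError:
                sil = np.nan
            rows.append({"k": k, "area": area, "pac": pac, "silhouette": sil})
        metrics = pd.DataFrame(rows).set_index("k")
        metrics["delta_area"] = pd.Series(compute_delta_area(areas))
        return ConsensusResults(
            matrices=matrices,
            labels_by_k=labels_by_k,
            metrics=metrics,
            patients=self.data.index,
            seed=self.seed,
            pac_bounds=self.pac_bounds,
        )


@dataclass
class ConsensusResults:
    """Per-k consensus matrices, model-selection metrics, and labels."""

    matrices: dict[int, np.ndarray]
    labels_by_k: dict[int, pd.Series]
    metrics: pd.DataFrame
    patients: pd.Index
    seed: int | None = None
    pac_bounds: tuple[float, float] = (0.1, 0.9)

    def select_k(self) -> int:
        """k minimizing PAC; ties broken toward smaller k."""
        pac = self.metrics["pac"]
        return int(pac.index[np.argmin(pac.to_numpy())])

    @property
    def labels(self) -> pd.Series:
        """Final labels at the selected k."""
        return self.labels_by_k[self.select_k()]

    def summary(self) -> pd.DataFrame:
        """Model-selection report: area, delta-area, PAC, silhouette per k."""
        out = self.metrics[["area", "delta_area", "pac", "silhouette"]].copy()
        out["selected"] = out.index == self.select_k()
        return out

    def plot_cdf(self, ax=None):
        """Consensus CDF curves per k (matplotlib axis returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for k, M in self.matrices.items():
            support, cdf, _ = compute_cdf_area(M)
            ax.step(support, cdf, where="post", label=f"k={k}")
        ax.set_xlabel("consensus index")
        ax.set_ylabel("CDF")
        ax.legend()
        return ax


def cluster_signatures(
    labels: pd.Series,
    ratios,
    *,
    q_max: float = 0.01,
    pct_min: float = 0.5,
    n_permutations: int = 1000,
    seed: int | None = None,
    min_patients: int = 3,
) -> dict:
    """Per-cluster DEP sets: paired SAM restricted to each cluster's patients.

    Clusters with fewer than *min_patients* members are skipped with a
    warning.  Returns ``{cluster: DataFrame of called proteins}``.
    """
    from .differential import PairedSAM, call_significant_deps, compute_dep_calls

    out = {}
    for cluster in sorted(labels.unique()):
        members = labels.index[labels == cluster]
        if len(members) < min_patients:
            logger.warning(
                "cluster %s has %d patients (< %d); skipped",
                cluster,
                len(members),
                min_patients,
            )
            continue
        sub = ratios.log_ratios[members]
        sub_ratios = _restrict_patients(ratios, members)
        sam = PairedSAM(sub, n_permutations=n_permutations, seed=seed).fit()
        deps = compute_dep_calls(sub_ratios)
        out[cluster] = call_significant_deps(sam, deps, q_max=q_max, pct_min=pct_min)
    return out


def _restrict_patients(ratios, patients):
    from .quantify import RatioMatrix

    cols = list(patients)
    return RatioMatrix(
        ratios.log_ratios[cols],
        ratios.detected_tumor[cols],
        ratios.detected_nearby[cols],
        ratios.floored_tumor[cols],
        ratios.floored_nearby[cols],
        ratios.floor,
    )
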