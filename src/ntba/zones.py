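"""Genomic-zone classification of window bins.

250 kb bins are clustered on their vectors of highly-enriched-feature
frequencies (F_he over 12 features: nTBA at TSS/HOT for two chemical
potentials, plus 8 epigenomic markers).  Clustering combines a seeded k-means
fit with a Gaussian mixture model: per bin, an inverse-distance probability is
computed from the k-means centroids, a mixture posterior from the GMM (with
components matched to centroids by Hungarian assignment), and the final label
is the argmax of their weighted sum ``w * p_dist + (1-w) * p_mixture``.

With k = 3 the clusters are ranked by their mean intra-chromosomal interaction
frequency F_i and named type I (Inactive), II (Poised) and III (Active)
Genomic Zones, in ascending interaction-frequency order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

ZONE_NAMES = {"I": "Inactive Genomic Zones", "II": "Poised Genomic Zones",
              "III": "Active Genomic Zones"}
_DIST_EPS = 1e-12


def _as_matrix(table) -> np.ndarray:
    X = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature table must be 2-D (bins x features)")
    if not np.isfinite(X).all():
        raise ValueError("feature table contains missing values; impute first")
    return X


def stress_curve(table, k_values=range(1, 7), seed: int = 0,
                 elbow: float = 0.10) -> tuple[dict[int, float], int]:
    """Normalised clustering stress per k and the elbow-selected k.

    stress(k) = sqrt(within-cluster SS / total SS about the global centroid),
    from a seeded k-means fit; stress(1) = 1 by definition.  The selected k is
    one below the smallest k whose relative stress decrease versus k-1 falls
    under the elbow fraction (default 10%); if no k qualifies, the largest k
    tried is returned.
    """
    X = _as_matrix(table)
    k_values = sorted(k_values)
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < max(k_values):
        raise ValueError(f"only {n_distinct} distinct rows for k up to {max(k_values)}")
    tss = float(((X - X.mean(axis=0)) ** 2).sum())
    if tss == 0:
        raise ValueError("all rows identical; stress undefined")
    stress: dict[int, float] = {}
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        stress[k] = float(np.sqrt(km.inertia_ / tss))
    selected = k_values[-1]
    for prev, k in zip(k_values, k_values[1:]):
        if stress[prev] <= 0:
            selected = prev
            break
        if (stress[prev] - stress[k]) / stress[prev] < elbow:
            selected = prev
            break
    return stress, selected


@dataclass
class ClusterModel:
    """Combined k-means / Gaussian-mixture clustering of bin feature vectors."""

    k: int
    w: float
    centroids: np.ndarray
    mixture_means: np.ndarray
    p_dist: np.ndarray       # (n, k), inverse-distance probabilities
    p_mixture: np.ndarray    # (n, k), GMM posteriors aligned to centroids
    probabilities: np.ndarray  # (n, k), w*p_dist + (1-w)*p_mixture
    labels: np.ndarray       # argmax cluster index per bin


def cluster_bins(table, k: int = 3, w: float = 0.5, seed: int = 0) -> ClusterModel:
    """Cluster bins on their F_he vectors; deterministic under the seed.

    Ties in the final argmax resolve to the lower component index.  A singular
    mixture covariance is regularised by diagonal inflation with a warning.
    """
    X = _as_matrix(table)
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixing weight w must be in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    centroids = km.cluster_centers_
    d = cdist(X, centroids)
    inv = 1.0 / (_DIST_EPS + d)
    p_dist = inv / inv.sum(axis=1, keepdims=True)

    gm = None
    for reg in (1e-6, 1e-3, 1e-1):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm = GaussianMixture(n_components=k, random_state=seed,
                                     reg_covar=reg, n_init=3).fit(X)
            break
        except ValueError:
            warnings.warn(f"singular mixture covariance; inflating reg_covar past {reg}")
    if gm is None:
        raise RuntimeError("Gaussian mixture fit failed even with inflated regularisation")
    post = gm.predict_proba(X)
    # match mixture components to k-means centroids (Hungarian on mean distance)
    cost = cdist(centroids, gm.means_)
    rows, cols = linear_sum_assignment(cost)
    order = np.empty(k, dtype=int)
    order[rows] = cols
    p_mixture = post[:, order]
    probabilities = w * p_dist + (1.0 - w) * p_mixture
    labels = probabilities.argmax(axis=1)
    return ClusterModel(k=k, w=w, centroids=centroids,
                        mixture_means=gm.means_[order], p_dist=p_dist,
                        p_mixture=p_mixture, probabilities=probabilities,
                        labels=labels)


@dataclass
class ZoneLabels:
    """Per-bin zone type (I/II/III) on one chromosome's bin grid."""

    chrom: str
    resolution: int
    types: np.ndarray        # array of "I"/"II"/"III"
    cell_line: str = ""

    @property
    def zone_names(self) -> np.ndarray:
        return np.array([ZONE_NAMES[t] for t in self.types])

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(len(self.types)) * self.resolution
        return pd.DataFrame({
            "chrom": self.chrom, "start": starts,
            "end": starts + self.resolution, "type": self.types,
            "zone": self.zone_names,
        })


def label_zones(model: ClusterModel, fi: np.ndarray, chrom: str = "chr",
                resolution: int = 250_000, cell_line: str = "") -> ZoneLabels:
    """Rank the 3 clusters by mean interaction frequency F_i (ascending) and
    name them types I/II/III = Inactive/Poised/Active Genomic Zones.

    A tie in mean F_i between clusters is broken by mean F_he over all
    features.  Asserts the I < II < III mean-F_i ordering on the labeled set.
    """
    if model.k != 3:
        raise ValueError("zone labelling requires k = 3")
    fi = np.asarray(fi, dtype=float)
    if len(fi) != len(model.labels):
        raise ValueError("F_i length does not match the number of labeled bins")
    mean_fi = np.array([fi[model.labels == c].mean() if (model.labels == c).any()
                        else -np.inf for c in range(3)])
    mean_fhe = np.array([model.centroids[c].mean() for c in range(3)])
    order = np.lexsort((mean_fhe, mean_fi))  # primary F_i, tie-break mean F_he
    type_of_cluster = {int(c): t for c, t in zip(order, ("I", "II", "III"))}
    types = np.array([type_of_cluster[int(c)] for c in model.labels])
    ordered = [fi[types == t].mean() for t in ("I", "II", "III") if (types == t).any()]
    if any(a > b for a, b in zip(ordered, ordered[1:])):
        raise AssertionError("mean F_i ordering I <= II <= III violated")
    return ZoneLabels(chrom=chrom, resolution=resolution, types=types,
                      cell_line=cell_line)
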