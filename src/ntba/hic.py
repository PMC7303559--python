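"""Hi-C contact-matrix statistics and marker enrichment in interactions.

A (pre-normalised) intra-chromosomal contact matrix at a fixed resolution
(default 250 kb) is Z-scored over its off-diagonal entries; bin pairs with
Z > 0 are the *detected* interactions (more frequent than the chromosome
average).  For every detected pair and every marker, enrichment is tested by a
two-sample rank-sum (Mann-Whitney) statistic of the pair's marker values
against the pooled values of 100 randomly drawn bin pairs.  Per bin the method
then counts detected interactions (Nvi) and detected interactions with high
marker enrichment (rank-sum Z >= 3, Nei), normalised by the chromosome's bin
count Nt into frequencies F_i = Nvi/Nt and F_he = Nei/Nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

DEFAULT_RESOLUTION = 250_000
HIGH_ENRICHMENT_Z = 3.0


@dataclass
class BinGrid:
    """Fixed-width bins tiling one chromosome: Nt = ceil(length/resolution)."""

    chrom_length: int
    resolution: int = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if self.chrom_length < 1 or self.resolution < 1:
            raise ValueError("length and resolution must be >= 1")

    @property
    def nt(self) -> int:
        return -(-self.chrom_length // self.resolution)

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.nt) * self.resolution

    @property
    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.resolution, self.chrom_length)


def make_bins(chrom_length: int, resolution: int = DEFAULT_RESOLUTION) -> BinGrid:
    return BinGrid(chrom_length=chrom_length, resolution=resolution)


@dataclass
class ContactMatrix:
    """Symmetric normalised contact matrix of one chromosome."""

    chrom: str
    matrix: np.ndarray
    resolution: int = DEFAULT_RESOLUTION
    zscored: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        finite = np.isfinite(self.matrix) & np.isfinite(self.matrix.T)
        if not np.allclose(self.matrix[finite], self.matrix.T[finite], atol=1e-6):
            raise ValueError("contact matrix not symmetric within 1e-6")

    @property
    def nt(self) -> int:
        return self.matrix.shape[0]


def zscore_matrix(contacts: ContactMatrix) -> ContactMatrix:
    """Z-score over the finite off-diagonal upper-triangle entries, mirrored to
    keep symmetry; the diagonal becomes missing."""
    m = contacts.matrix
    nt = contacts.nt
    iu = np.triu_indices(nt, k=1)
    vals = m[iu]
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValueError("need at least 2 finite off-diagonal entries")
    mu = vals[finite].mean()
    sd = vals[finite].std()
    if sd == 0:
        raise ValueError("zero variance: all off-diagonal contacts equal")
    z = np.full_like(m, np.nan)
    zvals = np.where(finite, (vals - mu) / sd, np.nan)
    z[iu] = zvals
    z[(iu[1], iu[0])] = zvals
    return ContactMatrix(chrom=contacts.chrom, matrix=z,
                         resolution=contacts.resolution, zscored=True)


def detect_interactions(zmatrix: ContactMatrix) -> pd.DataFrame:
    """Detected intra-chromosomal interactions: unordered pairs with Z > 0."""
    if not zmatrix.zscored:
        raise ValueError("matrix must be Z-scored first")
    i, j = np.triu_indices(zmatrix.nt, k=1)
    z = zmatrix.matrix[i, j]
    keep = np.isfinite(z) & (z > 0)
    return pd.DataFrame({"i": i[keep], "j": j[keep], "z": z[keep]})


@dataclass
class MarkerBinValues:
    """Per-bin marker summary and the underlying per-feature window values.

    For every TSS/HOT feature window in a bin, the feature value is the mean
    signal over its 1000 bp window.  The bin aggregate is the mean of feature
    values for epigenomic markers and the SUM for nTBA markers (the additive
    nTBA reading); bins without features are missing.
    """

    marker: str
    kind: str                                  # "epigenomic" or "ntba"
    values: np.ndarray                         # (nt,) aggregate, NaN if empty
    feature_values: list[list[float]] = field(repr=False, default_factory=list)


def marker_value_per_bin(grid: BinGrid, windows, signal, marker: str,
                         kind: str = "epigenomic", **signal_kwargs) -> MarkerBinValues:
    """Summarise a signal into per-bin marker values via feature windows."""
    if kind not in ("epigenomic", "ntba"):
        raise ValueError(f"unknown marker kind {kind!r}")
    nt = grid.nt
    per_bin: list[list[float]] = [[] for _ in range(nt)]
    for w in windows:
        positions = np.arange(w.start, w.end)
        vals = signal.values_at(w.chrom, positions, **signal_kwargs)
        v = float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan
        if not np.isfinite(v):
            continue
        b = w.center // grid.resolution
        if 0 <= b < nt:
            per_bin[b].append(v)
    agg = np.full(nt, np.nan)
    for b, vs in enumerate(per_bin):
        if vs:
            agg[b] = np.sum(vs) if kind == "ntba" else np.mean(vs)
    return MarkerBinValues(marker=marker, kind=kind, values=agg,
                           feature_values=per_bin)


def ranksum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample rank-sum Z (Mann-Whitney normal approximation with tie
    correction, no continuity correction); positive when ``a`` ranks higher."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie = float((counts.astype(float) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return float((u - mu) / np.sqrt(var))


def draw_random_pairs(nt: int, exclude: tuple[int, int], count: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform sample without replacement from all unordered bin pairs of the
    chromosome, excluding the tested pair."""
    i, j = np.triu_indices(nt, k=1)
    mask = ~((i == exclude[0]) & (j == exclude[1]))
    pool = np.column_stack([i[mask], j[mask]])
    take = min(count, len(pool))
    idx = rng.choice(len(pool), size=take, replace=False)
    return pool[idx]


def enrichment_test(pair: tuple[int, int], marker: MarkerBinValues,
                    random_pairs: np.ndarray, mode: str = "aggregate",
                    min_random_pairs: int = 10) -> tuple[float, str | None]:
    """Rank-sum enrichment Z of one marker in one detected pair.

    ``aggregate``: sample A is the two per-bin aggregate values of the pair and
    sample B the aggregates of the random pairs' bins.  ``pooled``: samples are
    the individual feature-window values instead (the only construction under
    which the Z >= 3 high-enrichment threshold is attainable, since with
    |A| = 2 the statistic is bounded near 2.43).  Returns (Z, reason) with
    reason set when the test could not run.
    """
    i, j = pair
    if mode == "aggregate":
        a = np.array([marker.values[i], marker.values[j]])
        b_groups = [np.array([marker.values[x], marker.values[y]])
                    for x, y in random_pairs]
    elif mode == "pooled":
        a = np.array(marker.feature_values[i] + marker.feature_values[j])
        b_groups = [np.array(marker.feature_values[x] + marker.feature_values[y])
                    for x, y in random_pairs]
    else:
        raise ValueError(f"unknown sample mode {mode!r}")
    if len(a) == 0 or not np.isfinite(a).all():
        return np.nan, "missing marker value in tested pair"
    b_groups = [g[np.isfinite(g)] for g in b_groups]
    contributing = sum(1 for g in b_groups if len(g) > 0)
    if contributing < min_random_pairs:
        return np.nan, f"only {contributing} random pairs with values"
    b = np.concatenate([g for g in b_groups if len(g) > 0])
    return ranksum_z(a, b), None


def enrichment_table(detected: pd.DataFrame, markers: list[MarkerBinValues],
                     nt: int, n_random: int = 100, seed: int = 0,
                     mode: str = "aggregate") -> pd.DataFrame:
    """Enrichment Z for every detected pair x marker.

    One seeded random-pair draw per tested pair is shared across all markers;
    the draw for pair (i, j) is seeded from (seed, i, j).
    """
    cols: dict[str, list[float]] = {m.marker: [] for m in markers}
    for i, j in zip(detected["i"], detected["j"]):
        rng = np.random.default_rng([seed, int(i), int(j)])
        rand = draw_random_pairs(nt, (int(i), int(j)), n_random, rng)
        for m in markers:
            z, _ = enrichment_test((int(i), int(j)), m, rand, mode=mode)
            cols[m.marker].append(z)
    out = detected[["i", "j"]].copy().reset_index(drop=True)
    for name, vals in cols.items():
        out[name] = vals
    return out


@dataclass
class BinFrequencies:
    """Per-bin interaction and high-enrichment frequencies.

    ``fi[b] = Nvi[b] / Nt`` with Nvi the number of detected interactions
    touching bin b; ``fhe[b, marker] = Nei / Nt`` with Nei the number of those
    in which the marker's rank-sum Z >= threshold.
    """

    nt: int
    nvi: np.ndarray
    fi: np.ndarray
    nei: pd.DataFrame
    fhe: pd.DataFrame
    threshold: float = HIGH_ENRICHMENT_Z


def bin_frequencies(detected: pd.DataFrame, enrichment: pd.DataFrame, nt: int,
                    threshold: float = HIGH_ENRICHMENT_Z) -> BinFrequencies:
    markers = [c for c in enrichment.columns if c not in ("i", "j")]
    nvi = np.zeros(nt, dtype=int)
    np.add.at(nvi, detected["i"].to_numpy(dtype=int), 1)
    np.add.at(nvi, detected["j"].to_numpy(dtype=int), 1)
    nei = pd.DataFrame(0, index=range(nt), columns=markers)
    ii = enrichment["i"].to_numpy(dtype=int)
    jj = enrichment["j"].to_numpy(dtype=int)
    for m in markers:
        z = enrichment[m].to_numpy(dtype=float)
        hot = np.isfinite(z) & (z >= threshold)
        col = np.zeros(nt, dtype=int)
        np.add.at(col, ii[hot], 1)
        np.add.at(col, jj[hot], 1)
        nei[m] = col
    return BinFrequencies(nt=nt, nvi=nvi, fi=nvi / nt, nei=nei, fhe=nei / nt,
                          threshold=threshold)
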