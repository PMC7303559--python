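"""Epigenomic coverage tracks: 100 bp binning and Z-score normalisation."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import defaultdict

import numpy as np


@dataclass
class CoverageTrack:
    """Raw per-bin read counts of one marker on one chromosome."""

    marker: str
    cell_line: str
    chrom: str
    counts: np.ndarray
    bin_width: int = 100

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError(f"{self.marker}: negative counts")


@dataclass
class NormalizedTrack:
    """Per-bin Z-scores of one marker (mean 0, SD 1 over covered bins)."""

    marker: str
    cell_line: str
    chrom: str
    values: np.ndarray
    bin_width: int = 100

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions)
        out = np.full(positions.shape, np.nan)
        if chrom != self.chrom:
            return out
        idx = positions // self.bin_width
        ok = (positions >= 0) & (idx < len(self.values))
        out[ok] = self.values[idx[ok].astype(int)]
        return out


@dataclass
class BinnedSignal:
    """Arbitrary per-bin signal (e.g. an affinity surrogate) with the same
    position-lookup interface as a normalised track; no Z-score invariant."""

    name: str
    chrom: str
    values: np.ndarray
    bin_width: int = 100

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions)
        out = np.full(positions.shape, np.nan)
        if chrom != self.chrom:
            return out
        idx = positions // self.bin_width
        ok = (positions >= 0) & (idx < len(self.values))
        out[ok] = self.values[idx[ok].astype(int)]
        return out


def bin_counts(intervals, chrom_length: int, bin_width: int = 100,
               marker: str = "marker", cell_line: str = "cell",
               chrom: str = "chr") -> CoverageTrack:
    """Count intervals per bin by the midpoint rule.

    ``intervals`` is an iterable of (start, end) half-open pairs (reads or
    fragments).  An interval is assigned to the bin containing its midpoint
    ``(start+end)//2``; the last partial bin is included.  Intervals whose
    midpoint lies beyond the chromosome are clipped into the last bin with a
    warning.  Total counts are conserved.
    """
    if bin_width < 1:
        raise ValueError("bin width must be >= 1")
    n_bins = -(-chrom_length // bin_width)
    arr = np.asarray(list(intervals), dtype=np.int64).reshape(-1, 2)
    if len(arr) == 0:
        return CoverageTrack(marker, cell_line, chrom, np.zeros(n_bins), bin_width)
    mids = (arr[:, 0] + arr[:, 1]) // 2
    beyond = mids >= chrom_length
    if beyond.any():
        warnings.warn(f"{int(beyond.sum())} interval(s) beyond chromosome length; clipped")
        mids = np.minimum(mids, chrom_length - 1)
    counts = np.bincount(mids // bin_width, minlength=n_bins).astype(float)
    return CoverageTrack(marker, cell_line, chrom, counts, bin_width)


def normalize_tracks(tracks: list[CoverageTrack], scale: float = 1e7,
                     per_chromosome: bool = True) -> list[NormalizedTrack]:
    """Normalise coverage tracks to per-marker Z-scores.

    Per track: scale counts to counts-per-``scale`` (default per 10 million) of
    the track total; replicate tracks of the same (marker, cell line,
    chromosome) are averaged bin-wise; then log2(x+1) and Z-scoring per marker
    and chromosome.  A zero-total track or a constant track (no variance after
    the transform) is an error.
    """
    groups: dict[tuple[str, str, str], list[CoverageTrack]] = defaultdict(list)
    for tr in tracks:
        groups[(tr.marker, tr.cell_line, tr.chrom)].append(tr)
    logged: dict[tuple[str, str, str], tuple[np.ndarray, int]] = {}
    for (marker, cell, chrom), reps in groups.items():
        widths = {tr.bin_width for tr in reps}
        lengths = {len(tr.counts) for tr in reps}
        if len(widths) != 1 or len(lengths) != 1:
            raise ValueError(f"{marker}/{cell}/{chrom}: replicates have mismatched binning")
        scaled = []
        for tr in reps:
            total = tr.counts.sum()
            if total == 0:
                raise ValueError(f"{marker}/{cell}/{chrom}: zero-total track")
            scaled.append(tr.counts / total * scale)
        logged[(marker, cell, chrom)] = (np.log2(np.mean(scaled, axis=0) + 1.0), widths.pop())
    # Z-scoring per marker: per chromosome by default, or jointly over all
    # chromosomes of the marker
    zgroups: dict[tuple, list[tuple]] = defaultdict(list)
    for key, (vals, bw) in logged.items():
        marker, cell, chrom = key
        gkey = key if per_chromosome else (marker, cell)
        zgroups[gkey].append((key, vals, bw))
    out = []
    for members in zgroups.values():
        allv = np.concatenate([vals for _, vals, _ in members])
        mu, sd = allv.mean(), allv.std()
        if sd <= 1e-12 * max(1.0, abs(mu)):  # constant up to round-off
            marker = members[0][0][0]
            raise ValueError(f"{marker}: constant track has no Z-score")
        for (marker, cell, chrom), vals, bw in members:
            out.append(NormalizedTrack(marker, cell, chrom, (vals - mu) / sd, bw))
    return out
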