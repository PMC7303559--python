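"""Genomic feature preprocessing, profile aggregation and overlap tables.

Feature sets (genes, TSS, enhancers, HOT regions, chromatin-state segments)
are reduced to fixed 1000 bp windows centred on each element so that signal
profiles from different element classes are directly comparable: elements
shorter than 100 bp are dropped, the window is centred on the interval
midpoint (for TSS features, on the strand-aware transcription start base) and
duplicate windows are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_CLASSES = ("gene", "tss", "enhancer", "super_enhancer", "hub_enhancer",
                   "hot", "chromatin_state", "peak")
STATE_CODES = ("TSS", "PF", "E", "WE", "CTCF", "T", "R")

MIN_ELEMENT_LENGTH = 100
WINDOW_SIZE = 1000
HALF_WINDOW = WINDOW_SIZE // 2


@dataclass
class GenomicFeature:
    chrom: str
    start: int
    end: int
    feature_class: str = "peak"
    strand: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureWindow:
    """1000 bp window centred on a feature."""

    feature: GenomicFeature
    center: int
    start: int
    end: int
    clipped: bool = False

    @property
    def chrom(self) -> str:
        return self.feature.chrom


def feature_center(feature: GenomicFeature) -> int:
    """Interval midpoint, or for TSS features the strand-aware 5' base."""
    if feature.feature_class == "tss":
        if feature.strand == "-":
            return feature.end - 1
        return feature.start
    return (feature.start + feature.end) // 2


def preprocess_features(features: list[GenomicFeature],
                        min_length: int = MIN_ELEMENT_LENGTH) -> list[FeatureWindow]:
    """Drop short elements, extract centred 1000 bp windows, deduplicate.

    Windows that would extend below position 0 are clipped and flagged.
    Duplicate (chromosome, window) pairs keep the first occurrence.
    Idempotent: windows of windows are unchanged.
    """
    out: list[FeatureWindow] = []
    seen: set[tuple[str, int]] = set()
    for f in features:
        if f.length < min_length:
            continue
        center = feature_center(f)
        start = center - HALF_WINDOW
        clipped = start < 0
        if clipped:
            warnings.warn(f"window at {f.chrom}:{center} clipped at chromosome start")
            start = 0
        end = start + WINDOW_SIZE
        key = (f.chrom, start)
        if key in seen:
            continue
        seen.add(key)
        out.append(FeatureWindow(feature=f, center=center, start=start, end=end,
                                 clipped=clipped))
    return out


@dataclass
class ProfileCurve:
    """Across-draw mean and SD of an aggregated signal profile around feature
    centres (offsets -500..+499)."""

    offsets: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    mode: str
    draws: int
    subsample: int


def aggregate_profile(windows: list[FeatureWindow], signal, mode: str = "total",
                      subsample: int = 200, draws: int = 5, seed: int = 0,
                      **signal_kwargs) -> ProfileCurve:
    """Aggregate a signal over feature windows by repeated subsampling.

    Each draw samples ``subsample`` windows without replacement (all windows
    when fewer are available), stacks the signal by offset relative to the
    feature centre and reduces by sum (``total``) or mean (``mean``), ignoring
    missing values.  Returns the across-draw mean and SD per offset.

    ``signal`` is any object with ``values_at(chrom, positions, **kwargs)``
    (an affinity profile or a normalised track).
    """
    if not windows:
        raise ValueError("empty window list")
    if mode not in ("total", "mean"):
        raise ValueError(f"unknown mode {mode!r}")
    offsets = np.arange(-HALF_WINDOW, HALF_WINDOW)
    values = np.stack([
        signal.values_at(w.chrom, w.center + offsets, **signal_kwargs) for w in windows
    ])
    rng = np.random.default_rng(seed)
    n_take = min(subsample, len(windows))
    reduce = np.nansum if mode == "total" else np.nanmean
    curves = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN offsets
        for _ in range(draws):
            idx = rng.choice(len(windows), size=n_take, replace=False)
            curves.append(reduce(values[idx], axis=0))
    curves = np.stack(curves)
    return ProfileCurve(offsets=offsets, mean=curves.mean(axis=0),
                        sd=curves.std(axis=0), mode=mode, draws=draws,
                        subsample=n_take)


def state_overlap(zones, states: list[GenomicFeature]) -> pd.DataFrame:
    """Percentage of chromatin-state segments overlapping each zone type.

    ``zones`` carries per-bin type labels (I/II/III) on a fixed bin grid; a
    segment counts once for every zone type whose bins it overlaps by >= 1 bp.
    Rows are zone types I/II/III, columns the seven state codes; each cell is
    100 x (overlapping segments of that code) / (total segments of that code).
    """
    unknown = sorted({s.label for s in states} - set(STATE_CODES))
    if unknown:
        raise ValueError(f"unknown chromatin-state code(s): {unknown}")
    res = zones.resolution
    counts = pd.DataFrame(0.0, index=["I", "II", "III"], columns=list(STATE_CODES))
    totals = {code: 0 for code in STATE_CODES}
    for seg in states:
        totals[seg.label] += 1
        if seg.chrom != zones.chrom:
            continue
        b0, b1 = seg.start // res, (seg.end - 1) // res
        hit = set()
        for b in range(b0, b1 + 1):
            if 0 <= b < len(zones.types):
                hit.add(zones.types[b])
        for t in hit:
            counts.loc[t, seg.label] += 1
    for code in STATE_CODES:
        if totals[code] == 0:
            warnings.warn(f"no segments with state code {code!r}; column left at 0")
        else:
            counts[code] = 100.0 * counts[code] / totals[code]
    return counts


@dataclass
class CoreBins:
    """Per-type bins shared by every cell line, plus Venn region counts."""

    core: dict[str, np.ndarray]                # type -> sorted bin indices
    venn: dict[str, dict[frozenset, int]]      # type -> {cell-line subset: count}
    cell_lines: tuple[str, ...]


def core_bins(labelings: dict[str, "object"]) -> CoreBins:
    """Intersect zone labelings from >= 2 cell lines.

    For each type the *core* set is the bins assigned that type in every cell
    line.  Venn counts give, for every non-empty subset of cell lines, the
    number of bins assigned the type in exactly that subset.
    """
    if len(labelings) < 2:
        raise ValueError("need zone labels for at least 2 cell lines")
    cells = tuple(labelings)
    grids = {(z.chrom, z.resolution, len(z.types)) for z in labelings.values()}
    if len(grids) != 1:
        raise ValueError("mismatched bin grids across cell lines")
    n = len(next(iter(labelings.values())).types)
    core: dict[str, np.ndarray] = {}
    venn: dict[str, dict[frozenset, int]] = {}
    for t in ("I", "II", "III"):
        members = {c: np.asarray(labelings[c].types) == t for c in cells}
        all_in = np.logical_and.reduce([members[c] for c in cells])
        core[t] = np.flatnonzero(all_in)
        regions: dict[frozenset, int] = {}
        for b in range(n):
            subset = frozenset(c for c in cells if members[c][b])
            if subset:
                regions[subset] = regions.get(subset, 0) + 1
        venn[t] = regions
    return CoreBins(core=core, venn=venn, cell_lines=cells)


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open coordinates throughout)

def read_bed(path: str | Path, feature_class: str = "peak") -> list[GenomicFeature]:
    """Read BED3/BED4/BED6; the name column becomes the label (used for
    chromatin-state codes)."""
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        label = parts[3] if len(parts) > 3 else None
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
        out.append(GenomicFeature(chrom, start, end, feature_class,
                                  strand=strand, label=label))
    return out


def write_bed(features: list[GenomicFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            cols = [f.chrom, str(f.start), str(f.end)]
            if f.label is not None or f.strand is not None:
                cols += [f.label or ".", "0", f.strand or "."]
            fh.write("\t".join(cols) + "\n")
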