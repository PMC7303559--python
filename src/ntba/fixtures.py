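"""Seeded synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here with known structure:

* ``gen_motifs`` draws motif matrices with one dominant base per position.
* ``gen_sequence`` builds an i.i.d. background sequence at a target GC
  fraction with exact consensus motif instances planted in a central cluster,
  so an affinity scan has a known peak location.
* ``gen_zone_dataset`` builds a three-regime chromosome: bins are split into
  low / medium / high contact regimes, the contact matrix mirrors the regime
  strengths, and marker tracks are elevated inside TSS/HOT feature windows
  with regime-specific effect sizes (active marks and nTBA surrogates in the
  high regime, repressive marks in the medium regime), so that the full
  tracks -> enrichment -> zones pipeline should recover the regimes as zone
  types I/II/III.

All generators are pure functions of the spec: a fixed seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .features import GenomicFeature
from .hic import ContactMatrix
from .motifs import ALPHABET, MotifMatrix, write_motifs_jaspar

ACTIVE_MARKERS = ("DNase", "Pol2", "H3K4me3", "H3K4me1", "H3K27ac", "CTCF")
REPRESSIVE_MARKERS = ("H3K27me3", "H3K9me3")
NTBA_TRACKS = ("ntba_tss_mu0", "ntba_tss_mu-10", "ntba_hot_mu0", "ntba_hot_mu-10")


def _default_marker_effects() -> dict[str, tuple[float, float, float]]:
    effects = {m: (0.0, 0.0, 60.0) for m in ACTIVE_MARKERS}
    effects.update({m: (0.0, 60.0, 10.0) for m in REPRESSIVE_MARKERS})
    effects["ntba_tss_mu0"] = (0.0, 0.0, 1.0)
    effects["ntba_tss_mu-10"] = (0.0, 0.0, 0.5)
    effects["ntba_hot_mu0"] = (0.0, 0.0, 1.0)
    effects["ntba_hot_mu-10"] = (0.0, 0.0, 0.5)
    return effects


@dataclass
class FixtureSpec:
    """Parameters of all synthetic generators (one seed, one ground truth)."""

    seed: int = 0
    # sequence fixture
    sequence_length: int = 5_000
    gc: float = 0.41                      # human-like GC fraction
    n_motifs: int = 5
    motif_width: int = 8
    concentration: float = 50.0           # Dirichlet weight of the dominant base
    n_planted: int = 12
    cluster_halfwidth: int = 100          # planted sites fall in centre +/- this
    cluster_center: int | None = None     # None -> sequence midpoint
    # zone fixture
    resolution: int = 250_000
    bins_per_regime: int = 20
    contact_strengths: tuple[float, float, float] = (0.0, 1.5, 2.0)
    contact_noise_sd: float = 0.5
    features_per_bin: int = 5             # TSS and HOT windows per bin
    track_bin_width: int = 100
    marker_baseline: float = 20.0
    marker_noise_sd: float = 4.0
    ntba_noise_sd: float = 0.2
    marker_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=_default_marker_effects)

    def __post_init__(self) -> None:
        if not 0 < self.gc < 1:
            raise ValueError("GC fraction must be in (0, 1)")
        if self.motif_width < 4:
            raise ValueError("motif width must be >= 4")
        lo, mid, hi = self.contact_strengths
        if not lo < mid < hi:
            raise ValueError("regime contact strengths must be strictly increasing")
        if self.bins_per_regime < 2:
            raise ValueError("need at least 2 bins per regime")


def gen_motifs(spec: FixtureSpec) -> list[MotifMatrix]:
    """Dirichlet-drawn frequency matrices with one dominant base per position."""
    rng = np.random.default_rng([spec.seed, 0])
    motifs = []
    for t in range(spec.n_motifs):
        cols = []
        for _ in range(spec.motif_width):
            alpha = np.ones(4)
            alpha[rng.integers(4)] = spec.concentration
            cols.append(rng.dirichlet(alpha))
        motifs.append(MotifMatrix(id=f"SYN{t:03d}", values=np.array(cols)))
    return motifs


def consensus(motif: MotifMatrix) -> str:
    return "".join(ALPHABET[b] for b in motif.values.argmax(axis=1))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def gen_sequence(spec: FixtureSpec,
                 motifs: list[MotifMatrix] | None = None) -> tuple[str, list[dict]]:
    """Background sequence with planted consensus sites in a central cluster.

    Returns the sequence and a manifest of planted instances
    ``{"position", "motif_id", "strand"}`` (position = 0-based start).  Each
    instance is the exact consensus of a randomly chosen motif, inserted on a
    random strand; overlapping placements are repositioned.
    """
    if motifs is None:
        motifs = gen_motifs(spec)
    rng = np.random.default_rng([spec.seed, 1])
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    seq = list("".join(rng.choice(list(ALPHABET), size=spec.sequence_length, p=p)))
    center = (spec.cluster_center if spec.cluster_center is not None
              else spec.sequence_length // 2)
    manifest: list[dict] = []
    occupied: list[tuple[int, int]] = []
    for _ in range(spec.n_planted):
        motif = motifs[rng.integers(len(motifs))]
        site = consensus(motif)
        m = len(site)
        lo = max(0, center - spec.cluster_halfwidth)
        hi = min(spec.sequence_length - m, center + spec.cluster_halfwidth - m)
        if hi < lo:
            raise ValueError("cluster region too small for the motif width")
        pos = None
        for _attempt in range(200):
            cand = int(rng.integers(lo, hi + 1))
            if all(cand + m <= s or cand >= e for s, e in occupied):
                pos = cand
                break
        if pos is None:
            import warnings
            warnings.warn("could not place a non-overlapping instance; skipped")
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        inst = site if strand == "+" else _revcomp(site)
        seq[pos:pos + m] = inst
        occupied.append((pos, pos + m))
        manifest.append({"position": pos, "motif_id": motif.id, "strand": strand})
    return "".join(seq), sorted(manifest, key=lambda d: d["position"])


@dataclass
class ZoneDataset:
    """Synthetic three-regime chromosome with planted zone structure."""

    spec: FixtureSpec
    chrom: str
    chrom_length: int
    truth: np.ndarray                     # 0 = low, 1 = medium, 2 = high regime
    tss: list[GenomicFeature]
    hot: list[GenomicFeature]
    tracks: dict[str, np.ndarray]         # marker -> per-100bp-bin values
    track_kinds: dict[str, str]           # marker -> "epigenomic" | "ntba"
    contacts: ContactMatrix

    @property
    def n_bins(self) -> int:
        return len(self.truth)


def gen_zone_dataset(spec: FixtureSpec, chrom: str = "chrS") -> ZoneDataset:
    rng = np.random.default_rng([spec.seed, 2])
    n_bins = 3 * spec.bins_per_regime
    res = spec.resolution
    length = n_bins * res
    truth = rng.permutation(np.repeat([0, 1, 2], spec.bins_per_regime))

    # TSS/HOT feature windows at fixed in-bin offsets, well separated
    tss, hot = [], []
    for b in range(n_bins):
        for f in range(spec.features_per_bin):
            c_tss = b * res + 20_000 + f * 10_000
            tss.append(GenomicFeature(chrom, c_tss, c_tss + 200, "tss", strand="+"))
            c_hot = b * res + 150_000 + f * 10_000
            hot.append(GenomicFeature(chrom, c_hot - 200, c_hot + 200, "hot"))

    # marker tracks: baseline + regime effect inside the +/-500 bp windows
    bw = spec.track_bin_width
    n_track_bins = length // bw
    tracks: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}

    def _window_slices(features):
        for feat in features:
            c = ((feat.start + feat.end) // 2 if feat.feature_class != "tss"
                 else feat.start)
            yield slice(max(0, (c - 500)) // bw, (c + 500) // bw), c // res

    for marker in ACTIVE_MARKERS + REPRESSIVE_MARKERS:
        vals = np.clip(spec.marker_baseline
                       + rng.normal(0, spec.marker_noise_sd, n_track_bins), 0, None)
        eff = spec.marker_effects[marker]
        for feats in (tss, hot):
            for sl, b in _window_slices(feats):
                vals[sl] += eff[truth[b]]
        tracks[marker] = vals
        kinds[marker] = "epigenomic"
    for marker in NTBA_TRACKS:
        vals = rng.normal(0, spec.ntba_noise_sd, n_track_bins)
        eff = spec.marker_effects[marker]
        feats = tss if "tss" in marker else hot
        for sl, b in _window_slices(feats):
            vals[sl] += eff[truth[b]]
        tracks[marker] = vals
        kinds[marker] = "ntba"

    # contact matrix: pair value = regime strength i + strength j + noise
    strengths = np.asarray(spec.contact_strengths)[truth]
    base = strengths[:, None] + strengths[None, :]
    noise = rng.normal(0, spec.contact_noise_sd, (n_bins, n_bins)) \
        if spec.contact_noise_sd > 0 else np.zeros((n_bins, n_bins))
    noise = np.triu(noise, 1)
    mat = base + noise + noise.T
    np.fill_diagonal(mat, base.max() + 1.0)
    contacts = ContactMatrix(chrom=chrom, matrix=mat, resolution=res)

    return ZoneDataset(spec=spec, chrom=chrom, chrom_length=length, truth=truth,
                       tss=tss, hot=hot, tracks=tracks, track_kinds=kinds,
                       contacts=contacts)


# ---------------------------------------------------------------------------
# file emission (same formats the pipeline readers consume)

def write_fasta(seq: str, path: str | Path, seq_id: str = "synthetic") -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq_id}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def write_bedgraph(values: np.ndarray, chrom: str, bin_width: int,
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            fh.write(f"{chrom}\t{i * bin_width}\t{(i + 1) * bin_width}\t{v:.6g}\n")


def write_zone_dataset(ds: ZoneDataset, outdir: str | Path) -> dict[str, str]:
    """Write every pipeline input for the zone dataset; returns a path map."""
    from .features import write_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    (outdir / "genome.chrom.sizes").write_text(f"{ds.chrom}\t{ds.chrom_length}\n")
    paths["chrom_sizes"] = str(outdir / "genome.chrom.sizes")

    write_bed(ds.tss, outdir / "tss.bed")
    write_bed(ds.hot, outdir / "hot.bed")
    paths["tss"] = str(outdir / "tss.bed")
    paths["hot"] = str(outdir / "hot.bed")

    markers_dir = outdir / "markers"
    markers_dir.mkdir(exist_ok=True)
    for name, vals in ds.tracks.items():
        p = markers_dir / f"{name}.bedGraph"
        write_bedgraph(vals, ds.chrom, ds.spec.track_bin_width, p)
        paths[f"track:{name}"] = str(p)

    np.savetxt(outdir / "contacts.tsv", ds.contacts.matrix, delimiter="\t", fmt="%.6g")
    paths["contacts"] = str(outdir / "contacts.tsv")

    truth = {
        "chrom": ds.chrom,
        "resolution": ds.spec.resolution,
        "regimes": ds.truth.tolist(),
        "track_kinds": ds.track_kinds,
        "spec": {k: v for k, v in asdict(ds.spec).items() if k != "marker_effects"},
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    paths["truth"] = str(outdir / "truth.json")
    return paths


def write_sequence_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    """Write the planted-cluster sequence fixture (FASTA + motifs + manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    motifs = gen_motifs(spec)
    seq, manifest = gen_sequence(spec, motifs)
    write_fasta(seq, outdir / "sequence.fa")
    write_motifs_jaspar(motifs, outdir / "motifs.jaspar")
    (outdir / "planted.json").write_text(json.dumps(manifest, indent=1))
    return {"fasta": str(outdir / "sequence.fa"),
            "motifs": str(outdir / "motifs.jaspar"),
            "manifest": str(outdir / "planted.json")}
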