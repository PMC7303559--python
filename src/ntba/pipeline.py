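"""Stage orchestration: file-level pipeline from inputs to zone labels.

Five major stages compose the workflow: ``scan`` (nTBA affinity profiles from
FASTA + motifs), ``profile`` (signal aggregation around feature windows),
``tracks`` (100 bp binning and Z-score normalisation of marker coverage),
``hic-enrich`` (contact-matrix Z-scoring, rank-sum enrichment, per-bin
frequencies) and ``zones`` (clustering of F_he vectors into zone types
I/II/III).  ``simulate`` writes a fully synthetic input set, and ``all`` runs
the stages end to end on it.  Every run echoes its configuration and a
manifest (inputs, parameters, seed, output checksums) into the output
directory; identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import engine, features, fixtures, hic, io, tracks, zones

log = logging.getLogger("ntba")


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults."""

    # inputs
    fasta: str | None = None
    motifs: str | None = None
    motif_format: str = "jaspar"
    features_bed: str | None = None
    tss_bed: str | None = None
    hot_bed: str | None = None
    tracks_dir: str | None = None
    contacts: str | None = None
    chrom_sizes: str | None = None
    chrom: str | None = None
    # scan parameters
    L: int = 50
    st: int = 5
    R: int = 10
    p: float = 1.0
    mus: tuple[float, ...] = (0.0, -10.0)
    workers: int = 1
    # integration parameters
    resolution: int = 250_000
    n_random_pairs: int = 100
    enrichment_threshold: float = 3.0
    enrichment_mode: str = "pooled"
    k: int = 3
    w: float = 0.5
    seed: int = 0
    # profile stage
    profile_mode: str = "total"
    subsample: int = 200
    draws: int = 5
    # simulate stage
    sim_bins_per_regime: int = 20
    sim_sequence_length: int = 5_000
    outdir: str = "ntba_out"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat TOML config file; keyword overrides win over the file."""
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mus" in data:
            data["mus"] = tuple(float(x) for x in data["mus"])
        return cls(**data)

    @property
    def potentials(self) -> tuple[engine.ChemicalPotential, ...]:
        return tuple(engine.ChemicalPotential("fermi_dirac", mu) for mu in self.mus)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(cfg: RunConfig, stage: str, inputs: list[str],
                    outputs: list[Path]) -> None:
    from importlib.metadata import version

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = version("ntba")
    except Exception:
        pkg_version = "unknown"
    manifest = {
        "stage": stage,
        "inputs": inputs,
        "parameters": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(cfg).items()},
        "seed": cfg.seed,
        "version": pkg_version,
        "checksums": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
    }
    (outdir / f"manifest_{stage.replace('-', '_')}.json").write_text(
        json.dumps(manifest, indent=1))


def _require(cfg: RunConfig, **paths: str | None) -> None:
    for name, p in paths.items():
        if p is None:
            raise FileNotFoundError(f"stage input {name!r} is not configured")
        if not Path(p).exists():
            raise FileNotFoundError(f"stage input {name!r} missing: {p}")


def stage_simulate(cfg: RunConfig) -> dict[str, str]:
    outdir = Path(cfg.outdir)
    spec = fixtures.FixtureSpec(seed=cfg.seed, resolution=cfg.resolution,
                                bins_per_regime=cfg.sim_bins_per_regime,
                                sequence_length=cfg.sim_sequence_length)
    paths = fixtures.write_sequence_fixture(spec, outdir / "sim")
    ds = fixtures.gen_zone_dataset(spec)
    paths.update(fixtures.write_zone_dataset(ds, outdir / "sim"))
    # a one-feature BED marking the planted cluster, for the profile stage
    manifest = json.loads(Path(paths["manifest"]).read_text())
    center = (spec.cluster_center if spec.cluster_center is not None
              else spec.sequence_length // 2)
    cluster = features.GenomicFeature("synthetic", center - 100, center + 100, "peak")
    features.write_bed([cluster], outdir / "sim" / "cluster.bed")
    paths["cluster_bed"] = str(outdir / "sim" / "cluster.bed")
    log.info("simulate: wrote %d files (%d planted sites)", len(paths), len(manifest))
    _write_manifest(cfg, "simulate", [], [Path(p) for p in paths.values()])
    return paths


def stage_scan(cfg: RunConfig) -> list[Path]:
    _require(cfg, fasta=cfg.fasta, motifs=cfg.motifs)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from .motifs import read_motifs, to_energy

    matrices = [to_energy(m) for m in read_motifs(cfg.motifs, cfg.motif_format)]
    outputs = []
    for seq_id, seq in io.read_fasta(cfg.fasta):
        profile = engine.ntba_scan(seq, matrices, cfg.potentials, L=cfg.L,
                                   st=cfg.st, p=cfg.p, R=cfg.R, seed=cfg.seed,
                                   workers=cfg.workers, seq_id=seq_id)
        tsv = outdir / f"ntba_{seq_id}.tsv"
        io.write_profile_tsv(profile, tsv)
        outputs.append(tsv)
        for j, pot in enumerate(cfg.potentials):
            bg = outdir / f"ntba_{seq_id}_{pot.label}.bedGraph"
            io.write_profile_bedgraph(profile, bg, j)
            outputs.append(bg)
        log.info("scan: %s -> %d windows x %d potentials", seq_id,
                 len(profile.positions), len(cfg.potentials))
    _write_manifest(cfg, "scan", [cfg.fasta, cfg.motifs], outputs)
    return outputs


def _load_profile(tsv: Path, seq_id: str) -> engine.AffinityProfile:
    df = pd.read_csv(tsv, sep="\t")
    pots = []
    for col in df.columns[1:]:
        if col == "boltzmann":
            pots.append(engine.ChemicalPotential("boltzmann"))
        else:
            pots.append(engine.ChemicalPotential("fermi_dirac", float(col[2:])))
    positions = df["position"].to_numpy()
    step = int(positions[1] - positions[0]) if len(positions) > 1 else 5
    return engine.AffinityProfile(seq_id=seq_id, positions=positions,
                                  values=df.iloc[:, 1:].to_numpy(),
                                  potentials=tuple(pots), n_motifs=0, step=step)


def stage_profile(cfg: RunConfig) -> Path:
    _require(cfg, features_bed=cfg.features_bed)
    outdir = Path(cfg.outdir)
    profile_tsvs = sorted(outdir.glob("ntba_*.tsv"))
    if not profile_tsvs:
        raise FileNotFoundError("profile stage needs a scan output (ntba_*.tsv) "
                                "in the output directory")
    feats = features.read_bed(cfg.features_bed)
    windows = features.preprocess_features(feats)
    rows = []
    for tsv in profile_tsvs:
        seq_id = tsv.stem[len("ntba_"):]
        profile = _load_profile(tsv, seq_id)
        for j, pot in enumerate(profile.potentials):
            curve = features.aggregate_profile(
                windows, profile, mode=cfg.profile_mode, subsample=cfg.subsample,
                draws=cfg.draws, seed=cfg.seed, potential=j)
            rows.append(pd.DataFrame({"seq": seq_id, "potential": pot.label,
                                      "offset": curve.offsets,
                                      "mean": curve.mean, "sd": curve.sd}))
    out = outdir / "profile_curves.tsv"
    pd.concat(rows).to_csv(out, sep="\t", index=False)
    _write_manifest(cfg, "profile", [cfg.features_bed], [out])
    return out


def stage_tracks(cfg: RunConfig) -> list[Path]:
    """Normalise marker bedGraphs to Z-scores (tracks whose name contains
    'ntba' are affinity surrogates and pass through unchanged)."""
    _require(cfg, tracks_dir=cfg.tracks_dir, chrom_sizes=cfg.chrom_sizes)
    outdir = Path(cfg.outdir) / "norm_tracks"
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = io.read_chrom_sizes(cfg.chrom_sizes)
    outputs = []
    raw = []
    passthrough = []
    for bg in sorted(Path(cfg.tracks_dir).glob("*.bedGraph")):
        name = bg.stem
        sig = io.read_bedgraph(bg, name=name)
        if "ntba" in name.lower():
            passthrough.append((name, sig))
            continue
        n_bins = -(-sizes[sig.chrom] // sig.bin_width)
        counts = np.zeros(n_bins)
        counts[:len(sig.values)] = sig.values[:n_bins]
        raw.append(tracks.CoverageTrack(marker=name, cell_line="run",
                                        chrom=sig.chrom, counts=counts,
                                        bin_width=sig.bin_width))
    for norm in tracks.normalize_tracks(raw):
        p = outdir / f"{norm.marker}.z.bedGraph"
        fixtures.write_bedgraph(norm.values, norm.chrom, norm.bin_width, p)
        outputs.append(p)
    for name, sig in passthrough:
        p = outdir / f"{name}.z.bedGraph"
        fixtures.write_bedgraph(sig.values, sig.chrom, sig.bin_width, p)
        outputs.append(p)
    _write_manifest(cfg, "tracks", [cfg.tracks_dir], outputs)
    return outputs


def stage_hic_enrich(cfg: RunConfig) -> tuple[Path, Path]:
    _require(cfg, contacts=cfg.contacts, chrom_sizes=cfg.chrom_sizes,
             tss_bed=cfg.tss_bed, hot_bed=cfg.hot_bed)
    outdir = Path(cfg.outdir)
    norm_dir = outdir / "norm_tracks"
    track_files = sorted(norm_dir.glob("*.z.bedGraph"))
    if not track_files:
        raise FileNotFoundError("hic-enrich needs normalised tracks "
                                f"(run the tracks stage first): {norm_dir}")
    sizes = io.read_chrom_sizes(cfg.chrom_sizes)
    chrom = cfg.chrom or next(iter(sizes))
    grid = hic.make_bins(sizes[chrom], cfg.resolution)
    contacts = io.read_contact_matrix(cfg.contacts, chrom, cfg.resolution,
                                      nt=grid.nt)
    z = hic.zscore_matrix(contacts)
    detected = hic.detect_interactions(z)
    log.info("hic-enrich: %d detected pairs of %d bins", len(detected), grid.nt)

    tss_windows = features.preprocess_features(features.read_bed(cfg.tss_bed, "tss"))
    hot_windows = features.preprocess_features(features.read_bed(cfg.hot_bed, "hot"))
    markers = []
    for tf in track_files:
        name = tf.stem[:-2] if tf.stem.endswith(".z") else tf.stem
        sig = io.read_bedgraph(tf, name=name)
        is_ntba = "ntba" in name.lower()
        wins = hot_windows if (is_ntba and "hot" in name.lower()) else tss_windows
        markers.append(hic.marker_value_per_bin(
            grid, wins, sig, marker=name,
            kind="ntba" if is_ntba else "epigenomic"))
    table = hic.enrichment_table(detected, markers, grid.nt,
                                 n_random=cfg.n_random_pairs, seed=cfg.seed,
                                 mode=cfg.enrichment_mode)
    freqs = hic.bin_frequencies(detected, table, grid.nt,
                                threshold=cfg.enrichment_threshold)
    enr_path = outdir / "enrichment.tsv"
    table.to_csv(enr_path, sep="\t", index=False, na_rep="nan")
    freq_df = pd.DataFrame({"bin": range(grid.nt), "chrom": chrom,
                            "start": grid.starts, "end": grid.ends,
                            "nvi": freqs.nvi, "fi": freqs.fi})
    for m in freqs.fhe.columns:
        freq_df[f"fhe_{m}"] = freqs.fhe[m].to_numpy()
    freq_path = outdir / "bin_frequencies.tsv"
    freq_df.to_csv(freq_path, sep="\t", index=False)
    _write_manifest(cfg, "hic-enrich",
                    [cfg.contacts, cfg.tss_bed, cfg.hot_bed], [enr_path, freq_path])
    return enr_path, freq_path


def stage_zones(cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    freq_path = outdir / "bin_frequencies.tsv"
    if not freq_path.exists():
        raise FileNotFoundError(f"zones stage needs the enrichment frequencies "
                                f"table (run hic-enrich first): {freq_path}")
    df = pd.read_csv(freq_path, sep="\t")
    fhe_cols = [c for c in df.columns if c.startswith("fhe_")]
    X = df[fhe_cols]
    n_distinct = len(np.unique(X.to_numpy(dtype=float), axis=0))
    kmax = min(6, n_distinct, len(df) - 1)
    if kmax >= 2:
        stress, _selected = zones.stress_curve(X, range(1, kmax + 1), seed=cfg.seed)
    else:
        stress = {1: 1.0}
        log.warning("zones: too few distinct F_he rows for a stress scan")
    model = zones.cluster_bins(X, k=cfg.k, w=cfg.w, seed=cfg.seed)
    labels = zones.label_zones(model, df["fi"].to_numpy(),
                               chrom=str(df["chrom"].iloc[0]),
                               resolution=cfg.resolution)
    out = labels.to_frame()
    for c in range(model.k):
        out[f"prob_{c}"] = model.probabilities[:, c]
    zones_path = outdir / "zones.tsv"
    out.to_csv(zones_path, sep="\t", index=False)
    stress_path = outdir / "stress.tsv"
    pd.DataFrame({"k": list(stress), "stress": list(stress.values())}).to_csv(
        stress_path, sep="\t", index=False)
    _write_manifest(cfg, "zones", [str(freq_path)], [zones_path, stress_path])
    return zones_path


@dataclass
class ZoneAnalysis:
    """In-memory result of the tracks -> hic-enrich -> zones chain."""

    detected: pd.DataFrame
    frequencies: "hic.BinFrequencies"
    model: "zones.ClusterModel"
    labels: "zones.ZoneLabels"


def analyze_zone_dataset(ds, seed: int = 0, enrichment_mode: str = "pooled",
                         n_random: int = 100, threshold: float = 3.0,
                         w: float = 0.5) -> ZoneAnalysis:
    """Run the integration chain on an in-memory synthetic zone dataset:
    normalise the marker tracks, Z-score the contact matrix, test marker
    enrichment in detected pairs, build F_i/F_he and classify bins into zone
    types I/II/III."""
    raw = [tracks.CoverageTrack(m, "sim", ds.chrom, ds.tracks[m],
                                ds.spec.track_bin_width)
           for m, kind in ds.track_kinds.items() if kind == "epigenomic"]
    signals = {t.marker: t for t in tracks.normalize_tracks(raw)}
    signals.update({m: tracks.BinnedSignal(m, ds.chrom, ds.tracks[m],
                                           ds.spec.track_bin_width)
                    for m, kind in ds.track_kinds.items() if kind == "ntba"})
    grid = hic.make_bins(ds.chrom_length, ds.spec.resolution)
    z = hic.zscore_matrix(ds.contacts)
    detected = hic.detect_interactions(z)
    tss_windows = features.preprocess_features(ds.tss)
    hot_windows = features.preprocess_features(ds.hot)
    markers = []
    for name, kind in ds.track_kinds.items():
        wins = hot_windows if (kind == "ntba" and "hot" in name) else tss_windows
        markers.append(hic.marker_value_per_bin(grid, wins, signals[name],
                                                name, kind))
    table = hic.enrichment_table(detected, markers, grid.nt, n_random=n_random,
                                 seed=seed, mode=enrichment_mode)
    freqs = hic.bin_frequencies(detected, table, grid.nt, threshold=threshold)
    model = zones.cluster_bins(freqs.fhe, k=3, w=w, seed=seed)
    labels = zones.label_zones(model, freqs.fi, chrom=ds.chrom,
                               resolution=ds.spec.resolution)
    return ZoneAnalysis(detected=detected, frequencies=freqs, model=model,
                        labels=labels)


def stage_all(cfg: RunConfig) -> Path:
    """simulate -> scan -> profile -> tracks -> hic-enrich -> zones."""
    paths = stage_simulate(cfg)
    cfg = dataclasses.replace(
        cfg, fasta=paths["fasta"], motifs=paths["motifs"],
        features_bed=paths["cluster_bed"], tss_bed=paths["tss"],
        hot_bed=paths["hot"], tracks_dir=str(Path(paths["tss"]).parent / "markers"),
        contacts=paths["contacts"], chrom_sizes=paths["chrom_sizes"])
    stage_scan(cfg)
    stage_profile(cfg)
    stage_tracks(cfg)
    stage_hic_enrich(cfg)
    return stage_zones(cfg)
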