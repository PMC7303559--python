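"""Readers and writers for the standard text formats the pipeline consumes."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .hic import ContactMatrix
from .tracks import BinnedSignal


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs, uppercased; each record is scanned independently."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """UCSC chrom.sizes: two whitespace-delimited columns (name, length)."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        name, length = line.split()[:2]
        sizes[name] = int(length)
    return sizes


def hg19_chrom_sizes() -> dict[str, int]:
    """Packaged hg19 assembly chromosome lengths (standard UCSC constants)."""
    with resources.files("ntba.data").joinpath("hg19.chrom.sizes").open() as fh:
        return {name: int(length) for name, length in
                (ln.split() for ln in fh if ln.strip())}


def read_bedgraph(path: str | Path, name: str = "signal",
                  bin_width: int = 100) -> BinnedSignal:
    """Read a single-chromosome fixed-bin bedGraph into a binned signal."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"{path}: expected a single chromosome, got {list(chroms)}")
    n = int(df["end"].max()) // bin_width
    vals = np.zeros(max(n, (int(df["end"].max()) + bin_width - 1) // bin_width))
    idx = df["start"].to_numpy() // bin_width
    vals[idx] = df["value"].to_numpy()
    return BinnedSignal(name=name, chrom=str(chroms[0]), values=vals,
                        bin_width=bin_width)


def read_contact_matrix(path: str | Path, chrom: str, resolution: int,
                        nt: int | None = None) -> ContactMatrix:
    """Dense Nt x Nt TSV, or 3-column (i, j, value) triplets (needs ``nt``)."""
    first = Path(path).open().readline().split("\t")
    if len(first) == 3 and nt is not None:
        trip = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "v"])
        mat = np.zeros((nt, nt))
        i = trip["i"].to_numpy(dtype=int)
        j = trip["j"].to_numpy(dtype=int)
        mat[i, j] = trip["v"]
        mat[j, i] = trip["v"]
    else:
        mat = np.loadtxt(path, delimiter="\t")
    return ContactMatrix(chrom=chrom, matrix=mat, resolution=resolution)


def write_profile_bedgraph(profile, path: str | Path, potential_index: int = 0) -> None:
    """One bedGraph line per window centre (centre..centre+1); missing values
    are omitted."""
    with open(path, "w") as fh:
        for pos, val in zip(profile.positions, profile.values[:, potential_index]):
            if np.isfinite(val):
                fh.write(f"{profile.seq_id}\t{pos}\t{pos + 1}\t{val:.6g}\n")


def write_profile_tsv(profile, path: str | Path) -> None:
    """Wide TSV: position plus one column per chemical potential; missing
    values written as nan."""
    profile.to_frame().to_csv(path, sep="\t", index=False, na_rep="nan")
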