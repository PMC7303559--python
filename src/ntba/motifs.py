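"""Motif collections and their binding-energy representation.

A transcription-factor motif is stored as an ``m x 4`` matrix of per-position
base counts or frequencies over the alphabet (A, C, G, T).  For the biophysical
binding model the motif is converted to a *binding energy matrix*: per position
``j`` and base ``b`` a dimensionless mismatch energy (in thermal units)

    E[j, b] = ln((f_max,j + p0) / (f_b,j + p0))

where ``f_b,j`` is the base frequency, ``f_max,j`` the per-position maximum and
``p0 > 0`` a pseudocount that keeps energies finite for unobserved bases.  The
consensus base at each position has energy exactly 0, so the consensus site is
the energy reference (minimum-energy) sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
#: integer codes: A=0, C=1, G=2, T=3, N=4
N_CODE = 4
_COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_TRANS = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _TRANS[ord(_b)] = _i
    _TRANS[ord(_b.lower())] = _i
_TRANS[ord("N")] = N_CODE
_TRANS[ord("n")] = N_CODE


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string over {A,C,G,T,N} (case-insensitive) to int8 codes."""
    codes = _TRANS[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes < 0)[:5]})
        raise ValueError(f"sequence contains unsupported characters: {bad}")
    return codes


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT_CODE[codes[::-1]]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join((ALPHABET + "N")[c] for c in codes)


@dataclass
class MotifMatrix:
    """Per-position base counts or frequencies of one motif."""

    id: str
    values: np.ndarray  # (m, 4), counts or frequencies, all >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError(f"motif {self.id!r}: values must be m x 4")
        if self.values.shape[0] < 1:
            raise ValueError(f"motif {self.id!r}: zero-length motif rejected")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError(f"motif {self.id!r}: negative or non-finite entries")

    @property
    def m(self) -> int:
        """Binding-site length (motif width)."""
        return self.values.shape[0]

    def frequencies(self) -> np.ndarray:
        """Row-normalised frequencies; rows that sum to 0 become uniform."""
        row_sums = self.values.sum(axis=1, keepdims=True)
        freq = np.where(row_sums > 0, self.values / np.where(row_sums == 0, 1, row_sums), 0.25)
        return freq


@dataclass
class EnergyMatrix:
    """Binding-energy matrix of one motif (dimensionless, thermal units).

    Invariant: per position the minimum over the 4 bases is exactly 0 (the
    consensus base), and all energies are finite and non-negative.
    """

    id: str
    energies: np.ndarray  # (m, 4)
    p0: float = 0.01
    _extended: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[1] != 4:
            raise ValueError(f"energy matrix {self.id!r}: must be m x 4")
        if not np.isfinite(self.energies).all() or (self.energies < 0).any():
            raise ValueError(f"energy matrix {self.id!r}: energies must be finite and >= 0")
        if not np.allclose(self.energies.min(axis=1), 0.0):
            raise ValueError(f"energy matrix {self.id!r}: per-position minimum must be 0")
        # 5th column scores N as the per-position mean energy
        self._extended = np.column_stack([self.energies, self.energies.mean(axis=1)])

    @property
    def m(self) -> int:
        return self.energies.shape[0]

    @property
    def extended(self) -> np.ndarray:
        """(m, 5) energy lookup including the N column (per-position mean)."""
        return self._extended

    def reverse_complement(self) -> "EnergyMatrix":
        """Energy matrix scoring the reverse-complement strand at the same offset."""
        rc = self.energies[::-1, ::-1]
        return EnergyMatrix(id=self.id + "_rc", energies=rc, p0=self.p0)


def to_energy(motif: MotifMatrix, p0: float = 0.01) -> EnergyMatrix:
    """Convert a motif (counts or frequencies) to a binding-energy matrix.

    Uses the mismatch form ``ln((f_max + p0)/(f + p0))`` per position; the
    consensus base gets energy exactly 0.  ``p0`` must be > 0.
    """
    if not p0 > 0:
        raise ValueError(f"pseudocount p0 must be > 0, got {p0}")
    freq = motif.frequencies()
    fmax = freq.max(axis=1, keepdims=True)
    energies = np.log((fmax + p0) / (freq + p0))
    # enforce the exact-zero invariant against floating-point round-off
    energies[np.arange(motif.m), freq.argmax(axis=1)] = 0.0
    np.clip(energies, 0.0, None, out=energies)
    return EnergyMatrix(id=motif.id, energies=energies, p0=p0)


def site_energy(matrix: EnergyMatrix, site: str | np.ndarray) -> float:
    """Total binding energy of one m-mer: the sum of per-position energies.

    ``N`` at any position contributes the mean of the 4 energies there.
    """
    codes = encode_sequence(site) if isinstance(site, str) else np.asarray(site)
    if len(codes) != matrix.m:
        raise ValueError(f"site length {len(codes)} != motif width {matrix.m}")
    return float(matrix.extended[np.arange(matrix.m), codes].sum())


# ---------------------------------------------------------------------------
# readers

_JASPAR_ROW = re.compile(r"^\s*([ACGTacgt])\s*[|\[]?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def read_motifs(path: str | Path, format: str = "jaspar") -> list[MotifMatrix]:
    """Read a motif collection from a text file.

    ``jaspar``: records ``>ID [name]`` followed by four base rows
    ``A [ 1 2 3 ]`` (brackets optional).  ``plain-matrix``: records are
    whitespace-delimited m x 4 blocks, optionally preceded by a ``>ID`` line,
    separated by blank lines.  Record order is preserved; matrices are returned
    un-normalised.
    """
    path = Path(path)
    text = path.read_text()
    if format == "jaspar":
        return _parse_jaspar(text, path)
    if format == "plain-matrix":
        return _parse_plain(text, path)
    raise ValueError(f"unknown motif format {format!r}")


def _parse_jaspar(text: str, path: Path) -> list[MotifMatrix]:
    motifs: list[MotifMatrix] = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        line = lines[i]
        if not line.startswith(">"):
            raise ValueError(f"{path}: expected '>' header, got {line!r}")
        motif_id = line[1:].strip().split()[0] if line[1:].strip() else "motif"
        rows: dict[str, list[float]] = {}
        i += 1
        while i < len(lines) and not lines[i].startswith(">"):
            m = _JASPAR_ROW.match(lines[i])
            if m is None:
                raise ValueError(f"{path}: malformed row in record {motif_id!r}: {lines[i]!r}")
            base = m.group(1).upper()
            try:
                vals = [float(x) for x in m.group(2).split()]
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row in record {motif_id!r}") from exc
            rows[base] = vals
            i += 1
        if set(rows) != set(ALPHABET):
            raise ValueError(f"{path}: record {motif_id!r} missing base rows "
                             f"{sorted(set(ALPHABET) - set(rows))}")
        widths = {len(v) for v in rows.values()}
        if len(widths) != 1:
            raise ValueError(f"{path}: record {motif_id!r} has ragged rows")
        if widths == {0}:
            raise ValueError(f"{path}: record {motif_id!r} is zero-length")
        values = np.array([rows[b] for b in ALPHABET]).T
        if (values < 0).any():
            raise ValueError(f"{path}: record {motif_id!r} contains a negative count")
        motifs.append(MotifMatrix(id=motif_id, values=values))
    return motifs


def _parse_plain(text: str, path: Path) -> list[MotifMatrix]:
    motifs: list[MotifMatrix] = []
    blocks: list[tuple[str | None, list[str]]] = []
    current_id: str | None = None
    current: list[str] = []
    for ln in text.splitlines() + [""]:
        stripped = ln.strip()
        if stripped.startswith(">"):
            if current:
                blocks.append((current_id, current))
                current = []
            current_id = stripped[1:].strip().split()[0] if stripped[1:].strip() else None
        elif not stripped:
            if current:
                blocks.append((current_id, current))
                current, current_id = [], None
        else:
            current.append(stripped)
    for idx, (motif_id, rows) in enumerate(blocks, start=1):
        name = motif_id or f"motif_{idx}"
        try:
            values = np.array([[float(x) for x in r.split()] for r in rows])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record {name!r}") from exc
        if values.ndim != 2 or values.shape[1] != 4:
            raise ValueError(f"{path}: record {name!r} is not an m x 4 block")
        if (values < 0).any():
            raise ValueError(f"{path}: record {name!r} contains a negative count")
        motifs.append(MotifMatrix(id=name, values=values))
    return motifs


def write_motifs_jaspar(motifs: list[MotifMatrix], path: str | Path) -> None:
    """Write motifs in JASPAR text format (counts/frequencies as given)."""
    with open(path, "w") as fh:
        for motif in motifs:
            fh.write(f">{motif.id}\n")
            for bi, base in enumerate(ALPHABET):
                vals = " ".join(f"{v:.6g}" for v in motif.values[:, bi])
                fh.write(f"{base} [ {vals} ]\n")
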