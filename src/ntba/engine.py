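"""Nonspecific TF binding affinity (nTBA) along DNA.

The model scores every sliding window ``S_i`` (default 50 bp, step 5 bp) of a
DNA sequence against an ensemble of binding-energy matrices.  For one motif the
window affinity is

    A_i = p * sum_{l=1..L-m+1} P(E * S_{i,l})

where ``P`` is a binding probability: the Fermi-Dirac form
``P = 1 / (1 + exp(E*S - mu))`` with chemical potential ``mu`` (the TF
concentration parameter), or the Maxwell-Boltzmann limit ``P = exp(-E*S)``
used when binding does not depend on the chemical potential (``mu = 0`` /
very low concentration).  Both strands are scored by default: each offset
contributes its forward-strand probability plus that of the reverse
complement.

Local sequence-composition bias is removed by subtracting the mean affinity of
``R`` mononucleotide shuffles of the same window (differential binding
affinity, ``dbA = A - A_background``).  The expected nTBA of a window is the
average dbA over all motifs in the collection, and it is assigned to the
window centre.

The scan is deterministic: the shuffle stream for window ``i`` and motif ``t``
is seeded from ``(seed, i, t)``, so results do not depend on the number of
worker processes or on motif processing order.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .motifs import N_CODE, EnergyMatrix, encode_sequence

_EXP_CLAMP = 700.0  # exp argument guard


@dataclass(frozen=True)
class ChemicalPotential:
    """Binding-probability mode: Fermi-Dirac at chemical potential mu, or the
    Boltzmann low-concentration limit (mu ignored)."""

    mode: str = "fermi_dirac"  # or "boltzmann"
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fermi_dirac", "boltzmann"):
            raise ValueError(f"unknown binding-probability mode {self.mode!r}")

    @property
    def label(self) -> str:
        if self.mode == "boltzmann":
            return "boltzmann"
        return f"mu{self.mu:g}"


def binding_probability(energy, potential: ChemicalPotential):
    """Probability that a site of the given energy is bound.

    Fermi-Dirac: ``1/(1+exp(E - mu))``; Boltzmann: ``exp(-E)``.  Accepts
    scalars or arrays; overflow is clamped so large energies underflow to 0.
    """
    energy = np.asarray(energy, dtype=float)
    if potential.mode == "boltzmann":
        out = np.exp(-np.clip(energy, -_EXP_CLAMP, _EXP_CLAMP))
    else:
        x = np.clip(energy - potential.mu, -_EXP_CLAMP, _EXP_CLAMP)
        out = 1.0 / (1.0 + np.exp(x))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SlidingWindowGrid:
    """Full sliding windows [start, start+L) at step st over a sequence of
    length N; k = floor((N-L)/st) + 1 when N >= L, else 0."""

    N: int
    L: int = 50
    st: int = 5

    def __post_init__(self) -> None:
        if self.L < 1 or self.st < 1:
            raise ValueError("window size and step must be >= 1")

    @property
    def k(self) -> int:
        return 0 if self.N < self.L else (self.N - self.L) // self.st + 1

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.k) * self.st

    @property
    def centers(self) -> np.ndarray:
        """Centre of each window: start + L//2 (position 25 of a 50 bp window)."""
        return self.starts + self.L // 2


def make_grid(N: int, L: int = 50, st: int = 5) -> SlidingWindowGrid:
    return SlidingWindowGrid(N=N, L=L, st=st)


def _offset_energies(codes: np.ndarray, matrix: EnergyMatrix) -> np.ndarray:
    """Site energies at every offset of ``codes`` (length >= m), forward strand."""
    m = matrix.m
    if len(codes) < m:
        return np.empty(0)
    windows = sliding_window_view(codes, m)
    return matrix.extended[np.arange(m), windows].sum(axis=1)


def _strand_energies(codes: np.ndarray, matrix: EnergyMatrix,
                     both_strands: bool) -> list[np.ndarray]:
    energies = [_offset_energies(codes, matrix)]
    if both_strands:
        # reverse-complement strand scored at the same offsets via the
        # reversed-complemented energy matrix
        energies.append(_offset_energies(codes, matrix.reverse_complement()))
    return energies


def window_affinity(window: str | np.ndarray, matrix: EnergyMatrix,
                    potential: ChemicalPotential, p: float = 1.0,
                    both_strands: bool = True) -> float:
    """Affinity A of one motif on one window: p times the sum of binding
    probabilities over all offsets (both strands by default).  Returns 0 when
    the motif is wider than the window (empty sum)."""
    codes = encode_sequence(window) if isinstance(window, str) else np.asarray(window)
    if len(codes) < matrix.m:
        return 0.0
    total = 0.0
    for energies in _strand_energies(codes, matrix, both_strands):
        total += binding_probability(energies, potential).sum()
    return p * total


def _shuffles(codes: np.ndarray, R: int, rng: np.random.Generator) -> np.ndarray:
    """R independent mononucleotide permutations of the window, one per row."""
    return rng.permuted(np.tile(codes, (R, 1)), axis=1)


def shuffled_background(window: str | np.ndarray, matrix: EnergyMatrix,
                        potential: ChemicalPotential, p: float = 1.0,
                        R: int = 10, seed: int | np.random.Generator = 0,
                        both_strands: bool = True) -> float:
    """Mean window affinity over R mononucleotide shuffles of the window.

    Shuffles preserve base composition exactly and are reproducible under the
    seed (an integer or a Generator).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    codes = encode_sequence(window) if isinstance(window, str) else np.asarray(window)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = _shuffles(codes, R, rng)
    return float(np.mean([
        window_affinity(row, matrix, potential, p, both_strands) for row in shuffled
    ]))


def differential_affinity(window: str | np.ndarray, matrix: EnergyMatrix,
                          potential: ChemicalPotential, p: float = 1.0,
                          R: int = 10, seed: int | np.random.Generator = 0,
                          both_strands: bool = True) -> float:
    """dbA = window affinity minus the shuffled-window background."""
    codes = encode_sequence(window) if isinstance(window, str) else np.asarray(window)
    fg = window_affinity(codes, matrix, potential, p, both_strands)
    bg = shuffled_background(codes, matrix, potential, p, R, seed, both_strands)
    return fg - bg


@dataclass
class AffinityProfile:
    """Expected nTBA per window centre, one series per chemical potential."""

    seq_id: str
    positions: np.ndarray            # window centres, strictly increasing
    values: np.ndarray               # (k, n_potentials)
    potentials: tuple[ChemicalPotential, ...]
    n_motifs: int
    step: int = 5

    def series(self, potential: ChemicalPotential) -> np.ndarray:
        return self.values[:, self.potentials.index(potential)]

    def values_at(self, chrom: str, positions: np.ndarray,
                  potential: ChemicalPotential | int = 0) -> np.ndarray:
        """Signal value at arbitrary positions: the value of the nearest window
        centre within step/2 (piecewise-constant profile); NaN outside coverage
        or on another sequence."""
        col = (potential if isinstance(potential, int)
               else self.potentials.index(potential))
        positions = np.asarray(positions)
        out = np.full(positions.shape, np.nan)
        if chrom != self.seq_id or len(self.positions) == 0:
            return out
        first = int(self.positions[0])
        idx = np.rint((positions - first) / self.step).astype(int)
        ok = (idx >= 0) & (idx < len(self.positions))
        ok &= np.abs(positions - (first + idx * self.step)) <= self.step / 2
        out[ok] = self.values[idx[ok], col]
        return out

    def to_frame(self):
        import pandas as pd

        data = {"position": self.positions}
        for j, pot in enumerate(self.potentials):
            data[pot.label] = self.values[:, j]
        return pd.DataFrame(data)


def _per_motif_dbA(codes: np.ndarray, grid: SlidingWindowGrid,
                   matrix: EnergyMatrix,
                   potentials: Sequence[ChemicalPotential],
                   p: float, R: int, seed: int, t_index: int,
                   both_strands: bool, valid: np.ndarray) -> np.ndarray:
    """dbA of one motif for every window and potential; (k, n_pot)."""
    k = grid.k
    out = np.zeros((k, len(potentials)))
    m = matrix.m
    n_off = grid.L - m + 1
    # foreground: per-offset probabilities over the whole sequence once,
    # window sums via cumulative sums
    strand_energies = _strand_energies(codes, matrix, both_strands)
    starts = grid.starts
    fg = np.zeros((k, len(potentials)))
    for energies in strand_energies:
        for j, pot in enumerate(potentials):
            probs = binding_probability(energies, pot)
            c = np.concatenate([[0.0], np.cumsum(probs)])
            fg[:, j] += c[starts + n_off] - c[starts]
    fg *= p
    # background: per-window shuffles, seeded by (seed, window, motif)
    for i in range(k):
        if not valid[i]:
            out[i] = np.nan
            continue
        win = codes[starts[i]:starts[i] + grid.L]
        rng = np.random.default_rng([seed, i, t_index])
        shuffled = _shuffles(win, R, rng)
        bg = np.zeros(len(potentials))
        for row in shuffled:
            for energies in _strand_energies(row, matrix, both_strands):
                for j, pot in enumerate(potentials):
                    bg[j] += binding_probability(energies, pot).sum()
        bg *= p / R
        out[i] = fg[i] - bg
    return out


def _worker(args) -> tuple[int, np.ndarray]:
    (t, codes, grid, matrix, potentials, p, R, seed, both_strands, valid) = args
    return t, _per_motif_dbA(codes, grid, matrix, potentials, p, R, seed, t,
                             both_strands, valid)


def ntba_scan(sequence: str, motifs: Sequence[EnergyMatrix],
              potentials: Sequence[ChemicalPotential] | None = None,
              L: int = 50, st: int = 5, p: float = 1.0, R: int = 10,
              seed: int = 0, workers: int = 1, both_strands: bool = True,
              seq_id: str = "seq") -> AffinityProfile:
    """Scan a sequence: expected nTBA (ensemble-mean dbA) per window centre.

    Motifs wider than the window are skipped with a warning; windows whose N
    content exceeds L/2 are emitted as missing values.  The result is
    bit-identical for any ``workers`` count.
    """
    if potentials is None:
        potentials = (ChemicalPotential("fermi_dirac", 0.0),
                      ChemicalPotential("fermi_dirac", -10.0))
    potentials = tuple(potentials)
    codes = encode_sequence(sequence)
    grid = make_grid(len(codes), L, st)
    usable = []
    for matrix in motifs:
        if matrix.m > L:
            warnings.warn(f"motif {matrix.id!r} wider than window (m={matrix.m} > L={L}); skipped")
        else:
            usable.append(matrix)
    if not usable:
        raise ValueError("no usable motif (all wider than the scan window)")

    # windows with more than L/2 ambiguous bases are masked
    is_n = np.concatenate([[0], np.cumsum(codes == N_CODE)])
    n_in_window = is_n[grid.starts + L] - is_n[grid.starts]
    valid = n_in_window <= L / 2

    tasks = [(t, codes, grid, matrix, potentials, p, R, seed, both_strands, valid)
             for t, matrix in enumerate(usable)]
    results: dict[int, np.ndarray] = {}
    if workers > 1 and len(tasks) > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            for t, arr in pool.map(_worker, tasks):
                results[t] = arr
    else:
        for task in tasks:
            t, arr = _worker(task)
            results[t] = arr
    # accumulate in motif-index order for bit-exact determinism
    total = np.zeros((grid.k, len(potentials)))
    for t in range(len(usable)):
        total += results[t]
    total /= len(usable)
    total[~valid] = np.nan
    return AffinityProfile(seq_id=seq_id, positions=grid.centers, values=total,
                           potentials=potentials, n_motifs=len(usable), step=st)
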