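"""The sliding-window affinity engine against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ntba.engine import (AffinityProfile, ChemicalPotential, binding_probability,
                         differential_affinity, make_grid, ntba_scan,
                         shuffled_background, window_affinity)
from ntba.motifs import MotifMatrix, encode_sequence, site_energy, to_energy
from ntba import fixtures

from conftest import BOLTZMANN, FD0, random_dna

REVCOMP = str.maketrans("ACGTN", "TGCAN")


def naive_window_affinity(window, matrix, potential, p=1.0):
    """Independent per-offset oracle: explicit loop over forward and
    reverse-complement offsets."""
    total = 0.0
    m = matrix.m
    for strand_seq in (window, window.translate(REVCOMP)[::-1]):
        for l in range(len(window) - m + 1):
            total += binding_probability(site_energy(matrix, strand_seq[l:l + m]),
                                         potential)
    return p * total


def naive_scan(sequence, matrices, potentials, L=50, st_=5, p=1.0, R=10, seed=0):
    """Triple-loop oracle (windows x motifs x offsets); shuffles follow the
    documented seeding contract (seed, window index, motif index)."""
    grid = make_grid(len(sequence), L, st_)
    values = np.zeros((grid.k, len(potentials)))
    for i, start in enumerate(grid.starts):
        window = sequence[start:start + L]
        for t, matrix in enumerate(matrices):
            rng = np.random.default_rng([seed, i, t])
            shuffled = rng.permuted(
                np.tile(encode_sequence(window), (R, 1)), axis=1)
            shuffled_strs = ["".join("ACGTN"[c] for c in row) for row in shuffled]
            for j, pot in enumerate(potentials):
                fg = naive_window_affinity(window, matrix, pot, p)
                bg = np.mean([naive_window_affinity(s, matrix, pot, p)
                              for s in shuffled_strs])
                values[i, j] += fg - bg
    return values / len(matrices)


class TestGrid:
    @pytest.mark.parametrize("N,L,st_,k", [(50, 50, 5, 1), (1000, 50, 5, 191),
                                           (49, 50, 5, 0), (100, 30, 7, 11)])
    def test_window_count(self, N, L, st_, k):
        grid = make_grid(N, L, st_)
        assert grid.k == k
        # enumeration oracle: all full windows at starts 0, st, 2st, ...
        assert grid.k == sum(1 for s in range(0, N + 1, st_) if s + L <= N)

    @given(N=st.integers(0, 2000), L=st.integers(1, 100), st_=st.integers(1, 20))
    @settings(max_examples=100, deadline=None)
    def test_windows_in_bounds(self, N, L, st_):
        grid = make_grid(N, L, st_)
        if grid.k:
            assert grid.starts[-1] + L <= N
            assert (np.diff(grid.centers) == st_).all()

    def test_center_of_even_window(self):
        assert make_grid(50, 50, 5).centers[0] == 25


class TestBindingProbability:
    def test_midpoint(self):
        pot = ChemicalPotential("fermi_dirac", -3.0)
        assert binding_probability(-3.0, pot) == 0.5

    def test_boltzmann_consensus(self):
        assert binding_probability(0.0, BOLTZMANN) == 1.0

    def test_fermi_dirac_value(self):
        pot = ChemicalPotential("fermi_dirac", -10.0)
        np.testing.assert_allclose(binding_probability(0.0, pot),
                                   1 / (1 + math.exp(10)), rtol=1e-12)

    def test_strictly_decreasing_in_energy(self):
        e = np.linspace(0, 20, 50)
        for pot in (FD0, BOLTZMANN, ChemicalPotential("fermi_dirac", -7.0)):
            p = binding_probability(e, pot)
            assert (np.diff(p) < 0).all()

    def test_increasing_in_mu(self):
        probs = [binding_probability(2.0, ChemicalPotential("fermi_dirac", mu))
                 for mu in (-20, -10, -1, 0, 1)]
        assert (np.diff(probs) > 0).all()

    def test_boltzmann_limit(self):
        # for energy - mu >= 5 the Fermi-Dirac form matches exp(-(E-mu))
        # within 1% relative error
        for mu in (0.0, -10.0):
            e = np.linspace(mu + 5, mu + 40, 200)
            fd = binding_probability(e, ChemicalPotential("fermi_dirac", mu))
            mb = np.exp(-(e - mu))
            assert np.max(np.abs(fd - mb) / mb) < 0.01

    def test_overflow_guarded(self):
        # huge energies underflow gracefully instead of raising/overflowing
        p = binding_probability(1e8, FD0)
        assert 0.0 <= p < 1e-300
        assert np.isfinite(binding_probability(np.array([0.0, 1e8, 1e300]), FD0)).all()


class TestWindowAffinity:
    def test_single_offset_consensus_boltzmann(self, simple_energy):
        # L = m: one forward offset (consensus, P=1) plus its reverse complement
        rc_energy = site_energy(simple_energy, "ACGT".translate(REVCOMP)[::-1])
        expected = 1.0 + math.exp(-rc_energy)
        np.testing.assert_allclose(
            window_affinity("ACGT", simple_energy, BOLTZMANN), expected, rtol=1e-12)

    def test_zero_prior(self, rng, simple_energy):
        assert window_affinity(random_dna(rng, 50), simple_energy, FD0, p=0.0) == 0.0

    def test_motif_wider_than_window(self, simple_energy):
        assert window_affinity("AC", simple_energy, FD0) == 0.0

    @pytest.mark.parametrize("pot", [BOLTZMANN, FD0,
                                     ChemicalPotential("fermi_dirac", -10.0)])
    def test_against_offset_oracle(self, rng, pot):
        motif = MotifMatrix("m8", rng.random((8, 4)) + 0.01)
        matrix = to_energy(motif)
        window = random_dna(rng, 50)
        np.testing.assert_allclose(
            window_affinity(window, matrix, pot, p=0.7),
            naive_window_affinity(window, matrix, pot, p=0.7), rtol=1e-12)

    def test_single_strand_mode(self, rng, simple_energy):
        window = random_dna(rng, 30)
        both = window_affinity(window, simple_energy, BOLTZMANN, both_strands=True)
        fwd = window_affinity(window, simple_energy, BOLTZMANN, both_strands=False)
        rc = window_affinity(window.translate(REVCOMP)[::-1], simple_energy,
                             BOLTZMANN, both_strands=False)
        np.testing.assert_allclose(both, fwd + rc, rtol=1e-12)


class TestShuffledBackground:
    def test_homopolymer_identity(self, simple_energy):
        window = "A" * 20
        wa = window_affinity(window, simple_energy, BOLTZMANN)
        for R in (1, 5):
            np.testing.assert_allclose(
                shuffled_background(window, simple_energy, BOLTZMANN, R=R, seed=7),
                wa, rtol=1e-12)

    def test_reproducible_under_seed(self, rng, simple_energy):
        window = random_dna(rng, 50)
        a = shuffled_background(window, simple_energy, FD0, R=1, seed=11)
        b = shuffled_background(window, simple_energy, FD0, R=1, seed=11)
        assert a == b
        c = shuffled_background(window, simple_energy, FD0, R=1, seed=12)
        assert a != c

    def test_converges_to_permutation_mean(self, rng):
        # exhaustive permutation average on a short window (L=6, m=2)
        matrix = to_energy(MotifMatrix("m2", rng.random((2, 4)) + 0.01))
        window = "AACGTT"
        perms = set(itertools.permutations(window))
        exact = np.mean([naive_window_affinity("".join(s), matrix, BOLTZMANN)
                         for s in perms])
        approx = shuffled_background(window, matrix, BOLTZMANN, R=4000, seed=1)
        np.testing.assert_allclose(approx, exact, rtol=0.02)


class TestDifferentialAffinity:
    def test_homopolymer_exact_zero(self, simple_energy):
        assert differential_affinity("C" * 50, simple_energy, FD0, seed=3) == 0.0

    def test_flat_energy_exact_zero(self, rng, flat_energy):
        window = random_dna(rng, 50)
        assert differential_affinity(window, flat_energy, BOLTZMANN, seed=5) == 0.0

    def test_planted_consensus_positive(self, rng, simple_motif, simple_energy):
        # a window saturated with consensus sites beats its shuffles
        window = "ACGT" * 12 + "AC"
        vals = [differential_affinity(window, simple_energy, BOLTZMANN, R=50,
                                      seed=s) for s in range(10)]
        assert sum(v > 0 for v in vals) >= 9


class TestScan:
    def test_flat_motif_all_zero(self, rng, flat_energy):
        profile = ntba_scan(random_dna(rng, 300), [flat_energy], [BOLTZMANN, FD0])
        np.testing.assert_array_equal(profile.values, 0.0)

    def test_triple_loop_oracle(self, rng):
        motifs = [to_energy(MotifMatrix(f"m{i}", rng.random((w, 4)) + 0.01))
                  for i, w in enumerate((6, 8, 10))]
        seq = random_dna(rng, 600)
        pots = (FD0, ChemicalPotential("fermi_dirac", -10.0))
        profile = ntba_scan(seq, motifs, pots, R=3, seed=21)
        expected = naive_scan(seq, motifs, pots, R=3, seed=21)
        np.testing.assert_allclose(profile.values, expected, atol=1e-10)

    def test_worker_count_bit_identical(self, rng):
        motifs = [to_energy(MotifMatrix(f"m{i}", rng.random((6, 4)) + 0.01))
                  for i in range(3)]
        seq = random_dna(rng, 400)
        a = ntba_scan(seq, motifs, [FD0], R=3, seed=9, workers=1)
        b = ntba_scan(seq, motifs, [FD0], R=3, seed=9, workers=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_motif_relabeling_invariance(self, rng):
        mats = [to_energy(MotifMatrix(f"m{i}", rng.random((6, 4)) + 0.01))
                for i in range(3)]
        seq = random_dna(rng, 300)
        a = ntba_scan(seq, mats, [FD0], R=2, seed=4)
        # same matrices under different ids give identical profiles
        renamed = [type(m)(id=f"y{i}", energies=m.energies, p0=m.p0)
                   for i, m in enumerate(mats)]
        b = ntba_scan(seq, renamed, [FD0], R=2, seed=4)
        np.testing.assert_array_equal(a.values, b.values)

    def test_wide_motifs_skipped_with_warning(self, rng, simple_energy):
        wide = to_energy(MotifMatrix("wide", rng.random((60, 4)) + 0.01))
        seq = random_dna(rng, 300)
        with pytest.warns(UserWarning, match="wide"):
            a = ntba_scan(seq, [simple_energy, wide], [FD0], R=2, seed=1)
        b = ntba_scan(seq, [simple_energy], [FD0], R=2, seed=1)
        np.testing.assert_array_equal(a.values, b.values)
        with pytest.raises(ValueError):
            ntba_scan(seq, [wide], [FD0])

    def test_n_runs_masked(self, rng, simple_energy):
        seq = random_dna(rng, 100) + "N" * 200 + random_dna(rng, 100)
        profile = ntba_scan(seq, [simple_energy], [FD0], R=2, seed=1)
        starts = profile.positions - 25
        n_frac = np.array([seq[s:s + 50].count("N") for s in starts])
        assert np.isnan(profile.values[n_frac > 25, 0]).all()
        assert np.isfinite(profile.values[n_frac == 0, 0]).all()

    def test_mu_ladder_magnitude_decreases(self):
        spec = fixtures.FixtureSpec(seed=5, sequence_length=3000)
        motifs = fixtures.gen_motifs(spec)
        seq, _ = fixtures.gen_sequence(spec, motifs)
        pots = [ChemicalPotential("fermi_dirac", mu) for mu in (0, -10, -20)]
        profile = ntba_scan(seq, [to_energy(m) for m in motifs], pots,
                            R=5, seed=5)
        maxima = np.nanmax(np.abs(profile.values), axis=0)
        assert maxima[0] > maxima[1] > maxima[2]

    def test_values_at_lookup(self):
        profile = AffinityProfile("s", np.array([25, 30, 35]),
                                  np.array([[1.0], [2.0], [3.0]]),
                                  (FD0,), n_motifs=1, step=5)
        np.testing.assert_array_equal(
            profile.values_at("s", np.array([25, 27, 33, 10, 100])),
            [1.0, 1.0, 3.0, np.nan, np.nan])
        assert np.isnan(profile.values_at("other", np.array([25]))).all()
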