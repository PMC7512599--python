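import math

import numpy as np
import pytest

from pdgain import (
    AlphaGrid,
    CountHistogram,
    FrameSequence,
    classify_spectrum,
    pdg,
    pdg_map,
    pdge,
    pdged,
    spectra,
    square_position,
    transition_table,
)
from pdgain.sequence import SpectrumTable, _basis_histogram

from oracle_utils import oracle_pdg


class TestFrameSequence:
    def test_shape_and_depth_checks(self):
        with pytest.raises(ValueError, match="shape"):
            FrameSequence((np.zeros((2, 2), int), np.zeros((3, 3), int)), bit_depth=8)
        with pytest.raises(ValueError, match="intensities outside"):
            FrameSequence((np.full((2, 2), 300),), bit_depth=8)
        with pytest.raises(ValueError, match="integer"):
            FrameSequence((np.zeros((2, 2)),), bit_depth=8)
        with pytest.raises(ValueError, match="bit_depth"):
            FrameSequence((np.zeros((2, 2), int),), bit_depth=10)

    def test_accessors(self):
        seq = FrameSequence((np.zeros((4, 5), int),) * 3, bit_depth=12)
        assert len(seq) == 3
        assert seq.shape == (4, 5)
        assert seq.n_levels == 4096


class TestTransitionTable:
    def test_identical_frames_all_diagonal(self):
        a = np.arange(16).reshape(4, 4)
        t = transition_table(a, a)
        assert np.array_equal(t.sources, t.targets)
        assert t.total == 16

    def test_tiny_pair_counts(self, tiny_pair):
        a, b = tiny_pair
        t = transition_table(a, b)
        assert t.as_dict() == {(0, 0): 3, (1, 0): 1}
        assert t.total == 4

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes differ"):
            transition_table(np.zeros((2, 2), int), np.zeros((3, 3), int))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_marginals_match_frame_histograms(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 16, size=(12, 12))
        b = rng.integers(0, 16, size=(12, 12))
        t = transition_table(a, b)
        assert sum(t.counts) == a.size
        np.testing.assert_array_equal(
            t.source_histogram(16).counts, np.bincount(a.ravel(), minlength=16)
        )
        np.testing.assert_array_equal(
            t.target_histogram(16).counts, np.bincount(b.ravel(), minlength=16)
        )

    def test_brute_force_tally(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 5, size=(6, 6))
        b = rng.integers(0, 5, size=(6, 6))
        expected = {}
        for l, m in zip(a.ravel(), b.ravel()):
            expected[(int(l), int(m))] = expected.get((int(l), int(m)), 0) + 1
        assert transition_table(a, b).as_dict() == expected


class TestPdgMap:
    def test_identical_frames_zero_map(self):
        a = np.arange(16).reshape(4, 4)
        pmap = pdg_map(a, a, 2.0)
        assert np.all(pmap.values == 0.0)

    def test_tiny_pair_value(self, tiny_pair):
        a, b = tiny_pair
        pmap = pdg_map(a, b, 2.0)
        assert pmap.values[0, 0] == 0.0
        # histogram of a: n0=3, n1=1; exchange 1->0: C2=10, n_m-n_l+1=3
        assert pmap.values[1, 1] == pytest.approx(-math.log2(1.6), rel=1e-12)
        assert pmap.values[1, 1] == pytest.approx(oracle_pdg([3, 1], 1, 0, 2.0), rel=1e-10)

    def test_matches_scalar_pdg(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 8, size=(10, 10))
        b = rng.integers(0, 8, size=(10, 10))
        hist = CountHistogram.from_values(a, n_levels=8)
        pmap = pdg_map(a, b, 0.99)
        for (i, j) in [(0, 0), (3, 4), (9, 9), (5, 2)]:
            want = pdg(hist, int(a[i, j]), int(b[i, j]), 0.99)
            assert pmap.values[i, j] == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_equal_transitions_equal_values(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 4, size=(8, 8))
        b = rng.integers(0, 4, size=(8, 8))
        pmap = pdg_map(a, b, 1.3)
        vals = {}
        for i in range(8):
            for j in range(8):
                key = (a[i, j], b[i, j])
                vals.setdefault(key, set()).add(pmap.values[i, j])
        assert all(len(s) == 1 for s in vals.values())

    def test_cache_transparency(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 32, size=(16, 16))
        b = rng.integers(0, 32, size=(16, 16))
        for alpha in (0.0, 0.5, 1.0, 2.0):
            cached = pdg_map(a, b, alpha, cache=True)
            plain = pdg_map(a, b, alpha, cache=False)
            np.testing.assert_array_equal(cached.values, plain.values)

    def test_alpha0_zero_map_when_support_stable(self):
        a = np.repeat(np.arange(4), 8).reshape(8, 4)  # every level appears 8x
        b = a.copy()
        b[0, 0] = 2  # target occupied, source keeps 7
        pmap = pdg_map(a, b, 0.0)
        assert np.all(pmap.values == 0.0)

    def test_pooled_basis(self, tiny_pair):
        a, b = tiny_pair
        pmap = pdg_map(a, b, 2.0, basis="pooled")
        pooled = CountHistogram.from_values(np.concatenate([a.ravel(), b.ravel()]), n_levels=2)
        want = pdg(pooled, 1, 0, 2.0)
        assert pmap.values[1, 1] == pytest.approx(want, rel=1e-12)
        assert pmap.basis == "pooled"

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes differ"):
            pdg_map(np.zeros((2, 2), int), np.zeros((2, 3), int), 1.0)


class TestMacroscopic:
    def test_identical_frames_zero(self):
        a = np.arange(16).reshape(4, 4)
        t = transition_table(a, a)
        h = CountHistogram.from_values(a, n_levels=16)
        assert pdge(t, h, 2.0) == 0.0
        assert pdged(t, h, 2.0) == 0.0

    def test_tiny_pair_single_transition(self, tiny_pair):
        a, b = tiny_pair
        t = transition_table(a, b)
        h = CountHistogram.from_values(a, n_levels=2)
        expected = math.log2(1.6)
        assert pdge(t, h, 2.0) == pytest.approx(expected, rel=1e-12)
        # realized pairs (0,0) [zero] and (1,0): same value for the density
        assert pdged(t, h, 2.0) == pytest.approx(expected, rel=1e-12)

    def test_multiplicity_weighting(self):
        a = np.full((10, 10), 5, dtype=int)
        a[0, :] = 9
        b = a.copy()
        b[0, :] = 5  # transition 9->5 occurs 10 times
        t = transition_table(a, b)
        h = CountHistogram.from_values(a, n_levels=10)
        omega = abs(pdg(h, 9, 5, 2.0))
        assert pdge(t, h, 2.0) == pytest.approx(10 * omega, rel=1e-12)
        assert pdged(t, h, 2.0) == pytest.approx(omega, rel=1e-12)

    def test_pdge_equals_per_pixel_sum_bitwise(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 64, size=(32, 32))
        b = rng.integers(0, 64, size=(32, 32))
        t = transition_table(a, b)
        h = CountHistogram.from_values(a, n_levels=64)
        for alpha in (0.1, 0.99, 1.0, 2.0, 4.0):
            pmap = pdg_map(a, b, alpha)
            per_pixel = math.fsum(np.abs(pmap.values).ravel())
            assert pdge(t, h, alpha) == per_pixel

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.99, 1.0, 2.0, 4.0])
    def test_pdged_le_pdge(self, alpha):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 32, size=(16, 16))
        b = rng.integers(0, 32, size=(16, 16))
        t = transition_table(a, b)
        h = CountHistogram.from_values(a, n_levels=32)
        assert pdged(t, h, alpha) <= pdge(t, h, alpha) + 1e-15

    def test_oracle_sum(self):
        """PDGE equals the brute-force per-pixel |Omega| sum from the oracle."""
        rng = np.random.default_rng(9)
        a = rng.integers(0, 4, size=(5, 5))
        b = rng.integers(0, 4, size=(5, 5))
        counts = np.bincount(a.ravel(), minlength=4).tolist()
        brute = math.fsum(
            abs(oracle_pdg(counts, int(l), int(m), 2.0))
            for l, m in zip(a.ravel(), b.ravel())
        )
        t = transition_table(a, b)
        h = CountHistogram.from_values(a, n_levels=4)
        assert pdge(t, h, 2.0) == pytest.approx(brute, rel=1e-10)


class TestSpectra:
    def test_constant_sequence_all_zero(self):
        seq = FrameSequence((np.full((8, 8), 3),) * 4, bit_depth=8)
        tab = spectra(seq, AlphaGrid.named("default13"))
        assert np.all(tab.data["I_alpha"] == 0.0)
        assert np.all(tab.data["P_alpha"] == 0.0)

    def test_row_count(self, moving_square_seq):
        _, seq = moving_square_seq
        tab = spectra(seq, AlphaGrid.named("default13"))
        assert len(tab.data) == (len(seq) - 1) * 13

    def test_motion_gives_positive_pdge(self, moving_square_seq):
        _, seq = moving_square_seq
        tab = spectra(seq, (0.5, 2.0))
        assert np.all(tab.data["I_alpha"] > 0)

    def test_p_le_i_everywhere(self, moving_square_seq):
        _, seq = moving_square_seq
        tab = spectra(seq, AlphaGrid.named("default13"))
        assert np.all(tab.data["P_alpha"] <= tab.data["I_alpha"] + 1e-15)

    def test_lag(self, moving_square_seq):
        spec, seq = moving_square_seq
        tab = spectra(seq, (2.0,), lag=2)
        assert len(tab.data) == len(seq) - 2
        # lag-2 pairs see a displacement twice as large -> more changed pixels
        tab1 = spectra(seq, (2.0,), lag=1)
        assert tab.data["I_alpha"].iloc[0] > tab1.data["I_alpha"].iloc[0]

    def test_lag_too_large(self, moving_square_seq):
        _, seq = moving_square_seq
        with pytest.raises(ValueError, match="too short"):
            spectra(seq, (2.0,), lag=len(seq))

    def test_changed_pixel_ground_truth(self, moving_square_seq):
        spec, seq = moving_square_seq
        pmap = pdg_map(seq[0], seq[1], 2.0)
        r0, c0 = square_position(spec, 0)
        r1, c1 = square_position(spec, 1)
        size = spec.square_size
        changed = np.zeros(spec.shape, dtype=bool)
        changed[r0 : r0 + size, c0 : c0 + size] = True
        moved = np.zeros(spec.shape, dtype=bool)
        moved[r1 : r1 + size, c1 : c1 + size] = True
        sym_diff = changed ^ moved
        assert np.array_equal(pmap.values != 0.0, sym_diff)

    def test_csv_round_trip(self, tmp_path, moving_square_seq):
        _, seq = moving_square_seq
        tab = spectra(seq, AlphaGrid.named("default13"))
        path = tmp_path / "spectra.csv"
        tab.to_csv(path)
        text = path.read_text()
        assert text.startswith("#")
        back = SpectrumTable.from_csv(path)
        assert back.alphas == tuple(sorted(tab.alphas))
        np.testing.assert_allclose(
            back.data[["I_alpha", "P_alpha"]].to_numpy(),
            tab.data[["I_alpha", "P_alpha"]].to_numpy(),
        )

    def test_basis_histogram_modes(self, tiny_pair):
        a, b = tiny_pair
        first = _basis_histogram(a, b, "first")
        pooled = _basis_histogram(a, b, "pooled")
        assert list(first.counts) == [3, 1]
        assert list(pooled.counts) == [7, 1]
        with pytest.raises(ValueError, match="basis"):
            _basis_histogram(a, b, "both")


class TestClassifySpectrum:
    def test_interior_peak(self):
        has_peak, arg = classify_spectrum([0.5, 1.0, 2.0, 4.0], [1.0, 3.0, 2.0, 0.5])
        assert has_peak and arg == 1.0

    def test_monotone(self):
        has_peak, arg = classify_spectrum([0.5, 1.0, 2.0], [3.0, 2.0, 1.0])
        assert not has_peak and arg == 0.5

    def test_rare_euclidean_object_monotone(self):
        """A translating rare object gives a monotone (unifractal) I spectrum.

        Rare-bin exchanges dominate at low alpha, so the spectrum decays from
        its left end instead of peaking inside the grid.
        """
        from pdgain import SyntheticSpec, synth_sequence

        spec = SyntheticSpec(
            kind="moving_square", frames=4, shape=(48, 48), square_size=1,
            start=(8, 8), displacement=(3, 0), seed=1,
        )
        seq = synth_sequence(spec)
        tab = spectra(seq, AlphaGrid.named("default13"))
        sub = tab.data[tab.data["pair_index"] == 1].sort_values("alpha")
        assert np.all(np.diff(sub["I_alpha"]) < 0)
        has_peak, _ = classify_spectrum(sub["alpha"], sub["I_alpha"])
        assert not has_peak

    def test_bulky_object_peaks(self, moving_square_seq):
        """A large two-level object peaks inside the grid (frequent-bin
        exchanges vanish at both alpha extremes)."""
        _, seq = moving_square_seq
        tab = spectra(seq, AlphaGrid.named("default13"))
        sub = tab.data[tab.data["pair_index"] == 1].sort_values("alpha")
        has_peak, arg = classify_spectrum(sub["alpha"], sub["I_alpha"])
        assert has_peak and 0.1 < arg < 4.0

    def test_validation(self):
        with pytest.raises(ValueError):
            classify_spectrum([1.0, 2.0], [1.0, 2.0])
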