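import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pollenvision import (
    FormatError,
    GridExample,
    GridSpec,
    HashModel,
    InputError,
    ParameterError,
    StateError,
    compute_hash,
    grid_configuration_count,
    grid_coordinates,
    hash_plane,
    load_model,
    make_grid_example,
    predict_pixel,
    predict_plane,
    quantize,
    save_model,
    train,
)


def _examples_from_levels(levels, spec):
    return [GridExample(levels=lv.reshape(spec.n_slots, 1)) for lv in levels]


class TestQuantize:
    def test_factor_one_is_identity(self):
        v = np.arange(256)
        assert np.array_equal(quantize(v, 1), v)

    def test_factor_128_leaves_two_levels(self):
        assert quantize(255, 128) == 1
        assert quantize(127, 128) == 0
        assert set(np.unique(quantize(np.arange(256), 128))) == {0, 1}

    def test_floor_division(self):
        assert quantize(127, 64) == 1

    def test_fractional_factor(self):
        # 14.24 is a legitimate (searched) operating value
        assert quantize(255, 14.24) == int(255 // 14.24)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ParameterError):
            quantize(10, 0.5)

    @given(v=st.integers(0, 255), q=st.floats(1, 128))
    @settings(deadline=None)
    def test_level_bounds(self, v, q):
        lev = quantize(v, q)
        assert 0 <= lev <= int(255 // q)


class TestGridCoordinates:
    def test_single_cell_grid_is_center(self):
        spec = GridSpec(grid_size=1, grid_spacing=13, bins=10)
        assert np.array_equal(grid_coordinates((5, 9), spec, (20, 20)), [[5, 9]])

    def test_grid8_spacing2_samples_every_other_pixel(self):
        spec = GridSpec(grid_size=8, grid_spacing=2, bins=10)
        coords = grid_coordinates((50, 50), spec, (101, 101))
        assert len(coords) == 64
        # footprint spans (g-1)*s + 1 pixels per side
        assert coords[:, 0].max() - coords[:, 0].min() == 14
        assert set(np.diff(sorted(set(coords[:, 0])))) == {2}

    def test_corner_center_is_clamped(self):
        spec = GridSpec(grid_size=4, grid_spacing=1, bins=10)
        coords = grid_coordinates((0, 0), spec, (10, 10))
        # hand enumeration: offsets -1..2 clamp to 0..2
        assert coords.min() == 0
        assert sorted(set(coords[:, 0])) == [0, 1, 2]
        assert (coords >= 0).all()

    def test_row_major_order(self):
        spec = GridSpec(grid_size=2, grid_spacing=3, bins=10)
        coords = grid_coordinates((10, 10), spec, (30, 30))
        assert coords.tolist() == [[10, 10], [10, 13], [13, 10], [13, 13]]


class TestComputeHash:
    def test_deterministic(self):
        spec = GridSpec(grid_size=3, grid_spacing=1, quantization=16, bins=1000)
        m = HashModel.empty(spec, 3)
        ex = GridExample(levels=np.arange(9).reshape(9, 1) % spec.n_levels)
        assert compute_hash(ex, m) == compute_hash(ex, m)
        m2 = HashModel.empty(spec, 3)
        assert compute_hash(ex, m) == compute_hash(ex, m2)

    def test_single_bin_maps_everything_to_zero(self):
        spec = GridSpec(grid_size=2, grid_spacing=1, quantization=64, bins=1)
        m = HashModel.empty(spec, 0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            lv = rng.integers(0, spec.n_levels, size=(4, 1))
            assert compute_hash(GridExample(levels=lv), m) == 0

    def test_bin_occupancy_uniform(self):
        # 1e5 random grid examples into 1024 bins: chi-square below the
        # 0.999 quantile of chi2(1023)
        spec = GridSpec(grid_size=3, grid_spacing=1, quantization=16, bins=1024)
        m = HashModel.empty(spec, 11)
        rng = np.random.default_rng(5)
        levels = rng.integers(0, spec.n_levels, size=(100_000, spec.n_slots))
        sums = np.zeros(len(levels), dtype=np.uint64)
        for slot in range(spec.n_slots):
            sums += m.random_table[slot, levels[:, slot]]
        bins = (sums % np.uint64(spec.bins)).astype(np.int64)
        counts = np.bincount(bins, minlength=spec.bins)
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert chi2 < stats.chi2.ppf(0.999, spec.bins - 1)

    def test_out_of_range_level_rejected(self):
        spec = GridSpec(grid_size=2, grid_spacing=1, quantization=64, bins=10)
        m = HashModel.empty(spec, 0)
        with pytest.raises(InputError):
            compute_hash(GridExample(levels=np.full((4, 1), spec.n_levels)), m)


class TestTrain:
    SPEC = GridSpec(grid_size=2, grid_spacing=1, quantization=32, bins=509)

    def _random_examples(self, n, seed):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, self.SPEC.n_levels, size=(n, self.SPEC.n_slots, 1))
        labels = rng.integers(0, 2, size=n)
        return [GridExample(levels=lv) for lv in levels], labels

    def test_single_positive_example(self):
        exs, _ = self._random_examples(1, 0)
        m = train([(exs[0], 1)], self.SPEC, 0)
        assert m.pos_counts.sum() == 1 and m.neg_counts.sum() == 0
        assert (m.pos_counts > 0).sum() == 1

    def test_duplicated_stream_doubles_counts(self):
        exs, labels = self._random_examples(50, 1)
        pairs = list(zip(exs, labels))
        m1 = train(pairs, self.SPEC, 2)
        m2 = train(pairs + pairs, self.SPEC, 2)
        assert np.array_equal(m2.pos_counts, 2 * m1.pos_counts)
        assert np.array_equal(m2.neg_counts, 2 * m1.neg_counts)

    def test_count_conservation(self):
        exs, labels = self._random_examples(500, 3)
        m = train(zip(exs, labels), self.SPEC, 0)
        assert m.pos_counts.sum() == labels.sum()
        assert m.neg_counts.sum() == (1 - labels).sum()

    def test_counts_match_explicit_histogram_oracle(self):
        exs, labels = self._random_examples(2000, 4)
        m = train(zip(exs, labels), self.SPEC, 9)
        # independent oracle: explicit (bin -> label counts) dictionary
        table: dict = {}
        for ex, lab in zip(exs, labels):
            b = compute_hash(ex, m)
            table.setdefault(b, [0, 0])[lab] += 1
        for b, (neg, pos) in table.items():
            assert m.pos_counts[b] == pos
            assert m.neg_counts[b] == neg
        assert m.pos_counts.sum() == sum(v[1] for v in table.values())

    def test_training_order_invariance(self):
        exs, labels = self._random_examples(100, 5)
        pairs = list(zip(exs, labels))
        m1 = train(pairs, self.SPEC, 1)
        m2 = train(pairs[::-1], self.SPEC, 1)
        assert np.array_equal(m1.pos_counts, m2.pos_counts)
        assert np.array_equal(m1.neg_counts, m2.neg_counts)

    def test_empty_stream_rejected(self):
        with pytest.raises(InputError):
            train([], self.SPEC, 0)


class TestPredict:
    def test_majority_rule_and_tie_break(self):
        spec = GridSpec(grid_size=1, grid_spacing=1, quantization=1, bins=4096)
        plane = np.full((3, 3, 1), 17, dtype=np.uint8)
        ex = make_grid_example(plane, (1, 1), spec)
        m = train([(ex, 1)] * 3 + [(ex, 0)], spec, 0)
        label, pos, neg = predict_pixel(m, plane, (1, 1))
        assert (label, pos, neg) == (1, 3, 1)
        # unseen pattern: 0/0 tie goes negative
        other = np.full((3, 3, 1), 200, dtype=np.uint8)
        label, pos, neg = predict_pixel(m, other, (1, 1))
        assert (label, pos, neg) == (0, 0, 0)

    def test_memorization_with_large_bin_count(self):
        # with B >> n and distinct grids, training pixels are re-predicted
        # with their own labels
        spec = GridSpec(grid_size=2, grid_spacing=1, quantization=1, bins=2**21)
        rng = np.random.default_rng(6)
        levels = rng.integers(0, 256, size=(500, 4, 1))
        labels = rng.integers(0, 2, size=500)
        exs = [GridExample(levels=lv) for lv in levels]
        m = train(zip(exs, labels), spec, 1)
        for ex, lab in zip(exs, labels):
            b = compute_hash(ex, m)
            assert (m.pos_counts[b] > m.neg_counts[b]) == bool(lab)

    def test_untrained_model_rejected(self):
        spec = GridSpec(grid_size=1, grid_spacing=1, bins=10)
        m = HashModel.empty(spec, 0)
        with pytest.raises(StateError):
            predict_pixel(m, np.zeros((3, 3, 1)), (1, 1))
        with pytest.raises(StateError):
            predict_plane(m, np.zeros((3, 3, 1)))


class TestVectorizedPlane:
    def test_hash_plane_matches_per_pixel_path(self):
        spec = GridSpec(grid_size=3, grid_spacing=2, quantization=16, bins=997)
        m = HashModel.empty(spec, 7)
        rng = np.random.default_rng(0)
        plane = rng.integers(0, 256, size=(24, 31, 1)).astype(np.uint8)
        bins = hash_plane(plane, m)
        for r in range(0, 24, 5):
            for c in range(0, 31, 7):
                ex = make_grid_example(plane, (r, c), spec)
                assert bins[r, c] == compute_hash(ex, m)


class TestModelIO:
    def _trained(self, bins=5003):
        spec = GridSpec(grid_size=2, grid_spacing=1, quantization=32, bins=bins)
        rng = np.random.default_rng(2)
        levels = rng.integers(0, spec.n_levels, size=(300, 4, 1))
        labels = rng.integers(0, 2, size=300)
        return train(zip((GridExample(levels=lv) for lv in levels), labels), spec, 8)

    def test_round_trip_preserves_predictions(self, tmp_path):
        m = self._trained()
        save_model(m, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        rng = np.random.default_rng(3)
        plane = rng.integers(0, 256, size=(10, 10, 1)).astype(np.uint8)
        for _ in range(100):
            r, c = rng.integers(10), rng.integers(10)
            assert predict_pixel(m, plane, (r, c)) == predict_pixel(back, plane, (r, c))

    def test_truncated_file_rejected(self, tmp_path):
        m = self._trained()
        save_model(m, tmp_path / "m.npz")
        data = (tmp_path / "m.npz").read_bytes()
        (tmp_path / "t.npz").write_bytes(data[: len(data) // 2])
        with pytest.raises(FormatError):
            load_model(tmp_path / "t.npz")

    def test_size_scales_with_bin_count(self, tmp_path):
        sizes = []
        for bins in (10**3, 10**4, 10**5):
            save_model(self._trained(bins), tmp_path / f"{bins}.npz")
            sizes.append((tmp_path / f"{bins}.npz").stat().st_size)
        assert sizes[0] < sizes[1] < sizes[2]
        # linear in B: 16 bytes per bin across the two count arrays
        assert sizes[2] - sizes[1] == pytest.approx(16 * (10**5 - 10**4), rel=0.01)


def test_configuration_count_exceeds_1e115():
    # 8x8 grid, 4 levels, 3 channels: (4^3)^64 distinct grid examples
    assert grid_configuration_count(8, 4, 3) == 64**64
    assert grid_configuration_count(8, 4, 3) > 10**115
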