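import numpy as np
import pytest

from vitalrep import (
    CNNSpec,
    GeneratorConfig,
    cohort_tensors,
    fuse_channels,
    grid_represent,
    predict_cnn,
    simulate_cohort,
    train_cnn,
)
from vitalrep.core_io import VitalSeries, _raw_series
from vitalrep.image import CHANNEL_ORDER


def brute_force_grid(times, values, m, n):
    """Per-point linear scan over all m*n rectangles (independent oracle)."""
    t_lo, t_hi = min(times), max(times)
    v_lo, v_hi = min(values), max(values)
    counts = np.zeros((m, n), dtype=int)
    for t, v in zip(times, values):
        placed = False
        for i in range(m):
            for j in range(n):
                r_lo = v_lo + (v_hi - v_lo) * i / m
                r_hi = v_hi if i == m - 1 else v_lo + (v_hi - v_lo) * (i + 1) / m
                c_lo = t_lo + (t_hi - t_lo) * j / n
                c_hi = t_hi if j == n - 1 else t_lo + (t_hi - t_lo) * (j + 1) / n
                in_row = (v_lo == v_hi and i == 0) or (
                    r_lo <= v < r_hi or (i == m - 1 and v == r_hi)
                )
                in_col = (t_lo == t_hi and j == 0) or (
                    c_lo <= t < c_hi or (j == n - 1 and t == c_hi)
                )
                if in_row and in_col:
                    assert not placed, "point in two rectangles"
                    counts[i, j] += 1
                    placed = True
        assert placed, "point in no rectangle"
    return counts


class TestGridRepresent:
    def test_hand_placed_two_by_two(self):
        s = _raw_series("hr", [0.0, 1.0, 2.0, 3.0], [0.0, 0.0, 1.0, 1.0])
        g = grid_represent(s, 2, 2)
        np.testing.assert_array_equal(g.counts, [[2, 0], [0, 2]])

    def test_counts_conserve_points(self, small_cohort):
        for rec in small_cohort.records[:4]:
            for ind, s in rec.series.items():
                g = grid_represent(s, 7, 5)
                assert g.counts.sum() == len(s)

    def test_constant_series_lands_in_one_row(self):
        s = _raw_series("hr", [0.0, 1.0, 2.0], [5.0, 5.0, 5.0])
        g = grid_represent(s, 3, 3)
        rows_used = np.flatnonzero(g.counts.sum(axis=1))
        assert len(rows_used) == 1 and g.counts.sum() == 3

    def test_matches_brute_force_oracle_all_small_grids(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n_pts = int(rng.integers(1, 40))
            t = np.sort(rng.choice(np.arange(1000.0), size=n_pts, replace=False))
            v = rng.normal(size=n_pts)
            s = _raw_series("hr", t, v)
            for m in range(1, 9):
                for n in range(1, 9):
                    got = grid_represent(s, m, n).counts
                    want = brute_force_grid(t, v, m, n)
                    np.testing.assert_array_equal(got, want)

    def test_coarsening_refined_grid_by_block_sums(self):
        rng = np.random.default_rng(3)
        t = np.arange(100.0)
        v = rng.normal(size=100)
        s = _raw_series("hr", t, v)
        fine = grid_represent(s, 8, 8).counts
        coarse = grid_represent(s, 4, 4).counts
        folded = fine.reshape(4, 2, 4, 2).sum(axis=(1, 3))
        np.testing.assert_array_equal(folded, coarse)

    def test_empty_series_is_error(self):
        with pytest.raises(ValueError):
            grid_represent(VitalSeries("hr", [0.0], [70.0]), 0, 2)


class TestFuseChannels:
    def test_shape_contract(self, complete_record):
        t = fuse_channels(complete_record, 16, 16)
        assert t.shape == (5, 16, 16)

    def test_channel_order_is_canonical(self, complete_record):
        t1 = fuse_channels(complete_record, 8, 8, normalize=False)
        reordered = complete_record
        reordered.series = dict(reversed(list(complete_record.series.items())))
        t2 = fuse_channels(reordered, 8, 8, normalize=False)
        np.testing.assert_array_equal(t1.data, t2.data)
        assert CHANNEL_ORDER == ("hr", "nisysbp", "nidiasbp", "spo2", "pp")

    def test_unnormalized_channels_sum_to_series_length(self, complete_record):
        t = fuse_channels(complete_record, 8, 8, normalize=False)
        for c, ind in enumerate(CHANNEL_ORDER):
            assert t.data[c].sum() == len(complete_record.series[ind])

    def test_normalized_channels_in_unit_range(self, complete_record):
        t = fuse_channels(complete_record, 8, 8, normalize=True)
        assert t.data.max() == 1.0 and t.data.min() >= 0.0

    def test_missing_channel_is_error(self, complete_record):
        del complete_record.series["pp"]
        with pytest.raises(ValueError, match="pp"):
            fuse_channels(complete_record)


class TestCNN:
    def test_probabilities_sum_to_one(self, small_cohort):
        X, y, _ = cohort_tensors(small_cohort, 8, 8)
        model = train_cnn(X, y, CNNSpec(epochs=2, seed=0))
        p = model.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        single = predict_cnn(model, X[0])
        assert 0.0 <= single <= 1.0

    def test_single_class_training_is_error(self, small_cohort):
        X, y, _ = cohort_tensors(small_cohort, 8, 8)
        with pytest.raises(ValueError, match="both classes"):
            train_cnn(X, np.zeros_like(y), CNNSpec(epochs=1))

    def test_reproducible_given_seed(self, small_cohort):
        X, y, _ = cohort_tensors(small_cohort, 8, 8)
        a = train_cnn(X, y, CNNSpec(epochs=3, seed=4))
        b = train_cnn(X, y, CNNSpec(epochs=3, seed=4))
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))

    def test_learns_strongly_separated_grids(self):
        cohort = simulate_cohort(GeneratorConfig(n_pos=30, n_neg=30, effect=2.0, seed=2))
        X, y, _ = cohort_tensors(cohort)
        model = train_cnn(X, y, CNNSpec(epochs=50, seed=0))
        acc = float(np.mean(model.predict_proba(X).argmax(axis=1) == y))
        assert acc >= 0.9
        assert len(model.history.train_loss) <= 50

    def test_history_records_validation_curve(self, small_cohort):
        X, y, _ = cohort_tensors(small_cohort, 8, 8)
        model = train_cnn(X, y, CNNSpec(epochs=3, seed=0), X, y)
        assert len(model.history.val_loss) == len(model.history.train_loss)
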