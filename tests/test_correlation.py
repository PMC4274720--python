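"""Autoscaling, peak correlation, cutoffs and plot merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsqcstocsy import correlation
from hsqcstocsy.correlation import (
    PeakSelection,
    apply_cutoff,
    autoscale,
    correlate_peak,
    full_correlation_matrix,
    merge_plots,
    singleton_plot,
)
from hsqcstocsy.dataset import apply_noise_exclusion
from hsqcstocsy.errors import GridMismatchError, HsqcStocsyError, ZeroVarianceError

from conftest import matrix_from_values, small_grid


def selection_for(matrix, column):
    cm = matrix.coordinate_map
    return PeakSelection(
        requested_ppm=(float(cm["ppm_f2"].iloc[column]), float(cm["ppm_f1"].iloc[column])),
        resolved_column=column,
        resolved_ppm=(float(cm["ppm_f2"].iloc[column]), float(cm["ppm_f1"].iloc[column])),
    )


def textbook_pearson(x, y):
    """Straight from the definition: covariance over product of deviations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


class TestAutoscale:
    def test_three_point_column(self):
        m = matrix_from_values(np.column_stack([[1, 2, 3]] * 12))
        s = autoscale(m)
        assert np.allclose(s.values[:, 0], [-1, 0, 1])  # n-1 denominator

    def test_constant_column_flagged(self):
        v = np.ones((3, 12))
        v[:, 0] = [7, 7, 7]
        v[:, 1] = [1, 2, 3]
        s = autoscale(matrix_from_values(v))
        assert s.zero_variance[0]
        assert np.all(s.values[:, 0] == 0)
        assert not s.zero_variance[1]

    def test_random_matrix_is_standardized(self):
        rng = np.random.default_rng(0)
        s = autoscale(matrix_from_values(rng.standard_normal((5, 20))))
        assert np.abs(s.values.mean(axis=0)).max() < 1e-12
        assert np.abs(s.values.std(axis=0, ddof=1) - 1).max() < 1e-12


class TestCorrelatePeak:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        m = matrix_from_values(rng.standard_normal((6, 12)))
        plot = correlate_peak(autoscale(m), selection_for(m, 4))
        cm = m.coordinate_map
        i1, i2 = int(cm["f1_index"].iloc[4]), int(cm["f2_index"].iloc[4])
        assert plot.coefficients[i1, i2] == pytest.approx(1.0, abs=1e-9)

    def test_exact_multiples_and_negatives(self):
        base = np.array([1.0, 2.0, 4.0])
        v = np.ones((3, 12))
        v[:, 0], v[:, 1], v[:, 2] = base, 3 * base, -2 * base
        v[:, 3] = [5, 1, 2]
        m = matrix_from_values(v)
        plot = correlate_peak(autoscale(m), selection_for(m, 0))
        flat = plot.coefficients.ravel()
        assert flat[1] == pytest.approx(1.0, abs=1e-12)
        assert flat[2] == pytest.approx(-1.0, abs=1e-12)

    def test_three_sample_toy_matches_textbook_pearson(self):
        v = np.ones((3, 12))
        v[:, 0] = [1, 2, 4]
        v[:, 1] = [1, 3, 3]
        m = matrix_from_values(v)
        plot = correlate_peak(autoscale(m), selection_for(m, 0))
        assert plot.coefficients.ravel()[1] == pytest.approx(
            textbook_pearson([1, 2, 4], [1, 3, 3]), abs=1e-12
        )

    def test_zero_variance_selection_rejected(self):
        v = np.ones((3, 12))
        v[:, 1] = [1, 2, 3]
        m = matrix_from_values(v)
        with pytest.raises(ZeroVarianceError):
            correlate_peak(autoscale(m), selection_for(m, 0))

    def test_excluded_columns_reconstructed_as_zero(self):
        rng = np.random.default_rng(2)
        m = apply_noise_exclusion(
            matrix_from_values(rng.uniform(-2, 2, (4, 12))), 1.0
        )
        plot = correlate_peak(autoscale(m), selection_for(m, 0))
        flat_support = plot.support.ravel()
        assert np.array_equal(flat_support, m.kept_mask)
        assert np.all(plot.coefficients.ravel()[~m.kept_mask] == 0)

    def test_out_of_range_coefficients_raise_not_clip(self):
        rng = np.random.default_rng(3)
        m = matrix_from_values(rng.standard_normal((4, 12)))
        s = autoscale(m)
        s.values *= 1.5  # corrupt the scaling
        with pytest.raises(HsqcStocsyError, match="scaling bug"):
            correlate_peak(s, selection_for(m, 0))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_coefficient_equals_pearson_of_raw_columns(self, seed):
        rng = np.random.default_rng(seed)
        m = matrix_from_values(rng.uniform(-3, 3, (5, 12)))
        plot = correlate_peak(autoscale(m), selection_for(m, 3))
        flat = plot.coefficients.ravel()
        for j in range(12):
            assert flat[j] == pytest.approx(
                textbook_pearson(m.values[:, 3], m.values[:, j]), abs=1e-10
            )

    def test_affine_invariance_of_raw_intensities(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(0, 3, (5, 12))
        m1 = matrix_from_values(v)
        v2 = v.copy()
        v2[:, 2] = 7.3 * v2[:, 2] + 11.0  # positive scale + offset on one column
        v2[:, 5] = 0.2 * v2[:, 5] - 4.0
        m2 = matrix_from_values(v2)
        p1 = correlate_peak(autoscale(m1), selection_for(m1, 2))
        p2 = correlate_peak(autoscale(m2), selection_for(m2, 2))
        assert np.allclose(p1.coefficients, p2.coefficients, atol=1e-12)


class TestFullMatrix:
    def test_rows_match_single_peak_route(self):
        rng = np.random.default_rng(5)
        m = matrix_from_values(rng.standard_normal((4, 30)), grid=small_grid(6, 5))
        s = autoscale(m)
        c = full_correlation_matrix(s)
        assert np.allclose(c, c.T, atol=1e-12)
        assert np.allclose(np.diag(c), 1.0, atol=1e-12)
        for j in range(30):
            row = correlate_peak(s, selection_for(m, j)).coefficients.ravel()
            assert np.allclose(row, c[j], atol=1e-12)

    def test_size_guard(self):
        rng = np.random.default_rng(6)
        m = matrix_from_values(rng.standard_normal((3, 12)))
        with pytest.raises(HsqcStocsyError, match="correlate_peak"):
            full_correlation_matrix(autoscale(m), k_limit=10)


class TestCutoff:
    def make_plot(self):
        v = np.ones((4, 12))
        rng = np.random.default_rng(7)
        v += rng.uniform(0, 1, (4, 12)) * np.arange(12)
        m = matrix_from_values(v)
        return correlate_peak(autoscale(m), selection_for(m, 11))

    def test_minus_one_only_records(self):
        plot = self.make_plot()
        out = apply_cutoff(plot, -1.0)
        assert out.cutoff == -1.0
        assert np.array_equal(out.coefficients, np.where(plot.support, plot.coefficients, 0))

    def test_strict_inequality(self):
        plot = self.make_plot()
        plot.coefficients = np.zeros((2, 6))
        plot.support = np.zeros((2, 6), dtype=bool)
        plot.coefficients[0, :3] = [1.0, 0.95, 0.85]
        plot.support[0, :3] = True
        out = apply_cutoff(plot, 0.9)
        assert set(np.round(out.coefficients[out.support], 2)) == {1.0, 0.95}

    def test_idempotent_and_composes_to_max(self):
        plot = self.make_plot()
        once = apply_cutoff(plot, 0.6)
        assert np.array_equal(apply_cutoff(once, 0.6).coefficients, once.coefficients)
        a = apply_cutoff(apply_cutoff(plot, 0.3), 0.6)
        assert np.array_equal(a.coefficients, once.coefficients)
        assert a.cutoff == 0.6
        b = apply_cutoff(apply_cutoff(plot, 0.6), 0.3)
        assert np.array_equal(b.coefficients, once.coefficients)
        assert b.cutoff == 0.6

    def test_cutoff_out_of_range(self):
        with pytest.raises(HsqcStocsyError):
            apply_cutoff(self.make_plot(), 1.01)


class TestMerge:
    def plot_at(self, grid, points, label):
        coeffs = np.zeros((grid.n_f1, grid.n_f2))
        for (i1, i2), value in points.items():
            coeffs[i1, i2] = value
        support = coeffs != 0
        return correlation.CorrelationPlot(
            coefficients=coeffs, support=support,
            source=PeakSelection((0.0, 0.0), 0, (0.0, 0.0)),
            grid=grid, cutoff=0.5, label=label,
        )

    def test_single_plot_identity(self):
        g = small_grid()
        p = self.plot_at(g, {(1, 2): 0.9}, "a")
        merged = merge_plots([p])
        assert np.array_equal(merged.spectrum.intensities, p.coefficients)

    def test_disjoint_union_and_overlap_max_with_provenance(self):
        g = small_grid()
        a = self.plot_at(g, {(1, 2): 0.92, (3, 4): 0.7}, "a")
        b = self.plot_at(g, {(1, 2): 0.95, (5, 6): 0.8}, "b")
        merged = merge_plots([a, b])
        assert merged.spectrum.intensities[1, 2] == 0.95
        assert merged.spectrum.intensities[3, 4] == 0.7
        assert merged.spectrum.intensities[5, 6] == 0.8
        at_overlap = merged.provenance.query("f1_index == 1 and f2_index == 2")
        assert sorted(at_overlap["label"]) == ["a", "b"]

    def test_singleton_injection(self):
        g = small_grid()
        a = self.plot_at(g, {(1, 2): 0.92}, "a")
        s = singleton_plot(g, "methanol-like", g.ppm_f2[5], g.ppm_f1[3])
        merged = merge_plots([a, s])
        assert merged.spectrum.intensities[3, 5] == 1.0

    def test_errors(self):
        g = small_grid()
        with pytest.raises(HsqcStocsyError):
            merge_plots([])
        a = self.plot_at(g, {(1, 2): 0.9}, "a")
        b = self.plot_at(small_grid(10, 8), {(1, 2): 0.9}, "b")
        with pytest.raises(GridMismatchError):
            merge_plots([a, b])
        c = self.plot_at(g, {(1, 2): 0.9}, "c")
        c.cutoff = None
        with pytest.raises(HsqcStocsyError, match="cutoff"):
            merge_plots([a, c])


def test_plot_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    m = matrix_from_values(rng.uniform(-2, 2, (4, 12)))
    plot = apply_cutoff(correlate_peak(autoscale(m), selection_for(m, 0)), 0.3)
    plot.label = "roundtrip"
    correlation.save_plot(plot, tmp_path / "p.h5")
    back = correlation.load_plot(tmp_path / "p.h5")
    assert np.array_equal(back.coefficients, plot.coefficients)
    assert np.array_equal(back.support, plot.support)
    assert back.cutoff == plot.cutoff
    assert back.label == plot.label
    assert back.source == plot.source
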