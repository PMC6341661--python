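"""Statistical primitives against hand computations and brute-force oracles."""

import math

import numpy as np
import pytest

from pubfig.stats import (
    box_statistics,
    density_estimate,
    format_scientific,
    hex_lattice,
    hexbin,
    manhattan_coords,
    qq_comparison_points,
    qq_fit_points,
    silverman_bandwidth,
)


class TestBoxStatistics:
    def test_one_to_seven_summary(self):
        s = box_statistics(range(1, 8))
        assert (s.median, s.lower_hinge, s.upper_hinge) == (4, 2, 6)
        assert (s.whisker_lo, s.whisker_hi) == (1, 7)
        assert s.outliers == ()

    def test_constant_values_degenerate(self):
        s = box_statistics([5, 5, 5])
        assert (
            s.median, s.lower_hinge, s.upper_hinge, s.whisker_lo, s.whisker_hi
        ) == (5, 5, 5, 5, 5)
        assert s.outliers == ()

    def test_extreme_point_is_outlier(self):
        s = box_statistics(list(range(1, 9)) + [100])
        # hinges 2.5 / 7.5 -> upper fence 7.5 + 1.5*5 = 15 < 100
        assert 100 in s.outliers
        assert s.whisker_hi <= 15

    def test_matches_direct_quantile_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(2, 60)))
            s = box_statistics(x, method="linear")
            q1, q3 = np.quantile(x, [0.25, 0.75])
            assert s.lower_hinge == pytest.approx(q1)
            assert s.upper_hinge == pytest.approx(q3)
            iqr = q3 - q1
            inside = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
            assert s.whisker_lo == pytest.approx(inside.min())
            assert s.whisker_hi == pytest.approx(inside.max())
            assert sorted(s.outliers) == sorted(x[(x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            box_statistics([])


class TestDensity:
    def test_integrates_to_one(self):
        rng = np.random.default_rng(0)
        for data in (rng.normal(size=50), rng.exponential(size=120)):
            grid, dens = density_estimate(data)
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_input_gives_symmetric_density(self):
        grid, dens = density_estimate([-1.0, 1.0], bandwidth=0.5)
        assert np.allclose(dens, dens[::-1], atol=1e-12)
        assert grid[0] == pytest.approx(-grid[-1])

    def test_matches_double_loop_kernel_sum(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=50)
        bw = silverman_bandwidth(x)
        grid, dens = density_estimate(x, gridsize=64)
        # independent oracle: explicit double loop
        expected = np.zeros_like(grid)
        for gi, g in enumerate(grid):
            total = 0.0
            for xi in x:
                total += math.exp(-0.5 * ((g - xi) / bw) ** 2)
            expected[gi] = total / (len(x) * bw * math.sqrt(2 * math.pi))
        assert np.allclose(dens, expected, rtol=1e-12, atol=1e-15)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            density_estimate([1.0])


class TestHexbin:
    def test_coincident_points_one_hexagon(self):
        cells = hexbin([(2.0, 3.0)] * 5, nbins=4)
        assert len(cells) == 1 and cells[0][1] == 5

    def test_counts_conserve_n(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(size=(137, 2))
        cells = hexbin(pts, nbins=6)
        assert sum(c for _, c in cells) == 137

    def test_matches_exhaustive_nearest_centre_oracle(self):
        rng = np.random.default_rng(19)
        pts = rng.uniform(-1, 1, size=(200, 2))
        extent = (-1.0, 1.0, -1.0, 1.0)
        nbins = 8
        cells = hexbin(pts, nbins, extent)
        centres, dx, dy = hex_lattice(extent, nbins)
        counts = {}
        for x, y in pts:  # brute force over every lattice centre
            d2 = (centres[:, 0] - x) ** 2 + (centres[:, 1] - y) ** 2
            idx = int(np.argmin(d2))  # argmin takes the lowest index on ties
            counts[idx] = counts.get(idx, 0) + 1
        expected = [
            ((float(centres[i, 0]), float(centres[i, 1])), counts[i])
            for i in sorted(counts)
        ]
        assert cells == expected

    def test_degenerate_explicit_extent_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hexbin([(0, 0), (1, 1)], nbins=3, extent=(0, 0, 0, 1))


class TestQQ:
    def test_self_comparison_on_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        qa, qb = qq_comparison_points(x, x)
        assert np.allclose(qa, qb)

    def test_constructed_normal_quantiles_on_identity(self):
        import scipy.stats

        n = 25
        sample = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        theo, obs = qq_fit_points(sample, "norm")
        assert np.allclose(theo, obs, atol=1e-12)

    def test_unequal_lengths_interpolate_longer_sample(self):
        rng = np.random.default_rng(8)
        a = np.sort(rng.normal(size=30))
        b = np.sort(rng.normal(size=12))
        qa, qb = qq_comparison_points(a, b)
        assert qa.size == qb.size == 12
        # oracle: explicit linear interpolation of the longer order statistics
        expected = np.interp(
            np.linspace(0, 1, 12), np.linspace(0, 1, 30), a
        )
        assert np.allclose(qa, expected)
        assert np.allclose(qb, b)


class TestManhattan:
    def test_neg_log10(self):
        _, y, _ = manhattan_coords(["1"], [5], [0.01], ["1"])
        assert y[0] == pytest.approx(2.0)

    def test_single_chromosome_preserves_spacing(self):
        x, _, _ = manhattan_coords(["1", "1"], [10, 20], [0.5, 0.5], ["1"])
        assert x[1] - x[0] == pytest.approx(10.0)

    def test_cumulative_offsets_zero_gap(self):
        # chr1 max position 100 -> chr2 position 1 maps to 101
        x, _, _ = manhattan_coords(
            ["1", "2"], [100, 1], [0.5, 0.5], ["1", "2"]
        )
        assert x.tolist() == [100.0, 101.0]

    def test_rejections(self):
        with pytest.raises(ValueError, match=r"p-values"):
            manhattan_coords(["1"], [1], [0.0], ["1"])
        with pytest.raises(ValueError, match="absent from chrom_order"):
            manhattan_coords(["7"], [1], [0.5], ["1"])


class TestFormatScientific:
    @pytest.mark.parametrize(
        "x, text, mantissa, exponent",
        [
            (0.000032, "3.2 x 10^-5", 3.2, -5),
            (0.0001, "1 x 10^-4", 1.0, -4),
            (0.00999, "1 x 10^-2", 1.0, -2),  # mantissa rounds up and carries
        ],
    )
    def test_scientific_decomposition(self, x, text, mantissa, exponent):
        f = format_scientific(x)
        assert f.is_scientific
        assert (f.mantissa, f.exponent) == (mantissa, exponent)
        assert f.text == text

    @pytest.mark.parametrize("x, text", [(1, "1"), (0.05, "0.05"), (12.5, "12.5")])
    def test_plain_above_threshold(self, x, text):
        f = format_scientific(x)
        assert not f.is_scientific and f.text == text

    def test_nonpositive_rejected(self):
        for bad in (0, -1e-5):
            with pytest.raises(ValueError, match="> 0"):
                format_scientific(bad)
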