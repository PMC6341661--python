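"""Composition: shared-axis resolution, harmonization, pixel alignment."""

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import pytest

from pubfig.charts import ChartSpec, create_chart
from pubfig.fixtures import cohort_figure
from pubfig.multiplot import (
    MultiplotLayout,
    compose,
    harmonize,
    resolve_shared_limits,
    single_panel_figure,
)
from pubfig.render import realize
from pubfig.theme import default_theme


def _scatter_panel(xlo, xhi, n=20, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {"x": np.linspace(xlo, xhi, n), "y": rng.normal(size=n)}
    )
    spec = ChartSpec("scatterplot", data_binding={"x": "x", "y": "y"})
    return create_chart(spec, df)


class TestResolveSharedLimits:
    def test_union_of_ranges(self):
        panels = [_scatter_panel(0, 10), _scatter_panel(2, 8)]
        kind, lo, hi = resolve_shared_limits(panels, "x", padding=0.0)
        assert (kind, lo, hi) == ("numeric", 0.0, 10.0)

    def test_single_panel_identity(self):
        (p,) = [_scatter_panel(3, 7)]
        kind, lo, hi = resolve_shared_limits([p], "x", padding=0.0)
        assert (lo, hi) == (3.0, 7.0)

    def test_disjoint_ranges_with_four_percent_padding(self):
        panels = [_scatter_panel(0, 1), _scatter_panel(5, 6)]
        kind, lo, hi = resolve_shared_limits(panels, "x", padding=0.04)
        # union span 6, padded by 0.24 on each side
        assert lo == pytest.approx(-0.24)
        assert hi == pytest.approx(6.24)

    def test_mixed_domains_rejected(self):
        bar = create_chart(
            ChartSpec("barplot", data_binding={"category": "c", "value": "v"}),
            pd.DataFrame({"c": ["a"], "v": [1.0]}),
        )
        with pytest.raises(ValueError, match="mixed domains"):
            resolve_shared_limits([bar, _scatter_panel(0, 1)], "x")

    def test_mismatched_category_order_rejected(self):
        mk = lambda cats: create_chart(
            ChartSpec("barplot", data_binding={"category": "c", "value": "v"}),
            pd.DataFrame({"c": cats, "v": [1.0] * len(cats)}),
        )
        with pytest.raises(ValueError, match="identical category order"):
            resolve_shared_limits([mk(["a", "b"]), mk(["b", "a"])], "x")


class TestHarmonize:
    def test_defaults_replaced_overrides_survive(self):
        theme = default_theme()
        plain = ChartSpec("scatterplot")
        custom = ChartSpec("scatterplot", theme_overrides={"title_size": 14.0})
        out = harmonize([plain, custom], theme)
        assert out[0].theme_overrides["tick_label_size"] == theme.font_sizes["tick_label"]
        assert out[1].theme_overrides["title_size"] == 14.0
        assert out[0].theme_overrides["tick_label_size"] == out[1].theme_overrides["tick_label_size"]

    def test_idempotent(self):
        theme = default_theme()
        specs = [ChartSpec("scatterplot", theme_overrides={"line_width": 2.0})]
        once = harmonize(specs, theme)
        twice = harmonize(once, theme)
        assert once == twice

    def test_empty_list_identity(self):
        assert harmonize([], default_theme()) == []


class TestLayoutValidation:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            MultiplotLayout.make(2, 2, [(0, 0, 0, 2, 1), (1, 1, 0)])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            MultiplotLayout.make(1, 1, [(0, 0, 1)])

    def test_panel_in_two_shared_groups_rejected(self):
        with pytest.raises(ValueError, match="more than one shared group"):
            MultiplotLayout.make(
                1, 3, [(0, 0, 0), (1, 0, 1), (2, 0, 2)],
                shared_x_groups=[(0, 1), (1, 2)],
            )

    def test_nonpositive_proportions_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MultiplotLayout.make(1, 1, [(0, 0, 0)], row_heights=[0.0])


class TestComposeGeometry:
    def _stacked(self, theme):
        p1 = _scatter_panel(0, 10, seed=1)
        p2 = _scatter_panel(2, 8, seed=2)
        layout = MultiplotLayout.make(
            2, 1, [(0, 0, 0), (1, 1, 0)], shared_x_groups=[(0, 1)]
        )
        return compose([p1, p2], layout, theme=theme)

    def test_shared_x_identical_pixel_mapping(self, small_theme):
        fig = self._stacked(small_theme)
        m = realize(fig)
        ax0, ax1 = m.axes
        assert ax0.get_xlim() == ax1.get_xlim()
        rng = np.random.default_rng(0)
        for v in rng.uniform(0, 10, size=10):
            px0 = ax0.transData.transform((v, 0))[0]
            px1 = ax1.transData.transform((v, 0))[0]
            assert px0 == pytest.approx(px1, abs=1e-9)
        plt.close(m)

    def test_row_height_proportions_within_one_pixel(self, small_theme):
        p1 = _scatter_panel(0, 1, seed=1)
        p2 = _scatter_panel(0, 1, seed=2)
        layout = MultiplotLayout.make(
            2, 1, [(0, 0, 0), (1, 1, 0)], row_heights=(1.0, 2.0), spacing=0.01
        )
        fig = compose([p1, p2], layout, theme=small_theme)
        m = realize(fig, dpi=100)
        h0 = m.axes[0].get_window_extent().height
        h1 = m.axes[1].get_window_extent().height
        assert h1 == pytest.approx(2 * h0, abs=1.0)
        plt.close(m)

    def test_single_panel_compose_matches_standalone(self, small_theme):
        panel = _scatter_panel(0, 10, seed=3)
        via_compose = compose(
            [panel], MultiplotLayout.make(1, 1, [(0, 0, 0)]), theme=small_theme
        )
        standalone = single_panel_figure(panel, theme=small_theme)
        ma, mb = realize(via_compose), realize(standalone)
        assert ma.axes[0].get_position().bounds == mb.axes[0].get_position().bounds
        assert ma.axes[0].get_xlim() == mb.axes[0].get_xlim()
        assert ma.axes[0].get_ylim() == mb.axes[0].get_ylim()
        plt.close(ma)
        plt.close(mb)

    def test_incompatible_shared_domains_rejected(self, small_theme):
        bar = create_chart(
            ChartSpec("barplot", data_binding={"category": "c", "value": "v"}),
            pd.DataFrame({"c": ["a"], "v": [1.0]}),
        )
        layout = MultiplotLayout.make(
            2, 1, [(0, 0, 0), (1, 1, 0)], shared_x_groups=[(0, 1)]
        )
        with pytest.raises(ValueError, match="mixed domains"):
            compose([bar, _scatter_panel(0, 1)], layout, theme=small_theme)

    def test_edge_policy_suppresses_interior_tick_labels(self, small_theme):
        fig = self._stacked(small_theme)
        m = realize(fig)
        # top panel of the shared-x pair draws no x tick labels
        top_labels = [t for t in m.axes[0].get_xticklabels() if t.get_visible()]
        assert not any(t.get_text() for t in top_labels) or not m.axes[
            0
        ].xaxis.get_ticklabels()[0].get_visible()
        plt.close(m)


class TestCohortFigure:
    def test_six_panel_figure_composes_and_aligns(self):
        fig = cohort_figure()
        assert len(fig.panels) == 6
        m = realize(fig)
        axs = m.axes
        # panels sharing the patient axis: counts bar (0), base-change bar (1),
        # dotmap (3), clinical heatmap (5)
        n_patients = len(fig.panels[3].x_domain[1])
        for col in range(n_patients):
            xs = [axs[i].transData.transform((col, 0))[0] for i in (0, 1, 3, 5)]
            assert np.allclose(xs, xs[0], atol=1e-9), f"column {col} misaligned"
        # gene axis shared between dotmap (3) and percentage barplot (4)
        n_genes = len(fig.panels[3].y_domain[1])
        for row in range(n_genes):
            ys = [axs[i].transData.transform((0, row))[1] for i in (3, 4)]
            assert np.allclose(ys, ys[0], atol=1e-9), f"row {row} misaligned"
        plt.close(m)
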