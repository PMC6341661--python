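"""Chart builders: data contracts, computed artifacts and the full gallery."""

import numpy as np
import pandas as pd
import pytest

from pubfig.charts import (
    CHART_TYPES,
    AxisSpec,
    ChartSpec,
    ContractError,
    CovariateBar,
    DotmapData,
    LegendSpec,
    create_chart,
    create_covariate_bar,
    create_dotmap,
    create_legend,
    create_manhattan,
    create_qq,
)
from pubfig.fixtures import fig1_gallery
from pubfig.multiplot import single_panel_figure
from pubfig.render import realize


def _render_artist_count(panel, theme):
    import matplotlib.pyplot as plt

    fig = realize(single_panel_figure(panel, theme=theme))
    n = sum(len(ax.get_children()) for ax in fig.axes)
    plt.close(fig)
    return n


def test_gallery_all_fifteen_chart_types_render(small_theme):
    gallery = fig1_gallery(seed=42)
    assert set(gallery) == set(CHART_TYPES)
    for name, (spec, data) in gallery.items():
        panel = create_chart(spec, data)
        assert _render_artist_count(panel, small_theme) > 0, name


def test_barplot_heights_proportional_to_values():
    df = pd.DataFrame({"category": ["A", "B"], "value": [3, 5]})
    spec = ChartSpec("barplot", data_binding={"category": "category", "value": "value"})
    panel = create_chart(spec, df)
    h = panel.artifacts["heights"]
    assert h == {"A": 3.0, "B": 5.0}
    assert h["B"] / h["A"] == pytest.approx(5 / 3)


def test_stacked_barplot_segments_sum_to_group_totals():
    df = pd.DataFrame(
        {
            "category": ["A", "A", "B", "B"],
            "group": ["u", "v", "u", "v"],
            "value": [1.0, 2.0, 3.0, 4.0],
        }
    )
    spec = ChartSpec(
        "barplot",
        data_binding={"category": "category", "value": "value", "group": "group"},
    )
    panel = create_chart(spec, df)
    for cat, segs in panel.artifacts["stacks"].items():
        assert sum(segs.values()) == pytest.approx(panel.artifacts["heights"][cat])


def test_histogram_counts_sum_to_n():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"value": rng.normal(size=100)})
    for bins in (5, 10, 23):
        spec = ChartSpec("histogram", data_binding={"value": "value"},
                         aesthetics={"bins": bins})
        panel = create_chart(spec, df)
        assert panel.artifacts["bin_counts"].sum() == 100


def test_boxplot_median_of_one_to_seven():
    df = pd.DataFrame({"value": list(range(1, 8))})
    panel = create_chart(
        ChartSpec("boxplot", data_binding={"value": "value"}), df
    )
    assert panel.artifacts["stats"][""].median == 4


def test_qq_self_comparison_points_on_identity_line():
    rng = np.random.default_rng(2)
    x = rng.normal(size=30)
    panel = create_qq(x, x, mode="comparison")
    assert np.allclose(panel.artifacts["qx"], panel.artifacts["qy"])
    assert panel.artifacts["slope"] == 1.0 and panel.artifacts["intercept"] == 0.0


def test_qq_unequal_lengths_plot_shorter_count():
    rng = np.random.default_rng(3)
    panel = create_qq(rng.normal(size=50), rng.normal(size=20), mode="comparison")
    assert panel.artifacts["qx"].size == 20


def test_manhattan_panel_coordinates():
    points = [("1", 10, 0.01), ("1", 20, 0.5), ("2", 1, 1e-3)]
    panel = create_manhattan(points, chrom_order=["1", "2"])
    y = panel.artifacts["y"]
    assert y[0] == pytest.approx(2.0) and y[2] == pytest.approx(3.0)
    x = panel.artifacts["x"]
    assert x[2] == pytest.approx(21.0)  # chr1 max 20, zero gap
    assert np.all(np.diff(x[:2]) > 0)


def test_manhattan_rejects_bad_p_and_unknown_chromosome():
    with pytest.raises(ValueError, match="p-values"):
        create_manhattan([("1", 5, 0.0)], chrom_order=["1"])
    with pytest.raises(ValueError, match="absent"):
        create_manhattan([("9", 5, 0.5)], chrom_order=["1"])


class TestDotmap:
    cmap = {"snv": "#2166AC"}
    dmap = {"cna": "#B2182B"}

    def test_cell_with_background_and_dot(self, small_theme):
        cell = [["snv", None], [None, "snv"]]
        dot = [["cna", None], [None, None]]
        d = DotmapData.make(cell, dot, self.cmap, self.dmap)
        panel = create_dotmap(d)
        assert panel.artifacts["shape"] == (2, 2)
        assert panel.artifacts["n_marked_cells"] == 2
        assert _render_artist_count(panel, small_theme) > 0

    def test_all_null_matrices_render_empty_grid(self, small_theme):
        d = DotmapData.make(
            [[None, None]], [[None, None]], self.cmap, self.dmap,
            row_labels=["g"], col_labels=["p1", "p2"],
        )
        panel = create_dotmap(d)
        assert panel.artifacts["n_marked_cells"] == 0
        assert _render_artist_count(panel, small_theme) > 0  # grid + labels

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share one shape"):
            DotmapData.make([["snv"]], [["cna", None]], self.cmap, self.dmap)

    def test_missing_colour_code_rejected(self):
        with pytest.raises(ValueError, match="no colour-map entry"):
            DotmapData.make([["other"]], [[None]], self.cmap, self.dmap)


def test_segplot_requires_ordered_triples():
    df = pd.DataFrame({"category": ["a"], "centre": [1.0], "lo": [2.0], "hi": [3.0]})
    spec = ChartSpec(
        "segplot",
        data_binding={"category": "category", "centre": "centre", "lo": "lo", "hi": "hi"},
    )
    with pytest.raises(ContractError, match="lo <= centre <= hi"):
        create_chart(spec, df)


def test_contract_violation_names_role():
    df = pd.DataFrame({"x": [1.0, 2.0]})
    spec = ChartSpec("scatterplot", data_binding={"x": "x"})
    with pytest.raises(ContractError, match="'y'"):
        create_chart(spec, df)
    spec2 = ChartSpec("scatterplot", data_binding={"x": "x", "y": "nope"})
    with pytest.raises(ContractError, match="absent column 'nope'"):
        create_chart(spec2, df)


def test_empty_data_rejected():
    spec = ChartSpec("scatterplot", data_binding={"x": "x", "y": "y"})
    with pytest.raises(ContractError, match="empty"):
        create_chart(spec, pd.DataFrame({"x": [], "y": []}))


def test_legend_rows_and_rejections(small_theme):
    legend = LegendSpec.make(
        [("missense", "#2166AC", "box"), ("gain", "#B2182B", "dot"),
         ("trend", "#000000", "line")]
    )
    panel = create_legend(legend)
    assert [e.label for e in panel.artifacts["entries"]] == [
        "missense", "gain", "trend"
    ]
    assert _render_artist_count(panel, small_theme) > 0
    with pytest.raises(ValueError, match="duplicate"):
        LegendSpec.make([("a", "#000000", "box"), ("a", "#FFFFFF", "box")])
    with pytest.raises(ValueError, match="at least one"):
        create_legend(LegendSpec(entries=()))


def test_covariate_bar_segments_and_rejection(small_theme):
    bar = CovariateBar.make("sex", ["M", "F", "M"], {"M": "#0000FF", "F": "#FF0000"})
    panel = create_covariate_bar(bar)
    assert panel.artifacts["values"] == ("M", "F", "M")
    assert panel.x_domain[0] == "categorical" and len(panel.x_domain[1]) == 3
    assert _render_artist_count(panel, small_theme) > 0
    with pytest.raises(ValueError, match="no\\s+colour-map entry"):
        CovariateBar.make("sex", ["M", "X"], {"M": "#0000FF"})


def test_panel_determinism_same_spec_same_data():
    gallery = fig1_gallery(seed=7)
    spec, data = gallery["stripplot"]
    p1 = create_chart(spec, data)
    p2 = create_chart(spec, data)
    for g in p1.artifacts["jitter"]:
        assert np.array_equal(p1.artifacts["jitter"][g], p2.artifacts["jitter"][g])


def test_axis_spec_invariants():
    with pytest.raises(ValueError, match="lo < hi"):
        AxisSpec(limits=(2, 1))
    with pytest.raises(ValueError, match="tick_labels"):
        AxisSpec(tick_positions=(1, 2), tick_labels=("a",))
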