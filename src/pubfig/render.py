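"""Realization of composed figures as matplotlib drawings.

The realizer turns a :class:`~pubfig.multiplot.ComposedFigure` into a
``matplotlib.figure.Figure`` with explicitly placed axes.  Placement is fully
deterministic: the drawing area (the figure minus fixed label gutters) is
divided into grid cells proportional to the layout's row/column weights, and
every panel's axes rectangle is exactly its cell span.  Two panels in the
same grid column therefore occupy identical horizontal extents, which —
combined with jointly resolved axis limits — is what makes shared-axis data
positions pixel-identical across panels.
"""

from __future__ import annotations

import numpy as np
from matplotlib.figure import Figure

from .multiplot import ComposedFigure

__all__ = ["realize", "panel_rects"]

# Fixed label gutters around the drawing area, in figure fractions.  Sized
# for the default fonts; generous enough for tick labels at every panel edge.
GUTTER = {"left": 0.11, "right": 0.03, "bottom": 0.11, "top": 0.05}


def panel_rects(layout) -> dict[int, tuple[float, float, float, float]]:
    """Axes rectangles (x0, y0, w, h in figure fractions) for every panel."""
    inner_w = 1.0 - GUTTER["left"] - GUTTER["right"]
    inner_h = 1.0 - GUTTER["bottom"] - GUTTER["top"]
    s = layout.spacing
    ncols, nrows = layout.n_cols, layout.n_rows
    avail_w = inner_w - s * (ncols - 1)
    avail_h = inner_h - s * (nrows - 1)
    cw = np.asarray(layout.col_widths, dtype=float)
    rh = np.asarray(layout.row_heights, dtype=float)
    widths = avail_w * cw / cw.sum()
    heights = avail_h * rh / rh.sum()
    x_starts = GUTTER["left"] + np.concatenate([[0.0], np.cumsum(widths + s)[:-1]])
    # rows are top-to-bottom; matplotlib y runs bottom-to-top
    y_tops = 1.0 - GUTTER["top"] - np.concatenate([[0.0], np.cumsum(heights + s)[:-1]])
    rects = {}
    for p in layout.placements:
        x0 = float(x_starts[p.col])
        w = float(widths[p.col : p.col + p.col_span].sum() + s * (p.col_span - 1))
        top = float(y_tops[p.row])
        h = float(heights[p.row : p.row + p.row_span].sum() + s * (p.row_span - 1))
        rects[p.panel_index] = (x0, top - h, w, h)
    return rects


def _limits_for(panel, axis: str, fig: ComposedFigure, idx: int):
    """Axis limits for one panel: shared resolution wins over own domain."""
    for (ax_name, group), resolved in fig.shared_limits.items():
        if ax_name == axis and idx in group:
            return resolved, True
    domain = panel.x_domain if axis == "x" else panel.y_domain
    if domain[0] == "categorical":
        return ("categorical", tuple(domain[1])), False
    lo, hi = domain[1], domain[2]
    pad = (hi - lo) * fig.theme.padding
    return ("numeric", lo - pad, hi + pad), False


def _is_label_edge(fig: ComposedFigure, idx: int, axis: str) -> bool:
    """Under the 'edge' policy, does this panel draw tick labels for `axis`?"""
    layout = fig.layout
    groups = layout.shared_x_groups if axis == "x" else layout.shared_y_groups
    place = {p.panel_index: p for p in layout.placements}
    for g in groups:
        if idx in g:
            if axis == "x":  # bottom-most panel of the group keeps labels
                edge = max(g, key=lambda i: place[i].row + place[i].row_span)
                return place[idx].row + place[idx].row_span == (
                    place[edge].row + place[edge].row_span
                )
            edge = min(g, key=lambda i: place[i].col)  # left-most keeps labels
            return place[idx].col == place[edge].col
    return True


def realize(fig: ComposedFigure, dpi: float = 100.0) -> Figure:
    """Draw a composed figure onto a fresh matplotlib Figure.

    The returned figure is resolution-independent; the caller chooses the
    output dpi at save time.
    """
    theme = fig.theme
    size = fig.figure_size or theme.figure_size
    mplfig = Figure(figsize=size, dpi=dpi)
    mplfig.patch.set_facecolor(theme.background.to_mpl())
    rects = panel_rects(fig.layout)
    family = theme.font_family

    # Matrix-style charts draw row 0 at the top; a shared-y group containing
    # one must invert every member or rows would not align.
    invert_y_of = {i: p.invert_y for i, p in enumerate(fig.panels)}
    for ax_name, group in fig.shared_limits:
        if ax_name == "y" and any(fig.panels[i].invert_y for i in group):
            for i in group:
                invert_y_of[i] = True

    for idx, panel in enumerate(fig.panels):
        rect = rects[idx]
        ax = mplfig.add_axes(rect)
        ax.set_facecolor(theme.background.to_mpl())
        style = {**theme.style_defaults(), **panel.spec.theme_overrides}
        panel.draw(ax, style)

        for axis in ("x", "y"):
            resolved, _ = _limits_for(panel, axis, fig, idx)
            axis_spec = panel.spec.x_axis if axis == "x" else panel.spec.y_axis
            default_ticks = panel.x_ticks if axis == "x" else panel.y_ticks
            set_lim = ax.set_xlim if axis == "x" else ax.set_ylim
            set_ticks = ax.set_xticks if axis == "x" else ax.set_yticks
            invert = axis == "y" and invert_y_of[idx]
            if resolved[0] == "categorical":
                n = len(resolved[1])
                lims = (n - 0.5, -0.5) if invert else (-0.5, n - 0.5)
                set_lim(*lims)
                if default_ticks is None:
                    default_ticks = (tuple(range(n)), tuple(resolved[1]))
            else:
                lo, hi = resolved[1], resolved[2]
                set_lim((hi, lo) if invert else (lo, hi))
            if axis_spec.limits is not None:
                set_lim(*axis_spec.limits)
            if axis_spec.log_scale is not None:
                (ax.set_xscale if axis == "x" else ax.set_yscale)(
                    "log", base=axis_spec.log_scale
                )
            if axis_spec.tick_positions is not None:
                set_ticks(
                    axis_spec.tick_positions,
                    labels=axis_spec.tick_labels or None,
                )
            elif default_ticks is not None:
                positions, labels = default_ticks
                rotation = panel.spec.aesthetics.get(f"{axis}_tick_rotation", 0)
                set_ticks(positions, labels=[str(l) for l in labels])
                for t in (ax.get_xticklabels() if axis == "x" else ax.get_yticklabels()):
                    t.set_rotation(rotation)
            if axis_spec.label:
                (ax.set_xlabel if axis == "x" else ax.set_ylabel)(
                    axis_spec.label, fontsize=style["axis_label_size"], family=family
                )

        length = theme.tick_length if theme.tick_visible else 0.0
        ax.tick_params(
            labelsize=style["tick_label_size"],
            length=length,
            width=0.8 * style["line_width"],
        )
        for label in ax.get_xticklabels() + ax.get_yticklabels():
            label.set_family(family)
        if fig.layout.axis_label_policy == "edge":
            if not _is_label_edge(fig, idx, "x"):
                ax.tick_params(labelbottom=False)
            if not _is_label_edge(fig, idx, "y"):
                ax.tick_params(labelleft=False)
        if panel.spec.title:
            ax.set_title(
                panel.spec.title, fontsize=style["title_size"], family=family
            )
        if not panel.frame:
            for spine in ax.spines.values():
                spine.set_visible(False)
            ax.set_xticks([])
            ax.set_yticks([])
        else:
            for spine in ax.spines.values():
                spine.set_linewidth(0.8 * style["line_width"])

        if panel.spec.legend is not None:
            handles = []
            from matplotlib.lines import Line2D
            from matplotlib.patches import Patch

            for e in panel.spec.legend.entries:
                col = e.colour.to_mpl()
                if e.glyph == "box":
                    handles.append(Patch(facecolor=col, label=e.label))
                elif e.glyph == "dot":
                    handles.append(
                        Line2D([], [], marker="o", linestyle="none", color=col,
                               label=e.label)
                    )
                else:
                    handles.append(Line2D([], [], color=col, label=e.label))
            ax.legend(
                handles=handles,
                fontsize=style["legend_size"],
                loc="best",
                frameon=False,
            )
    return mplfig
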