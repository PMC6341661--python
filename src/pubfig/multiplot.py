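"""Multi-panel figure composition with axis alignment and style harmonization.

Complex datasets rarely fit one chart: an oncoprint-style figure needs the
mutation matrix, per-sample mutation counts above it, per-gene frequencies
beside it and clinical tracks below — all sharing the sample axis.  This
module composes chart panels on a proportional grid, resolves shared-axis
limits so a data value maps to the same canvas position in every panel of a
group, and pushes one figure-level theme onto every panel (explicit per-panel
overrides survive).

Alignment is geometric, not post-hoc: panels in the same grid column receive
identical horizontal canvas extents, so equal axis limits imply pixel-equal
data positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .charts import ChartSpec, Panel
from .output import MetadataRecord
from .theme import Theme, default_theme

__all__ = [
    "MultiplotLayout",
    "ComposedFigure",
    "compose",
    "harmonize",
    "resolve_shared_limits",
    "single_panel_figure",
]


@dataclass(frozen=True)
class Placement:
    panel_index: int
    row: int
    col: int
    row_span: int = 1
    col_span: int = 1

    def to_dict(self) -> dict:
        return {
            "panel_index": self.panel_index,
            "row": self.row,
            "col": self.col,
            "row_span": self.row_span,
            "col_span": self.col_span,
        }


@dataclass(frozen=True)
class MultiplotLayout:
    """Panel grid: placements, relative cell sizes and shared-axis groups.

    ``row_heights`` / ``col_widths`` are relative proportions of the drawing
    area; ``spacing`` is the inter-panel gap as a fraction of the figure
    dimension; ``shared_x_groups`` / ``shared_y_groups`` list sets of panel
    indices whose axis limits are resolved jointly.  ``axis_label_policy``
    is ``"edge"`` (only the bottom panel of a shared-x group and the left
    panel of a shared-y group draw tick labels) or ``"all"``.
    """

    n_rows: int
    n_cols: int
    placements: tuple[Placement, ...]
    row_heights: tuple[float, ...] = ()
    col_widths: tuple[float, ...] = ()
    shared_x_groups: tuple[tuple[int, ...], ...] = ()
    shared_y_groups: tuple[tuple[int, ...], ...] = ()
    spacing: float = 0.01
    axis_label_policy: str = "edge"

    @classmethod
    def make(
        cls,
        n_rows: int,
        n_cols: int,
        placements: Sequence,
        row_heights: Sequence[float] | None = None,
        col_widths: Sequence[float] | None = None,
        shared_x_groups: Sequence[Sequence[int]] = (),
        shared_y_groups: Sequence[Sequence[int]] = (),
        spacing: float = 0.01,
        axis_label_policy: str = "edge",
    ) -> "MultiplotLayout":
        pls = tuple(
            p if isinstance(p, Placement) else Placement(*p) for p in placements
        )
        return cls(
            n_rows=n_rows,
            n_cols=n_cols,
            placements=pls,
            row_heights=tuple(row_heights) if row_heights else tuple([1.0] * n_rows),
            col_widths=tuple(col_widths) if col_widths else tuple([1.0] * n_cols),
            shared_x_groups=tuple(tuple(sorted(g)) for g in shared_x_groups),
            shared_y_groups=tuple(tuple(sorted(g)) for g in shared_y_groups),
            spacing=spacing,
            axis_label_policy=axis_label_policy,
        )

    def __post_init__(self) -> None:
        if self.axis_label_policy not in ("edge", "all"):
            raise ValueError(f"axis_label_policy must be 'edge' or 'all'")
        if len(self.row_heights) != self.n_rows or len(self.col_widths) != self.n_cols:
            raise ValueError("row_heights/col_widths must match grid dimensions")
        if any(h <= 0 for h in self.row_heights) or any(w <= 0 for w in self.col_widths):
            raise ValueError("grid proportions must be positive")
        occupied: dict[tuple[int, int], int] = {}
        for p in self.placements:
            if p.row < 0 or p.col < 0 or p.row_span < 1 or p.col_span < 1:
                raise ValueError(f"invalid placement {p}")
            if p.row + p.row_span > self.n_rows or p.col + p.col_span > self.n_cols:
                raise ValueError(
                    f"panel {p.panel_index} placed out of bounds: {p} in "
                    f"{self.n_rows}x{self.n_cols} grid"
                )
            for r in range(p.row, p.row + p.row_span):
                for c in range(p.col, p.col + p.col_span):
                    if (r, c) in occupied:
                        raise ValueError(
                            f"panels {occupied[(r, c)]} and {p.panel_index} "
                            f"overlap at grid cell ({r}, {c})"
                        )
                    occupied[(r, c)] = p.panel_index
        for groups in (self.shared_x_groups, self.shared_y_groups):
            seen: set[int] = set()
            for g in groups:
                for idx in g:
                    if idx in seen:
                        raise ValueError(
                            f"panel {idx} appears in more than one shared group "
                            f"for the same axis"
                        )
                    seen.add(idx)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "placements": [p.to_dict() for p in self.placements],
            "row_heights": list(self.row_heights),
            "col_widths": list(self.col_widths),
            "shared_x_groups": [list(g) for g in self.shared_x_groups],
            "shared_y_groups": [list(g) for g in self.shared_y_groups],
            "spacing": self.spacing,
            "axis_label_policy": self.axis_label_policy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MultiplotLayout":
        return cls.make(
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            placements=[
                Placement(**p) if isinstance(p, dict) else Placement(*p)
                for p in d["placements"]
            ],
            row_heights=d.get("row_heights"),
            col_widths=d.get("col_widths"),
            shared_x_groups=d.get("shared_x_groups", ()),
            shared_y_groups=d.get("shared_y_groups", ()),
            spacing=d.get("spacing", 0.01),
            axis_label_policy=d.get("axis_label_policy", "edge"),
        )


@dataclass
class ComposedFigure:
    """Panels arranged on a layout under one governing theme."""

    layout: MultiplotLayout
    panels: tuple[Panel, ...]
    theme: Theme
    metadata: MetadataRecord | None = None
    shared_limits: dict = field(default_factory=dict)  # (axis, group) -> limits
    figure_size: tuple | None = None

    def to_dict(self) -> dict:
        return {
            "kind": "multiplot",
            "layout": self.layout.to_dict(),
            "panels": [p.spec.to_dict() for p in self.panels],
            "theme": self.theme.to_dict(),
        }


def harmonize(specs: Sequence[ChartSpec], theme: Theme) -> list[ChartSpec]:
    """Standardize style parameters across panels under one theme.

    Every style value a panel left at its default is replaced by the
    figure-level theme's value; explicit per-panel ``theme_overrides``
    survive.  Idempotent: applying it twice changes nothing further.
    """
    base = theme.style_defaults()
    return [s.with_overrides({**base, **s.theme_overrides}) for s in specs]


def resolve_shared_limits(
    panels: Sequence[Panel], axis: str, padding: float = 0.04
):
    """Joint axis limits for a shared-axis panel group.

    Numeric domains: the union of the panels' data ranges, expanded by
    ``padding`` of the union span on each side (never clips any panel's
    data).  Categorical domains: the common category order, which must be
    identical across the group.  Mixing the two in one group is an error.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    domains = [p.x_domain if axis == "x" else p.y_domain for p in panels]
    kinds = {d[0] for d in domains}
    if len(kinds) > 1:
        raise ValueError(
            f"cannot share {axis} axis across mixed domains: "
            + "; ".join(repr(d) for d in domains)
        )
    kind = kinds.pop()
    if kind == "categorical":
        cats = domains[0][1]
        for d in domains[1:]:
            if tuple(d[1]) != tuple(cats):
                raise ValueError(
                    f"shared {axis} axis requires identical category order: "
                    f"{list(cats)} vs {list(d[1])}"
                )
        return ("categorical", tuple(cats))
    lo = min(d[1] for d in domains)
    hi = max(d[2] for d in domains)
    pad = (hi - lo) * padding
    return ("numeric", lo - pad, hi + pad)


def compose(
    panels: Sequence[Panel],
    layout: MultiplotLayout,
    theme: Theme | None = None,
    metadata: MetadataRecord | None = None,
    figure_size: tuple | None = None,
) -> ComposedFigure:
    """Compose chart panels into one aligned, style-harmonized figure.

    Validates the layout against the panel list, harmonizes every panel's
    style under ``theme`` and resolves shared-axis limits up front; the
    resulting object renders identically wherever it is written.
    """
    theme = theme or default_theme()
    panels = list(panels)
    for p in layout.placements:
        if not 0 <= p.panel_index < len(panels):
            raise ValueError(
                f"placement references panel {p.panel_index}, but only "
                f"{len(panels)} panels were supplied"
            )
    placed = {p.panel_index for p in layout.placements}
    missing = [i for i in range(len(panels)) if i not in placed]
    if missing:
        raise ValueError(f"panels {missing} have no placement in the layout")

    specs = harmonize([p.spec for p in panels], theme)
    panels = [replace(p, spec=s) for p, s in zip(panels, specs)]

    shared: dict = {}
    for axis, groups in (("x", layout.shared_x_groups), ("y", layout.shared_y_groups)):
        for g in groups:
            shared[(axis, g)] = resolve_shared_limits(
                [panels[i] for i in g], axis, padding=theme.padding
            )
    return ComposedFigure(
        layout=layout,
        panels=tuple(panels),
        theme=theme,
        metadata=metadata,
        shared_limits=shared,
        figure_size=figure_size,
    )


def single_panel_figure(
    panel: Panel, theme: Theme | None = None, figure_size: tuple | None = None
) -> ComposedFigure:
    """Wrap one panel as a 1x1 composition (the standalone render path)."""
    layout = MultiplotLayout.make(1, 1, [(0, 0, 0)])
    return compose([panel], layout, theme=theme, figure_size=figure_size)
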