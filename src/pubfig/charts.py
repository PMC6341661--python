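"""The fifteen chart builders.

Every builder takes a declarative :class:`ChartSpec` plus the data it binds
and returns a :class:`Panel`: the validated, computed form of one plot.  A
panel records the numeric artifacts the chart displays (bar heights, box
statistics, hexagon counts, ...) alongside a drawing routine, so the numbers
behind a figure are testable without rasterizing anything.

Chart types
-----------
density, boxplot, violin, segplot, stripplot, barplot, scatterplot,
histogram, qq_fit, qq_comparison, manhattan, polygonplot, heatmap, dotmap
and hexbinplot.  The dotmap is the four-dimensional matrix chart: a grid
whose cell backgrounds encode one categorical variable and whose inset
circles encode a second (with optional circle-size scaling as the fourth
dimension) — used for oncoprint-style mutation matrices where shaded cells
carry SNVs and dots copy-number changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from matplotlib.patches import Circle, Polygon, Rectangle

from . import stats
from .colours import Colour, parse_colour
from .palettes import get_palette

__all__ = [
    "CHART_TYPES",
    "AxisSpec",
    "ChartSpec",
    "Panel",
    "DotmapData",
    "GenomicPoint",
    "LegendSpec",
    "CovariateBar",
    "ContractError",
    "create_chart",
    "create_qq",
    "create_manhattan",
    "create_dotmap",
    "create_legend",
    "create_covariate_bar",
]

CHART_TYPES = (
    "density",
    "boxplot",
    "violin",
    "segplot",
    "stripplot",
    "barplot",
    "scatterplot",
    "histogram",
    "qq_fit",
    "qq_comparison",
    "manhattan",
    "polygonplot",
    "heatmap",
    "dotmap",
    "hexbinplot",
)

_NEUTRAL = "#404040"


class ContractError(ValueError):
    """A chart's data contract was violated (missing role, wrong dtype, ...)."""


@dataclass(frozen=True)
class AxisSpec:
    """Axis configuration: label, explicit limits, ticks and log scaling."""

    label: str = ""
    limits: tuple[float, float] | None = None
    tick_positions: tuple | None = None
    tick_labels: tuple | None = None
    log_scale: float | None = None

    def __post_init__(self) -> None:
        if self.limits is not None:
            lo, hi = self.limits
            if not lo < hi:
                raise ValueError(f"axis limits must satisfy lo < hi, got {self.limits}")
        if (
            self.tick_labels is not None
            and self.tick_positions is not None
            and len(self.tick_labels) != len(self.tick_positions)
        ):
            raise ValueError("tick_labels length must match tick_positions")

    def to_dict(self) -> dict:
        d: dict = {}
        if self.label:
            d["label"] = self.label
        if self.limits is not None:
            d["limits"] = list(self.limits)
        if self.tick_positions is not None:
            d["tick_positions"] = list(self.tick_positions)
        if self.tick_labels is not None:
            d["tick_labels"] = list(self.tick_labels)
        if self.log_scale is not None:
            d["log_scale"] = self.log_scale
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AxisSpec":
        return cls(
            label=d.get("label", ""),
            limits=tuple(d["limits"]) if d.get("limits") is not None else None,
            tick_positions=tuple(d["tick_positions"])
            if d.get("tick_positions") is not None
            else None,
            tick_labels=tuple(d["tick_labels"])
            if d.get("tick_labels") is not None
            else None,
            log_scale=d.get("log_scale"),
        )


class LegendEntry(NamedTuple):
    label: str
    colour: Colour
    glyph: str  # box | dot | line


@dataclass(frozen=True)
class LegendSpec:
    """Ordered legend entries (label, colour, glyph shape)."""

    entries: tuple[LegendEntry, ...]
    title: str = ""

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate legend labels: {dupes}")
        for e in self.entries:
            if e.glyph not in ("box", "dot", "line"):
                raise ValueError(f"unknown legend glyph {e.glyph!r}")

    @classmethod
    def make(cls, entries: Sequence[tuple], title: str = "") -> "LegendSpec":
        return cls(
            tuple(LegendEntry(lab, parse_colour(col), glyph) for lab, col, glyph in entries),
            title=title,
        )

    def to_dict(self) -> dict:
        d = {
            "entries": [
                {"label": e.label, "colour": e.colour.to_hex(), "glyph": e.glyph}
                for e in self.entries
            ]
        }
        if self.title:
            d["title"] = self.title
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LegendSpec":
        return cls.make(
            [(e["label"], e["colour"], e["glyph"]) for e in d["entries"]],
            title=d.get("title", ""),
        )


@dataclass(frozen=True)
class ChartSpec:
    """Declarative description of one plot.

    ``data_binding`` maps aesthetic roles (``x``, ``y``, ``value``,
    ``group``, ``category``, ...) to column names of the bound table;
    ``aesthetics`` holds styling and chart-specific parameters (colour
    schemes, bin counts, chromosome order, ...); ``theme_overrides`` holds
    per-panel style values that survive figure-level harmonization.
    All fields are JSON-serializable, enabling the lossless spec round-trip.
    """

    chart_type: str
    data_binding: dict = field(default_factory=dict)
    aesthetics: dict = field(default_factory=dict)
    x_axis: AxisSpec = field(default_factory=AxisSpec)
    y_axis: AxisSpec = field(default_factory=AxisSpec)
    legend: LegendSpec | None = None
    theme_overrides: dict = field(default_factory=dict)
    data: str = "data"  # name of the bound dataset (for multi-table figures)
    title: str = ""

    def __post_init__(self) -> None:
        if self.chart_type not in CHART_TYPES:
            raise ValueError(
                f"unknown chart_type {self.chart_type!r}; expected one of {CHART_TYPES}"
            )

    def to_dict(self) -> dict:
        return {
            "chart_type": self.chart_type,
            "data": self.data,
            "title": self.title,
            "data_binding": dict(self.data_binding),
            "aesthetics": _plain(self.aesthetics),
            "x_axis": self.x_axis.to_dict(),
            "y_axis": self.y_axis.to_dict(),
            "legend": self.legend.to_dict() if self.legend else None,
            "theme_overrides": dict(self.theme_overrides),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChartSpec":
        return cls(
            chart_type=d["chart_type"],
            data=d.get("data", "data"),
            title=d.get("title", ""),
            data_binding=dict(d.get("data_binding", {})),
            aesthetics=dict(d.get("aesthetics", {})),
            x_axis=AxisSpec.from_dict(d.get("x_axis", {})),
            y_axis=AxisSpec.from_dict(d.get("y_axis", {})),
            legend=LegendSpec.from_dict(d["legend"]) if d.get("legend") else None,
            theme_overrides=dict(d.get("theme_overrides", {})),
        )

    def with_overrides(self, overrides: dict) -> "ChartSpec":
        from dataclasses import replace

        return replace(self, theme_overrides=dict(overrides))


def _plain(obj):
    """Recursively coerce to JSON-representable plain types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, Colour):
        return obj.to_hex()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# auxiliary data containers
# ---------------------------------------------------------------------------


class GenomicPoint(NamedTuple):
    """One association-test result: chromosome, 1-based position, p-value."""

    chromosome: str
    position: int
    p_value: float


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, pd.DataFrame):
        return m.to_numpy()
    return np.asarray(m)


@dataclass(frozen=True)
class DotmapData:
    """Paired category matrices for the four-dimensional dotmap.

    ``cell_categories`` colours each cell's background, ``dot_categories``
    the inset circle; either entry may be null (None/NaN) for absent.
    ``dot_sizes`` optionally scales circle radii.  All matrices share the
    same R×C shape.
    """

    cell_categories: np.ndarray
    dot_categories: np.ndarray
    cell_colour_map: dict
    dot_colour_map: dict
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    dot_sizes: np.ndarray | None = None

    @classmethod
    def make(
        cls,
        cell_categories,
        dot_categories,
        cell_colour_map,
        dot_colour_map,
        row_labels=None,
        col_labels=None,
        dot_sizes=None,
    ) -> "DotmapData":
        if row_labels is None and isinstance(cell_categories, pd.DataFrame):
            row_labels = [str(i) for i in cell_categories.index]
        if col_labels is None and isinstance(cell_categories, pd.DataFrame):
            col_labels = [str(c) for c in cell_categories.columns]
        cell = _as_matrix(cell_categories).astype(object)
        dot = _as_matrix(dot_categories).astype(object)
        sizes = None if dot_sizes is None else _as_matrix(dot_sizes).astype(float)
        if cell.shape != dot.shape or (sizes is not None and sizes.shape != cell.shape):
            raise ValueError(
                f"dotmap matrices must share one shape; got cell {cell.shape}, "
                f"dot {dot.shape}"
                + (f", sizes {sizes.shape}" if sizes is not None else "")
            )
        r, c = cell.shape
        row_labels = tuple(row_labels) if row_labels is not None else tuple(map(str, range(r)))
        col_labels = tuple(col_labels) if col_labels is not None else tuple(map(str, range(c)))
        if len(row_labels) != r or len(col_labels) != c:
            raise ValueError("label lengths must match matrix dimensions")
        obj = cls(
            cell_categories=cell,
            dot_categories=dot,
            cell_colour_map={k: parse_colour(v) for k, v in cell_colour_map.items()},
            dot_colour_map={k: parse_colour(v) for k, v in dot_colour_map.items()},
            row_labels=row_labels,
            col_labels=col_labels,
            dot_sizes=sizes,
        )
        obj._check_codes()
        return obj

    def _check_codes(self) -> None:
        for name, matrix, cmap in (
            ("cell", self.cell_categories, self.cell_colour_map),
            ("dot", self.dot_categories, self.dot_colour_map),
        ):
            for code in _present_codes(matrix):
                if code not in cmap:
                    raise ValueError(
                        f"{name} category {code!r} has no colour-map entry"
                    )

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_categories.shape


def _is_null(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA


def _present_codes(matrix: np.ndarray) -> list:
    seen = []
    for v in matrix.ravel():
        if not _is_null(v) and v not in seen:
            seen.append(v)
    return seen


@dataclass(frozen=True)
class CovariateBar:
    """One clinical-annotation track: a category per sample position."""

    track_name: str
    values: tuple
    colour_map: dict

    @classmethod
    def make(cls, track_name, values, colour_map) -> "CovariateBar":
        cmap = {k: parse_colour(v) for k, v in colour_map.items()}
        values = tuple(values)
        for v in values:
            if not _is_null(v) and v not in cmap:
                raise ValueError(
                    f"covariate track {track_name!r}: value {v!r} has no "
                    f"colour-map entry"
                )
        return cls(track_name, values, cmap)


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------

Domain = tuple  # ("numeric", lo, hi) | ("categorical", (cats...))


@dataclass
class Panel:
    """The computed form of one chart: artifacts plus a drawing routine.

    ``x_domain`` / ``y_domain`` describe the panel's data extent for
    shared-axis resolution: ``("numeric", lo, hi)`` or ``("categorical",
    categories)``.  ``draw`` renders the data artists onto a matplotlib axes;
    axis limits, ticks and fonts are applied by the figure realizer so that
    multi-panel alignment controls them centrally.
    """

    spec: ChartSpec
    x_domain: Domain
    y_domain: Domain
    artifacts: dict
    draw: Callable
    x_ticks: tuple | None = None  # (positions, labels) defaults
    y_ticks: tuple | None = None
    frame: bool = True
    invert_y: bool = False  # matrix-style charts draw row 0 at the top


def _colour_cycle(aes: dict, n: int) -> list[Colour]:
    scheme = aes.get("colour_scheme")
    if scheme:
        pal = get_palette(scheme)
        if n > len(pal):
            raise ValueError(
                f"colour scheme {scheme!r} has {len(pal)} colours; {n} requested"
            )
        return list(pal.colours[:n])
    if "colours" in aes:
        cols = [parse_colour(c) for c in aes["colours"]]
        if len(cols) < n:
            raise ValueError(f"{n} colours needed, {len(cols)} supplied")
        return cols[:n]
    if n == 1:
        return [parse_colour(aes.get("colour", _NEUTRAL))]
    return list(get_palette("tab10").colours[:n])


def _require(binding: dict, data: pd.DataFrame, role: str, kind: str = "numeric"):
    if role not in binding:
        raise ContractError(
            f"role {role!r} missing from data_binding; a {kind} column is required"
        )
    col = binding[role]
    if not isinstance(data, pd.DataFrame):
        raise ContractError(
            f"role {role!r} requires tabular data, got {type(data).__name__}"
        )
    if col not in data.columns:
        raise ContractError(f"role {role!r} is bound to absent column {col!r}")
    series = data[col]
    if kind == "numeric":
        if not np.issubdtype(np.asarray(series).dtype, np.number):
            try:
                series = pd.to_numeric(series)
            except (TypeError, ValueError):
                raise ContractError(
                    f"role {role!r} (column {col!r}) must be numeric"
                ) from None
        vals = series.to_numpy(dtype=float)
        if not np.isfinite(vals).any():
            raise ContractError(f"role {role!r} (column {col!r}) has no finite values")
        return vals
    return series.to_numpy()


def _check_not_empty(data) -> None:
    size = data.shape[0] if hasattr(data, "shape") else len(data)
    if size == 0:
        raise ContractError("empty data: nothing to plot")


def _grouped(values: np.ndarray, groups: np.ndarray | None):
    if groups is None:
        return [("", values)]
    order = list(dict.fromkeys(groups))
    return [(g, values[groups == g]) for g in order]


def _numeric_domain(*arrays) -> Domain:
    lo = min(float(np.nanmin(a)) for a in arrays)
    hi = max(float(np.nanmax(a)) for a in arrays)
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return ("numeric", lo, hi)


def _cat_domain(cats: Sequence) -> Domain:
    return ("categorical", tuple(cats))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _build_density(spec: ChartSpec, data) -> Panel:
    values = _require(spec.data_binding, data, "value")
    groups = (
        _require(spec.data_binding, data, "group", kind="categorical")
        if "group" in spec.data_binding
        else None
    )
    bw = spec.aesthetics.get("bandwidth")
    series = {}
    for g, vals in _grouped(values, groups):
        if vals.size < 2:
            raise ContractError(f"density group {g!r} has fewer than 2 values")
        series[g] = stats.density_estimate(vals, bandwidth=bw)
    colours = _colour_cycle(spec.aesthetics, len(series))
    lw = spec.theme_overrides.get("line_width")

    def draw(ax, style):
        for (g, (grid, dens)), col in zip(series.items(), colours):
            ax.plot(grid, dens, color=col.to_mpl(), lw=style["line_width"], label=g or None)
            ax.fill_between(grid, dens, color=col.to_mpl(), alpha=0.25, lw=0)

    _ = lw
    xs = [grid for grid, _ in series.values()]
    ys = [dens for _, dens in series.values()]
    return Panel(
        spec=spec,
        x_domain=_numeric_domain(*xs),
        y_domain=("numeric", 0.0, max(float(d.max()) for d in ys) * 1.05),
        artifacts={"series": series},
        draw=draw,
    )


def _build_boxlike(spec: ChartSpec, data, kind: str) -> Panel:
    values = _require(spec.data_binding, data, "value")
    groups = (
        _require(spec.data_binding, data, "group", kind="categorical")
        if "group" in spec.data_binding
        else None
    )
    grouped = _grouped(values, groups)
    cats = [str(g) for g, _ in grouped]
    colours = _colour_cycle(spec.aesthetics, len(grouped))
    box_stats = {
        str(g): stats.box_statistics(v, method=spec.aesthetics.get("quartile_method", "exclusive"))
        for g, v in grouped
    }

    if kind == "boxplot":

        def draw(ax, style):
            bxp_stats = []
            for g, _v in grouped:
                s = box_stats[str(g)]
                bxp_stats.append(
                    {
                        "med": s.median,
                        "q1": s.lower_hinge,
                        "q3": s.upper_hinge,
                        "whislo": s.whisker_lo,
                        "whishi": s.whisker_hi,
                        "fliers": list(s.outliers),
                        "label": str(g),
                    }
                )
            arts = ax.bxp(
                bxp_stats,
                positions=range(len(grouped)),
                widths=0.6,
                showfliers=True,
                patch_artist=True,
            )
            for patch, col in zip(arts["boxes"], colours):
                patch.set_facecolor((*col.to_mpl()[:3], 0.5))
                patch.set_linewidth(style["line_width"])
            for key in ("whiskers", "caps", "medians"):
                for artist in arts[key]:
                    artist.set_linewidth(style["line_width"])
                    artist.set_color("black")

        artifacts = {"stats": box_stats}
    elif kind == "violin":
        bw = spec.aesthetics.get("bandwidth")
        dens = {}
        for g, v in grouped:
            if v.size < 2:
                raise ContractError(f"violin group {g!r} has fewer than 2 values")
            dens[str(g)] = stats.density_estimate(v, bandwidth=bw)

        def draw(ax, style):
            for i, (g, _v) in enumerate(grouped):
                grid, d = dens[str(g)]
                half = 0.4 * d / d.max()
                col = colours[i].to_mpl()
                ax.fill_betweenx(grid, i - half, i + half, color=col, alpha=0.6, lw=0)
                ax.plot(i - half, grid, color=col, lw=style["line_width"])
                ax.plot(i + half, grid, color=col, lw=style["line_width"])
                s = box_stats[str(g)]
                ax.plot([i - 0.15, i + 0.15], [s.median] * 2, color="black",
                        lw=style["line_width"])

        artifacts = {"stats": box_stats, "densities": dens}
    else:  # stripplot
        rng = np.random.default_rng(int(spec.aesthetics.get("jitter_seed", 0)))
        jitter = float(spec.aesthetics.get("jitter", 0.08))
        offsets = {str(g): rng.uniform(-jitter, jitter, size=v.size) for g, v in grouped}

        def draw(ax, style):
            for i, (g, v) in enumerate(grouped):
                ax.plot(
                    i + offsets[str(g)],
                    v,
                    linestyle="none",
                    marker="o",
                    markersize=spec.aesthetics.get("point_size", 3.5),
                    color=colours[i].to_mpl(),
                    alpha=0.8,
                )

        artifacts = {"stats": box_stats, "jitter": offsets}

    all_vals = np.concatenate([v for _, v in grouped])
    return Panel(
        spec=spec,
        x_domain=_cat_domain(cats),
        y_domain=_numeric_domain(all_vals),
        artifacts=artifacts,
        draw=draw,
        x_ticks=(tuple(range(len(cats))), tuple(cats)),
    )


def _build_segplot(spec: ChartSpec, data) -> Panel:
    cats = _require(spec.data_binding, data, "category", kind="categorical")
    centre = _require(spec.data_binding, data, "centre")
    lo = _require(spec.data_binding, data, "lo")
    hi = _require(spec.data_binding, data, "hi")
    if not (np.all(lo <= centre) and np.all(centre <= hi)):
        raise ContractError("segplot requires lo <= centre <= hi for every category")
    labels = [str(c) for c in cats]
    colour = parse_colour(spec.aesthetics.get("colour", _NEUTRAL))

    def draw(ax, style):
        for i, (c, l, h) in enumerate(zip(centre, lo, hi)):
            ax.plot([l, h], [i, i], color=colour.to_mpl(), lw=style["line_width"])
            ax.plot(
                [c], [i], marker="o", color=colour.to_mpl(),
                markersize=spec.aesthetics.get("point_size", 5),
            )

    return Panel(
        spec=spec,
        x_domain=_numeric_domain(lo, hi),
        y_domain=_cat_domain(labels),
        artifacts={"categories": labels, "centre": centre, "lo": lo, "hi": hi},
        draw=draw,
        y_ticks=(tuple(range(len(labels))), tuple(labels)),
    )


def _build_barplot(spec: ChartSpec, data) -> Panel:
    cats = _require(spec.data_binding, data, "category", kind="categorical")
    values = _require(spec.data_binding, data, "value")
    horizontal = spec.aesthetics.get("orientation", "vertical") == "horizontal"
    groups = (
        _require(spec.data_binding, data, "group", kind="categorical")
        if "group" in spec.data_binding
        else None
    )
    order = list(dict.fromkeys(str(c) for c in cats))
    cats_s = np.array([str(c) for c in cats])
    if groups is None:
        heights = {c: float(values[cats_s == c].sum()) for c in order}
        stacks = {c: {"": heights[c]} for c in order}
        group_order = [""]
    else:
        group_order = list(dict.fromkeys(str(g) for g in groups))
        groups_s = np.array([str(g) for g in groups])
        stacks = {
            c: {
                g: float(values[(cats_s == c) & (groups_s == g)].sum())
                for g in group_order
            }
            for c in order
        }
        heights = {c: sum(stacks[c].values()) for c in order}
    colours = _colour_cycle(spec.aesthetics, len(group_order))
    colour_map = spec.aesthetics.get("group_colours")
    if colour_map:
        colours = [parse_colour(colour_map[g]) for g in group_order]
    width = float(spec.aesthetics.get("bar_width", 0.8))

    def draw(ax, style):
        bottom = {c: 0.0 for c in order}
        for gi, g in enumerate(group_order):
            pos = np.arange(len(order))
            vals = np.array([stacks[c][g] for c in order])
            offs = np.array([bottom[c] for c in order])
            if horizontal:
                ax.barh(pos, vals, left=offs, height=width,
                        color=colours[gi].to_mpl(), edgecolor="black",
                        linewidth=0.4 * style["line_width"])
            else:
                ax.bar(pos, vals, bottom=offs, width=width,
                       color=colours[gi].to_mpl(), edgecolor="black",
                       linewidth=0.4 * style["line_width"])
            for c, v in zip(order, vals):
                bottom[c] += v

    max_h = max(heights.values()) if heights else 1.0
    value_domain = ("numeric", 0.0, max_h * 1.05 if max_h > 0 else 1.0)
    ticks = (tuple(range(len(order))), tuple(order))
    if horizontal:
        x_domain, y_domain = value_domain, _cat_domain(order)
        x_ticks, y_ticks = None, ticks
    else:
        x_domain, y_domain = _cat_domain(order), value_domain
        x_ticks, y_ticks = ticks, None
    return Panel(
        spec=spec,
        x_domain=x_domain,
        y_domain=y_domain,
        artifacts={"categories": order, "heights": heights, "stacks": stacks,
                   "groups": group_order},
        draw=draw,
        x_ticks=x_ticks,
        y_ticks=y_ticks,
    )


def _build_scatter(spec: ChartSpec, data) -> Panel:
    x = _require(spec.data_binding, data, "x")
    y = _require(spec.data_binding, data, "y")
    if x.size != y.size:
        raise ContractError("scatterplot x and y columns must have equal length")
    colour = parse_colour(spec.aesthetics.get("colour", _NEUTRAL))

    def draw(ax, style):
        ax.plot(
            x, y, linestyle="none", marker="o",
            markersize=spec.aesthetics.get("point_size", 4),
            color=colour.to_mpl(), alpha=float(spec.aesthetics.get("alpha", 0.9)),
        )

    return Panel(
        spec=spec,
        x_domain=_numeric_domain(x),
        y_domain=_numeric_domain(y),
        artifacts={"x": x, "y": y},
        draw=draw,
    )


def _build_histogram(spec: ChartSpec, data) -> Panel:
    values = _require(spec.data_binding, data, "value")
    bins = spec.aesthetics.get("bins", 10)
    counts, edges = np.histogram(values, bins=bins)
    colour = parse_colour(spec.aesthetics.get("colour", "#7F7F7F"))

    def draw(ax, style):
        ax.bar(
            edges[:-1], counts, width=np.diff(edges), align="edge",
            color=colour.to_mpl(), edgecolor="black",
            linewidth=0.4 * style["line_width"],
        )

    return Panel(
        spec=spec,
        x_domain=("numeric", float(edges[0]), float(edges[-1])),
        y_domain=("numeric", 0.0, float(counts.max()) * 1.05 if counts.max() else 1.0),
        artifacts={"bin_edges": edges, "bin_counts": counts},
        draw=draw,
    )


def _build_qq(spec: ChartSpec, data) -> Panel:
    mode = spec.chart_type  # qq_fit | qq_comparison
    if mode == "qq_fit":
        sample = _require(spec.data_binding, data, "value")
        dist = spec.aesthetics.get("distribution", "norm")
        params = spec.aesthetics.get("distribution_params", {})
        qx, qy = stats.qq_fit_points(sample, dist, params)
        # reference line through the first and third quartile points
        tx = np.quantile(qx, [0.25, 0.75])
        ty = np.quantile(qy, [0.25, 0.75])
        slope = (ty[1] - ty[0]) / (tx[1] - tx[0]) if tx[1] != tx[0] else 1.0
        intercept = ty[0] - slope * tx[0]
    else:
        a = _require(spec.data_binding, data, "a")
        b = _require(spec.data_binding, data, "b")
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        qx, qy = stats.qq_comparison_points(a, b)
        slope, intercept = 1.0, 0.0  # identity reference
    colour = parse_colour(spec.aesthetics.get("colour", _NEUTRAL))

    def draw(ax, style):
        lo = min(float(qx.min()), float(qy.min()))
        hi = max(float(qx.max()), float(qy.max()))
        ax.plot(
            [lo, hi], [slope * lo + intercept, slope * hi + intercept],
            color="#B0B0B0", lw=style["line_width"], zorder=1,
        )
        ax.plot(qx, qy, linestyle="none", marker="o", markersize=3.5,
                color=colour.to_mpl(), zorder=2)

    return Panel(
        spec=spec,
        x_domain=_numeric_domain(qx),
        y_domain=_numeric_domain(qy),
        artifacts={"qx": qx, "qy": qy, "slope": slope, "intercept": intercept},
        draw=draw,
    )


def _build_manhattan(spec: ChartSpec, data) -> Panel:
    chrom = _require(spec.data_binding, data, "chromosome", kind="categorical")
    pos = _require(spec.data_binding, data, "position")
    p = _require(spec.data_binding, data, "p_value")
    chrom = np.array([str(c) for c in chrom])
    chrom_order = [str(c) for c in spec.aesthetics.get(
        "chrom_order", list(dict.fromkeys(chrom))
    )]
    lengths = spec.aesthetics.get("chrom_lengths")
    x, y, ticks = stats.manhattan_coords(chrom, pos, p, chrom_order, lengths)
    scheme = spec.aesthetics.get("colour_scheme")
    if scheme:
        pal = get_palette(scheme)
        chrom_colours = [pal.colours[i % len(pal)] for i in range(len(chrom_order))]
    else:  # alternate two colours by default
        pair = [parse_colour("#2166AC"), parse_colour("#92C5DE")]
        chrom_colours = [pair[i % 2] for i in range(len(chrom_order))]
    colour_of = dict(zip(chrom_order, chrom_colours))

    def draw(ax, style):
        for c in chrom_order:
            mask = chrom == c
            if mask.any():
                ax.plot(x[mask], y[mask], linestyle="none", marker="o",
                        markersize=2.5, color=colour_of[c].to_mpl())
        sig = spec.aesthetics.get("significance_line")
        if sig:
            ax.axhline(-np.log10(float(sig)), color="#B2182B", lw=style["line_width"],
                       linestyle="--")

    return Panel(
        spec=spec,
        x_domain=("numeric", 0.0, float(x.max()) * 1.01),
        y_domain=("numeric", 0.0, float(y.max()) * 1.05),
        artifacts={"x": x, "y": y, "ticks": ticks},
        draw=draw,
        x_ticks=(tuple(ticks[c] for c in chrom_order), tuple(chrom_order)),
    )


def _build_polygonplot(spec: ChartSpec, data) -> Panel:
    x = _require(spec.data_binding, data, "x")
    series_cols = spec.data_binding.get("series")
    if not series_cols:
        raise ContractError(
            "role 'series' missing from data_binding; one or more y-columns required"
        )
    if isinstance(series_cols, str):
        series_cols = [series_cols]
    ys = {}
    for col in series_cols:
        if col not in data.columns:
            raise ContractError(f"role 'series' is bound to absent column {col!r}")
        ys[col] = data[col].to_numpy(dtype=float)
    colours = _colour_cycle(spec.aesthetics, len(ys))

    def draw(ax, style):
        for (name, y), col in zip(ys.items(), colours):
            verts = [(x[0], 0.0), *zip(x, y), (x[-1], 0.0)]
            ax.add_patch(Polygon(verts, closed=True, facecolor=(*col.to_mpl()[:3], 0.55),
                                 edgecolor=col.to_mpl(), lw=style["line_width"],
                                 label=name))

    ymax = max(float(np.nanmax(y)) for y in ys.values())
    return Panel(
        spec=spec,
        x_domain=_numeric_domain(x),
        y_domain=("numeric", 0.0, ymax * 1.05),
        artifacts={"series": ys},
        draw=draw,
    )


def _build_heatmap(spec: ChartSpec, data) -> Panel:
    if isinstance(data, pd.DataFrame):
        matrix = data
    else:
        matrix = pd.DataFrame(np.asarray(data))
    _check_not_empty(matrix)
    rows = [str(r) for r in matrix.index]
    cols = [str(c) for c in matrix.columns]
    cat_map = spec.aesthetics.get("colour_map")
    if cat_map:  # categorical heatmap
        cmap = {k: parse_colour(v) for k, v in cat_map.items()}
        arr = matrix.to_numpy(dtype=object)
        for code in _present_codes(arr):
            if code not in cmap:
                raise ContractError(f"heatmap category {code!r} has no colour-map entry")
        bg = parse_colour(spec.aesthetics.get("null_colour", "#FFFFFF"))
        rgb = np.empty((*arr.shape, 3))
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                c = bg if _is_null(arr[i, j]) else cmap[arr[i, j]]
                rgb[i, j] = c.to_mpl()[:3]

        def draw(ax, style):
            ax.imshow(rgb, aspect="auto", interpolation="nearest",
                      extent=(-0.5, len(cols) - 0.5, len(rows) - 0.5, -0.5))

        artifacts = {"matrix": arr, "mode": "categorical"}
    else:
        arr = matrix.to_numpy(dtype=float)
        scheme = spec.aesthetics.get("colour_scheme", "Blues")
        pal = get_palette(scheme)
        from matplotlib.colors import LinearSegmentedColormap

        cmap_mpl = LinearSegmentedColormap.from_list(
            scheme, [c.to_mpl() for c in pal.colours]
        )

        def draw(ax, style):
            ax.imshow(arr, aspect="auto", interpolation="nearest", cmap=cmap_mpl,
                      extent=(-0.5, len(cols) - 0.5, len(rows) - 0.5, -0.5))

        artifacts = {"matrix": arr, "mode": "numeric"}

    return Panel(
        spec=spec,
        x_domain=_cat_domain(cols),
        y_domain=_cat_domain(rows),
        artifacts=artifacts,
        draw=draw,
        x_ticks=(tuple(range(len(cols))), tuple(cols)),
        y_ticks=(tuple(range(len(rows))), tuple(rows)),
        invert_y=True,
    )


def _build_dotmap(spec: ChartSpec, data) -> Panel:
    if not isinstance(data, DotmapData):
        raise ContractError(
            f"dotmap requires DotmapData, got {type(data).__name__}"
        )
    d = data
    r, c = d.shape
    sizes = d.dot_sizes
    max_size = float(np.nanmax(sizes)) if sizes is not None and np.isfinite(sizes).any() else None

    def draw(ax, style):
        for i in range(r):
            for j in range(c):
                cell = d.cell_categories[i, j]
                if not _is_null(cell):
                    ax.add_patch(
                        Rectangle((j - 0.5, i - 0.5), 1, 1,
                                  facecolor=d.cell_colour_map[cell].to_mpl(),
                                  edgecolor="none")
                    )
                dot = d.dot_categories[i, j]
                if not _is_null(dot):
                    radius = 0.32
                    if sizes is not None and max_size and np.isfinite(sizes[i, j]):
                        radius = 0.32 * float(sizes[i, j]) / max_size
                    ax.add_patch(
                        Circle((j, i), radius,
                               facecolor=d.dot_colour_map[dot].to_mpl(),
                               edgecolor="black", lw=0.3 * style["line_width"])
                    )
        # light grid between cells
        for j in range(c + 1):
            ax.axvline(j - 0.5, color="#DDDDDD", lw=0.3 * style["line_width"], zorder=0)
        for i in range(r + 1):
            ax.axhline(i - 0.5, color="#DDDDDD", lw=0.3 * style["line_width"], zorder=0)

    n_cells = int(
        sum(
            (not _is_null(d.cell_categories[i, j])) or (not _is_null(d.dot_categories[i, j]))
            for i in range(r)
            for j in range(c)
        )
    )
    return Panel(
        spec=spec,
        x_domain=_cat_domain(d.col_labels),
        y_domain=_cat_domain(d.row_labels),
        artifacts={"shape": (r, c), "n_marked_cells": n_cells, "data": d},
        draw=draw,
        x_ticks=(tuple(range(c)), tuple(d.col_labels)),
        y_ticks=(tuple(range(r)), tuple(d.row_labels)),
        invert_y=True,
    )


def _build_hexbinplot(spec: ChartSpec, data) -> Panel:
    x = _require(spec.data_binding, data, "x")
    y = _require(spec.data_binding, data, "y")
    nbins = int(spec.aesthetics.get("nbins", 12))
    extent = spec.aesthetics.get("extent")
    cells = stats.hexbin(np.column_stack([x, y]), nbins, extent)
    scheme = spec.aesthetics.get("colour_scheme", "Blues")
    pal = get_palette(scheme)
    max_count = max(cnt for _, cnt in cells)
    xmin, xmax = float(x.min()), float(x.max())
    dx = ((extent[1] - extent[0]) if extent else (xmax - xmin or 1.0)) / nbins
    radius = dx / np.sqrt(3)  # circumradius of a pointy-top hexagon with width dx

    def draw(ax, style):
        angles = np.pi / 180 * (np.arange(6) * 60 + 30)  # pointy-top vertices
        for (cx, cy), cnt in cells:
            frac = cnt / max_count
            ci = min(int(frac * (len(pal) - 1) + 0.5), len(pal) - 1)
            verts = np.column_stack(
                [cx + radius * np.cos(angles), cy + radius * np.sin(angles)]
            )
            ax.add_patch(Polygon(verts, closed=True,
                                 facecolor=pal.colours[ci].to_mpl(),
                                 edgecolor="white", lw=0.2 * style["line_width"]))

    return Panel(
        spec=spec,
        x_domain=_numeric_domain(x),
        y_domain=_numeric_domain(y),
        artifacts={"cells": cells, "n_points": int(x.size)},
        draw=draw,
    )


_BUILDERS = {
    "density": _build_density,
    "boxplot": lambda s, d: _build_boxlike(s, d, "boxplot"),
    "violin": lambda s, d: _build_boxlike(s, d, "violin"),
    "stripplot": lambda s, d: _build_boxlike(s, d, "stripplot"),
    "segplot": _build_segplot,
    "barplot": _build_barplot,
    "scatterplot": _build_scatter,
    "histogram": _build_histogram,
    "qq_fit": _build_qq,
    "qq_comparison": _build_qq,
    "manhattan": _build_manhattan,
    "polygonplot": _build_polygonplot,
    "heatmap": _build_heatmap,
    "dotmap": _build_dotmap,
    "hexbinplot": _build_hexbinplot,
}


def create_chart(spec: ChartSpec, data) -> Panel:
    """Build the panel for any chart type from its spec and bound data.

    Validates the chart type's data contract first; violations raise
    :class:`ContractError` naming the offending role.
    """
    if data is None:
        raise ContractError("no data bound to chart")
    _check_not_empty(data)
    return _BUILDERS[spec.chart_type](spec, data)


# ---------------------------------------------------------------------------
# convenience constructors for the specialised charts
# ---------------------------------------------------------------------------


def create_qq(sample_a, reference, mode: str = "comparison", **aesthetics) -> Panel:
    """Quantile-quantile panel.

    ``mode="fit"`` compares ``sample_a`` against a named theoretical
    distribution (``reference`` is ``(name, params)`` or a name string);
    ``mode="comparison"`` against a second sample (``reference`` is the
    sample).
    """
    if mode == "fit":
        if isinstance(reference, str):
            dist, params = reference, {}
        else:
            dist, params = reference
        df = pd.DataFrame({"value": np.asarray(sample_a, dtype=float)})
        spec = ChartSpec(
            "qq_fit",
            data_binding={"value": "value"},
            aesthetics={"distribution": dist, "distribution_params": params, **aesthetics},
        )
        return create_chart(spec, df)
    if mode == "comparison":
        a = np.asarray(sample_a, dtype=float)
        b = np.asarray(reference, dtype=float)
        n = max(a.size, b.size)
        df = pd.DataFrame(
            {
                "a": np.concatenate([a, np.full(n - a.size, np.nan)]),
                "b": np.concatenate([b, np.full(n - b.size, np.nan)]),
            }
        )
        spec = ChartSpec(
            "qq_comparison", data_binding={"a": "a", "b": "b"}, aesthetics=aesthetics
        )
        return create_chart(spec, df)
    raise ValueError(f"qq mode must be 'fit' or 'comparison', got {mode!r}")


def create_manhattan(points: Sequence[GenomicPoint], chrom_order, **aesthetics) -> Panel:
    """Manhattan panel from a list of (chromosome, position, p-value) points."""
    pts = [GenomicPoint(*p) for p in points]
    df = pd.DataFrame(pts)
    spec = ChartSpec(
        "manhattan",
        data_binding={"chromosome": "chromosome", "position": "position",
                      "p_value": "p_value"},
        aesthetics={"chrom_order": [str(c) for c in chrom_order], **aesthetics},
        y_axis=AxisSpec(label=r"$-\log_{10} p$"),
    )
    return create_chart(spec, df)


def create_dotmap(d: DotmapData, **aesthetics) -> Panel:
    """Dotmap panel from paired cell/dot category matrices."""
    spec = ChartSpec("dotmap", aesthetics=aesthetics)
    return create_chart(spec, d)


def create_legend(legend: LegendSpec) -> Panel:
    """A legend drawn as its own panel: one row per entry, glyph then label."""
    if not legend.entries:
        raise ValueError("legend requires at least one entry")
    n = len(legend.entries)

    def draw(ax, style):
        for i, e in enumerate(legend.entries):
            y = n - 1 - i
            col = e.colour.to_mpl()
            if e.glyph == "box":
                ax.add_patch(Rectangle((0.05, y + 0.25), 0.5, 0.5, facecolor=col,
                                       edgecolor="black", lw=0.4 * style["line_width"]))
            elif e.glyph == "dot":
                ax.add_patch(Circle((0.3, y + 0.5), 0.22, facecolor=col,
                                    edgecolor="black", lw=0.4 * style["line_width"]))
            else:  # line
                ax.plot([0.05, 0.55], [y + 0.5] * 2, color=col,
                        lw=1.6 * style["line_width"])
            ax.text(0.75, y + 0.5, e.label, va="center", ha="left",
                    fontsize=style["legend_size"])
        if legend.title:
            ax.text(0.05, n + 0.4, legend.title, va="center", ha="left",
                    fontsize=style["legend_size"], fontweight="bold")

    spec = ChartSpec("heatmap")  # carrier spec only; the panel draws itself
    panel = Panel(
        spec=spec,
        x_domain=("numeric", 0.0, 4.0),
        y_domain=("numeric", 0.0, n + (0.8 if legend.title else 0.0)),
        artifacts={"entries": legend.entries},
        draw=draw,
        frame=False,
    )
    return panel


def create_covariate_bar(bar: CovariateBar, orientation: str = "horizontal") -> Panel:
    """One-track annotation strip aligned 1:1 with a companion panel's samples."""
    if orientation not in ("horizontal", "vertical"):
        raise ValueError(f"orientation must be horizontal or vertical, got {orientation!r}")
    n = len(bar.values)
    null_colour = parse_colour("#FFFFFF")

    def draw(ax, style):
        for i, v in enumerate(bar.values):
            col = (null_colour if _is_null(v) else bar.colour_map[v]).to_mpl()
            if orientation == "horizontal":
                ax.add_patch(Rectangle((i - 0.5, -0.5), 1, 1, facecolor=col,
                                       edgecolor="white", lw=0.2 * style["line_width"]))
            else:
                ax.add_patch(Rectangle((-0.5, i - 0.5), 1, 1, facecolor=col,
                                       edgecolor="white", lw=0.2 * style["line_width"]))

    positions = tuple(range(n))
    labels = tuple(str(i) for i in positions)
    spec = ChartSpec("heatmap", title=bar.track_name)
    if orientation == "horizontal":
        x_domain, y_domain = _cat_domain(labels), _cat_domain((bar.track_name,))
        y_ticks = ((0,), (bar.track_name,))
        x_ticks = (positions, labels)
    else:
        x_domain, y_domain = _cat_domain((bar.track_name,)), _cat_domain(labels)
        x_ticks = ((0,), (bar.track_name,))
        y_ticks = (positions, labels)
    return Panel(
        spec=spec,
        x_domain=x_domain,
        y_domain=y_domain,
        artifacts={"values": bar.values, "orientation": orientation},
        draw=draw,
        x_ticks=x_ticks,
        y_ticks=y_ticks,
    )
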