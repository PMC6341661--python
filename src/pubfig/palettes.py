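"""The palette registry: 45 named colour schemes and their selection helpers.

The registry spans four kinds:

* 10 **qualitative** schemes for unordered categories (tab10, Set1, Dark2, ...);
* 15 **sequential** schemes for ordered magnitudes (Blues, YlOrRd, ...),
  sampled at 7 steps from the ColorBrewer ramps;
* 10 **diverging** schemes for data with a meaningful midpoint (RdBu, PiYG, ...),
  also 7 steps;
* 10 **use-case** schemes: labelled maps for recurring biological variables —
  chromosomes (1-22, X, Y), SNV mutation types, copy-number classes, the six
  pyrimidine-context base changes, sex, microsatellite status, tissue types,
  tumour stage, risk groups and strand.

Use-case colour assignments are fixed so the same category is always drawn in
the same colour across a project's figures.  ``default_colors`` warns — without
failing — when the scheme subset it returns would not survive greyscale print.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from matplotlib import colormaps

from .colours import (
    Colour,
    Palette,
    greyscale_check,
    parse_colour,
    warn_if_incompatible,
)

__all__ = [
    "default_colors",
    "force_colour_scheme",
    "list_palettes",
    "get_palette",
    "PaletteInfo",
    "ColourSelection",
]

_QUALITATIVE = (
    "tab10",
    "tab20",
    "Set1",
    "Set2",
    "Set3",
    "Dark2",
    "Paired",
    "Accent",
    "Pastel1",
    "Pastel2",
)
_SEQUENTIAL = (
    "Blues",
    "Greens",
    "Reds",
    "Oranges",
    "Purples",
    "Greys",
    "BuGn",
    "BuPu",
    "GnBu",
    "OrRd",
    "PuBu",
    "YlGn",
    "YlGnBu",
    "YlOrBr",
    "YlOrRd",
)
_DIVERGING = (
    "RdBu",
    "RdYlBu",
    "RdYlGn",
    "PiYG",
    "PRGn",
    "BrBG",
    "PuOr",
    "RdGy",
    "Spectral",
    "coolwarm",
)
_RAMP_STEPS = 7  # discretization of continuous ramps


def _rgb255(rgba: Sequence[float]) -> Colour:
    r, g, b = (int(round(255 * float(v))) for v in rgba[:3])
    return Colour(r, g, b)


def _from_listed(name: str, kind: str) -> Palette:
    cmap = colormaps[name]
    return Palette(name, kind, tuple(_rgb255(c) for c in cmap.colors))


def _from_ramp(name: str, kind: str, steps: int = _RAMP_STEPS) -> Palette:
    cmap = colormaps[name]
    pts = np.linspace(0.0, 1.0, steps)
    return Palette(name, kind, tuple(_rgb255(cmap(float(t))) for t in pts))


def _labelled(name: str, pairs: Sequence[tuple[str, str]]) -> Palette:
    labels, hexes = zip(*pairs)
    return Palette(name, "use_case", tuple(parse_colour(h) for h in hexes), labels)


# Chromosome colours: a widely used 24-colour convention for ideogram-style
# plots, one colour per human chromosome.
_CHROMOSOME_COLOURS = [
    ("1", "#996600"), ("2", "#666600"), ("3", "#99991E"), ("4", "#CC0000"),
    ("5", "#FF0000"), ("6", "#FF00CC"), ("7", "#FFCCCC"), ("8", "#FF9900"),
    ("9", "#FFCC00"), ("10", "#FFFF00"), ("11", "#CCFF00"), ("12", "#00FF00"),
    ("13", "#358000"), ("14", "#0000CC"), ("15", "#6699FF"), ("16", "#99CCFF"),
    ("17", "#00FFFF"), ("18", "#CCFFFF"), ("19", "#9900CC"), ("20", "#CC33FF"),
    ("21", "#CC99FF"), ("22", "#666666"), ("X", "#999999"), ("Y", "#CCCCCC"),
]

_USE_CASE_TABLES: dict[str, list[tuple[str, str]]] = {
    "chromosomes": _CHROMOSOME_COLOURS,
    "mutation.types": [
        ("missense", "#2166AC"),
        ("nonsense", "#B2182B"),
        ("frameshift", "#E08214"),
        ("splice", "#542788"),
        ("in.frame.indel", "#1B7837"),
        ("silent", "#BABABA"),
        ("other", "#4D4D4D"),
    ],
    "cna.types": [
        ("gain", "#B2182B"),
        ("neutral", "#F7F7F7"),
        ("loss", "#2166AC"),
    ],
    "base.changes": [
        ("C>A", "#5AB4E5"),
        ("C>G", "#050708"),
        ("C>T", "#D33C32"),
        ("T>A", "#CBCACB"),
        ("T>C", "#ABCD72"),
        ("T>G", "#E7C9C6"),
    ],
    "sex": [
        ("male", "#80B1D3"),
        ("female", "#FB8072"),
    ],
    "msi.status": [
        ("MSI", "#FDB462"),
        ("MSS", "#8DD3C7"),
    ],
    "tissue.types": [
        ("breast", "#CC79A7"),
        ("colon", "#8B4513"),
        ("lung", "#999999"),
        ("prostate", "#0072B2"),
        ("kidney", "#D55E00"),
        ("liver", "#661100"),
        ("brain", "#F0E442"),
        ("blood", "#CC0000"),
        ("skin", "#E69F00"),
        ("ovary", "#009E73"),
    ],
    "tumour.stage": [
        ("I", "#FEE5D9"),
        ("II", "#FCAE91"),
        ("III", "#FB6A4A"),
        ("IV", "#A50F15"),
    ],
    "risk.groups": [
        ("low", "#1A9850"),
        ("intermediate", "#FEE08B"),
        ("high", "#D73027"),
    ],
    "strand": [
        ("+", "#404040"),
        ("-", "#BABABA"),
    ],
}


def _build_registry() -> dict[str, Palette]:
    reg: dict[str, Palette] = {}
    for name in _QUALITATIVE:
        reg[name] = _from_listed(name, "qualitative")
    for name in _SEQUENTIAL:
        reg[name] = _from_ramp(name, "sequential")
    for name in _DIVERGING:
        kind = "diverging"
        cmap = colormaps[name]
        reg[name] = (
            _from_listed(name, kind) if hasattr(cmap, "colors") else _from_ramp(name, kind)
        )
    for name, table in _USE_CASE_TABLES.items():
        reg[name] = _labelled(name, table)
    return reg


_REGISTRY: dict[str, Palette] = _build_registry()
assert len(_REGISTRY) == 45, f"palette registry holds {len(_REGISTRY)}, expected 45"


class PaletteInfo(dict):
    """Inventory entry: ``{"name", "kind", "size"}`` with attribute access."""

    @property
    def name(self) -> str:
        return self["name"]

    @property
    def kind(self) -> str:
        return self["kind"]

    @property
    def size(self) -> int:
        return self["size"]


def list_palettes() -> list[PaletteInfo]:
    """Inventory of all registered palettes (name, kind, size); 45 entries."""
    return [
        PaletteInfo(name=p.name, kind=p.kind, size=len(p)) for p in _REGISTRY.values()
    ]


def get_palette(name: str) -> Palette:
    """Look up a registered palette by name."""
    if name not in _REGISTRY:
        available = ", ".join(sorted(_REGISTRY))
        raise KeyError(f"unknown palette {name!r}; available schemes: {available}")
    return _REGISTRY[name]


class ColourSelection(list):
    """A list of :class:`Colour` that also carries its greyscale report."""

    def __init__(self, colours, report):
        super().__init__(colours)
        self.greyscale_report = report


def default_colors(scheme: str, n: int | None = None) -> ColourSelection:
    """Return the first ``n`` colours of a registered scheme.

    Emits a non-fatal :class:`~pubfig.colours.GreyscaleCompatibilityWarning`
    (and a log record) when the returned subset is not greyscale-compatible;
    the structured report travels on the returned object as
    ``.greyscale_report`` so pipelines can assert on it.
    """
    palette = get_palette(scheme)
    if n is None:
        n = len(palette)
    if not 1 <= n <= len(palette):
        raise ValueError(
            f"requested {n} colours from scheme {scheme!r}; "
            f"must be between 1 and {len(palette)}"
        )
    subset = list(palette.colours[:n])
    report = greyscale_check(subset)
    warn_if_incompatible(scheme, report)
    return ColourSelection(subset, report)


def force_colour_scheme(use_case: str) -> Palette:
    """Return the fixed, labelled palette for a named use case.

    Use cases cover recurring biological variables (chromosomes, mutation
    types, tissue types, sex, microsatellite status, ...) so that a category
    keeps one colour across every figure of a project.
    """
    cases = {name: p for name, p in _REGISTRY.items() if p.kind == "use_case"}
    if use_case not in cases:
        raise KeyError(
            f"unknown use case {use_case!r}; supported use cases: "
            + ", ".join(sorted(cases))
        )
    return cases[use_case]


force_color_scheme = force_colour_scheme  # US-spelling alias
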