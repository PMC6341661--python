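"""Publication style defaults.

The theme collects everything that should be consistent across a project's
figures: output resolution, fonts and their point sizes, tick marks, stroke
widths and the background colour.  The defaults are tuned for print
reproduction — 1600 dpi raster output, visible tick marks, a widely available
sans-serif — so that a figure written with no styling arguments is already
suitable for journal submission.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .colours import Colour, parse_colour

__all__ = ["Theme", "default_theme", "FONT_ROLES"]

#: The text roles whose point sizes a theme controls.
FONT_ROLES = ("title", "axis_label", "tick_label", "legend")


@dataclass(frozen=True)
class Theme:
    """Figure-wide style defaults.

    Parameters
    ----------
    resolution : float
        Raster output resolution in dots per inch.  1600 dpi keeps hairlines
        and small glyphs crisp at journal column widths.
    font_family : str
        Font family for all text; DejaVu Sans ships with matplotlib and is
        therefore available on every platform.
    font_sizes : dict
        Point sizes for the roles in :data:`FONT_ROLES`.
    tick_length : float
        Tick mark length in points.
    tick_visible : bool
        Whether axes draw tick marks (on by default).
    line_width : float
        Default stroke width in points.
    background : Colour
        Panel background.
    padding : float
        Fraction of the data span added on each side when axis limits are
        derived from data (also the shared-axis padding in multi-panel
        figures).
    figure_size : tuple
        Default (width, height) of a single-panel figure in inches.
    """

    resolution: float = 1600.0
    font_family: str = "DejaVu Sans"
    font_sizes: dict = field(
        default_factory=lambda: {
            "title": 12.0,
            "axis_label": 10.0,
            "tick_label": 8.0,
            "legend": 8.0,
        }
    )
    tick_length: float = 3.5
    tick_visible: bool = True
    line_width: float = 1.0
    background: Colour = field(default_factory=lambda: parse_colour("white"))
    padding: float = 0.04
    figure_size: tuple = (6.0, 4.0)

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        missing = [r for r in FONT_ROLES if r not in self.font_sizes]
        if missing:
            raise ValueError(f"font_sizes missing roles: {missing}")
        bad = {k: v for k, v in self.font_sizes.items() if not v > 0}
        if bad:
            raise ValueError(f"font sizes must be positive: {bad}")

    def with_(self, **changes) -> "Theme":
        """A copy of this theme with the given fields replaced."""
        return replace(self, **changes)

    def style_defaults(self) -> dict:
        """The harmonizable style parameters as a flat mapping.

        Keys: ``title_size``, ``axis_label_size``, ``tick_label_size``,
        ``legend_size``, ``line_width``.  Multi-panel composition pushes these
        onto every panel that did not override them explicitly.
        """
        out = {f"{role}_size": float(self.font_sizes[role]) for role in FONT_ROLES}
        out["line_width"] = float(self.line_width)
        return out

    def to_dict(self) -> dict:
        return {
            "resolution": self.resolution,
            "font_family": self.font_family,
            "font_sizes": dict(self.font_sizes),
            "tick_length": self.tick_length,
            "tick_visible": self.tick_visible,
            "line_width": self.line_width,
            "background": self.background.to_hex(),
            "padding": self.padding,
            "figure_size": list(self.figure_size),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Theme":
        d = dict(d)
        if "background" in d:
            d["background"] = parse_colour(d["background"])
        if "figure_size" in d:
            d["figure_size"] = tuple(d["figure_size"])
        return cls(**d)


def default_theme() -> Theme:
    """The publication defaults: 1600 dpi, visible ticks, sans-serif text."""
    return Theme()
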