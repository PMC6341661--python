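"""Colour handling: parsing, grey conversion and greyscale-compatibility checking.

Figures are frequently reproduced in black and white, so a colour scheme is
only as good as its grey rendition.  Every colour is mapped onto a 1-100 grey
scale and any pair of scheme members whose grey values differ by less than a
threshold (default 10) is flagged as not greyscale-compatible.

The grey conversion uses ITU-R BT.601 luma, ``Y = 0.299 R + 0.587 G + 0.114 B``
(on the 0-1 scale), mapped affinely so pure black gives 1 and pure white 100::

    grey = round(1 + 99 * Y)

Luma is the standard perceptual weighting for achromatic reproduction; the
1-100 range makes differences easy to reason about ("ten grey units apart").
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from matplotlib.colors import CSS4_COLORS

__all__ = [
    "Colour",
    "Palette",
    "GreyscaleReport",
    "FlaggedPair",
    "GreyscaleCompatibilityWarning",
    "GREYSCALE_THRESHOLD",
    "parse_colour",
    "to_grey",
    "greyscale_check",
]

logger = logging.getLogger("pubfig.colours")

#: Minimum grey-value separation (on the 1-100 scale) for two colours to be
#: considered distinguishable in greyscale print.  Pairs strictly below this
#: are flagged.
GREYSCALE_THRESHOLD = 10


class GreyscaleCompatibilityWarning(UserWarning):
    """Raised (non-fatally) when a requested colour scheme fails the greyscale check."""


@dataclass(frozen=True, order=True)
class Colour:
    """An RGB colour with 8-bit channels and a fractional alpha.

    Parameters
    ----------
    r, g, b : int
        Channel values in [0, 255].
    alpha : float
        Opacity in [0, 1]; default fully opaque.
    """

    r: int
    g: int
    b: int
    alpha: float = 1.0

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 255:
                raise ValueError(f"channel {name}={v!r} outside [0, 255]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha!r} outside [0, 1]")

    def to_hex(self) -> str:
        """Format as ``#RRGGBB``, or ``#RRGGBBAA`` when not fully opaque."""
        s = f"#{self.r:02X}{self.g:02X}{self.b:02X}"
        if self.alpha < 1.0:
            s += f"{round(self.alpha * 255):02X}"
        return s

    def to_mpl(self) -> tuple[float, float, float, float]:
        """The colour as an (r, g, b, a) tuple on the 0-1 scale matplotlib uses."""
        return (self.r / 255, self.g / 255, self.b / 255, self.alpha)

    @property
    def luma(self) -> float:
        """Relative luma (BT.601) in [0, 1]."""
        return (0.299 * self.r + 0.587 * self.g + 0.114 * self.b) / 255


# Named colours: the CSS/X11 set, case-insensitive.
_NAMED = {name.lower(): hex_ for name, hex_ in CSS4_COLORS.items()}


def parse_colour(spec: str | Colour) -> Colour:
    """Parse a colour string into a :class:`Colour`.

    Accepts ``#RRGGBB`` / ``#RRGGBBAA`` hex strings and the CSS/X11 named
    colours ("white", "firebrick", ...), case-insensitively.  An existing
    :class:`Colour` passes through unchanged.

    Raises
    ------
    ValueError
        If the token is neither valid hex nor a known colour name.
    """
    if isinstance(spec, Colour):
        return spec
    if not isinstance(spec, str):
        raise ValueError(f"colour spec must be a string, got {type(spec).__name__}")
    token = spec.strip()
    if token.lower() in _NAMED:
        token = _NAMED[token.lower()]
    if not token.startswith("#"):
        raise ValueError(
            f"unknown colour name {spec!r}: expected #RRGGBB[AA] hex or a CSS/X11 name"
        )
    body = token[1:]
    if len(body) not in (6, 8) or any(c not in "0123456789abcdefABCDEF" for c in body):
        raise ValueError(f"malformed hex colour {spec!r}: expected #RRGGBB or #RRGGBBAA")
    r, g, b = (int(body[i : i + 2], 16) for i in (0, 2, 4))
    alpha = int(body[6:8], 16) / 255 if len(body) == 8 else 1.0
    return Colour(r, g, b, alpha)


def to_grey(c: Colour | str) -> int:
    """Convert a colour to its grey value on the 1-100 scale.

    Black maps to 1, white to 100, and the mapping is monotone in luma.
    Alpha is ignored.  Rounding is half-up so the result is deterministic
    across platforms.
    """
    c = parse_colour(c)
    return int(math.floor(1 + 99 * c.luma + 0.5))


@dataclass(frozen=True)
class Palette:
    """A named, ordered colour scheme.

    ``kind`` classifies the scheme: ``qualitative`` (unordered categories),
    ``sequential`` (ordered low-to-high), ``diverging`` (ordered about a
    midpoint) or ``use_case`` (a labelled map for a specific biological
    variable such as chromosomes or mutation types).
    """

    name: str
    kind: str
    colours: tuple[Colour, ...]
    labels: tuple[str, ...] | None = None

    KINDS = ("qualitative", "sequential", "diverging", "use_case")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"palette kind {self.kind!r} not in {self.KINDS}")
        if len(self.colours) == 0:
            raise ValueError(f"palette {self.name!r} is empty")
        if self.labels is not None and len(self.labels) != len(self.colours):
            raise ValueError(
                f"palette {self.name!r}: {len(self.labels)} labels for "
                f"{len(self.colours)} colours"
            )

    def __len__(self) -> int:
        return len(self.colours)

    def __iter__(self):
        return iter(self.colours)

    def __getitem__(self, i):
        return self.colours[i]

    def to_dict(self) -> dict:
        d: dict = {
            "name": self.name,
            "kind": self.kind,
            "colours": [c.to_hex() for c in self.colours],
        }
        if self.labels is not None:
            d["labels"] = list(self.labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Palette":
        return cls(
            name=d["name"],
            kind=d["kind"],
            colours=tuple(parse_colour(h) for h in d["colours"]),
            labels=tuple(d["labels"]) if d.get("labels") is not None else None,
        )


class FlaggedPair(NamedTuple):
    """One colour pair too close in grey value to survive black-and-white print."""

    index_a: int
    index_b: int
    grey_a: int
    grey_b: int
    difference: int


@dataclass(frozen=True)
class GreyscaleReport:
    """Outcome of a greyscale-compatibility check.

    ``compatible`` is true exactly when ``flagged_pairs`` is empty; each
    flagged pair records the two palette indices, their grey values and the
    (sub-threshold) absolute difference.
    """

    compatible: bool
    flagged_pairs: tuple[FlaggedPair, ...] = field(default_factory=tuple)
    threshold: int = GREYSCALE_THRESHOLD

    def __post_init__(self) -> None:
        assert self.compatible == (len(self.flagged_pairs) == 0)


def greyscale_check(
    palette: Palette | Sequence[Colour | str], threshold: int = GREYSCALE_THRESHOLD
) -> GreyscaleReport:
    """Check whether a colour scheme survives conversion to greyscale.

    Every unordered pair of distinct entries is compared — any two scheme
    colours may end up side by side in a figure — and a pair is flagged when
    its grey values differ by strictly less than ``threshold``.  A singleton
    palette is trivially compatible.
    """
    colours: Iterable = palette.colours if isinstance(palette, Palette) else palette
    greys = [to_grey(c) for c in colours]
    if not greys:
        raise ValueError("greyscale_check requires at least one colour")
    flagged = []
    for i in range(len(greys)):
        for j in range(i + 1, len(greys)):
            diff = abs(greys[i] - greys[j])
            if diff < threshold:
                flagged.append(FlaggedPair(i, j, greys[i], greys[j], diff))
    return GreyscaleReport(
        compatible=not flagged, flagged_pairs=tuple(flagged), threshold=threshold
    )


def warn_if_incompatible(name: str, report: GreyscaleReport) -> None:
    """Emit the non-fatal greyscale warning through both channels (warnings + logging)."""
    if report.compatible:
        return
    msg = (
        f"colour scheme {name!r} is not grey-scale compatible: "
        f"{len(report.flagged_pairs)} colour pair(s) differ by < "
        f"{report.threshold} grey units (e.g. indices "
        f"{report.flagged_pairs[0].index_a} and {report.flagged_pairs[0].index_b}, "
        f"greys {report.flagged_pairs[0].grey_a} vs {report.flagged_pairs[0].grey_b})"
    )
    logger.warning(msg)
    warnings.warn(msg, GreyscaleCompatibilityWarning, stacklevel=3)


def palettes_to_json(palettes: Iterable[Palette]) -> str:
    """Serialize palettes to a JSON document (name, kind, hex list, labels)."""
    return json.dumps([p.to_dict() for p in palettes], indent=2)


def palettes_from_json(text: str) -> list[Palette]:
    """Inverse of :func:`palettes_to_json`."""
    return [Palette.from_dict(d) for d in json.loads(text)]
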