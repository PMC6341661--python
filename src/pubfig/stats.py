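"""Statistical primitives behind the chart builders.

These are the numeric computations the charts visualize — box-and-whisker
summaries, kernel density estimates, hexagonal binning, quantile pairing for
Q-Q plots, cumulative genome coordinates for Manhattan plots, and p-value
formatting.  They are exposed directly so their output can be tested (and
reused) without rendering anything.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

__all__ = [
    "BoxStatistics",
    "box_statistics",
    "density_estimate",
    "silverman_bandwidth",
    "hexbin",
    "hex_lattice",
    "qq_fit_points",
    "qq_comparison_points",
    "manhattan_coords",
    "format_scientific",
    "ScientificText",
]


# ---------------------------------------------------------------------------
# box-and-whisker
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoxStatistics:
    """Five-number summary plus whisker extents and outliers."""

    median: float
    lower_hinge: float
    upper_hinge: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


def _hinges(x: np.ndarray, method: str) -> tuple[float, float]:
    n = len(x)
    if method == "exclusive":
        # Medians of the lower/upper halves, excluding the overall median
        # when n is odd (Moore-McCabe quartiles).
        half = n // 2
        lower = x[:half]
        upper = x[n - half :]
        if half == 0:  # n == 1
            return float(x[0]), float(x[0])
        return float(np.median(lower)), float(np.median(upper))
    if method == "tukey":
        # Tukey hinges: halves include the median when n is odd.
        d = (math.floor((n + 1) / 2) + 1) / 2
        lo = 0.5 * (x[math.floor(d) - 1] + x[math.ceil(d) - 1])
        hi = 0.5 * (x[n - math.floor(d)] + x[n - math.ceil(d)])
        return float(lo), float(hi)
    if method == "linear":
        return float(np.quantile(x, 0.25)), float(np.quantile(x, 0.75))
    raise ValueError(f"unknown quartile method {method!r}; use exclusive, tukey or linear")


def box_statistics(
    values: Sequence[float], whisker: float = 1.5, method: str = "exclusive"
) -> BoxStatistics:
    """Five-number summary with 1.5·IQR whiskers.

    Hinges default to medians of the half-samples excluding the overall
    median; ``method`` switches to Tukey hinges (halves include the median)
    or linear-interpolation quartiles.  Whiskers extend to the most extreme
    data point within ``whisker``·IQR of the hinges; everything beyond is an
    outlier.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("box_statistics requires at least one finite value")
    x = np.sort(x)
    med = float(np.median(x))
    lh, uh = _hinges(x, method)
    iqr = uh - lh
    lo_fence = lh - whisker * iqr
    hi_fence = uh + whisker * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    outliers = tuple(float(v) for v in x[(x < lo_fence) | (x > hi_fence)])
    return BoxStatistics(
        median=med,
        lower_hinge=lh,
        upper_hinge=uh,
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# kernel density estimation
# ---------------------------------------------------------------------------


def silverman_bandwidth(values: Sequence[float]) -> float:
    """Silverman's rule of thumb: ``0.9 min(sd, IQR/1.34) n^(-1/5)``.

    Falls back to the remaining non-zero spread measure (or a small positive
    constant for zero-spread data) so the estimate is always well defined.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.quantile(x, 0.75) - np.quantile(x, 0.25))
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0.0:
        spread = max(abs(float(np.mean(x))) * 1e-3, 1e-3)
    return 0.9 * spread * n ** (-0.2)


def density_estimate(
    values: Sequence[float],
    bandwidth: float | None = None,
    gridsize: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density on a regular grid.

    The grid spans the data range extended by three bandwidths on each side,
    so the density has decayed essentially to zero at the grid edges and the
    trapezoid integral is ~1.  Bandwidth defaults to Silverman's rule.
    Returns ``(grid, density)``.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("density_estimate requires at least 2 finite values")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(x)
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    grid = np.linspace(x.min() - 3 * bandwidth, x.max() + 3 * bandwidth, gridsize)
    z = (grid[:, None] - x[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bandwidth * math.sqrt(2 * math.pi))
    return grid, dens


# ---------------------------------------------------------------------------
# hexagonal binning
# ---------------------------------------------------------------------------


def hex_lattice(
    extent: tuple[float, float, float, float], nbins: int
) -> tuple[np.ndarray, float, float]:
    """Centres of a pointy-top hexagonal lattice covering ``extent``.

    The lattice is anchored at the extent's lower-left corner; columns are
    spaced ``width / nbins`` apart, odd rows shifted half a column, rows
    spaced ``dx * sqrt(3) / 2``.  Centres are returned row-major (bottom row
    first), which defines the index order used for tie-breaking.
    """
    xmin, xmax, ymin, ymax = extent
    dx = (xmax - xmin) / nbins
    dy = dx * math.sqrt(3) / 2
    n_rows = int(math.ceil((ymax - ymin) / dy)) + 1
    centres = []
    for j in range(n_rows):
        shift = 0.5 * dx if j % 2 else 0.0
        n_cols = nbins + 1
        for i in range(n_cols):
            centres.append((xmin + i * dx + shift, ymin + j * dy))
    return np.asarray(centres), dx, dy


def hexbin(
    points: Sequence[tuple[float, float]],
    nbins: int,
    extent: tuple[float, float, float, float] | None = None,
) -> list[tuple[tuple[float, float], int]]:
    """Assign points to a regular pointy-top hexagonal lattice.

    Each point goes to the nearest lattice centre (Euclidean), ties broken
    toward the lower lattice index.  Only non-empty hexagons are returned, in
    lattice-index order, as ``((centre_x, centre_y), count)``.

    When ``extent`` is omitted it is taken from the data; a zero span in
    either direction is widened by ±0.5 so coincident points still bin.  An
    explicitly supplied degenerate extent is rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("hexbin requires at least one point")
    pts = pts.reshape(-1, 2)
    if nbins < 1:
        raise ValueError(f"nbins must be >= 1, got {nbins}")
    if extent is not None:
        xmin, xmax, ymin, ymax = extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate extent {extent}: zero width or height")
    else:
        xmin, xmax = float(pts[:, 0].min()), float(pts[:, 0].max())
        ymin, ymax = float(pts[:, 1].min()), float(pts[:, 1].max())
        if xmax == xmin:
            xmin, xmax = xmin - 0.5, xmax + 0.5
        if ymax == ymin:
            ymin, ymax = ymin - 0.5, ymax + 0.5
    centres, dx, dy = hex_lattice((xmin, xmax, ymin, ymax), nbins)

    # Candidate search over the neighbouring rows/columns of each point;
    # exact nearest-centre with deterministic lower-index tie-break.
    n_cols = nbins + 1
    counts: dict[int, int] = {}
    n_rows = len(centres) // n_cols
    for x, y in pts:
        j0 = int(round((y - ymin) / dy))
        best = None
        for j in range(max(0, j0 - 2), min(n_rows, j0 + 3)):
            shift = 0.5 * dx if j % 2 else 0.0
            i0 = int(round((x - xmin - shift) / dx))
            for i in range(max(0, i0 - 2), min(n_cols, i0 + 3)):
                idx = j * n_cols + i
                cx, cy = centres[idx]
                d2 = (x - cx) ** 2 + (y - cy) ** 2
                if best is None or d2 < best[0] - 1e-12 or (
                    abs(d2 - best[0]) <= 1e-12 and idx < best[1]
                ):
                    best = (d2, idx)
        counts[best[1]] = counts.get(best[1], 0) + 1
    return [
        ((float(centres[i, 0]), float(centres[i, 1])), counts[i])
        for i in sorted(counts)
    ]


# ---------------------------------------------------------------------------
# quantile-quantile pairing
# ---------------------------------------------------------------------------


def qq_fit_points(
    sample: Sequence[float], distribution: str, params: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical quantiles of a named scipy distribution vs. order statistics.

    Plotting positions are ``(i - 0.5) / n``.  Returns ``(theoretical,
    observed)`` arrays.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size < 2:
        raise ValueError("qq plots require a sample of at least 2 values")
    try:
        dist = getattr(scipy.stats, distribution)
    except AttributeError:
        raise ValueError(f"unknown distribution {distribution!r}") from None
    params = dict(params or {})
    pp = (np.arange(1, x.size + 1) - 0.5) / x.size
    theo = dist.ppf(pp, **params)
    return theo, x


def qq_comparison_points(
    a: Sequence[float], b: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Pair two samples quantile-by-quantile.

    Equal lengths: sorted values are paired directly.  Unequal: the longer
    sample's order statistics are linearly interpolated down to the shorter
    length, so the number of plotted points equals the shorter sample size.
    Returns ``(qa, qb)``.
    """
    xa = np.sort(np.asarray(a, dtype=float))
    xb = np.sort(np.asarray(b, dtype=float))
    if xa.size < 2 or xb.size < 2:
        raise ValueError("qq plots require samples of at least 2 values")

    def shrink(long: np.ndarray, n: int) -> np.ndarray:
        return np.interp(
            np.linspace(0.0, 1.0, n), np.linspace(0.0, 1.0, long.size), long
        )

    if xa.size > xb.size:
        xa = shrink(xa, xb.size)
    elif xb.size > xa.size:
        xb = shrink(xb, xa.size)
    return xa, xb


# ---------------------------------------------------------------------------
# Manhattan coordinates
# ---------------------------------------------------------------------------


def manhattan_coords(
    chromosome: Sequence,
    position: Sequence[int],
    p_value: Sequence[float],
    chrom_order: Sequence,
    chrom_lengths: dict | None = None,
):
    """Cumulative genome x-coordinates and ``-log10(p)`` heights.

    Chromosomes are laid end to end in ``chrom_order``; each chromosome's
    span is its supplied length, or the maximum observed position when
    lengths are not given, with no gap between chromosomes.  Positions are
    1-based.  Returns ``(x, y, chrom_ticks)`` where ``chrom_ticks`` maps each
    chromosome to the x midpoint of its span.
    """
    chrom = np.asarray(chromosome)
    pos = np.asarray(position, dtype=float)
    p = np.asarray(p_value, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        bad = p[(p <= 0) | (p > 1)][0]
        raise ValueError(f"p-values must lie in (0, 1]; got {bad}")
    if np.any(pos < 1):
        raise ValueError("genomic positions are 1-based and must be >= 1")
    known = set(chrom_order)
    unknown = sorted({str(c) for c in chrom if c not in known})
    if unknown:
        raise ValueError(
            f"chromosome(s) {unknown} absent from chrom_order {list(chrom_order)}"
        )
    spans = {}
    for c in chrom_order:
        if chrom_lengths and c in chrom_lengths:
            spans[c] = float(chrom_lengths[c])
        else:
            mask = chrom == c
            spans[c] = float(pos[mask].max()) if mask.any() else 0.0
    offsets = {}
    running = 0.0
    ticks = {}
    for c in chrom_order:
        offsets[c] = running
        ticks[c] = running + spans[c] / 2
        running += spans[c]
    x = np.array([offsets[c] for c in chrom]) + pos
    y = -np.log10(p)
    return x, y, ticks


# ---------------------------------------------------------------------------
# scientific notation for p-values
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScientificText:
    """A number formatted for display, either plain or as ``m × 10^e``."""

    text: str
    is_scientific: bool
    mantissa: float | None = None
    exponent: int | None = None

    def mathtext(self) -> str:
        """Matplotlib mathtext rendering of the value."""
        if self.is_scientific:
            return rf"${self.mantissa:g} \times 10^{{{self.exponent}}}$"
        return f"${self.text}$"


def format_scientific(
    x: float, threshold_exponent: int = -2, sig_digits: int = 2
) -> ScientificText:
    """Format a positive number, switching to ``m × 10^e`` for small values.

    Values whose decimal exponent (``floor(log10 x)``) is below
    ``threshold_exponent`` are decomposed into a mantissa in [1, 10) rounded
    to ``sig_digits`` significant digits and an integer exponent; larger
    values stay plain decimals.  Designed for p-value annotation, where
    0.03 should print as-is but 3.2e-5 should not.
    """
    if not x > 0:
        raise ValueError(f"format_scientific requires x > 0, got {x}")
    exponent = math.floor(math.log10(x))
    if exponent >= threshold_exponent:
        return ScientificText(text=f"{x:g}", is_scientific=False)
    mantissa = round(x / 10**exponent, sig_digits - 1)
    if mantissa >= 10:  # rounding pushed it out of [1, 10)
        mantissa /= 10
        exponent += 1
    return ScientificText(
        text=f"{mantissa:g} x 10^{exponent}",
        is_scientific=True,
        mantissa=mantissa,
        exponent=exponent,
    )
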