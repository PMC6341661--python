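# Methods

This note documents the conventions, formulas and design choices behind
pubfig, in the spirit of a statistical software methods section. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Grey conversion and greyscale compatibility

Figures are routinely reproduced in black and white, so every palette is
checkable for greyscale survival. A colour is reduced to relative luma
under ITU-R BT.601 weighting,

    Y = (0.299 R + 0.587 G + 0.114 B) / 255,   Y ∈ [0, 1]

and mapped affinely onto an integer 1–100 scale, `grey = round(1 + 99·Y)`
(half-up rounding, so results are platform-independent). Pure black gives 1
and pure white 100, and the map is monotone in luma. Luma was chosen over a
plain channel average because it matches how achromatic reproduction and
human brightness perception weight the channels; the 1–100 range makes
differences directly interpretable.

The compatibility check compares **all unordered pairs** of a scheme — any
two scheme colours can end up adjacent in a figure, so checking only
neighbouring palette entries would under-flag. A pair is flagged when its
grey values differ by **strictly less than 10** units; 10 or more passes.
The threshold is exposed as a parameter (`greyscale_check(…, threshold=…)`)
but the default is the one used throughout. `default_colors` runs the check
on exactly the subset of colours it returns and reports failure through
three channels at once: a `GreyscaleCompatibilityWarning`, a log record,
and a structured `GreyscaleReport` attached to the returned selection, so
interactive users see it and pipelines can assert on it.

## The palette registry

The registry holds 45 schemes: 10 qualitative (tab10/tab20 and the
ColorBrewer qualitative families), 15 sequential and 10 diverging
(ColorBrewer ramps discretized at 7 steps), and 10 labelled use-case maps
(human chromosomes 1–22/X/Y, SNV mutation types, CNA classes, the six
pyrimidine-context base changes, sex, microsatellite status, tissue types,
tumour stage, risk groups, strand). Use-case maps are labelled so a
category keeps one colour across every figure of a project. The individual
colour values of the use-case maps are this package's own choices,
following widely used community conventions where they exist (e.g. the
ideogram chromosome colours, the COSMIC-style base-change hues).

## Chart statistics

**Boxplots.** Hinges default to the medians of the lower and upper
half-samples *excluding* the overall median when n is odd (Moore–McCabe
quartiles); `method="tukey"` (halves include the median) and
`method="linear"` (linear-interpolation quantiles) are available because no
single convention is universal. Whiskers extend to the most extreme data
point within 1.5·IQR of the hinges; everything beyond is drawn as an
outlier point.

**Kernel density estimates** (used by the density and violin builders) are
Gaussian-kernel sums on a regular 512-point grid spanning the data range
extended by three bandwidths per side, so the density has decayed to
numerical zero at the grid edges and the trapezoid integral is 1 within
1e-3. The bandwidth default is Silverman's rule,
`0.9·min(sd, IQR/1.34)·n^(−1/5)`, falling back to the remaining positive
spread measure (or a small constant) for degenerate samples.

**Q–Q plots.** Fit mode plots order statistics against theoretical
quantiles at plotting positions `(i − 0.5)/n`, with a reference line
through the first- and third-quartile points (robust to tail departures).
Comparison mode pairs sorted samples directly when lengths match and
linearly interpolates the longer sample's order statistics down to the
shorter length otherwise; the reference is the identity line.

**Manhattan plots.** Chromosomes are laid end to end in the caller's
order with *zero gap*; each chromosome's span is its supplied length or,
by default, the maximum observed position. x is the chromosome offset plus
the 1-based position; y is exactly −log10(p). Ticks sit at chromosome
midpoints; colouring alternates two blues by default, or walks a named
palette. p-values outside (0, 1] and chromosomes missing from the order are
rejected rather than silently dropped.

**Hexagonal binning** uses a pointy-top lattice anchored at the extent's
lower-left corner: column spacing `dx = width/nbins`, odd rows shifted
`dx/2`, row spacing `dx·√3/2`. Each point is assigned to its nearest
lattice centre (a local candidate search over the neighbouring rows and
columns, exact because a point's nearest centre cannot be further away);
distance ties break to the lower lattice index, deterministically. When the
extent is derived from data, a zero span is widened by ±0.5 so coincident
points still bin; an explicitly supplied degenerate extent is an error.

**Scientific notation.** Values with `floor(log10 x) < −2` are decomposed
into a 2-significant-digit mantissa in [1, 10) and an integer exponent
(with carry when rounding pushes the mantissa to 10); larger values print
as plain decimals, so 0.05 stays `0.05` while 3.2e-5 becomes `3.2 × 10⁻⁵`.

## Multi-panel composition

The figure minus fixed label gutters is divided into grid cells
proportional to the layout's row/column weights, with a configurable
inter-panel gap (default 1 % of the figure dimension); every panel's axes
rectangle is exactly its cell span. Because two panels in one grid column
therefore occupy identical horizontal extents, shared-axis alignment
reduces to giving them identical limits — alignment is geometric, never
post-hoc image shifting.

Shared numeric limits are the union of the group's data ranges padded by
4 % of the union span per side (a rule that never clips any member's data);
shared categorical axes require an identical category order and use it
directly. Matrix-style panels (heatmap, dotmap) draw row 0 at the top; if
one sits in a shared-y group the whole group inverts so rows stay aligned.
Under the default `edge` label policy only the bottom panel of a shared-x
group and the left-most panel of a shared-y group draw tick labels.

Harmonization pushes the figure theme's font sizes and line width onto
every panel that did not override them explicitly; explicit overrides
survive, and the operation is idempotent.

## Output and provenance

The output format is dispatched on the file extension alone. Rasters are
written at the theme's resolution — 1600 dpi by default, chosen for crisp
hairlines at journal column widths, and applied uniformly to TIFF and PNG —
with the dpi recorded in the container's resolution tags; PDF and SVG keep
resolution-independent geometry but record the nominal dpi in metadata.
Every write embeds a provenance record (software version, OS description,
ISO-8601 timestamp, SHA-256 digest of the canonical spec JSON) as a single
JSON object in the format's native metadata slot: TIFF ImageDescription,
PNG tEXt chunk, the PDF information dictionary (with post-hoc embedding
implemented as a standard PDF incremental update), and an SVG `<metadata>`
element. The timestamp is injectable so writes can be made byte-reproducible;
the default is the UTC wall clock. SVG element ids are salted with the spec
digest so vector output is deterministic too.

## Declarative specs

Documents are JSON (YAML accepted on input) with a mandatory version field,
validated against the schema in `pubfig/schema/plotspec-v1.json`; unknown
fields are rejected with the offending field path. Data is referenced by
name, never embedded, keeping specs small and diffable. Serialization uses
fixed field order, so saving is deterministic. `emit_code` produces a
Python script in pubfig's own API — one builder call per panel plus one
compose call — that reproduces the figure byte-identically when the
timestamp is pinned.

## The synthetic cohort generator

`make_mutation_dataset` draws a genes × patients cohort with independent
per-cell events: an SNV with probability `p_snv` and a CNA with probability
`p_cna` (defaults 0.1 and 0.05 over 20 genes × 40 patients — rates that
give the sparse, oncoprint-like occupancy typical of driver-gene panels).
SNV types follow a missense-dominated categorical distribution, base
changes a C>T-dominated one over the six pyrimidine-context classes, and
clinical covariates (sex, stage, MSI status) realistic marginal
frequencies. All derived summaries — per-gene alteration percentage,
per-patient SNV/CNA counts, per-patient base-change proportions as a
fraction of total mutation count — are recomputed from the matrices, never
sampled, so the multi-panel figure is internally consistent by
construction.

The generator emulates structure, not biology: it has no mutual
exclusivity between drivers, no patient-level burden heterogeneity, no
covariate–genotype correlation, and no linkage between CNA segments.
Passing tests therefore demonstrate the plotting and summarization
machinery, not fidelity to any real cohort.

## Problem sizes and determinism

The test suite works at deliberately small sizes — gallery datasets of
60–510 observations, a 20 × 40 cohort, rasters of a few hundred pixels —
because every property tested (conservation, oracle equivalence, alignment,
round-trips) is size-independent. All randomness flows through explicitly
seeded `numpy` generators; two runs with the same seed produce identical
datasets, panels and (with a pinned timestamp) identical output bytes.

## Known limitations

Heatmaps draw the matrix in the caller's row/column order; clustering and
dendrograms are out of scope. There is no colour-blindness simulation
beyond the greyscale check, no EPS/JPEG output, no colour-profile
management, and no freeform (non-grid) panel placement. PDF metadata uses
the classic information dictionary rather than XMP. The dotmap draws
circles in data coordinates, so strongly non-square cells render them as
ellipses; layouts that keep cells near-square (as the cohort figure does)
avoid this.
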