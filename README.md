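# pubfig

Publication-quality scientific figure generation for Python, aimed at
computational biologists who build figures inside analysis pipelines and
need them reproducible, print-ready and consistent across a project.

The library provides:

* **Fifteen chart builders** — density, boxplot, violin, segplot, strip
  plot, barplot, scatterplot, histogram, Q–Q fit and Q–Q comparison plots,
  Manhattan plot, polygon plot, heatmap, hexagonally binned scatterplot and
  the **dotmap**: a grid of circles inset inside a matrix encoding up to
  four dimensions (row, column, cell category, dot category/size), used as
  an oncoprint-style mutation grid where shaded cells carry SNV types and
  inset dots copy-number changes.
* **Multi-panel composition** with pixel-exact shared-axis alignment and
  figure-level style harmonization: panels in a shared group get joint axis
  limits (the union of their data ranges plus 4 % padding) and identical
  canvas spans, so a data value maps to the same pixel in every panel.
* **A colour system** of 45 named palettes (qualitative, sequential,
  diverging, and labelled use-case maps for chromosomes, mutation types,
  tissue types, sex, microsatellite status, …) with a greyscale-compatibility
  check: each colour is converted to a grey value on a 1–100 scale,
  `grey = round(1 + 99·Y)` with BT.601 luma `Y = 0.299R + 0.587G + 0.114B`,
  and any colour pair whose greys differ by **less than 10** is flagged as
  not safe for black-and-white print. `default_colors` warns (non-fatally)
  whenever a requested scheme fails this check.
* **Publication output defaults** — 1600 dpi rasters with the resolution
  written into the file's tags, format chosen purely by the output
  extension (`.tiff`/`.tif`, `.png`, `.pdf`, `.svg`) — and **provenance
  metadata** (software version, OS, timestamp, spec digest) embedded in
  every file and recoverable from it.
* **Declarative figure specs** (JSON, YAML accepted) that round-trip
  losslessly, render via library or CLI, and from which the library can
  emit a runnable reproduction script or a manuscript methods paragraph.

## Worked example

```python
from pubfig import write_figure
from pubfig.fixtures import cohort_figure, make_mutation_dataset

ds = make_mutation_dataset(n_genes=20, n_patients=40,
                           p_snv=0.1, p_cna=0.05, seed=42)
counts = ds.derived["per_patient_counts"]
print(f"total SNVs {int(counts['snv'].sum())}, total CNAs {int(counts['cna'].sum())}")
fig = cohort_figure(ds)          # six aligned panels
write_figure(fig, "cohort_figure.png")
```

prints

```
total SNVs 80, total CNAs 30
```

and writes the six-panel cohort figure: a central dotmap of the 20 × 40
mutation matrix, a clinical covariate heatmap below it (sex, stage,
microsatellite status), a horizontal barplot of the per-gene alteration
percentage on the right (here topped by GENE11 at 25.0 % of patients), and
stacked barplots of per-patient mutation counts and base-change proportions
above — every panel sharing the patient axis pixel-for-pixel. The derived
numbers are recomputed from the matrices, never sampled, so the panels are
internally consistent by construction.

The greyscale check in action:

```python
from pubfig import default_colors, to_grey
sel = default_colors("Set1", 9)       # warns: not grey-scale compatible
print([to_grey(c) for c in sel])      # [35, 44, 53, 44, 60, 91, 42, 68, 60]
print(sel.greyscale_report.compatible)  # False — 13 pairs closer than 10
```

More narrative walk-throughs live in `examples/` (gallery of all fifteen
chart types, the cohort multiplot, palettes and greyscale, spec round-trip
with code emission); run each with `python examples/<name>.py`.

The CLI renders spec documents directly:

```bash
pubfig render --spec manhattan.json --data points.csv=manhattan --output fig.tiff
pubfig palettes
```

## Documentation

`docs/methods.md` describes the models and conventions behind the package:
the grey-conversion formula, boxplot hinge conventions, KDE bandwidth rule,
hexagonal-lattice geometry, shared-axis resolution, what the synthetic
cohort generator does and does not emulate, and the numerical choices made
where the design was open.
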