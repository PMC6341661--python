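"""Render the full chart-type gallery from generated example data.

Builds every one of the fifteen chart types from the deterministic example
generators and writes them as one PNG each.  The printed numbers are the
computed artifacts behind two of the panels: the five-number summary a
boxplot draws, and the hexagon counts of the binned scatterplot (which must
sum to the number of input points).
"""

from pathlib import Path

from pubfig import create_chart, default_theme, single_panel_figure, write_figure
from pubfig.fixtures import fig1_gallery

out = Path("gallery_output")
out.mkdir(exist_ok=True)
theme = default_theme().with_(figure_size=(3.2, 2.4), resolution=200)

gallery = fig1_gallery(seed=42)
for name, (spec, data) in gallery.items():
    panel = create_chart(spec, data)
    write_figure(single_panel_figure(panel, theme=theme), out / f"{name}.png")

box = create_chart(*gallery["boxplot"]).artifacts["stats"]
print("boxplot five-number summaries per group:")
for group, s in box.items():
    print(
        f"  {group:>10}: median {s.median:6.3f}, hinges "
        f"[{s.lower_hinge:6.3f}, {s.upper_hinge:6.3f}], "
        f"{len(s.outliers)} outlier(s)"
    )

hexes = create_chart(*gallery["hexbinplot"]).artifacts
total = sum(c for _, c in hexes["cells"])
print(
    f"hexbinplot: {len(hexes['cells'])} occupied hexagons, counts sum to "
    f"{total} of {hexes['n_points']} points"
)
print(f"wrote {len(gallery)} charts to {out}/")
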