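"""Inspect the palette registry and the greyscale-compatibility check.

Lists the registry inventory, converts one palette to its 1-100 grey values
and reports which colour pairs would be indistinguishable in black-and-white
print (grey difference below 10).
"""

import warnings

from pubfig import default_colors, force_colour_scheme, greyscale_check, to_grey
from pubfig.palettes import list_palettes

info = list_palettes()
by_kind = {}
for entry in info:
    by_kind.setdefault(entry["kind"], []).append(entry["name"])
print(f"{len(info)} registered palettes:")
for kind, names in sorted(by_kind.items()):
    print(f"  {kind:<12} {len(names):>2}: {', '.join(names[:6])}, ...")

chroms = force_colour_scheme("chromosomes")
print(f"\nchromosome palette: {len(chroms)} labelled colours "
      f"({chroms.labels[0]}..{chroms.labels[-1]})")

with warnings.catch_warnings(record=True) as caught:
    warnings.simplefilter("always")
    selection = default_colors("Set1", 9)
report = selection.greyscale_report
greys = [to_grey(c) for c in selection]
print(f"\nSet1 grey values (1-100 scale): {greys}")
print(f"greyscale compatible: {report.compatible}; "
      f"{len(report.flagged_pairs)} pair(s) closer than {report.threshold} grey units")
for p in report.flagged_pairs[:4]:
    print(f"  colours {p.index_a} and {p.index_b}: greys {p.grey_a} vs {p.grey_b} "
          f"(difference {p.difference})")
if caught:
    print(f"(a {type(caught[0].message).__name__} was emitted, as expected)")
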