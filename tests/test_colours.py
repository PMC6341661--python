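"""Colour parsing, grey conversion and the greyscale-compatibility check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pubfig.colours import (
    Colour,
    GreyscaleCompatibilityWarning,
    Palette,
    greyscale_check,
    palettes_from_json,
    palettes_to_json,
    parse_colour,
    to_grey,
)
from pubfig.palettes import (
    default_colors,
    force_colour_scheme,
    get_palette,
    list_palettes,
)

channels = st.integers(min_value=0, max_value=255)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("#FF0000", (255, 0, 0, 1.0)),
        ("#ff0000", (255, 0, 0, 1.0)),
        ("white", (255, 255, 255, 1.0)),
        ("WHITE", (255, 255, 255, 1.0)),
        ("#80808080", (128, 128, 128, 128 / 255)),
    ],
)
def test_parse_colour_decomposition(text, expected):
    c = parse_colour(text)
    assert (c.r, c.g, c.b, c.alpha) == expected


@pytest.mark.parametrize("bad", ["#12345", "#GG0000", "notacolour", ""])
def test_parse_colour_rejects_malformed(bad):
    with pytest.raises(ValueError, match="colour"):
        parse_colour(bad)


@given(r=channels, g=channels, b=channels, a=st.integers(0, 255))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_parse_format_roundtrip(r, g, b, a):
    c = Colour(r, g, b, a / 255)
    assert parse_colour(c.to_hex()) == c


def test_grey_scale_endpoints():
    assert to_grey(Colour(0, 0, 0)) == 1
    assert to_grey(Colour(255, 255, 255)) == 100


def test_grey_mid_value():
    # Y = 128/255, grey = round(1 + 99 * Y) = 51
    assert to_grey(Colour(128, 128, 128)) == 51


@given(
    a=st.tuples(channels, channels, channels),
    b=st.tuples(channels, channels, channels),
)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_grey_monotone_in_luma_and_in_range(a, b):
    ca, cb = Colour(*a), Colour(*b)
    ga, gb = to_grey(ca), to_grey(cb)
    assert 1 <= ga <= 100 and 1 <= gb <= 100
    if ca.luma <= cb.luma:
        assert ga <= gb


def _brute_force_check(colours, threshold=10):
    """Independent oracle: enumerate all pairs directly."""
    greys = [to_grey(c) for c in colours]
    flagged = [
        (i, j)
        for i in range(len(greys))
        for j in range(i + 1, len(greys))
        if abs(greys[i] - greys[j]) < threshold
    ]
    return flagged


def test_greyscale_check_black_white_compatible():
    report = greyscale_check([Colour(0, 0, 0), Colour(255, 255, 255)])
    assert report.compatible and report.flagged_pairs == ()


def test_greyscale_check_identical_pair_flagged():
    c = Colour(10, 120, 200)
    report = greyscale_check([c, c])
    assert not report.compatible
    (pair,) = report.flagged_pairs
    assert (pair.index_a, pair.index_b, pair.difference) == (0, 1, 0)


def test_greyscale_check_matches_brute_force_oracle():
    rng = np.random.default_rng(20190121)
    for _ in range(1000):
        size = int(rng.integers(1, 13))
        colours = [
            Colour(int(r), int(g), int(b))
            for r, g, b in rng.integers(0, 256, size=(size, 3))
        ]
        report = greyscale_check(colours)
        expected = _brute_force_check(colours)
        got = [(p.index_a, p.index_b) for p in report.flagged_pairs]
        assert got == expected
        assert report.compatible == (not expected)


def test_greyscale_flagging_boundary_is_exactly_ten():
    # grey values hit every integer in 1..100 over the 0..255 grey ramp
    grey_of = {}
    for v in range(256):
        grey_of.setdefault(to_grey(Colour(v, v, v)), v)
    base = grey_of[1]
    outcomes = {}
    for d in range(1, 31):
        partner = grey_of[1 + d]
        report = greyscale_check(
            [Colour(base, base, base), Colour(partner, partner, partner)]
        )
        outcomes[d] = report.compatible
    assert min(d for d, ok in outcomes.items() if ok) == 10
    assert all(not outcomes[d] for d in range(1, 10))
    assert all(outcomes[d] for d in range(10, 31))


def test_registry_holds_45_unique_palettes_of_known_kinds():
    info = list_palettes()
    assert len(info) == 45
    names = [i["name"] for i in info]
    assert len(set(names)) == 45
    assert {i["kind"] for i in info} <= {
        "qualitative", "sequential", "diverging", "use_case"
    }
    # all four kinds are represented
    assert {i["kind"] for i in info} == {
        "qualitative", "sequential", "diverging", "use_case"
    }


import warnings as _warnings


def _silently(scheme, n=None):
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return list(default_colors(scheme, n))


def test_default_colors_prefix_property_and_bounds():
    for scheme in ("tab10", "Blues", "RdBu"):
        full = _silently(scheme)
        for n in range(1, len(full)):
            assert _silently(scheme, n) == full[:n]
    with pytest.raises(ValueError, match="between 1 and"):
        default_colors("tab10", 99)
    with pytest.raises(KeyError, match="available schemes"):
        default_colors("nonexistent", 1)


def test_default_colors_warns_on_incompatible_subset():
    # Greys sampled densely contains near-equal luma neighbours
    with pytest.warns(GreyscaleCompatibilityWarning):
        sel = default_colors("Greys", 7)
    assert not sel.greyscale_report.compatible


def test_force_colour_scheme_chromosomes_and_labels():
    p = force_colour_scheme("chromosomes")
    assert len(p) == 24
    assert p.labels == tuple([str(i) for i in range(1, 23)] + ["X", "Y"])
    for case in ("mutation.types", "tissue.types", "sex", "msi.status"):
        pal = force_colour_scheme(case)
        assert pal.labels is not None and len(pal.labels) == len(pal.colours)
    with pytest.raises(KeyError, match="supported use cases"):
        force_colour_scheme("unknown.case")


def test_palette_registry_json_roundtrip():
    pals = [get_palette("tab10"), force_colour_scheme("sex")]
    back = palettes_from_json(palettes_to_json(pals))
    assert back == pals


def test_palette_invariants_enforced():
    with pytest.raises(ValueError, match="empty"):
        Palette("x", "qualitative", ())
    with pytest.raises(ValueError, match="labels"):
        Palette("x", "use_case", (Colour(0, 0, 0),), labels=("a", "b"))
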