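"""Declarative plot documents: save/load, validation, code emission, methods text.

A figure — single chart or multi-panel composition — can be captured as a
small JSON document (YAML accepted on input) that references its data by
name rather than embedding it.  Documents round-trip losslessly, serialize
with stable field order, and are validated against the schema shipped in
``pubfig/schema/plotspec-v1.json``; violations report the offending field
path.  From a document the library can re-render the figure, emit a runnable
Python script that reproduces it, or generate a manuscript-ready methods
paragraph describing the plotting options used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .charts import ChartSpec, DotmapData, Panel, create_chart
from .multiplot import ComposedFigure, MultiplotLayout, compose, single_panel_figure
from .output import MetadataRecord
from .theme import Theme, default_theme

__all__ = [
    "SpecDocument",
    "SpecValidationError",
    "save_spec",
    "load_spec",
    "document_from",
    "render_document",
    "resolve_panel_data",
    "load_datasets",
    "emit_code",
    "methods_paragraph",
]

SUPPORTED_VERSIONS = ("1",)


class SpecValidationError(ValueError):
    """A spec document violates the schema; the message carries the field path."""


@dataclass(frozen=True)
class SpecDocument:
    """A versioned, serializable description of one figure."""

    version: str
    kind: str  # chart | multiplot
    body: dict
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "kind": self.kind,
            "seed": self.seed,
            "body": self.body,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpecDocument":
        return cls(
            version=d["version"], kind=d["kind"], body=d["body"], seed=d.get("seed")
        )


def _schema() -> dict:
    text = resources.files("pubfig.schema").joinpath("plotspec-v1.json").read_text()
    return json.loads(text)


# --- minimal schema checker -------------------------------------------------
#
# Supports the subset the shipped schema uses: type (scalar or list), enum,
# required, properties + additionalProperties (false / schema / true), items
# and local $ref.  Errors name the dotted field path.

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _deref(schema: dict, root: dict) -> dict:
    while "$ref" in schema:
        node = root
        for part in schema["$ref"].lstrip("#/").split("/"):
            node = node[part]
        schema = node
    return schema


def _check(value, schema: dict, root: dict, path: str) -> None:
    schema = _deref(schema, root)
    if "enum" in schema:
        if value not in schema["enum"]:
            raise SpecValidationError(
                f"{path}: value {value!r} not one of {schema['enum']}"
            )
        return
    types = schema.get("type")
    if types is not None:
        allowed = types if isinstance(types, list) else [types]
        py = tuple(
            t for name in allowed for t in (
                _TYPES[name] if isinstance(_TYPES[name], tuple) else (_TYPES[name],)
            )
        )
        if not isinstance(value, py) or (
            isinstance(value, bool) and "boolean" not in allowed
        ):
            raise SpecValidationError(
                f"{path}: expected {'/'.join(allowed)}, got {type(value).__name__}"
            )
        if value is None:
            return
    if isinstance(value, dict):
        props = schema.get("properties", {})
        for req in schema.get("required", []):
            if req not in value:
                raise SpecValidationError(f"{path}: missing required field {req!r}")
        extra = schema.get("additionalProperties", True)
        for key, sub in value.items():
            child = f"{path}.{key}" if path else key
            if key in props:
                _check(sub, props[key], root, child)
            elif extra is False:
                known = ", ".join(sorted(props))
                raise SpecValidationError(
                    f"{child}: unknown field (known fields: {known})"
                )
            elif isinstance(extra, dict):
                _check(sub, extra, root, child)
    elif isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _check(item, schema["items"], root, f"{path}[{i}]")


def validate_document(d: dict) -> None:
    """Validate a raw document dict against the shipped schema."""
    schema = _schema()
    _check(d, schema, schema, "")
    version = d.get("version")
    if version not in SUPPORTED_VERSIONS:
        raise SpecValidationError(
            f"version: document version {version!r} is not supported "
            f"(supported: {list(SUPPORTED_VERSIONS)})"
        )
    body_schema = schema["bodies"][d["kind"]]
    _check(d["body"], body_schema, schema, "body")


# --- save / load ------------------------------------------------------------


def save_spec(doc: SpecDocument | ChartSpec | ComposedFigure, path) -> Path:
    """Serialize a document (or chart/figure) to JSON with stable field order."""
    doc = document_from(doc)
    validate_document(doc.to_dict())
    path = Path(path)
    path.write_text(json.dumps(doc.to_dict(), indent=2) + "\n")
    return path


def load_spec(path) -> SpecDocument:
    """Load and validate a JSON or YAML spec document."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise SpecValidationError(f"{path.name}: document must be a mapping")
    validate_document(raw)
    return SpecDocument.from_dict(raw)


def document_from(obj, seed: int | None = None) -> SpecDocument:
    """Wrap a ChartSpec or ComposedFigure as a versioned document."""
    if isinstance(obj, SpecDocument):
        return obj
    if isinstance(obj, ChartSpec):
        return SpecDocument(version="1", kind="chart", body=obj.to_dict(), seed=seed)
    if isinstance(obj, ComposedFigure):
        return SpecDocument(version="1", kind="multiplot", body=obj.to_dict(), seed=seed)
    raise TypeError(f"cannot build a spec document from {type(obj).__name__}")


# --- rendering a document ---------------------------------------------------


def load_datasets(paths: dict) -> dict:
    """Read named CSV/TSV files into DataFrames (matrix files keep row labels)."""
    out = {}
    for name, path in paths.items():
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        out[name] = pd.read_csv(path, sep=sep)
    return out


def resolve_panel_data(datasets: dict, spec: ChartSpec):
    """Find (and, for dotmaps, assemble) the dataset a chart spec binds.

    Dotmap specs reference paired matrices ``<name>_cell`` and ``<name>_dot``
    (optionally ``<name>_sizes``), with colour maps carried in the spec's
    aesthetics, unless ``datasets[name]`` is already a
    :class:`~pubfig.charts.DotmapData`.
    Heatmap matrices are re-indexed by their first column when it is textual.
    """
    name = spec.data
    if spec.chart_type == "dotmap" and name not in datasets:
        try:
            cell = _as_labelled_matrix(datasets[f"{name}_cell"])
            dot = _as_labelled_matrix(datasets[f"{name}_dot"])
        except KeyError:
            raise KeyError(
                f"dotmap data {name!r} absent: expected datasets "
                f"{name}_cell and {name}_dot"
            ) from None
        sizes = datasets.get(f"{name}_sizes")
        if sizes is not None:
            sizes = _as_labelled_matrix(sizes)
        return DotmapData.make(
            cell_categories=cell,
            dot_categories=dot,
            cell_colour_map=spec.aesthetics.get("cell_colour_map", {}),
            dot_colour_map=spec.aesthetics.get("dot_colour_map", {}),
            dot_sizes=sizes,
        )
    if name not in datasets:
        raise KeyError(
            f"spec binds dataset {name!r} but only {sorted(datasets)} are loaded"
        )
    data = datasets[name]
    if spec.chart_type == "heatmap" and isinstance(data, pd.DataFrame):
        data = _as_labelled_matrix(data)
    return data


def _as_labelled_matrix(df):
    if isinstance(df, pd.DataFrame) and df.shape[1] > 1:
        first = df.columns[0]
        if df[first].dtype == object or str(first).lower() in ("", "unnamed: 0"):
            df = df.set_index(first)
            df.index.name = None
    return df


def render_document(
    doc: SpecDocument, datasets: dict, theme: Theme | None = None
) -> ComposedFigure:
    """Build the composed figure a document describes, binding named datasets."""
    if doc.kind == "chart":
        spec = ChartSpec.from_dict(doc.body)
        panel = create_chart(spec, resolve_panel_data(datasets, spec))
        return single_panel_figure(panel, theme=theme)
    specs = [ChartSpec.from_dict(p) for p in doc.body["panels"]]
    layout = MultiplotLayout.from_dict(doc.body["layout"])
    if theme is None and doc.body.get("theme"):
        theme = Theme.from_dict(doc.body["theme"])
    panels = [create_chart(s, resolve_panel_data(datasets, s)) for s in specs]
    return compose(panels, layout, theme=theme)


# --- code emission ----------------------------------------------------------


def emit_code(
    doc: SpecDocument,
    data_paths: dict | None = None,
    output_path: str = "figure.png",
    timestamp: str | None = None,
    theme: Theme | None = None,
) -> str:
    """Emit a runnable Python script reproducing the document's figure.

    The script contains one builder call per panel plus one compose call (for
    multi-panel documents), loads the referenced data files, and writes the
    figure; executed on the same data it produces geometry-identical output.
    """
    doc = document_from(doc)
    validate_document(doc.to_dict())
    lines = [
        '"""Figure-reproduction script emitted by pubfig."""',
        "",
        "from pubfig.charts import ChartSpec",
        "from pubfig.multiplot import MultiplotLayout, compose, single_panel_figure",
        "from pubfig.output import write_figure",
        "from pubfig.specio import load_datasets, resolve_panel_data",
        "from pubfig.theme import Theme, default_theme",
        "",
    ]
    paths = {k: str(v) for k, v in (data_paths or {}).items()}
    lines.append(f"datasets = load_datasets({paths!r})")
    lines.append("")
    theme_d = theme.to_dict() if theme is not None else doc.body.get("theme")
    theme_expr = f"Theme.from_dict({theme_d!r})" if theme_d else "default_theme()"
    if doc.kind == "chart":
        lines += [
            f"spec_0 = ChartSpec.from_dict({doc.body!r})",
            "from pubfig.charts import create_chart",
            "panel_0 = create_chart(spec_0, resolve_panel_data(datasets, spec_0))",
            f"figure = single_panel_figure(panel_0, theme={theme_expr})",
        ]
    else:
        lines.append("from pubfig.charts import create_chart")
        panel_names = []
        for i, p in enumerate(doc.body["panels"]):
            lines.append(f"spec_{i} = ChartSpec.from_dict({p!r})")
            lines.append(
                f"panel_{i} = create_chart(spec_{i}, "
                f"resolve_panel_data(datasets, spec_{i}))"
            )
            panel_names.append(f"panel_{i}")
        lines.append(f"layout = MultiplotLayout.from_dict({doc.body['layout']!r})")
        lines.append(
            f"figure = compose([{', '.join(panel_names)}], layout, theme={theme_expr})"
        )
    lines.append("")
    ts = f"{timestamp!r}" if timestamp else "None"
    lines.append(f"write_figure(figure, {str(output_path)!r}, timestamp={ts})")
    lines.append("")
    return "\n".join(lines)


# --- methods paragraph ------------------------------------------------------

_HUMAN_NAMES = {
    "qq_fit": "quantile-quantile fit plot",
    "qq_comparison": "quantile-quantile comparison plot",
    "manhattan": "Manhattan plot",
    "hexbinplot": "hexagonally binned scatterplot",
    "polygonplot": "polygon plot",
    "segplot": "segment plot",
    "stripplot": "strip plot",
    "dotmap": "dotmap",
}


def methods_paragraph(
    doc: SpecDocument,
    meta: MetadataRecord,
    output_format: str = "tiff",
    theme: Theme | None = None,
) -> str:
    """Manuscript-ready prose describing the plotting options of a figure.

    Names the chart type(s), any colour schemes and non-default parameters,
    the output format and resolution, and the software version; deterministic
    for fixed inputs.
    """
    doc = document_from(doc)
    theme = theme or default_theme()
    bodies = [doc.body] if doc.kind == "chart" else doc.body["panels"]
    type_counts: dict[str, int] = {}
    palettes: list[str] = []
    nondefault: list[str] = []
    for b in bodies:
        t = b["chart_type"]
        type_counts[t] = type_counts.get(t, 0) + 1
        aes = b.get("aesthetics", {})
        for key in ("colour_scheme",):
            if aes.get(key) and aes[key] not in palettes:
                palettes.append(aes[key])
        for key in sorted(aes):
            if key not in ("colour_scheme",) and f"{t}:{key}" not in nondefault:
                nondefault.append(f"{t}:{key}")
        for key in sorted(b.get("theme_overrides", {})):
            item = f"{t}:{key}"
            if item not in nondefault:
                nondefault.append(item)

    def describe(t: str, n: int) -> str:
        name = _HUMAN_NAMES.get(t, t)
        return name if n == 1 else f"{n} {name}s"

    chart_text = ", ".join(describe(t, n) for t, n in type_counts.items())
    sentences = []
    if doc.kind == "multiplot":
        sentences.append(
            f"The figure was assembled as a multi-panel composition of "
            f"{chart_text} with aligned shared axes and harmonized styling."
        )
    else:
        sentences.append(f"The figure shows a {chart_text}.")
    if palettes:
        sentences.append(
            "Colour schemes: " + ", ".join(f"'{p}'" for p in palettes) + "."
        )
    if nondefault:
        sentences.append(
            "Non-default plotting parameters: " + ", ".join(nondefault) + "."
        )
    sentences.append(
        f"The figure was rendered at {theme.resolution:g} dpi and written in "
        f"{output_format.upper()} format using pubfig version "
        f"{meta.software_version} ({meta.os_description}); plot specification "
        f"digest {meta.spec_digest[:12]}."
    )
    return " ".join(sentences)
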