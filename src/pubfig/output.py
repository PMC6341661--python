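"""Figure output: extension-dispatched writing and provenance metadata.

The output format is chosen purely by the file extension (``.tiff``/``.tif``,
``.png``, ``.pdf``, ``.svg``).  Rasters are written at the theme's resolution
— 1600 dpi by default — with the resolution recorded in the container's
native tags; vector formats keep resolution-independent geometry but still
record the nominal dpi in their metadata.

Every written figure carries a provenance record (software version, operating
system, timestamp, and a content digest of the plot specification) embedded
in the format's own metadata container:

======  =======================================
TIFF    ImageDescription tag
PNG     tEXt chunk (``pubfig:metadata``)
PDF     document information dictionary (Keywords)
SVG     ``<metadata>`` element
======  =======================================

The record is stored as one JSON object so a round-trip read recovers every
field exactly.  The timestamp may be pinned by the caller, which makes writes
byte-reproducible — the basis of the determinism guarantees in the test
suite.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import io
import json
import platform
import re
from dataclasses import dataclass
from pathlib import Path

import matplotlib as mpl
import numpy as np
import tifffile
from PIL import Image
from PIL.PngImagePlugin import PngInfo

from ._version import __version__

__all__ = [
    "MetadataRecord",
    "build_metadata",
    "write_figure",
    "embed_metadata",
    "read_metadata",
    "SUPPORTED_EXTENSIONS",
]

SUPPORTED_EXTENSIONS = (".tiff", ".tif", ".png", ".pdf", ".svg")

_PNG_KEY = "pubfig:metadata"
_SVG_MARK = "pubfig-metadata"


@dataclass(frozen=True)
class MetadataRecord:
    """Provenance descriptors embedded in every written figure."""

    software_version: str
    os_description: str
    timestamp: str
    spec_digest: str

    def __post_init__(self) -> None:
        for f in ("software_version", "os_description", "timestamp", "spec_digest"):
            if not getattr(self, f):
                raise ValueError(f"metadata field {f} must be non-empty")

    def to_json(self) -> str:
        return json.dumps(
            {
                "software_version": self.software_version,
                "os_description": self.os_description,
                "timestamp": self.timestamp,
                "spec_digest": self.spec_digest,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MetadataRecord":
        return cls(**json.loads(text))


def spec_digest(spec_dict: dict) -> str:
    """Content hash (sha256) of a spec's canonical JSON form."""
    canonical = json.dumps(spec_dict, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def build_metadata(spec, timestamp: str | None = None) -> MetadataRecord:
    """Populate a provenance record from the running environment.

    ``spec`` is anything with a ``to_dict`` method (a chart spec or a composed
    figure) or a plain dict.  ``timestamp`` (ISO-8601) may be pinned for
    reproducible output; default is the current UTC wall clock.
    """
    d = spec.to_dict() if hasattr(spec, "to_dict") else dict(spec)
    if timestamp is None:
        timestamp = (
            _dt.datetime.now(_dt.timezone.utc).replace(microsecond=0).isoformat()
        )
    return MetadataRecord(
        software_version=__version__,
        os_description=platform.platform(),
        timestamp=timestamp,
        spec_digest=spec_digest(d),
    )


def _check_extension(path: Path) -> str:
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise ValueError(
            f"unsupported output extension {ext!r} for {path.name!r}; "
            f"supported: tiff, png, pdf, svg"
        )
    return ext


def _parse_iso(ts: str) -> _dt.datetime:
    return _dt.datetime.fromisoformat(ts)


def write_figure(fig, path, timestamp: str | None = None) -> MetadataRecord:
    """Write a composed figure to ``path`` in the format its extension implies.

    ``fig`` is a :class:`~pubfig.multiplot.ComposedFigure` (a single chart is
    a one-panel composition).  Provenance metadata is embedded during the
    write; the record used is returned.  With ``timestamp`` pinned the output
    bytes are reproducible run-to-run.
    """
    from .charts import Panel  # deferred: these modules import this one
    from .multiplot import single_panel_figure
    from .render import realize

    if isinstance(fig, Panel):
        fig = single_panel_figure(fig)
    path = Path(path)
    ext = _check_extension(path)
    record = fig.metadata
    if record is None or timestamp is not None:
        record = build_metadata(fig, timestamp=timestamp)
    theme = fig.theme
    dpi = float(theme.resolution)
    payload = record.to_json()

    mplfig = realize(fig)
    try:
        if ext in (".tiff", ".tif"):
            from matplotlib.backends.backend_agg import FigureCanvasAgg

            canvas = FigureCanvasAgg(mplfig)
            mplfig.set_dpi(dpi)
            canvas.draw()
            arr = np.asarray(canvas.buffer_rgba())
            tifffile.imwrite(
                path,
                arr,
                photometric="rgb",
                resolution=(dpi, dpi),
                resolutionunit="INCH",
                description=payload,
            )
        elif ext == ".png":
            mplfig.savefig(
                path, format="png", dpi=dpi, metadata={_PNG_KEY: payload}
            )
        elif ext == ".pdf":
            meta = {
                "Creator": f"pubfig {record.software_version}",
                "Subject": record.os_description,
                "Keywords": payload,
                "CreationDate": _parse_iso(record.timestamp),
            }
            mplfig.savefig(path, format="pdf", metadata=meta)
        elif ext == ".svg":
            with mpl.rc_context({"svg.hashsalt": record.spec_digest}):
                mplfig.savefig(path, format="svg", metadata={"Date": None})
            _svg_insert(path, payload)
    finally:
        import matplotlib.pyplot as plt

        plt.close(mplfig)
    return record


# ---------------------------------------------------------------------------
# metadata embedding / reading, per container
# ---------------------------------------------------------------------------


def embed_metadata(path, record: MetadataRecord) -> None:
    """Embed (or replace) a provenance record in an existing figure file."""
    path = Path(path)
    ext = _check_extension(path)
    payload = record.to_json()
    if ext in (".tiff", ".tif"):
        _tiff_embed(path, payload)
    elif ext == ".png":
        _png_embed(path, payload)
    elif ext == ".pdf":
        _pdf_embed(path, record)
    elif ext == ".svg":
        _svg_insert(path, payload)


def read_metadata(path) -> MetadataRecord | None:
    """Read an embedded provenance record; ``None`` when the file has none."""
    path = Path(path)
    ext = _check_extension(path)
    try:
        if ext in (".tiff", ".tif"):
            with tifffile.TiffFile(path) as tf:
                desc = tf.pages[0].description
            return MetadataRecord.from_json(desc) if desc else None
        if ext == ".png":
            with Image.open(path) as im:
                text = getattr(im, "text", {}) or im.info
            payload = text.get(_PNG_KEY)
            return MetadataRecord.from_json(payload) if payload else None
        if ext == ".pdf":
            payload = _pdf_read_keywords(path.read_bytes())
            return MetadataRecord.from_json(payload) if payload else None
        if ext == ".svg":
            m = re.search(
                rf'<metadata id="{_SVG_MARK}">(.*?)</metadata>',
                path.read_text(),
                re.S,
            )
            return MetadataRecord.from_json(_xml_unescape(m.group(1))) if m else None
    except (json.JSONDecodeError, TypeError, KeyError):
        return None
    return None


def _tiff_embed(path: Path, payload: str) -> None:
    # Rewrite the page with the new ImageDescription, preserving resolution tags.
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        tags = page.tags
        res = None
        unit = None
        if "XResolution" in tags and "YResolution" in tags:
            res = (tags["XResolution"].value, tags["YResolution"].value)
            unit = tags.get("ResolutionUnit")
            unit = unit.value if unit is not None else None
    kwargs = {}
    if res is not None:
        kwargs["resolution"] = res
        if unit is not None:
            kwargs["resolutionunit"] = unit
    photometric = "rgb" if arr.ndim == 3 else "minisblack"
    tifffile.imwrite(path, arr, photometric=photometric, description=payload, **kwargs)


def _png_embed(path: Path, payload: str) -> None:
    with Image.open(path) as im:
        im.load()
        info = PngInfo()
        for k, v in (getattr(im, "text", {}) or {}).items():
            if k != _PNG_KEY:
                info.add_text(k, v)
        info.add_text(_PNG_KEY, payload)
        dpi = im.info.get("dpi")
        kwargs = {"pnginfo": info}
        if dpi:
            kwargs["dpi"] = dpi
        im.save(path, format="PNG", **kwargs)


def _xml_escape(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _xml_unescape(s: str) -> str:
    return s.replace("&lt;", "<").replace("&gt;", ">").replace("&amp;", "&")


def _svg_insert(path: Path, payload: str) -> None:
    text = Path(path).read_text()
    element = f'<metadata id="{_SVG_MARK}">{_xml_escape(payload)}</metadata>'
    pattern = rf'<metadata id="{_SVG_MARK}">.*?</metadata>'
    if re.search(pattern, text, re.S):
        text = re.sub(pattern, element, text, flags=re.S)
    else:
        m = re.search(r"<svg\b[^>]*>", text)
        if m is None:
            raise ValueError(f"{path} does not look like an SVG document")
        text = text[: m.end()] + "\n  " + element + text[m.end() :]
    Path(path).write_text(text)


# --- minimal PDF information-dictionary handling ---------------------------
#
# No PDF-reading library is bundled, so the few strings we need are extracted
# directly: PDF literal strings are '(...)' with backslash escapes, hex
# strings '<...>' (UTF-16BE when BOM-prefixed).  The last occurrence of a key
# wins, which is exactly the semantics of PDF incremental updates.


def _pdf_decode_string(raw: bytes, kind: str) -> str:
    if kind == "hex":
        data = bytes.fromhex(raw.decode("ascii"))
        if data.startswith(b"\xfe\xff"):
            return data[2:].decode("utf-16-be")
        return data.decode("latin-1")
    out = bytearray()
    i = 0
    esc = {b"n"[0]: 10, b"r"[0]: 13, b"t"[0]: 9, b"b"[0]: 8, b"f"[0]: 12}
    while i < len(raw):
        c = raw[i]
        if c == 0x5C and i + 1 < len(raw):  # backslash
            nxt = raw[i + 1]
            if nxt in esc:
                out.append(esc[nxt])
                i += 2
            elif 0x30 <= nxt <= 0x37:  # octal escape, up to 3 digits
                j = i + 1
                oct_digits = b""
                while j < len(raw) and len(oct_digits) < 3 and 0x30 <= raw[j] <= 0x37:
                    oct_digits += bytes([raw[j]])
                    j += 1
                out.append(int(oct_digits, 8))
                i = j
            else:
                out.append(nxt)
                i += 2
        else:
            out.append(c)
            i += 1
    data = bytes(out)
    if data.startswith(b"\xfe\xff"):
        return data[2:].decode("utf-16-be")
    return data.decode("latin-1")


def _pdf_find_strings(data: bytes, key: bytes) -> list[str]:
    results = []
    for m in re.finditer(rb"/" + key + rb"\s*(\(|<)", data):
        start = m.end()
        if m.group(1) == b"(":
            depth = 1
            i = start
            while i < len(data) and depth:
                c = data[i]
                if c == 0x5C:
                    i += 2
                    continue
                if c == 0x28:
                    depth += 1
                elif c == 0x29:
                    depth -= 1
                i += 1
            results.append(_pdf_decode_string(data[start : i - 1], "literal"))
        else:
            end = data.index(b">", start)
            results.append(_pdf_decode_string(data[start:end], "hex"))
    return results


def _pdf_read_keywords(data: bytes) -> str | None:
    found = _pdf_find_strings(data, b"Keywords")
    return found[-1] if found else None


def _pdf_escape(s: str) -> bytes:
    raw = s.encode("latin-1", errors="replace")
    return raw.replace(b"\\", b"\\\\").replace(b"(", b"\\(").replace(b")", b"\\)")


def _pdf_embed(path: Path, record: MetadataRecord) -> None:
    """Append an incremental update installing a fresh /Info dictionary."""
    data = path.read_bytes()
    sizes = re.findall(rb"/Size\s+(\d+)", data)
    roots = re.findall(rb"/Root\s+(\d+)\s+(\d+)\s+R", data)
    starts = re.findall(rb"startxref\s+(\d+)", data)
    if not (sizes and roots and starts):
        raise ValueError(f"{path} does not look like a well-formed PDF")
    size = int(sizes[-1])
    root = roots[-1]
    prev = int(starts[-1])
    obj_num = size
    info = (
        b"<< /Creator (" + _pdf_escape(f"pubfig {record.software_version}") + b")"
        b" /Subject (" + _pdf_escape(record.os_description) + b")"
        b" /Keywords (" + _pdf_escape(record.to_json()) + b") >>"
    )
    if not data.endswith(b"\n"):
        data += b"\n"
    obj_offset = len(data)
    body = b"%d 0 obj\n" % obj_num + info + b"\nendobj\n"
    xref_offset = obj_offset + len(body)
    xref = (
        b"xref\n%d 1\n%010d 00000 n \n" % (obj_num, obj_offset)
        + b"trailer\n<< /Size %d /Root %s %s R /Info %d 0 R /Prev %d >>\n"
        % (size + 1, root[0], root[1], obj_num, prev)
        + b"startxref\n%d\n%%%%EOF\n" % xref_offset
    )
    path.write_bytes(data + body + xref)
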