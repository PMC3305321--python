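"""Readers and writers for slide rasters, annotation files, and output maps.

Rasters are plain/tiled TIFF (base pyramid level only) or PNG.  Annotations
come in the ImageScope XML dialect
(``Annotations/Annotation/Regions/Region/Vertices/Vertex`` with ``X``/``Y``
attributes, ``NegativeROA="1"`` marking negative-pen exclusion regions) or as
GeoJSON FeatureCollections with ``{layer, label, negative}`` properties.
Annotation coordinates are never rescaled on read; they remain in the source
slide's base pixel frame.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from lxml import etree
from PIL import Image

from .geometry import Polygon

__all__ = [
    "AnnotationSet",
    "SlideImage",
    "read_annotations",
    "read_map_csv",
    "read_slide",
    "write_annotations",
    "write_map",
    "write_slide",
]

DEFAULT_MICRONS_PER_PIXEL = 0.5

#: versioned CSV column order; bumped only on layout changes
MAP_CSV_VERSION = "ihcmap-map-csv/1"


@dataclass
class SlideImage:
    """8-bit RGB raster with physical pixel size and a stain name."""

    pixels: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float = DEFAULT_MICRONS_PER_PIXEL
    name: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:  # grayscale promoted to RGB
            px = np.stack([px] * 3, axis=-1)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("expected an (H, W, 3) RGB raster")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty raster")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        self.pixels = np.ascontiguousarray(px, dtype=np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def size(self) -> tuple[int, int]:
        """(width, height) in pixels."""
        return (self.width, self.height)


@dataclass
class AnnotationSet:
    """Labeled polygon layers drawn on one slide."""

    layers: list[tuple[str, list[Polygon]]] = field(default_factory=list)
    source_slide: str = ""

    def layer_names(self) -> list[str]:
        return [name for name, _ in self.layers]

    def all_polygons(self) -> list[Polygon]:
        return [p for _, polys in self.layers for p in polys]

    def positive_layers(self) -> list[tuple[str, list[Polygon]]]:
        out = []
        for name, polys in self.layers:
            pos = [p for p in polys if not p.negative]
            if pos:
                out.append((name, pos))
        return out

    def negative_polygons(self) -> list[Polygon]:
        return [p for p in self.all_polygons() if p.negative]


# ---------------------------------------------------------------------------
# rasters


def read_slide(path, microns_per_pixel_override: float | None = None, name: str | None = None) -> SlideImage:
    """Read a TIFF (base level) or PNG slide raster.

    Pixel size is taken from file metadata when present, else from the
    override, else the 0.5 um default (with a warning).
    """
    path = Path(path)
    mpp = None
    if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            tags = page.tags
            if "XResolution" in tags and "ResolutionUnit" in tags:
                num, den = tags["XResolution"].value
                unit = tags["ResolutionUnit"].value
                if den and num:
                    px_per = num / den
                    # RESUNIT: 2 = inch, 3 = centimeter
                    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))
                    if unit_um and px_per > 0:
                        mpp = unit_um / px_per
    else:
        with Image.open(path) as im:
            im = im.convert("RGB") if im.mode not in ("RGB", "L") else im
            arr = np.asarray(im)
            dpi = im.info.get("dpi")
            if dpi and dpi[0]:
                mpp = 25400.0 / float(dpi[0])
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if mpp is None:
        mpp = microns_per_pixel_override
    if mpp is None:
        warnings.warn(
            f"{path.name}: no resolution metadata and no override; "
            f"assuming {DEFAULT_MICRONS_PER_PIXEL} um/px",
            stacklevel=2,
        )
        mpp = DEFAULT_MICRONS_PER_PIXEL
    return SlideImage(pixels=arr, microns_per_pixel=float(mpp), name=name or path.stem)


def write_slide(slide: SlideImage, path) -> None:
    """Write a slide as TIFF (with resolution tags) or PNG (with dpi)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px_per_cm = 10000.0 / slide.microns_per_pixel
        tifffile.imwrite(path, slide.pixels, resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER")
    else:
        dpi = 25400.0 / slide.microns_per_pixel
        Image.fromarray(slide.pixels).save(path, dpi=(dpi, dpi))


# ---------------------------------------------------------------------------
# annotations


def _parse_imagescope(path) -> AnnotationSet:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed annotation XML {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "Annotations":
        raise ValueError(f"{path}: expected <Annotations> root, found <{root.tag}>")
    layers: list[tuple[str, list[Polygon]]] = []
    for i, ann in enumerate(root.findall("Annotation")):
        layer_name = ann.get("Name") or ann.get("Id") or f"layer{i + 1}"
        polys: list[Polygon] = []
        for region in ann.findall(".//Regions/Region"):
            negative = region.get("NegativeROA", "0") == "1"
            label = region.get("Text") or layer_name
            verts = [
                (float(v.get("X")), float(v.get("Y")))
                for v in region.findall(".//Vertices/Vertex")
            ]
            if len(verts) >= 3 and verts[0] == verts[-1]:
                verts = verts[:-1]
            if len(verts) < 3:
                warnings.warn(
                    f"{Path(path).name}: skipping Region with <3 vertices in layer {layer_name!r}",
                    stacklevel=3,
                )
                continue
            polys.append(Polygon(np.array(verts), label=label, negative=negative))
        layers.append((layer_name, polys))
    return AnnotationSet(layers=layers, source_slide=Path(path).stem)


def _parse_geojson(path) -> AnnotationSet:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    by_layer: dict[str, list[Polygon]] = {}
    order: list[str] = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Polygon":
            continue
        ring = geom["coordinates"][0]
        if len(ring) >= 2 and ring[0] == ring[-1]:
            ring = ring[:-1]
        layer = str(props.get("layer", "layer1"))
        if len(ring) < 3:
            warnings.warn(f"{Path(path).name}: skipping polygon with <3 vertices", stacklevel=3)
            continue
        poly = Polygon(
            np.array(ring, dtype=float),
            label=str(props.get("label", layer)),
            negative=bool(props.get("negative", False)),
        )
        if layer not in by_layer:
            by_layer[layer] = []
            order.append(layer)
        by_layer[layer].append(poly)
    return AnnotationSet(layers=[(k, by_layer[k]) for k in order], source_slide=Path(path).stem)


def read_annotations(path, dialect: str = "auto") -> AnnotationSet:
    """Read polygon annotations (ImageScope XML or GeoJSON; pixel coordinates)."""
    path = Path(path)
    if dialect == "auto":
        dialect = "imagescope_xml" if path.suffix.lower() == ".xml" else "geojson"
    if dialect == "imagescope_xml":
        return _parse_imagescope(path)
    if dialect == "geojson":
        return _parse_geojson(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_annotations(aset: AnnotationSet, path, dialect: str = "auto") -> None:
    path = Path(path)
    if dialect == "auto":
        dialect = "imagescope_xml" if path.suffix.lower() == ".xml" else "geojson"
    if dialect == "imagescope_xml":
        root = etree.Element("Annotations")
        for layer_name, polys in aset.layers:
            ann = etree.SubElement(root, "Annotation", Name=layer_name)
            regions = etree.SubElement(ann, "Regions")
            for poly in polys:
                region = etree.SubElement(
                    regions,
                    "Region",
                    Text=poly.label,
                    NegativeROA="1" if poly.negative else "0",
                )
                verts = etree.SubElement(region, "Vertices")
                for x, y in poly.vertices:
                    etree.SubElement(verts, "Vertex", X=repr(float(x)), Y=repr(float(y)))
        etree.ElementTree(root).write(str(path), pretty_print=True, xml_declaration=True, encoding="utf-8")
    elif dialect == "geojson":
        features = []
        for layer_name, polys in aset.layers:
            for poly in polys:
                ring = [[float(x), float(y)] for x, y in poly.vertices]
                ring.append(ring[0])
                features.append(
                    {
                        "type": "Feature",
                        "properties": {
                            "layer": layer_name,
                            "label": poly.label,
                            "negative": poly.negative,
                        },
                        "geometry": {"type": "Polygon", "coordinates": [ring]},
                    }
                )
        doc = {
            "type": "FeatureCollection",
            "crs_note": "pixel coordinates of the source slide (x=col, y=row, origin top-left)",
            "features": features,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# score maps


def _map_dataframe(map_obj, microns_per_pixel: float) -> pd.DataFrame:
    """Tidy per-cell table for an IHCMap or SignatureMap (duck-typed)."""
    rows = []
    for (r, c), rec in sorted(map_obj.scores.items()):
        cell = map_obj.cells[(r, c)]
        entry = {
            "row": r,
            "col": c,
            "x_px": cell.x0,
            "y_px": cell.y0,
            "x_um": cell.x0 * microns_per_pixel,
            "y_um": cell.y0 * microns_per_pixel,
            "region": cell.region_label or "",
        }
        if hasattr(rec, "score"):  # per-stain cell score
            entry[f"score_{map_obj.stain}"] = rec.score
        else:  # signature value
            entry["signature"] = float(rec)
        rows.append(entry)
    return pd.DataFrame(rows)


def write_map(map_obj, path, format: str = "csv", reference: SlideImage | None = None,
              annotations: AnnotationSet | None = None, microns_per_pixel: float | None = None) -> None:
    """Write a per-cell score map as csv, geojson, or a PNG heatmap overlay.

    The PNG heatmap uses a diverging palette (red positive, blue negative,
    neutral at zero) drawn over the grayscale reference, with annotation
    outlines in per-layer colors.
    """
    if not map_obj.scores:
        raise ValueError("refusing to write an empty map")
    mpp = microns_per_pixel or getattr(map_obj, "microns_per_pixel", None) or DEFAULT_MICRONS_PER_PIXEL
    path = Path(path)
    if format == "csv":
        df = _map_dataframe(map_obj, mpp)
        with open(path, "w") as fh:
            fh.write(f"# {MAP_CSV_VERSION} columns={','.join(df.columns)}\n")
            df.to_csv(fh, index=False, float_format="%.12g")
    elif format == "geojson":
        df = _map_dataframe(map_obj, mpp)
        features = []
        for (r, c), _ in sorted(map_obj.scores.items()):
            cell = map_obj.cells[(r, c)]
            ring = [
                [cell.x0, cell.y0], [cell.x1, cell.y0], [cell.x1, cell.y1], [cell.x0, cell.y1], [cell.x0, cell.y0]
            ]
            props = df[(df.row == r) & (df.col == c)].iloc[0].to_dict()
            features.append(
                {"type": "Feature", "properties": props, "geometry": {"type": "Polygon", "coordinates": [ring]}}
            )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1, default=float)
    elif format == "png":
        _render_map_png(map_obj, path, reference, annotations)
    else:
        raise ValueError(f"unknown map format {format!r}")


def read_map_csv(path) -> pd.DataFrame:
    """Read back a map CSV written by :func:`write_map` (csv format)."""
    return pd.read_csv(path, comment="#")


def _render_map_png(map_obj, path, reference: SlideImage | None, annotations: AnnotationSet | None) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import patches

    values = {
        k: (rec.score if hasattr(rec, "score") else float(rec)) for k, rec in map_obj.scores.items()
    }
    vmax = max(abs(v) for v in values.values() if v is not None) or 1.0
    fig, ax = plt.subplots(figsize=(8, 8))
    if reference is not None:
        ax.imshow(reference.pixels, interpolation="nearest")
    cmap = plt.get_cmap("RdBu_r")
    for (r, c), v in values.items():
        cell = map_obj.cells[(r, c)]
        color = cmap(0.5 + 0.5 * (v / vmax))
        ax.add_patch(
            patches.Rectangle((cell.x0, cell.y0), cell.x1 - cell.x0, cell.y1 - cell.y0,
                              facecolor=color, edgecolor="none", alpha=0.7)
        )
    if annotations is not None:
        layer_colors = plt.get_cmap("tab10")
        for i, (layer, polys) in enumerate(annotations.layers):
            for poly in polys:
                v = np.vstack([poly.vertices, poly.vertices[:1]])
                ax.plot(v[:, 0], v[:, 1], color=layer_colors(i % 10), lw=1.5,
                        ls="--" if poly.negative else "-")
    if reference is None:
        ax.set_xlim(min(c.x0 for c in map_obj.cells.values()), max(c.x1 for c in map_obj.cells.values()))
        ax.set_ylim(max(c.y1 for c in map_obj.cells.values()), min(c.y0 for c in map_obj.cells.values()))
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
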