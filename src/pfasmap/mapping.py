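"""Renderable structure-function map documents.

A map document joins embedding coordinates with classification labels
and (optionally) a per-compound property table.  Marker colors encode
either the selected classification level (categorical palette, fixed by
sorted label order so two runs color identically) or the overlaid
property (continuous scale over its min-max range).  Documents are pure
data; overlays and 2D projections return new documents and never touch
coordinates or labels.  Rendering is an adapter concern: the same
document can be written as a CSV point table, a JSON model, or a
self-contained interactive HTML page.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from .classify import ClassificationResult
from .embed import EmbeddingCoordinates

__all__ = [
    "MapPoint",
    "MapDocument",
    "build_map",
    "overlay_property",
    "project_2d",
    "fraction_to_percent",
]

AXIS_LABELS = ("TSNE-PCA-1", "TSNE-PCA-2", "TSNE-PCA-3")

# Paul Tol's bright + muted qualitative palettes: colorblind-safe and
# stable under the sorted-label assignment rule.
_PALETTE = [
    "#4477AA", "#EE6677", "#228833", "#CCBB44", "#66CCEE", "#AA3377",
    "#BBBBBB", "#332288", "#88CCEE", "#44AA99", "#117733", "#999933",
    "#DDCC77", "#CC6677", "#882255", "#AA4499", "#DDDDDD", "#000000",
]
_NEUTRAL = "#C8C8C8"


@dataclass(frozen=True)
class MapPoint:
    id: str
    coordinates: tuple[float, float, float]
    category: str
    class_label: str
    subclass_label: str
    provenance: str
    color: str
    hover: str
    property_value: float | None = None


@dataclass(frozen=True)
class MapDocument:
    points: tuple[MapPoint, ...]
    level: str                                 # category | class | subclass
    axis_labels: tuple[str, ...] = AXIS_LABELS
    view_mode: str = "3d"                      # "3d" | "2d"
    axis_pair: tuple[int, int] | None = None   # 1-based, for 2d views
    color_mode: str = "categorical"            # categorical | continuous
    property_name: str = ""
    legend: tuple[tuple[str, str], ...] = ()   # (label, color)

    # -- exports -----------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "axis_labels": list(self.axis_labels),
            "view_mode": self.view_mode,
            "axis_pair": list(self.axis_pair) if self.axis_pair else None,
            "color_mode": self.color_mode,
            "level": self.level,
            "property_name": self.property_name,
            "legend": [list(e) for e in self.legend],
            "points": [
                {
                    "id": p.id,
                    "coordinates": list(p.coordinates),
                    "category": p.category,
                    "class": p.class_label,
                    "subclass": p.subclass_label,
                    "provenance": p.provenance,
                    "color": p.color,
                    "hover": p.hover,
                    "property_value": p.property_value,
                }
                for p in self.points
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["id", "tsne_pca_1", "tsne_pca_2", "tsne_pca_3",
                 "category", "class", "subclass", "provenance", "color",
                 "property_value"]
            )
            for p in self.points:
                writer.writerow(
                    [p.id, *p.coordinates, p.category, p.class_label,
                     p.subclass_label, p.provenance, p.color,
                     "" if p.property_value is None else p.property_value]
                )

    def to_html(self, path: str | Path, title: str = "PFAS map") -> None:
        """Write a self-contained interactive scatter page.

        The document model is embedded as JSON and rendered client-side
        with plotly.js loaded from its CDN; nothing in the Python
        environment is required at view time.
        """
        if self.view_mode == "2d" and self.axis_pair:
            i, j = self.axis_pair[0] - 1, self.axis_pair[1] - 1
            trace_type, dims = "scattergl", (i, j)
            axes = {"xaxis": {"title": self.axis_labels[i]},
                    "yaxis": {"title": self.axis_labels[j]}}
        else:
            trace_type, dims = "scatter3d", (0, 1, 2)
            axes = {"scene": {
                "xaxis": {"title": self.axis_labels[0]},
                "yaxis": {"title": self.axis_labels[1]},
                "zaxis": {"title": self.axis_labels[2]},
            }}
        groups: dict[str, list[MapPoint]] = {}
        for p in self.points:
            key = _label_for_level(p, self.level) if self.color_mode == "categorical" else "points"
            groups.setdefault(key, []).append(p)
        traces = []
        for name in sorted(groups):
            pts = groups[name]
            trace: dict = {
                "type": trace_type,
                "mode": "markers",
                "name": name or "(none)",
                "text": [p.hover for p in pts],
                "hoverinfo": "text",
            }
            for axis, d in zip(("x", "y", "z"), dims):
                trace[axis] = [p.coordinates[d] for p in pts]
            if self.color_mode == "continuous":
                trace["marker"] = {
                    "size": 4,
                    "color": [
                        p.property_value if p.property_value is not None else None
                        for p in pts
                    ],
                    "colorscale": "RdBu",
                    "reversescale": True,
                    "showscale": True,
                    "colorbar": {"title": self.property_name},
                }
            else:
                trace["marker"] = {"size": 4, "color": [p.color for p in pts]}
            traces.append(trace)
        layout = {"title": title, **axes}
        html = (
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            f"<title>{title}</title>"
            "<script src='https://cdn.plot.ly/plotly-2.35.2.min.js'></script>"
            "</head><body><div id='map' style='width:100%;height:95vh'></div>"
            "<script>Plotly.newPlot('map', "
            f"{json.dumps(traces)}, {json.dumps(layout)}"
            ");</script></body></html>"
        )
        Path(path).write_text(html, encoding="utf-8")


def _label_for_level(point: MapPoint, level: str) -> str:
    if level == "category":
        return point.category
    if level == "class":
        return point.class_label or point.category
    if level == "subclass":
        return point.subclass_label or point.class_label or point.category
    raise ValueError(f"unknown level {level!r}")


def build_map(
    coords: EmbeddingCoordinates,
    classes: Mapping[str, ClassificationResult],
    level: str = "class",
) -> tuple[MapDocument, list[str]]:
    """Join coordinates with classifications into a 3D map document.

    Returns the document plus the ids present in only one of the two
    inputs (reported and dropped, never fatal).
    """
    if level not in ("category", "class", "subclass"):
        raise ValueError(f"unknown level {level!r}")
    coord_ids = set(coords.ids)
    mismatched = sorted(coord_ids.symmetric_difference(classes.keys()))
    labels: dict[str, str] = {}
    usable: list[tuple[str, int]] = []
    for i, ident in enumerate(coords.ids):
        if ident not in classes:
            continue
        usable.append((ident, i))
        dummy = classes[ident]
        labels[ident] = _label_for_level(
            MapPoint(
                id=ident, coordinates=(0, 0, 0), category=dummy.category,
                class_label=dummy.class_label, subclass_label=dummy.subclass_label,
                provenance="", color="", hover="",
            ),
            level,
        )
    palette = {
        lab: _PALETTE[i % len(_PALETTE)]
        for i, lab in enumerate(sorted(set(labels.values())))
    }
    points = []
    for ident, i in usable:
        res = classes[ident]
        hover = (
            f"{ident}<br>{res.category} / {res.class_label or '-'} / "
            f"{res.subclass_label or '-'}"
        )
        points.append(
            MapPoint(
                id=ident,
                coordinates=tuple(float(x) for x in coords.coords[i]),
                category=res.category,
                class_label=res.class_label,
                subclass_label=res.subclass_label,
                provenance=coords.provenance[i],
                color=palette[labels[ident]],
                hover=hover,
            )
        )
    doc = MapDocument(
        points=tuple(points),
        level=level,
        legend=tuple(sorted(palette.items())),
    )
    return doc, mismatched


def overlay_property(
    doc: MapDocument, table: Mapping[str, float], property_name: str
) -> MapDocument:
    """Color points by a property table; ids absent from the table stay neutral."""
    new_points = []
    for p in doc.points:
        if p.id in table:
            value = float(table[p.id])
            new_points.append(
                replace(
                    p,
                    property_value=value,
                    color=p.color,
                    hover=p.hover + f"<br>{property_name}: {value:g}",
                )
            )
        else:
            new_points.append(replace(p, property_value=None, color=_NEUTRAL))
    mode = "continuous" if table else doc.color_mode
    return replace(
        doc, points=tuple(new_points), color_mode=mode, property_name=property_name
    )


def project_2d(doc: MapDocument, axis_pair: Sequence[int]) -> MapDocument:
    """Switch to a 2D view using two of the three stored components.

    Coordinates are retained in full (the dropped component stays
    available in hover text and for re-rendering in 3D).
    """
    pair = tuple(axis_pair)
    if len(pair) != 2 or len(set(pair)) != 2 or not set(pair) <= {1, 2, 3}:
        raise ValueError(f"invalid_axes: {axis_pair!r}")
    return replace(doc, view_mode="2d", axis_pair=pair)  # type: ignore[arg-type]


def fraction_to_percent(text: str) -> float:
    """Convert an ``"a/b"`` fraction string to a percentage, one decimal.

    Used for assay hit ratios reported as active/total counts
    (e.g. ``"210/851"`` -> ``24.7``).
    """
    parts = text.strip().split("/")
    if len(parts) != 2:
        raise ValueError(f"malformed_fraction: {text!r}")
    try:
        a, b = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"malformed_fraction: {text!r}") from exc
    if a < 0 or b < 0:
        raise ValueError(f"malformed_fraction: {text!r}")
    if b == 0:
        raise ZeroDivisionError(f"zero_denominator: {text!r}")
    return round(float(Fraction(a, b) * 100), 1)
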