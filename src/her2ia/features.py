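"""Region restriction and slide-level feature aggregation.

Clinical guidelines require HER-2 scoring on invasive tumour only, so a
pathologist's polygon annotations (include invasive regions, exclude DCIS
and other non-invasive tissue) gate every pixel and cell count. With no
include polygon the whole frame is analysed — whole full-face sections are
submitted as-is — while exclude polygons always subtract.

The aggregated outputs are the quantitative measurements the classifier
consumes: mean membrane absorbance (OD), percent membrane-positive pixels
in tissue, percent membrane continuity, and percent immunopositive pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import ValidationError
from .membrane import CellMembraneTrace, membrane_mask

INCLUDE_LABEL = "include_invasive"
EXCLUDE_LABEL = "exclude"


@dataclass
class AnnotationSet:
    """Labelled polygons in image (x, y) coordinates, origin top-left."""

    polygons: list[tuple[str, list[tuple[float, float]]]] = field(
        default_factory=list
    )

    def validate(self) -> None:
        for i, (lbl, verts) in enumerate(self.polygons):
            if lbl not in (INCLUDE_LABEL, EXCLUDE_LABEL):
                raise ValidationError(
                    f"polygon {i}: unknown label {lbl!r} "
                    f"(expected {INCLUDE_LABEL!r} or {EXCLUDE_LABEL!r})"
                )
            if len(verts) < 3:
                raise ValidationError(f"polygon {i}: fewer than 3 vertices")
            if not Polygon(verts).is_valid:
                raise ValidationError(f"polygon {i}: self-intersecting or invalid")

    # -- GeoJSON ----------------------------------------------------------

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"label": lbl},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [[list(map(float, v)) for v in verts]
                                        + [list(map(float, verts[0]))]],
                    },
                }
                for lbl, verts in self.polygons
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "AnnotationSet":
        with open(path) as fh:
            gj = json.load(fh)
        polys = []
        for feat in gj.get("features", []):
            lbl = feat.get("properties", {}).get("label")
            ring = feat["geometry"]["coordinates"][0]
            verts = [tuple(p) for p in ring]
            if len(verts) > 1 and verts[0] == verts[-1]:
                verts = verts[:-1]
            polys.append((lbl, verts))
        ann = cls(polys)
        ann.validate()
        return ann


@dataclass
class SlideFeatures:
    """Slide- or region-level quantitative staining summary."""

    mean_membrane_absorbance: float   # OD over positive membrane pixels
    pct_membrane_positive_pixels: float  # % of tissue pixels
    pct_membrane_continuity: float    # % (per-cell mean x 100 by default)
    pct_immunopositive_pixels: float  # % of analysed tissue pixels
    n_cells: int

    FIELDS = (
        "mean_membrane_absorbance",
        "pct_membrane_positive_pixels",
        "pct_membrane_continuity",
        "pct_immunopositive_pixels",
        "n_cells",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


def _poly_coverage(
    verts: list[tuple[float, float]], width: int, height: int
) -> np.ndarray:
    """Pixel-centre polygon coverage: pixel (r, c) in iff (c+0.5, r+0.5) in."""
    poly = Polygon(verts)
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(int(np.floor(minx - 0.5)), 0)
    c1 = min(int(np.ceil(maxx + 0.5)), width - 1)
    r0 = max(int(np.floor(miny - 0.5)), 0)
    r1 = min(int(np.ceil(maxy + 0.5)), height - 1)
    mask = np.zeros((height, width), dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cx, cy = np.meshgrid(cols + 0.5, rows + 0.5)
    inside = shapely.contains_xy(poly, cx.ravel(), cy.ravel())
    mask[r0:r1 + 1, c0:c1 + 1] = inside.reshape(len(rows), len(cols))
    return mask


def rasterize_annotations(
    ann: AnnotationSet | None, width: int, height: int
) -> np.ndarray:
    """Inclusion mask: union of includes minus union of excludes.

    With no include polygon the whole frame is included; exclude polygons
    always subtract. A pixel belongs to a polygon iff its centre does.
    """
    if ann is None:
        return np.ones((height, width), dtype=bool)
    for i, (lbl, verts) in enumerate(ann.polygons):
        if len(verts) >= 3 and not Polygon(verts).is_valid:
            raise ValidationError(f"polygon {i}: self-intersecting or invalid")
    includes = [p for p in ann.polygons if p[0] == INCLUDE_LABEL]
    excludes = [p for p in ann.polygons if p[0] == EXCLUDE_LABEL]
    if includes:
        mask = np.zeros((height, width), dtype=bool)
        for _, verts in includes:
            mask |= _poly_coverage(verts, width, height)
    else:
        mask = np.ones((height, width), dtype=bool)
    for _, verts in excludes:
        mask &= ~_poly_coverage(verts, width, height)
    return mask


def aggregate_features(
    traces: list[CellMembraneTrace],
    positive: np.ndarray,
    tissue: np.ndarray,
    inclusion: np.ndarray,
    dab: np.ndarray | None = None,
    continuity_weighting: str = "cell",
) -> SlideFeatures:
    """Aggregate per-cell traces and pixel masks into slide features.

    Cells straddling the inclusion boundary count iff their centroid lies
    inside. ``continuity_weighting`` is ``"cell"`` (unweighted per-cell
    mean, the default) or ``"perimeter"`` (perimeter-weighted mean).
    """
    if not (positive.shape == tissue.shape == inclusion.shape):
        raise ValidationError("masks differ in shape")
    denom = int((tissue & inclusion).sum())
    if denom == 0:
        raise ValidationError("no analysable tissue in the included region")

    inside = [
        t for t in traces
        if inclusion[
            min(max(int(round(t.centre[0])), 0), inclusion.shape[0] - 1),
            min(max(int(round(t.centre[1])), 0), inclusion.shape[1] - 1),
        ]
    ]
    memb = membrane_mask(inside, tissue.shape, thickness=1)

    pos_in = positive & inclusion
    pos_memb = pos_in & memb
    pct_memb_pos = 100.0 * pos_memb.sum() / denom
    pct_immuno = 100.0 * pos_in.sum() / denom

    if dab is not None and pos_memb.any():
        mean_abs = float(dab[pos_memb].mean())
    elif inside and any(t.stained_flags.any() for t in inside):
        vals = [t.mean_absorbance for t in inside if t.stained_flags.any()]
        mean_abs = float(np.mean(vals))
    else:
        mean_abs = 0.0

    if inside:
        if continuity_weighting == "perimeter":
            w = np.array([t.perimeter_px for t in inside])
            c = np.array([t.continuity for t in inside])
            pct_cont = 100.0 * float((w * c).sum() / w.sum())
        else:
            pct_cont = 100.0 * float(np.mean([t.continuity for t in inside]))
    else:
        pct_cont = 0.0

    return SlideFeatures(
        mean_membrane_absorbance=mean_abs,
        pct_membrane_positive_pixels=float(pct_memb_pos),
        pct_membrane_continuity=pct_cont,
        pct_immunopositive_pixels=float(pct_immuno),
        n_cells=len(inside),
    )
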