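"""Synthetic two-stain histology slides with per-cell ground truth.

Clinical HER-2 slides cannot ship with a software package, so validation
rests on a generator that emulates the staining phenotypes the algorithm
must quantify: haematoxylin-stained nuclei, DAB-stained membranes whose
intensity (OD) and circumferential continuity are controlled per cell,
saturated chromogen artefact blobs, and excluded (non-invasive) regions.
Colour composition inverts the analysis OD transform exactly
(I = I0*10**(-OD) - eps), so the generator is an inverse model of the stain
separation step up to uint8 quantisation and additive pixel noise.

Every slide carries its ground truth — cell centres, radii, intensities,
continuity fractions, artefact footprints, pixel counts — and an ordinal
label applied with the guideline cell-fraction rules (<10% of cells with
complete membranous staining is negative; >30% uniform and intense is
positive; equivocal otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .features import EXCLUDE_LABEL, AnnotationSet
from .stains import OD_EPSILON, ColourDefinition
from .classify import Her2Category


@dataclass(frozen=True)
class ArtefactSpec:
    """Saturated chromogen blobs stamped onto the slide."""

    count: int = 0
    radius: float = 30.0
    od: float = 2.0
    centres: tuple[tuple[float, float], ...] | None = None  # (row, col)


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Full description of one synthetic slide; fixed seed => identical bytes."""

    width: int = 256
    height: int = 256
    n_cells: int = 40
    cell_radius_range: tuple[float, float] = (9.0, 14.0)
    membrane_thickness: float = 3.0
    stained_fraction: float = 1.0      # fraction of cells with any membrane DAB
    dab_od_mean: float = 0.6           # per-cell membrane DAB intensity (OD)
    dab_od_sd: float = 0.05
    continuity_mean: float = 1.0       # per-cell stained arc fraction
    continuity_sd: float = 0.0
    nucleus_od: float = 0.6            # haematoxylin OD of the nuclear disc
    nucleus_radius_frac: float = 0.5   # nucleus radius as a fraction of cell radius
    background_intensity: float = 255.0
    noise_sd: float = 2.0              # additive Gaussian noise, intensity units
    fragmented: bool = False           # split the stained arc into dashes
    n_fragments: int = 4
    artefacts: ArtefactSpec = field(default_factory=ArtefactSpec)
    exclusion_rects: tuple[tuple[float, float, float, float], ...] = ()
    #: (x0, y0, x1, y1) rectangles emitted as exclude polygons
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_radius_range[0] < 3.0:
            raise ValidationError("cell radii must be >= 3 px")
        if self.dab_od_mean < 0 or self.nucleus_od < 0:
            raise ValidationError("optical densities must be >= 0")
        if not (0.0 <= self.stained_fraction <= 1.0):
            raise ValidationError("stained_fraction must be in [0, 1]")

    def with_(self, **kwargs) -> "SyntheticSlideSpec":
        return replace(self, **kwargs)


@dataclass
class CellTruth:
    centre: tuple[float, float]  # (row, col)
    radius: float
    intensity_od: float          # membrane DAB OD (0 for unstained cells)
    continuity: float            # stained arc fraction in [0, 1]
    inside_exclusion: bool = False


@dataclass
class LabelThresholds:
    """Cutoffs giving the guideline words operational meaning."""

    stained_od: float = 0.15          # minimum OD counting as stained at all
    complete_continuity: float = 0.5  # "complete" membranous staining
    uniform_continuity: float = 0.9   # "uniform" circumferential staining
    intense_od: float = 0.6           # "intense" staining
    neg_fraction: float = 0.10        # below this stained-cell fraction: negative
    pos_fraction: float = 0.30        # above this uniform+intense fraction: positive


@dataclass
class GroundTruth:
    cells: list[CellTruth]
    positive_px: int              # rendered membrane (+ artefact) DAB pixels
    tissue_px: int                # rendered non-background pixels
    total_px: int
    artefact_footprints: list[np.ndarray] = field(default_factory=list)
    label: Her2Category = Her2Category.NEG

    @property
    def positive_fraction(self) -> float:
        return self.positive_px / self.total_px if self.total_px else 0.0

    @property
    def positive_fraction_tissue(self) -> float:
        return self.positive_px / self.tissue_px if self.tissue_px else 0.0

    @property
    def analysed_cells(self) -> list[CellTruth]:
        return [c for c in self.cells if not c.inside_exclusion]


def label_from_ground_truth(
    gt: GroundTruth, thresholds: LabelThresholds | None = None
) -> Her2Category:
    """Apply the 10%/30% cell-fraction rules to ground-truth cells.

    Only cells outside exclusion regions count. "Complete membranous
    staining" means continuity at or above the completeness cutoff;
    "uniform, intense" requires both the uniformity and intensity cutoffs.
    """
    th = thresholds or LabelThresholds()
    cells = gt.analysed_cells
    if not cells:
        return Her2Category.NEG
    n = len(cells)
    stained = [
        c for c in cells
        if c.intensity_od >= th.stained_od and c.continuity >= th.complete_continuity
    ]
    if len(stained) / n < th.neg_fraction:
        return Her2Category.NEG
    uniform_intense = [
        c for c in cells
        if c.intensity_od >= th.intense_od and c.continuity >= th.uniform_continuity
    ]
    if len(uniform_intense) / n > th.pos_fraction:
        return Her2Category.POSITIVE
    return Her2Category.EQUIVOCAL


# -- rendering ------------------------------------------------------------


def _place_cells(
    spec: SyntheticSlideSpec, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Dart-throwing placement; membranes may not overlap."""
    placed: list[tuple[float, float, float]] = []
    margin = spec.cell_radius_range[1] + spec.membrane_thickness
    tries = 0
    max_tries = 10_000
    while len(placed) < spec.n_cells:
        if tries >= max_tries:
            raise ValidationError(
                f"could not place {spec.n_cells} cells in "
                f"{spec.width}x{spec.height} after {max_tries} tries; "
                "lower n_cells or enlarge the slide"
            )
        tries += 1
        r = rng.uniform(*spec.cell_radius_range)
        cy = rng.uniform(margin, spec.height - margin)
        cx = rng.uniform(margin, spec.width - margin)
        gap = spec.membrane_thickness + 2.0
        if all(
            math.hypot(cy - py, cx - px) >= r + pr + gap
            for py, px, pr in placed
        ):
            placed.append((cy, cx, r))
    return placed


def _stamp_annulus(
    dab: np.ndarray,
    centre: tuple[float, float],
    radius: float,
    thickness: float,
    od: float,
    continuity: float,
    theta0: float,
    fragmented: bool,
    n_fragments: int,
) -> int:
    """Render a stained membrane arc; returns the number of stained pixels."""
    if od <= 0 or continuity <= 0:
        return 0
    cy, cx = centre
    r_out = radius + thickness / 2.0
    r_in = max(radius - thickness / 2.0, 0.0)
    r0 = max(int(math.floor(cy - r_out)), 0)
    r1 = min(int(math.ceil(cy + r_out)), dab.shape[0] - 1)
    c0 = max(int(math.floor(cx - r_out)), 0)
    c1 = min(int(math.ceil(cx + r_out)), dab.shape[1] - 1)
    rows, cols = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    d = np.hypot(rows - cy, cols - cx)
    ring = (d >= r_in) & (d <= r_out)
    phi = (np.arctan2(rows - cy, cols - cx) - theta0) % (2 * math.pi)
    frac = phi / (2 * math.pi)
    if fragmented and continuity < 1.0:
        # split the stained fraction into n dashes spread around the circle
        seg = 1.0 / n_fragments
        arc = (frac % seg) < seg * continuity
    else:
        arc = frac <= continuity
    sel = ring & arc
    dab[r0:r1 + 1, c0:c1 + 1][sel] = od
    return int(sel.sum())


def _stamp_disc(
    img: np.ndarray, centre: tuple[float, float], radius: float, od: float
) -> np.ndarray:
    """Set a filled disc to ``od``; returns the (K, 2) stamped coordinates."""
    cy, cx = centre
    r0 = max(int(math.floor(cy - radius)), 0)
    r1 = min(int(math.ceil(cy + radius)), img.shape[0] - 1)
    c0 = max(int(math.floor(cx - radius)), 0)
    c1 = min(int(math.ceil(cx + radius)), img.shape[1] - 1)
    rows, cols = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    sel = np.hypot(rows - cy, cols - cx) <= radius
    img[r0:r1 + 1, c0:c1 + 1][sel] = od
    return np.stack([rows[sel], cols[sel]], axis=1)


def generate_slide(
    spec: SyntheticSlideSpec,
    cdef: ColourDefinition | None = None,
    thresholds: LabelThresholds | None = None,
) -> tuple[np.ndarray, AnnotationSet, GroundTruth]:
    """Render a synthetic slide; returns (uint8 RGB, annotations, truth).

    Cells are placed by dart throwing (no membrane overlap), each rendered
    as a haematoxylin nuclear disc plus a DAB annulus covering a contiguous
    arc (or dashes, in fragmented mode) of the cell's continuity fraction.
    Artefact blobs are nucleus-free saturated DAB discs. Exclusion
    rectangles are emitted as exclude polygons in the annotation set.
    """
    cdef = cdef or ColourDefinition()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    dab_conc = np.zeros((h, w), dtype=float)
    haem_conc = np.zeros((h, w), dtype=float)

    placed = _place_cells(spec, rng) if spec.n_cells else []
    cells: list[CellTruth] = []
    for cy, cx, r in placed:
        stained = rng.random() < spec.stained_fraction
        if stained:
            od = max(float(rng.normal(spec.dab_od_mean, spec.dab_od_sd)), 0.05)
            cont = float(np.clip(
                rng.normal(spec.continuity_mean, spec.continuity_sd), 0.02, 1.0
            )) if spec.continuity_sd > 0 else float(
                np.clip(spec.continuity_mean, 0.0, 1.0)
            )
        else:
            od, cont = 0.0, 0.0
        theta0 = rng.uniform(0, 2 * math.pi)
        _stamp_disc(haem_conc, (cy, cx), r * spec.nucleus_radius_frac,
                    spec.nucleus_od)
        _stamp_annulus(
            dab_conc, (cy, cx), r, spec.membrane_thickness, od, cont,
            theta0, spec.fragmented, spec.n_fragments,
        )
        cells.append(CellTruth(centre=(cy, cx), radius=r,
                               intensity_od=od, continuity=cont))

    # artefact blobs: saturated chromogen with no nucleus
    footprints: list[np.ndarray] = []
    art = spec.artefacts
    if art.count:
        centres = list(art.centres or [])
        tries = 0
        while len(centres) < art.count:
            if tries >= 10_000:
                raise ValidationError(
                    "could not place artefact blobs clear of cells; use "
                    "explicit centres or a smaller artefact radius"
                )
            tries += 1
            cy = rng.uniform(art.radius, h - art.radius)
            cx = rng.uniform(art.radius, w - art.radius)
            if all(
                math.hypot(cy - c.centre[0], cx - c.centre[1])
                > art.radius + c.radius + spec.membrane_thickness
                for c in cells
            ):
                centres.append((cy, cx))
        for cy, cx in centres[: art.count]:
            footprints.append(_stamp_disc(dab_conc, (cy, cx), art.radius, art.od))

    # mark cells inside exclusion rectangles
    for x0, y0, x1, y1 in spec.exclusion_rects:
        for c in cells:
            if x0 <= c.centre[1] <= x1 and y0 <= c.centre[0] <= y1:
                c.inside_exclusion = True

    # compose to RGB: OD vector per pixel, exact inverse of the OD transform
    od_img = (
        haem_conc[..., None] * cdef.haematoxylin[None, None, :]
        + dab_conc[..., None] * cdef.dab[None, None, :]
    )
    intensity = cdef.background_intensity * np.power(10.0, -od_img) - OD_EPSILON
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape)
    image = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)

    th = thresholds or LabelThresholds()
    positive_px = int((dab_conc >= th.stained_od).sum())
    tissue_px = int(((dab_conc > 0) | (haem_conc > 0)).sum())
    gt = GroundTruth(
        cells=cells,
        positive_px=positive_px,
        tissue_px=tissue_px,
        total_px=h * w,
        artefact_footprints=footprints,
    )
    gt.label = label_from_ground_truth(gt, th)

    polygons = [
        (EXCLUDE_LABEL, [(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
        for x0, y0, x1, y1 in spec.exclusion_rects
    ]
    return image, AnnotationSet(polygons), gt


# -- study-condition presets ----------------------------------------------

#: Typical per-category phenotypes (fixed parameters), used by the CLI
#: simulator: negatives show sparse weak low-continuity staining, equivocals
#: widespread weak-to-moderate partially continuous staining, positives
#: intense near-complete membranes.
CLASS_PRESETS: dict[str, dict] = {
    "0/1+": dict(stained_fraction=0.05, dab_od_mean=0.35, dab_od_sd=0.05,
                 continuity_mean=0.25, continuity_sd=0.08),
    "2+": dict(stained_fraction=0.70, dab_od_mean=0.45, dab_od_sd=0.07,
               continuity_mean=0.60, continuity_sd=0.10),
    "3+": dict(stained_fraction=0.95, dab_od_mean=0.90, dab_od_sd=0.10,
               continuity_mean=0.95, continuity_sd=0.03),
}


def sample_spec_kwargs(label: str, rng: np.random.Generator) -> dict:
    """Draw one slide's staining parameters for a category.

    Cases vary: each slide draws its own staining extent, intensity and
    continuity around the category phenotype. The negative category is a
    mixture of two clinically recognised sub-phenotypes — essentially
    unstained tumours (0) and tumours with weak *incomplete* membranous
    staining in many cells (1+), which share a category despite very
    different stained extents; continuity is what keeps the 1+ mode apart
    from the equivocal class.
    """
    def n(mu, sd, lo, hi):
        return float(np.clip(rng.normal(mu, sd), lo, hi))

    if label == "0/1+":
        if rng.random() < 0.5:  # "0": minimal staining
            return dict(
                stained_fraction=float(rng.uniform(0.0, 0.10)),
                dab_od_mean=n(0.35, 0.05, 0.2, 0.6), dab_od_sd=0.05,
                continuity_mean=n(0.25, 0.05, 0.05, 0.45), continuity_sd=0.05,
            )
        return dict(  # "1+": widespread but weak and incomplete
            stained_fraction=float(rng.uniform(0.5, 0.9)),
            dab_od_mean=n(0.40, 0.05, 0.2, 0.6), dab_od_sd=0.05,
            continuity_mean=n(0.30, 0.05, 0.05, 0.42), continuity_sd=0.05,
        )
    if label == "2+":
        return dict(
            stained_fraction=float(rng.uniform(0.6, 0.95)),
            dab_od_mean=n(0.45, 0.05, 0.25, 0.58), dab_od_sd=0.05,
            continuity_mean=n(0.62, 0.06, 0.5, 0.8), continuity_sd=0.08,
        )
    if label == "3+":
        return dict(
            stained_fraction=float(rng.uniform(0.9, 1.0)),
            dab_od_mean=n(0.90, 0.08, 0.65, 1.3), dab_od_sd=0.08,
            continuity_mean=n(0.95, 0.02, 0.9, 1.0), continuity_sd=0.03,
        )
    raise ValidationError(f"unknown category preset {label!r}")


def generate_feature_table(
    per_label_n: int,
    seed: int,
    base_spec: SyntheticSlideSpec | None = None,
    presets: dict[str, dict] | None = None,
    cdef: ColourDefinition | None = None,
):
    """Render slides per category, run the full analysis pipeline, and
    return a labelled feature table (one row per slide).

    Each slide's staining parameters are drawn per case around the category
    phenotype (:func:`sample_spec_kwargs`), unless fixed ``presets`` are
    supplied. Labels are the ground-truth categories of the rendered
    slides, so the table is a faithful training surrogate: features come
    from the measuring pipeline, labels from the guideline rules on the
    known cells.
    """
    import pandas as pd

    from .pipeline import analyze_arrays

    if per_label_n < 1:
        raise ValidationError("per_label_n must be >= 1")
    base = base_spec or SyntheticSlideSpec()
    cdef = cdef or ColourDefinition()
    param_rng = np.random.default_rng(seed)
    rows = []
    slide_idx = 0
    for lbl in (presets or CLASS_PRESETS):
        for i in range(per_label_n):
            kw = presets[lbl] if presets else sample_spec_kwargs(lbl, param_rng)
            spec = base.with_(seed=seed + 7919 * slide_idx, **kw)
            try:
                image, ann, gt = generate_slide(spec, cdef)
                result = analyze_arrays(image, ann, cdef)
            except Exception as exc:  # propagate with slide context
                raise ValidationError(
                    f"slide {slide_idx} (label {lbl!r}) failed: {exc}"
                ) from exc
            row = result.features.as_dict()
            row["label"] = str(gt.label)
            row["preset"] = lbl
            row["slide"] = slide_idx
            rows.append(row)
            slide_idx += 1
    return pd.DataFrame(rows)
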