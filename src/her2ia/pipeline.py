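"""End-to-end orchestration: image -> features -> HER-2 call.

`analyze_arrays` is the in-memory pipeline used everywhere (tests, the
synthetic feature-table generator, the CLI): stain separation, membrane
tracing, artefact exclusion, region-restricted aggregation, and — when a
trained classifier is supplied — the probability classification. File-based
wrappers add image/annotation IO, per-slide batch processing with failure
logging, and the statistics report.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import membrane as memb
from . import stains
from .classify import Her2Call, Her2Category, Her2Classifier, parse_category
from .errors import Her2iaError, ValidationError
from .features import AnnotationSet, SlideFeatures, aggregate_features, \
    rasterize_annotations
from .membrane import ArtefactRegion, CellMembraneTrace, MembraneParams
from .stats import confusion_matrix, diagnostic_accuracy, fish_concordance

log = logging.getLogger("her2ia")


@dataclass
class RunConfig:
    """Everything needed to reproduce an analysis run."""

    colour_definition: stains.ColourDefinition = field(
        default_factory=stains.ColourDefinition
    )
    membrane_params: MembraneParams = field(default_factory=MembraneParams)
    classifier_path: str | None = None
    seed: int = 0

    def save(self, path) -> None:
        d = {
            "colour_definition": self.colour_definition.to_dict(),
            "membrane_params": vars(self.membrane_params),
            "classifier_path": self.classifier_path,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class AnalysisResult:
    features: SlideFeatures
    traces: list[CellMembraneTrace]
    artefacts: list[ArtefactRegion]
    call: Her2Call | None
    positive_mask: np.ndarray
    tissue_mask: np.ndarray
    inclusion_mask: np.ndarray


def analyze_arrays(
    image: np.ndarray,
    annotations: AnnotationSet | None = None,
    cdef: stains.ColourDefinition | None = None,
    params: MembraneParams | None = None,
    classifier: Her2Classifier | None = None,
) -> AnalysisResult:
    """Run the full measurement pipeline on an in-memory RGB image."""
    cdef = cdef or stains.ColourDefinition()
    params = params or MembraneParams(dab_threshold=cdef.dab_positive_threshold)

    od = stains.rgb_to_optical_density(image, cdef)
    ch = stains.separate_stains(od, cdef)
    tissue = stains.tissue_mask(od, cdef)
    positive = stains.immunopositive_mask(ch, cdef)
    inclusion = rasterize_annotations(annotations, od.width, od.height)

    traces = memb.detect_membranes(ch, tissue, params)
    artefacts, traces = memb.exclude_artefacts(ch, traces, params)
    if artefacts:
        positive = memb.apply_artefact_exclusion(positive, artefacts)
        tissue = memb.apply_artefact_exclusion(tissue, artefacts)
        log.info("excluded %d artefact region(s), %d px",
                 len(artefacts), sum(a.area for a in artefacts))

    # re-measure continuity/absorbance against the final positive mask
    for t in traces:
        memb.membrane_continuity(t, positive)
        rows, cols = t.contour[:, 0], t.contour[:, 1]
        flags = t.stained_flags
        t.mean_absorbance = (
            float(ch.dab[rows[flags], cols[flags]].mean()) if flags.any() else 0.0
        )

    if not (tissue & inclusion).any():
        # blank (all-background) region: nothing to measure, negative by the
        # <1% immunopositive-pixel rule
        feats = SlideFeatures(
            mean_membrane_absorbance=0.0,
            pct_membrane_positive_pixels=0.0,
            pct_membrane_continuity=0.0,
            pct_immunopositive_pixels=0.0,
            n_cells=0,
        )
    else:
        feats = aggregate_features(traces, positive, tissue, inclusion, dab=ch.dab)
    log.info("cells=%d, immunopositive=%.2f%%, continuity=%.1f%%",
             feats.n_cells, feats.pct_immunopositive_pixels,
             feats.pct_membrane_continuity)

    if classifier is not None and classifier.fitted:
        call = classifier.classify(feats)
    elif feats.pct_immunopositive_pixels < 1.0:
        call = Her2Call(category=Her2Category.NEG, confidence_pct=100.0,
                        override_rule=True)
    else:
        call = None
    return AnalysisResult(
        features=feats, traces=traces, artefacts=artefacts, call=call,
        positive_mask=positive, tissue_mask=tissue, inclusion_mask=inclusion,
    )


def analyze(
    image_path,
    annotation_path=None,
    config: RunConfig | None = None,
    classifier: Her2Classifier | None = None,
    out_dir=None,
) -> AnalysisResult:
    """File-based analysis of one slide; optionally writes outputs.

    Outputs (when ``out_dir`` is given): features CSV, per-cell trace CSV,
    membrane overlay PNG, the call as structured text, and the exact run
    configuration for provenance.
    """
    config = config or RunConfig()
    image = iio.imread(image_path)
    if image.ndim == 3 and image.shape[2] == 4:
        image = image[..., :3]
    ann = AnnotationSet.load(annotation_path) if annotation_path else None
    if classifier is None and config.classifier_path:
        classifier = Her2Classifier.load(config.classifier_path)
    result = analyze_arrays(
        image, ann, config.colour_definition, config.membrane_params, classifier
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([result.features.as_dict()]).to_csv(
            out / "features.csv", index=False
        )
        memb.traces_to_dataframe(result.traces).to_csv(
            out / "cells.csv", index=False
        )
        iio.imwrite(out / "overlay.png", memb.overlay(image, result.traces))
        config.save(out / "run_config.yaml")
        if result.call is not None:
            with open(out / "call.yaml", "w") as fh:
                yaml.safe_dump(
                    {
                        "category": str(result.call.category),
                        "confidence_pct": float(result.call.confidence_pct),
                        "override_rule": bool(result.call.override_rule),
                    },
                    fh, sort_keys=False,
                )
    return result


def batch(
    manifest: pd.DataFrame,
    config: RunConfig | None = None,
    classifier: Her2Classifier | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-slide analysis over a manifest (columns: slide_id, image[, annotations]).

    Failures are logged and collected; remaining slides still run. The output
    table is sorted by slide_id, so results are independent of manifest order.
    """
    if "slide_id" not in manifest.columns or "image" not in manifest.columns:
        raise ValidationError("manifest needs 'slide_id' and 'image' columns")
    rows = []
    failures: list[tuple[str, str]] = []
    for _, m in manifest.iterrows():
        sid = str(m["slide_id"])
        ann = m.get("annotations")
        ann = None if (ann is None or (isinstance(ann, float) and np.isnan(ann))
                       or ann == "") else ann
        try:
            res = analyze(m["image"], ann, config, classifier)
        except Exception as exc:  # unreadable image, bad annotation, ...
            log.error("slide %s failed: %s", sid, exc)
            failures.append((sid, str(exc)))
            continue
        row = {"slide_id": sid, **res.features.as_dict()}
        if res.call is not None:
            row["category"] = str(res.call.category)
            row["confidence_pct"] = res.call.confidence_pct
            row["override_rule"] = res.call.override_rule
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("slide_id").reset_index(drop=True)
    return table, failures


def stats_report(
    calls: pd.DataFrame,
    second_rater: pd.DataFrame | None = None,
    fish: pd.DataFrame | None = None,
    stream=None,
) -> str:
    """Agreement and FISH-accuracy report from call tables.

    ``calls`` needs columns case_id and category; ``second_rater`` likewise;
    ``fish`` needs case_id and ratio. Sections appear as the inputs allow.
    """
    stream = stream or sys.stdout
    if "case_id" not in calls.columns or "category" not in calls.columns:
        raise ValidationError("calls table needs 'case_id' and 'category' columns")
    sections = []
    if second_rater is not None:
        merged = calls.merge(second_rater, on="case_id", suffixes=("_a", "_b"))
        if merged.empty:
            raise ValidationError("no common case_ids between the two raters")
        cm = confusion_matrix(merged["category_a"], merged["category_b"])
        sections.append("== Inter-rater agreement ==\n" + cm.report())
    if fish is not None:
        if "ratio" not in fish.columns:
            raise ValidationError("FISH table needs a 'ratio' column")
        bad = fish[fish["ratio"] < 0]
        if len(bad):
            raise ValidationError(
                f"negative HER2/Chr17 ratio in FISH row(s) {bad.index.tolist()}"
            )
        merged = calls.merge(fish, on="case_id")
        if merged.empty:
            raise ValidationError("no common case_ids between calls and FISH")
        conc = fish_concordance(merged["category"], merged["ratio"])
        acc = diagnostic_accuracy(merged["category"], merged["ratio"])
        sections.append(
            "== FISH gold standard ==\n"
            f"informative cases: {conc.n_informative}\n"
            f"concordance: {conc.pct:.1f}% (reported {conc.pct_rounded}%)\n"
            f"sensitivity: {acc.sensitivity_pct:.1f}%  "
            f"specificity: {acc.specificity_pct:.1f}%\n"
            f"equivocal test calls excluded: {acc.n_equivocal_excluded}; "
            f"FISH-equivocal excluded: {acc.n_fish_equivocal_excluded}"
        )
    report = "\n\n".join(sections) if sections else "(no comparators supplied)"
    print(report, file=stream)
    return report


def parse_calls_csv(path) -> pd.DataFrame:
    """Read a calls CSV (case_id, category), validating category labels."""
    df = pd.read_csv(path)
    if "case_id" not in df.columns or "category" not in df.columns:
        raise ValidationError(f"{path}: needs 'case_id' and 'category' columns")
    df["category"] = [str(parse_category(v)) for v in df["category"]]
    return df
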