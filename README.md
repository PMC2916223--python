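# her2ia — quantitative HER-2 immunohistochemistry image analysis

Accurate HER-2 scoring decides who receives trastuzumab, yet manual reading
of DAB-stained breast-tissue sections is notoriously variable, especially
around the equivocal (2+) category that triggers costly confirmatory FISH
testing. `her2ia` implements an automated scoring pipeline for brightfield
IHC images built on a simple observation: what separates a negative (0/1+)
from an equivocal or positive tumour is not just how *dark* the membrane
staining is, but how *complete* the circumferential staining of each cell
is. The package is aimed at image-analysis researchers and pathology
informatics groups who need a transparent, fully testable reference
implementation.

## What it computes

1. **Stain separation.** Each RGB pixel is converted to optical density,
   `OD = −log10((I + 1)/I0)`, and decomposed in a stain basis
   (haematoxylin, DAB, residual) by solving the per-pixel 3×3 linear
   system — Beer–Lambert colour deconvolution. A colour-definition file
   holds the stain vectors and the thresholds that define immunopositive
   and tissue pixels.
2. **Membrane isolation and continuity.** Nuclei seed cell detection
   (local maxima of the haematoxylin channel); DAB ridges are skeletonised
   and assembled into per-cell membrane contours. For each cell the
   *membrane continuity* `c ∈ [0, 1]` is the fraction of the full
   reconstructed circumference that is immunopositive, and the mean DAB OD
   over stained membrane is its absorbance. Saturated chromogen blobs and
   other artefacts are excluded from every count.
3. **Region restriction and features.** Pathologist annotations (GeoJSON
   include/exclude polygons) gate the analysis to invasive tumour. Slide
   features: mean membrane absorbance (OD), % membrane-positive pixels in
   tissue, % membrane continuity, % immunopositive pixels.
4. **Probability classification.** A Gaussian class-conditional (quadratic
   discriminant) model over (absorbance, continuity) yields posterior
   probabilities for 0/1+, 2+ and 3+; the call is the MAP category and the
   reported confidence is `100 × max posterior`. Any region with < 1%
   immunopositive pixels is negative by rule.
5. **Validation statistics.** 3×3 confusion matrices with concordance and
   Cohen's κ (Landis–Koch labels), sensitivity/specificity and concordance
   against FISH (HER2/Chr17 < 1.8 negative, 1.8–2.2 equivocal, > 2.2
   positive), tie-corrected rank AUC, and control-slide drift checks.
6. **Synthetic slides.** A generator renders two-stain cells with known
   per-cell intensity and continuity, artefact blobs and excluded regions,
   and labels slides with the guideline cell-fraction rules — so the whole
   pipeline is testable without clinical material.

## Worked example

```python
from her2ia import SyntheticSlideSpec, generate_slide, analyze_arrays, Her2Classifier
from her2ia.synthslide import generate_feature_table

train = generate_feature_table(10, seed=7)          # 30 slides, 10 per category
model = Her2Classifier.fit(train)

spec = SyntheticSlideSpec(n_cells=40, seed=11, stained_fraction=0.9,
                          dab_od_mean=0.45, continuity_mean=0.9, continuity_sd=0.05)
image, annotations, truth = generate_slide(spec)
result = analyze_arrays(image, annotations, classifier=model)
```

prints (via the accompanying report lines):

```
cells detected:          40
immunopositive pixels:   61.9% of tissue
membrane continuity:     80.4%
mean membrane absorbance:0.46 OD
ground-truth category:   2+
call: 2+ (68.4% confidence)
```

The rendered slide has weak-to-moderate staining (0.45 OD — far below the
~0.9 OD of a strong positive) but nearly complete membranes, exactly the
phenotype where continuity, not intensity, drives the call: the classifier
assigns 2+ (equivocal, refer to FISH) and agrees with the ground-truth
guideline label.

The same pipeline is available from the shell:

```
her2ia simulate --out-dir sim --preset 2+ --seed 5
her2ia analyze sim/slide.png --annotations sim/annotations.geojson --out-dir out
her2ia train features.csv --out model.yaml
her2ia stats calls.csv --second-rater pathologist.csv --fish ratios.csv
```

## Layout

- `her2ia.stains` — optical density, colour deconvolution, masks
- `her2ia.membrane` — membrane tracing, continuity, artefact exclusion
- `her2ia.features` — annotation rasterization, slide-level aggregates
- `her2ia.classify` — probability classifier, FISH categories, training split
- `her2ia.stats` — concordance, κ, sensitivity/specificity, AUC, drift
- `her2ia.synthslide` — synthetic slide generator with ground truth
- `her2ia.pipeline` / `her2ia.cli` — orchestration and the `her2ia` command
- `docs/methods.md` — models, parameters, design choices, limitations
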