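"""Published clinical validation cross-tabulations.

Small reference tables from a 275-case multi-antibody HER-2 validation
study: the manual-review vs automated-review 3x3 contingency table, and
the FISH (gene amplification) vs IHC cross-tabulation for the 136 cases
with informative FISH, for both the manual and automated reviews. They
drive worked examples and the reproduction of the study's agreement
statistics; the underlying images are clinical material and are not
distributable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import Her2Category

CATEGORIES = (Her2Category.NEG, Her2Category.EQUIVOCAL, Her2Category.POSITIVE)

#: Manual review (rows) vs automated image-analysis review (cols),
#: category order 0/1+, 2+, 3+; 275 cases.
MANUAL_VS_IA_COUNTS = np.array(
    [
        [178, 5, 0],
        [15, 23, 2],
        [0, 3, 49],
    ]
)

#: FISH status vs IHC category counts for the 136 FISH-informative cases.
#: Keys: review method; values: {fish status: (n 0/1+, n 2+, n 3+)}.
FISH_VS_IHC_COUNTS = {
    "manual": {
        "amplified": (7, 7, 13),
        "not_amplified": (83, 25, 1),
    },
    "image_analysis": {
        "amplified": (6, 8, 13),
        "not_amplified": (92, 17, 0),
    },
}


def manual_vs_ia_pairs() -> tuple[list[Her2Category], list[Her2Category]]:
    """Reconstruct the paired (manual, image-analysis) call lists."""
    a: list[Her2Category] = []
    b: list[Her2Category] = []
    for i, row_cat in enumerate(CATEGORIES):
        for j, col_cat in enumerate(CATEGORIES):
            n = int(MANUAL_VS_IA_COUNTS[i, j])
            a.extend([row_cat] * n)
            b.extend([col_cat] * n)
    return a, b


def fish_pairs(
    method: str, drop_false_negatives: bool = False
) -> tuple[list[Her2Category], list[Her2Category]]:
    """Reconstruct paired (IHC call, FISH category) lists for one review.

    ``drop_false_negatives`` removes the FISH-amplified cases both reviews
    called negative — the antigen-loss cases whose omission yields the
    study's 100%/100% sensitivity and specificity for the automated review.
    """
    counts = FISH_VS_IHC_COUNTS[method]
    calls: list[Her2Category] = []
    fish: list[Her2Category] = []
    for status, fish_cat in (
        ("amplified", Her2Category.POSITIVE),
        ("not_amplified", Her2Category.NEG),
    ):
        per_cat = counts[status]
        for cat, n in zip(CATEGORIES, (per_cat[0], per_cat[1], per_cat[2])):
            if (
                drop_false_negatives
                and status == "amplified"
                and cat == Her2Category.NEG
            ):
                continue
            calls.extend([cat] * n)
            fish.extend([fish_cat] * n)
    return calls, fish


def fish_table(method: str) -> pd.DataFrame:
    """The FISH cross-tabulation for one review method as a DataFrame."""
    counts = FISH_VS_IHC_COUNTS[method]
    return pd.DataFrame(
        {str(c): [counts["amplified"][i], counts["not_amplified"][i]]
         for i, c in enumerate(CATEGORIES)},
        index=["amplified", "not_amplified"],
    )
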