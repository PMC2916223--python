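"""HER-2 probability classification.

Maps the two slide-level staining features — mean membrane absorbance and
percent membrane continuity — to an ordinal HER-2 category (0/1+, 2+, 3+)
with a percentage confidence. The classifier is a Gaussian class-conditional
(quadratic discriminant) model: each category is summarised by a prior, a
mean vector and a covariance on standardized features, and Bayes' rule
yields the posterior whose maximum is the call and whose value is the
confidence. A hard rule overrides the model: any region with fewer than 1%
immunopositive pixels is negative (0/1+) by construction.

FISH (HER2/Chr17 ratio) categories follow the clinical thresholds: below
1.8 negative, 1.8-2.2 equivocal (boundaries inclusive), above 2.2 positive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ValidationError
from .features import SlideFeatures

FEATURE_COLUMNS = ("mean_membrane_absorbance", "pct_membrane_continuity")

#: regions below this immunopositive-pixel percentage are negative by rule
OVERRIDE_PCT = 1.0


class Her2Category(enum.IntEnum):
    """Ordinal IHC category: negative < equivocal (FISH referral) < positive."""

    NEG = 0        # "0/1+"
    EQUIVOCAL = 1  # "2+"
    POSITIVE = 2   # "3+"

    def __str__(self) -> str:
        return _CATEGORY_LABELS[self]


_CATEGORY_LABELS = {
    Her2Category.NEG: "0/1+",
    Her2Category.EQUIVOCAL: "2+",
    Her2Category.POSITIVE: "3+",
}
_LABEL_SYNONYMS = {
    "0/1+": Her2Category.NEG,
    "0": Her2Category.NEG,
    "1+": Her2Category.NEG,
    "2+": Her2Category.EQUIVOCAL,
    "3+": Her2Category.POSITIVE,
}


def parse_category(label: str | Her2Category) -> Her2Category:
    """Parse "0/1+", "2+", "3+" (synonyms "0" and "1+" accepted)."""
    if isinstance(label, Her2Category):
        return label
    try:
        return _LABEL_SYNONYMS[str(label).strip()]
    except KeyError:
        raise ValidationError(f"unknown HER-2 category label {label!r}") from None


@dataclass
class Her2Call:
    """A categorical HER-2 score with its percentage confidence."""

    category: Her2Category
    confidence_pct: float
    override_rule: bool = False
    posteriors: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_pct <= 100.0):
            raise ValidationError("confidence_pct outside [0, 100]")
        if self.override_rule and self.category != Her2Category.NEG:
            raise ValidationError("override rule implies a negative call")


@dataclass
class FishResult:
    """A FISH HER2/Chr17 ratio and its derived category."""

    ratio: float
    category: Her2Category = field(init=False)

    def __post_init__(self) -> None:
        self.category = fish_category(self.ratio)


def fish_category(ratio: float) -> Her2Category:
    """Clinical FISH thresholds; 1.8 and 2.2 are equivocal (inclusive)."""
    if ratio < 0:
        raise ValidationError(f"negative HER2/Chr17 ratio: {ratio}")
    if ratio < 1.8:
        return Her2Category.NEG
    if ratio <= 2.2:
        return Her2Category.EQUIVOCAL
    return Her2Category.POSITIVE


def select_training_set(
    cohorts: dict[str, list], n: int, seed: int
) -> tuple[list, list]:
    """Random per-cohort training split by the highest-random-number rule.

    Each case in each assay cohort draws one uniform number in [0, 1); the
    ``n`` highest per cohort form the training set, the rest validation.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    training: list = []
    validation: list = []
    for name in cohorts:
        ids = list(cohorts[name])
        if len(ids) < n:
            raise ValidationError(
                f"cohort {name!r} has {len(ids)} cases, fewer than n={n}"
            )
        draws = rng.random(len(ids))
        order = np.argsort(draws)[::-1]  # highest first
        chosen = set(order[:n].tolist())
        training.extend(ids[i] for i in sorted(chosen))
        validation.extend(ids[i] for i in range(len(ids)) if i not in chosen)
    return training, validation


@dataclass
class Her2Classifier:
    """Gaussian class-conditional model over (absorbance, continuity).

    Build with :meth:`fit` (or the module-level :func:`train_classifier`);
    an unfitted instance refuses to classify.
    """

    priors: np.ndarray | None = None          # (3,)
    means: np.ndarray | None = None           # (3, 2) standardized
    covariances: np.ndarray | None = None     # (3, 2, 2) standardized
    feature_mean: np.ndarray | None = None    # (2,) standardization constants
    feature_scale: np.ndarray | None = None   # (2,)
    regularization: float = 1e-3
    version: str = "her2ia-qdc-1"

    @property
    def fitted(self) -> bool:
        return self.priors is not None

    # -- training ---------------------------------------------------------

    @classmethod
    def fit(
        cls, table: pd.DataFrame, regularization: float = 1e-3
    ) -> "Her2Classifier":
        """Fit priors, class means and covariances from a labelled table.

        ``table`` needs the two feature columns plus a ``label`` column with
        values in {"0/1+", "2+", "3+"}; at least 3 examples per class.
        """
        for col in FEATURE_COLUMNS:
            if col not in table.columns:
                raise ValidationError(f"training table lacks column {col!r}")
        if "label" not in table.columns:
            raise ValidationError("training table lacks a 'label' column")
        y = np.array([parse_category(v) for v in table["label"]])
        x = table.loc[:, FEATURE_COLUMNS].to_numpy(dtype=float)

        missing = [str(c) for c in Her2Category if (y == c).sum() < 3]
        if missing:
            raise ValidationError(
                "need >= 3 training examples per class; insufficient for: "
                + ", ".join(missing)
            )

        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd

        priors = np.empty(3)
        means = np.empty((3, 2))
        covs = np.empty((3, 2, 2))
        for c in Her2Category:
            zc = z[y == c]
            priors[c] = len(zc) / len(z)
            means[c] = zc.mean(axis=0)
            covs[c] = np.cov(zc, rowvar=False, ddof=1) + regularization * np.eye(2)
        return cls(
            priors=priors,
            means=means,
            covariances=covs,
            feature_mean=mu,
            feature_scale=sd,
            regularization=regularization,
        )

    # -- inference --------------------------------------------------------

    def posterior(self, features: np.ndarray) -> np.ndarray:
        """Class posterior P(category | features) for one feature 2-vector."""
        if not self.fitted:
            raise ConfigError("classifier is not trained")
        z = (np.asarray(features, float) - self.feature_mean) / self.feature_scale
        logp = np.empty(3)
        for c in range(3):
            cov = self.covariances[c]
            diff = z - self.means[c]
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise ConfigError("class covariance not positive definite")
            maha = diff @ np.linalg.solve(cov, diff)
            logp[c] = np.log(self.priors[c]) - 0.5 * (logdet + maha)
        logp -= logp.max()
        p = np.exp(logp)
        return p / p.sum()

    def classify(self, f: SlideFeatures) -> Her2Call:
        """Call a slide: <1% immunopositive pixels forces negative, else MAP.

        Posterior ties break toward the equivocal category so that
        borderline cases are referred for confirmatory FISH.
        """
        if f.pct_immunopositive_pixels < OVERRIDE_PCT:
            return Her2Call(
                category=Her2Category.NEG,
                confidence_pct=100.0,
                override_rule=True,
            )
        x = np.array(
            [f.mean_membrane_absorbance, f.pct_membrane_continuity], float
        )
        post = self.posterior(x)
        top = post.max()
        tied = np.flatnonzero(post >= top - 1e-12)
        if Her2Category.EQUIVOCAL in tied:
            cat = Her2Category.EQUIVOCAL
        else:
            cat = Her2Category(int(tied[0]))
        return Her2Call(
            category=cat,
            confidence_pct=100.0 * float(post[cat]),
            override_rule=False,
            posteriors=post,
        )

    def classify_table(self, table: pd.DataFrame) -> pd.DataFrame:
        """Classify every row of a feature table; returns calls as a frame."""
        rows = []
        for _, r in table.iterrows():
            f = SlideFeatures(
                mean_membrane_absorbance=float(r["mean_membrane_absorbance"]),
                pct_membrane_positive_pixels=float(
                    r.get("pct_membrane_positive_pixels", 0.0)
                ),
                pct_membrane_continuity=float(r["pct_membrane_continuity"]),
                pct_immunopositive_pixels=float(
                    r.get("pct_immunopositive_pixels", 100.0)
                ),
                n_cells=int(r.get("n_cells", 0)),
            )
            call = self.classify(f)
            rows.append(
                {
                    "category": str(call.category),
                    "confidence_pct": call.confidence_pct,
                    "override_rule": call.override_rule,
                }
            )
        return pd.DataFrame(rows, index=table.index)

    # -- reporting and persistence ---------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted model parameters."""
        if not self.fitted:
            return "Her2Classifier (unfitted)"
        lines = [
            "HER-2 Gaussian class-conditional classifier",
            f"version: {self.version}",
            f"features: {', '.join(FEATURE_COLUMNS)}",
            f"standardization mean: {self.feature_mean.tolist()}",
            f"standardization scale: {self.feature_scale.tolist()}",
            f"covariance regularization: {self.regularization}",
            "",
            f"{'class':>8} {'prior':>8} {'mean (std units)':>28} {'cov diag':>24}",
        ]
        for c in Her2Category:
            lines.append(
                f"{str(c):>8} {self.priors[c]:8.4f} "
                f"{np.array2string(self.means[c], precision=3):>28} "
                f"{np.array2string(np.diag(self.covariances[c]), precision=3):>24}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        if not self.fitted:
            raise ConfigError("cannot serialize an unfitted classifier")
        return {
            "version": self.version,
            "features": list(FEATURE_COLUMNS),
            "regularization": float(self.regularization),
            "feature_mean": [float(v) for v in self.feature_mean],
            "feature_scale": [float(v) for v in self.feature_scale],
            "classes": {
                str(c): {
                    "prior": float(self.priors[c]),
                    "mean": [float(v) for v in self.means[c]],
                    "covariance": [[float(v) for v in row]
                                   for row in self.covariances[c]],
                }
                for c in Her2Category
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "Her2Classifier":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        try:
            classes = d["classes"]
            return cls(
                priors=np.array([classes[str(c)]["prior"] for c in Her2Category]),
                means=np.array([classes[str(c)]["mean"] for c in Her2Category]),
                covariances=np.array(
                    [classes[str(c)]["covariance"] for c in Her2Category]
                ),
                feature_mean=np.array(d["feature_mean"], float),
                feature_scale=np.array(d["feature_scale"], float),
                regularization=float(d["regularization"]),
                version=str(d.get("version", "unknown")),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad classifier model file {path}: {exc}") from exc


def train_classifier(table: pd.DataFrame, **kwargs) -> Her2Classifier:
    """Functional alias for :meth:`Her2Classifier.fit`."""
    return Her2Classifier.fit(table, **kwargs)


def classify(model: Her2Classifier, f: SlideFeatures) -> Her2Call:
    """Functional alias for :meth:`Her2Classifier.classify`."""
    return model.classify(f)
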