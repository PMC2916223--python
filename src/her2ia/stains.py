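"""Stain separation for brightfield IHC images.

Converts RGB images to optical density (absorbance) under the Beer-Lambert
law, separates the haematoxylin (nuclear counterstain) and DAB (HER-2
chromogen) contributions in a configurable stain-vector basis, and derives
the immunopositive-pixel and tissue masks that all downstream membrane and
feature measurements rest on.

The "colour definition" bundles everything that defines immunopositive
tissue: the three unit stain vectors, the background (blank-glass)
intensity, and the DAB-positivity and tissue OD thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from skimage.morphology import remove_small_objects

from .errors import ConfigError, FormatError

# Published haematoxylin / DAB reference absorbance vectors (RGB, unit norm
# after normalisation below). Third vector is the mutually orthogonal
# residual completing the basis.
_HAEM_RGB = (0.650, 0.704, 0.286)
_DAB_RGB = (0.268, 0.570, 0.776)

#: Intensity offset in the OD transform; avoids log(0) at saturated black.
OD_EPSILON = 1.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ConfigError("stain vector has zero norm")
    return v / n


@dataclass(frozen=True)
class ColourDefinition:
    """Stain reference vectors and thresholds defining immunopositive tissue.

    Parameters
    ----------
    stain_vectors : (3, 3) array
        Rows are unit OD-space RGB vectors for haematoxylin, DAB and the
        residual channel, in that order.
    background_intensity : float
        Blank-glass intensity I0 per channel, in [1, 255].
    dab_positive_threshold : float
        DAB concentration (OD units along the DAB vector) at or above which
        a pixel counts as immunopositive. Must be > 0.
    tissue_threshold : float
        OD-vector magnitude at or above which a pixel counts as tissue.
        Must be > 0.
    min_tissue_object_px : int
        Connected components of tissue smaller than this are dropped from
        the tissue mask (speckle removal).
    """

    stain_vectors: np.ndarray = field(
        default_factory=lambda: _default_stain_matrix()
    )
    background_intensity: float = 255.0
    dab_positive_threshold: float = 0.15
    tissue_threshold: float = 0.10
    min_tissue_object_px: int = 16

    def __post_init__(self) -> None:
        m = np.asarray(self.stain_vectors, dtype=float)
        if m.shape != (3, 3):
            raise ConfigError(f"stain_vectors must be 3x3, got {m.shape}")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ConfigError("stain vectors must have unit Euclidean norm")
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e8:
            raise ConfigError("stain vectors are linearly dependent")
        if not (1.0 <= self.background_intensity <= 255.0):
            raise ConfigError(
                "background_intensity must be in [1, 255], got "
                f"{self.background_intensity}"
            )
        if self.dab_positive_threshold <= 0:
            raise ConfigError("dab_positive_threshold must be > 0")
        if self.tissue_threshold <= 0:
            raise ConfigError("tissue_threshold must be > 0")
        object.__setattr__(self, "stain_vectors", m)

    @property
    def haematoxylin(self) -> np.ndarray:
        return self.stain_vectors[0]

    @property
    def dab(self) -> np.ndarray:
        return self.stain_vectors[1]

    def with_(self, **kwargs) -> "ColourDefinition":
        return replace(self, **kwargs)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "stain_vectors": {
                "haematoxylin": [float(x) for x in self.stain_vectors[0]],
                "dab": [float(x) for x in self.stain_vectors[1]],
                "residual": [float(x) for x in self.stain_vectors[2]],
            },
            "background_intensity": float(self.background_intensity),
            "dab_positive_threshold": float(self.dab_positive_threshold),
            "tissue_threshold": float(self.tissue_threshold),
            "min_tissue_object_px": int(self.min_tissue_object_px),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ColourDefinition":
        kwargs = dict(d)
        sv = kwargs.pop("stain_vectors", None)
        if sv is not None:
            if isinstance(sv, dict):
                rows = [sv["haematoxylin"], sv["dab"], sv["residual"]]
            else:
                rows = sv
            kwargs["stain_vectors"] = np.array(
                [_unit(np.asarray(r, dtype=float)) for r in rows]
            )
        return cls(**kwargs)

    @classmethod
    def load(cls, path) -> "ColourDefinition":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"colour definition file {path} is not a mapping")
        try:
            return cls.from_dict(d)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad colour definition file {path}: {exc}") from exc


def _default_stain_matrix() -> np.ndarray:
    h = _unit(np.asarray(_HAEM_RGB))
    d = _unit(np.asarray(_DAB_RGB))
    r = _unit(np.cross(h, d))
    return np.vstack([h, d, r])


@dataclass(frozen=True)
class OpticalDensityImage:
    """Per-pixel optical-density 3-vectors, shape (H, W, 3), values >= 0."""

    od: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.od, dtype=float)
        if a.ndim != 3 or a.shape[2] != 3:
            raise FormatError(f"optical density array must be (H, W, 3), got {a.shape}")
        object.__setattr__(self, "od", a)

    @property
    def height(self) -> int:
        return self.od.shape[0]

    @property
    def width(self) -> int:
        return self.od.shape[1]

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.od, axis=2)


@dataclass(frozen=True)
class StainChannels:
    """Per-pixel stain concentrations after deconvolution (OD units)."""

    dab: np.ndarray
    haematoxylin: np.ndarray
    residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dab.shape != self.haematoxylin.shape:
            raise FormatError("stain channel shapes differ")


def rgb_to_optical_density(
    image: np.ndarray, cdef: ColourDefinition
) -> OpticalDensityImage:
    """Convert an 8-bit RGB image to optical density.

    OD = -log10((v + eps) / I0) per channel, clamped below at zero; eps = 1
    keeps saturated-black pixels finite.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(
            f"expected a 3-channel RGB image, got array of shape {img.shape}"
        )
    i0 = cdef.background_intensity
    v = img.astype(float)
    od = -np.log10((v + OD_EPSILON) / i0)
    np.clip(od, 0.0, None, out=od)
    return OpticalDensityImage(od)


def separate_stains(
    od: OpticalDensityImage, cdef: ColourDefinition
) -> StainChannels:
    """Express each pixel's OD vector in the stain basis.

    Solves the 3x3 linear system per pixel; noise-driven negative
    coefficients are clamped to zero.
    """
    m = cdef.stain_vectors
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e8:
        raise ConfigError("stain matrix is singular; cannot deconvolve")
    # OD = C @ M with C the concentration row vectors => C = OD @ inv(M)
    inv = np.linalg.inv(m)
    conc = od.od @ inv
    np.clip(conc, 0.0, None, out=conc)
    return StainChannels(
        haematoxylin=conc[..., 0], dab=conc[..., 1], residual=conc[..., 2]
    )


def immunopositive_mask(ch: StainChannels, cdef: ColourDefinition) -> np.ndarray:
    """Pixels whose DAB concentration meets the positivity threshold."""
    if cdef.dab_positive_threshold <= 0:  # defensive; constructor enforces
        raise ConfigError("dab_positive_threshold must be > 0")
    return ch.dab >= cdef.dab_positive_threshold


def tissue_mask(od: OpticalDensityImage, cdef: ColourDefinition) -> np.ndarray:
    """Pixels with enough total absorbance to count as tissue.

    OD-vector magnitude >= tissue_threshold (boundary included), followed by
    small-object removal to suppress isolated speckle.
    """
    mask = od.magnitude >= cdef.tissue_threshold
    if cdef.min_tissue_object_px > 1:
        mask = remove_small_objects(mask, max_size=cdef.min_tissue_object_px - 1)
    return mask


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def load_mask(path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into a boolean mask."""
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)) > 127
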