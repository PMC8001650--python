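"""Whole-section DAB immunohistochemistry positivity quantification.

Five-stage pipeline over an RGB section image:

1. tissue segmentation — Otsu threshold on grayscale luminance separates
   tissue from the white slide background;
2. k-means colour clustering (default k = 6) of the tissue pixels in RGB;
3. positive-cluster selection — a cluster is DAB-positive when its mean
   colour's hue lies within a window of the DAB reference hue and its
   saturation clears a floor;
4. refinement — the same hue/saturation gate applied per pixel inside the
   candidate mask, then small connected components dropped as noise;
5. percent positive = 100 · positive pixels / tissue pixels.

Hue/saturation gating is used for "positive" because hue is nearly invariant
to staining intensity and illumination, which is what makes DAB brown
separable from the hematoxylin counterstain.  Clustering is run on the
sorted unique tissue colours with multiplicity weights, which makes the
result deterministic for a given seed and invariant to pixel order (hence to
rotations and flips of the section).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import morphology
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

__all__ = [
    "StainProfile",
    "IHCResult",
    "segment_tissue",
    "cluster_stains",
    "select_positive_clusters",
    "refine_positive_mask",
    "percent_positive",
    "quantify_section",
]

#: DAB brown and hematoxylin blue references used by the default profile.
DAB_BROWN = (130, 80, 50)
HEMATOXYLIN_BLUE = (70, 70, 150)


@dataclass
class StainProfile:
    """Colour gates defining "positively stained" for one IHC marker.

    ``hue_window`` is the maximum circular hue distance (degrees) from the
    reference colour's hue; ``min_saturation`` floors the HSV saturation so
    near-grey pixels never count; components smaller than
    ``min_component_px`` (8-connectivity) are discarded as noise.
    """

    positive_reference_color: tuple[int, int, int] = DAB_BROWN
    counter_reference_color: tuple[int, int, int] = HEMATOXYLIN_BLUE
    hue_window: float = 20.0
    min_saturation: float = 0.15
    min_component_px: int = 25

    def __post_init__(self) -> None:
        if not 0 <= self.hue_window <= 180:
            raise ValueError("hue_window must be in [0, 180] degrees")
        if not 0 <= self.min_saturation <= 1:
            raise ValueError("min_saturation must be in [0, 1]")

    @property
    def reference_hue(self) -> float:
        return _rgb_hue_sat(np.array(self.positive_reference_color, float))[0]


@dataclass
class IHCResult:
    n_tissue_px: int
    n_positive_px: int
    percent_positive: float
    stage_counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"n_tissue_px": self.n_tissue_px, "n_positive_px": self.n_positive_px,
                "percent_positive": self.percent_positive}


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB image, got shape {img.shape}")
    return img


def _rgb_hue_sat(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hue (degrees) and saturation of RGB values scaled 0–255."""
    hsv = skcolor.rgb2hsv(np.asarray(rgb, float).reshape(-1, 1, 3) / 255.0)
    return hsv[..., 0].ravel() * 360.0, hsv[..., 1].ravel()


def _hue_distance(h: np.ndarray, ref: float) -> np.ndarray:
    d = np.abs(h - ref) % 360.0
    return np.minimum(d, 360.0 - d)


def segment_tissue(img: np.ndarray) -> np.ndarray:
    """Separate tissue from white background by Otsu on luminance.

    Pixels darker than the optimal global threshold are tissue.  A blank
    single-intensity image yields an empty mask with a warning rather than
    an error (a slide with no section on it).
    """
    img = _check_rgb(img)
    gray = skcolor.rgb2gray(img.astype(float) / 255.0)
    if np.ptp(gray) == 0:
        warnings.warn("blank image: no tissue found", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    mask = gray < threshold_otsu(gray)
    log.debug("segment_tissue: %d tissue px of %d", mask.sum(), mask.size)
    return mask


def cluster_stains(img: np.ndarray, tissue: np.ndarray, k: int = 6,
                   seed: int = 0) -> np.ndarray:
    """k-means colour clustering of tissue pixels; background stays −1.

    Fits on the sorted unique colours weighted by multiplicity (same
    objective as fitting every pixel, but deterministic and order
    invariant); k-means++ init with 10 restarts at the given seed.  If the
    tissue has fewer distinct colours than k, the achievable number of
    clusters is returned with a warning.
    """
    img = _check_rgb(img)
    tissue = np.asarray(tissue, dtype=bool)
    if tissue.shape != img.shape[:2]:
        raise ValueError("tissue mask shape mismatch")
    if not tissue.any():
        raise ValueError("tissue mask is empty")
    if k < 2:
        raise ValueError("k must be >= 2")

    colors = img[tissue].reshape(-1, 3).astype(float)
    uniq, inverse, counts = np.unique(colors, axis=0, return_inverse=True,
                                      return_counts=True)
    if uniq.shape[0] < k:
        warnings.warn(f"only {uniq.shape[0]} distinct tissue colours; using that many clusters")
        k = uniq.shape[0]
    if k == 1:
        uniq_labels = np.zeros(uniq.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        uniq_labels = km.fit_predict(uniq, sample_weight=counts)
    labels = np.full(img.shape[:2], -1, dtype=int)
    labels[tissue] = uniq_labels[inverse]
    return labels


def select_positive_clusters(labels: np.ndarray, img: np.ndarray,
                             profile: StainProfile | None = None) -> np.ndarray:
    """Union of clusters whose mean colour passes the DAB hue/saturation gate.

    An empty mask is a valid outcome: a fully negative section.
    """
    profile = profile or StainProfile()
    img = _check_rgb(img)
    labels = np.asarray(labels)
    mask = np.zeros(labels.shape, dtype=bool)
    for lab in np.unique(labels[labels >= 0]):
        mean_color = img[labels == lab].reshape(-1, 3).mean(axis=0)
        hue, sat = _rgb_hue_sat(mean_color)
        if (_hue_distance(hue, profile.reference_hue)[0] <= profile.hue_window
                and sat[0] >= profile.min_saturation):
            mask |= labels == lab
    log.debug("select_positive_clusters: %d candidate px", mask.sum())
    return mask


def refine_positive_mask(candidate: np.ndarray, img: np.ndarray,
                         profile: StainProfile | None = None) -> np.ndarray:
    """Per-pixel colour thresholding inside the candidate, then de-noising.

    Keeps only candidate pixels individually passing the hue/saturation
    gate, then removes 8-connected components smaller than
    ``min_component_px``.  Never adds pixels.
    """
    profile = profile or StainProfile()
    img = _check_rgb(img)
    candidate = np.asarray(candidate, dtype=bool)
    if not candidate.any():
        return candidate.copy()
    px = img[candidate].reshape(-1, 3).astype(float)
    hue, sat = _rgb_hue_sat(px)
    keep = (_hue_distance(hue, profile.reference_hue) <= profile.hue_window) & (
        sat >= profile.min_saturation)
    refined = np.zeros_like(candidate)
    refined[candidate] = keep
    # drop components strictly smaller than min_component_px (max_size keeps >=)
    refined = morphology.remove_small_objects(
        refined, max_size=profile.min_component_px - 1, connectivity=2)
    return refined


def percent_positive(pos: np.ndarray, tissue: np.ndarray) -> IHCResult:
    """Positive fraction of the tissue, as a percentage."""
    pos = np.asarray(pos, dtype=bool)
    tissue = np.asarray(tissue, dtype=bool)
    if pos.shape != tissue.shape:
        raise ValueError("mask shape mismatch")
    if not tissue.any():
        raise ValueError("tissue mask is empty; percent positive undefined")
    if (pos & ~tissue).any():
        raise ValueError("positive mask extends outside the tissue mask")
    n_t = int(tissue.sum())
    n_p = int(pos.sum())
    return IHCResult(n_t, n_p, 100.0 * n_p / n_t)


def quantify_section(img: np.ndarray, profile: StainProfile | None = None,
                     seed: int = 0, k: int = 6) -> IHCResult:
    """Run the full five-stage positivity pipeline on one section image."""
    profile = profile or StainProfile()
    img = _check_rgb(img)
    tissue = segment_tissue(img)
    if not tissue.any():
        raise ValueError("no tissue found in image")
    labels = cluster_stains(img, tissue, k=k, seed=seed)
    candidate = select_positive_clusters(labels, img, profile)
    refined = refine_positive_mask(candidate, img, profile)
    refined &= tissue
    result = percent_positive(refined, tissue)
    result.stage_counts = {
        "tissue_px": int(tissue.sum()),
        "candidate_px": int(candidate.sum()),
        "refined_px": int(refined.sum()),
    }
    log.info("quantify_section: %s", result.stage_counts)
    return result
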