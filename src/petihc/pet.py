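"""SUV quantification of PET activity volumes inside tumour ROIs.

The standardized uptake value normalises the tissue activity concentration
``C`` (kBq/mL) by the injected dose per unit body weight::

    SUV = C / (dose / weight)

with dose in kBq and weight in grams; under the 1 g ≡ 1 mL tissue-density
convention the SUV is dimensionless.  Decay correction of the dose
(``dose · 2^(−t/T½)``) is available but off by default: uncorrected dose is
what the plain formula states, and whether a given study decay-corrected is
an acquisition detail, not a property of the quantification.

Volumes and masks are exchanged as NIfTI-1 with a JSON metadata sidecar
(``injected_dose_kbq``, ``body_weight_g``, ``tracer`` and optional
``time_post_injection_h``, ``half_life_h``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ConfigurationError",
    "PETVolume",
    "ROIMask",
    "SUVSummary",
    "CaliperMeasurement",
    "compute_suv",
    "summarize_roi",
    "caliper_volume",
    "save_pet_volume",
    "load_pet_volume",
    "save_mask",
    "load_mask",
]


class ConfigurationError(ValueError):
    """Raised when requested processing needs metadata the volume lacks."""


@dataclass
class PETVolume:
    """A 3-D activity-concentration grid plus the acquisition metadata SUV needs.

    Parameters
    ----------
    voxels : ndarray
        Activity concentration per voxel, kBq/mL; finite and non-negative.
    spacing : tuple of float
        Voxel size along each axis, mm.
    injected_dose_kbq : float
        Injected activity at injection time, kBq.
    body_weight_g : float
        Animal body weight, g.
    tracer : str
        Tracer label, e.g. ``"Zr89-pertuzumab"`` or ``"F18-FDG"``.
    time_post_injection_h, half_life_h : float, optional
        Needed only when decay-correcting the dose.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    injected_dose_kbq: float
    body_weight_g: float
    tracer: str
    time_post_injection_h: float | None = None
    half_life_h: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3-D, got ndim={self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("voxel activities must be finite and >= 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not self.injected_dose_kbq > 0:
            raise ValueError(f"injected_dose_kbq must be > 0, got {self.injected_dose_kbq}")
        if not self.body_weight_g > 0:
            raise ValueError(f"body_weight_g must be > 0, got {self.body_weight_g}")


@dataclass
class ROIMask:
    """Boolean voxel mask delineating a whole-tumour region of interest."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class SUVSummary:
    """Mean / max / sum / SD and frequency histogram of SUV inside an ROI."""

    mean: float
    max: float
    sum: float
    sd: float
    n_voxels: int
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "max": self.max,
            "sum": self.sum,
            "sd": self.sd,
            "n_voxels": self.n_voxels,
            "histogram": {
                "bin_edges": np.asarray(self.bin_edges).tolist(),
                "counts": np.asarray(self.counts).tolist(),
            },
        }


@dataclass
class CaliperMeasurement:
    """Transverse and longitudinal tumour diameters from caliper, mm."""

    transverse: float
    longitudinal: float

    def __post_init__(self) -> None:
        if not (self.transverse > 0 and self.longitudinal > 0):
            raise ValueError("caliper diameters must be > 0")


def compute_suv(volume: PETVolume, decay_correct: bool = False) -> np.ndarray:
    """Convert an activity volume to a dimensionless SUV grid.

    Every voxel becomes ``C / (dose_eff / weight)`` where ``dose_eff`` is the
    injected dose, decay-corrected to the scan time when ``decay_correct``
    is set (``dose · 2^(−t/T½)``).
    """
    dose = volume.injected_dose_kbq
    if decay_correct:
        if volume.time_post_injection_h is None or volume.half_life_h is None:
            raise ConfigurationError(
                "decay correction needs time_post_injection_h and half_life_h"
            )
        dose = dose * 2.0 ** (-volume.time_post_injection_h / volume.half_life_h)
    return volume.voxels / (dose / volume.body_weight_g)


def summarize_roi(
    suv: np.ndarray, mask: ROIMask | np.ndarray, bin_width: float = 0.1
) -> SUVSummary:
    """Summarise SUV statistics over the masked voxels only.

    The frequency histogram covers [0, max] with uniform bins of
    ``bin_width``; the final bin is right-closed so the maximum is counted.
    The SD is the population SD of the masked voxels (a singleton ROI has
    SD 0).
    """
    suv = np.asarray(suv, dtype=float)
    m = mask.voxels if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if m.shape != suv.shape:
        raise ValueError(f"mask shape {m.shape} != SUV shape {suv.shape}")
    if not m.any():
        raise ValueError("ROI mask is empty")
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")

    vals = suv[m]
    vmax = float(vals.max())
    n_bins = max(1, math.ceil(vmax / bin_width)) if vmax > 0 else 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    return SUVSummary(
        mean=float(vals.mean()),
        max=vmax,
        sum=float(vals.sum()),
        sd=float(vals.std(ddof=0)),
        n_voxels=int(vals.size),
        bin_edges=edges,
        counts=counts,
    )


def caliper_volume(m: CaliperMeasurement) -> float:
    """Ellipsoid tumour volume from caliper diameters, mm³.

    ``V = (π/6) · transverse² · longitudinal`` — the standard two-diameter
    xenograft formula (a sphere when the diameters agree).
    """
    return math.pi / 6.0 * m.transverse**2 * m.longitudinal


# ---------------------------------------------------------------------------
# NIfTI + JSON-sidecar I/O


def save_pet_volume(volume: PETVolume, nii_path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a ``.json`` metadata sidecar alongside."""
    nii_path = Path(nii_path)
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels.astype(np.float32), affine), nii_path)
    meta = {
        "injected_dose_kbq": volume.injected_dose_kbq,
        "body_weight_g": volume.body_weight_g,
        "tracer": volume.tracer,
        "time_post_injection_h": volume.time_post_injection_h,
        "half_life_h": volume.half_life_h,
    }
    _sidecar(nii_path).write_text(json.dumps(meta, indent=1))


def load_pet_volume(nii_path: str | Path, meta_path: str | Path | None = None) -> PETVolume:
    nii_path = Path(nii_path)
    img = nib.load(nii_path)
    meta = json.loads(Path(meta_path or _sidecar(nii_path)).read_text())
    return PETVolume(
        voxels=np.asanyarray(img.dataobj, dtype=float),
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
        injected_dose_kbq=meta["injected_dose_kbq"],
        body_weight_g=meta["body_weight_g"],
        tracer=meta["tracer"],
        time_post_injection_h=meta.get("time_post_injection_h"),
        half_life_h=meta.get("half_life_h"),
    )


def save_mask(mask: ROIMask, nii_path: str | Path) -> None:
    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), Path(nii_path))


def load_mask(nii_path: str | Path) -> ROIMask:
    img = nib.load(Path(nii_path))
    return ROIMask(
        voxels=np.asanyarray(img.dataobj) > 0,
        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


def _sidecar(nii_path: Path) -> Path:
    name = nii_path.name
    for suff in (".nii.gz", ".nii"):
        if name.endswith(suff):
            return nii_path.with_name(name[: -len(suff)] + ".json")
    return nii_path.with_suffix(".json")
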