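"""Synthetic whole-body-like PET phantoms and acquisition emulation.

The phantom is a noiseless 3D activity map in SUV units: a soft-tissue
background, a large uniform liver ellipsoid (the reference region for the
coefficient-of-variation noise metric) and a handful of spherical focal
hotspots ("lesions") with known true uptake. Acquisition is emulated
statistically rather than event-by-event: a frame of a given duration is an
independent per-voxel Poisson draw whose mean is activity x duration x
scanner sensitivity, and list-mode interval extraction is emulated by exact
multinomial splitting of the parent frame's counts. A regularized iterative
reconstruction is emulated by converting counts back to concentration and
applying a Gaussian with a regularization-strength (beta) dependent width:
larger beta means stronger noise suppression, mirroring the penalty weight
of a penalized-likelihood PET reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "ActivityVolume",
    "CountVolume",
    "SUVVolume",
    "ScannerCalib",
    "build_phantom",
    "random_phantom_spec",
    "simulate_frame",
    "split_frame",
    "sum_frames",
    "emulate_reconstruction",
    "default_beta_fwhm",
    "FWHM_TO_SIGMA",
]

#: conversion factor between Gaussian FWHM and standard deviation
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: default voxel geometry, (slice, row, col) in mm
DEFAULT_VOXEL_SIZE = (2.8, 2.7, 2.7)


class GeometryError(ValueError):
    """A phantom structure does not fit inside the voxel grid."""


@dataclass(frozen=True)
class LesionSpec:
    """A spherical focal hotspot with known true uptake.

    center is in voxel coordinates (slice, row, col); diameter in mm;
    suv is the true uptake painted inside the sphere (hotspot convention:
    must exceed the background).
    """

    center: Tuple[float, float, float]
    diameter_mm: float
    suv: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError(f"lesion diameter must be > 0, got {self.diameter_mm}")
        if self.suv < 0:
            raise ValueError("lesion SUV must be >= 0")


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid (used for the liver), in voxel coords / mm."""

    center: Tuple[float, float, float]
    semi_axes_mm: Tuple[float, float, float]
    suv: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a noiseless phantom.

    shape is (slices, rows, cols); voxel_size is (slice, row, col) in mm.
    """

    shape: Tuple[int, int, int] = (71, 128, 128)
    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    background_suv: float = 0.7
    liver: Optional[EllipsoidSpec] = None
    lesions: Tuple[LesionSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_suv < 0:
            raise ValueError("background SUV must be >= 0")
        if any(s <= 0 for s in self.shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("shape and voxel size must be positive")
        for les in self.lesions:
            if les.suv <= self.background_suv:
                raise ValueError(
                    "hotspot convention: lesion SUV must exceed the background"
                )


@dataclass
class ActivityVolume:
    """Noiseless ground-truth activity map (SUV units) plus named masks."""

    values: np.ndarray
    voxel_size: Tuple[float, float, float]
    masks: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape


@dataclass
class CountVolume:
    """Integer event-count field for one acquisition frame."""

    counts: np.ndarray
    duration_min: float
    sensitivity: float

    def __post_init__(self) -> None:
        if self.duration_min < 0:
            raise ValueError("frame duration must be >= 0")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise TypeError("counts must be an integer array")


@dataclass
class SUVVolume:
    """Reconstructed image in SUV units."""

    values: np.ndarray
    voxel_size: Tuple[float, float, float]
    label: str = ""

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape


def default_beta_fwhm(beta: float) -> float:
    """Default monotone map from regularization strength to smoothing FWHM (mm)."""
    return 2.0 + beta / 250.0


@dataclass(frozen=True)
class ScannerCalib:
    """Emulated scanner calibration.

    sensitivity: expected counts per SUV-unit per minute per voxel.
    psf_fwhm_mm: intrinsic reconstructed resolution, combined in quadrature
    with the beta-dependent smoothing.
    """

    sensitivity: float = 1.0
    psf_fwhm_mm: float = 4.0
    beta_fwhm: Callable[[float], float] = default_beta_fwhm

    def __post_init__(self) -> None:
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be > 0")

    def total_fwhm_mm(self, beta: float) -> float:
        return float(np.hypot(self.psf_fwhm_mm, self.beta_fwhm(beta)))


def _sphere_mask(
    shape: Sequence[int],
    voxel_size: Sequence[float],
    center: Sequence[float],
    radius_mm: float,
) -> np.ndarray:
    """Voxel-center rasterization of a sphere (distance <= radius)."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(
        ((g - c) * v) ** 2 for g, c, v in zip(grids, center, voxel_size)
    )
    return d2 <= radius_mm**2


def _ellipsoid_mask(
    shape: Sequence[int],
    voxel_size: Sequence[float],
    center: Sequence[float],
    semi_axes_mm: Sequence[float],
) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(
        (((g - c) * v) / a) ** 2
        for g, c, v, a in zip(grids, center, voxel_size, semi_axes_mm)
    )
    return d2 <= 1.0


def _check_inside(mask: np.ndarray, name: str) -> None:
    """A structure must not touch the grid boundary (it would be clipped)."""
    if not mask.any():
        raise GeometryError(f"{name} rasterizes to an empty region")
    for ax in range(mask.ndim):
        first = np.take(mask, 0, axis=ax)
        last = np.take(mask, mask.shape[ax] - 1, axis=ax)
        if first.any() or last.any():
            raise GeometryError(f"{name} extends outside the grid")


def build_phantom(spec: PhantomSpec) -> ActivityVolume:
    """Rasterize a PhantomSpec into a noiseless SUV map with named masks.

    The volume equals the background everywhere except inside the liver and
    lesion masks, where the respective SUV level is painted. Lesions are
    spheres rasterized by voxel-center inclusion; a lesion overrides the
    liver where they would overlap, so returned masks are pairwise disjoint
    and match the painted regions exactly.
    """
    values = np.full(spec.shape, spec.background_suv, dtype=np.float64)
    masks: Dict[str, np.ndarray] = {}

    liver_mask = None
    if spec.liver is not None:
        liver_mask = _ellipsoid_mask(
            spec.shape, spec.voxel_size, spec.liver.center, spec.liver.semi_axes_mm
        )
        _check_inside(liver_mask, "liver")
        values[liver_mask] = spec.liver.suv

    for i, les in enumerate(spec.lesions):
        m = _sphere_mask(
            spec.shape, spec.voxel_size, les.center, les.diameter_mm / 2.0
        )
        _check_inside(m, f"lesion_{i}")
        values[m] = les.suv
        if liver_mask is not None:
            liver_mask &= ~m
        for prev in masks.values():
            prev &= ~m
        masks[f"lesion_{i}"] = m

    if liver_mask is not None:
        masks["liver"] = liver_mask

    return ActivityVolume(values=values, voxel_size=spec.voxel_size, masks=masks)


def random_phantom_spec(
    seed: int,
    shape: Tuple[int, int, int] = (71, 64, 64),
    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    n_lesions: int = 3,
    background_suv: float = 0.7,
    liver_suv: float = 2.0,
    lesion_suv_range: Tuple[float, float] = (2.0, 8.0),
    lesion_diameter_range_mm: Tuple[float, float] = (10.0, 20.0),
) -> PhantomSpec:
    """Draw a whole-body-like phantom: uniform liver + focal hotspots.

    Lesion true SUVs are uniform over a wide range so the evaluated lesions
    span small-to-large uptake; lesions are placed in the background,
    outside the liver and away from the grid edges, pairwise non-adjacent.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    vz, vy, vx = voxel_size

    # liver large enough to host the three 6-cm noise ROIs with margin,
    # as the liver-COV protocol presumes
    liver_center = (nz * 0.5, ny * 0.5, nx * 0.5)
    liver = EllipsoidSpec(
        center=liver_center, semi_axes_mm=(30.0, 45.0, 45.0), suv=liver_suv
    )

    lesions: List[LesionSpec] = []
    attempts = 0
    while len(lesions) < n_lesions:
        attempts += 1
        if attempts > 1000:
            raise GeometryError("could not place lesions without overlap")
        d = rng.uniform(*lesion_diameter_range_mm)
        r_vox = np.array([d / 2 / vz, d / 2 / vy, d / 2 / vx])
        lo = r_vox + 1.5
        hi = np.array(shape) - r_vox - 1.5
        c = rng.uniform(lo, hi)
        # keep outside a safety margin around the liver ellipsoid
        rel = (c - np.array(liver_center)) * np.array(voxel_size)
        margin = np.array(liver.semi_axes_mm) + d / 2 + 6.0
        if float(np.sum((rel / margin) ** 2)) < 1.0:
            continue
        ok = True
        for prev in lesions:
            dist = np.linalg.norm(
                (c - np.array(prev.center)) * np.array(voxel_size)
            )
            if dist < (d + prev.diameter_mm) / 2 + 6.0:
                ok = False
                break
        if not ok:
            continue
        suv = rng.uniform(*lesion_suv_range)
        lesions.append(LesionSpec(center=tuple(c), diameter_mm=d, suv=suv))

    return PhantomSpec(
        shape=shape,
        voxel_size=voxel_size,
        background_suv=background_suv,
        liver=liver,
        lesions=tuple(lesions),
        seed=seed,
    )


def simulate_frame(
    act: ActivityVolume, duration_min: float, calib: ScannerCalib, seed: int
) -> CountVolume:
    """Acquire one frame: independent Poisson counts per voxel.

    Mean counts = activity (SUV) x duration (min) x sensitivity. The same
    (inputs, seed) always produce the same frame.
    """
    if duration_min < 0:
        raise ValueError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    lam = act.values * duration_min * calib.sensitivity
    counts = rng.poisson(lam).astype(np.int64)
    return CountVolume(
        counts=counts, duration_min=duration_min, sensitivity=calib.sensitivity
    )


def split_frame(frame: CountVolume, n_intervals: int, seed: int) -> List[CountVolume]:
    """Partition a frame's counts into equal sub-intervals, exactly.

    Per voxel the counts are split by a multinomial draw with equal
    probabilities 1/n_intervals (sequential binomial thinning, which is the
    exact multinomial scheme); the voxelwise sum over all outputs equals
    the input. This is the statistical stand-in for reconstructing list-mode
    sub-intervals of one acquisition; at fixed total the sub-frames are
    negatively correlated, as are real sub-intervals at fixed event count.
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if n_intervals == 1:
        return [replace(frame, counts=frame.counts.copy())]
    rng = np.random.default_rng(seed)
    remaining = frame.counts.copy()
    sub_duration = frame.duration_min / n_intervals
    out: List[CountVolume] = []
    for i in range(n_intervals - 1):
        p = 1.0 / (n_intervals - i)
        c = rng.binomial(remaining, p)
        remaining -= c
        out.append(
            CountVolume(
                counts=c.astype(np.int64),
                duration_min=sub_duration,
                sensitivity=frame.sensitivity,
            )
        )
    out.append(
        CountVolume(
            counts=remaining.astype(np.int64),
            duration_min=sub_duration,
            sensitivity=frame.sensitivity,
        )
    )
    return out


def sum_frames(frames: Sequence[CountVolume]) -> CountVolume:
    """Concatenate consecutive sub-intervals back into one frame."""
    if not frames:
        raise ValueError("need at least one frame")
    counts = np.sum([f.counts for f in frames], axis=0).astype(np.int64)
    duration = float(sum(f.duration_min for f in frames))
    return CountVolume(
        counts=counts, duration_min=duration, sensitivity=frames[0].sensitivity
    )


def emulate_reconstruction(
    frame: CountVolume,
    beta: float,
    calib: ScannerCalib,
    voxel_size: Tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    weight_kg: float = 70.0,
    injected_mbq: float = 280.0,
    label: str = "",
) -> SUVVolume:
    """Emulated regularized reconstruction of one frame, in SUV units.

    Counts are converted back to activity concentration, smoothed with a
    Gaussian whose FWHM combines the intrinsic PSF and the beta-mapped
    smoothing in quadrature, and scaled to SUV with the standard convention
    (concentration x body weight / injected activity, 1 g/mL tissue).
    Reflective boundaries with a normalized kernel make a constant field a
    fixed point of the smoothing, and conserve total activity away from
    strong gradients at the boundary.
    """
    from .metrics import suv_convert

    if frame.duration_min <= 0:
        raise ValueError("frame duration must be > 0 to reconstruct")
    if frame.sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    # counts/(duration x sensitivity) estimates uptake in SUV units; express
    # it as concentration (kBq/mL) for this subject so the reconstruction
    # goes through the same SUV scaling as a real scanner pipeline.
    est_suv = frame.counts.astype(np.float64) / (
        frame.duration_min * frame.sensitivity
    )
    concentration = est_suv * (injected_mbq / weight_kg)
    fwhm = calib.total_fwhm_mm(beta)
    sigma_vox = [fwhm * FWHM_TO_SIGMA / v for v in voxel_size]
    smoothed = ndimage.gaussian_filter(concentration, sigma=sigma_vox, mode="reflect")
    suv = suv_convert(smoothed, weight_kg=weight_kg, injected_mbq=injected_mbq)
    return SUVVolume(values=suv, voxel_size=tuple(voxel_size), label=label)
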