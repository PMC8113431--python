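"""Quantitative image-quality and quantification metrics.

SUV conversion, lesion SUVmax and SUVpeak (mean in a 1 cm^3 sphere), the
liver-ROI coefficient-of-variation noise protocol (three 6-cm circles on
alternating transaxial slices, averaged), Pearson correlation and
Bland-Altman agreement analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "VOI",
    "LiverROISet",
    "MetricsRecord",
    "BlandAltmanResult",
    "suv_convert",
    "suv_max",
    "suv_peak",
    "peak_sphere_offsets",
    "cov_liver",
    "bland_altman",
    "pearson_r",
    "records_to_frame",
    "plot_bland_altman",
    "PEAK_SPHERE_RADIUS_MM",
]

#: radius of a 1 cm^3 sphere: (3/(4 pi))^(1/3) cm
PEAK_SPHERE_RADIUS_MM = 10.0 * (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


class DegenerateInputError(ValueError):
    """Input is formally valid but statistically degenerate."""


@dataclass
class VOI:
    """Volume of interest over a lesion: a named boolean voxel mask."""

    label: str
    mask: np.ndarray
    image_set: str = ""

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError(f"VOI {self.label!r} is empty")

    @property
    def indices(self) -> Tuple[np.ndarray, ...]:
        return np.nonzero(self.mask)


@dataclass(frozen=True)
class LiverROISet:
    """Three 6-cm circles on transaxial slices i, i+2, i+4 (one in-between).

    Defined once per subject (on the reference image set) and applied
    unchanged to every other image set of that subject.
    """

    center_rc: Tuple[float, float]
    slice_indices: Tuple[int, int, int]
    diameter_mm: float = 60.0
    image_set: str = ""

    def __post_init__(self) -> None:
        i, j, k = self.slice_indices
        if not (j == i + 2 and k == i + 4):
            raise ValueError(
                "slice indices must be (i, i+2, i+4): one slice in-between"
            )
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be > 0")

    @classmethod
    def centered_on(
        cls, center_slice: int, center_rc: Tuple[float, float], **kw
    ) -> "LiverROISet":
        return cls(
            center_rc=center_rc,
            slice_indices=(center_slice - 2, center_slice, center_slice + 2),
            **kw,
        )


@dataclass
class MetricsRecord:
    """One row of the evaluation table: subject x image set (x lesion)."""

    subject: str
    image_set: str
    lesion: Optional[str] = None
    suv_max: Optional[float] = None
    suv_peak: Optional[float] = None
    cov: Optional[float] = None

    def __post_init__(self) -> None:
        if (
            self.suv_max is not None
            and self.suv_peak is not None
            and self.suv_peak > self.suv_max + 1e-9
        ):
            raise ValueError("SUVpeak cannot exceed SUVmax on the same VOI")
        if self.cov is not None and self.cov < 0:
            raise ValueError("COV must be >= 0")


def records_to_frame(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    """Tidy DataFrame with one MetricsRecord per row."""
    return pd.DataFrame(
        [
            {
                "subject": r.subject,
                "image_set": r.image_set,
                "lesion": r.lesion,
                "suv_max": r.suv_max,
                "suv_peak": r.suv_peak,
                "cov": r.cov,
            }
            for r in records
        ]
    )


def suv_convert(
    concentration: np.ndarray, weight_kg: float, injected_mbq: float
) -> np.ndarray:
    """Convert activity concentration (kBq/mL) to SUV.

    SUV = concentration x body weight / injected activity, assuming 1 g/mL
    tissue density; a subject injected at exactly 4 MBq/kg with uniformly
    distributed tracer has SUV 1.0 everywhere.
    """
    if weight_kg <= 0:
        raise ValueError("body weight must be > 0")
    if injected_mbq <= 0:
        raise ValueError("injected activity must be > 0")
    return np.asarray(concentration, dtype=np.float64) * (weight_kg / injected_mbq)


def suv_max(values: np.ndarray, voi: VOI) -> float:
    """Maximum voxel value inside the VOI."""
    return float(values[voi.mask].max())


def peak_sphere_offsets(
    voxel_size: Sequence[float], radius_mm: float = PEAK_SPHERE_RADIUS_MM
) -> np.ndarray:
    """Voxel-center rasterization of the 1 cm^3 peak sphere, as offsets.

    Returns an (n, 3) integer array of (slice, row, col) offsets whose
    centers lie within radius_mm of the sphere center.
    """
    r_vox = [int(np.ceil(radius_mm / v)) for v in voxel_size]
    grids = np.mgrid[tuple(slice(-r, r + 1) for r in r_vox)]
    d2 = sum((g * v) ** 2 for g, v in zip(grids, voxel_size))
    return np.argwhere(d2 <= radius_mm**2) - np.array(r_vox)


def suv_peak(
    values: np.ndarray,
    voi: VOI,
    voxel_size: Sequence[float],
    center_mode: str = "max_mean",
) -> float:
    """SUVpeak: maximal mean over a 1 cm^3 sphere placed inside the VOI.

    Candidate sphere centers are the VOI voxels; a candidate is valid only
    if its sphere lies fully inside the volume. center_mode "max_mean"
    (default) returns the largest sphere mean over all candidates; the
    alternative "max_voxel" centers the sphere on the SUVmax voxel.
    """
    offsets = peak_sphere_offsets(voxel_size)
    lo = -offsets.min(axis=0)
    hi = np.array(values.shape) - offsets.max(axis=0)

    # sphere-mean field via correlation with the normalized sphere kernel
    r_vox = lo
    kernel = np.zeros(2 * r_vox + 1)
    kernel[tuple((offsets + r_vox).T)] = 1.0
    kernel /= kernel.sum()
    sphere_mean = ndimage.correlate(
        np.asarray(values, dtype=np.float64), kernel, mode="constant"
    )

    valid = np.zeros(values.shape, dtype=bool)
    valid[tuple(slice(a, b) for a, b in zip(lo, hi))] = True

    if center_mode == "max_voxel":
        inside = values.copy()
        inside[~voi.mask] = -np.inf
        center = np.unravel_index(np.argmax(inside), values.shape)
        if not valid[center]:
            raise ValueError("peak sphere exceeds volume bounds at the SUVmax voxel")
        return float(sphere_mean[center])
    if center_mode != "max_mean":
        raise ValueError(f"unknown center_mode {center_mode!r}")

    cand = voi.mask & valid
    if not cand.any():
        raise ValueError("peak sphere exceeds volume bounds for all candidates")
    return float(sphere_mean[cand].max())


def _circle_values(
    values2d: np.ndarray,
    center_rc: Sequence[float],
    diameter_mm: float,
    voxel_size_rc: Sequence[float],
) -> np.ndarray:
    """Values at voxel centers strictly inside the circle."""
    r, c = np.ogrid[0 : values2d.shape[0], 0 : values2d.shape[1]]
    d2 = ((r - center_rc[0]) * voxel_size_rc[0]) ** 2 + (
        (c - center_rc[1]) * voxel_size_rc[1]
    ) ** 2
    mask = d2 < (diameter_mm / 2.0) ** 2
    if not mask.any():
        raise ValueError("liver circle rasterizes to an empty region")
    edge = (
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    if edge:
        raise ValueError("liver circle does not fit within the slice")
    return values2d[mask]


def cov_liver(
    values: np.ndarray,
    rois: LiverROISet,
    voxel_size: Sequence[float],
    ddof: int = 0,
) -> float:
    """Liver noise: mean over three circular ROIs of (SD / mean).

    Each circle's coefficient of variation uses the population SD by
    default (ddof=0, configurable); the three per-circle values are then
    averaged arithmetically.
    """
    covs = []
    for z in rois.slice_indices:
        if not 0 <= z < values.shape[0]:
            raise ValueError(f"ROI slice {z} outside the volume")
        vals = _circle_values(
            values[z], rois.center_rc, rois.diameter_mm, voxel_size[1:]
        )
        mean = float(vals.mean())
        if mean <= 0:
            raise DegenerateInputError(
                f"liver circle on slice {z} has non-positive mean"
            )
        covs.append(float(vals.std(ddof=ddof)) / mean)
    return float(np.mean(covs))


@dataclass
class BlandAltmanResult:
    """Mean difference, 95% limits of agreement, trend and LoA confidence limits."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    trend_slope: float
    loa_lower_ci: Tuple[float, float]
    loa_upper_ci: Tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_lower - 1e-12 <= self.mean_diff <= self.loa_upper + 1e-12):
            raise ValueError("limits of agreement must bracket the mean difference")


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltmanResult:
    """Agreement between paired measurements x and y.

    Differences d = x - y; limits of agreement are mean(d) +/- 1.96 SD(d)
    with the sample SD; the trend is the least-squares slope of d against
    the pair mean (x + y)/2; LoA confidence limits use the standard
    t-based approximation Var(LoA) ~= SD^2 (1/n + 1.96^2 / (2(n-1))).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_lo = mean - 1.96 * sd
    loa_hi = mean + 1.96 * sd
    avg = (x + y) / 2.0
    if np.ptp(avg) > 0:
        slope = float(np.polyfit(avg, d, 1)[0])
    else:
        slope = 0.0
    se_loa = sd * np.sqrt(1.0 / n + 1.96**2 / (2.0 * (n - 1)))
    t = float(stats.t.ppf(0.975, n - 1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        trend_slope=slope,
        loa_lower_ci=(loa_lo - t * se_loa, loa_lo + t * se_loa),
        loa_upper_ci=(loa_hi - t * se_loa, loa_hi + t * se_loa),
        n=n,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on degenerate (zero-variance) input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1-D, equal length, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def plot_bland_altman(x, y, ax=None, label_x: str = "", label_y: str = ""):
    """Bland-Altman plot: differences vs pair means with mean and LoA lines."""
    import matplotlib.pyplot as plt

    res = bland_altman(x, y)
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if ax is None:
        _, ax = plt.subplots()
    avg, d = (x + y) / 2.0, x - y
    ax.scatter(avg, d, s=18)
    ax.axhline(res.mean_diff, color="k")
    ax.axhline(res.loa_lower, color="k", linestyle=":")
    ax.axhline(res.loa_upper, color="k", linestyle=":")
    if np.ptp(avg) > 0:
        coef = np.polyfit(avg, d, 1)
        xs = np.linspace(avg.min(), avg.max(), 50)
        ax.plot(xs, np.polyval(coef, xs), "k--", linewidth=1)
    ax.set_xlabel(f"mean of {label_x or 'x'} and {label_y or 'y'}")
    ax.set_ylabel(f"{label_x or 'x'} - {label_y or 'y'}")
    return ax, res
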