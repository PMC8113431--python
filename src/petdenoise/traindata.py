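"""Construction of noisy/clean training pairs from reconstructed volumes.

A reconstruction of the long (clean) frame and the reconstructions of the
short (noisy) sub-frames of the same anatomy are cropped to the centremost
slices, partitioned into contiguous 5-slice blocks ("subsets"), optionally
geometrically augmented in the transaxial plane, and paired: each noisy
block with the clean block at the same spatial location under the same
transform. Pair counts follow
subsets x sources x reconstructions x (1 + augmentations).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "SubsetVolume",
    "TrainingPair",
    "TrainSource",
    "AugmentParams",
    "AugmentTransform",
    "crop_central",
    "crop_inplane_central",
    "partition_subsets",
    "draw_transforms",
    "augment",
    "build_pairs",
    "pair_count",
]


class SizeError(ValueError):
    """Volume has the wrong number of slices for the requested operation."""


class AlignmentError(ValueError):
    """Noisy and clean members do not describe the same anatomy."""


@dataclass
class SubsetVolume:
    """A 5-slice block cut from one reconstruction, with provenance."""

    values: np.ndarray  # (depth, rows, cols)
    source_id: str
    recon_id: str
    subset_index: int
    augmentation: str = "original"

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("subset values must be 3-D")
        if not 0 <= self.subset_index <= 9:
            raise ValueError("subset index must lie in [0, 9]")


@dataclass
class TrainingPair:
    """Aligned (noisy, clean) subset pair sharing location and transform."""

    noisy: SubsetVolume
    clean: SubsetVolume

    def __post_init__(self) -> None:
        if self.noisy.values.shape != self.clean.values.shape:
            raise AlignmentError("noisy and clean shapes differ")
        same = (
            self.noisy.source_id == self.clean.source_id
            and self.noisy.subset_index == self.clean.subset_index
            and self.noisy.augmentation == self.clean.augmentation
        )
        if not same:
            raise AlignmentError("noisy and clean provenance differs")


@dataclass
class TrainSource:
    """One subject's clean reconstruction plus its short-frame reconstructions."""

    source_id: str
    clean: np.ndarray
    noisy: Sequence[np.ndarray]
    clean_id: str = "clean"
    noisy_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        for i, n in enumerate(self.noisy):
            if n.shape != self.clean.shape:
                raise AlignmentError(
                    f"source {self.source_id}: noisy recon {i} shape {n.shape} "
                    f"!= clean shape {self.clean.shape}"
                )
        if self.noisy_ids is None:
            self.noisy_ids = [f"noisy_{i}" for i in range(len(self.noisy))]


def crop_central(values: np.ndarray, keep: int = 50) -> np.ndarray:
    """Keep the `keep` centremost contiguous slices.

    When the discard count d is odd, floor(d/2) slices are dropped at the
    start and ceil(d/2) at the end (one more from the end), a fixed
    documented convention.
    """
    n = values.shape[0]
    if n < keep:
        raise SizeError(f"cannot keep {keep} slices from a {n}-slice volume")
    d = n - keep
    start = d // 2
    return values[start : start + keep]


def crop_inplane_central(values: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Central in-plane crop (same start/end convention as crop_central)."""
    _, nr, nc = values.shape
    if nr < rows or nc < cols:
        raise SizeError("in-plane crop larger than the volume")
    r0 = (nr - rows) // 2
    c0 = (nc - cols) // 2
    return values[:, r0 : r0 + rows, c0 : c0 + cols]


def partition_subsets(
    values: np.ndarray,
    depth: int = 5,
    source_id: str = "",
    recon_id: str = "",
) -> List[SubsetVolume]:
    """Cut a volume into contiguous non-overlapping depth-slice blocks."""
    n = values.shape[0]
    if n % depth != 0:
        raise SizeError(f"{n} slices not divisible by subset depth {depth}")
    return [
        SubsetVolume(
            values=values[i * depth : (i + 1) * depth],
            source_id=source_id,
            recon_id=recon_id,
            subset_index=i,
        )
        for i in range(n // depth)
    ]


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the random in-plane transforms (mild by default)."""

    scale_range: Tuple[float, float] = (0.9, 1.1)
    shear_range: Tuple[float, float] = (-0.1, 0.1)
    flip_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.scale_range[0] <= 0 or self.scale_range[0] > self.scale_range[1]:
            raise ValueError("invalid scale range")
        if self.shear_range[0] > self.shear_range[1]:
            raise ValueError("invalid shear range")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip probability must be in [0, 1]")


@dataclass(frozen=True)
class AugmentTransform:
    """A concrete in-plane transform, reusable on a paired volume.

    Applied identically to every slice: uniform scale, shear, and
    independent flips along the two in-plane axes, about the slice center.
    """

    scale: float = 1.0
    shear: float = 0.0
    flip_rows: bool = False
    flip_cols: bool = False

    def matrix(self) -> np.ndarray:
        s = np.diag([self.scale, self.scale])
        sh = np.array([[1.0, self.shear], [0.0, 1.0]])
        f = np.diag([-1.0 if self.flip_rows else 1.0, -1.0 if self.flip_cols else 1.0])
        return f @ sh @ s

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Resample each slice under the transform; shape is preserved."""
        a = self.matrix()
        a_inv = np.linalg.inv(a)
        center = (np.array(values.shape[1:], dtype=np.float64) - 1.0) / 2.0
        offset = center - a_inv @ center
        out = np.empty_like(values, dtype=np.float64)
        for z in range(values.shape[0]):
            out[z] = ndimage.affine_transform(
                np.asarray(values[z], dtype=np.float64),
                a_inv,
                offset=offset,
                order=1,
                mode="nearest",
            )
        return out


def draw_transforms(
    n_samples: int, params: AugmentParams, rng: np.random.Generator
) -> List[AugmentTransform]:
    """Draw n random transforms; seeded rng makes them reproducible."""
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    out = []
    for _ in range(n_samples):
        out.append(
            AugmentTransform(
                scale=float(rng.uniform(*params.scale_range)),
                shear=float(rng.uniform(*params.shear_range)),
                flip_rows=bool(rng.random() < params.flip_prob),
                flip_cols=bool(rng.random() < params.flip_prob),
            )
        )
    return out


def augment(
    values: np.ndarray,
    n_samples: int = 5,
    params: AugmentParams = AugmentParams(),
    seed: int = 0,
) -> List[Tuple[AugmentTransform, np.ndarray]]:
    """Random in-plane augmentations of one volume.

    Returns (transform, volume) tuples so the identical transform can be
    re-applied to the clean counterpart of a noisy volume.
    """
    rng = np.random.default_rng(seed)
    return [
        (t, t.apply(values)) for t in draw_transforms(n_samples, params, rng)
    ]


def pair_count(
    n_subsets: int, n_sources: int, n_recons: int, n_aug: int
) -> int:
    """subsets x sources x reconstructions x (1 + augmentations)."""
    return n_subsets * n_sources * n_recons * (1 + n_aug)


def build_pairs(
    sources: Sequence[TrainSource],
    n_aug: int = 5,
    depth: int = 5,
    params: AugmentParams = AugmentParams(),
    seed: int = 0,
    dtype=np.float32,
) -> List[TrainingPair]:
    """Assemble the full training-pair list from per-subject reconstructions.

    For every source, every short reconstruction and every subset location,
    one original pair plus n_aug augmented pairs are produced; the same
    transform is applied to both members of a pair so they stay spatially
    consistent. The returned list is shuffled with a seeded permutation.
    """
    rng = np.random.default_rng(seed)
    pairs: List[TrainingPair] = []
    for src in sources:
        clean_subsets = partition_subsets(
            src.clean, depth=depth, source_id=src.source_id, recon_id=src.clean_id
        )
        for recon_id, noisy_vol in zip(src.noisy_ids, src.noisy):
            noisy_subsets = partition_subsets(
                noisy_vol, depth=depth, source_id=src.source_id, recon_id=recon_id
            )
            for ns, cs in zip(noisy_subsets, clean_subsets):
                pairs.append(
                    TrainingPair(
                        noisy=replace(ns, values=np.asarray(ns.values, dtype=dtype)),
                        clean=replace(cs, values=np.asarray(cs.values, dtype=dtype)),
                    )
                )
                transforms = draw_transforms(n_aug, params, rng)
                for k, t in enumerate(transforms):
                    tag = f"sample_{k + 1}"
                    pairs.append(
                        TrainingPair(
                            noisy=replace(
                                ns,
                                values=t.apply(ns.values).astype(dtype),
                                augmentation=tag,
                            ),
                            clean=replace(
                                cs,
                                values=t.apply(cs.values).astype(dtype),
                                augmentation=tag,
                            ),
                        )
                    )
    perm = rng.permutation(len(pairs))
    return [pairs[i] for i in perm]
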