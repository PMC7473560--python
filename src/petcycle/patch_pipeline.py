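"""Patch extraction and intensity scaling for training.

Slices are cropped into co-located low-dose/full-dose patches (default
56x56 with sliding step 40, no edge-flush patches) and each volume pair is
jointly scaled to [0, 1] by the full-dose maximum, so both domains live on
one intensity scale and recovered images can be mapped back to kBq/ml.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import PETVolume, validate_pair

log = logging.getLogger(__name__)

DEFAULT_PATCH = 56
DEFAULT_STRIDE = 40


@dataclass
class PatchSet:
    """Co-located LD/FD patch pairs with their provenance.

    ``ld`` and ``fd`` are ``(n, patch, patch)`` arrays; ``origin`` rows are
    ``(pair index, slice, row, col)``; ``scale_factors[i]`` is the kBq/ml
    factor that rescales pair ``i`` back to physical units.
    """

    ld: np.ndarray
    fd: np.ndarray
    origin: np.ndarray
    scale_factors: np.ndarray = field(default_factory=lambda: np.ones(1))

    def __post_init__(self):
        if self.ld.shape != self.fd.shape:
            raise ValueError("LD and FD patch arrays must have equal shapes")
        if len(self.origin) != len(self.ld):
            raise ValueError("origin table must have one row per patch")

    def __len__(self) -> int:
        return len(self.ld)

    def save(self, path):
        np.savez_compressed(
            path,
            ld=self.ld,
            fd=self.fd,
            origin=self.origin,
            scale_factors=self.scale_factors,
        )

    @classmethod
    def load(cls, path) -> "PatchSet":
        with np.load(path) as z:
            return cls(z["ld"], z["fd"], z["origin"], z["scale_factors"])


def patch_anchors(length: int, patch: int, stride: int) -> np.ndarray:
    """Anchor offsets {0, stride, 2*stride, ...} with anchor+patch <= length."""
    if patch > length:
        raise ValueError(f"patch {patch} exceeds image dimension {length}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return np.arange(0, length - patch + 1, stride)


def extract_patches(
    slice_image: np.ndarray, patch: int = DEFAULT_PATCH, stride: int = DEFAULT_STRIDE
) -> list[tuple[int, int, np.ndarray]]:
    """Row-major (row, col, patch) triples from one 2-D slice."""
    img = np.asarray(slice_image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D slice")
    rows = patch_anchors(img.shape[0], patch, stride)
    cols = patch_anchors(img.shape[1], patch, stride)
    return [
        (int(r), int(c), img[r : r + patch, c : c + patch])
        for r in rows
        for c in cols
    ]


def patches_per_volume(shape, patch: int = DEFAULT_PATCH, stride: int = DEFAULT_STRIDE) -> int:
    """Number of patches extracted from one (nx, ny, nz) volume."""
    nr = len(patch_anchors(shape[0], patch, stride))
    nc = len(patch_anchors(shape[1], patch, stride))
    return nr * nc * shape[2]


def scale_to_unit(
    ld: PETVolume, fd: PETVolume
) -> tuple[PETVolume, PETVolume, float]:
    """Divide both volumes by max(FD) (joint scale; preserves SUV ratios).

    The low-dose volume may retain values slightly above 1 where its noise
    peaks exceed the full-dose maximum; the full-dose volume lands in [0, 1]
    exactly.
    """
    if not validate_pair(ld, fd):
        raise ValueError("scale_to_unit requires a validated LD/FD pair")
    factor = float(fd.values.max())
    if factor == 0.0:
        log.warning("all-zero full-dose volume; scale factor 1 applied")
        factor = 1.0
    return (
        PETVolume(ld.values / factor, ld.voxel_size_mm, ld.domain_role),
        PETVolume(fd.values / factor, fd.voxel_size_mm, fd.domain_role),
        factor,
    )


def unscale(vol: PETVolume, scale_factor: float) -> PETVolume:
    """Map a unit-scaled volume back to kBq/ml; flags the result recovered."""
    if scale_factor <= 0:
        raise ValueError("scale factor must be positive")
    return PETVolume(
        vol.values * scale_factor, vol.voxel_size_mm, domain_role="recovered"
    )


def build_dataset(
    pairs,
    patch: int = DEFAULT_PATCH,
    stride: int = DEFAULT_STRIDE,
    shuffle_seed: int = 0,
    drop_empty: bool = False,
) -> PatchSet:
    """Assemble a shuffled PatchSet from (ld, fd) PETVolume pairs.

    ``drop_empty`` removes patch pairs whose full-dose patch is identically
    zero (off by default: no such exclusion is part of the standard
    protocol).
    """
    ld_patches, fd_patches, origin, factors = [], [], [], []
    for pi, (ld, fd) in enumerate(pairs):
        if not validate_pair(ld, fd):
            raise ValueError(f"pair {pi} failed validation")
        lds, fds, factor = scale_to_unit(ld, fd)
        factors.append(factor)
        for z in range(ld.shape[2]):
            fd_items = extract_patches(fds.values[:, :, z], patch, stride)
            ld_items = extract_patches(lds.values[:, :, z], patch, stride)
            for (r, c, fp), (_, _, lp) in zip(fd_items, ld_items):
                if drop_empty and not fp.any():
                    continue
                ld_patches.append(lp)
                fd_patches.append(fp)
                origin.append((pi, z, r, c))
    ld_arr = np.stack(ld_patches) if ld_patches else np.empty((0, patch, patch))
    fd_arr = np.stack(fd_patches) if fd_patches else np.empty((0, patch, patch))
    origin_arr = np.asarray(origin, dtype=np.int64).reshape(len(ld_patches), 4)
    order = np.random.default_rng(shuffle_seed).permutation(len(ld_arr))
    return PatchSet(
        ld_arr[order], fd_arr[order], origin_arr[order], np.asarray(factors)
    )
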