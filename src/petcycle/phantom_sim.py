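"""Digital phantom simulation of paired low-dose / full-dose PET volumes.

The simulator emulates the count-statistics mechanism that separates a
low-dose from a full-dose acquisition while staying desk-scale:

1. a truth phantom is voxelized — an elliptic "head" support at a uniform
   background activity (default 30 kBq/ml) with embedded spherical lesions
   whose diameters derive from their volumes via the equivalent-sphere
   relation d = (6V/pi)^(1/3);
2. each transverse slice is forward-projected with a 2-D parallel-beam
   line-integral projector and Poisson event counts are drawn at a chosen
   full-dose count budget;
3. the low-dose sinogram is obtained from the *same* count realization by
   binomial thinning — every event kept independently with probability equal
   to the dose fraction, mirroring event discarding in list-mode data;
4. both sinograms are reconstructed with MLEM (multiplicative EM, which
   preserves non-negativity), giving spatially aligned LD/FD volumes.

No attenuation, scatter, randoms or scanner-geometry modelling is included;
the projector/backprojector pair is exactly adjoint, which MLEM's
count-preservation property relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core_io import PETVolume, VOIMask

log = logging.getLogger(__name__)

#: Lesion geometry used in the reference simulation study: five lesions,
#: each in a small/middle/large variant.  Centers are 0-based (x, y, z)
#: voxel indices on a 192x192x96 grid; volumes in mm^3.
REFERENCE_LESIONS = (
    # (lesion number, center, volume_mm3, size label)
    (1, (99, 92, 29), 240.78, "small"),
    (1, (99, 92, 29), 481.57, "middle"),
    (1, (99, 92, 29), 963.14, "large"),
    (2, (108, 62, 49), 213.0, "small"),
    (2, (108, 62, 49), 416.74, "middle"),
    (2, (108, 62, 49), 833.49, "large"),
    (3, (95, 86, 61), 509.36, "small"),
    (3, (95, 86, 61), 1009.45, "middle"),
    (3, (95, 86, 61), 2018.9, "large"),
    (4, (74, 68, 43), 222.26, "small"),
    (4, (74, 68, 43), 388.96, "middle"),
    (4, (74, 68, 43), 759.4, "large"),
    (5, (98, 35, 57), 277.83, "small"),
    (5, (98, 35, 57), 500.09, "middle"),
    (5, (98, 35, 57), 981.67, "large"),
)

#: Lesion activity levels (kBq/ml) spanned by the reference study.
ACTIVITY_LEVELS_KBQ_ML = (45.23, 60.56, 91.12, 152.23, 274.47)

DEFAULT_BACKGROUND_KBQ_ML = 30.0
DEFAULT_COUNT_BUDGET = 2.0e5  # full-dose expected counts per slice


def equivalent_diameter(volume_mm3: float) -> float:
    """Equivalent-sphere diameter d with (pi/6) d^3 = V, in mm."""
    if volume_mm3 <= 0:
        raise ValueError("volume must be positive")
    return float((6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0))


def sphere_volume(diameter_mm: float) -> float:
    """Inverse of :func:`equivalent_diameter`."""
    return float(np.pi / 6.0 * diameter_mm**3)


@dataclass
class LesionSpec:
    center_voxel: tuple[int, int, int]
    volume_mm3: float
    activity_kbq_ml: float
    shape: str = "sphere"
    label: str = ""

    def __post_init__(self):
        if self.volume_mm3 <= 0:
            raise ValueError("lesion volume must be positive")
        if self.activity_kbq_ml <= 0:
            raise ValueError("lesion activity must be positive")
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown lesion shape {self.shape!r}")


@dataclass
class PhantomSpec:
    grid_dims: tuple[int, int, int] = (192, 192, 96)
    voxel_size_mm: float = 2.1
    background_kbq_ml: float = DEFAULT_BACKGROUND_KBQ_ML
    lesions: list[LesionSpec] = field(default_factory=list)
    head_mask: str = "ellipsoid"

    def __post_init__(self):
        if self.background_kbq_ml <= 0:
            raise ValueError("background activity must be positive")
        if self.head_mask not in ("ellipsoid", "full"):
            raise ValueError(f"unknown head mask {self.head_mask!r}")


@dataclass
class SinogramCounts:
    """Poisson event counts indexed (angle, radial bin)."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("sinogram must be 2-D (angle, radial bin)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_angles(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def reference_phantom_spec(
    activity_kbq_ml: float = ACTIVITY_LEVELS_KBQ_ML[2],
    sizes: tuple[str, ...] = ("small", "middle", "large"),
) -> PhantomSpec:
    """The five-lesion reference phantom at one activity level.

    With all three size variants selected the 15 size rows of the reference
    lesion table become 15 VOIs.  Size variants of one lesion share a center,
    so each variant is offset along z by one variant index to keep lesions
    disjoint (small at the nominal slice, middle +8, large -8).
    """
    z_off = {"small": 0, "middle": 8, "large": -8}
    lesions = []
    for no, (x, y, z), vol, size in REFERENCE_LESIONS:
        if size not in sizes:
            continue
        lesions.append(
            LesionSpec(
                center_voxel=(x, y, z + z_off[size]),
                volume_mm3=vol,
                activity_kbq_ml=activity_kbq_ml,
                label=f"lesion{no}-{size}",
            )
        )
    return PhantomSpec(lesions=lesions)


# ---------------------------------------------------------------------------
# phantom voxelization
# ---------------------------------------------------------------------------

def _head_mask(dims, kind: str) -> np.ndarray:
    if kind == "full":
        return np.ones(dims, dtype=bool)
    nx, ny, nz = dims
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ax, ay, az = 0.45 * nx, 0.45 * ny, 0.48 * nz
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    r2 = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
    return r2 <= 1.0


def _lesion_mask(dims, lesion: LesionSpec, voxel_size_mm: float) -> np.ndarray:
    radius_mm = equivalent_diameter(lesion.volume_mm3) / 2.0
    cx, cy, cz = lesion.center_voxel
    nx, ny, nz = dims
    if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
        raise ValueError(f"lesion {lesion.label!r} center outside grid")
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    d2 = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) * voxel_size_mm**2
    return d2 <= radius_mm**2


def build_phantom(spec: PhantomSpec) -> tuple[PETVolume, list[VOIMask]]:
    """Voxelize a phantom spec into a truth volume plus one VOI per lesion."""
    head = _head_mask(spec.grid_dims, spec.head_mask)
    values = np.where(head, spec.background_kbq_ml, 0.0)
    masks: list[VOIMask] = []
    occupied = np.zeros(spec.grid_dims, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        if lesion.activity_kbq_ml < spec.background_kbq_ml:
            raise ValueError(
                f"lesion {lesion.label or i} activity below background"
            )
        m = _lesion_mask(spec.grid_dims, lesion, spec.voxel_size_mm)
        if not m.any():
            # sub-voxel lesion: keep at least the center voxel
            m[lesion.center_voxel] = True
        if np.any(m & ~head):
            raise ValueError(
                f"lesion {lesion.label or i} extends outside the head mask"
            )
        if np.any(m & occupied):
            raise ValueError(f"lesion {lesion.label or i} overlaps another lesion")
        occupied |= m
        values[m] = lesion.activity_kbq_ml
        masks.append(VOIMask(m, label=lesion.label or f"lesion{i}"))
    return PETVolume(values, spec.voxel_size_mm, domain_role="truth"), masks


# ---------------------------------------------------------------------------
# parallel-beam projector with exact adjoint
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _geometry(n: int, n_angles: int):
    """Precomputed linear-interpolation projection geometry for an n x n slice.

    For each angle the detector coordinate of every pixel center is split
    between its two neighbouring radial bins, so forward projection and
    backprojection are an exactly adjoint pair of sparse linear maps.
    """
    thetas = np.arange(n_angles) * np.pi / n_angles
    c = (n - 1) / 2.0
    xs, ys = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    n_bins = int(np.ceil(n * np.sqrt(2.0))) + 3
    t0 = (n_bins - 1) / 2.0
    idx = np.empty((n_angles, n * n), dtype=np.int64)
    w = np.empty((n_angles, n * n))
    for a, th in enumerate(thetas):
        t = xs * np.cos(th) + ys * np.sin(th) + t0
        i0 = np.floor(t).astype(np.int64)
        idx[a] = i0.ravel()
        w[a] = (t - i0).ravel()
    return idx, w, n_bins


def _forward(img: np.ndarray, n_angles: int) -> np.ndarray:
    n = img.shape[0]
    idx, w, n_bins = _geometry(n, n_angles)
    flat = img.ravel()
    sino = np.empty((n_angles, n_bins))
    for a in range(n_angles):
        sino[a] = np.bincount(
            idx[a], weights=flat * (1.0 - w[a]), minlength=n_bins
        ) + np.bincount(idx[a] + 1, weights=flat * w[a], minlength=n_bins)
    return sino


def _backproject(sino: np.ndarray, n: int) -> np.ndarray:
    n_angles = sino.shape[0]
    idx, w, n_bins = _geometry(n, n_angles)
    img = np.zeros(n * n)
    for a in range(n_angles):
        img += sino[a, idx[a]] * (1.0 - w[a]) + sino[a, idx[a] + 1] * w[a]
    return img.reshape(n, n)


def project(
    truth: PETVolume,
    slice_index: int,
    n_angles: int = 60,
    count_budget: float = DEFAULT_COUNT_BUDGET,
    seed: int = 0,
) -> SinogramCounts:
    """Poisson counts from the line integrals of one transverse slice.

    Expected counts are the forward projection of the slice scaled so their
    total equals ``count_budget``; realized counts are independent Poisson
    draws under ``seed``.
    """
    if count_budget <= 0:
        raise ValueError("count budget must be positive")
    if not 0 <= slice_index < truth.shape[2]:
        raise ValueError("slice index outside volume")
    img = truth.values[:, :, slice_index]
    if img.shape[0] != img.shape[1]:
        raise ValueError("projector expects square transverse slices")
    expected = _forward(img, n_angles)
    total = expected.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero slice to a count budget")
    expected *= count_budget / total
    rng = np.random.default_rng(seed)
    return SinogramCounts(rng.poisson(expected))


def expected_sinogram(img: np.ndarray, n_angles: int = 60) -> np.ndarray:
    """Noise-free line integrals of a square slice (the system model A)."""
    return _forward(np.asarray(img, dtype=np.float64), n_angles)


def thin_counts(sino: SinogramCounts, fraction: float, seed: int = 0) -> SinogramCounts:
    """Binomial thinning: keep each event independently with prob ``fraction``.

    Thinning a Poisson(lambda) count this way yields Poisson(fraction*lambda),
    the statistical content of discarding list-mode events to emulate a
    lower injected dose.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return SinogramCounts(sino.counts.copy())
    rng = np.random.default_rng(seed)
    return SinogramCounts(rng.binomial(sino.counts.astype(np.int64), fraction))


def reconstruct(
    sino: SinogramCounts, n_iter: int = 20, grid_dims: tuple[int, int] = (192, 192)
) -> np.ndarray:
    """MLEM reconstruction of one slice from sinogram counts.

    The multiplicative update keeps the image non-negative at every
    iteration; with the exactly adjoint projector pair the sensitivity-
    weighted image total equals the measured count total after each update.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    n = grid_dims[0]
    if grid_dims[0] != grid_dims[1]:
        raise ValueError("reconstruction grid must be square")
    y = sino.counts.astype(np.float64)
    if y.sum() == 0:
        log.warning("zero-count sinogram: returning a zero image")
        return np.zeros(grid_dims)
    n_angles = sino.n_angles
    sens = _backproject(np.ones_like(y), n)
    x = np.ones(grid_dims)
    tiny = 1e-12
    for _ in range(n_iter):
        proj = _forward(x, n_angles)
        ratio = np.where(proj > tiny, y / np.maximum(proj, tiny), 0.0)
        x = x / np.maximum(sens, tiny) * _backproject(ratio, n)
    return x


def generate_pair(
    spec: PhantomSpec,
    dose_fraction: float = 0.1,
    count_budget: float = DEFAULT_COUNT_BUDGET,
    n_iter: int = 20,
    seed: int = 0,
    n_angles: int = 60,
) -> tuple[PETVolume, PETVolume, PETVolume, list[VOIMask]]:
    """Simulate an aligned (LD, FD, truth, VOIs) set slice by slice.

    The low-dose sinogram of each slice is a thinned copy of the same
    full-dose count realization, so the pair is spatially aligned by
    construction.  Reconstructions are rescaled to kBq/ml with the known
    per-slice count-to-activity factor (for LD including the dose fraction,
    mimicking the dose correction applied to clinical low-dose scans).
    """
    if not 0 < dose_fraction <= 1:
        raise ValueError("dose_fraction must lie in (0, 1]")
    truth, masks = build_phantom(spec)
    nx, ny, nz = truth.shape
    fd = np.zeros_like(truth.values)
    ld = np.zeros_like(truth.values)
    root = np.random.default_rng(seed)
    slice_seeds = root.integers(0, 2**31 - 1, size=(nz, 2))
    for z in range(nz):
        img = truth.values[:, :, z]
        total_act = _forward(img, n_angles).sum()
        if total_act <= 0:
            continue
        sino_fd = project(truth, z, n_angles, count_budget, int(slice_seeds[z, 0]))
        sino_ld = thin_counts(sino_fd, dose_fraction, int(slice_seeds[z, 1]))
        scale = count_budget / total_act  # counts per (kBq/ml * projector unit)
        fd[:, :, z] = reconstruct(sino_fd, n_iter, (nx, ny)) / scale
        if dose_fraction == 1.0:
            ld[:, :, z] = fd[:, :, z]
        else:
            ld[:, :, z] = reconstruct(sino_ld, n_iter, (nx, ny)) / (
                scale * dose_fraction
            )
    return (
        PETVolume(ld, spec.voxel_size_mm, domain_role="low_dose"),
        PETVolume(fd, spec.voxel_size_mm, domain_role="full_dose"),
        truth,
        masks,
    )
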