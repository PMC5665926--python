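"""Phase segmentation of grayscale CT volumes: root / solid matrix / pore.

The protocol, applied in order:

1. radius-3 median filter (spherical footprint, reflect boundaries) to remove
   point noise while preserving structural borders;
2. surface-calibration global threshold — 50 % of the range between the mean
   gray of an air (background) region and of the aluminium reference object,
   giving a threshold transferable across scans and days;
3. solid matrix = filtered gray >= threshold (reference insert excluded);
4. root = adaptive region growing from user-supplied seed voxels;
5. pore = everything else inside the analysis region;
6. one-voxel exclusion margin around the root surface to discard
   partial-volume voxels, and an edge crop to drop container-wall effects.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phases import EXCLUDED, PORE, ROOT, SOLID

__all__ = [
    "CalibrationRegions",
    "PhaseMasks",
    "SegmentationError",
    "RegionGrowthError",
    "median_filter_3d",
    "calibrate_threshold",
    "segment_solid",
    "region_grow_root",
    "exclude_root_margin",
    "crop_edges",
    "segment_volume",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class SegmentationError(ValueError):
    pass


class RegionGrowthError(SegmentationError):
    """Region growing flooded the volume or was seeded inconsistently."""


@dataclass(frozen=True)
class CalibrationRegions:
    """Voxel-coordinate boxes sampling air (background) and the reference insert."""

    background: tuple[slice, slice, slice]
    reference: tuple[slice, slice, slice]

    def validate(self, shape: tuple[int, int, int]) -> None:
        for name, box in (("background", self.background), ("reference", self.reference)):
            if len(box) != 3:
                raise SegmentationError(f"{name} region must be a 3-D box")
            for s, n in zip(box, shape):
                if not (0 <= s.start < s.stop <= n):
                    raise SegmentationError(f"{name} region lies outside the volume")
        probe = np.zeros(shape, dtype=np.uint8)
        probe[self.background] += 1
        probe[self.reference] += 1
        if probe.max() > 1:
            raise SegmentationError("calibration regions overlap")

    def n_voxels(self, which: str) -> int:
        box = getattr(self, which)
        return int(np.prod([s.stop - s.start for s in box]))

    def to_dict(self) -> dict:
        return {
            name: [[s.start, s.stop] for s in getattr(self, name)]
            for name in ("background", "reference")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationRegions":
        return cls(**{
            name: tuple(slice(int(a), int(b)) for a, b in d[name])
            for name in ("background", "reference")
        })


@dataclass
class PhaseMasks:
    """Mutually exclusive root / solid / pore masks plus the analysis region.

    ``analysis_region`` is the set of voxels the morphometry is computed on:
    inside the edge crop, outside the root-margin exclusion and outside the
    reference insert.  Within it, root | solid | pore covers every voxel.
    """

    root: np.ndarray
    solid: np.ndarray
    pore: np.ndarray
    analysis_region: np.ndarray
    voxel_size: float = 12.0

    def validate(self) -> None:
        if (self.root & self.solid).any() or (self.root & self.pore).any() \
                or (self.solid & self.pore).any():
            raise SegmentationError("phase masks overlap")
        uncovered = self.analysis_region & ~(self.root | self.solid | self.pore)
        if uncovered.any():
            raise SegmentationError(
                f"{int(uncovered.sum())} analysis voxels carry no phase"
            )

    def to_labels(self) -> np.ndarray:
        """uint8 label volume (0 pore, 1 solid, 2 root, 3 excluded, 4 reference)."""
        out = np.full(self.root.shape, EXCLUDED, dtype=np.uint8)
        out[self.pore] = PORE
        out[self.solid] = SOLID
        out[self.root] = ROOT
        return out


# ---------------------------------------------------------------------------


def spherical_footprint(radius: float) -> np.ndarray:
    """Boolean ball of offsets with Euclidean norm <= radius."""
    r = int(np.floor(radius))
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (zz * zz + yy * yy + xx * xx) <= radius * radius


def median_filter_3d(gray: np.ndarray, radius_voxels: int = 3) -> np.ndarray:
    """Median filter with a spherical neighborhood, reflecting at edges."""
    if radius_voxels < 1:
        raise SegmentationError("median filter radius must be >= 1")
    if radius_voxels >= min(gray.shape):
        raise SegmentationError("median filter radius exceeds a volume dimension")
    return ndimage.median_filter(
        gray, footprint=spherical_footprint(radius_voxels), mode="reflect"
    )


def calibrate_threshold(gray: np.ndarray, calib: CalibrationRegions) -> float:
    """Surface-calibration threshold: background mean + half the range to reference.

    Both sampled regions must hold at least 100 voxels; the reference must be
    brighter than the background (otherwise the contrast is inverted and the
    scan cannot be thresholded by this rule).
    """
    calib.validate(gray.shape)
    for which in ("background", "reference"):
        if calib.n_voxels(which) < 100:
            raise SegmentationError(f"{which} calibration region has < 100 voxels")
    bg = float(gray[calib.background].mean())
    ref = float(gray[calib.reference].mean())
    if ref <= bg:
        raise SegmentationError(
            f"contrast inversion: reference mean {ref:.1f} <= background mean {bg:.1f}"
        )
    return bg + 0.5 * (ref - bg)


def segment_solid(gray: np.ndarray, threshold: float,
                  exclude: np.ndarray | None = None) -> np.ndarray:
    """Solid matrix = voxels at or above the calibrated threshold."""
    solid = gray >= threshold
    if exclude is not None:
        solid &= ~exclude
    return solid


# ---------------------------------------------------------------------------
# adaptive region growing


def region_grow_root(gray: np.ndarray, seeds, tolerance: float = 2.5, *,
                     sigma_floor_frac: float = 0.02,
                     max_fraction: float = 0.25,
                     update_every: int = 1000,
                     freeze_after: int = 10000,
                     frozen_stats: tuple[float, float] | None = None,
                     ) -> np.ndarray:
    """Grow a connected root mask from seed voxels by adaptive gray acceptance.

    Breadth-first accretion over face-connected (6-neighborhood) voxels whose
    gray lies within ``mu +/- tolerance * sigma``, where ``mu`` and ``sigma``
    are running statistics of the accepted region: initialised from the seeds
    (sigma floored at ``sigma_floor_frac`` of the gray range so a single seed
    can bootstrap under noise), recomputed every ``update_every`` accepted
    voxels and frozen once ``freeze_after`` voxels are accepted, which makes
    the result monotone in ``tolerance`` under a frozen schedule and
    guarantees termination.  Pass ``frozen_stats=(mu, sigma)`` to bypass the
    adaptive schedule entirely.

    Raises
    ------
    RegionGrowthError
        if the region floods more than ``max_fraction`` of the volume
        ("tolerance too loose") or a seed falls outside its own window.
    """
    if tolerance < 0:
        raise SegmentationError("tolerance must be >= 0")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.intp))
    if seeds.shape[1] != 3 or seeds.shape[0] == 0:
        raise SegmentationError("seeds must be an (n, 3) array of voxel coordinates")
    shape = gray.shape
    for axis in range(3):
        if (seeds[:, axis] < 0).any() or (seeds[:, axis] >= shape[axis]).any():
            raise SegmentationError("seed outside volume")

    gray_range = float(gray.max() - gray.min())
    sigma_floor = max(sigma_floor_frac * gray_range, 1e-12)

    accepted = np.zeros(shape, dtype=bool)
    accepted[tuple(seeds.T)] = True
    seed_vals = gray[tuple(seeds.T)].astype(float)

    if frozen_stats is not None:
        mu, sigma = float(frozen_stats[0]), float(frozen_stats[1])
        frozen = True
    else:
        mu = float(seed_vals.mean())
        sigma = max(float(seed_vals.std()), sigma_floor)
        frozen = False
    if np.any(np.abs(seed_vals - mu) > tolerance * sigma + 1e-9):
        raise RegionGrowthError("seed gray outside its own acceptance window")

    max_voxels = max_fraction * gray.size
    n_accepted = int(accepted.sum())
    next_update = update_every
    frontier = np.argwhere(accepted)
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.intp)

    while frontier.size:
        cand = (frontier[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
        ok = np.all((cand >= 0) & (cand < np.array(shape)), axis=1)
        cand = cand[ok]
        lin = np.ravel_multi_index(cand.T, shape)
        lin = np.unique(lin)
        cand = np.stack(np.unravel_index(lin, shape), axis=1)
        fresh = ~accepted[tuple(cand.T)]
        cand = cand[fresh]
        if cand.size == 0:
            break
        vals = gray[tuple(cand.T)]
        hit = np.abs(vals - mu) <= tolerance * sigma
        newly = cand[hit]
        if newly.size == 0:
            break
        accepted[tuple(newly.T)] = True
        n_accepted += newly.shape[0]
        if n_accepted > max_voxels:
            raise RegionGrowthError(
                "tolerance too loose: region flooded "
                f"{100.0 * n_accepted / gray.size:.0f}% of the volume"
            )
        frontier = newly
        if not frozen and n_accepted >= next_update:
            vals_all = gray[accepted].astype(float)
            mu = float(vals_all.mean())
            sigma = max(float(vals_all.std()), sigma_floor)
            if n_accepted >= freeze_after:
                frozen = True
            else:
                next_update += update_every
            # window changed: re-expand from the whole region boundary
            frontier = np.argwhere(accepted)
    return accepted


def refine_root_mask(mask: np.ndarray, seeds, open_radius: float = 2.5,
                     collar: float = 1.0) -> np.ndarray:
    """Regularize a grown root mask: drop tendrils, fill holes, keep seeded parts.

    Adaptive growing along blurred gray values leaves thin tendrils poking
    into the pore space; these locally corrupt the distance origin of every
    downstream shell.  A morphological opening finds the root body, then a
    one-voxel collar of the raw mask around the body is restored, so the
    operation is the identity on an already-smooth mask (tendrils shorter
    than ``collar`` survive; anything thinner than ``open_radius`` and longer
    is removed).  Internal holes are filled and only components containing a
    seed are kept.
    """
    if not mask.any():
        return mask.copy()
    st = spherical_footprint(open_radius)
    body = ndimage.binary_erosion(mask, st, border_value=1)
    body = ndimage.binary_dilation(body, st, border_value=0)
    out = mask & ndimage.binary_dilation(body, spherical_footprint(collar))
    out = ndimage.binary_fill_holes(out)
    lbl, _ = ndimage.label(out)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.intp))
    keep = set(int(v) for v in lbl[tuple(seeds.T)]) - {0}
    if keep:
        out = np.isin(lbl, sorted(keep))
    return out


# ---------------------------------------------------------------------------


def exclude_root_margin(root: np.ndarray, solid: np.ndarray, pore: np.ndarray,
                        margin_voxels: float = 1,
                        analysis_region: np.ndarray | None = None,
                        voxel_size: float = 12.0) -> PhaseMasks:
    """Remove all voxels within ``margin_voxels`` (Euclidean) of the root surface.

    Compensates for partial-volume blending at the root-soil interface: the
    margin voxels leave the solid and pore masks and the analysis region; the
    root mask itself is unchanged.  Euclidean distance (EDT) is used rather
    than a box-element dilation so the margin is isotropic.
    """
    if margin_voxels < 0:
        raise SegmentationError("margin must be >= 0")
    if analysis_region is None:
        analysis_region = np.ones(root.shape, dtype=bool)
    if margin_voxels == 0 or not root.any():
        return PhaseMasks(root=root, solid=solid, pore=pore,
                          analysis_region=analysis_region, voxel_size=voxel_size)
    edt = ndimage.distance_transform_edt(~root)
    margin = ~root & (edt <= margin_voxels)
    return PhaseMasks(
        root=root,
        solid=solid & ~margin,
        pore=pore & ~margin,
        analysis_region=analysis_region & ~(margin & ~root),
        voxel_size=voxel_size,
    )


def crop_edges(shape: tuple[int, int, int], voxel_size: float,
               crop_mm: float = 3.0, geometry: str = "box",
               region: np.ndarray | None = None) -> np.ndarray:
    """Analysis-region mask with ``crop_mm`` removed from the column edge.

    ``geometry="cylinder"`` keeps the disc of radius (half the smaller lateral
    extent minus the crop) around the column axis, matching scans of round
    columns; ``geometry="box"`` crops the four lateral faces of a synthetic
    box volume.  The depth axis (z) is never cropped.
    """
    nz, ny, nx = shape
    crop_um = crop_mm * 1000.0
    n = int(round(crop_um / voxel_size))
    if 2 * n >= min(ny, nx):
        raise SegmentationError("crop exceeds half the smallest lateral dimension")
    mask = np.zeros(shape, dtype=bool)
    if geometry == "box":
        mask[:, n:ny - n if n else ny, n:nx - n if n else nx] = True
    elif geometry == "cylinder":
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        radius = min(ny, nx) / 2.0 - n
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
        mask[:] = disc[None, :, :]
    else:
        raise SegmentationError(f"unknown geometry {geometry!r}")
    if region is not None:
        mask &= region
    if not mask.any():
        raise SegmentationError("analysis region empty after edge crop")
    return mask


# ---------------------------------------------------------------------------


def segment_volume(gray: np.ndarray, voxel_size: float,
                   calib: CalibrationRegions, seeds, *,
                   median_radius: int = 3,
                   tolerance: float = 2.5,
                   margin_voxels: float = 1,
                   crop_mm: float = 0.24,
                   geometry: str = "box",
                   reference_mask: np.ndarray | None = None,
                   refine_root: bool = True,
                   ) -> PhaseMasks:
    """Full segmentation chain: filter, calibrate, threshold, grow, exclude, crop."""
    if calib is None:
        raise SegmentationError("calibration regions are required for segmentation")
    filt = median_filter_3d(gray, median_radius) if median_radius else gray
    threshold = calibrate_threshold(filt, calib)
    root = region_grow_root(filt, seeds, tolerance)
    if refine_root:
        root = refine_root_mask(root, seeds)
    if reference_mask is None:
        reference_mask = np.zeros(gray.shape, dtype=bool)
        reference_mask[calib.reference] = True
    solid = segment_solid(filt, threshold, exclude=reference_mask) & ~root
    analysis = crop_edges(gray.shape, voxel_size, crop_mm, geometry)
    analysis &= ~reference_mask
    pore = analysis & ~solid & ~root
    solid = solid & analysis
    masks = exclude_root_margin(root, solid, pore, margin_voxels,
                                analysis_region=analysis, voxel_size=voxel_size)
    masks.validate()
    return masks
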