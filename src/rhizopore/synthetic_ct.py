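"""Ground-truthed synthetic root-in-soil micro-CT volumes.

Every downstream stage of the pipeline (segmentation, shell partition, pore
morphology) is exercised against volumes produced here, because the scans the
protocol was developed on are not publicly deposited.  The generator emulates
the statistical structure the analysis assumes:

* a granular soil medium at a controlled bulk porosity — a Gaussian random
  field smoothed to a target correlation length and thresholded at the
  empirical quantile that yields the requested pore fraction exactly (up to
  ties, which a continuous field does not produce);
* an embedded tapering primary root (linear radius interpolation top to
  bottom) with optional lateral branches, all voxels carrying a root code;
* an imposed exponential porosity enhancement around the root:  within each
  one-voxel Euclidean distance band from the root surface, solid voxels are
  flipped to pore (uniformly at random, seeded) until the band reaches
  ``bulk + amplitude * exp(-d / decay_length)``, never the reverse, so bulk
  statistics away from the root are untouched;
* grayscale rendering: per-phase mean gray, Gaussian point-spread blur,
  additive Gaussian noise, an aluminium-like reference insert and an air
  pocket in corners clear of the root annulus (these provide the two
  calibration regions the thresholding protocol needs);
* a rigid "artificial root" control — a straight constant-radius rod in
  gradient-free soil — whose true porosity profile is flat.

Axes follow the numpy ``(z, y, x)`` convention with the root axis along z
(depth).  Voxels are isotropic, 12 µm by default.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phases import EXCLUDED, PORE, REFERENCE, ROOT, SOLID
from .segmentation import CalibrationRegions

__all__ = [
    "GrayLevels",
    "SyntheticSpec",
    "GroundTruth",
    "SimulationResult",
    "generate_soil",
    "embed_root",
    "impose_gradient",
    "render_grayscale",
    "simulate",
    "generate_artificial_root_control",
    "sand_spec",
    "clay_spec",
]

# RNG stream offsets so each stochastic stage draws from its own substream
_STREAM_SOIL = 0
_STREAM_ROOT = 1
_STREAM_GRADIENT = 2
_STREAM_NOISE = 3


class SyntheticSpecError(ValueError):
    """Raised when a SyntheticSpec is internally inconsistent."""


@dataclass(frozen=True)
class GrayLevels:
    """Mean gray value per phase, in arbitrary scanner units.

    Defaults mimic the imaged contrast ordering: air/pore darkest, root
    organic material intermediate, soil matrix bright, aluminium reference
    brightest.  The surface-calibration threshold (midpoint of pore and
    reference means) then falls between root and solid, as in the protocol.
    """

    pore: float = 20.0
    solid: float = 140.0
    root: float = 70.0
    reference: float = 200.0

    def validate(self) -> None:
        vals = [self.pore, self.solid, self.root, self.reference]
        if len(set(vals)) != 4:
            raise SyntheticSpecError("phase gray means must be pairwise distinct")

    def lut(self) -> np.ndarray:
        """Lookup table indexed by phase code (EXCLUDED never occurs here)."""
        out = np.zeros(5, dtype=np.float32)
        out[PORE] = self.pore
        out[SOLID] = self.solid
        out[ROOT] = self.root
        out[EXCLUDED] = self.pore
        out[REFERENCE] = self.reference
        return out


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic scan.

    Attributes
    ----------
    shape : (nz, ny, nx) voxels; default 512 x 256 x 256 = 6.1 x 3.1 x 3.1 mm
        at 12 µm — large enough for a 1 mm annulus plus bulk reference.
    voxel_size : isotropic voxel edge, µm.
    bulk_porosity : target pore fraction of the undisturbed medium
        (0.40 sand-like, 0.25 clay-like).
    grain_length_scale : µm, correlation length of the soil texture field.
    root_radius_top, root_radius_bottom : µm, linear taper of the primary
        root from the soil surface (z=0) downward.
    n_laterals, lateral_radius : lateral branch count and radius (µm);
        laterals attach to the primary axis, keeping the root one component.
    gradient_amplitude : added porosity fraction at the root surface.
    gradient_decay_length : µm, e-folding length of the porosity enhancement.
    gray : per-phase mean grays for rendering.
    psf_sigma : µm, Gaussian blur emulating partial-volume effects.  The
        default is sub-voxel (3 µm at 12 µm voxels), modelling a scan whose
        blur is minimal relative to the voxel size, as good-quality micro-CT
        at this resolution achieves.
    noise_sigma : additive Gaussian noise, gray units.
    rng_seed : master seed; every stochastic stage derives a substream.
    """

    shape: tuple[int, int, int] = (512, 256, 256)
    voxel_size: float = 12.0
    bulk_porosity: float = 0.40
    grain_length_scale: float = 72.0
    root_radius_top: float = 354.0
    root_radius_bottom: float = 210.0
    n_laterals: int = 0
    lateral_radius: float = 90.0
    gradient_amplitude: float = 0.30
    gradient_decay_length: float = 100.0
    gray: GrayLevels = field(default_factory=GrayLevels)
    psf_sigma: float = 3.0
    noise_sigma: float = 6.0
    rng_seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 16 for s in self.shape):
            raise SyntheticSpecError("shape must be 3-D with every axis >= 16")
        if self.voxel_size <= 0:
            raise SyntheticSpecError("voxel_size must be positive")
        if not 0.0 <= self.bulk_porosity <= 1.0:
            raise SyntheticSpecError("bulk_porosity must lie in [0, 1]")
        if self.gradient_amplitude < 0:
            raise SyntheticSpecError("gradient_amplitude must be >= 0")
        if self.bulk_porosity + self.gradient_amplitude > 1.0 + 1e-12:
            raise SyntheticSpecError("bulk_porosity + gradient_amplitude must be <= 1")
        if self.root_radius_top <= 0 or self.root_radius_bottom <= 0:
            raise SyntheticSpecError("root radii must be positive")
        if self.lateral_radius <= 0:
            raise SyntheticSpecError("lateral_radius must be positive")
        if self.gradient_decay_length <= 0:
            raise SyntheticSpecError("gradient_decay_length must be positive")
        if self.grain_length_scale <= 0:
            raise SyntheticSpecError("grain_length_scale must be positive")
        self.gray.validate()
        # the volume must be able to hold the root plus a 1 mm annulus
        lateral_um = min(self.shape[1], self.shape[2]) * self.voxel_size
        needed = 2.0 * (max(self.root_radius_top, self.root_radius_bottom) + 1000.0)
        if needed > lateral_um:
            raise SyntheticSpecError(
                f"volume too small: root + 1 mm annulus needs {needed:.0f} µm "
                f"laterally but the volume spans only {lateral_um:.0f} µm"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.rng_seed), int(stream)])

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)


def sand_spec(**kw) -> SyntheticSpec:
    """Loamy-sand-like preset: high bulk porosity, coarse texture, thick root."""
    base = dict(bulk_porosity=0.40, grain_length_scale=96.0,
                root_radius_top=354.0, root_radius_bottom=300.0, n_laterals=1)
    base.update(kw)
    return SyntheticSpec(**base)


def clay_spec(**kw) -> SyntheticSpec:
    """Clay-loam-like preset: low bulk porosity, fine texture, thinner root."""
    base = dict(bulk_porosity=0.25, grain_length_scale=48.0,
                root_radius_top=250.0, root_radius_bottom=207.5, n_laterals=3)
    base.update(kw)
    return SyntheticSpec(**base)


def gradient_phantom_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Validation phantom for gradient recovery and control experiments.

    A straight 300 µm-radius root in a 2.3 x 2.7 x 2.7 mm volume with a
    60 µm-texture medium: fine enough that every distance shell holds many
    independent texture elements (so shell porosities self-average), coarse
    enough that the radius-3 median filter preserves the structures it is
    asked to measure.
    """
    base = dict(shape=(192, 224, 224), root_radius_top=300.0,
                root_radius_bottom=300.0, grain_length_scale=60.0)
    base.update(kw, rng_seed=seed)
    return SyntheticSpec(**base)


def control_phantom_spec(seed: int = 0, **kw) -> SyntheticSpec:
    """Phantom for the artificial-root (rigid rod) control experiment.

    Extra-fine 18 µm texture: the control verifies the pipeline imposes no
    artificial porosity gradient, which demands the smallest attainable
    texture-sampling noise in the thin near-surface shells.
    """
    return gradient_phantom_spec(seed, grain_length_scale=18.0, **kw)


@dataclass
class GroundTruth:
    """What the generator actually built, for validating the pipeline."""

    phase_labels: np.ndarray          # uint8, codes from .phases
    root_mask: np.ndarray             # bool
    root_volume_mm3: float
    root_mean_diameter_um: float
    bulk_porosity: float
    gradient_amplitude: float
    gradient_decay_length: float
    axis_seeds: np.ndarray            # (n, 3) voxel coords on the root axis

    def porosity_profile(self, distance_um):
        """True porosity at Euclidean distance ``distance_um`` from the root."""
        d = np.asarray(distance_um, dtype=float)
        p = self.bulk_porosity + self.gradient_amplitude * np.exp(
            -d / self.gradient_decay_length
        )
        return np.minimum(p, 1.0)


@dataclass
class SimulationResult:
    gray: np.ndarray                  # float32 grayscale volume
    truth: GroundTruth
    calibration: CalibrationRegions
    spec: SyntheticSpec


# ---------------------------------------------------------------------------
# soil texture


def generate_soil(spec: SyntheticSpec) -> np.ndarray:
    """Binary solid/pore texture at exactly the requested bulk porosity.

    A seeded standard-normal field is band-pass filtered (difference of
    Gaussians at ``grain_length_scale`` and twice that) and the
    ``bulk_porosity`` quantile of the filtered values is taken as the pore
    threshold, so the global pore fraction is exact by construction (to
    within one voxel in the rounding of the count).  The band-pass, rather
    than a plain low-pass, suppresses supra-grain density fluctuations:
    uniformly packed granular media are statistically homogeneous above the
    grain scale (grain exclusion leaves no long-wavelength porosity drift),
    and the distance-shell statistics downstream assume exactly that
    homogeneity.
    """
    spec.validate()
    nz, ny, nx = (int(s) for s in spec.shape)
    n_total = nz * ny * nx
    labels = np.full((nz, ny, nx), SOLID, dtype=np.uint8)
    n_pore = int(round(spec.bulk_porosity * n_total))
    if n_pore == 0:
        return labels
    if n_pore == n_total:
        labels[:] = PORE
        return labels

    fld = texture_field(spec)
    flat = fld.ravel()
    pore_idx = np.argpartition(flat, n_pore - 1)[:n_pore]
    labels.ravel()[pore_idx] = PORE
    return labels


def texture_field(spec: SyntheticSpec) -> np.ndarray:
    """The seeded band-pass random field behind the soil texture.

    Thresholding this field at a quantile produces the solid/pore texture;
    the gradient stage re-thresholds it locally, so both stages must derive
    it from the same spec.
    """
    rng = spec.rng(_STREAM_SOIL)
    white = rng.standard_normal(tuple(int(s) for s in spec.shape), dtype=np.float32)
    sigma_vox = spec.grain_length_scale / spec.voxel_size
    fld = ndimage.gaussian_filter(white, sigma_vox)
    fld -= ndimage.gaussian_filter(white, 2.0 * sigma_vox)
    return fld


# ---------------------------------------------------------------------------
# root geometry


class RootPlacementError(ValueError):
    """Root geometry does not fit the volume."""


def _paint_capsule(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   radius_vox: float) -> None:
    """Set True every voxel within ``radius_vox`` of segment p0-p1 (voxel coords)."""
    nz, ny, nx = mask.shape
    lo = np.floor(np.minimum(p0, p1) - radius_vox).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius_vox).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, [nz, ny, nx])
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(float)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0.0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - p0) @ d) / len2, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub |= dist2 <= radius_vox * radius_vox


def embed_root(phase_labels: np.ndarray, spec: SyntheticSpec
               ) -> tuple[np.ndarray, np.ndarray]:
    """Replace voxels of a tapered primary root (plus laterals) with the root code.

    The primary root runs the full depth of the volume along z, centred
    laterally, radius interpolated linearly from ``root_radius_top`` to
    ``root_radius_bottom``.  Laterals start on the axis and extend outward
    with a slight downward dip; their length is limited so they stay clear of
    the cropped faces.  Returns the updated labels and the exact root mask.
    """
    spec.validate()
    nz, ny, nx = phase_labels.shape
    vox = spec.voxel_size
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0

    r_vox = np.linspace(spec.root_radius_top, spec.root_radius_bottom, nz) / vox
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    lat2 = ((yy - cy) ** 2 + (xx - cx) ** 2).astype(np.float32)
    root = lat2[None, :, :] <= (r_vox ** 2)[:, None, None]

    if spec.n_laterals > 0:
        rng = spec.rng(_STREAM_ROOT)
        half_extent_um = min(cy, cx) * vox
        r_lat_vox = spec.lateral_radius / vox
        for i in range(spec.n_laterals):
            zfrac = 0.25 + 0.5 * (i + 0.5) / spec.n_laterals
            z0 = zfrac * (nz - 1)
            azimuth = rng.uniform(0.0, 2.0 * math.pi)
            dip = math.radians(rng.uniform(10.0, 30.0))
            # keep the lateral tip >= 1 mm inside the lateral faces
            avail_um = half_extent_um - 1000.0 - spec.lateral_radius
            if avail_um <= 2 * vox:
                warnings.warn("volume too small for laterals; skipping them")
                break
            length_vox = 0.9 * avail_um / vox / math.cos(dip)
            direction = np.array([
                math.sin(dip),
                math.cos(dip) * math.sin(azimuth),
                math.cos(dip) * math.cos(azimuth),
            ])
            p0 = np.array([z0, cy, cx])
            p1 = p0 + length_vox * direction
            p1[0] = min(p1[0], nz - 1.0)
            _paint_capsule(root, p0, p1, r_lat_vox)

    # boundary checks on the lateral faces
    if root[:, 0, :].any() or root[:, -1, :].any() \
            or root[:, :, 0].any() or root[:, :, -1].any():
        raise RootPlacementError("root touches a lateral volume face")
    proj = root.any(axis=0)
    ys, xs = np.nonzero(proj)
    clearance_vox = min(ys.min(), ny - 1 - ys.max(), xs.min(), nx - 1 - xs.max())
    if clearance_vox * vox < 1000.0:
        warnings.warn(
            f"root clearance to lateral faces is {clearance_vox * vox:.0f} µm "
            "(< 1 mm); outer shells will be truncated",
            stacklevel=2,
        )

    out = phase_labels.copy()
    out[root] = ROOT
    return out, root


# ---------------------------------------------------------------------------
# rhizosphere porosity gradient


def impose_gradient(phase_labels: np.ndarray, root_mask: np.ndarray,
                    spec: SyntheticSpec) -> np.ndarray:
    """Enlarge pores near the root to impose an exponential porosity profile.

    Within every one-voxel EDT band from the root surface the pore fraction is
    raised to ``bulk + amplitude * exp(-d_mid / decay)`` (band midpoint
    distance, µm), capped at 1.  Solid voxels are flipped to pore in order of
    the underlying texture-field value — i.e. the band's pore threshold is
    raised — so the added porosity enlarges existing pores at the grain scale
    instead of sprinkling isolated sub-resolution voxels that a median filter
    would erase (particle rearrangement widens pores; it does not pepper the
    matrix).  Bands already above target are left alone — the medium is never
    densified, so statistics outside the annulus are untouched.
    """
    spec.validate()
    if spec.gradient_amplitude == 0.0:
        return phase_labels.copy()

    out = phase_labels.copy()
    vox = spec.voxel_size
    edt = ndimage.distance_transform_edt(~root_mask)
    fld = texture_field(spec).ravel()

    # bands out to where the enhancement falls below half a voxel count per mil
    d_max_um = spec.gradient_decay_length * math.log(spec.gradient_amplitude / 5e-4)
    k_max = min(int(math.ceil(d_max_um / vox)), int(math.ceil(edt.max())))
    flat_out = out.ravel()
    band_idx = np.ceil(edt).astype(np.int32)  # band k: edt in (k-1, k]
    band_idx[root_mask] = 0
    for k in range(1, k_max + 1):
        band = np.flatnonzero(band_idx.ravel() == k)
        if band.size == 0:
            continue
        d_mid = (k - 0.5) * vox
        target = min(1.0, spec.bulk_porosity
                     + spec.gradient_amplitude * math.exp(-d_mid / spec.gradient_decay_length))
        vals = flat_out[band]
        soil = (vals == PORE) | (vals == SOLID)
        n_pore = int(np.count_nonzero(vals == PORE))
        n_soil = int(np.count_nonzero(soil))
        need = int(round(target * n_soil)) - n_pore
        if need <= 0:
            continue
        solid_here = band[vals == SOLID]
        order = np.argsort(fld[solid_here], kind="stable")
        flat_out[solid_here[order[:need]]] = PORE
    return out


# ---------------------------------------------------------------------------
# grayscale rendering


class InsertPlacementError(ValueError):
    """No corner can host the reference insert clear of the root annulus."""


def _corner_box(shape, dims, corner, offset=2):
    """Slices of a ``dims`` box in one of the four lateral corners (low z)."""
    nz, ny, nx = shape
    dz, dy, dx = dims
    z0 = offset
    y0 = offset if corner in (0, 1) else ny - offset - dy
    x0 = offset if corner in (0, 2) else nx - offset - dx
    return (slice(z0, z0 + dz), slice(y0, y0 + dy), slice(x0, x0 + dx))


def _place_box(labels, avoid, dims_vox, shape):
    """First lateral corner (shrinking if needed) where the box avoids ``avoid``."""
    dims = np.array(dims_vox, dtype=int)
    for _ in range(5):
        dims = np.maximum(dims, 4)
        for corner in range(4):
            box = _corner_box(shape, dims, corner)
            if any(s.start < 0 or s.stop > n for s, n in zip(box, shape)):
                continue
            if not avoid[box].any():
                return box
        dims = (dims * 4) // 5  # shrink 20 % and retry
    raise InsertPlacementError(
        "reference insert / air pocket collides with the root annulus in every corner"
    )


def render_grayscale(phase_labels: np.ndarray, spec: SyntheticSpec,
                     root_mask: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, CalibrationRegions, np.ndarray]:
    """Render phase labels to a grayscale volume with insert, blur and noise.

    An aluminium-like reference insert (nominally 5 x 3 x 0.5 mm, shrunk to at
    most a quarter of each axis so it fits desk-scale volumes) and an air
    pocket are placed in lateral corners clear of the root plus its 1 mm
    annulus; they provide the reference and background calibration regions.
    The phase-mean image is blurred with a Gaussian PSF (``psf_sigma``) and
    seeded Gaussian noise (``noise_sigma``) is added.

    Returns ``(gray, calibration_regions, labels_with_insert)``.
    """
    spec.validate()
    shape = phase_labels.shape
    vox = spec.voxel_size
    labels = phase_labels.copy()

    if root_mask is None:
        root_mask = labels == ROOT
    if root_mask.any():
        annulus = ndimage.distance_transform_edt(~root_mask) * vox <= 1000.0
        avoid = annulus | root_mask
    else:
        avoid = np.zeros(shape, dtype=bool)

    def _capped(dims_um):
        d = [max(4, int(round(u / vox))) for u in dims_um]
        return [min(di, max(4, s // 4)) for di, s in zip(d, shape)]

    insert_box = _place_box(labels, avoid, _capped((5000.0, 3000.0, 500.0)), shape)
    labels[insert_box] = REFERENCE
    avoid = avoid.copy()
    avoid[insert_box] = True
    pocket_box = _place_box(labels, avoid, _capped((600.0, 600.0, 600.0)), shape)
    labels[pocket_box] = PORE

    # calibration boxes are inset past the blur so they sample pure phase
    inset = int(math.ceil(2.0 * spec.psf_sigma / vox)) + 1

    def _inner(box):
        ins = [min(inset, max(0, (s.stop - s.start - 3) // 2)) for s in box]
        return tuple(slice(s.start + i, s.stop - i) for s, i in zip(box, ins))

    calib = CalibrationRegions(background=_inner(pocket_box),
                               reference=_inner(insert_box))

    gray = spec.gray.lut()[labels]
    if spec.psf_sigma > 0:
        ndimage.gaussian_filter(gray, spec.psf_sigma / vox, output=gray)
    if spec.noise_sigma > 0:
        rng = spec.rng(_STREAM_NOISE)
        gray += spec.noise_sigma * rng.standard_normal(shape, dtype=np.float32)
    return gray, calib, labels


# ---------------------------------------------------------------------------
# top-level drivers


def _root_truth(root_mask: np.ndarray, spec: SyntheticSpec) -> tuple[float, float]:
    vox = spec.voxel_size
    volume_mm3 = float(root_mask.sum()) * (vox / 1000.0) ** 3
    mean_diam_um = spec.root_radius_top + spec.root_radius_bottom  # mean of 2*r(z)
    return volume_mm3, mean_diam_um


def _axis_seeds(spec: SyntheticSpec, n: int = 5) -> np.ndarray:
    nz, ny, nx = spec.shape
    zs = np.linspace(0.1 * (nz - 1), 0.9 * (nz - 1), n).round().astype(int)
    return np.stack([zs, np.full(n, (ny - 1) // 2), np.full(n, (nx - 1) // 2)], axis=1)


def simulate(spec: SyntheticSpec) -> SimulationResult:
    """Run the full generator: soil, root, gradient, rendering."""
    soil = generate_soil(spec)
    labelled, root = embed_root(soil, spec)
    labelled = impose_gradient(labelled, root, spec)
    gray, calib, labels = render_grayscale(labelled, spec, root_mask=root)
    vol, diam = _root_truth(root, spec)
    truth = GroundTruth(
        phase_labels=labels,
        root_mask=root,
        root_volume_mm3=vol,
        root_mean_diameter_um=diam,
        bulk_porosity=spec.bulk_porosity,
        gradient_amplitude=spec.gradient_amplitude,
        gradient_decay_length=spec.gradient_decay_length,
        axis_seeds=_axis_seeds(spec),
    )
    return SimulationResult(gray=gray, truth=truth, calibration=calib, spec=spec)


def generate_artificial_root_control(spec: SyntheticSpec) -> SimulationResult:
    """Rigid-rod control: straight constant-radius root, no porosity gradient.

    The ground-truth porosity profile is flat at ``bulk_porosity``, emulating
    the nylon-wire control used to confirm that measured gradients are caused
    by the living root and not by the imaging protocol.
    """
    rod_spec = spec.replace(
        gradient_amplitude=0.0,
        root_radius_bottom=spec.root_radius_top,
        n_laterals=0,
    )
    return simulate(rod_spec)
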