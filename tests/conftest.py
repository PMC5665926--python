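"""Shared fixtures: phantom pipeline runs (expensive, session-scoped) and
independent brute-force oracles used across test modules."""
from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from rhizopore import shell_partition as sp
from rhizopore.phases import REFERENCE, SOLID
from rhizopore.segmentation import segment_volume
from rhizopore.synthetic_ct import (SyntheticSpec, control_phantom_spec,
                                    generate_artificial_root_control,
                                    gradient_phantom_spec, simulate)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_edt(mask_background: np.ndarray) -> np.ndarray:
    """Per-voxel Euclidean distance to the nearest True voxel, by enumeration.

    ``mask_background`` marks the feature voxels distances are measured TO.
    Only for tiny volumes (pairwise distances are materialised).
    """
    pts = np.argwhere(mask_background).astype(float)
    all_idx = np.indices(mask_background.shape).reshape(3, -1).T.astype(float)
    d = cdist(all_idx, pts).min(axis=1)
    return d.reshape(mask_background.shape)


def thickness_oracle(mask: np.ndarray, voxel_size: float = 1.0) -> np.ndarray:
    """Exhaustive maximal-inscribed-sphere thickness for small masks.

    Every pore voxel c is a candidate sphere centre of radius equal to its
    distance to the phase boundary (volume faces count as boundary); a voxel
    x gets the largest diameter 2 r_c over all spheres that contain it.
    Candidate spheres are enumerated pairwise (chunked so masks up to 32³
    stay within memory); no sphere-painting shortcut is shared with the
    implementation under test.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float32)
    if not mask.any():
        return out
    pore = np.argwhere(mask).astype(float)
    # radius of each candidate sphere: distance to nearest non-pore voxel,
    # with a one-voxel border of background around the volume
    padded = np.pad(mask, 1)
    bg = np.argwhere(~padded).astype(float) - 1.0
    radii = np.empty(len(pore))
    for i in range(0, len(pore), 2048):
        radii[i:i + 2048] = cdist(pore[i:i + 2048], bg).min(axis=1)
    diam = np.zeros(len(pore))
    for i in range(0, len(pore), 512):               # chunk over centres c
        dist = cdist(pore, pore[i:i + 512])
        covered = dist <= radii[None, i:i + 512] + 1e-9
        local = np.where(covered, 2.0 * radii[None, i:i + 512], 0.0).max(axis=1)
        np.maximum(diam, local, out=diam)
    out[tuple(pore.astype(int).T)] = diam * voxel_size
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * float((a & b).sum()) / float(a.sum() + b.sum())


# ---------------------------------------------------------------------------
# phantom runs


class PipelineRun:
    """One synthetic scan pushed through segmentation and shell partition."""

    def __init__(self, spec: SyntheticSpec, control: bool = False, **seg_kw):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.sim = (generate_artificial_root_control if control
                        else simulate)(spec)
            self.spec = self.sim.spec
            labels = self.sim.truth.phase_labels
            self.masks = segment_volume(
                self.sim.gray, self.spec.voxel_size, self.sim.calibration,
                self.sim.truth.axis_seeds,
                reference_mask=labels == REFERENCE, **seg_kw)
            self.schedule = sp.ShellSchedule.default(self.spec.voxel_size)
            self.shells = sp.build_shells(self.masks.root, self.schedule,
                                          self.masks.analysis_region)
            self.discrete = sp.shell_porosity(self.shells, self.masks,
                                              self.schedule, "discrete")
            self.cumulative = sp.shell_porosity(self.shells, self.masks,
                                                self.schedule, "cumulative")
            self.named = sp.named_region_porosity(self.shells, self.masks,
                                                  self.schedule)

    @property
    def truth_solid(self):
        return self.sim.truth.phase_labels == SOLID

    def solid_accuracy(self) -> float:
        region = self.masks.analysis_region & ~self.masks.root \
            & ~self.sim.truth.root_mask
        return float(((self.masks.solid == self.truth_solid) & region).sum()
                     / region.sum())

    def root_dice(self) -> float:
        return dice(self.masks.root, self.sim.truth.root_mask)


@pytest.fixture(scope="session")
def gradient_run() -> PipelineRun:
    """Gradient phantom (bulk 0.40, amplitude 0.30, decay 100 µm) through the
    full pipeline."""
    return PipelineRun(gradient_phantom_spec(seed=7))


@pytest.fixture(scope="session")
def noisy_run() -> PipelineRun:
    """Sand-texture scan at half-voxel PSF and noise at 10 % of the
    pore-solid gray gap — the stress conditions for segmentation accuracy."""
    spec = SyntheticSpec(shape=(96, 232, 232), root_radius_top=354.0,
                         root_radius_bottom=300.0, grain_length_scale=96.0,
                         psf_sigma=6.0, noise_sigma=12.0, rng_seed=11)
    return PipelineRun(spec)


@pytest.fixture(scope="session")
def clean_run() -> PipelineRun:
    """Noise-free, blur-free render: segmentation must be exact.

    The median denoising step is off — there is no noise to remove, and the
    exactness contract concerns the calibrate / threshold / grow chain.
    """
    spec = SyntheticSpec(shape=(48, 192, 192), root_radius_top=150.0,
                         root_radius_bottom=120.0, psf_sigma=0.0,
                         noise_sigma=0.0, rng_seed=5)
    return PipelineRun(spec, median_radius=0)


@pytest.fixture(scope="session")
def control_runs() -> list[PipelineRun]:
    """Two replicate artificial-root (rigid rod) control experiments."""
    return [PipelineRun(control_phantom_spec(seed=s), control=True)
            for s in (31, 32)]
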