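"""Distance shells: schedule arithmetic, EDT binning, porosity tables,
named regions, depth profiles and gradient fitting."""
import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_edt
from rhizopore import shell_partition as sp
from rhizopore.segmentation import PhaseMasks
from rhizopore.synthetic_ct import (SyntheticSpec, embed_root, generate_soil,
                                    impose_gradient)

VOX = 12.0


def _rod_mask(shape, radius_vox):
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    lat = (yy - (ny - 1) / 2) ** 2 + (xx - (nx - 1) / 2) ** 2
    rod = np.zeros(shape, dtype=bool)
    rod[:] = lat[None] <= radius_vox ** 2
    return rod


def _uniform_masks(root, porosity, seed=0, analysis=None):
    rng = np.random.default_rng(seed)
    pore = (rng.uniform(size=root.shape) < porosity) & ~root
    if analysis is None:
        analysis = np.ones(root.shape, dtype=bool)
    return PhaseMasks(root=root, solid=~root & ~pore & analysis,
                      pore=pore & analysis, analysis_region=analysis,
                      voxel_size=VOX)


# ---------------------------------------------------------------------------
# schedule


def test_default_schedule_has_17_regions_and_34_stacks():
    sched = sp.ShellSchedule.default(VOX)
    assert sched.n_regions == 17
    assert sp.n_export_stacks(sched) == 34
    assert sched.intervals[0] == (1.0, 2.0)
    assert sched.intervals[9] == (18.0, 20.0)
    assert sched.intervals[10] == (20.0, 25.0)
    assert sched.intervals[-1] == (50.0, 83.0)      # 1 mm floored to 996 µm


def test_alternative_schedule_without_margin_band():
    sched = sp.ShellSchedule.default(VOX, include_margin_band=False)
    assert sched.n_regions == 16
    assert sched.intervals[0] == (2.0, 4.0)
    assert sched.margin_adjacent == ()


def test_schedule_rejects_non_increasing_boundaries():
    with pytest.raises(sp.ShellError):
        sp.ShellSchedule(boundaries=(2.0, 2.0, 4.0))
    with pytest.raises(sp.ShellError):
        sp.ShellSchedule(boundaries=(0.5, 2.0), inner_exclusion=1.0)


# ---------------------------------------------------------------------------
# shell construction


def test_rod_shells_have_all_17_labels_and_match_analytic_annuli():
    """Shell voxel counts around a rod match continuum annulus volumes.

    Integer-lattice EDT values cluster unevenly inside the narrow two-voxel
    bins, so those are checked as a union; the five-voxel shells and the
    outer region are checked individually.
    """
    radius, length = 12.0, 16
    rod = _rod_mask((length, 240, 240), radius)
    sched = sp.ShellSchedule.default(VOX)
    shells = sp.build_shells(rod, sched)
    assert set(np.unique(shells)) == set(range(18))

    def analytic(lo, hi):
        return np.pi * ((radius + hi) ** 2 - (radius + lo) ** 2) * length

    for region in range(11, 18):                     # 5-voxel and outer shells
        lo, hi = sched.intervals[region - 1]
        measured = (shells == region).sum()
        assert abs(measured - analytic(lo, hi)) / analytic(lo, hi) < 0.03
    inner = ((shells >= 1) & (shells <= 10)).sum()   # union of 2-voxel shells
    assert abs(inner - analytic(1.0, 20.0)) / analytic(1.0, 20.0) < 0.03


def test_shell_binning_matches_brute_force_edt():
    root = np.zeros((12, 16, 16), dtype=bool)
    root[5:7, 7:9, 7:9] = True
    sched = sp.ShellSchedule(boundaries=(2.0, 4.0, 6.0), voxel_size=VOX)
    shells = sp.build_shells(root, sched)
    d = brute_force_edt(root)
    bounds = (1.0, 2.0, 4.0, 6.0)
    for region in (1, 2, 3):
        expected = ~root & (d > bounds[region - 1]) & (d <= bounds[region])
        assert np.array_equal(shells == region, expected)


def test_shells_are_pairwise_disjoint_and_exclude_root(gradient_run):
    shells = gradient_run.shells
    assert shells[gradient_run.masks.root].max() == 0
    # labels are single-valued per voxel by construction; check the partition sum
    sched = gradient_run.schedule
    total = sum(int((shells == r).sum()) for r in range(1, 18))
    assert total == int((shells > 0).sum())


def test_empty_root_mask_rejected():
    with pytest.raises(sp.ShellError):
        sp.build_shells(np.zeros((8, 8, 8), dtype=bool),
                        sp.ShellSchedule.default(VOX))


def test_partition_sum_over_analysis_region(gradient_run):
    """Shells + root + margin/beyond account for every analysis voxel."""
    m = gradient_run.masks
    shells = gradient_run.shells
    edt_bins = (shells > 0).sum()
    root_in = (m.root & m.analysis_region).sum()
    import scipy.ndimage as ndi
    edt = ndi.distance_transform_edt(~m.root)
    outside = (m.analysis_region & ~m.root
               & ((edt <= 1.0) | (edt > 83.0))).sum()
    assert edt_bins + root_in + outside == m.analysis_region.sum()


# ---------------------------------------------------------------------------
# porosity tables


def test_uniform_medium_has_uniform_shell_porosity():
    rod = _rod_mask((24, 200, 200), 5.0)
    masks = _uniform_masks(rod, 0.35, seed=1)
    sched = sp.ShellSchedule.default(VOX)
    shells = sp.build_shells(rod, sched)
    tab = sp.shell_porosity(shells, masks, sched, "discrete")
    n = tab["pore_vox"] + tab["solid_vox"]
    ci = 3.0 * np.sqrt(0.35 * 0.65 / n)
    assert (np.abs(tab["porosity"] - 0.35) <= ci).all()


def test_cumulative_equals_volume_weighted_discrete(gradient_run):
    disc = gradient_run.discrete
    cum = gradient_run.cumulative
    start = cum["region"].iloc[0]
    for _, row in cum.iterrows():
        sel = disc[(disc.region >= start) & (disc.region <= row.region)]
        pore, solid = sel["pore_vox"].sum(), sel["solid_vox"].sum()
        assert row["pore_vox"] == pore and row["solid_vox"] == solid
        assert row["porosity"] == pytest.approx(pore / (pore + solid), abs=0, rel=1e-15)


def test_cumulative_starts_at_24_um(gradient_run):
    cum = gradient_run.cumulative
    assert (cum["inner_um"] == 24.0).all()
    assert cum["outer_um"].iloc[0] == 48.0


def test_named_region_bounds():
    sched = sp.ShellSchedule.default(VOX)
    assert sched.regions_spanning(2.0, 10.0) == (2, 3, 4, 5)    # 24-120 µm
    assert sched.regions_spanning(40.0, 50.0) == (15, 16)       # 480-600 µm
    short = sp.ShellSchedule(boundaries=(3.0, 9.0), voxel_size=VOX)
    with pytest.raises(sp.ShellError):
        short.regions_spanning(40.0, 50.0)


def test_named_region_porosity_table(gradient_run):
    named = gradient_run.named
    rs = named.set_index("region").loc["root_surface"]
    bulk = named.set_index("region").loc["bulk_soil"]
    assert rs["inner_um"] == 24.0 and rs["outer_um"] == 120.0
    assert bulk["inner_um"] == 480.0 and bulk["outer_um"] == 600.0
    assert rs["porosity"] > bulk["porosity"]        # imposed gradient visible


# ---------------------------------------------------------------------------
# depth profiles


def test_depth_profile_constant_stack_is_flat():
    rod = _rod_mask((24, 128, 128), 5.0)
    pore2d = np.random.default_rng(3).uniform(size=(128, 128)) < 0.4
    pore = np.broadcast_to(pore2d, (24, 128, 128)) & ~rod
    masks = PhaseMasks(root=rod, solid=~rod & ~pore, pore=pore,
                       analysis_region=np.ones_like(rod), voxel_size=VOX)
    sched = sp.ShellSchedule.default(VOX)
    shells = sp.build_shells(rod, sched)
    prof, _ = sp.depth_profile(shells, masks, sched, with_objects=False)
    for _, grp in prof.groupby("region"):
        assert grp["porosity"].nunique() == 1


def test_depth_profile_conserves_volumes(gradient_run):
    prof, _ = sp.depth_profile(gradient_run.shells, gradient_run.masks,
                               gradient_run.schedule, with_objects=False)
    named = gradient_run.named.set_index("region")
    slab_mm = 2 * VOX / 1000.0
    for region in ("root_surface", "bulk_soil"):
        grp = prof[prof.region == region]
        vol = ((grp["pore_area_mm2"] + grp["solid_area_mm2"]) * slab_mm).sum()
        assert vol == pytest.approx(named.loc[region, "volume_mm3"], rel=1e-12)


def test_depth_profile_localises_gradient_to_upper_half():
    rod = _rod_mask((32, 128, 128), 5.0)
    rng = np.random.default_rng(4)
    pore = np.zeros_like(rod)
    pore[:16] = rng.uniform(size=(16, 128, 128)) < 0.7   # enhanced upper half
    pore[16:] = rng.uniform(size=(16, 128, 128)) < 0.3
    pore &= ~rod
    masks = PhaseMasks(root=rod, solid=~rod & ~pore, pore=pore,
                       analysis_region=np.ones_like(rod), voxel_size=VOX)
    sched = sp.ShellSchedule.default(VOX)
    shells = sp.build_shells(rod, sched)
    prof, _ = sp.depth_profile(shells, masks, sched, with_objects=False)
    rs = prof[prof.region == "root_surface"]
    upper = rs[rs.slab < 8]["porosity"].mean()
    lower = rs[rs.slab >= 8]["porosity"].mean()
    assert upper > 0.6 and lower < 0.4


def test_depth_profile_object_areas_partition_projection():
    """2-D object areas in a slab sum exactly to the projected phase image."""
    rod = _rod_mask((8, 96, 96), 4.0)
    masks = _uniform_masks(rod, 0.3, seed=5)
    sched = sp.ShellSchedule.default(VOX)
    shells = sp.build_shells(rod, sched)
    _, objects = sp.depth_profile(shells, masks, sched, with_objects=True)
    assert not objects.empty
    px_mm2 = (VOX / 1000.0) ** 2
    region = np.isin(shells, sched.regions_spanning(2.0, 10.0))
    one = objects[(objects.slab == 0) & (objects.region == "root_surface")
                  & (objects.phase == "pore")]
    projected = (masks.pore[0:2] & region[0:2]).any(axis=0).sum()
    assert one["area_mm2"].sum() == pytest.approx(projected * px_mm2)
    assert (one["area_mm2"] > 0).all()


def test_depth_profile_rejects_bad_slab():
    rod = _rod_mask((8, 96, 96), 4.0)
    masks = _uniform_masks(rod, 0.3)
    sched = sp.ShellSchedule.default(VOX)
    shells = sp.build_shells(rod, sched)
    with pytest.raises(sp.ShellError):
        sp.depth_profile(shells, masks, sched, slab_voxels=9)


# ---------------------------------------------------------------------------
# gradient fitting


def test_fit_recovers_imposed_gradient_from_truth_labels():
    spec = SyntheticSpec(shape=(96, 192, 192), root_radius_top=150.0,
                         root_radius_bottom=150.0, grain_length_scale=36.0,
                         gradient_amplitude=0.30, gradient_decay_length=100.0,
                         rng_seed=8)
    labelled, root = embed_root(generate_soil(spec), spec)
    graded = impose_gradient(labelled, root, spec)
    masks = PhaseMasks(root=root, solid=graded == 1, pore=(graded == 0) & ~root,
                       analysis_region=np.ones_like(root), voxel_size=VOX)
    sched = sp.ShellSchedule.default(VOX)
    shells = sp.build_shells(root, sched)
    disc = sp.shell_porosity(shells, masks, sched, "discrete")
    fit = sp.fit_porosity_gradient(disc, sched)
    assert abs(fit.decay_um - 100.0) / 100.0 <= 0.20
    assert abs(fit.amplitude - 0.30) <= 0.03
    assert abs(fit.offset - 0.40) <= 0.02


def test_fit_requires_enough_shells():
    tab = pd.DataFrame({"mode": ["discrete"] * 2, "region": [2, 3],
                        "inner_um": [24.0, 48.0], "outer_um": [48.0, 72.0],
                        "porosity": [0.5, 0.45]})
    with pytest.raises(sp.ShellError):
        sp.fit_porosity_gradient(tab, sp.ShellSchedule.default(VOX))
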