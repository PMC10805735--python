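"""Radial profiling: analytic-law oracles, smoothing, windows, robustness."""

import numpy as np
import pytest
from scipy import ndimage

import nucleoshell as ns
from nucleoshell.errors import ConfigError, EmptyWindowError, NucleolusExcluded, ProfilingError
from nucleoshell.profiling import profile_nucleolus, smooth_profile
from nucleoshell.simulate import CustomLaw, UniformLaw, core_step_law
from nucleoshell.types import ImageField, LabeledMask

from helpers import disk_field, pixel_binning_oracle, profile_crossing


def test_flat_field_profile_is_flat_and_windows_equal():
    field, mask, _ = disk_field(23.6, UniformLaw(4.5))
    prof = profile_nucleolus(field, mask, 1)
    assert np.all(np.abs(prof.mean_intensity[prof.n_samples > 0] - 4.5) < 1e-6)
    wm = ns.window_means(prof)
    assert wm.inside_mean == pytest.approx(4.5, abs=1e-6)
    assert wm.outside_mean == pytest.approx(4.5, abs=1e-6)


def test_linear_law_recovered_within_tolerance():
    field, mask, _ = disk_field(20.3, CustomLaw(lambda d: 1 - d / 2, baseline=0.0))
    prof = profile_nucleolus(field, mask, 1)
    sel = prof.n_samples >= 50
    expect = 1 - prof.bin_centers / 2
    assert np.max(np.abs(prof.mean_intensity[sel] - expect[sel])) < 0.02


def test_disk_boundary_radius_accuracy():
    # 20 px disk: every ray within 0.5 px of the true radius
    field, mask, _ = disk_field(20.0, UniformLaw(1.0))
    prof = profile_nucleolus(field, mask, 1)
    assert np.nanmax(np.abs(prof.boundary_radii - 20.0)) <= 0.5
    # other radii: unbiased to < 0.15 px, excursions bounded by pixelation
    for radius in (25.4, 30.2, 55.7):
        field, mask, _ = disk_field(radius, UniformLaw(1.0))
        prof = profile_nucleolus(field, mask, 1)
        assert abs(np.nanmean(prof.boundary_radii) - radius) < 0.15
        assert np.nanmax(np.abs(prof.boundary_radii - radius)) <= 0.75


def test_step_law_window_means():
    field, mask, _ = disk_field(25.4, core_step_law(1.0, 0.0))
    wm = ns.window_means(profile_nucleolus(field, mask, 1))
    assert wm.inside_mean == pytest.approx(1.0, abs=1e-9)
    assert wm.outside_mean == pytest.approx(0.0, abs=1e-9)


def test_control_preset_window_ratio(noiseless_single_nucleolus):
    field, truth = noiseless_single_nucleolus
    label = truth.nucleolus_mask.region_labels[0]
    prof = profile_nucleolus(
        field, truth.nucleolus_mask, label, nuclei=truth.nucleus_mask
    )
    wm = ns.window_means(prof)
    assert wm.inside_mean / wm.outside_mean == pytest.approx(3.0, rel=0.05)


def test_window_validation_and_empty_window():
    field, mask, _ = disk_field(20.3, UniformLaw(1.0))
    prof = profile_nucleolus(field, mask, 1)
    with pytest.raises(ConfigError):
        ns.window_means(prof, inner=(0.0, 1.6), outer=(1.5, 2.0))
    with pytest.raises(ConfigError):
        ns.window_means(prof, inner=(0.0, 0.5), outer=(1.5, 2.5))
    # nucleus truncates the annulus below d = 1.5 -> outside window empty
    field3, mask3, d3 = disk_field(22.2, UniformLaw(1.0))
    nuc = (d3 <= 1.3).astype(np.int32)
    mask3.parent = {1: 1}
    prof3 = profile_nucleolus(field3, mask3, 1, nuclei=LabeledMask(nuc))
    with pytest.raises(EmptyWindowError):
        ns.window_means(prof3)


def test_samples_outside_parent_nucleus_are_discarded():
    """Samples beyond the nuclear envelope never enter the profile."""
    field, mask, d = disk_field(22.2, UniformLaw(3.0))
    # nucleus that truncates the annulus at d ~ 1.4 on one side
    nuc = np.zeros(mask.labels.shape, dtype=np.int32)
    rr, cc = np.meshgrid(np.arange(256.0), np.arange(256.0), indexing="ij")
    nuc[np.hypot(rr - 127.37, cc - 128.81) <= 31.0] = 1
    nuclei = LabeledMask(nuc)
    mask.parent = {1: 1}
    prof = profile_nucleolus(field, mask, 1, nuclei=nuclei)
    assert np.all(prof.samples_d * 22.2 <= 31.0 + 1.0)


def test_smoothing_identity_constant_and_convolution_oracle():
    field, mask, _ = disk_field(20.3, CustomLaw(lambda d: np.sin(3 * d) + 2, baseline=2.0))
    prof = profile_nucleolus(field, mask, 1)
    assert np.allclose(
        smooth_profile(prof, 1).mean_intensity, prof.mean_intensity, equal_nan=True
    )
    const_prof = profile_nucleolus(*disk_field(20.3, UniformLaw(5.0))[:2], 1)
    sm = smooth_profile(const_prof, 5)
    ok = const_prof.n_samples > 0
    assert np.allclose(sm.mean_intensity[ok], 5.0, atol=1e-6)
    # direct convolution oracle away from edges
    y = prof.mean_intensity
    kernel = np.ones(5) / 5.0
    direct = np.convolve(y, kernel, mode="valid")
    sm5 = smooth_profile(prof, 5)
    assert np.allclose(sm5.mean_intensity[2:-2], direct)
    with pytest.raises(ValueError):
        smooth_profile(prof, 4)


def test_smoothing_skips_missing_bins():
    field, mask, _ = disk_field(20.3, UniformLaw(1.0))
    prof = profile_nucleolus(field, mask, 1)
    prof.mean_intensity[10] = np.nan
    sm = smooth_profile(prof, 3)
    assert np.isnan(sm.mean_intensity[10])  # missing stays missing
    # neighbors average only over present bins
    assert sm.mean_intensity[11] == pytest.approx(1.0, abs=1e-6)


def test_aggregate_two_point_formulas():
    field, mask, _ = disk_field(20.3, UniformLaw(1.0))
    p1 = profile_nucleolus(field, mask, 1)
    p3 = profile_nucleolus(field, mask, 1)
    p3.mean_intensity = p3.mean_intensity * 3.0
    summary = ns.aggregate([p1, p3])
    ok = p1.n_samples > 0
    assert np.allclose(summary.mean[ok], 2.0, atol=1e-6)
    assert np.allclose(summary.sd[ok], np.sqrt(2.0), atol=1e-5)
    same = ns.aggregate([p1, p1])
    assert np.allclose(same.sd[ok], 0.0, atol=1e-12)
    assert same.n_nucleoli == 2

    p_bad = profile_nucleolus(field, mask, 1, n_bins=20)
    with pytest.raises(ConfigError):
        ns.aggregate([p1, p_bad])


def test_normalize_summary_modes():
    field, mask, _ = disk_field(25.4, CustomLaw(lambda d: 6 - 2 * d, baseline=2.0))
    prof = profile_nucleolus(field, mask, 1)
    summary = ns.aggregate([prof, prof])
    mm = ns.normalize_summary(summary, "minmax")
    finite = np.isfinite(mm.mean)
    assert mm.mean[finite].min() == pytest.approx(0.0)
    assert mm.mean[finite].max() == pytest.approx(1.0)
    span = np.nanmax(summary.mean) - np.nanmin(summary.mean)
    assert np.allclose(mm.sd[finite], summary.sd[finite] / span, equal_nan=True)

    mo = ns.normalize_summary(summary, "mean_outside")
    sel = (summary.bin_centers >= 1.5) & (summary.bin_centers <= 2.0) & finite
    ref = summary.mean[sel].mean()
    assert np.allclose(mo.mean[finite], summary.mean[finite] / ref)

    ident = ns.normalize_summary(summary, "none")
    assert np.allclose(ident.mean, summary.mean, equal_nan=True)

    flat = ns.aggregate([profile_nucleolus(*disk_field(20.3, UniformLaw(2.0))[:2], 1)] * 2)
    with pytest.raises(ValueError):
        ns.normalize_summary(flat, "minmax")
    with pytest.raises(ValueError):
        ns.normalize_summary(summary, "quantile")


def test_resolution_consistency(segmented_control):
    """Doubling rays / halving step changes bin means by < 1% of the law max."""
    field, _, nuclei, nucleoli = segmented_control
    label = nucleoli.region_labels[0]
    base = profile_nucleolus(field, nucleoli, label, nuclei=nuclei)
    fine = profile_nucleolus(
        field, nucleoli, label, nuclei=nuclei, n_rays=360, step=0.125
    )
    sel = (base.n_samples > 0) & (fine.n_samples > 0)
    rel = np.nanmax(np.abs(base.mean_intensity[sel] - fine.mean_intensity[sel])) / 150.0
    assert rel < 0.01


def test_mask_dilation_shifts_crossing_at_most_1p5_bins(segmented_control):
    field, _, nuclei, nucleoli = segmented_control
    label = nucleoli.region_labels[0]
    dil = ndimage.grey_dilation(nucleoli.labels, size=(3, 3))
    dil[nucleoli.labels > 0] = nucleoli.labels[nucleoli.labels > 0]
    dilated = LabeledMask(dil.astype(np.int32), parent=nucleoli.parent)
    p0 = profile_nucleolus(field, nucleoli, label, nuclei=nuclei)
    p1 = profile_nucleolus(field, dilated, label, nuclei=nuclei)
    shift = abs(profile_crossing(p0) - profile_crossing(p1)) / p0.bin_width
    assert shift <= 1.5


def test_concave_region_with_external_centroid_errors():
    shape = (200, 200)
    rr, cc = np.meshgrid(np.arange(200.0), np.arange(200.0), indexing="ij")
    dist = np.hypot(rr - 100.2, cc - 99.7)
    horseshoe = (dist <= 40) & (dist >= 25) & (cc < 115)
    field = ImageField(
        pixels=np.ones((1,) + shape), pixel_size=0.063, channel_roles={"target": 0}
    )
    with pytest.raises(ProfilingError):
        profile_nucleolus(field, LabeledMask(horseshoe.astype(np.int32)), 1)


def test_undetectable_boundary_excludes_nucleolus():
    """A plus-shaped region with arms longer than the search range."""
    shape = (360, 360)
    labels = np.zeros(shape, dtype=np.int32)
    labels[176:185, 30:330] = 1
    labels[30:330, 176:185] = 1
    field = ImageField(
        pixels=np.ones((1,) + shape), pixel_size=0.063, channel_roles={"target": 0}
    )
    with pytest.raises(NucleolusExcluded) as err:
        profile_nucleolus(field, LabeledMask(labels), 1, n_rays=4)
    assert err.value.reason == "no-boundary"


def test_neighbor_policies_control_halo_contamination():
    """Partition and margin policies keep a bright neighbor's halo out of
    the outside window; disabling exclusion lets it contaminate."""
    shape = (256, 256)
    rr, cc = np.meshgrid(np.arange(256.0), np.arange(256.0), indexing="ij")
    d1 = np.hypot(rr - 127.4, cc - 100.2)
    d2 = np.hypot(rr - 127.4, cc - 152.2)
    labels = np.zeros(shape, dtype=np.int32)
    labels[d1 <= 20] = 1
    labels[d2 <= 20] = 2
    img = np.where(d2 <= 24, 100.0, 1.0)  # neighbor halo out to 4 px
    field = ImageField(pixels=img[None], pixel_size=0.063, channel_roles={"target": 0})
    mask = LabeledMask(labels)
    part = ns.window_means(profile_nucleolus(field, mask, 1))
    marg = ns.window_means(
        profile_nucleolus(field, mask, 1, neighbor_policy="margin", neighbor_margin=6.0)
    )
    none = ns.window_means(profile_nucleolus(field, mask, 1, neighbor_policy="none"))
    assert part.outside_mean == pytest.approx(1.0, abs=1e-6)
    assert marg.outside_mean == pytest.approx(1.0, abs=1e-6)
    assert none.outside_mean > 1.5  # halo contaminates without exclusion
    # partition is the strictest policy: every pixel goes to one nucleolus
    assert part.n_outside <= marg.n_outside < none.n_outside
    with pytest.raises(ValueError):
        profile_nucleolus(field, mask, 1, neighbor_policy="voronoi-ish")


def test_foreign_guard_matches_brute_force_nearest_label():
    from nucleoshell.profiling import foreign_guard

    rr, cc = np.meshgrid(np.arange(200.0), np.arange(200.0), indexing="ij")
    labels = np.zeros((200, 200), dtype=np.int32)
    labels[np.hypot(rr - 70.3, cc - 60.7) <= 15] = 1
    labels[np.hypot(rr - 120.6, cc - 130.2) <= 22] = 2
    gdist, gnear = foreign_guard(labels, margin=8.0)
    d_full, idx = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    near_full = labels[tuple(idx)]
    # inside the evaluated box the nearest label matches the exact transform;
    # every pixel within twice its nearest region's radius is covered
    covered = d_full <= 30
    assert np.array_equal(gnear[covered], near_full[covered])
    assert np.allclose(gdist[covered], np.minimum(d_full[covered], 9.0))


def test_profile_on_3d_stack_uses_central_plane():
    from nucleoshell.simulate import SyntheticSpec, condition_preset

    spec = condition_preset("control")(
        SyntheticSpec(
            image_shape=(24, 160, 160),
            nucleus_radius=(30.0, 1.0),
            nucleoli_per_nucleus=(1, 1),
            nucleolus_radius=(9.0, 0.5),
            nucleolus_radius_limits=(8.0, 10.0),
            blur_sigma=0.0,
            poisson_scale=None,
            gaussian_noise_sd=0.0,
            seed=6,
        )
    )
    field, truth = ns.generate_field(spec)
    label = truth.nucleolus_mask.region_labels[0]
    prof = profile_nucleolus(
        field, truth.nucleolus_mask, label, nuclei=truth.nucleus_mask, n_rays=90
    )
    wm = ns.window_means(prof)
    assert wm.inside_mean / wm.outside_mean == pytest.approx(3.0, rel=0.1)


def test_line_profile_constant_and_step_edge():
    img = np.ones((64, 128))
    img[:, 100:] = 0.0
    field = ImageField(
        pixels=img[None], pixel_size=0.1, channel_roles={"target": 0}
    )
    flat = ns.line_profile(field, (30.0, 10.0), (30.0, 60.0))
    assert np.allclose(flat["target"], 1.0)
    trans = ns.line_profile(field, (30.0, 80.0), (30.0, 120.0))
    pos_px = trans["position_um"].to_numpy() / 0.1 + 80.0
    mid = np.interp(0.5, trans["target"].to_numpy()[::-1], pos_px[::-1])
    assert abs(mid - 100.0) <= 0.5
    with pytest.raises(ValueError):
        ns.line_profile(field, (30.0, 10.0), (30.0, 300.0))
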