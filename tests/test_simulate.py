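"""Synthetic generator: analytic laws, determinism, noise model, assay tables."""

import numpy as np
import pandas as pd
import pytest

import nucleoshell as ns
from nucleoshell.errors import PlacementError
from nucleoshell.simulate import (
    CONDITION_PRESETS,
    SyntheticSpec,
    UniformLaw,
    condition_preset,
    core_step_law,
    generate_gel_table,
    generate_qpcr_table,
    shell_marker_law,
)


def _noiseless(**kw):
    kw.setdefault("blur_sigma", 0.0)
    kw.setdefault("poisson_scale", None)
    kw.setdefault("gaussian_noise_sd", 0.0)
    kw.setdefault("nucleoli_per_nucleus", (2, 3))
    return SyntheticSpec(seed=kw.pop("seed", 1), **kw)


def test_noiseless_step_law_renders_exact_disks():
    spec = _noiseless(
        channel_laws={"target": core_step_law(1.0, 0.0)}, seed=4
    )
    field, truth = ns.generate_field(spec)
    target = field.channel("target")
    body = truth.nucleolus_mask.labels > 0
    assert np.all(target[body] == 1.0)
    # beyond every nucleolus body the value is the baseline 0
    assert np.all(target[~body] == 0.0)


def test_uniform_law_constant_over_nucleus():
    spec = _noiseless(channel_laws={"target": UniformLaw(7.0)}, seed=5)
    field, truth = ns.generate_field(spec)
    inside = truth.nucleus_mask.labels > 0
    assert np.all(field.channel("target")[inside] == 7.0)
    assert np.all(field.channel("target")[~inside] == 0.0)


def test_identical_spec_and_seed_bit_identical():
    spec_a = ns.make_condition_spec("control", seed=7)
    spec_b = ns.make_condition_spec("control", seed=7)
    fa, ta = ns.generate_field(spec_a)
    fb, tb = ns.generate_field(spec_b)
    assert np.array_equal(fa.pixels, fb.pixels)
    assert np.array_equal(ta.nucleolus_mask.labels, tb.nucleolus_mask.labels)
    assert ta.centroids == tb.centroids


def test_different_seed_changes_output():
    fa, _ = ns.generate_field(ns.make_condition_spec("control", seed=1))
    fb, _ = ns.generate_field(ns.make_condition_spec("control", seed=2))
    assert not np.array_equal(fa.pixels, fb.pixels)


@pytest.mark.parametrize(
    "name, expected_ratio",
    [("control", 3.0), ("RNAPI_inhibited_like", 1.0), ("G4_ligand_like", 1.0)],
)
def test_preset_inside_outside_ratio(name, expected_ratio):
    spec = condition_preset(name)(SyntheticSpec())
    law = spec.channel_laws["target"]
    ratio = law.window_mean(0.0, 0.5) / law.window_mean(1.5, 2.0)
    assert ratio == pytest.approx(expected_ratio)
    assert spec.condition_label == name


def test_blm_preset_halves_the_whole_law():
    base = condition_preset("control")(SyntheticSpec()).channel_laws["target"]
    blm = condition_preset("BLM_like", reduction=0.5)(SyntheticSpec()).channel_laws[
        "target"
    ]
    d = np.linspace(0, 2.5, 101)
    assert np.allclose(blm(d), 0.5 * base(d))


def test_g4_preset_reduces_shell_marker():
    base = SyntheticSpec().channel_laws["shell_marker"]
    mod = condition_preset("G4_ligand_like", shell_reduction=0.5)(
        SyntheticSpec()
    ).channel_laws["shell_marker"]
    d = np.linspace(0, 2, 41)
    assert np.allclose(mod(d), 0.5 * base(d))


def test_unknown_preset_error_lists_valid_names():
    with pytest.raises(ValueError) as err:
        condition_preset("nonsense")
    for name in CONDITION_PRESETS:
        assert name in str(err.value)


def test_infeasible_placement_raises():
    spec = SyntheticSpec(
        image_shape=(160, 160),
        nucleus_radius=(60.0, 1.0),
        nucleoli_per_nucleus=(8, 8),
        nucleolus_radius=(22.0, 0.5),
        nucleolus_radius_limits=(21.0, 23.0),
        seed=0,
    )
    with pytest.raises(PlacementError):
        ns.generate_field(spec)


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(shell_thickness=1.5)
    with pytest.raises(ValueError):
        SyntheticSpec(pixel_size=-1.0)
    with pytest.raises(ValueError):
        SyntheticSpec(nucleoli_per_nucleus=(3, 2))
    with pytest.raises(ValueError):
        SyntheticSpec(poisson_scale=0.0)


def test_radial_law_fidelity_by_analytic_binning():
    """Binning noiseless pixels by their analytic d recovers the law."""
    spec = _noiseless(nucleoli_per_nucleus=(1, 1), seed=9)
    field, truth = ns.generate_field(spec)
    label = truth.nucleolus_mask.region_labels[0]
    d = truth.distance_field(label)
    target = field.channel("target")
    law = truth.channel_laws["target"]
    inside_nucleus = truth.nucleus_mask.labels > 0
    sel = (d <= 2.0) & inside_nucleus
    width = 0.05
    idx = np.minimum((d[sel] / width).astype(int), 39)
    sums = np.bincount(idx, weights=target[sel], minlength=40)
    counts = np.bincount(idx, minlength=40)
    means = sums / np.maximum(counts, 1)
    centers = width * (np.arange(40) + 0.5)
    assert np.allclose(means[counts > 0], law(centers)[counts > 0])


def test_poisson_noise_variance_matches_mean():
    """Photon-count variance/mean ~ 1 on a constant region (>= 1e5 px)."""
    scale = 2.0
    spec = SyntheticSpec(
        image_shape=(768, 768),
        nucleus_radius=(190.0, 1.0),
        channel_laws={"target": UniformLaw(50.0)},
        blur_sigma=0.0,
        poisson_scale=scale,
        gaussian_noise_sd=0.0,
        nucleoli_per_nucleus=(1, 1),
        seed=13,
    )
    field, truth = ns.generate_field(spec)
    inside = truth.nucleus_mask.labels > 0
    counts = field.channel("target")[inside] * scale
    assert counts.size >= 100_000
    assert 0.9 <= counts.var() / counts.mean() <= 1.1


def test_boundary_harmonics_preserve_truth_consistency():
    spec = _noiseless(
        boundary_harmonics=((3, 0.12),), nucleoli_per_nucleus=(1, 1), seed=21
    )
    field, truth = ns.generate_field(spec)
    label = truth.nucleolus_mask.region_labels[0]
    d = truth.distance_field(label)
    mask = truth.nucleolus_mask.labels == label
    inside_nucleus = truth.nucleus_mask.labels > 0
    assert np.array_equal(mask, (d <= 1.0) & inside_nucleus)
    b = truth.boundary[label]
    theta = np.linspace(0, 2 * np.pi, 73)
    assert b.radius_at(theta).std() > 0  # genuinely non-circular


def test_3d_field_shapes_and_anisotropy():
    spec = SyntheticSpec(
        image_shape=(24, 128, 128),
        nucleus_radius=(26.0, 1.0),
        nucleoli_per_nucleus=(1, 1),
        nucleolus_radius=(8.0, 0.5),
        nucleolus_radius_limits=(7.0, 9.0),
        seed=2,
    )
    field, truth = ns.generate_field(spec)
    assert field.is_3d and field.pixels.shape[1:] == (24, 128, 128)
    label = truth.nucleolus_mask.region_labels[0]
    body = truth.nucleolus_mask.labels == label
    z_extent = np.ptp(np.nonzero(body)[0])
    xy_extent = np.ptp(np.nonzero(body)[1])
    # 0.3 um z-spacing vs 0.063 um pixels: the sphere spans ~4.8x fewer planes
    assert z_extent < xy_extent


# --- assay tables ---------------------------------------------------------


def test_gel_table_zero_noise_exact_fraction():
    table = generate_gel_table(0, {"underwound+psoralen+UV": 0.5}, noise_cv=0.0)
    ratios = table["band_nondenatured"] / table["band_total"]
    assert np.allclose(ratios, 0.5)


def test_gel_table_rejects_bad_fraction():
    with pytest.raises(ValueError):
        generate_gel_table(0, {"x": 1.2})


def test_qpcr_zero_noise_ip_equals_input_ct():
    enrichment = {("PQS-1", "NPM", "water"): 0.02}
    table = generate_qpcr_table(0, enrichment, input_fraction=0.02, ct_noise_sd=0.0)
    ip = table[table.antibody == "NPM"].set_index("replicate")["ct"]
    inp = table[table.antibody == "input"].set_index("replicate")["ct"]
    assert np.allclose(ip, inp.loc[ip.index])


def test_qpcr_rejects_nonpositive_enrichment():
    with pytest.raises(ValueError):
        generate_qpcr_table(0, {("PQS-1", "NPM", "water"): 0.0})


def test_assay_tables_deterministic():
    g1, q1 = ns.generate_assay_tables(5)
    g2, q2 = ns.generate_assay_tables(5)
    pd.testing.assert_frame_equal(g1, g2)
    pd.testing.assert_frame_equal(q1, q2)
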