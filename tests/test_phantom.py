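"""Phantom generator: surface statistics, vessel layout, constriction
schedules, rendering geometry, and the analytic projected-area oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pamvasc.phantom import (ConstrictionSchedule, GroundTruth, InvalidSpecError,
                             PhantomSpec, apply_constriction, generate_study,
                             generate_surface, ground_truth_layer_density,
                             place_vessels, preset_groups, realized_band_centers,
                             render_volume)
from pamvasc.surface import SurfaceMap


# ---------------------------------------------------------------------------
# surface field
# ---------------------------------------------------------------------------

def test_zero_amplitude_gives_flat_surface():
    spec = PhantomSpec.small(seed=1)
    spec = replace(spec, surface_amplitude_um=0.0)
    surf = generate_surface(spec)
    assert np.allclose(surf.depth_um, spec.surface_mean_depth_um)


def test_surface_reproducible_and_bounded():
    spec = PhantomSpec.small(seed=5)
    a = generate_surface(spec)
    b = generate_surface(spec)
    assert np.array_equal(a.z_surface, b.z_surface)
    dev = a.depth_um - spec.surface_mean_depth_um
    assert np.abs(dev).max() <= spec.surface_amplitude_um + 1e-9


def test_surface_autocorrelation_length_matches_spec():
    """Empirical e-folding distance of the lateral autocorrelation must land
    within a factor of two of the requested correlation length."""
    spec = PhantomSpec(shape=(256, 256, 240), spacing_um=(10.0, 10.0, 3.0),
                       surface_corr_length_um=500.0, surface_amplitude_um=30.0,
                       n_pd=10, n_rd=4, n_hd=2, seed=3)
    field = generate_surface(spec).depth_um
    f = field - field.mean()
    power = np.abs(np.fft.fft2(f)) ** 2
    acov = np.real(np.fft.ifft2(power))
    acorr_x = acov[:, 0] / acov[0, 0]
    below = np.flatnonzero(acorr_x[: 128] < 1.0 / math.e)
    assert below.size, "autocorrelation never decays below 1/e"
    efold_um = below[0] * spec.spacing_um[0]
    assert 250.0 <= efold_um <= 1000.0


def test_surface_leaving_grid_is_invalid():
    with pytest.raises(InvalidSpecError):
        PhantomSpec.small(seed=0).__class__(
            shape=(96, 96, 240), surface_mean_depth_um=50.0, surface_amplitude_um=80.0)


# ---------------------------------------------------------------------------
# vessel placement
# ---------------------------------------------------------------------------

def test_vessel_counts_and_tags():
    spec = replace(PhantomSpec.small(seed=2), n_pd=0, n_rd=0, n_hd=1)
    vessels = place_vessels(spec)
    assert len(vessels) == 1 and vessels[0].layer_tag == "HD"

    spec = PhantomSpec.small(seed=2)
    vessels = place_vessels(spec)
    by_layer = {tag: [v for v in vessels if v.layer_tag == tag] for tag in ("PD", "RD", "HD")}
    assert len(by_layer["PD"]) == spec.n_pd
    assert len(by_layer["RD"]) == spec.n_rd
    assert len(by_layer["HD"]) == spec.n_hd
    assert sum(len(g) for g in by_layer.values()) == len(vessels)


def test_hypodermal_vessels_are_larger_than_papillary():
    vessels = place_vessels(PhantomSpec.small(seed=4))
    mean_r = {tag: np.mean([v.radius_um for v in vessels if v.layer_tag == tag])
              for tag in ("PD", "HD")}
    assert mean_r["HD"] > mean_r["PD"]


def test_reticular_connectors_are_near_vertical():
    vessels = place_vessels(PhantomSpec.small(seed=4))
    for v in vessels:
        if v.layer_tag != "RD":
            continue
        dz = abs(v.centerline[-1, 2] - v.centerline[0, 2])
        lateral = np.linalg.norm(v.centerline[-1, :2] - v.centerline[0, :2])
        assert dz > lateral


def test_vessels_lie_inside_the_grid():
    spec = PhantomSpec.small(seed=9)
    ex, ey, ez = spec.extent_um
    for v in place_vessels(spec):
        assert v.centerline[:, 0].min() >= 0 and v.centerline[:, 0].max() <= ex
        assert v.centerline[:, 1].min() >= 0 and v.centerline[:, 1].max() <= ey
        assert v.centerline[:, 2].min() >= 0 and v.centerline[:, 2].max() <= ez


# ---------------------------------------------------------------------------
# constriction schedules
# ---------------------------------------------------------------------------

def test_constriction_factor_closed_form():
    sched = ConstrictionSchedule("PD", c_max=0.5, tau_min=20.0)
    assert sched.factor(0.0) == 1.0
    assert sched.factor(20.0) == pytest.approx(1 - 0.5 * (1 - math.exp(-1)), abs=1e-9)
    assert sched.factor(20.0) == pytest.approx(0.6839, abs=1e-4)
    # near-zero time constant: immediate saturation at 1 - c_max
    assert ConstrictionSchedule("PD", 0.5, 1e-9).factor(10.0) == pytest.approx(0.5)


def test_apply_constriction_identity_and_selectivity():
    vessels = place_vessels(PhantomSpec.small(seed=1))
    schedules = {"RD": ConstrictionSchedule("RD", 0.4, 20.0)}
    at0 = apply_constriction(vessels, schedules, 0.0)
    assert [v.radius_um for v in at0] == [v.radius_um for v in vessels]
    at60 = apply_constriction(vessels, schedules, 60.0)
    f = schedules["RD"].factor(60.0)
    for v0, v1 in zip(vessels, at60):
        expect = v0.radius_um * f if v0.layer_tag == "RD" else v0.radius_um
        assert v1.radius_um == pytest.approx(expect)
    with pytest.raises(ValueError):
        apply_constriction(vessels, schedules, -1.0)


def test_dropout_mode_removes_scheduled_fraction_nested():
    vessels = place_vessels(PhantomSpec.small(seed=1))
    n_rd = sum(v.layer_tag == "RD" for v in vessels)
    sched = {"RD": ConstrictionSchedule("RD", 0.5, 1e-9, mode="dropout")}
    survivors = apply_constriction(vessels, sched, 60.0)
    n_left = sum(v.layer_tag == "RD" for v in survivors)
    assert n_left == n_rd - round(0.5 * n_rd)
    # nested removal: survivors at high drop are a subset of those at low drop
    ids_30 = {id(v) for v in apply_constriction(
        vessels, {"RD": ConstrictionSchedule("RD", 0.3, 1e-9, mode="dropout")}, 60.0)}
    assert {id(v) for v in survivors} <= ids_30


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _flat_spec(**kw):
    base = dict(shape=(60, 60, 240), spacing_um=(5.0, 10.0, 3.0),
                surface_amplitude_um=0.0, noise_sd=0.0, n_pd=0, n_rd=0, n_hd=0, seed=0)
    base.update(kw)
    return PhantomSpec(**base)


def test_empty_scene_renders_to_zero():
    spec = _flat_spec()
    vol = render_volume([], generate_surface(spec), spec, 0.0)
    assert vol.amplitude.max() == 0.0


def test_tube_voxel_count_matches_capsule_volume():
    """Suprathreshold voxel count of one unblurred tube must agree with the
    analytic capsule volume to within voxelization error (<= 10%)."""
    spec = _flat_spec()
    r, length = 20.0, 400.0
    tube = [dict(centerline=np.array([[120.0, 100.0, 300.0], [120.0, 100.0 + length, 300.0]]),
                 radius_um=r, layer_tag="HD", intensity=1.0)]
    from pamvasc.phantom import VesselPrimitive
    vol = render_volume([VesselPrimitive(**tube[0])], generate_surface(spec), spec, 0.0,
                        apply_psf=False, apply_noise=False)
    count = int(np.count_nonzero(vol.amplitude > 0.5))
    capsule_um3 = math.pi * r * r * length + 4.0 / 3.0 * math.pi * r ** 3
    expected = capsule_um3 / np.prod(spec.spacing_um)
    assert abs(count - expected) / expected <= 0.10


def test_axial_psf_broadens_a_thin_tube():
    """The suprathreshold axial extent of a thin tube grows by roughly the
    axial resolution width once the PSF is applied."""
    from pamvasc.phantom import VesselPrimitive
    spec = _flat_spec()
    tube = VesselPrimitive(centerline=np.array([[150.0, 50.0, 300.0], [150.0, 550.0, 300.0]]),
                           radius_um=6.0, layer_tag="PD", intensity=1.0)
    surface = generate_surface(spec)

    def fwhm_um(apply_psf):
        vol = render_volume([tube], surface, spec, 0.0, apply_psf=apply_psf,
                            apply_noise=False)
        line = vol.amplitude[30, 30, :]
        assert line.max() > 0
        return np.count_nonzero(line >= 0.5 * line.max()) * spec.spacing_um[2]

    growth = fwhm_um(True) - fwhm_um(False)
    assert 0.5 * spec.psf_axial_um <= growth <= 2.0 * spec.psf_axial_um


def test_render_is_deterministic():
    spec = PhantomSpec.small(seed=11)
    surf = generate_surface(spec)
    vessels = place_vessels(spec)
    a = render_volume(vessels, surf, spec, 10.0)
    b = render_volume(vessels, surf, spec, 10.0)
    assert np.array_equal(a.amplitude, b.amplitude)


# ---------------------------------------------------------------------------
# analytic projected-area oracle
# ---------------------------------------------------------------------------

def _lone_tube_truth(r, length, extent=(1000.0, 1000.0)):
    from pamvasc.phantom import VesselPrimitive
    v = VesselPrimitive(centerline=np.array([[100.0, 500.0, 300.0],
                                             [100.0 + length, 500.0, 300.0]]),
                        radius_um=r, layer_tag="PD", intensity=1.0)
    return GroundTruth(baseline_vessels=[v], schedules={}, timepoints_min=(0.0,),
                       pd_depth_um=300.0, hd_depth_um=500.0, lateral_extent_um=extent)


def test_projected_area_of_lone_tube():
    truth = _lone_tube_truth(r=10.0, length=800.0)
    # rectangle projection 2 r L / A (end caps add ~2%)
    assert ground_truth_layer_density(truth, "PD", 0.0) == pytest.approx(
        2 * 10 * 800 / 1e6, rel=0.02)
    assert ground_truth_layer_density(truth, "RD", 0.0) == 0.0
    with pytest.raises(ValueError):
        ground_truth_layer_density(truth, "DERMIS", 0.0)


def test_projected_area_scales_linearly_with_radius():
    a = ground_truth_layer_density(_lone_tube_truth(10.0, 800.0), "PD", 0.0)
    b = ground_truth_layer_density(_lone_tube_truth(5.0, 800.0), "PD", 0.0)
    assert b / a == pytest.approx(0.5, rel=0.02)


def test_no_vessels_zero_density():
    truth = GroundTruth(baseline_vessels=[], schedules={}, timepoints_min=(0.0,),
                        pd_depth_um=60.0, hd_depth_um=500.0,
                        lateral_extent_um=(1000.0, 1000.0))
    assert ground_truth_layer_density(truth, "WHOLE", 0.0) == 0.0


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def test_study_shape_and_presets():
    bundle = generate_study(PhantomSpec.small(seed=0), n_subjects=6)
    assert len(bundle.subjects) == 24            # 4 groups x 6 subjects
    assert bundle.n_volumes == 168               # x 7 timepoints

    control = next(s for s in bundle.subjects if s.group == "control")
    for layer in ("PD", "RD", "HD"):
        a0 = control.truth.projected_area_fraction(layer, 0.0)
        a60 = control.truth.projected_area_fraction(layer, 60.0)
        assert a0 == pytest.approx(a60)

    injection = next(s for s in bundle.subjects if s.group == "injection")
    rd = [injection.truth.projected_area_fraction("RD", t) for t in (0, 20, 40, 60)]
    assert all(x > y for x, y in zip(rd, rd[1:])), "RD fraction must strictly decrease"
    for layer in ("PD", "HD"):
        assert injection.truth.projected_area_fraction(layer, 0.0) == pytest.approx(
            injection.truth.projected_area_fraction(layer, 60.0))


def test_duplicate_group_names_rejected():
    groups = preset_groups()[:1] * 2
    with pytest.raises(ValueError, match="duplicate"):
        generate_study(PhantomSpec.small(seed=0), groups=groups, n_subjects=1)


def test_subjects_reproducible_from_master_seed():
    a = generate_study(PhantomSpec.small(seed=42), n_subjects=2)
    b = generate_study(PhantomSpec.small(seed=42), n_subjects=2)
    for sa, sb in zip(a.subjects, b.subjects):
        assert sa.spec.seed == sb.spec.seed
        assert np.array_equal(sa.baseline_vessels[0].centerline,
                              sb.baseline_vessels[0].centerline)


def test_realized_band_centers_near_nominal():
    spec = PhantomSpec.small(seed=13)
    centers = realized_band_centers(place_vessels(spec))
    assert abs(centers["PD"] - spec.pd_depth_um) <= spec.pd_depth_jitter_um
    assert abs(centers["HD"] - spec.hd_depth_um) <= spec.hd_depth_jitter_um
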