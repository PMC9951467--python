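"""Depth histogram, peak finding, slab segmentation and layer projections."""

import numpy as np
import pytest

from pamvasc.layers import (DepthHistogram, SegmentationError, b_scan_map,
                            depth_histogram, find_layer_peaks, layer_map,
                            segment_layers)
from pamvasc.surface import FlattenedVolume
from pamvasc.volume_io import LAYERS


def _flat(amp):
    return FlattenedVolume(amplitude=np.asarray(amp, dtype=np.float32),
                           spacing_um=(5.0, 10.0, 3.0))


def _hist(counts, dz=50.0, smooth=0.0):
    return DepthHistogram(counts=np.asarray(counts, dtype=float), dz_um=dz,
                          voxel_threshold=0.0, smooth_window_um=smooth)


# ---------------------------------------------------------------------------
# depth histogram
# ---------------------------------------------------------------------------

def test_histogram_counts_suprathreshold_voxels(rng):
    amp = np.zeros((6, 7, 20), dtype=np.float32)
    amp[:, :, 10:15] = 1.0                      # a slab spanning depths 10..14
    h = depth_histogram(_flat(amp), voxel_threshold=0.5)
    assert np.all(h.counts[10:15] == 42)
    assert np.all(h.counts[:10] == 0) and np.all(h.counts[15:] == 0)

    h0 = depth_histogram(_flat(np.zeros((3, 3, 8))), voxel_threshold=0.5)
    assert np.all(h0.counts == 0)


def test_histogram_scale_invariance(rng):
    amp = rng.random((5, 5, 16)).astype(np.float32)
    a = depth_histogram(_flat(amp), voxel_threshold=0.4)
    b = depth_histogram(_flat(2 * amp), voxel_threshold=0.8)
    assert np.array_equal(a.counts, b.counts)


# ---------------------------------------------------------------------------
# peak finding
# ---------------------------------------------------------------------------

def test_two_local_maxima_found():
    d_pd, d_hd = find_layer_peaks(_hist([0, 1, 5, 2, 1, 4, 1]), min_separation_um=100)
    assert (d_pd, d_hd) == (2, 5)


def test_unimodal_histogram_reports_peak_count():
    with pytest.raises(SegmentationError, match="1"):
        find_layer_peaks(_hist([0, 1, 5, 1, 0, 0, 0]))


def test_all_zero_histogram_is_an_error():
    with pytest.raises(SegmentationError):
        find_layer_peaks(_hist([0, 0, 0, 0]))


def test_min_separation_excludes_adjacent_peaks():
    # two close peaks and a remote one: the pair must respect the separation
    counts = [0, 10, 0, 9, 0, 0, 0, 0, 0, 0, 0, 8, 0]
    d1, d2 = find_layer_peaks(_hist(counts, dz=50.0), min_separation_um=200.0)
    assert (d1, d2) == (1, 11)


# ---------------------------------------------------------------------------
# slab segmentation
# ---------------------------------------------------------------------------

def test_peaks_rule_slabs():
    b = segment_layers((20, 166), nz=300, rule="peaks", dz_um=3.0)
    assert b.slab("PD") == (0, 21)
    assert b.slab("RD") == (21, 166)
    assert b.slab("HD") == (166, 300)
    assert b.slab("WHOLE") == (0, 300)


def test_adjacent_peaks_give_empty_rd_error():
    with pytest.raises(SegmentationError, match="RD"):
        segment_layers((10, 11), nz=20, rule="peaks")


def test_valleys_rule_places_boundaries_in_the_gaps():
    counts = np.zeros(100)
    counts[8:13] = [5, 20, 40, 20, 5]           # shallow plexus around 10
    counts[70:77] = [4, 10, 30, 35, 30, 10, 4]  # deep plexus around 73
    h = _hist(counts, dz=10.0)
    b = segment_layers((10, 73), nz=100, rule="valleys", hist=h)
    assert 13 <= b.z_pd_rd <= 45
    assert 45 <= b.z_rd_hd <= 70
    assert b.rule == "valleys"


def test_slabs_tile_the_depth_range():
    counts = np.zeros(60)
    counts[5] = 10
    counts[40] = 12
    b = segment_layers((5, 40), nz=60, rule="valleys", hist=_hist(counts, dz=10.0))
    covered = []
    for layer in LAYERS:
        lo, hi = b.slab(layer)
        covered.extend(range(lo, hi))
    assert covered == list(range(60))


# ---------------------------------------------------------------------------
# layer projections
# ---------------------------------------------------------------------------

def test_layer_maps_conserve_the_whole_map(rng):
    flat = _flat(rng.random((8, 9, 50)))
    b = segment_layers((10, 40), nz=50, rule="peaks", dz_um=3.0)
    maps = {layer: layer_map(flat, b, layer) for layer in ("PD", "RD", "HD", "WHOLE")}
    stacked = np.maximum.reduce([maps[l].values for l in LAYERS])
    assert np.array_equal(stacked, maps["WHOLE"].values)
    for layer in LAYERS:
        assert np.all(maps["WHOLE"].values >= maps[layer].values)


def test_bright_voxel_appears_only_in_its_slab():
    amp = np.zeros((4, 4, 50), dtype=np.float32)
    amp[2, 3, 25] = 7.0                          # inside the RD slab
    flat = _flat(amp)
    b = segment_layers((10, 40), nz=50, rule="peaks", dz_um=3.0)
    assert layer_map(flat, b, "RD").values[2, 3] == 7.0
    assert layer_map(flat, b, "PD").values[2, 3] == 0.0
    assert layer_map(flat, b, "HD").values[2, 3] == 0.0
    with pytest.raises(ValueError):
        layer_map(flat, b, "EPIDERMIS")


def test_b_scan_projection():
    amp = np.zeros((5, 6, 7), dtype=np.float32)
    amp[2, 4, 3] = 2.0
    proj = b_scan_map(_flat(amp))
    assert proj.shape == (5, 7)
    assert proj[2, 3] == 2.0 and proj.sum() == 2.0
    assert b_scan_map(_flat(np.zeros((3, 3, 3)))).sum() == 0


# ---------------------------------------------------------------------------
# phantom smoke check: peaks land at the plexus depths
# ---------------------------------------------------------------------------

def test_phantom_peaks_recovered_from_rendered_volume(small_scene):
    from pamvasc.phantom import realized_band_centers
    from pamvasc.surface import detect_surface, flatten

    spec = small_scene["spec"]
    surf = detect_surface(small_scene["volume"])
    flat = flatten(small_scene["volume"], surf)
    hist = depth_histogram(flat)
    d_pd, d_hd = find_layer_peaks(hist)
    centers = realized_band_centers(small_scene["vessels"])
    tol = 2 * spec.psf_axial_um
    assert abs(d_pd * spec.spacing_um[2] - centers["PD"]) <= tol
    assert abs(d_hd * spec.spacing_um[2] - centers["HD"]) <= tol
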