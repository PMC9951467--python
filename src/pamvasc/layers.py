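"""Depth-histogram layer segmentation and layer-wise projections.

After flattening, the number of suprathreshold voxels per depth index forms
a histogram with two prominent local maxima: the superficial capillary
plexus of the papillary dermis (PD) and the large-vessel plexus of the
hypodermis (HD).  Those two peaks anchor the segmentation of the volume into
PD / reticular dermis (RD) / HD slabs, from which layer-wise maximum
amplitude projections (MAPs) are produced.

Two boundary rules are provided.  ``"peaks"`` uses the peak depths
themselves as slab boundaries (PD runs from the surface through the shallow
peak, HD from the deep peak downward).  ``"valleys"`` — the default — places
each boundary at the count minimum between a peak and the inter-peak
midpoint, which isolates each plexus in its own slab; with peaks-as-
boundaries half of each plexus' voxel mass falls into the RD slab and
contaminates the mid-dermis density measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .quantify import otsu_threshold
from .surface import FlattenedVolume
from .volume_io import LAYER_TAGS, MAPImage


class SegmentationError(RuntimeError):
    """Raised when the depth histogram does not support a PD/RD/HD split."""


@dataclass
class DepthHistogram:
    """Suprathreshold voxel count per depth index of a flattened volume."""

    counts: np.ndarray
    dz_um: float
    voxel_threshold: float
    smooth_window_um: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or np.any(self.counts < 0):
            raise ValueError("counts must be a 1-D non-negative array")

    def smoothed(self, smooth_window_um: float | None = None) -> np.ndarray:
        """Moving-average counts over a window given in micrometres."""
        w_um = self.smooth_window_um if smooth_window_um is None else smooth_window_um
        n = max(int(round(w_um / self.dz_um)), 1)
        if n <= 1:
            return self.counts.astype(float)
        kernel = np.full(n, 1.0 / n)
        return np.convolve(self.counts.astype(float), kernel, mode="same")


@dataclass
class LayerBoundaries:
    """Peak depths and slab limits for the PD/RD/HD partition.

    Slabs are half-open index ranges that tile ``[0, nz)`` exactly:
    PD = [0, z_pd_rd], RD = (z_pd_rd, z_rd_hd), HD = [z_rd_hd, nz).
    """

    d_pd: int
    d_hd: int
    z_pd_rd: int
    z_rd_hd: int
    nz: int
    rule: str
    dz_um: float = 1.0

    def slab(self, layer: str) -> tuple[int, int]:
        if layer == "PD":
            return (0, self.z_pd_rd + 1)
        if layer == "RD":
            return (self.z_pd_rd + 1, self.z_rd_hd)
        if layer == "HD":
            return (self.z_rd_hd, self.nz)
        if layer == "WHOLE":
            return (0, self.nz)
        raise ValueError(f"unknown layer tag {layer!r}")

    @property
    def peak_depths_um(self) -> tuple[float, float]:
        return (self.d_pd * self.dz_um, self.d_hd * self.dz_um)


def depth_histogram(flat: FlattenedVolume, voxel_threshold: float | None = None,
                    smooth_window_um: float = 30.0) -> DepthHistogram:
    """Count voxels above threshold per depth index.

    ``voxel_threshold`` defaults to Otsu's threshold over all voxel
    amplitudes of the flattened volume, making the histogram invariant to
    global amplitude rescaling.
    """
    if voxel_threshold is None:
        voxel_threshold = otsu_threshold(flat.amplitude)
    elif voxel_threshold < 0:
        raise ValueError("voxel_threshold must be >= 0")
    counts = np.count_nonzero(flat.amplitude > voxel_threshold, axis=(0, 1))
    return DepthHistogram(counts=counts, dz_um=flat.dz_um,
                          voxel_threshold=float(voxel_threshold),
                          smooth_window_um=smooth_window_um)


def find_layer_peaks(hist: DepthHistogram, smooth_window_um: float | None = None,
                     min_separation_um: float = 100.0) -> tuple[int, int]:
    """Locate the PD and HD peaks as the two most prominent local maxima of
    the smoothed counts whose depth separation is at least
    ``min_separation_um``; returned shallow-first.

    Raises :class:`SegmentationError` naming the number of candidates found
    when fewer than two compatible peaks exist.
    """
    sm = hist.smoothed(smooth_window_um)
    if not np.any(sm > 0):
        raise SegmentationError("depth histogram is identically zero")
    idx, props = signal.find_peaks(sm, prominence=0.0)
    if idx.size < 2:
        raise SegmentationError(
            f"found {idx.size} depth-histogram peak(s); need 2 to segment layers")
    prom = props["prominences"]
    min_sep = min_separation_um / hist.dz_um
    # best pair by total prominence subject to the separation constraint
    best: tuple[float, int, int] | None = None
    for ai in range(len(idx)):
        for bi in range(ai + 1, len(idx)):
            if abs(int(idx[ai]) - int(idx[bi])) >= min_sep:
                score = float(prom[ai] + prom[bi])
                if best is None or score > best[0]:
                    best = (score, int(min(idx[ai], idx[bi])), int(max(idx[ai], idx[bi])))
    if best is None:
        raise SegmentationError(
            f"found {idx.size} peak(s) but no two are separated by >= {min_separation_um} um")
    return int(best[1]), int(best[2])


def segment_layers(peaks: tuple[int, int], nz: int, rule: str = "valleys",
                   hist: DepthHistogram | None = None,
                   dz_um: float | None = None) -> LayerBoundaries:
    """Derive slab boundaries from the two histogram peaks.

    ``rule="peaks"``: boundaries at the peak depths themselves.
    ``rule="valleys"``: boundaries at the least-count depth between each peak
    and the inter-peak midpoint (requires ``hist``).
    """
    d_pd, d_hd = int(peaks[0]), int(peaks[1])
    if not 0 < d_pd < d_hd < nz:
        raise SegmentationError(f"invalid peak pair {peaks} for nz={nz}")
    if rule == "peaks":
        z_pd_rd, z_rd_hd = d_pd, d_hd
    elif rule == "valleys":
        if hist is None:
            raise ValueError("the valleys rule requires the depth histogram")
        sm = hist.smoothed()
        mid = (d_pd + d_hd) // 2

        low_peak = min(sm[d_pd], sm[d_hd])

        def _valley(lo: int, hi: int) -> int:
            seg = sm[lo:hi + 1]
            # center of the near-minimal plateau; a tolerance proportional to
            # the valley-to-peak range keeps the boundary stable when the
            # valley floor is flat and only count noise picks the argmin
            tol = seg.min() + 0.05 * max(low_peak - seg.min(), 1.0)
            plateau = np.flatnonzero(seg <= tol)
            return lo + int(round(plateau.mean()))

        z_pd_rd = _valley(d_pd, mid)
        z_rd_hd = _valley(mid, d_hd)
    else:
        raise ValueError(f"unknown boundary rule {rule!r}")
    if z_rd_hd - z_pd_rd < 2:
        raise SegmentationError(
            f"empty RD slab with rule {rule!r} (boundaries {z_pd_rd}, {z_rd_hd}); "
            "try the alternative boundary rule")
    return LayerBoundaries(d_pd=d_pd, d_hd=d_hd, z_pd_rd=z_pd_rd, z_rd_hd=z_rd_hd,
                           nz=nz, rule=rule,
                           dz_um=dz_um if dz_um is not None else (hist.dz_um if hist else 1.0))


def layer_map(flat: FlattenedVolume, bounds: LayerBoundaries, layer: str) -> MAPImage:
    """Maximum-amplitude projection over one layer's depth slab."""
    if layer not in LAYER_TAGS:
        raise ValueError(f"unknown layer tag {layer!r}")
    lo, hi = bounds.slab(layer)
    values = flat.amplitude[:, :, lo:hi].max(axis=2)
    return MAPImage(values=values, layer_tag=layer, t_min=flat.t_min,
                    subject_id=flat.subject_id, group=flat.group)


def b_scan_map(amplitude_source) -> np.ndarray:
    """Maximum projection along Y — the cross-sectional "A view" used to
    visualize vascular stratification with depth."""
    amp = getattr(amplitude_source, "amplitude", amplitude_source)
    return np.asarray(amp).max(axis=1)
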