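"""Vascular-density and centroid quantification.

The density statistic follows the averaged-Otsu scheme: each of a subject's
per-timepoint MAP images receives its own Otsu global threshold, the seven
thresholds are averaged (the images come from the same location, so a single
threshold is applied to the whole series), and the vascular density of an
image is the number of pixels strictly greater than that averaged threshold.
Densities are normalized by the t=0 value to give relative density, and the
constriction percentage is ``100 * (1 - relative density at the final
timepoint)``.

Because thresholds are derived from each image's own histogram, every
statistic here is invariant to global amplitude rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .surface import FlattenedVolume
from .volume_io import MAPImage


class DegenerateImageError(ValueError):
    """Raised when an image has no contrast to threshold."""


def otsu_threshold(values: np.ndarray | MAPImage, n_bins: int = 256) -> float:
    """Otsu's global threshold: the histogram bin edge maximizing the
    between-class variance over an ``n_bins`` histogram spanning the data
    range; ties break toward the lower threshold.

    The two classes of a candidate edge ``e`` are ``{v < e}`` and
    ``{v >= e}``.  A constant image raises :class:`DegenerateImageError`.
    """
    data = np.asarray(values.values if isinstance(values, MAPImage) else values)
    data = data.ravel().astype(np.float64)
    vmin, vmax = float(data.min()), float(data.max())
    if vmin == vmax:
        raise DegenerateImageError("cannot threshold a constant image")
    counts, edges = np.histogram(data, bins=n_bins, range=(vmin, vmax))
    counts = counts.astype(np.float64)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1]                      # class {v < edges[k]}, k = 1..n-1
    w1 = total - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = m0[-1] + counts[-1] * centers[-1] - m0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.zeros(n_bins - 1)
    var_between[valid] = w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    k = int(np.argmax(var_between))                  # first occurrence = lower edge on ties
    return float(edges[k + 1])


def series_threshold(maps: Sequence[MAPImage], n_bins: int = 256) -> float:
    """Arithmetic mean of the per-timepoint Otsu thresholds of one series.

    All maps must share a lateral shape and layer tag; a degenerate map is
    reported with its series index.
    """
    if len(maps) < 2:
        raise ValueError("a series threshold needs at least two maps")
    shape = maps[0].values.shape
    tag = maps[0].layer_tag
    thresholds = []
    for i, m in enumerate(maps):
        if m.values.shape != shape:
            raise ValueError(f"map {i} shape {m.values.shape} != {shape}")
        if m.layer_tag != tag:
            raise ValueError(f"map {i} layer {m.layer_tag!r} != {tag!r}")
        try:
            thresholds.append(otsu_threshold(m.values, n_bins=n_bins))
        except DegenerateImageError as exc:
            raise DegenerateImageError(f"map {i} (t={m.t_min} min) is degenerate") from exc
    return float(np.mean(thresholds))


def vascular_density(map_image: MAPImage | np.ndarray, threshold: float) -> int:
    """Number of MAP pixels strictly greater than the threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    values = map_image.values if isinstance(map_image, MAPImage) else np.asarray(map_image)
    return int(np.count_nonzero(values > threshold))


@dataclass
class DensityTrace:
    """Per-subject, per-layer vascular density over the monitoring series."""

    subject_id: str
    group: str
    layer_tag: str
    t_min: list[float]
    density: list[int]
    threshold_used: float
    relative: list[float] = field(init=False)
    constriction_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.t_min) != len(self.density):
            raise ValueError("t_min and density length mismatch")
        if any(d < 0 for d in self.density):
            raise ValueError("densities must be non-negative")
        if self.density[0] <= 0:
            raise ValueError(
                f"undefined baseline: t=0 density is {self.density[0]} for "
                f"{self.subject_id}/{self.layer_tag}")
        base = float(self.density[0])
        self.relative = [d / base for d in self.density]
        self.relative[0] = 1.0
        self.constriction_pct = 100.0 * (1.0 - self.relative[-1])


def relative_trace(subject_id: str, group: str, layer_tag: str,
                   t_min: Sequence[float], densities: Sequence[int],
                   threshold_used: float) -> DensityTrace:
    """Bundle densities into a :class:`DensityTrace` (relative density and
    constriction percentage are derived on construction)."""
    return DensityTrace(subject_id=subject_id, group=group, layer_tag=layer_tag,
                        t_min=list(t_min), density=[int(d) for d in densities],
                        threshold_used=float(threshold_used))


def centroid_depth(flat: FlattenedVolume, threshold: float,
                   weighting: str = "binary") -> float:
    """Mean depth (um below surface) of the suprathreshold voxel set.

    ``weighting="binary"`` (default) averages depths of voxels above the
    threshold; ``"amplitude"`` weights each voxel by its amplitude.
    """
    amp = flat.amplitude
    mask = amp > threshold
    if not mask.any():
        raise ValueError("no suprathreshold voxels; centroid undefined")
    depths = np.arange(amp.shape[2]) * flat.dz_um
    per_depth = mask.sum(axis=(0, 1)).astype(np.float64)
    if weighting == "binary":
        weights = per_depth
    elif weighting == "amplitude":
        weights = np.where(mask, amp, 0).sum(axis=(0, 1)).astype(np.float64)
    else:
        raise ValueError(f"unknown centroid weighting {weighting!r}")
    return float((weights * depths).sum() / weights.sum())


@dataclass
class CentroidTrace:
    """Depth of the vascular-network centroid over the monitoring series."""

    subject_id: str
    group: str
    layer_tag: str
    t_min: list[float]
    centroid_um: list[float]
    displacement_um: list[float] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.t_min) != len(self.centroid_um):
            raise ValueError("t_min and centroid length mismatch")
        base = self.centroid_um[0]
        self.displacement_um = [c - base for c in self.centroid_um]
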