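"""Containers and file I/O for OR-PAM amplitude volumes and projections.

A :class:`PAVolume` is a 3-D non-negative amplitude grid indexed ``(x, y, z)``
with ``z`` increasing downward into the tissue (``z = 0`` is the shallowest
slice).  Volumes round-trip through multi-page TIFF (one page per depth slice,
16-bit with a recorded scale factor) or HDF5 (float, lossless).  All
quantification operates on the raw arrays; display exports (PNG) carry their
scaling in a JSON sidecar so they are never fed back into measurement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

LAYERS = ("PD", "RD", "HD")
LAYER_TAGS = LAYERS + ("WHOLE",)


class VolumeFormatError(ValueError):
    """Raised when a volume file is unreadable or missing required metadata."""


@dataclass
class PAVolume:
    """One photoacoustic amplitude stack with its acquisition metadata.

    Parameters
    ----------
    amplitude : ndarray, shape (nx, ny, nz)
        Non-negative PA amplitudes; z increases into the tissue.
    spacing_um : tuple of float
        Voxel pitch ``(dx, dy, dz)`` in micrometres.
    t_min : float
        Acquisition time in minutes relative to the start of monitoring.
    """

    amplitude: np.ndarray
    spacing_um: tuple[float, float, float]
    t_min: float = 0.0
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude)
        if self.amplitude.ndim != 3 or self.amplitude.size == 0:
            raise ValueError("amplitude must be a non-empty 3-D array")
        if np.any(self.amplitude < 0):
            raise ValueError("PA amplitudes must be non-negative")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.amplitude.shape

    @property
    def dz_um(self) -> float:
        return self.spacing_um[2]

    def with_amplitude(self, amplitude: np.ndarray) -> "PAVolume":
        return replace(self, amplitude=amplitude)


@dataclass
class MAPImage:
    """Maximum-amplitude projection over a depth slab, in the (x, y) plane."""

    values: np.ndarray
    layer_tag: str = "WHOLE"
    t_min: float = 0.0
    subject_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("MAP image must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("MAP values must be non-negative")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer tag {self.layer_tag!r}")


def write_volume(volume: PAVolume, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF (``.tif``) or HDF5 (``.h5``/``.hdf5``).

    TIFF pages are depth slices (page index = z) stored as uint16 with the
    float scale factor recorded in the image description; HDF5 stores the raw
    float array in dataset ``"amplitude"`` with metadata as attributes.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    meta = {
        "spacing_um": list(volume.spacing_um),
        "t_min": volume.t_min,
        "subject_id": volume.subject_id,
        "group": volume.group,
    }
    if suffix in (".tif", ".tiff"):
        amax = float(volume.amplitude.max())
        scale = amax / 65535.0 if amax > 0 else 1.0
        pages = np.transpose(volume.amplitude, (2, 0, 1))  # page index = z
        data = np.round(pages / scale).astype(np.uint16)
        meta["amplitude_scale"] = scale
        tifffile.imwrite(path, data, description=json.dumps(meta))
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("amplitude", data=volume.amplitude)
            for k, v in meta.items():
                ds.attrs[k] = v
    else:
        raise VolumeFormatError(f"unsupported volume format {suffix!r}")
    return path


def read_volume(path: str | Path) -> PAVolume:
    """Read a volume written by :func:`write_volume`.

    Missing spacing metadata raises :class:`VolumeFormatError` naming the key;
    a silent default would corrupt every depth-calibrated statistic downstream.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            desc = tf.pages[0].description
        try:
            meta = json.loads(desc) if desc else {}
        except json.JSONDecodeError as exc:
            raise VolumeFormatError(f"unparseable TIFF metadata in {path}") from exc
        if "spacing_um" not in meta:
            raise VolumeFormatError(f"{path}: missing required metadata key 'spacing_um'")
        if pages.ndim == 2:
            pages = pages[None]
        amplitude = np.transpose(pages, (1, 2, 0)).astype(np.float32)
        amplitude *= np.float32(meta.get("amplitude_scale", 1.0))
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "amplitude" not in f:
                raise VolumeFormatError(f"{path}: missing dataset 'amplitude'")
            ds = f["amplitude"]
            if "spacing_um" not in ds.attrs:
                raise VolumeFormatError(f"{path}: missing required metadata key 'spacing_um'")
            amplitude = ds[()]
            meta = {k: ds.attrs[k] for k in ("spacing_um", "t_min", "subject_id", "group") if k in ds.attrs}
    else:
        raise VolumeFormatError(f"unsupported volume format {suffix!r}")
    return PAVolume(
        amplitude=amplitude,
        spacing_um=tuple(np.asarray(meta["spacing_um"], dtype=float)),
        t_min=float(meta.get("t_min", 0.0)),
        subject_id=str(meta.get("subject_id", "")),
        group=str(meta.get("group", "")),
    )


def read_volume_meta(path: str | Path) -> dict:
    """Read only the metadata of a volume file (no amplitude data)."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            desc = tf.pages[0].description
        try:
            meta = json.loads(desc) if desc else {}
        except json.JSONDecodeError as exc:
            raise VolumeFormatError(f"unparseable TIFF metadata in {path}") from exc
    elif suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "amplitude" not in f:
                raise VolumeFormatError(f"{path}: missing dataset 'amplitude'")
            meta = {k: f["amplitude"].attrs[k] for k in f["amplitude"].attrs}
    else:
        raise VolumeFormatError(f"unsupported volume format {suffix!r}")
    if "spacing_um" not in meta:
        raise VolumeFormatError(f"{path}: missing required metadata key 'spacing_um'")
    return {
        "spacing_um": tuple(np.asarray(meta["spacing_um"], dtype=float)),
        "t_min": float(meta.get("t_min", 0.0)),
        "subject_id": str(meta.get("subject_id", "")),
        "group": str(meta.get("group", "")),
    }


def write_map_png(map_image: MAPImage, path: str | Path) -> Path:
    """Export a MAP as 16-bit grayscale PNG plus a JSON scaling sidecar.

    The sidecar records the min/max used for scaling so the original range is
    recoverable; quantification never reads the PNG.
    """
    path = Path(path)
    values = map_image.values.astype(np.float64)
    vmin, vmax = float(values.min()), float(values.max())
    span = vmax - vmin
    if span == 0:
        scaled = np.zeros_like(values, dtype=np.uint16)
    else:
        scaled = np.round((values - vmin) / span * 65535.0).astype(np.uint16)
    iio.imwrite(path, scaled, extension=".png")
    sidecar = {
        "vmin": vmin,
        "vmax": vmax,
        "layer_tag": map_image.layer_tag,
        "t_min": map_image.t_min,
        "subject_id": map_image.subject_id,
        "group": map_image.group,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_map_png(path: str | Path) -> MAPImage:
    """Recover a MAP image (original float range) from a PNG + sidecar pair."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    raw = np.asarray(iio.imread(path), dtype=np.float64)
    span = sidecar["vmax"] - sidecar["vmin"]
    values = raw / 65535.0 * span + sidecar["vmin"] if span > 0 else np.full(raw.shape, sidecar["vmin"])
    return MAPImage(
        values=values,
        layer_tag=sidecar["layer_tag"],
        t_min=sidecar["t_min"],
        subject_id=sidecar["subject_id"],
        group=sidecar["group"],
    )


def export_map_series(maps: list[MAPImage], out_dir: str | Path, stem: str) -> list[Path]:
    """Write one PNG per timepoint, with ``t_min`` encoded in the filename."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in maps:
        p = out_dir / f"{stem}_{m.layer_tag}_t{int(round(m.t_min)):03d}min.png"
        write_map_png(m, p)
        paths.append(p)
    return paths
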