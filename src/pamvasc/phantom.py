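"""Synthetic skin-vasculature phantom for OR-PAM pipeline validation.

The phantom emulates the features of a depth-resolved photoacoustic skin
volume that the analysis pipeline depends on:

* a smooth, undulating skin surface (heartbeat/respiration leave real
  surfaces non-flat, so flattening must be exercised);
* a dense superficial capillary plexus in the papillary dermis (PD), sparse
  near-vertical connector vessels in the reticular dermis (RD), and long
  paired large-calibre tubes (arteriole/venule pairs) in the hypodermis (HD);
* anisotropic Gaussian point-spread blur (lateral/axial resolution of the
  imaging system) and additive, non-negative-clipped Gaussian noise;
* per-layer, time-dependent vasoconstriction with a saturating-exponential
  radius schedule.

Every generated scene carries its own :class:`GroundTruth`: the exact vessel
geometry per timepoint and an analytic projected-area oracle, so downstream
density estimates can be validated against geometry rather than against the
pipeline itself.

Vessel radii are "apparent" OR-PAM calibres: no tube is thinner than the
axial resolution, because sub-resolution vessels render PSF-limited and their
binarized width would not track the radius that constriction scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, Point, box
from shapely.ops import unary_union

from .surface import SurfaceMap, axial_shift
from .volume_io import LAYERS, PAVolume

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


class InvalidSpecError(ValueError):
    """Raised when a phantom specification is internally inconsistent."""


@dataclass(frozen=True)
class ConstrictionSchedule:
    """Time course of fractional radius reduction for one skin layer.

    The radius at time ``t`` (minutes) is ``r0 * factor(t)`` with

    ``factor(t) = 1 - c_max * (1 - exp(-t / tau_min))``    (exponential form)

    which is monotonically non-increasing and saturates at ``1 - c_max``.
    A linear ramp (reaching ``1 - c_max`` at ``t = tau_min`` and constant
    after) is available via ``form="linear"``.
    """

    layer_tag: str
    c_max: float
    tau_min: float
    form: str = "exponential"
    mode: str = "radius"

    def __post_init__(self) -> None:
        if self.layer_tag not in LAYERS:
            raise InvalidSpecError(f"unknown layer tag {self.layer_tag!r}")
        if not 0.0 <= self.c_max < 1.0:
            raise InvalidSpecError("c_max must be in [0, 1)")
        if self.tau_min <= 0:
            raise InvalidSpecError("tau_min must be positive")
        if self.form not in ("exponential", "linear"):
            raise InvalidSpecError(f"unknown schedule form {self.form!r}")
        if self.mode not in ("radius", "dropout"):
            raise InvalidSpecError(f"unknown schedule mode {self.mode!r}")

    def factor(self, t_min: float) -> float:
        if t_min < 0:
            raise ValueError("time must be non-negative")
        if self.form == "exponential":
            return 1.0 - self.c_max * (1.0 - math.exp(-t_min / self.tau_min))
        return 1.0 - self.c_max * min(t_min / self.tau_min, 1.0)


@dataclass
class VesselPrimitive:
    """A tube: polyline centerline (um, flattened frame: z = depth below skin)."""

    centerline: np.ndarray  # (n, 3) points in um
    radius_um: float
    layer_tag: str
    intensity: float = 1.0
    dropout_rank: float = 1.0  # persistent U(0,1) draw used by dropout schedules

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
            raise InvalidSpecError("centerline needs >= 2 three-dimensional points")
        if self.radius_um <= 0:
            raise InvalidSpecError("radius_um must be positive")
        if self.layer_tag not in LAYERS:
            raise InvalidSpecError(f"unknown layer tag {self.layer_tag!r}")
        if self.intensity <= 0:
            raise InvalidSpecError("intensity must be positive")

    def scaled(self, factor: float) -> "VesselPrimitive":
        return replace(self, radius_um=self.radius_um * factor)


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of the synthetic scene.

    Depths are micrometres below the (local) skin surface; the surface itself
    sits ``surface_mean_depth_um`` +/- ``surface_amplitude_um`` below the top
    of the grid.  PSF widths are FWHM resolution figures (converted to
    Gaussian sigmas internally).
    """

    shape: tuple[int, int, int] = (200, 200, 300)
    spacing_um: tuple[float, float, float] = (5.0, 10.0, 3.0)
    surface_mean_depth_um: float = 60.0
    surface_amplitude_um: float = 30.0
    surface_corr_length_um: float = 400.0
    pd_depth_um: float = 60.0
    pd_depth_jitter_um: float = 8.0
    hd_depth_um: float = 500.0
    hd_depth_jitter_um: float = 15.0
    n_pd: int = 70
    n_rd: int = 20
    n_hd: int = 4
    pd_radius_um: tuple[float, float] = (10.0, 16.0)
    rd_radius_um: tuple[float, float] = (9.0, 15.0)
    hd_radius_um: tuple[float, float] = (35.0, 55.0)
    intensity_range: tuple[float, float] = (0.7, 1.0)
    psf_lateral_um: float = 5.0
    psf_axial_um: float = 30.0
    noise_sd: float = 0.02
    bscan_jitter_um: float = 0.0
    timepoints_min: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- geometry helpers ---------------------------------------------------
    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.shape, self.spacing_um))

    @property
    def psf_sigma_um(self) -> tuple[float, float, float]:
        s_lat = self.psf_lateral_um * FWHM_TO_SIGMA
        return (s_lat, s_lat, self.psf_axial_um * FWHM_TO_SIGMA)

    def validate(self) -> None:
        if any(n <= 0 for n in self.shape) or any(d <= 0 for d in self.spacing_um):
            raise InvalidSpecError("grid shape and spacing must be positive")
        if self.surface_amplitude_um < 0:
            raise InvalidSpecError("surface amplitude must be >= 0")
        if self.surface_mean_depth_um - self.surface_amplitude_um < 0:
            raise InvalidSpecError("surface undulation leaves the top of the grid")
        if not self.pd_depth_um < self.hd_depth_um:
            raise InvalidSpecError("PD band center must be shallower than HD band center")
        depth_needed = (
            self.surface_mean_depth_um
            + self.surface_amplitude_um
            + self.hd_depth_um
            + self.hd_depth_jitter_um
            + max(self.hd_radius_um)
            + 3.0 * self.psf_sigma_um[2]
        )
        if depth_needed > self.extent_um[2]:
            raise InvalidSpecError(
                f"depth bands do not fit: need {depth_needed:.0f} um below grid top, "
                f"grid depth is {self.extent_um[2]:.0f} um"
            )
        if any(n < 0 for n in (self.n_pd, self.n_rd, self.n_hd)):
            raise InvalidSpecError("vessel counts must be >= 0")
        t = np.asarray(self.timepoints_min, dtype=float)
        if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise InvalidSpecError("timepoints must start at 0 and strictly increase")

    @classmethod
    def default(cls, seed: int = 0) -> "PhantomSpec":
        """Desk-scale default grid (1.0 x 2.0 x 0.9 mm at 5/10/3 um pitch)."""
        return cls(seed=seed)

    @classmethod
    def small(cls, seed: int = 0) -> "PhantomSpec":
        """Reduced field of view (0.48 x 0.96 x 0.72 mm) for multi-seed sweeps;
        same spacing, depth structure and vessel calibres, counts scaled to
        the smaller lateral area."""
        return cls(shape=(96, 96, 240), n_pd=25, n_rd=12, n_hd=2, seed=seed)

    @classmethod
    def full_size(cls, seed: int = 0) -> "PhantomSpec":
        """The acquisition-scale grid (4 x 6 x 3 mm): 800 x 600 x 1000 voxels."""
        return cls(shape=(800, 600, 1000), n_pd=600, n_rd=160, n_hd=10, seed=seed)


# dataclass(frozen=True) + __post_init__ validation needs object.__setattr__-free
# fields, so keep validate() side-effect free (it only raises).


def _rngs(spec: PhantomSpec) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(spec.seed)
    surf, vess = root.spawn(2)
    return {"surface": np.random.default_rng(surf), "vessels": np.random.default_rng(vess)}


def generate_surface(spec: PhantomSpec) -> SurfaceMap:
    """Smooth random skin-depth field with the specified mean, amplitude and
    lateral correlation length.  Deterministic given ``spec.seed``."""
    nx, ny, _ = spec.shape
    dx, dy, dz = spec.spacing_um
    rng = _rngs(spec)["surface"]
    if spec.surface_amplitude_um == 0:
        depth = np.full((nx, ny), spec.surface_mean_depth_um)
    else:
        noise = rng.standard_normal((nx, ny))
        # Gaussian filter sigma = L/2 gives autocorrelation exp(-d^2 / L^2):
        # e-folding distance equals the requested correlation length.
        sig = (spec.surface_corr_length_um / 2.0 / dx, spec.surface_corr_length_um / 2.0 / dy)
        fieldv = ndimage.gaussian_filter(noise, sigma=sig, mode="wrap")
        fieldv -= fieldv.mean()
        peak = np.abs(fieldv).max()
        if peak > 0:
            fieldv *= spec.surface_amplitude_um / peak
        depth = spec.surface_mean_depth_um + fieldv
    return SurfaceMap(z_surface=depth / dz, dz_um=dz)


def _clip_lateral(points: np.ndarray, spec: PhantomSpec, margin: float = 2.0) -> np.ndarray:
    ex, ey, _ = spec.extent_um
    points[:, 0] = np.clip(points[:, 0], margin, ex - margin)
    points[:, 1] = np.clip(points[:, 1], margin, ey - margin)
    return points


def place_vessels(spec: PhantomSpec) -> list[VesselPrimitive]:
    """Lay out the three-layer vascular scene.  Deterministic given the seed."""
    rng = _rngs(spec)["vessels"]
    ex, ey, _ = spec.extent_um
    vessels: list[VesselPrimitive] = []

    # papillary plexus: wandering horizontal capillaries in a thin band
    for _ in range(spec.n_pd):
        n_pts = 9
        length = rng.uniform(0.8, 1.6) * min(ex, ey)
        theta = rng.uniform(0, 2 * np.pi)
        step = length / (n_pts - 1)
        pts = np.empty((n_pts, 3))
        pts[0, 0] = rng.uniform(0, ex)
        pts[0, 1] = rng.uniform(0, ey)
        z0 = spec.pd_depth_um + rng.uniform(-1, 1) * spec.pd_depth_jitter_um
        pts[0, 2] = z0
        for i in range(1, n_pts):
            theta += rng.normal(0, 0.3)
            pts[i, 0] = pts[i - 1, 0] + step * np.cos(theta)
            pts[i, 1] = pts[i - 1, 1] + step * np.sin(theta)
            pts[i, 2] = np.clip(z0 + rng.normal(0, 2.0),
                                spec.pd_depth_um - spec.pd_depth_jitter_um,
                                spec.pd_depth_um + spec.pd_depth_jitter_um)
        vessels.append(VesselPrimitive(
            centerline=_clip_lateral(pts, spec),
            radius_um=rng.uniform(*spec.pd_radius_um),
            layer_tag="PD",
            intensity=rng.uniform(*spec.intensity_range),
        ))

    # reticular connectors: near-vertical segments rising from the deep
    # plexus to join the superficial plexus (their tops sit at the PD band,
    # as ascending dermal vessels do)
    z_top = spec.pd_depth_um
    z_bot = spec.hd_depth_um - spec.hd_depth_jitter_um
    span = z_bot - z_top
    for _ in range(spec.n_rd):
        n_pts = 6
        theta = rng.uniform(0, 2 * np.pi)
        drift = rng.uniform(0.1, 0.3) * span  # lateral run << depth run
        pts = np.empty((n_pts, 3))
        pts[:, 2] = np.linspace(z_top, z_bot, n_pts)
        x0, y0 = rng.uniform(0, ex), rng.uniform(0, ey)
        frac = np.linspace(0, 1, n_pts)
        pts[:, 0] = x0 + frac * drift * np.cos(theta) + rng.normal(0, 6.0, n_pts)
        pts[:, 1] = y0 + frac * drift * np.sin(theta) + rng.normal(0, 6.0, n_pts)
        vessels.append(VesselPrimitive(
            centerline=_clip_lateral(pts, spec),
            radius_um=rng.uniform(*spec.rd_radius_um),
            layer_tag="RD",
            intensity=rng.uniform(*spec.intensity_range),
        ))

    # hypodermal arteriole-venule pairs: long sinuous tubes along y
    n_pts = 13
    k = 0
    while k < spec.n_hd:
        r1 = rng.uniform(*spec.hd_radius_um)
        xc = rng.uniform(0.2, 0.8) * ex
        zc = spec.hd_depth_um + rng.uniform(-1, 1) * spec.hd_depth_jitter_um
        wiggle_amp = rng.uniform(20.0, 60.0)
        wiggle_lambda = rng.uniform(0.8, 1.5) * ey
        phase = rng.uniform(0, 2 * np.pi)
        halfsep = 1.3 * r1
        in_pair = min(2, spec.n_hd - k)
        for side in range(in_pair):
            r = r1 if side == 0 else min(max(r1 * rng.uniform(1.0, 1.25), spec.hd_radius_um[0]),
                                         spec.hd_radius_um[1])
            offset = (-halfsep, halfsep)[side] if in_pair == 2 else 0.0
            y = np.linspace(0, ey, n_pts)
            x = xc + offset + wiggle_amp * np.sin(2 * np.pi * y / wiggle_lambda + phase)
            z = np.full(n_pts, zc) + rng.normal(0, 2.0, n_pts)
            pts = np.stack([x, y, z], axis=1)
            vessels.append(VesselPrimitive(
                centerline=_clip_lateral(pts, spec),
                radius_um=r,
                layer_tag="HD",
                intensity=rng.uniform(*spec.intensity_range),
            ))
            k += 1
    # Dropout order: shuffled evenly-spaced quantile ranks per layer, so a
    # dropout schedule removes exactly the scheduled fraction of each
    # layer's vessels (random order, deterministic count).
    for layer in LAYERS:
        members = [v for v in vessels if v.layer_tag == layer]
        if members:
            ranks = rng.permutation((np.arange(len(members)) + 0.5) / len(members))
            for v, u in zip(members, ranks):
                v.dropout_rank = float(u)
    return vessels


def apply_constriction(
    vessels: Sequence[VesselPrimitive],
    schedules: Mapping[str, ConstrictionSchedule],
    t_min: float,
) -> list[VesselPrimitive]:
    """Scale each vessel's radius by its layer's schedule factor at time ``t``.

    Layers without a schedule are unchanged; at ``t = 0`` all radii are
    identical to baseline.  Negative times are rejected.
    """
    if t_min < 0:
        raise ValueError("time must be non-negative")
    out = []
    for v in vessels:
        sched = schedules.get(v.layer_tag)
        if sched is None:
            out.append(v)
        elif sched.mode == "radius":
            out.append(v.scaled(sched.factor(t_min)))
        else:  # dropout: remove the vessels with the lowest persistent ranks
            if v.dropout_rank >= 1.0 - sched.factor(t_min):
                out.append(v)
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _rasterize_capsule(out: np.ndarray, spec: PhantomSpec,
                       p0: np.ndarray, p1: np.ndarray, radius: float, value: float) -> None:
    """Max-composite one capsule (distance-to-segment <= radius) into ``out``."""
    dx, dy, dz = spec.spacing_um
    spacing = np.array([dx, dy, dz])
    lo = np.minimum(p0, p1) - radius - spacing
    hi = np.maximum(p0, p1) + radius + spacing
    i0 = np.maximum(np.floor(lo / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / spacing).astype(int) + 1, np.array(out.shape))
    if np.any(i0 >= i1):
        return
    xs = (np.arange(i0[0], i1[0]) * dx)[:, None, None]
    ys = (np.arange(i0[1], i1[1]) * dy)[None, :, None]
    zs = (np.arange(i0[2], i1[2]) * dz)[None, None, :]
    u = p1 - p0
    L2 = float(u @ u)
    if L2 == 0:
        d2 = (xs - p0[0]) ** 2 + (ys - p0[1]) ** 2 + (zs - p0[2]) ** 2
    else:
        tt = ((xs - p0[0]) * u[0] + (ys - p0[1]) * u[1] + (zs - p0[2]) * u[2]) / L2
        np.clip(tt, 0.0, 1.0, out=tt)
        d2 = ((xs - (p0[0] + tt * u[0])) ** 2
              + (ys - (p0[1] + tt * u[1])) ** 2
              + (zs - (p0[2] + tt * u[2])) ** 2)
    sub = out[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    np.maximum(sub, np.where(d2 <= radius * radius, np.float32(value), np.float32(0.0)), out=sub)


def render_scene_flat(vessels: Sequence[VesselPrimitive], spec: PhantomSpec) -> np.ndarray:
    """Rasterize tubes in the flattened frame (z = depth below the surface)."""
    out = np.zeros(spec.shape, dtype=np.float32)
    for v in vessels:
        for a, b in zip(v.centerline[:-1], v.centerline[1:]):
            _rasterize_capsule(out, spec, np.asarray(a, float), np.asarray(b, float),
                               v.radius_um, v.intensity)
    return out


def _noise_rng(spec: PhantomSpec, t_min: float) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, 7701, int(round(t_min * 100))]))


def render_volume(
    vessels: Sequence[VesselPrimitive],
    surface: SurfaceMap,
    spec: PhantomSpec,
    t_min: float = 0.0,
    *,
    apply_psf: bool = True,
    apply_noise: bool = True,
    subject_id: str = "",
    group: str = "",
) -> PAVolume:
    """Render one volume: rasterize -> shift below the local surface ->
    anisotropic Gaussian PSF -> additive noise clipped at zero.

    Deterministic given ``spec.seed`` and ``t_min``.
    """
    dx, dy, dz = spec.spacing_um
    # Vessels run at constant depth below the *local* surface, so their lab-
    # frame centerlines carry the local surface depth added per point (the
    # surface is smooth on the scale of a centerline segment).
    depth_um = surface.z_surface * surface.dz_um

    def _lab(v: VesselPrimitive) -> VesselPrimitive:
        pts = v.centerline.copy()
        ix = np.clip(np.round(pts[:, 0] / dx).astype(int), 0, depth_um.shape[0] - 1)
        iy = np.clip(np.round(pts[:, 1] / dy).astype(int), 0, depth_um.shape[1] - 1)
        pts[:, 2] = pts[:, 2] + depth_um[ix, iy]
        return replace(v, centerline=pts)

    lab = render_scene_flat([_lab(v) for v in vessels], spec)
    if spec.bscan_jitter_um > 0:
        jrng = np.random.default_rng(np.random.SeedSequence([spec.seed, 5501, int(round(t_min * 100))]))
        jitter = (jrng.normal(0, spec.bscan_jitter_um, spec.shape[1]) / dz).astype(np.float32)
        lab = axial_shift(lab, -jitter[None, :])
    if apply_psf:
        sig = spec.psf_sigma_um
        lab = ndimage.gaussian_filter(lab, sigma=(sig[0] / dx, sig[1] / dy, sig[2] / dz),
                                      mode="constant", truncate=3.0)
    if apply_noise and spec.noise_sd > 0:
        rng = _noise_rng(spec, t_min)
        lab = lab + rng.standard_normal(lab.shape, dtype=np.float32) * np.float32(spec.noise_sd)
        np.clip(lab, 0.0, None, out=lab)
    return PAVolume(amplitude=lab, spacing_um=spec.spacing_um, t_min=t_min,
                    subject_id=subject_id, group=group)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def realized_band_centers(vessels: Sequence[VesselPrimitive]) -> dict[str, float]:
    """Projected-area-weighted mean depth of each layer's placed vessels —
    the true plexus depths of the realized scene (they differ from the
    nominal band centers by the placement jitter)."""
    centers: dict[str, float] = {}
    for layer in LAYERS:
        num = den = 0.0
        for v in vessels:
            if v.layer_tag != layer:
                continue
            seg = np.diff(v.centerline, axis=0)
            length = float(np.linalg.norm(seg, axis=1).sum())
            w = 2.0 * v.radius_um * max(length, 1e-9)
            num += w * float(v.centerline[:, 2].mean())
            den += w
        if den > 0:
            centers[layer] = num / den
    return centers


@dataclass
class GroundTruth:
    """Exact scene description: vessel set per timepoint plus an analytic
    projected-area oracle (no rendering, no thresholds).

    ``pd_depth_um``/``hd_depth_um`` are the *realized* plexus depths of the
    placed vessels (area-weighted mean centerline depth below the surface).
    """

    baseline_vessels: list[VesselPrimitive]
    schedules: Mapping[str, ConstrictionSchedule]
    timepoints_min: tuple[float, ...]
    pd_depth_um: float
    hd_depth_um: float
    lateral_extent_um: tuple[float, float]

    def vessels_at(self, t_min: float) -> list[VesselPrimitive]:
        return apply_constriction(self.baseline_vessels, self.schedules, t_min)

    def projected_area_fraction(self, layer: str, t_min: float) -> float:
        return ground_truth_layer_density(self, layer, t_min)


def ground_truth_layer_density(truth: GroundTruth, layer: str, t_min: float) -> float:
    """Projected vessel-area fraction of a layer's tubes on the lateral plane.

    The lateral projection of a 3-D capsule is exactly the 2-D buffer of its
    projected centerline, so the union area is computed geometrically
    (clipped to the field of view) and divided by the lateral area.
    """
    if layer not in ("PD", "RD", "HD", "WHOLE"):
        raise ValueError(f"unknown layer tag {layer!r}")
    vessels = truth.vessels_at(t_min)
    if layer != "WHOLE":
        vessels = [v for v in vessels if v.layer_tag == layer]
    if not vessels:
        return 0.0
    ex, ey = truth.lateral_extent_um
    fov = box(0.0, 0.0, ex, ey)
    shapes = []
    for v in vessels:
        xy = v.centerline[:, :2]
        if np.allclose(xy, xy[0]):
            geom = Point(xy[0])
        else:
            geom = LineString(xy)
        shapes.append(geom.buffer(v.radius_um, quad_segs=32))
    area = unary_union(shapes).intersection(fov).area
    return float(min(area / (ex * ey), 1.0))


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

#: The four experimental arms, with constriction asymptotes chosen so that the
#: saturating-exponential schedule (tau = 20 min) reaches the layer-wise
#: density losses reported for corticosteroid injection/topical application
#: if density tracked radius linearly.
PRESET_SCHEDULES: dict[str, dict[str, ConstrictionSchedule]] = {
    "injection": {"RD": ConstrictionSchedule("RD", 0.521, 20.0, mode="dropout")},
    "topical": {
        "PD": ConstrictionSchedule("PD", 0.670, 20.0, mode="dropout"),
        "RD": ConstrictionSchedule("RD", 0.475, 20.0, mode="dropout"),
        "HD": ConstrictionSchedule("HD", 0.250, 20.0, mode="radius"),
    },
    "nonsteroid": {},
    "control": {},
}

PRESET_GROUP_ORDER = ("injection", "topical", "nonsteroid", "control")


@dataclass(frozen=True)
class GroupDefinition:
    name: str
    schedules: Mapping[str, ConstrictionSchedule] = field(default_factory=dict)


def preset_groups() -> list[GroupDefinition]:
    return [GroupDefinition(name, PRESET_SCHEDULES[name]) for name in PRESET_GROUP_ORDER]


@dataclass
class SubjectSeries:
    """One subject: its scene, schedules, ground truth, and lazy volumes."""

    group: str
    subject_id: str
    spec: PhantomSpec
    schedules: Mapping[str, ConstrictionSchedule]
    surface: SurfaceMap
    baseline_vessels: list[VesselPrimitive]
    truth: GroundTruth

    def volume_at(self, t_min: float) -> PAVolume:
        vessels = apply_constriction(self.baseline_vessels, self.schedules, t_min)
        return render_volume(vessels, self.surface, self.spec, t_min,
                             subject_id=self.subject_id, group=self.group)

    def volumes(self) -> Iterator[PAVolume]:
        for t in self.spec.timepoints_min:
            yield self.volume_at(t)


@dataclass
class StudyBundle:
    spec: PhantomSpec
    groups: list[GroupDefinition]
    n_subjects: int
    subjects: list[SubjectSeries]

    @property
    def n_volumes(self) -> int:
        return len(self.subjects) * len(self.spec.timepoints_min)


def subject_seed(master_seed: int, group_index: int, subject_index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    ss = np.random.SeedSequence([master_seed, group_index, subject_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_study(
    spec: PhantomSpec,
    groups: Sequence[GroupDefinition] | None = None,
    n_subjects: int = 6,
) -> StudyBundle:
    """Build the group x subject scene collection (volumes render lazily).

    Each subject gets an independent scene from a seed derived from the
    master seed, its group index and subject index, so any subject is
    reproducible in isolation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    groups = list(groups) if groups is not None else preset_groups()
    names = [g.name for g in groups]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate group names: {names}")
    subjects = []
    for gi, grp in enumerate(groups):
        for si in range(n_subjects):
            sub_spec = replace(spec, seed=subject_seed(spec.seed, gi, si))
            surface = generate_surface(sub_spec)
            vessels = place_vessels(sub_spec)
            centers = realized_band_centers(vessels)
            truth = GroundTruth(
                baseline_vessels=vessels,
                schedules=grp.schedules,
                timepoints_min=tuple(sub_spec.timepoints_min),
                pd_depth_um=centers.get("PD", sub_spec.pd_depth_um),
                hd_depth_um=centers.get("HD", sub_spec.hd_depth_um),
                lateral_extent_um=sub_spec.extent_um[:2],
            )
            subjects.append(SubjectSeries(
                group=grp.name,
                subject_id=f"{grp.name}_s{si}",
                spec=sub_spec,
                schedules=grp.schedules,
                surface=surface,
                baseline_vessels=vessels,
                truth=truth,
            ))
    return StudyBundle(spec=spec, groups=groups, n_subjects=n_subjects, subjects=subjects)
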