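"""Synthetic dynamic LA/LAA phantoms with analytic ground truth.

The phantom emulates a contrast-enhanced cardiac CT blood pool: a bright
left-atrial sphere joined by a cylindrical neck to a lobed half-ellipsoid
appendage, rendered on a voxel grid at CT resolution (default
0.419 x 0.419 x 1 mm, 10 cardiac phases) with additive Gaussian noise.
Appendage contraction is modelled by an isotropic per-phase scale factor
s(t) applied to everything distal to the ostium plane, about a point on
that plane, while the LA body stays static.  Because the scaling centre
lies on the ostium plane, the distal volume is exactly s(t)^3 times the
base volume and the ostium cross-section scales as s(t)^2, giving closed
truth values:

    EF_truth = 1 - (min s / max s)^3.

The base appendage volume is the analytic neck-cylinder segment plus the
lobed half-ellipsoid integrated by dense indicator sampling at 10x the
grid resolution -- an oracle independent of every measurement routine in
this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ImageVolume, LandmarkSet, PhaseStack, Plane

__all__ = ["PhantomSpec", "PhantomTruth", "make_static_phantom", "make_dynamic_series"]

#: cardiac-cycle scale profile applied to the appendage (10 phases, 0-90% RR)
DEFAULT_SCALE_PROFILE = (1.0, 0.98, 0.93, 0.89, 0.87, 0.89, 0.93, 0.96, 0.99, 1.0)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic LA/LAA phantom (lengths in mm)."""

    la_radius: float = 15.0
    laa_semiaxes: tuple[float, float, float] = (18.0, 14.0, 13.0)
    neck_radius: float = 6.0
    neck_length: float = 9.0  # junction plane sits at la_radius + neck_length
    ostium_offset: float = 4.0  # ostium plane sits at la_radius + ostium_offset
    n_lobes: int = 3
    lobe_amplitude: float = 1.5
    blood_intensity: float = 300.0
    background_intensity: float = 50.0
    noise_sd: float = 20.0
    spacing: tuple[float, float, float] = (0.419, 0.419, 1.0)
    n_phases: int = 10
    scale_profile: tuple[float, ...] = DEFAULT_SCALE_PROFILE
    seed: int = 0
    margin: float = 4.0
    fov_min: tuple[float, float, float] | None = None
    fov_max: tuple[float, float, float] | None = None
    truth_oversampling: int = 10

    def __post_init__(self) -> None:
        if min(self.la_radius, self.neck_radius, self.neck_length, self.ostium_offset) <= 0:
            raise ValueError("geometric parameters must be positive")
        if min(self.laa_semiaxes) <= 0:
            raise ValueError("appendage semiaxes must be positive")
        if self.lobe_amplitude < 0 or self.n_lobes < 0:
            raise ValueError("lobe parameters must be non-negative")
        if self.n_phases < 2:
            raise ValueError("a dynamic phantom needs at least 2 phases")
        if len(self.scale_profile) != self.n_phases:
            raise ValueError("scale_profile length must equal n_phases")
        if min(self.scale_profile) <= 0:
            raise ValueError("scale factors must be positive")
        if min(self.spacing) <= 0:
            raise ValueError("spacing components must be positive")
        if self.blood_intensity <= self.background_intensity + 3.0 * self.noise_sd:
            raise ValueError(
                "blood_intensity must exceed background_intensity + 3*noise_sd "
                "so the two classes remain separable"
            )
        if self.ostium_offset >= self.neck_length:
            raise ValueError("the ostium plane must lie proximal to the neck-ellipsoid junction")

    # --- derived geometry (appendage axis = +x, LA centred at the origin) ---

    @property
    def x_neck_start(self) -> float:
        return 0.8 * self.la_radius

    @property
    def x_junction(self) -> float:
        return self.la_radius + self.neck_length

    @property
    def x_ostium(self) -> float:
        return self.la_radius + self.ostium_offset

    @property
    def lobe_eps(self) -> float:
        """Relative radial lobe amplitude on the normalised ellipsoid."""
        return self.lobe_amplitude / float(np.mean(self.laa_semiaxes))

    def ostium_plane(self) -> Plane:
        return Plane(np.array([self.x_ostium, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))

    def landmarks(self) -> LandmarkSet:
        """Ostium-cut points on the neck circle plus appendage and LA seeds."""
        r, x0 = self.neck_radius, self.x_ostium
        names = [f"ostium_{k}" for k in range(4)] + ["laa_seed", "la_seed"]
        roles = ["ostium_cut"] * 4 + ["laa_seed", "la_seed"]
        points = np.array(
            [
                [x0, r, 0.0],
                [x0, 0.0, r],
                [x0, -r, 0.0],
                [x0, 0.0, -r],
                [self.x_junction, 0.0, 0.0],
                [0.0, 0.0, 0.0],
            ]
        )
        return LandmarkSet(names, roles, points)


@dataclass
class PhantomTruth:
    """Ground-truth values for a phantom series (the acceptance oracle)."""

    phase_percents: np.ndarray
    volumes_cm3: np.ndarray  # appendage volume distal to the ostium plane
    ostium_areas_cm2: np.ndarray
    ef: float
    neck_plane: Plane
    landmarks: LandmarkSet
    base_volume_cm3: float
    scale_profile: np.ndarray


# ---------------------------------------------------------------------------
# implicit solid
# ---------------------------------------------------------------------------

def _inside_base_appendage_distal(spec: PhantomSpec, x, y, z):
    """Indicator of the base (s = 1) appendage solid distal to the junction
    geometry: neck cylinder on [x_ostium, x_junction) plus lobed half-ellipsoid."""
    a, b, c = spec.laa_semiaxes
    xj = spec.x_junction
    in_cyl = (x >= spec.x_ostium) & (x < xj) & (y * y + z * z <= spec.neck_radius**2)
    X = (x - xj) / a
    Y = y / b
    Z = z / c
    rho2 = X * X + Y * Y + Z * Z
    if spec.lobe_eps > 0 and spec.n_lobes > 0:
        phi = np.arctan2(z, y)
        rmax = 1.0 + spec.lobe_eps * np.cos(spec.n_lobes * phi)
    else:
        rmax = 1.0
    in_ell = (X >= 0) & (rho2 <= rmax * rmax)
    return in_cyl | in_ell


def _inside_phantom(spec: PhantomSpec, s: float, x, y, z):
    """Indicator of the full blood pool at appendage scale ``s``."""
    static = (x * x + y * y + z * z <= spec.la_radius**2) | (
        (x >= spec.x_neck_start)
        & (x < spec.x_ostium)
        & (y * y + z * z <= spec.neck_radius**2)
    )
    x0 = spec.x_ostium
    qx = x0 + (x - x0) / s
    dynamic = (x >= x0) & _inside_base_appendage_distal(spec, qx, y / s, z / s)
    return static | dynamic


# ---------------------------------------------------------------------------
# truth oracle
# ---------------------------------------------------------------------------

_BASE_VOLUME_CACHE: dict[tuple, float] = {}


def _base_distal_volume_mm3(spec: PhantomSpec) -> float:
    """Base appendage volume distal to the ostium plane.

    Analytic neck-cylinder segment plus the lobed half-ellipsoid integrated
    by indicator sampling at ``truth_oversampling`` times the grid
    resolution (voxel-centre convention).
    """
    key = (
        spec.la_radius,
        spec.laa_semiaxes,
        spec.neck_radius,
        spec.neck_length,
        spec.ostium_offset,
        spec.n_lobes,
        spec.lobe_amplitude,
        spec.spacing,
        spec.truth_oversampling,
    )
    if key in _BASE_VOLUME_CACHE:
        return _BASE_VOLUME_CACHE[key]
    v_cyl = np.pi * spec.neck_radius**2 * (spec.x_junction - spec.x_ostium)
    a, b, c = spec.laa_semiaxes
    grow = 1.0 + spec.lobe_eps
    h = np.asarray(spec.spacing) / spec.truth_oversampling
    xj = spec.x_junction
    xs = np.arange(xj + h[0] / 2, xj + a * grow + h[0], h[0])
    ys = np.arange(-b * grow - h[1], b * grow + h[1], h[1]) + h[1] / 2
    zs = np.arange(-c * grow - h[2], c * grow + h[2], h[2]) + h[2] / 2
    cell = float(np.prod(h))
    count = 0
    chunk = max(1, int(4e6 // (len(ys) * len(zs))) or 1)
    yg = ys[None, :, None]
    zg = zs[None, None, :]
    for i0 in range(0, len(xs), chunk):
        xg = xs[i0 : i0 + chunk, None, None]
        inside = _inside_base_appendage_distal(spec, xg, yg, zg)
        # restrict to the ellipsoid part; the cylinder segment is analytic
        count += int(np.count_nonzero(inside & (xg >= xj)))
    v_ell = count * cell
    total = v_cyl + v_ell
    _BASE_VOLUME_CACHE[key] = total
    return total


def _make_truth(spec: PhantomSpec) -> PhantomTruth:
    s = np.asarray(spec.scale_profile, dtype=float)
    v_base = _base_distal_volume_mm3(spec)
    volumes = s**3 * v_base / 1000.0
    areas = np.pi * (s * spec.neck_radius) ** 2 / 100.0
    ef = 1.0 - (s.min() / s.max()) ** 3
    phases = 100.0 * np.arange(spec.n_phases) / spec.n_phases
    return PhantomTruth(
        phase_percents=phases,
        volumes_cm3=volumes,
        ostium_areas_cm2=areas,
        ef=float(ef),
        neck_plane=spec.ostium_plane(),
        landmarks=spec.landmarks(),
        base_volume_cm3=v_base / 1000.0,
        scale_profile=s,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _grid_axes(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a, b, c = spec.laa_semiaxes
    grow = 1.0 + spec.lobe_eps
    smax = max(spec.scale_profile)
    x0 = spec.x_ostium
    apex = x0 + smax * (spec.x_junction + a * grow - x0)
    e = max(spec.la_radius, smax * b * grow, smax * c * grow, spec.neck_radius) + spec.margin
    lo = np.array([-spec.la_radius - spec.margin, -e, -e])
    hi = np.array([apex + spec.margin, e, e])
    if spec.fov_min is not None or spec.fov_max is not None:
        fmin = np.asarray(spec.fov_min if spec.fov_min is not None else lo, dtype=float)
        fmax = np.asarray(spec.fov_max if spec.fov_max is not None else hi, dtype=float)
        need_lo = lo + spec.margin - 1.0
        need_hi = hi - spec.margin + 1.0
        if np.any(fmin > need_lo) or np.any(fmax < need_hi):
            raise ValueError(
                "enlarge field of view: the phantom anatomy reaches the volume boundary"
            )
        lo, hi = fmin, fmax
    spacing = np.asarray(spec.spacing, dtype=float)
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = tuple(lo[k] + np.arange(n[k]) * spacing[k] for k in range(3))
    return axes[0], axes[1], axes[2], lo


def make_static_phantom(spec: PhantomSpec, phase_index: int = 0) -> tuple[ImageVolume, PhantomTruth]:
    """Render one cardiac phase of the phantom and return it with the truth.

    Voxel intensity is ``blood_intensity`` where the voxel centre lies in
    the implicit solid, else ``background_intensity``, plus Gaussian noise
    of sd ``noise_sd`` drawn from a generator seeded by (seed, phase).
    """
    if not 0 <= phase_index < spec.n_phases:
        raise ValueError(f"phase_index must be in [0, {spec.n_phases})")
    xs, ys, zs, origin = _grid_axes(spec)
    s = spec.scale_profile[phase_index]
    inside = _inside_phantom(spec, s, xs[:, None, None], ys[None, :, None], zs[None, None, :])
    data = np.where(inside, spec.blood_intensity, spec.background_intensity).astype(np.float64)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, phase_index])
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    phase_percent = 100.0 * phase_index / spec.n_phases
    vol = ImageVolume(data, np.asarray(spec.spacing), origin, phase_label=phase_percent)
    return vol, _make_truth(spec)


def make_dynamic_series(spec: PhantomSpec) -> tuple[PhaseStack, PhantomTruth]:
    """Render all cardiac phases (appendage scaled, LA body static)."""
    volumes = []
    for k in range(spec.n_phases):
        vol, truth = make_static_phantom(spec, k)
        volumes.append(vol)
    stack = PhaseStack(volumes, list(truth.phase_percents))
    return stack, truth
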