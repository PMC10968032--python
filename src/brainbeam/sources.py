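"""Emission models for the sixteen optical source types.

Every source is centered on the illuminated surface at (7, 7, 0) mm and
aimed along +z (into the tissue).  Lengths quoted in grid units in the
study design are converted to mm at 0.1 mm per grid cell.

The sixteen types fall into three geometric categories:

* point   — pencil, isotropic, cone, arcsine
* line    — line (diffuse), slit (collimated)
* surface — collimated/angular/hyperboloid Gaussian, planar, disk, ring,
            pencil array, spatial-frequency pattern, 1D/2D Fourier patterns

Pattern-modulated sources (spatial-frequency and Fourier types) launch
exactly ``n`` photons with position-dependent weights proportional to the
normalized pattern intensity, so all sources are comparable per unit
launched energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

#: Table lengths are given in grid cells of the 0.1 mm voxel grid.
GRID_TO_MM = 0.1

SOURCE_TYPES = (
    "pencil",
    "isotropic",
    "cone",
    "arcsine",
    "collimated_gaussian",
    "angular_gaussian",
    "hyperboloid_gaussian",
    "line",
    "slit",
    "planar",
    "disk",
    "ring",
    "pencil_array",
    "spatial_freq_fourier",
    "fourier_1d",
    "fourier_2d",
)

#: Default per-type parameters (mm / radians / counts), matching the study
#: configuration: cone half-angle pi/6; Gaussian waist radius 10 grid = 1 mm;
#: line/slit length 10 grid = 1 mm; planar & array extents 10x10 grid;
#: disk radius 5 grid; ring outer/inner 5/1 grid; spatial frequencies 2/2
#: cycles across the extent; Fourier vectors [10,0,0,10] grid with
#: [kx, ky, phi0, M] = [1, 1, 0, 0].
DEFAULT_PARAMS = {
    "pencil": {},
    "isotropic": {},
    "cone": {"half_angle_rad": np.pi / 6},
    "arcsine": {},
    "collimated_gaussian": {"waist_radius_mm": 10 * GRID_TO_MM},
    "angular_gaussian": {"zenith_sigma_rad": np.pi / 6},
    "hyperboloid_gaussian": {
        "waist_radius_mm": 10 * GRID_TO_MM,
        "focus_distance_mm": 1 * GRID_TO_MM,
        # dimensionless shape parameter quoted in grid units
        "rayleigh_range_mm": (np.pi / 6) * GRID_TO_MM,
    },
    "line": {"length_mm": 10 * GRID_TO_MM},
    "slit": {"length_mm": 10 * GRID_TO_MM},
    "planar": {"length_x_mm": 10 * GRID_TO_MM, "length_y_mm": 10 * GRID_TO_MM},
    "disk": {"radius_mm": 5 * GRID_TO_MM},
    "ring": {"outer_radius_mm": 5 * GRID_TO_MM, "inner_radius_mm": 1 * GRID_TO_MM},
    "pencil_array": {
        "length_x_mm": 10 * GRID_TO_MM,
        "length_y_mm": 10 * GRID_TO_MM,
        "nx": 2,
        "ny": 2,
    },
    "spatial_freq_fourier": {
        "length_x_mm": 10 * GRID_TO_MM,
        "length_y_mm": 10 * GRID_TO_MM,
        "freq_x": 2.0,
        "freq_y": 2.0,
    },
    "fourier_1d": {
        "v1_mm": (10 * GRID_TO_MM, 0.0, 0.0),
        "v2_len_mm": 10 * GRID_TO_MM,
        "kx": 1.0,
        "ky": 1.0,
        "phi0": 0.0,
        "mod_depth": 0.0,
    },
    "fourier_2d": {
        "v1_mm": (10 * GRID_TO_MM, 0.0, 0.0),
        "v2_len_mm": 10 * GRID_TO_MM,
        "kx": 1.0,
        "ky": 1.0,
        "phi0": 0.0,
        "mod_depth": 0.0,
    },
}

DEFAULT_CENTER_MM = (7.0, 7.0, 0.0)


@dataclass(frozen=True)
class SourceSpec:
    """One optical source: type, center, beam axis, and type-specific parameters."""

    type_tag: str
    center_mm: tuple = DEFAULT_CENTER_MM
    direction: tuple = (0.0, 0.0, 1.0)
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.type_tag not in SOURCE_TYPES:
            raise ValueError(f"unknown source type {self.type_tag!r}")
        d = np.asarray(self.direction, float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        merged = dict(DEFAULT_PARAMS[self.type_tag])
        merged.update(self.params)
        object.__setattr__(self, "params", merged)
        for key, val in merged.items():
            if key.endswith("_mm") and np.any(np.asarray(val, float) < 0):
                raise ValueError(f"{self.type_tag}: parameter {key} must be >= 0")
        if self.type_tag == "ring" and merged["inner_radius_mm"] >= merged["outer_radius_mm"]:
            raise ValueError("ring inner radius must be smaller than outer radius")

    def to_dict(self) -> dict:
        return {
            "type_tag": self.type_tag,
            "center_mm": list(self.center_mm),
            "direction": list(self.direction),
            "params": {
                k: (list(v) if isinstance(v, (tuple, list)) else float(v))
                for k, v in self.params.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SourceSpec":
        params = {
            k: (tuple(v) if isinstance(v, list) else v) for k, v in d.get("params", {}).items()
        }
        return cls(
            type_tag=d["type_tag"],
            center_mm=tuple(d.get("center_mm", DEFAULT_CENTER_MM)),
            direction=tuple(d.get("direction", (0.0, 0.0, 1.0))),
            params=params,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SourceSpec":
        return cls.from_dict(yaml.safe_load(text))


def default_sources() -> list:
    """All sixteen study sources with their default parameters, in table order."""
    return [SourceSpec(type_tag=t) for t in SOURCE_TYPES]


@dataclass
class PhotonBatch:
    """Initial photon states: positions (mm), unit directions, weights, times (s)."""

    positions: np.ndarray
    directions: np.ndarray
    weights: np.ndarray
    times: np.ndarray

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


# ---------------------------------------------------------------------------
# Per-type samplers (source frame: center at origin, beam axis +z)
# ---------------------------------------------------------------------------

def _unit_sphere(n, rng):
    cost = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    sint = np.sqrt(1.0 - cost**2)
    return np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])


def _dirs_from_zenith(cost, rng):
    n = cost.shape[0]
    phi = rng.uniform(0.0, 2 * np.pi, n)
    sint = np.sqrt(np.clip(1.0 - cost**2, 0.0, 1.0))
    return np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])


def _zeros(n):
    return np.zeros((n, 3))


def _plus_z(n):
    d = np.zeros((n, 3))
    d[:, 2] = 1.0
    return d


def _sample_pencil(p, n, rng):
    return _zeros(n), _plus_z(n), np.ones(n)


def _sample_isotropic(p, n, rng):
    # full-sphere emission: the downward half leaves the tissue immediately
    # and is scored as escaped energy by the transport step
    return _zeros(n), _unit_sphere(n, rng), np.ones(n)


def _sample_cone(p, n, rng):
    # uniform in solid angle within the half-angle: cos(theta) ~ U[cos(a), 1]
    cosa = np.cos(p["half_angle_rad"])
    cost = rng.uniform(cosa, 1.0, n)
    return _zeros(n), _dirs_from_zenith(cost, rng), np.ones(n)


def _sample_arcsine(p, n, rng):
    # wide-angle point emitter with a cosine-squared radiance over the
    # forward hemisphere: p(cos t) ~ cos^2 t  =>  cos t = u^(1/3)
    cost = rng.uniform(0.0, 1.0, n) ** (1.0 / 3.0)
    return _zeros(n), _dirs_from_zenith(cost, rng), np.ones(n)


def _gaussian_xy(n, rng, waist_mm):
    # intensity ~ exp(-2 r^2 / w0^2): per-axis sigma = w0 / 2
    sigma = waist_mm / 2.0
    pos = _zeros(n)
    pos[:, :2] = rng.normal(0.0, sigma, (n, 2))
    return pos


def _sample_collimated_gaussian(p, n, rng):
    return _gaussian_xy(n, rng, p["waist_radius_mm"]), _plus_z(n), np.ones(n)


def _sample_angular_gaussian(p, n, rng):
    # point launch; zenith angle |N(0, sigma)| truncated to the forward
    # hemisphere so every photon enters the tissue
    sigma = p["zenith_sigma_rad"]
    theta = np.abs(rng.normal(0.0, sigma, n))
    while True:
        bad = theta >= np.pi / 2
        if not bad.any():
            break
        theta[bad] = np.abs(rng.normal(0.0, sigma, int(bad.sum())))
    return _zeros(n), _dirs_from_zenith(np.cos(theta), rng), np.ones(n)


def _sample_hyperboloid_gaussian(p, n, rng):
    # Gaussian-beam hyperboloid: each photon rides the ray through a
    # waist point (focus at depth d below the launch plane); at the launch
    # plane the beam radius is scaled by sqrt(1 + (d/zR)^2) and rays
    # converge toward the waist along the hyperboloid tangent
    w0 = p["waist_radius_mm"]
    d = p["focus_distance_mm"]
    zr = p["rayleigh_range_mm"]
    waist_pts = rng.normal(0.0, w0 / 2.0, (n, 2))
    scale = np.sqrt(1.0 + (d / zr) ** 2)
    pos = _zeros(n)
    pos[:, :2] = waist_pts * scale
    # dr/dz of r(z) = r0 sqrt(1+(z/zR)^2) evaluated at z = -d, per axis
    slope = -d / (zr**2 * scale)
    dirs = np.column_stack([waist_pts[:, 0] * slope, waist_pts[:, 1] * slope, np.ones(n)])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return pos, dirs, np.ones(n)


def _segment_x(n, rng, length_mm):
    pos = _zeros(n)
    pos[:, 0] = rng.uniform(-length_mm / 2, length_mm / 2, n)
    return pos


def _sample_line(p, n, rng):
    # diffuse line: uniform emission over the half-space perpendicular to
    # the segment (directions in the y-z plane, forward-going)
    pos = _segment_x(n, rng, p["length_mm"])
    psi = rng.uniform(-np.pi / 2, np.pi / 2, n)
    dirs = np.column_stack([np.zeros(n), np.sin(psi), np.cos(psi)])
    return pos, dirs, np.ones(n)


def _sample_slit(p, n, rng):
    return _segment_x(n, rng, p["length_mm"]), _plus_z(n), np.ones(n)


def _rect_uv(p, n, rng):
    u = rng.uniform(0.0, 1.0, n)
    v = rng.uniform(0.0, 1.0, n)
    pos = _zeros(n)
    pos[:, 0] = (u - 0.5) * p["length_x_mm"]
    pos[:, 1] = (v - 0.5) * p["length_y_mm"]
    return pos, u, v


def _sample_planar(p, n, rng):
    pos, _, _ = _rect_uv(p, n, rng)
    return pos, _plus_z(n), np.ones(n)


def _sample_disk(p, n, rng):
    r = p["radius_mm"] * np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    pos = _zeros(n)
    pos[:, 0] = r * np.cos(phi)
    pos[:, 1] = r * np.sin(phi)
    return pos, _plus_z(n), np.ones(n)


def _sample_ring(p, n, rng):
    ro, ri = p["outer_radius_mm"], p["inner_radius_mm"]
    r = np.sqrt(rng.uniform(0.0, 1.0, n) * (ro**2 - ri**2) + ri**2)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    pos = _zeros(n)
    pos[:, 0] = r * np.cos(phi)
    pos[:, 1] = r * np.sin(phi)
    return pos, _plus_z(n), np.ones(n)


def pencil_array_positions(p) -> np.ndarray:
    """Beam centers of the pencil array: an nx-by-ny grid spanning the extent."""
    xs = np.linspace(-p["length_x_mm"] / 2, p["length_x_mm"] / 2, int(p["nx"]))
    ys = np.linspace(-p["length_y_mm"] / 2, p["length_y_mm"] / 2, int(p["ny"]))
    return np.array([(x, y) for x in xs for y in ys])


def _sample_pencil_array(p, n, rng):
    beams = pencil_array_positions(p)
    pick = rng.integers(0, len(beams), n)
    pos = _zeros(n)
    pos[:, :2] = beams[pick]
    return pos, _plus_z(n), np.ones(n)


def _sample_spatial_freq(p, n, rng):
    pos, u, v = _rect_uv(p, n, rng)
    w = 0.5 * (1.0 + np.cos(2 * np.pi * (p["freq_x"] * u + p["freq_y"] * v)))
    return pos, _plus_z(n), w


def _fourier_quad(p, n, rng):
    v1 = np.asarray(p["v1_mm"], float)
    # v2 is perpendicular to both v1 and the beam axis, with the given length
    v2 = np.cross((0.0, 0.0, 1.0), v1)
    v2 = v2 / np.linalg.norm(v2) * p["v2_len_mm"]
    u = rng.uniform(0.0, 1.0, n)
    v = rng.uniform(0.0, 1.0, n)
    pos = np.outer(u, v1) + np.outer(v, v2) - (v1 + v2) / 2.0
    return pos, u, v


def _sample_fourier_1d(p, n, rng):
    pos, u, _ = _fourier_quad(p, n, rng)
    w = 0.5 * (1.0 + p["mod_depth"] * np.cos(2 * np.pi * p["kx"] * u + p["phi0"]))
    return pos, _plus_z(n), w


def _sample_fourier_2d(p, n, rng):
    pos, u, v = _fourier_quad(p, n, rng)
    w = 0.5 * (
        1.0 + p["mod_depth"] * np.cos(2 * np.pi * (p["kx"] * u + p["ky"] * v) + p["phi0"])
    )
    return pos, _plus_z(n), w


_SAMPLERS = {
    "pencil": _sample_pencil,
    "isotropic": _sample_isotropic,
    "cone": _sample_cone,
    "arcsine": _sample_arcsine,
    "collimated_gaussian": _sample_collimated_gaussian,
    "angular_gaussian": _sample_angular_gaussian,
    "hyperboloid_gaussian": _sample_hyperboloid_gaussian,
    "line": _sample_line,
    "slit": _sample_slit,
    "planar": _sample_planar,
    "disk": _sample_disk,
    "ring": _sample_ring,
    "pencil_array": _sample_pencil_array,
    "spatial_freq_fourier": _sample_spatial_freq,
    "fourier_1d": _sample_fourier_1d,
    "fourier_2d": _sample_fourier_2d,
}


def _rotation_to(direction):
    """Rotation matrix taking +z to the given unit direction."""
    d = np.asarray(direction, float)
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(d, z):
        return np.eye(3)
    if np.allclose(d, -z):
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, d)
    s = np.linalg.norm(axis)
    c = float(z @ d)
    k = axis / s
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * kx + (1 - c) * (kx @ kx)


def sample_photons(spec: SourceSpec, n: int, rng) -> PhotonBatch:
    """Draw ``n`` i.i.d. initial photon states from the source's emission law.

    ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    Positions are returned on the launch plane (z = center z); the
    transport step nudges them just inside the first voxel layer.
    """
    if n < 1:
        raise ValueError("need at least one photon")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    pos, dirs, w = _SAMPLERS[spec.type_tag](spec.params, int(n), rng)
    rot = _rotation_to(spec.direction)
    if not np.allclose(rot, np.eye(3)):
        pos = pos @ rot.T
        dirs = dirs @ rot.T
    pos = pos + np.asarray(spec.center_mm, float)
    return PhotonBatch(
        positions=np.ascontiguousarray(pos),
        directions=np.ascontiguousarray(dirs),
        weights=np.ascontiguousarray(w, dtype=float),
        times=np.zeros(n),
    )


def launch_plane_image(
    spec: SourceSpec,
    n: int,
    rng,
    grid_shape=(140, 140),
    voxel_size_mm: float = 0.1,
    plane_z_mm: float = 0.05,
) -> np.ndarray:
    """Weighted launch-position histogram at the first voxel slab.

    Photons are advanced ballistically from the launch plane to the
    mid-plane of the first voxel layer (one transport half-step) and
    binned on the lateral voxel grid; diagnostic image of the emission
    pattern (a ring shows its central hole, a pencil array its spots).
    """
    batch = sample_photons(spec, n, rng)
    dz = batch.directions[:, 2]
    fwd = dz > 1e-12
    t = (plane_z_mm - batch.positions[fwd, 2]) / dz[fwd]
    xy = batch.positions[fwd, :2] + batch.directions[fwd, :2] * t[:, None]
    img, _, _ = np.histogram2d(
        xy[:, 0],
        xy[:, 1],
        bins=grid_shape,
        range=[[0, grid_shape[0] * voxel_size_mm], [0, grid_shape[1] * voxel_size_mm]],
        weights=batch.weights[fwd],
    )
    return img
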