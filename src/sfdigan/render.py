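"""Image formation: fringe-illuminated inputs and pure-colour ground truths.

A scene is rasterised once into per-pixel material-factor fields; the fringe
image and the ground-truth map are both derived from that single
rasterisation, so the two halves of a training pair are pixel-exact
co-registered by construction.

Flat geometry uses telecentric projection: the illumination is

    I(p) = g * [ Rd(0)/2 + Rd(fx)/2 * cos(2 pi fx u(p) + phase) ],

with ``u`` the lateral position in mm and ``g`` a fixed linear gain chosen so
that the brightest material in the calibrated property rectangle peaks at
0.95 of full scale (no material ever clips).

Cylinder geometry uses a pinhole camera on the lumen axis looking along it,
with the fringe projector a small baseline to the side.  Each view ray is
intersected with the wall (polyps protrude inward as hemispheroid bumps); the
projected sinusoid's phase is evaluated at the 3-D wall point, the local
surface spatial frequency is estimated by finite differences, and the
returned power falls off as 1/d^2 with wall distance.  This produces the
characteristic dark lumen centre, distorted fringes and spatially varying
effective frequency.

Ground truths are flat-shaded: R encodes absorption, G reduced scattering
(each linearly remapped from the property scale into [0.05, 0.95] and then
quantised to 8 bits, i.e. 13..242), B is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .config import Calibration, DEFAULT_CALIBRATION
from .optics import (DomainError, diffuse_reflectance, factors_to_property_arrays)
from .scenes import SceneSpec

__all__ = [
    "SfdiImage",
    "GroundTruthMap",
    "CameraParams",
    "encode_channel",
    "rasterise_factors",
    "render_flat_sfdi",
    "render_cylinder_sfdi",
    "render_sfdi",
    "render_ground_truth",
    "render_pair",
    "illumination_gain",
]

_MU_S_FLOOR = 1e-4  # keeps the diffusion formula defined for near-transparent materials
_FX_CAP = 1.2       # mm^-1; local-frequency estimates are clipped to the tabulated range


@dataclass
class SfdiImage:
    """A fringe-illuminated render; intensities are fractions in [0, 1]."""

    intensity: np.ndarray  # H x W float
    fx: float
    phase: float
    geometry: str
    meta: dict = dc_field(default_factory=dict)

    @property
    def pixels(self) -> np.ndarray:
        """H x W x 3 view (the fringe image is monochrome)."""
        return np.repeat(self.intensity[..., None], 3, axis=2)

    def quantise(self) -> np.ndarray:
        """8-bit RGB image (identical channels)."""
        q = np.floor(np.clip(self.intensity, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
        return np.repeat(q[..., None], 3, axis=2)


@dataclass
class GroundTruthMap:
    """Pure-colour optical-property map; uint8, R=absorption, G=scattering, B=0."""

    pixels: np.ndarray  # H x W x 3 uint8
    meta: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class CameraParams:
    """Pinhole camera / projector for cylinder scenes.

    ``half_fov_deg`` is the half-angle of the square field of view;
    ``baseline_mm`` offsets the projector from the camera along +x (the
    stripe-normal direction), which is what bends the fringes over depth
    changes; ``proj_ref_mm`` is the perpendicular distance at which the
    projected pattern has exactly the nominal spatial frequency.
    """

    half_fov_deg: float = 40.0
    baseline_mm: float = 4.0
    proj_ref_mm: float = 20.0


def encode_channel(value):
    """Scale a colour parameter in [0.05, 0.95] to its 8-bit level (half-up).

    0.05 -> 13 and 0.95 -> 242, the extremes of the ground-truth encoding.
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0.05 - 1e-12) or np.any(arr > 0.95 + 1e-12):
        raise DomainError("channel value outside [0.05, 0.95]")
    out = np.floor(arr * 255.0 + 0.5).astype(np.uint8)
    return out if out.shape else int(out)


def properties_to_colour(mu_a, mu_s, calib: Calibration):
    """Linear remap of normalised properties into the [0.05, 0.95] colour range."""
    span = calib.colour_hi - calib.colour_lo
    r = calib.colour_lo + span * np.clip(np.asarray(mu_a) / calib.mu_a_max, 0, 1)
    g = calib.colour_lo + span * np.clip(np.asarray(mu_s) / calib.mu_s_max, 0, 1)
    return r, g


# ---------------------------------------------------------------------------
# rasterisation

def _boundary_curve(style: str, params: dict, v: np.ndarray) -> np.ndarray:
    """Boundary x(v) in normalised coordinates, v in [0, 1] running down rows."""
    if style == "curved":
        c = float(params["chord_pos"])
        s = float(params.get("sagitta", 0.0))
        if s == 0.0:
            return np.full_like(v, c)
        radius = (s * s + 0.25) / (2.0 * s)
        x0 = c + s - radius
        return x0 + np.sqrt(np.maximum(radius**2 - (v - 0.5) ** 2, 0.0))
    if style == "ragged":
        b = float(params["base_pos"])
        amp = float(params.get("amplitude", 0.08))
        smooth = float(params.get("smooth", 0.12))
        rng = np.random.default_rng(int(params.get("seed", 0)))
        walk = np.cumsum(rng.standard_normal(v.size))
        w = max(3, int(smooth * v.size) | 1)
        kernel = np.ones(w) / w
        walk = np.convolve(np.pad(walk, w // 2, mode="edge"), kernel, mode="valid")
        walk -= walk.mean()
        peak = np.max(np.abs(walk))
        if peak > 0:
            walk = walk / peak
        return b + amp * walk
    raise DomainError(f"region boundary style {style!r} cannot be rasterised")


def rasterise_factors(scene: SceneSpec, resolution: int):
    """Per-pixel (final, absorption, scattering) factor fields for a flat scene.

    Regions partition the field left-to-right along their boundary curves;
    spheroids are stamped afterwards in list order (later occludes earlier).
    Returns the three factor fields plus the material index map.
    """
    n = resolution
    v = (np.arange(n) + 0.5) / n          # row coordinate
    u = (np.arange(n) + 0.5) / n          # column coordinate
    uu = np.broadcast_to(u[None, :], (n, n))
    index = np.zeros((n, n), dtype=np.int32)
    for region in scene.regions[1:]:
        xb = _boundary_curve(region.boundary_style, region.boundary_params, v)
        index[uu >= xb[:, None]] = region.region_id
    finals = np.array([r.factors.final_factor for r in scene.regions])
    absorbs = np.array([r.factors.absorption_factor for r in scene.regions])
    scatters = np.array([r.factors.scattering_factor for r in scene.regions])
    f_map = finals[index]
    a_map = absorbs[index]
    s_map = scatters[index]

    fov = scene.fov_mm
    x_mm = (np.arange(n) + 0.5) * fov / n
    y_mm = (np.arange(n) + 0.5) * fov / n
    xx, yy = np.meshgrid(x_mm, y_mm)
    for k, sph in enumerate(scene.spheroids):
        cx, cy = sph.center[0], sph.center[1]
        a, b = sph.semi_axes[0], sph.semi_axes[1]
        inside = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 < 1.0
        f_map[inside] = sph.factors.final_factor
        a_map[inside] = sph.factors.absorption_factor
        s_map[inside] = sph.factors.scattering_factor
        index[inside] = len(scene.regions) + k
    return f_map, a_map, s_map, index


def _cylinder_geometry(scene: SceneSpec, camera: CameraParams, resolution: int):
    """Ray-cast the lumen wall; returns per-pixel geometry and factor fields."""
    n = resolution
    radius = scene.cylinder_params["radius"]
    length = scene.cylinder_params["length"]
    t_half = np.tan(np.deg2rad(camera.half_fov_deg))
    px = ((np.arange(n) + 0.5) / n * 2.0 - 1.0) * t_half
    py = ((np.arange(n) + 0.5) / n * 2.0 - 1.0) * t_half
    dx, dy = np.meshgrid(px, py)
    dz = np.ones_like(dx)
    norm = np.sqrt(dx**2 + dy**2 + dz**2)
    dx, dy, dz = dx / norm, dy / norm, dz / norm
    rho = np.hypot(dx, dy)
    with np.errstate(divide="ignore"):
        t = np.where(rho > 0, radius / np.maximum(rho, 1e-12), np.inf)
    z = t * dz
    theta = np.arctan2(dy, dx)
    arc = radius * theta  # in (-pi R, pi R]

    # factor fields on the wall, then polyp bumps (footprints in (arc, z))
    wall = scene.regions[0].factors
    f_map = np.full((n, n), wall.final_factor)
    a_map = np.full((n, n), wall.absorption_factor)
    s_map = np.full((n, n), wall.scattering_factor)
    index = np.zeros((n, n), dtype=np.int32)
    height = np.zeros((n, n))
    circumference = 2.0 * np.pi * radius
    for k, sph in enumerate(scene.spheroids):
        s0, z0 = sph.center[0], sph.center[1]
        a, b, c = sph.semi_axes
        ds = (arc - s0 + 0.5 * circumference) % circumference - 0.5 * circumference
        m2 = (ds / a) ** 2 + ((z - z0) / b) ** 2
        inside = m2 < 1.0
        f_map[inside] = sph.factors.final_factor
        a_map[inside] = sph.factors.absorption_factor
        s_map[inside] = sph.factors.scattering_factor
        index[inside] = 1 + k
        height[inside] = c * np.sqrt(np.maximum(1.0 - m2[inside], 0.0))

    t_eff = np.where(height > 0, (radius - height) / np.maximum(rho, 1e-12), t)
    z_eff = t_eff * dz
    hit = np.isfinite(t_eff) & (z_eff >= 0.0) & (z_eff <= length)
    points = np.stack([t_eff * dx, t_eff * dy, z_eff], axis=-1)
    return {
        "hit": hit, "distance": t_eff, "points": points, "theta": theta,
        "z": z_eff, "f": f_map, "a": a_map, "s": s_map, "index": index,
    }


# ---------------------------------------------------------------------------
# illumination gain

def illumination_gain(calib: Calibration = DEFAULT_CALIBRATION) -> float:
    """Linear source gain anchored so no admissible material clips.

    The brightest material in the calibrated rectangle (mu_a -> 0, mu_s' at
    its maximum) peaks at 0.95 of full scale.  The absolute wattage of the
    source is irrelevant after 8-bit normalisation; only this gain matters.
    """
    rd_dc = diffuse_reflectance(1e-9, calib.mu_s_max, 0.0, calib.n_rel)
    rd_ac = diffuse_reflectance(1e-9, calib.mu_s_max, calib.fx, calib.n_rel)
    return 0.95 / (0.5 * (rd_dc + rd_ac))


def _apply_noise(intensity: np.ndarray, noise: dict, rng) -> np.ndarray:
    """Optional seeded Poisson-Gaussian measurement noise (off by default)."""
    photons = float(noise.get("photons", 1e4))
    sigma = float(noise.get("sigma", 0.0))
    out = rng.poisson(np.clip(intensity, 0, None) * photons) / photons
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# renderers

def render_flat_sfdi(scene: SceneSpec, calib: Calibration = DEFAULT_CALIBRATION,
                     resolution: int = 256, noise: dict | None = None,
                     rng=None) -> SfdiImage:
    """Telecentric fringe render of a flat scene."""
    if scene.geometry != "flat":
        raise DomainError(f"render_flat_sfdi needs a flat scene, got {scene.geometry!r}")
    f_map, a_map, s_map, _ = rasterise_factors(scene, resolution)
    mu_a, mu_s = factors_to_property_arrays(f_map, a_map, s_map, calib)
    mu_s = np.maximum(mu_s, _MU_S_FLOOR)
    fx = scene.illumination["fx"]
    phase = scene.illumination.get("phase", 0.0)
    rd_dc = diffuse_reflectance(mu_a, mu_s, 0.0, calib.n_rel)
    rd_ac = diffuse_reflectance(mu_a, mu_s, fx, calib.n_rel)
    x_mm = (np.arange(resolution) + 0.5) * scene.fov_mm / resolution
    carrier = np.cos(2.0 * np.pi * fx * x_mm + phase)[None, :]
    gain = illumination_gain(calib)
    intensity = gain * (0.5 * rd_dc + 0.5 * rd_ac * carrier)
    if noise:
        rng = rng if rng is not None else np.random.default_rng(scene.seed)
        intensity = _apply_noise(intensity, noise, rng)
    return SfdiImage(np.clip(intensity, 0.0, 1.0), fx=fx, phase=phase,
                     geometry="flat", meta={"model_tag": scene.model_tag,
                                            "frame_index": scene.frame_index})


def render_cylinder_sfdi(scene: SceneSpec, calib: Calibration = DEFAULT_CALIBRATION,
                         resolution: int = 256, camera: CameraParams | None = None,
                         noise: dict | None = None, rng=None,
                         return_aux: bool = False):
    """Fringe render inside a cylindrical lumen (axial pinhole camera)."""
    if scene.geometry != "cylinder":
        raise DomainError(f"render_cylinder_sfdi needs a cylinder scene")
    camera = camera or CameraParams()
    geo = _cylinder_geometry(scene, camera, resolution)
    hit, pts, dist = geo["hit"], geo["points"], geo["distance"]
    mu_a, mu_s = factors_to_property_arrays(geo["f"], geo["a"], geo["s"], calib)
    mu_s = np.maximum(mu_s, _MU_S_FLOOR)
    fx = scene.illumination["fx"]
    phase = scene.illumination.get("phase", 0.0)

    # projected sinusoid phase at the wall point (projector offset by the baseline)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = (2.0 * np.pi * fx * camera.proj_ref_mm
               * (pts[..., 0] - camera.baseline_mm) / np.maximum(pts[..., 2], 1e-9)
               + phase)

    # local surface spatial frequency from finite differences of the phase
    safe_pts = np.where(hit[..., None], pts, 0.0)
    safe_psi = np.where(hit, psi, 0.0)
    fx_local = np.zeros_like(safe_psi)
    for axis in (0, 1):
        dpsi = np.gradient(safe_psi, axis=axis)
        dpos = np.linalg.norm(np.gradient(safe_pts, axis=axis), axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            comp = dpsi / np.maximum(dpos, 1e-9)
        fx_local += comp**2
    fx_local = np.clip(np.sqrt(fx_local) / (2.0 * np.pi), 0.0, _FX_CAP)

    rd_dc = diffuse_reflectance(mu_a, mu_s, 0.0, calib.n_rel)
    rd_ac = diffuse_reflectance(mu_a, mu_s, np.where(hit, fx_local, 0.0), calib.n_rel)
    radius = scene.cylinder_params["radius"]
    falloff = np.where(hit, (radius / np.maximum(dist, radius)) ** 2, 0.0)
    gain = illumination_gain(calib)
    intensity = gain * falloff * (0.5 * rd_dc + 0.5 * rd_ac * np.cos(safe_psi))
    intensity = np.where(hit, intensity, 0.0)
    if noise:
        rng = rng if rng is not None else np.random.default_rng(scene.seed)
        intensity = _apply_noise(intensity, noise, rng)
    img = SfdiImage(np.clip(intensity, 0.0, 1.0), fx=fx, phase=phase,
                    geometry="cylinder", meta={"model_tag": scene.model_tag,
                                               "frame_index": scene.frame_index})
    if return_aux:
        aux = dict(geo)
        aux["fx_local"] = np.where(hit, fx_local, np.nan)
        return img, aux
    return img


def render_sfdi(scene: SceneSpec, calib: Calibration = DEFAULT_CALIBRATION,
                resolution: int = 256, camera: CameraParams | None = None,
                noise: dict | None = None, rng=None) -> SfdiImage:
    """Geometry dispatch for the fringe render."""
    if scene.geometry == "flat":
        return render_flat_sfdi(scene, calib, resolution, noise=noise, rng=rng)
    return render_cylinder_sfdi(scene, calib, resolution, camera=camera,
                                noise=noise, rng=rng)


def render_ground_truth(scene: SceneSpec, calib: Calibration = DEFAULT_CALIBRATION,
                        resolution: int = 256,
                        camera: CameraParams | None = None) -> GroundTruthMap:
    """Flat-shaded pure-colour property map, co-registered with the fringe render."""
    if scene.geometry == "flat":
        f_map, a_map, s_map, _ = rasterise_factors(scene, resolution)
        visible = np.ones(f_map.shape, dtype=bool)
    else:
        geo = _cylinder_geometry(scene, camera or CameraParams(), resolution)
        f_map, a_map, s_map, visible = geo["f"], geo["a"], geo["s"], geo["hit"]
    mu_a, mu_s = factors_to_property_arrays(f_map, a_map, s_map, calib)
    r_col, g_col = properties_to_colour(mu_a, mu_s, calib)
    out = np.zeros((resolution, resolution, 3), dtype=np.uint8)
    out[..., 0] = np.where(visible, encode_channel(r_col), 0)
    out[..., 1] = np.where(visible, encode_channel(g_col), 0)
    return GroundTruthMap(out, meta={"model_tag": scene.model_tag,
                                     "frame_index": scene.frame_index})


def render_pair(scene: SceneSpec, calib: Calibration = DEFAULT_CALIBRATION,
                resolution: int = 256, camera: CameraParams | None = None,
                noise: dict | None = None, rng=None):
    """Render the (fringe image, ground truth) pair for one scene."""
    img = render_sfdi(scene, calib, resolution, camera=camera, noise=noise, rng=rng)
    truth = render_ground_truth(scene, calib, resolution, camera=camera)
    return img, truth
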