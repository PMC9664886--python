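"""Parametric sample models and keyframe sweeps.

Five scene families mirror typical clinical SFDI samples: flat fields with
one, two (curved boundary) or three (ragged boundary) materials, flat fields
with spheroidal tumours, and a cylindrical lumen with polyp structures on the
wall.  Datasets are enumerated animation-style: selected scene parameters are
keyframed and linearly interpolated across frames, so one base scene plus a
set of tracks defines a whole dataset.

Coordinate conventions
----------------------
Flat scenes live in a square field of ``fov_mm`` millimetres; region
boundaries are curves ``x(y)`` in normalised [0, 1] field coordinates and
spheroid centres/semi-axes are in mm.  Cylinder scenes are parametrised by
wall-surface coordinates: spheroid (polyp) centres are ``(arc_length_mm,
axial_z_mm, 0)`` and semi-axes ``(along-arc, along-axis, radial-height)``.
"""

from __future__ import annotations

import copy
import dataclasses
import re
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from .config import DEFAULT_CALIBRATION
from .optics import MaterialFactors

__all__ = [
    "ConfigError",
    "Region",
    "Spheroid",
    "SceneSpec",
    "KeyframeTrack",
    "make_flat_scene",
    "add_spheroids",
    "make_cylinder_scene",
    "scatter_polyps",
    "interpolate_track",
    "keyframe_sweep",
    "final_factor_track",
    "rectangular_model",
    "rect_curved_model",
    "rect_ragged_model",
    "rect_tumour_model",
    "cylinder_model",
    "flat_dataset_scenes",
    "cylinder_dataset_scenes",
    "scene_to_dict",
    "scene_from_dict",
]


class ConfigError(ValueError):
    """A scene or sweep definition is internally inconsistent."""


@dataclass
class Region:
    """One material band of a flat sample (or the cylinder wall).

    ``boundary_style``/``boundary_params`` describe the region's *left* edge;
    the first region has style ``none`` and starts at the field edge.
    """

    region_id: int
    boundary_style: str  # none | curved | ragged
    boundary_params: dict
    factors: MaterialFactors

    def __post_init__(self):
        if self.boundary_style not in ("none", "curved", "ragged"):
            raise ConfigError(f"unknown boundary style {self.boundary_style!r}")


@dataclass
class Spheroid:
    """A tumour/polyp spheroid; coordinates in mm (see module docstring)."""

    center: list
    semi_axes: list
    factors: MaterialFactors

    def __post_init__(self):
        self.center = [float(v) for v in self.center]
        self.semi_axes = [float(v) for v in self.semi_axes]
        if any(a <= 0 for a in self.semi_axes):
            raise ConfigError(f"spheroid semi-axes must be > 0, got {self.semi_axes}")


@dataclass
class SceneSpec:
    """Full description of one rendered frame."""

    geometry: str  # flat | cylinder
    regions: list
    spheroids: list = dc_field(default_factory=list)
    cylinder_params: dict | None = None
    illumination: dict = dc_field(default_factory=lambda: {
        "fx": DEFAULT_CALIBRATION.fx, "phase": 0.0,
        "power": DEFAULT_CALIBRATION.source_power_w})
    fov_mm: float = DEFAULT_CALIBRATION.field_of_view_mm
    frame_index: int = 0
    seed: int = 0
    model_tag: str = ""

    def __post_init__(self):
        if self.geometry not in ("flat", "cylinder"):
            raise ConfigError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "flat" and self.cylinder_params is not None:
            raise ConfigError("flat scenes must not carry cylinder_params")
        if self.geometry == "cylinder":
            if not self.cylinder_params or self.cylinder_params.get("radius", 0) <= 0:
                raise ConfigError("cylinder scenes need cylinder_params with radius > 0")
        if self.illumination.get("fx", 0) <= 0:
            raise ConfigError("illumination fx must be > 0")


@dataclass
class KeyframeTrack:
    """Piecewise-linear animation of one scene parameter."""

    parameter_path: str
    keyframes: list  # [(frame, value), ...] with strictly increasing frames

    def __post_init__(self):
        frames = [f for f, _ in self.keyframes]
        if len(frames) < 1:
            raise ConfigError("a track needs at least one keyframe")
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ConfigError("keyframe frames must be strictly increasing")


# ---------------------------------------------------------------------------
# scene factories

def _default_boundary(style: str, position: float, seed: int) -> dict:
    if style == "curved":
        return {"chord_pos": position, "sagitta": 0.12}
    if style == "ragged":
        return {"base_pos": position, "amplitude": 0.08, "smooth": 0.12, "seed": seed}
    return {}


def make_flat_scene(n_materials: int, boundary_style: str, factors_list,
                    seed: int = 0, boundary_params: list | None = None,
                    fov_mm: float = DEFAULT_CALIBRATION.field_of_view_mm) -> SceneSpec:
    """Flat sample with ``n_materials`` bands separated by the given boundary style."""
    if n_materials not in (1, 2, 3):
        raise ConfigError(f"n_materials must be 1, 2 or 3, got {n_materials}")
    if len(factors_list) != n_materials:
        raise ConfigError(
            f"{n_materials} materials but {len(factors_list)} factor triples given")
    if (boundary_style == "none") != (n_materials == 1):
        raise ConfigError("boundary_style 'none' iff a single material")
    regions = [Region(0, "none", {}, factors_list[0])]
    for k in range(1, n_materials):
        if boundary_params is not None:
            params = boundary_params[k - 1]
        else:
            params = _default_boundary(boundary_style, k / n_materials, seed + k)
        regions.append(Region(k, boundary_style, params, factors_list[k]))
    return SceneSpec(geometry="flat", regions=regions, seed=seed, fov_mm=fov_mm)


def add_spheroids(scene: SceneSpec, spheroids) -> SceneSpec:
    """Return a scene with the spheroids appended (later ones occlude earlier)."""
    out = copy.deepcopy(scene)
    for sph in spheroids:
        if scene.geometry == "flat":
            x, y = sph.center[0], sph.center[1]
            a, b = sph.semi_axes[0], sph.semi_axes[1]
            if x + a < 0 or x - a > scene.fov_mm or y + b < 0 or y - b > scene.fov_mm:
                warnings.warn(f"spheroid at {sph.center} lies outside the field of view",
                              stacklevel=2)
        out.spheroids.append(copy.deepcopy(sph))
    return out


def make_cylinder_scene(radius: float, length: float, wall_factors: MaterialFactors,
                        spheroids=(), seed: int = 0) -> SceneSpec:
    """Hollow-cylinder lumen viewed along its axis, with optional wall polyps."""
    if radius <= 0:
        raise ConfigError(f"cylinder radius must be > 0, got {radius}")
    for sph in spheroids:
        if max(sph.semi_axes) > radius:
            raise ConfigError(
                f"polyp semi-axis {max(sph.semi_axes)} exceeds cylinder radius {radius}")
    scene = SceneSpec(
        geometry="cylinder",
        regions=[Region(0, "none", {}, wall_factors)],
        cylinder_params={"radius": float(radius), "length": float(length)},
        seed=seed,
    )
    return add_spheroids(scene, list(spheroids))


def scatter_polyps(radius: float, length: float, n: int, seed: int,
                   size_range=(2.0, 6.0), height_range=(1.0, 4.0),
                   final_range=(0.05, 0.95)) -> list:
    """Seeded uniform scatter of polyp hemispheroids over the wall surface."""
    rng = np.random.default_rng(seed)
    polyps = []
    for _ in range(n):
        theta = rng.uniform(0.0, 2.0 * np.pi)
        z = rng.uniform(0.25 * length, 0.95 * length)
        a, b = rng.uniform(*size_range, size=2)
        c = min(rng.uniform(*height_range), 0.9 * radius)
        f = rng.uniform(*final_range)
        polyps.append(Spheroid(center=[radius * theta, z, 0.0],
                               semi_axes=[a, b, c],
                               factors=MaterialFactors(f, 0.0, 1.0)))
    return polyps


# ---------------------------------------------------------------------------
# keyframe machinery

_TOKEN_RE = re.compile(r"([A-Za-z_][A-Za-z_0-9]*)|\[(\d+)\]")


def _parse_path(path: str):
    tokens, pos = [], 0
    for m in _TOKEN_RE.finditer(path):
        tokens.append(("attr", m.group(1)) if m.group(1) is not None
                      else ("idx", int(m.group(2))))
    if not tokens:
        raise ConfigError(f"cannot parse parameter path {path!r}")
    return tokens


def _get_token(obj, tok):
    kind, key = tok
    try:
        if kind == "attr":
            return obj[key] if isinstance(obj, dict) else getattr(obj, key)
        return obj[key]
    except (AttributeError, KeyError, IndexError, TypeError) as exc:
        raise ConfigError(f"parameter path token {key!r} not found on {type(obj).__name__}") from exc


def _set_token(obj, tok, value):
    kind, key = tok
    if kind == "attr":
        if isinstance(obj, dict):
            obj[key] = value
            return obj
        if dataclasses.is_dataclass(obj) and obj.__dataclass_params__.frozen:
            return dataclasses.replace(obj, **{key: value})
        setattr(obj, key, value)
        return obj
    if isinstance(obj, tuple):
        lst = list(obj)
        lst[key] = value
        return tuple(lst)
    obj[key] = value
    return obj


def _set_path(obj, tokens, value):
    if len(tokens) == 1:
        return _set_token(obj, tokens[0], value)
    child = _get_token(obj, tokens[0])
    new_child = _set_path(child, tokens[1:], value)
    return _set_token(obj, tokens[0], new_child)


def get_by_path(obj, path: str):
    for tok in _parse_path(path):
        obj = _get_token(obj, tok)
    return obj


def set_by_path(obj, path: str, value):
    return _set_path(obj, _parse_path(path), value)


def interpolate_track(track: KeyframeTrack, frame: int) -> float:
    """Piecewise-linear value of the track at ``frame`` (inclusive range)."""
    frames = np.array([f for f, _ in track.keyframes], dtype=float)
    values = np.array([v for _, v in track.keyframes], dtype=float)
    if frame < frames[0] or frame > frames[-1]:
        raise ConfigError(
            f"frame {frame} outside keyframe range [{frames[0]:g}, {frames[-1]:g}]")
    return float(np.interp(frame, frames, values))


def keyframe_sweep(base_scene: SceneSpec, tracks, start: int, end: int) -> list:
    """One SceneSpec per frame in [start, end] with all tracks interpolated."""
    if start > end:
        raise ConfigError(f"start frame {start} after end frame {end}")
    for track in tracks:
        get_by_path(base_scene, track.parameter_path)  # validates the path
    scenes = []
    for frame in range(start, end + 1):
        scene = copy.deepcopy(base_scene)
        for track in tracks:
            scene = set_by_path(scene, track.parameter_path,
                                interpolate_track(track, frame))
        scene.frame_index = frame
        scenes.append(scene)
    return scenes


def final_factor_track(region_index: int, start_frame: int, end_frame: int,
                       lo: float = 0.05, hi: float = 0.95) -> KeyframeTrack:
    """The canonical material sweep: final factor lo -> hi across the dataset."""
    return KeyframeTrack(f"regions[{region_index}].factors.final_factor",
                         [(start_frame, lo), (end_frame, hi)])


# ---------------------------------------------------------------------------
# the five dataset models
#
# Default sweeps run the final factor 0.05 -> 0.95 at full component strength
# (absorption_factor = 0, scattering_factor = 1), walking the material from
# 0.95:0.05 to 0.05:0.95 absorbing:scattering proportion.  Multi-material
# scenes stagger or reverse the sweeps so the materials differ in every frame.

def _mat(final: float, absorption: float = 0.0, scattering: float = 1.0) -> MaterialFactors:
    return MaterialFactors(final, absorption, scattering)


def rectangular_model(n_frames: int = 50, seed: int = 0,
                      factor_ranges: dict | None = None) -> list:
    """Flat, single material; final factor swept over the dataset."""
    fr = factor_ranges or {}
    base = make_flat_scene(1, "none", [_mat(0.5)], seed=seed)
    tracks = _material_tracks(fr, [(0.05, 0.95)], n_frames)
    scenes = keyframe_sweep(base, tracks, 1, n_frames)
    for s in scenes:
        s.model_tag = "rectangular"
    return scenes


def rect_curved_model(n_frames: int = 50, seed: int = 0,
                      factor_ranges: dict | None = None) -> list:
    """Flat, two materials meeting along a circular-arc boundary."""
    fr = factor_ranges or {}
    base = make_flat_scene(2, "curved", [_mat(0.5), _mat(0.5)], seed=seed)
    tracks = _material_tracks(fr, [(0.05, 0.95), (0.95, 0.05)], n_frames)
    tracks.append(KeyframeTrack("regions[1].boundary_params.sagitta",
                                [(1, 0.04), (n_frames, 0.2)]))
    scenes = keyframe_sweep(base, tracks, 1, n_frames)
    for s in scenes:
        s.model_tag = "rect_curved"
    return scenes


def rect_ragged_model(n_frames: int = 50, seed: int = 0,
                      factor_ranges: dict | None = None) -> list:
    """Flat, three materials meeting along seeded ragged boundaries."""
    fr = factor_ranges or {}
    base = make_flat_scene(3, "ragged", [_mat(0.5), _mat(0.5), _mat(0.5)], seed=seed)
    tracks = _material_tracks(fr, [(0.05, 0.95), (0.95, 0.05), (0.3, 0.9)], n_frames)
    scenes = keyframe_sweep(base, tracks, 1, n_frames)
    for s in scenes:
        s.model_tag = "rect_ragged"
    return scenes


def rect_tumour_model(n_frames: int = 50, seed: int = 0,
                      factor_ranges: dict | None = None) -> list:
    """Two-material curved model plus translating/scaling tumour spheroids."""
    fr = factor_ranges or {}
    base = make_flat_scene(2, "curved", [_mat(0.5), _mat(0.5)], seed=seed)
    fov = base.fov_mm
    base = add_spheroids(base, [
        Spheroid([0.3 * fov, 0.35 * fov, 0.0], [0.1 * fov, 0.08 * fov, 0.05 * fov],
                 _mat(0.5)),
        Spheroid([0.7 * fov, 0.7 * fov, 0.0], [0.06 * fov, 0.06 * fov, 0.05 * fov],
                 _mat(0.5)),
    ])
    tracks = _material_tracks(fr, [(0.05, 0.95), (0.95, 0.05)], n_frames)
    tracks += [
        KeyframeTrack("spheroids[0].factors.final_factor", [(1, 0.9), (n_frames, 0.1)]),
        KeyframeTrack("spheroids[1].factors.final_factor", [(1, 0.2), (n_frames, 0.8)]),
        KeyframeTrack("spheroids[0].center[0]", [(1, 0.25 * fov), (n_frames, 0.6 * fov)]),
        KeyframeTrack("spheroids[1].center[1]", [(1, 0.75 * fov), (n_frames, 0.3 * fov)]),
        KeyframeTrack("spheroids[1].semi_axes[0]", [(1, 0.05 * fov), (n_frames, 0.12 * fov)]),
    ]
    scenes = keyframe_sweep(base, tracks, 1, n_frames)
    for s in scenes:
        s.model_tag = "rect_tumour"
    return scenes


def cylinder_model(n_frames: int = 50, seed: int = 0, n_polyps: int = 0,
                   radius: float = 10.0, length: float = 80.0,
                   factor_ranges: dict | None = None) -> list:
    """Lumen model: fringe projection into a hollow cylinder, optional polyps."""
    fr = factor_ranges or {}
    polyps = scatter_polyps(radius, length, n_polyps, seed) if n_polyps else []
    base = make_cylinder_scene(radius, length, _mat(0.5), polyps, seed=seed)
    tracks = _material_tracks(fr, [(0.05, 0.95)], n_frames)
    for k in range(n_polyps):
        lo, hi = (0.9, 0.1) if k % 2 == 0 else (0.15, 0.85)
        tracks.append(KeyframeTrack(f"spheroids[{k}].factors.final_factor",
                                    [(1, lo), (n_frames, hi)]))
        tracks.append(KeyframeTrack(f"spheroids[{k}].center[1]",
                                    [(1, polyps[k].center[1]),
                                     (n_frames, min(0.95 * length,
                                                    polyps[k].center[1] + 0.2 * length))]))
    scenes = keyframe_sweep(base, tracks, 1, n_frames)
    tag = "cylinder_polyp" if n_polyps else "cylinder_plain"
    for s in scenes:
        s.model_tag = tag
    return scenes


def _material_tracks(factor_ranges: dict, final_sweeps, n_frames: int) -> list:
    """Tracks for regional material factors.

    ``factor_ranges`` optionally sweeps the absorption/scattering strength
    factors ("absorption"/"scattering" entries, (lo, hi) tuples); the final
    factor always follows the per-region sweeps in ``final_sweeps``.
    """
    tracks = []
    for i, (lo, hi) in enumerate(final_sweeps):
        tracks.append(final_factor_track(i, 1, n_frames, lo, hi))
        if "absorption" in factor_ranges:
            a_lo, a_hi = factor_ranges["absorption"]
            if i % 2 == 1:
                a_lo, a_hi = a_hi, a_lo
            tracks.append(KeyframeTrack(f"regions[{i}].factors.absorption_factor",
                                        [(1, a_lo), (n_frames, a_hi)]))
        if "scattering" in factor_ranges:
            s_lo, s_hi = factor_ranges["scattering"]
            if i % 2 == 1:
                s_lo, s_hi = s_hi, s_lo
            tracks.append(KeyframeTrack(f"regions[{i}].factors.scattering_factor",
                                        [(1, s_lo), (n_frames, s_hi)]))
    return tracks


def flat_dataset_scenes(frames_per_model: int = 50, seed: int = 0,
                        factor_ranges: dict | None = None) -> list:
    """The 'complex rectangular' dataset: four flat models in equal parts."""
    scenes = []
    scenes += rectangular_model(frames_per_model, seed, factor_ranges)
    scenes += rect_curved_model(frames_per_model, seed + 1, factor_ranges)
    scenes += rect_ragged_model(frames_per_model, seed + 2, factor_ranges)
    scenes += rect_tumour_model(frames_per_model, seed + 3, factor_ranges)
    return scenes


def cylinder_dataset_scenes(n_plain: int = 200, n_polyp: int = 120, seed: int = 0,
                            factor_ranges: dict | None = None) -> list:
    """The lumen dataset: plain cylinders plus polyp-bearing cylinders."""
    scenes = cylinder_model(n_plain, seed, n_polyps=0, factor_ranges=factor_ranges)
    if n_polyp:
        scenes += cylinder_model(n_polyp, seed + 7, n_polyps=3,
                                 factor_ranges=factor_ranges)
    return scenes


# ---------------------------------------------------------------------------
# serialisation

def scene_to_dict(scene: SceneSpec) -> dict:
    return dataclasses.asdict(scene)


def scene_from_dict(data: dict) -> SceneSpec:
    regions = [Region(r["region_id"], r["boundary_style"], r["boundary_params"],
                      MaterialFactors(**r["factors"])) for r in data["regions"]]
    spheroids = [Spheroid(s["center"], s["semi_axes"], MaterialFactors(**s["factors"]))
                 for s in data.get("spheroids", [])]
    return SceneSpec(
        geometry=data["geometry"], regions=regions, spheroids=spheroids,
        cylinder_params=data.get("cylinder_params"),
        illumination=data.get("illumination", {"fx": DEFAULT_CALIBRATION.fx,
                                               "phase": 0.0,
                                               "power": DEFAULT_CALIBRATION.source_power_w}),
        fov_mm=data.get("fov_mm", DEFAULT_CALIBRATION.field_of_view_mm),
        frame_index=data.get("frame_index", 0), seed=data.get("seed", 0),
        model_tag=data.get("model_tag", ""))


def save_scene(scene: SceneSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scene_to_dict(scene), fh)


def load_scene(path) -> SceneSpec:
    with open(path) as fh:
        return scene_from_dict(yaml.safe_load(fh))
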