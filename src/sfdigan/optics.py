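"""Forward optics: material factors, diffusion-approximation reflectance, LUT inversion.

The image-formation surrogate for ray tracing is the standard diffusion
approximation for spatially modulated illumination of a semi-infinite turbid
medium.  With transport coefficient ``mu_tr = mu_a + mu_s'``, reduced albedo
``a' = mu_s'/mu_tr`` and the modulated effective attenuation

    mu_eff'(fx) = sqrt(3 mu_a mu_tr + (2 pi fx)^2),

the diffuse reflectance at spatial frequency ``fx`` is

    Rd(fx) = 3 A a' / ((mu_eff'/mu_tr + 1) (mu_eff'/mu_tr + 3A)),

where ``A`` is the internal-reflection parameter obtained from the relative
refractive index via the Groenhuis polynomial for the effective Fresnel
reflection coefficient.  Rd is decreasing in ``mu_a`` and ``fx`` and
increasing in ``mu_s'`` over the calibrated range, which is what both the
renderer and the single-snapshot (SSOP) inversion rely on.

The mapping from Blender-style material factors to optical properties is a
declared calibration convention (the rendering pipeline treats the factors as
proxies):

    mu_a  = mu_a_max * (1 - final_factor) * (1 - absorption_factor)
    mu_s' = mu_s_max * final_factor * scattering_factor

It is bilinear, continuous, spans the full property rectangle, and is
monotone in every factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from .config import Calibration, DEFAULT_CALIBRATION

__all__ = [
    "MaterialFactors",
    "OpticalProperties",
    "ReflectanceLUT",
    "DomainError",
    "DiffusionValidityError",
    "factors_to_properties",
    "factors_to_property_arrays",
    "internal_reflection_parameter",
    "diffuse_reflectance",
    "build_inversion_lut",
    "invert_reflectance",
]


class DomainError(ValueError):
    """A physical parameter lies outside its admissible domain."""


class DiffusionValidityError(ValueError):
    """The diffusion approximation is not valid for the requested medium."""


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class MaterialFactors:
    """Blender-style material weights, each a unitless fraction in [0, 1].

    ``final_factor`` mixes the absorbing component (0) against the scattering
    component (1); ``absorption_factor`` is the transparency of the absorbing
    component (0 = fully absorbing, 1 = transparent); ``scattering_factor``
    is the strength of the subsurface-scattering component (0 = transparent).
    """

    final_factor: float
    absorption_factor: float
    scattering_factor: float

    def __post_init__(self) -> None:
        _check_unit("final_factor", self.final_factor)
        _check_unit("absorption_factor", self.absorption_factor)
        _check_unit("scattering_factor", self.scattering_factor)


@dataclass(frozen=True)
class OpticalProperties:
    """Proxy absorption / reduced scattering pair in mm^-1."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise DomainError(f"mu_a must be >= 0, got {self.mu_a!r}")
        if self.mu_s_prime < 0:
            raise DomainError(f"mu_s_prime must be >= 0, got {self.mu_s_prime!r}")


def factors_to_property_arrays(final, absorption, scattering,
                               calib: Calibration = DEFAULT_CALIBRATION):
    """Vectorised factor -> (mu_a, mu_s') map for per-pixel factor fields."""
    final = np.asarray(final, dtype=float)
    absorption = np.asarray(absorption, dtype=float)
    scattering = np.asarray(scattering, dtype=float)
    for name, arr in (("final_factor", final), ("absorption_factor", absorption),
                      ("scattering_factor", scattering)):
        if np.any(arr < 0) or np.any(arr > 1):
            raise DomainError(f"{name} must lie in [0, 1]")
    mu_a = calib.mu_a_max * (1.0 - final) * (1.0 - absorption)
    mu_s = calib.mu_s_max * final * scattering
    return mu_a, mu_s


def factors_to_properties(factors: MaterialFactors,
                          calib: Calibration = DEFAULT_CALIBRATION) -> OpticalProperties:
    """Map a factor triple to its proxy optical properties (mm^-1)."""
    mu_a, mu_s = factors_to_property_arrays(
        factors.final_factor, factors.absorption_factor, factors.scattering_factor, calib)
    return OpticalProperties(float(mu_a), float(mu_s))


def internal_reflection_parameter(n_rel: float) -> float:
    """Internal-reflection parameter A(n) of diffusion theory.

    Uses the Groenhuis polynomial approximation for the effective Fresnel
    reflection coefficient, ``R_eff = 0.0636 n + 0.668 + 0.710/n - 1.440/n^2``,
    and ``A = (1 - R_eff) / (2 (1 + R_eff))``.
    """
    if n_rel < 1.0:
        raise DomainError(f"relative refractive index must be >= 1, got {n_rel!r}")
    r_eff = 0.0636 * n_rel + 0.668 + 0.710 / n_rel - 1.440 / n_rel**2
    return (1.0 - r_eff) / (2.0 * (1.0 + r_eff))


def diffuse_reflectance(mu_a, mu_s_prime, fx, n_rel: float = DEFAULT_CALIBRATION.n_rel):
    """Diffuse reflectance Rd(fx) of a semi-infinite turbid medium.

    Parameters are broadcastable arrays; ``mu_a`` and ``mu_s_prime`` in mm^-1,
    ``fx`` in cycles/mm.  Returns values in [0, 1].
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if np.any(mu_s_prime <= 0):
        raise DiffusionValidityError("mu_s_prime must be > 0 for the diffusion approximation")
    if np.any(mu_a < 0):
        raise DomainError("mu_a must be >= 0")
    if np.any(fx < 0):
        raise DomainError("spatial frequency must be >= 0")
    a_param = internal_reflection_parameter(n_rel)
    mu_tr = mu_a + mu_s_prime
    albedo = mu_s_prime / mu_tr
    mu_eff = np.sqrt(3.0 * mu_a * mu_tr + (2.0 * np.pi * fx) ** 2)
    ratio = mu_eff / mu_tr
    rd = 3.0 * a_param * albedo / ((ratio + 1.0) * (ratio + 3.0 * a_param))
    return rd if rd.shape else float(rd)


@dataclass
class ReflectanceLUT:
    """Tabulated (Rd_dc, Rd_ac) over a regular (mu_a, mu_s') grid.

    Supports the forward direction by construction and the inverse direction
    (reflectance pair -> property pair) through piecewise-linear interpolation
    of the scattered inverse map, with flagged nearest-node fallback outside
    the tabulated gamut.
    """

    fx_ac: float
    mu_a_grid: np.ndarray
    mu_s_grid: np.ndarray
    rd_dc: np.ndarray  # shape (n_mu_a, n_mu_s)
    rd_ac: np.ndarray
    n_rel: float = DEFAULT_CALIBRATION.n_rel
    _inv: object = field(default=None, repr=False, compare=False)
    _tree: object = field(default=None, repr=False, compare=False)
    _nodes: object = field(default=None, repr=False, compare=False)

    def _build_inverse(self):
        if self._inv is None:
            pts = np.column_stack([self.rd_dc.ravel(), self.rd_ac.ravel()])
            vals = np.column_stack([
                np.repeat(self.mu_a_grid, self.mu_s_grid.size),
                np.tile(self.mu_s_grid, self.mu_a_grid.size),
            ])
            self._inv = LinearNDInterpolator(pts, vals)
            self._tree = cKDTree(pts)
            self._nodes = vals
        return self._inv, self._tree, self._nodes

    def save(self, path: str | Path) -> None:
        """Serialise to a plain-text table (header plus one row per node)."""
        with open(path, "w") as fh:
            fh.write(f"# fx_ac={self.fx_ac} n_rel={self.n_rel} "
                     f"n_mu_a={self.mu_a_grid.size} n_mu_s={self.mu_s_grid.size}\n")
            fh.write("# mu_a mu_s_prime rd_dc rd_ac\n")
            for i, mu_a in enumerate(self.mu_a_grid):
                for j, mu_s in enumerate(self.mu_s_grid):
                    fh.write(f"{mu_a:.8g} {mu_s:.8g} "
                             f"{self.rd_dc[i, j]:.10g} {self.rd_ac[i, j]:.10g}\n")

    @classmethod
    def load(cls, path: str | Path) -> "ReflectanceLUT":
        lines = Path(path).read_text().splitlines()
        header = dict(kv.split("=") for kv in lines[0].lstrip("# ").split())
        body = np.array([[float(v) for v in ln.split()]
                         for ln in lines if not ln.startswith("#")])
        n_a, n_s = int(header["n_mu_a"]), int(header["n_mu_s"])
        return cls(
            fx_ac=float(header["fx_ac"]),
            mu_a_grid=body[::n_s, 0].copy(),
            mu_s_grid=body[:n_s, 1].copy(),
            rd_dc=body[:, 2].reshape(n_a, n_s),
            rd_ac=body[:, 3].reshape(n_a, n_s),
            n_rel=float(header["n_rel"]),
        )


def build_inversion_lut(fx_ac: float,
                        calib: Calibration = DEFAULT_CALIBRATION,
                        n_mu_a: int = 101,
                        n_mu_s: int = 101,
                        mu_a_range: tuple[float, float] | None = None,
                        mu_s_range: tuple[float, float] | None = None) -> ReflectanceLUT:
    """Tabulate (Rd(0), Rd(fx_ac)) over the calibrated property rectangle."""
    if fx_ac <= 0:
        raise DomainError(f"fx_ac must be > 0, got {fx_ac!r}")
    if mu_a_range is None:
        mu_a_range = (1e-4, calib.mu_a_max)
    if mu_s_range is None:
        mu_s_range = (0.02, calib.mu_s_max)
    mu_a_grid = np.linspace(*mu_a_range, n_mu_a)
    mu_s_grid = np.linspace(*mu_s_range, n_mu_s)
    mu_a2, mu_s2 = np.meshgrid(mu_a_grid, mu_s_grid, indexing="ij")
    rd_dc = diffuse_reflectance(mu_a2, mu_s2, 0.0, calib.n_rel)
    rd_ac = diffuse_reflectance(mu_a2, mu_s2, fx_ac, calib.n_rel)
    return ReflectanceLUT(fx_ac=fx_ac, mu_a_grid=mu_a_grid, mu_s_grid=mu_s_grid,
                          rd_dc=rd_dc, rd_ac=rd_ac, n_rel=calib.n_rel)


def invert_reflectance(lut: ReflectanceLUT, rd_dc, rd_ac):
    """Invert reflectance pairs to (mu_a, mu_s') via the LUT.

    Returns ``(mu_a, mu_s_prime, out_of_gamut)`` with the same shape as the
    inputs.  Queries outside the tabulated reflectance gamut fall back to the
    nearest tabulated node and are flagged True in ``out_of_gamut``.
    """
    interp, tree, nodes = lut._build_inverse()
    rd_dc = np.asarray(rd_dc, dtype=float)
    rd_ac = np.asarray(rd_ac, dtype=float)
    shape = np.broadcast_shapes(rd_dc.shape, rd_ac.shape)
    q = np.column_stack([np.broadcast_to(rd_dc, shape).ravel(),
                         np.broadcast_to(rd_ac, shape).ravel()])
    out = interp(q)
    oog = ~np.isfinite(out[:, 0])
    if np.any(oog):
        _, idx = tree.query(q[oog])
        out[oog] = nodes[idx]
    mu_a = out[:, 0].reshape(shape)
    mu_s = out[:, 1].reshape(shape)
    oog = oog.reshape(shape)
    if shape == ():
        return float(mu_a), float(mu_s), bool(oog)
    return mu_a, mu_s, oog
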