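"""Calibration constants and run configuration.

All physical scales used across the package live in :class:`Calibration` so
that rendering, channel encoding and metric decoding are guaranteed to share
one set of constants.  Values are serialisable to/from YAML for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Calibration:
    """Physical scales tying Blender-style material factors to optics.

    Attributes
    ----------
    mu_a_max:
        Absorption coefficient mapped to the full 8-bit scale, mm^-1.
    mu_s_max:
        Reduced scattering coefficient mapped to the full 8-bit scale, mm^-1.
    n_rel:
        Relative refractive index of the sample (tissue-like, 1.43).
    fx:
        Base illumination spatial frequency, cycles/mm.
    field_of_view_mm:
        Physical width of the square rendered field.  The default gives ten
        full fringe periods across the image at the base spatial frequency.
    source_power_w:
        Nominal illumination source power.  Only the derived linear gain
        matters after 8-bit normalisation; the wattage is recorded for
        provenance.
    colour_lo, colour_hi:
        Range of the pure-colour ground-truth channels before 8-bit
        quantisation (0.05..0.95 -> 13..242).
    """

    mu_a_max: float = 0.25
    mu_s_max: float = 2.5
    n_rel: float = 1.43
    fx: float = 0.2
    field_of_view_mm: float = 50.0
    source_power_w: float = 3.5
    colour_lo: float = 0.05
    colour_hi: float = 0.95

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Calibration":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def with_(self, **kwargs) -> "Calibration":
        return replace(self, **kwargs)


DEFAULT_CALIBRATION = Calibration()
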