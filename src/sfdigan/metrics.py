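"""Evaluation metrics: NMAE, per-pixel difference maps, channel decoding.

NMAE (normalised mean absolute error) over T pixels is

    NMAE = sum_i |p_i - p_i_ref| / sum_i p_i_ref,

reported as a percentage.  It is computed on the 8-bit encoded channels;
decoding to mm^-1 is a monotone linear rescale, so the value is identical on
either scale.  The per-pixel difference map is |p - p_ref| / p_ref * 100 with
zero-reference pixels masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .config import Calibration, DEFAULT_CALIBRATION

__all__ = [
    "UndefinedMetricError",
    "DifferenceMap",
    "NMAEReport",
    "nmae",
    "difference_map",
    "decode_optical_maps",
    "report_from_per_image",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for the given reference (e.g. all zeros)."""


def nmae(pred, ref) -> float:
    """Normalised mean absolute error of one channel (fraction, not %)."""
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    denom = ref.sum()
    if denom <= 0:
        raise UndefinedMetricError("reference channel sums to zero; NMAE undefined")
    return float(np.abs(pred - ref).sum() / denom)


@dataclass
class DifferenceMap:
    """Per-pixel percentage error with a mask for zero-reference pixels."""

    values: np.ndarray   # percent, NaN where masked
    mask: np.ndarray     # True where the reference is zero

    @property
    def unmasked_mean(self) -> float:
        return float(np.nanmean(self.values))


def difference_map(pred, ref) -> DifferenceMap:
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    mask = ref == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.abs(pred - ref) / ref * 100.0
    values[mask] = np.nan
    return DifferenceMap(values, mask)


def decode_optical_maps(output, calib: Calibration = DEFAULT_CALIBRATION):
    """8-bit R/G channels -> (mu_a, mu_s') maps in mm^-1 (255 = full scale)."""
    output = np.asarray(output)
    mu_a = output[..., 0].astype(float) / 255.0 * calib.mu_a_max
    mu_s = output[..., 1].astype(float) / 255.0 * calib.mu_s_max
    return mu_a, mu_s


@dataclass
class NMAEReport:
    """Per-image NMAE values and summary statistics for a validation set."""

    per_image: pd.DataFrame  # columns: sample_id, nmae_abs, nmae_sct
    label: str = ""
    extras: dict = dc_field(default_factory=dict)

    @property
    def mean_abs(self) -> float:
        return float(self.per_image["nmae_abs"].mean())

    @property
    def mean_sct(self) -> float:
        return float(self.per_image["nmae_sct"].mean())

    @property
    def envelope_abs(self) -> float:
        return float(self.per_image["nmae_abs"].max())

    @property
    def envelope_sct(self) -> float:
        return float(self.per_image["nmae_sct"].max())

    def summary(self) -> dict:
        return {
            "label": self.label,
            "n_images": int(len(self.per_image)),
            "mean_abs_pct": 100.0 * self.mean_abs,
            "mean_sct_pct": 100.0 * self.mean_sct,
            "envelope_abs_pct": 100.0 * self.envelope_abs,
            "envelope_sct_pct": 100.0 * self.envelope_sct,
            **self.extras,
        }


def report_from_per_image(rows, label: str = "", extras: dict | None = None) -> NMAEReport:
    """Build a report from (sample_id, nmae_abs, nmae_sct) tuples (fractions)."""
    frame = pd.DataFrame(rows, columns=["sample_id", "nmae_abs", "nmae_sct"])
    return NMAEReport(frame, label=label, extras=extras or {})
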