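"""Single-snapshot optical property (SSOP) baseline.

Conventional single-shot demodulation: the fringe image is separated in the
spatial-frequency domain along the fringe axis into a low-pass DC component
and a band-pass AC component around the carrier frequency.  The AC magnitude
is recovered as the envelope of the analytic (single-sideband) signal.  With
the known illumination gain g the calibrated reflectance pair is

    Rd_dc = 2 I_dc / g,        Rd_ac = 2 |I_ac| / g,

which a reflectance lookup table inverts per pixel to (mu_a, mu_s').  The
frequency filtering is what makes SSOP single-shot, and also what produces
its characteristic artefacts at material boundaries and image borders.
"""

from __future__ import annotations

import numpy as np

from .config import Calibration, DEFAULT_CALIBRATION
from .optics import DomainError, ReflectanceLUT, build_inversion_lut, invert_reflectance
from .render import SfdiImage, illumination_gain

__all__ = ["DemodulationError", "ssop_demodulate", "ssop_predict"]


class DemodulationError(ValueError):
    """The carrier frequency cannot be resolved from the image."""


def _as_intensity(image) -> np.ndarray:
    if isinstance(image, SfdiImage):
        return image.intensity
    arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    return arr.astype(float)


def ssop_demodulate(image, fx: float, pixel_mm: float,
                    filter_sigma: float | None = None):
    """Split a fringe image into DC level and AC envelope along the fringe axis.

    Returns ``(i_dc, i_ac)`` intensity maps.  ``pixel_mm`` is the physical
    pixel pitch.  The low-pass (DC) and single-sideband band-pass (AC)
    filters are Gaussian-shaped with standard deviation ``filter_sigma``
    (cycles/mm, default fx/4): a Gaussian passband has no spatial sidelobes,
    so boundary artefacts stay localised to a few filter widths instead of
    ringing across the field.
    """
    intensity = _as_intensity(image)
    n = intensity.shape[1]
    nyquist = 0.5 / pixel_mm
    if fx <= 0 or fx >= nyquist:
        raise DemodulationError(
            f"carrier fx={fx} not resolvable (Nyquist {nyquist:.3g} cycles/mm)")
    sigma = filter_sigma if filter_sigma is not None else fx / 4.0
    freqs = np.fft.fftfreq(n, d=pixel_mm)
    spectrum = np.fft.fft(intensity, axis=1)
    dc_filt = np.exp(-0.5 * (freqs / sigma) ** 2)
    i_dc = np.real(np.fft.ifft(spectrum * dc_filt[None, :], axis=1))
    # analytic single-sideband: keep only the positive carrier lobe, doubled
    ac_filt = np.where(freqs > 0,
                       2.0 * np.exp(-0.5 * ((freqs - fx) / sigma) ** 2), 0.0)
    i_ac = np.abs(np.fft.ifft(spectrum * ac_filt[None, :], axis=1))
    return i_dc, i_ac


def ssop_predict(image, fx: float, lut: ReflectanceLUT | None = None,
                 calib: Calibration = DEFAULT_CALIBRATION,
                 pixel_mm: float | None = None,
                 filter_sigma: float | None = None):
    """Per-pixel (mu_a, mu_s') maps from a single fringe image.

    Returns ``(mu_a, mu_s_prime, out_of_gamut)``; out-of-gamut pixels carry
    the nearest tabulated properties and are flagged.
    """
    intensity = _as_intensity(image)
    if pixel_mm is None:
        pixel_mm = calib.field_of_view_mm / intensity.shape[1]
    if lut is None:
        lut = build_inversion_lut(fx, calib)
    elif abs(lut.fx_ac - fx) > 1e-9:
        raise DomainError(f"LUT tabulated at fx={lut.fx_ac}, queried at fx={fx}")
    i_dc, i_ac = ssop_demodulate(intensity, fx, pixel_mm, filter_sigma)
    gain = illumination_gain(calib)
    rd_dc = np.clip(2.0 * i_dc / gain, 0.0, 1.0)
    rd_ac = np.clip(2.0 * i_ac / gain, 0.0, 1.0)
    return invert_reflectance(lut, rd_dc, rd_ac)
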