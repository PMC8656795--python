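"""Phantom calibration: modulation amplitudes -> absolute diffuse reflectance.

Raw modulation amplitudes mix the tissue response with the instrument
response (source power, projector modulation depth, optics, vignetting).
Measuring a reference phantom of known optical properties under the same
illumination removes the instrument term:

    R_d,sample(fx) = (M_sample(fx) / M_ref(fx)) * R_d,model(ref_op, fx)

where R_d,model is the forward-model prediction for the reference
phantom.  Any smooth multiplicative gain field shared by sample and
reference cancels exactly, as does global exposure scaling.  Sample and
reference are assumed co-registered and acquired at the same geometry
(no surface-profile correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demodulation import ModulationMaps
from .forward_model import OpticalProperties, diffuse_reflectance

__all__ = ["ReflectanceMaps", "reflectance_from_modulation"]

#: Pixels where the reference amplitude falls below this fraction of its
#: maximum are masked out rather than divided (field edges, dead pixels).
REFERENCE_FLOOR_FRAC = 1e-6


@dataclass
class ReflectanceMaps:
    """Calibrated diffuse reflectance maps at the low/high frequency pair."""

    rd_dc: np.ndarray
    rd_ac: np.ndarray
    wavelength: float
    fx_pair: tuple[float, float]
    mask: np.ndarray  # True where pixels are valid


def reflectance_from_modulation(
    m_sample: ModulationMaps,
    m_ref: ModulationMaps,
    ref_op: OpticalProperties,
    fx_pair: tuple[float, float],
    wavelength: float,
    ref_wavelength: float | None = None,
) -> ReflectanceMaps:
    """Calibrate sample modulation maps against a reference phantom.

    Parameters
    ----------
    m_sample, m_ref : ModulationMaps
        Demodulated sample and reference stacks; must be co-registered,
        same shape and same AC frequency.
    ref_op : OpticalProperties
        Known optical properties of the reference phantom at this
        wavelength.
    fx_pair : (fx_dc, fx_ac)
        Spatial frequencies in cycles/mm of the DC and AC maps.
    wavelength, ref_wavelength : float
        Acquisition wavelengths (nm); they must agree.
    """
    if ref_wavelength is not None and ref_wavelength != wavelength:
        raise ValueError(
            f"wavelength mismatch: sample {wavelength} nm vs reference {ref_wavelength} nm"
        )
    if not np.isclose(m_sample.fx_ac, m_ref.fx_ac):
        raise ValueError(
            f"fx mismatch: sample {m_sample.fx_ac} vs reference {m_ref.fx_ac}"
        )
    if m_sample.m_dc.shape != m_ref.m_dc.shape:
        raise ValueError("sample and reference maps must be co-registered (same shape)")

    fx_dc, fx_ac = fx_pair
    rd_model_dc = diffuse_reflectance(ref_op, fx_dc)
    rd_model_ac = diffuse_reflectance(ref_op, fx_ac)

    mask = np.ones(m_sample.m_dc.shape, dtype=bool)
    out = []
    for m_s, m_r, rd_model in (
        (m_sample.m_dc, m_ref.m_dc, rd_model_dc),
        (m_sample.m_ac, m_ref.m_ac, rd_model_ac),
    ):
        floor = REFERENCE_FLOOR_FRAC * float(np.nanmax(m_r))
        ok = m_r > floor
        mask &= ok
        rd = np.full(m_s.shape, np.nan)
        np.divide(m_s, m_r, out=rd, where=ok)
        rd[ok] *= rd_model
        out.append(rd)

    return ReflectanceMaps(
        rd_dc=out[0], rd_ac=out[1], wavelength=wavelength,
        fx_pair=(fx_dc, fx_ac), mask=mask,
    )
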