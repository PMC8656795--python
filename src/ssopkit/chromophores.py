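"""Beer-Lambert hemoglobin unmixing and tissue oxygen saturation (StO2).

Absorption of perfused tissue in the red/NIR window is dominated by the
two hemoglobin species.  With decadic molar extinction coefficients
eps (mm^-1 mM^-1), per-pixel absorption at wavelength lambda is

    mu_a(lambda) = ln(10) * [eps_HbO2(lambda) * C_HbO2 + eps_Hb(lambda) * C_Hb]

Measuring mu_a at two wavelengths straddling the isosbestic point
(~800 nm) — one deoxy-dominant (e.g. 665 nm), one oxy-dominant (e.g.
860 nm) — gives a well-conditioned 2x2 linear system per pixel, solved
in closed form.  Oxygen saturation is

    StO2% = 100 * C_HbO2 / (C_HbO2 + C_Hb)

Negative concentration solutions (noise, model mismatch) are flagged,
not truncated, so downstream statistics can choose their own handling;
StO2 is clamped to [0, 100] with the clamp recorded in the QC flags.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExtinctionTable",
    "StO2Map",
    "load_extinction_table",
    "concentrations_from_mua",
    "sto2",
]

LN10 = np.log(10.0)

#: QC flag bits.
QC_OK = 0
QC_NEGATIVE_CONC = 1  # at least one unmixed concentration < 0
QC_UNDEFINED = 2  # total hemoglobin <= 0, StO2 undefined
QC_CLAMPED = 4  # StO2 clamped into [0, 100]

#: Relative condition-number ceiling for the extinction matrix.
MAX_CONDITION_NUMBER = 1e6


@dataclass
class ExtinctionTable:
    """Decadic molar extinction spectra of HbO2 and Hb.

    Coefficients are stored in mm^-1 mM^-1 (converted from the cm^-1 M^-1
    values in the packaged CSV); values at arbitrary wavelengths are
    linearly interpolated.
    """

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def interpolate(self, wavelength: float) -> tuple[float, float]:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(
                f"wavelength {wavelength} nm outside tabulated range [{lo}, {hi}]"
            )
        return (
            float(np.interp(wavelength, self.wavelengths, self.eps_hbo2)),
            float(np.interp(wavelength, self.wavelengths, self.eps_hb)),
        )

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 extinction matrix [[eps_HbO2(l1), eps_Hb(l1)], [..l2..]].

        Raises a config error when the matrix is singular or too
        ill-conditioned to unmix (e.g. proportional columns).
        """
        rows = [self.interpolate(l) for l in wavelengths]
        e = np.array(rows, dtype=float)
        cond = np.linalg.cond(e)
        if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
            raise ValueError(
                f"extinction matrix at {wavelengths} nm is singular or "
                f"near-singular (condition number {cond:.3g})"
            )
        return e


def load_extinction_table() -> ExtinctionTable:
    """Load the packaged hemoglobin extinction compilation (600-1000 nm)."""
    src = resources.files("ssopkit.data").joinpath("hemoglobin_extinction.csv")
    with resources.as_file(src) as path:
        df = pd.read_csv(path, comment="#")
    # cm^-1 M^-1 -> mm^-1 mM^-1
    return ExtinctionTable(
        wavelengths=df["wavelength_nm"].to_numpy(float),
        eps_hbo2=df["eps_hbo2_cm1_M"].to_numpy(float) * 1e-4,
        eps_hb=df["eps_hb_cm1_M"].to_numpy(float) * 1e-4,
    )


@dataclass
class StO2Map:
    """Hemoglobin concentration maps (mM) and oxygen saturation (%)."""

    c_hbo2: np.ndarray
    c_hb: np.ndarray
    sto2: np.ndarray
    qc: np.ndarray  # uint8 bitmask


def concentrations_from_mua(
    mua_l1,
    mua_l2,
    table: ExtinctionTable,
    wavelengths: tuple[float, float],
):
    """Unmix two absorption maps into (C_HbO2, C_Hb) concentration maps (mM).

    Solves the per-pixel 2x2 system mu_a = ln(10) * E @ c in closed form
    (Cramer's rule on the shared extinction matrix).  Negative solutions
    are returned as-is; flagging happens in :func:`sto2`.
    """
    mua_l1 = np.asarray(mua_l1, dtype=float)
    mua_l2 = np.asarray(mua_l2, dtype=float)
    if mua_l1.shape != mua_l2.shape:
        raise ValueError("absorption maps must be co-registered (same shape)")
    e = table.matrix(wavelengths)
    det = e[0, 0] * e[1, 1] - e[0, 1] * e[1, 0]
    a1 = mua_l1 / LN10
    a2 = mua_l2 / LN10
    c_hbo2 = (a1 * e[1, 1] - a2 * e[0, 1]) / det
    c_hb = (a2 * e[0, 0] - a1 * e[1, 0]) / det
    return c_hbo2, c_hb


def remix_to_mua(c_hbo2, c_hb, table: ExtinctionTable, wavelengths):
    """Forward Beer-Lambert mix: concentrations (mM) -> mu_a maps (mm^-1)."""
    e = table.matrix(tuple(wavelengths))
    c_hbo2 = np.asarray(c_hbo2, dtype=float)
    c_hb = np.asarray(c_hb, dtype=float)
    return tuple(LN10 * (e[i, 0] * c_hbo2 + e[i, 1] * c_hb) for i in range(2))


def sto2(c_hbo2, c_hb, clamp: bool = True) -> StO2Map:
    """Oxygen saturation map from concentration maps.

    StO2 = 100 * C_HbO2 / (C_HbO2 + C_Hb) where the total is positive;
    elsewhere the pixel is NaN and flagged undefined.  Negative input
    concentrations are flagged; clamping to [0, 100] (on by default, for
    display/ROI use) is recorded per pixel.
    """
    c_hbo2 = np.asarray(c_hbo2, dtype=float)
    c_hb = np.asarray(c_hb, dtype=float)
    if c_hbo2.shape != c_hb.shape:
        raise ValueError("concentration maps must share one shape")
    total = c_hbo2 + c_hb
    qc = np.zeros(np.broadcast(c_hbo2, c_hb).shape, dtype=np.uint8)
    qc[(c_hbo2 < 0) | (c_hb < 0)] |= QC_NEGATIVE_CONC
    defined = total > 0
    qc[~defined] |= QC_UNDEFINED
    s = np.full(total.shape, np.nan)
    np.divide(100.0 * c_hbo2, total, out=s, where=defined)
    if clamp:
        clamped = defined & ((s < 0) | (s > 100))
        qc[clamped] |= QC_CLAMPED
        s = np.clip(s, 0.0, 100.0, out=s)
        s[~defined] = np.nan
    return StO2Map(c_hbo2=c_hbo2, c_hb=c_hb, sto2=s, qc=qc)
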