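"""Diffusion-approximation forward model of spatially modulated diffuse
reflectance and the look-up table (LUT) used for per-pixel inversion.

The model is the standard closed form for a semi-infinite homogeneous
turbid medium under sinusoidal irradiance at spatial frequency ``fx``
(cycles/mm).  With absorption ``mu_a`` and reduced scattering
``mu_s_prime`` (both mm^-1):

    mu_tr    = mu_a + mu_s_prime                 (transport coefficient)
    a'       = mu_s_prime / mu_tr                (reduced albedo)
    mu_eff'  = sqrt(3 mu_a mu_tr + (2 pi fx)^2)  (scalar attenuation)
    R_d(fx)  = 3 A a' / ((mu_eff'/mu_tr + 1) (mu_eff'/mu_tr + 3 A))

where ``A = (1 - R_eff) / (2 (1 + R_eff))`` and ``R_eff`` is the
effective internal reflection coefficient of the tissue-air boundary,
approximated by the Groenhuis / Egan-Hilgeman polynomial in the
refractive index ``n``:

    R_eff(n) = 0.0636 n + 0.668 + 0.710/n - 1.440/n^2

The closed form is accurate in the scattering-dominated regime
(mu_s_prime >> mu_a) that covers soft tissue and tissue-mimicking
phantoms.  The inversion maps a measured (R_DC, R_AC) pair at a
low/high spatial-frequency pair back to (mu_a, mu_s_prime) through a
precomputed LUT: nearest-node search followed by Gauss-Newton
refinement on the bilinear interpolant of the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "OpticalProperties",
    "LUT",
    "OpticalPropertyMaps",
    "diffuse_reflectance",
    "build_lut",
    "invert_optical_properties",
    "effective_reflection_coefficient",
]

#: QC flag bits used by the inversion.
QC_OK = 0
QC_OUT_OF_RANGE = 1  # reflectance pair clamped to the LUT boundary
QC_NAN = 2  # non-finite input pixel


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of a homogeneous medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.  Must be > 0.
    mu_s_prime : float
        Reduced scattering coefficient, mm^-1.  Must be > 0.
    n : float
        Refractive index (>= 1).  Soft tissue is typically ~1.4.
    """

    mu_a: float
    mu_s_prime: float
    n: float = 1.4

    def __post_init__(self) -> None:
        if not (self.mu_a > 0):
            raise ValueError(f"mu_a must be > 0, got {self.mu_a}")
        if not (self.mu_s_prime > 0):
            raise ValueError(f"mu_s_prime must be > 0, got {self.mu_s_prime}")
        if not (self.n >= 1):
            raise ValueError(f"refractive index must be >= 1, got {self.n}")


def effective_reflection_coefficient(n: float) -> float:
    """Groenhuis / Egan-Hilgeman polynomial approximation of R_eff(n)."""
    return 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2


def diffuse_reflectance(op, fx, *, mu_a=None, mu_s_prime=None, n=None):
    """Spatially modulated diffuse reflectance R_d(fx) of a semi-infinite medium.

    Parameters
    ----------
    op : OpticalProperties or None
        Medium properties.  Alternatively pass ``mu_a``/``mu_s_prime``/``n``
        arrays directly (broadcast) for map-wise evaluation.
    fx : float or ndarray
        Spatial frequency of the sinusoidal irradiance, cycles/mm (>= 0).

    Returns
    -------
    float or ndarray
        R_d in [0, 1]; non-increasing in ``fx``, decreasing in ``mu_a``,
        increasing in ``mu_s_prime``.
    """
    if op is not None:
        mu_a, mu_s_prime, n = op.mu_a, op.mu_s_prime, op.n
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_a <= 0) or np.any(mu_s_prime <= 0):
        raise ValueError("mu_a and mu_s_prime must be strictly positive")
    fx = np.asarray(fx, dtype=float)
    if np.any(fx < 0):
        raise ValueError("spatial frequency fx must be >= 0")
    n = 1.4 if n is None else float(n)

    mu_tr = mu_a + mu_s_prime
    albedo = mu_s_prime / mu_tr
    mu_eff = np.sqrt(3.0 * mu_a * mu_tr + (2.0 * np.pi * fx) ** 2)
    r_eff = effective_reflection_coefficient(n)
    a_coef = (1.0 - r_eff) / (2.0 * (1.0 + r_eff))
    x = mu_eff / mu_tr
    rd = 3.0 * a_coef * albedo / ((x + 1.0) * (x + 3.0 * a_coef))
    if rd.ndim == 0:
        return float(rd)
    return rd


@dataclass
class LUT:
    """Look-up table mapping (mu_a, mu_s_prime) -> (R_DC, R_AC).

    ``rd_dc``/``rd_ac`` are (len(mu_a_grid), len(mu_s_grid)) matrices of
    diffuse reflectance at the two spatial frequencies ``fx_dc < fx_ac``.
    The table may come from :func:`build_lut` (diffusion model) or be
    loaded from an externally produced file (e.g. a Monte Carlo table)
    with :meth:`load`.
    """

    mu_a_grid: np.ndarray
    mu_s_grid: np.ndarray
    fx_dc: float
    fx_ac: float
    rd_dc: np.ndarray
    rd_ac: np.ndarray
    n: float = 1.4

    def __post_init__(self) -> None:
        self.mu_a_grid = np.asarray(self.mu_a_grid, dtype=float)
        self.mu_s_grid = np.asarray(self.mu_s_grid, dtype=float)
        self.rd_dc = np.asarray(self.rd_dc, dtype=float)
        self.rd_ac = np.asarray(self.rd_ac, dtype=float)
        shape = (self.mu_a_grid.size, self.mu_s_grid.size)
        if self.rd_dc.shape != shape or self.rd_ac.shape != shape:
            raise ValueError("rd tables must have shape (n_mu_a, n_mu_s)")

    def save(self, path: str | Path) -> None:
        """Serialize as a self-describing long-format CSV table."""
        path = Path(path)
        a_idx, s_idx = np.meshgrid(
            np.arange(self.mu_a_grid.size), np.arange(self.mu_s_grid.size), indexing="ij"
        )
        cols = np.column_stack(
            [
                self.mu_a_grid[a_idx.ravel()],
                self.mu_s_grid[s_idx.ravel()],
                self.rd_dc.ravel(),
                self.rd_ac.ravel(),
            ]
        )
        header = (
            f"# ssopkit LUT v1\n"
            f"# fx_dc={self.fx_dc!r} fx_ac={self.fx_ac!r} n={self.n!r}\n"
            f"# n_mu_a={self.mu_a_grid.size} n_mu_s={self.mu_s_grid.size}\n"
            "mu_a,mu_s_prime,rd_dc,rd_ac"
        )
        np.savetxt(path, cols, delimiter=",", header=header, comments="", fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "LUT":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if "=" in tok:
                            k, v = tok.split("=")
                            meta[k] = float(v)
                elif line.strip() and not line[0].isalpha():
                    break
        data = np.loadtxt(path, delimiter=",", skiprows=4)
        na, ns = int(meta["n_mu_a"]), int(meta["n_mu_s"])
        return cls(
            mu_a_grid=data[::ns, 0],
            mu_s_grid=data[:ns, 1],
            fx_dc=meta["fx_dc"],
            fx_ac=meta["fx_ac"],
            rd_dc=data[:, 2].reshape(na, ns),
            rd_ac=data[:, 3].reshape(na, ns),
            n=meta.get("n", 1.4),
        )


@dataclass
class OpticalPropertyMaps:
    """Per-pixel recovered optical properties with QC flags."""

    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    qc: np.ndarray  # uint8 bitmask: QC_OUT_OF_RANGE, QC_NAN
    wavelength: float | None = None


#: Default LUT grids: log-spaced absorption with headroom around the
#: 0.005-0.05 mm^-1 phantom range, linear reduced scattering around 0.5-3.
DEFAULT_MU_A_GRID = np.geomspace(0.001, 0.1, 201)
DEFAULT_MU_S_GRID = np.linspace(0.1, 5.0, 201)


def build_lut(
    mu_a_grid=None,
    mu_s_grid=None,
    fx_dc: float = 0.0,
    fx_ac: float = 0.2,
    n: float = 1.4,
) -> LUT:
    """Tabulate the forward model on a (mu_a, mu_s_prime) grid.

    Grids must be strictly ascending and ``fx_dc < fx_ac``.  Defaults
    cover absorption 0.001-0.1 mm^-1 (201 log-spaced points) and reduced
    scattering 0.1-5 mm^-1 (201 linear points), a superset of typical
    tissue-mimicking phantom ranges, with the canonical (0, 0.2) mm^-1
    frequency pair.
    """
    mu_a_grid = DEFAULT_MU_A_GRID if mu_a_grid is None else np.asarray(mu_a_grid, float)
    mu_s_grid = DEFAULT_MU_S_GRID if mu_s_grid is None else np.asarray(mu_s_grid, float)
    if mu_a_grid.size == 0 or mu_s_grid.size == 0:
        raise ValueError("LUT grids must be non-empty")
    if mu_a_grid.size > 1 and np.any(np.diff(mu_a_grid) <= 0):
        raise ValueError("mu_a_grid must be strictly ascending")
    if mu_s_grid.size > 1 and np.any(np.diff(mu_s_grid) <= 0):
        raise ValueError("mu_s_grid must be strictly ascending")
    if not fx_dc < fx_ac:
        raise ValueError(f"fx_dc ({fx_dc}) must be < fx_ac ({fx_ac})")
    mu_a = mu_a_grid[:, None]
    mu_s = mu_s_grid[None, :]
    rd_dc = diffuse_reflectance(None, fx_dc, mu_a=mu_a, mu_s_prime=mu_s, n=n)
    rd_ac = diffuse_reflectance(None, fx_ac, mu_a=mu_a, mu_s_prime=mu_s, n=n)
    return LUT(mu_a_grid, mu_s_grid, fx_dc, fx_ac, np.atleast_2d(rd_dc), np.atleast_2d(rd_ac), n)


def _bilinear_and_jacobian(u, v, table_dc, table_ac):
    """Evaluate both tables and their gradients at fractional grid coords."""
    na, ns = table_dc.shape
    i = np.clip(np.floor(u).astype(int), 0, max(na - 2, 0))
    j = np.clip(np.floor(v).astype(int), 0, max(ns - 2, 0))
    s = u - i
    t = v - j
    out = []
    i1 = np.minimum(i + 1, na - 1)
    j1 = np.minimum(j + 1, ns - 1)
    for tab in (table_dc, table_ac):
        f00 = tab[i, j]
        f10 = tab[i1, j]
        f01 = tab[i, j1]
        f11 = tab[i1, j1]
        f = (1 - s) * (1 - t) * f00 + s * (1 - t) * f10 + (1 - s) * t * f01 + s * t * f11
        dfdu = (1 - t) * (f10 - f00) + t * (f11 - f01)
        dfdv = (1 - s) * (f01 - f00) + s * (f11 - f10)
        out.append((f, dfdu, dfdv))
    return out


def _coord_to_value(coord, grid):
    """Fractional grid coordinate -> physical value (piecewise linear)."""
    if grid.size == 1:
        return np.full_like(np.asarray(coord, float), grid[0])
    i = np.clip(np.floor(coord).astype(int), 0, grid.size - 2)
    s = coord - i
    return grid[i] * (1 - s) + grid[i + 1] * s


def invert_optical_properties(rd_dc, rd_ac, lut: LUT, n_iter: int = 12):
    """Per-pixel inversion of (R_DC, R_AC) reflectance maps to (mu_a, mu_s_prime).

    Nearest LUT node (k-d tree in reflectance space) followed by
    Gauss-Newton refinement on the bilinear interpolant of the table.
    Pixels whose reflectance pair falls outside the image of the LUT are
    clamped to the nearest boundary solution and flagged
    ``QC_OUT_OF_RANGE``; non-finite inputs propagate as flagged NaNs.

    Returns
    -------
    OpticalPropertyMaps
        Maps with the same shape as the inputs (scalars allowed).
    """
    rd_dc = np.asarray(rd_dc, dtype=float)
    rd_ac = np.asarray(rd_ac, dtype=float)
    if rd_dc.shape != rd_ac.shape:
        raise ValueError(f"shape mismatch: {rd_dc.shape} vs {rd_ac.shape}")
    shape = rd_dc.shape
    x = rd_dc.ravel()
    y = rd_ac.ravel()
    finite = np.isfinite(x) & np.isfinite(y)

    nodes = np.column_stack([lut.rd_dc.ravel(), lut.rd_ac.ravel()])
    tree = cKDTree(nodes)
    # non-finite pixels iterate on placeholder zeros; they are overwritten
    # with NaN and flagged after refinement
    x = np.where(finite, x, 0.0)
    y = np.where(finite, y, 0.0)
    q = np.column_stack([x, y])
    _, idx = tree.query(q)
    na, ns = lut.rd_dc.shape
    u = (idx // ns).astype(float)
    v = (idx % ns).astype(float)
    # ties toward the lower-mu_a node are inherited from argmin order in the
    # k-d tree (first of equidistant nodes in row-major = lower mu_a index)

    if na > 1 or ns > 1:
        for _ in range(n_iter):
            (f1, a11, a12), (f2, a21, a22) = _bilinear_and_jacobian(u, v, lut.rd_dc, lut.rd_ac)
            r1 = x - f1
            r2 = y - f2
            det = a11 * a22 - a12 * a21
            safe = np.abs(det) > 1e-300
            du = np.where(safe, (r1 * a22 - r2 * a12) / np.where(safe, det, 1.0), 0.0)
            dv = np.where(safe, (r2 * a11 - r1 * a21) / np.where(safe, det, 1.0), 0.0)
            step = np.clip(du, -1.0, 1.0), np.clip(dv, -1.0, 1.0)
            u = np.clip(u + step[0], 0.0, na - 1.0)
            v = np.clip(v + step[1], 0.0, ns - 1.0)

    mu_a = _coord_to_value(u, lut.mu_a_grid)
    mu_s = _coord_to_value(v, lut.mu_s_grid)

    (f1, _, _), (f2, _, _) = _bilinear_and_jacobian(u, v, lut.rd_dc, lut.rd_ac)
    scale = max(float(np.nanmax(np.abs(nodes))), 1e-12)
    resid = np.hypot(x - f1, y - f2) / scale
    at_edge = (u <= 0) | (u >= na - 1) | (v <= 0) | (v >= ns - 1)
    qc = np.zeros(x.shape, dtype=np.uint8)
    qc[at_edge & (resid > 1e-6)] |= QC_OUT_OF_RANGE
    qc[~finite] |= QC_NAN
    mu_a[~finite] = np.nan
    mu_s[~finite] = np.nan

    return OpticalPropertyMaps(
        mu_a=mu_a.reshape(shape), mu_s_prime=mu_s.reshape(shape), qc=qc.reshape(shape)
    )
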