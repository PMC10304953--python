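"""UV-vis quantification of cytochrome redox state and ET feasibility.

A reduced c-type cytochrome shows a Soret band near 420 nm plus alpha/beta
bands at ~550/520 nm; on oxidation the Soret moves to ~409 nm and the
alpha/beta bands bleach.  Treating a spectrum as a linear two-state mixture
of fully reduced and fully oxidized basis spectra, the oxidized fraction f
is the least-squares solution of

    spectrum ~ (1 - f) * reduced + f * oxidized,   f in [0, 1]

which has a closed form (projection onto the difference spectrum, clipped
to the physical interval).  The module also locates Soret maxima with
sub-grid quadratic interpolation, converts absorbance to concentration
(Beer-Lambert), and evaluates the thermodynamic feasibility of electron
transfer from a redox-Bohr donor to a fixed-potential acceptor across pH.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .redox import RedoxBohrParams, model_potential

SORET_WINDOW_NM = (380.0, 440.0)


@dataclass
class Spectrum:
    """Absorbance sampled on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.size != self.absorbance.size:
            raise ValueError("wavelength and absorbance grids differ in length")
        if self.wavelengths.size < 3:
            raise ValueError("need at least 3 spectral points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({"wavelength_nm": self.wavelengths,
                      "absorbance": self.absorbance}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(),
                   df["absorbance"].to_numpy())


@dataclass
class OxidationResult:
    fraction_oxidized: float
    residual_norm: float
    soret_position: float


def soret_peak(spectrum: Spectrum,
               window: tuple[float, float] = SORET_WINDOW_NM) -> float:
    """Soret maximum position (nm) inside ``window``.

    The discrete maximum is refined by fitting a parabola through the three
    surrounding points, giving sub-grid accuracy on a 1-nm grid; a maximum
    at a window edge is returned unrefined.
    """
    lo, hi = window
    wl, ab = spectrum.wavelengths, spectrum.absorbance
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(f"window {window} outside grid "
                         f"({wl[0]:.0f}-{wl[-1]:.0f} nm)")
    mask = (wl >= lo) & (wl <= hi)
    idx = np.flatnonzero(mask)
    imax = idx[np.argmax(ab[idx])]
    if imax in (idx[0], idx[-1]) or imax in (0, wl.size - 1):
        return float(wl[imax])
    x = wl[imax - 1:imax + 2]
    y = ab[imax - 1:imax + 2]
    # vertex of the parabola through the three points (polyfit handles a
    # non-uniform grid); fall back to the grid point when not concave
    coeffs = np.polyfit(x, y, 2)
    if coeffs[0] >= -1e-15:
        return float(wl[imax])
    return float(-coeffs[1] / (2 * coeffs[0]))


def unmix(spectrum: Spectrum, reduced_basis: Spectrum,
          oxidized_basis: Spectrum) -> OxidationResult:
    """Oxidized fraction from two-state linear unmixing.

    Solves min_f || s - [(1-f) r + f o] || with f constrained to [0, 1];
    identical bases are unidentifiable and raise.
    """
    for basis in (reduced_basis, oxidized_basis):
        if not np.array_equal(basis.wavelengths, spectrum.wavelengths):
            raise ValueError("bases must share the spectrum's wavelength grid")
    s = spectrum.absorbance
    r = reduced_basis.absorbance
    o = oxidized_basis.absorbance
    d = o - r
    dd = float(d @ d)
    if dd < 1e-20:
        raise ValueError("reduced and oxidized bases are identical; "
                         "oxidized fraction is unidentifiable")
    f = float(np.clip((s - r) @ d / dd, 0.0, 1.0))
    residual = float(np.linalg.norm(s - ((1 - f) * r + f * o)))
    return OxidationResult(fraction_oxidized=f, residual_norm=residual,
                           soret_position=soret_peak(spectrum))


def beer_lambert_conc(absorbance: float, epsilon: float,
                      path_cm: float = 1.0) -> float:
    """Concentration (M) from A = epsilon * c * l."""
    if epsilon <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    if absorbance < 0:
        warnings.warn("negative absorbance; returning a negative concentration")
    return absorbance / (epsilon * path_cm)


@dataclass
class ETFeasibilityReport:
    """Thermodynamic feasibility of donor -> acceptor electron transfer.

    ``favorable`` marks grid points where the acceptor potential exceeds
    the donor midpoint potential (Delta E > 0, downhill transfer);
    ``crossing_ph`` is the pH where Delta E changes sign, if any in range.
    """

    ph_grid: np.ndarray
    delta_e_mv: np.ndarray
    favorable: np.ndarray
    crossing_ph: float | None
    acceptor_e_mv: float

    @property
    def favorable_ph(self) -> np.ndarray:
        return self.ph_grid[self.favorable]


def et_feasibility(donor: RedoxBohrParams, acceptor_e_mv: float,
                   ph_range: tuple[float, float] = (5.0, 9.0),
                   n_grid: int = 201) -> ETFeasibilityReport:
    """Scan Delta E(pH) = E_acceptor - E_donor(pH) over a pH range.

    For a redox-Bohr donor the midpoint potential falls with pH, so Delta E
    rises; when Delta E changes sign inside the range the unique crossing
    is located by root bisection.
    """
    lo, hi = ph_range
    if not (0.0 <= lo < hi <= 14.0):
        raise ValueError("ph_range must be an increasing pair within 0-14")
    ph = np.linspace(lo, hi, n_grid)
    delta = acceptor_e_mv - model_potential(donor, ph)
    favorable = delta > 0
    crossing = None
    if delta[0] * delta[-1] < 0:
        crossing = float(brentq(
            lambda p: acceptor_e_mv - model_potential(donor, p), lo, hi,
            xtol=1e-10))
    return ETFeasibilityReport(ph_grid=ph, delta_e_mv=delta,
                               favorable=favorable, crossing_ph=crossing,
                               acceptor_e_mv=acceptor_e_mv)
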