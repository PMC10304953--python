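"""Redox-Bohr thermodynamics of proton-coupled electron transfer.

A high-potential iron-sulfur protein (HiPIP) whose reduction is coupled to
the protonation of a nearby group shows a pH-dependent midpoint potential
("redox-Bohr effect").  For a single proton coupled to a single electron the
midpoint potential is

    E_m(pH) = E_alk + (RT ln10 / F) * log10[(1 + 10^(pKa_red - pH))
                                            / (1 + 10^(pKa_ox - pH))]

where ``E_alk`` is the alkaline-limit potential and ``pKa_ox``/``pKa_red``
are the acidity constants of the coupled group in the oxidized and reduced
protein.  Reduction raises the proton affinity, so pKa_red >= pKa_ox; the
total pH-driven potential drop ("Bohr amplitude") is
(RT ln10 / F) * (pKa_red - pKa_ox).

This module provides the model, electrode-reference conversion to the
standard hydrogen electrode (SHE), cyclic-voltammetry midpoint arithmetic,
and a bounded nonlinear least-squares fit with per-parameter confidence
intervals and flags marking estimates pinned at a bound (the usual outcome
when the measured pH window does not bracket a pKa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.constants import R as GAS_CONSTANT
from scipy.constants import physical_constants

FARADAY = physical_constants["Faraday constant"][0]

#: Additive offsets (mV) converting a measured potential to the SHE scale.
REFERENCE_OFFSETS_MV = {
    "SHE": 0.0,
    "AgAgCl_3M_KCl": 210.0,
}

DEFAULT_BOUNDS = {"e_alk": (-500.0, 800.0), "pka": (3.0, 11.0)}
BOUND_FLAG_TOL = 0.05  # pKa units from a bound -> flagged


def nernst_slope_mv(temperature: float = 298.15) -> float:
    """RT ln(10) / F in mV per pH (or per log10) unit.

    59.16 mV at 25 C; computed from the temperature rather than hard-coded
    so that simulated datasets at other temperatures stay consistent.
    """
    return 1000.0 * GAS_CONSTANT * temperature * np.log(10.0) / FARADAY


def to_she(e_mv: float, reference: str) -> float:
    """Convert a potential in mV from the given reference electrode to SHE.

    Ag/AgCl (3 M KCl) potentials convert by adding 210 mV.
    """
    try:
        offset = REFERENCE_OFFSETS_MV[reference]
    except KeyError:
        raise ValueError(
            f"unknown reference electrode {reference!r}; "
            f"known: {sorted(REFERENCE_OFFSETS_MV)}"
        ) from None
    return e_mv + offset


def cv_midpoint(e_pa: float, e_pc: float) -> float:
    """Midpoint potential from anodic/cathodic peak potentials: (E_pa + E_pc)/2.

    Both peaks must be on the same reference scale.
    """
    return 0.5 * (e_pa + e_pc)


@dataclass(frozen=True)
class RedoxBohrParams:
    """Parameters of the one-proton, one-electron redox-Bohr model.

    e_alk      alkaline-limit midpoint potential, mV vs SHE
    pka_ox     pKa of the coupled group in the oxidized protein
    pka_red    pKa of the coupled group in the reduced protein
    temperature  K (sets the Nernst slope)
    n_protons  fixed at 1 in this model
    """

    e_alk: float
    pka_ox: float
    pka_red: float
    temperature: float = 298.15
    n_protons: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.pka_ox < 14.0 and 0.0 < self.pka_red < 14.0):
            raise ValueError("pKa values must lie in (0, 14)")
        if self.pka_red < self.pka_ox - 1e-9:
            raise ValueError(
                "redox-Bohr convention requires pKa_red >= pKa_ox "
                f"(got ox={self.pka_ox}, red={self.pka_red})"
            )
        if not (273.0 <= self.temperature <= 330.0):
            raise ValueError("temperature must be within 273-330 K")
        if self.n_protons != 1:
            raise ValueError("only the single-proton model is supported")


@dataclass(frozen=True)
class RedoxDataPoint:
    """One measured midpoint potential at one pH, on a stated reference."""

    ph: float
    e_mv: float
    reference: str = "SHE"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ph <= 14.0):
            raise ValueError(f"pH {self.ph} outside 0-14")
        if self.reference not in REFERENCE_OFFSETS_MV:
            raise ValueError(f"unknown reference {self.reference!r}")

    def e_she(self) -> float:
        return to_she(self.e_mv, self.reference)


def model_potential(params: RedoxBohrParams, ph):
    """Midpoint potential (mV vs SHE) of the redox-Bohr model at ``ph``.

    Monotone non-increasing in pH when pKa_red > pKa_ox; tends to ``e_alk``
    at high pH and to ``e_alk + slope*(pKa_red - pKa_ox)`` at low pH.
    Accepts a scalar or array pH.
    """
    ph = np.asarray(ph, dtype=float)
    slope = nernst_slope_mv(params.temperature)
    # log10((1+10^(pKa_red-pH)) / (1+10^(pKa_ox-pH))), computed via log1p
    # for stability at pH far below the pKas.
    ln10 = np.log(10.0)
    num = np.log1p(np.exp(ln10 * (params.pka_red - ph))) / ln10
    den = np.log1p(np.exp(ln10 * (params.pka_ox - ph))) / ln10
    out = params.e_alk + slope * (num - den)
    return out if out.ndim else float(out)


def bohr_amplitude(params: RedoxBohrParams) -> float:
    """Total pH-driven potential drop, (RT ln10 / F)*(pKa_red - pKa_ox), in mV."""
    return nernst_slope_mv(params.temperature) * (params.pka_red - params.pka_ox)


@dataclass
class FitResult:
    """Outcome of :func:`fit_redox_bohr`.

    ``ci`` maps parameter name to a 95% interval half-width-based (lo, hi)
    tuple from the Gauss-Newton covariance; ``bound_flags`` maps each pKa to
    ``well_defined``, ``lower_bound`` or ``upper_bound`` depending on whether
    the estimate sits against a box bound (within 0.05 pKa units).
    """

    params: RedoxBohrParams
    rss: float
    ci: dict = field(default_factory=dict)
    bound_flags: dict = field(default_factory=dict)
    n_points: int = 0
    ordering_refit: bool = False


def _initial_guess(ph: np.ndarray, e: np.ndarray, slope: float,
                   bounds: dict) -> np.ndarray:
    """Data-driven starting point: alkaline limit from the high-pH end,
    pKa pair centred on the half-drop pH with separation from the span."""
    order = np.argsort(ph)
    ph_s, e_s = ph[order], e[order]
    e_alk0 = float(np.mean(e_s[-2:]))
    drop = max(float(e_s[0] - e_alk0), 1e-3)
    sep = min(drop / slope, 6.0)
    half = e_alk0 + 0.5 * drop
    mid = float(ph_s[np.argmin(np.abs(e_s - half))])
    lo, hi = bounds["pka"]
    pka_ox0 = float(np.clip(mid - 0.5 * sep, lo + 0.1, hi - 0.2))
    pka_red0 = float(np.clip(mid + 0.5 * sep, pka_ox0 + 0.05, hi - 0.1))
    return np.array([e_alk0, pka_ox0, pka_red0])


def fit_redox_bohr(
    data: list[RedoxDataPoint],
    bounds: dict | None = None,
    init: tuple[float, float, float] | None = None,
    temperature: float = 298.15,
) -> FitResult:
    """Least-squares fit of (E_alk, pKa_ox, pKa_red) to E-pH data.

    Data are converted to the SHE scale before fitting.  Requires at least
    four points spanning more than 0.5 pH units.  If the unconstrained
    optimum violates pKa_red >= pKa_ox, the fit is repeated with the
    ordering enforced (reparameterized separation >= 0) and a warning is
    emitted.  Deterministic given data and starting point.
    """
    if len(data) < 4:
        raise ValueError("need at least 4 data points")
    ph = np.array([d.ph for d in data], dtype=float)
    e = np.array([d.e_she() for d in data], dtype=float)
    if np.ptp(ph) <= 0.5:
        raise ValueError("pH span must exceed 0.5 units")

    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    slope = nernst_slope_mv(temperature)
    x0 = np.asarray(init, dtype=float) if init is not None \
        else _initial_guess(ph, e, slope, bounds)
    lo = np.array([bounds["e_alk"][0], bounds["pka"][0], bounds["pka"][0]])
    hi = np.array([bounds["e_alk"][1], bounds["pka"][1], bounds["pka"][1]])
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    def resid_free(x):
        return _model_raw(x[0], x[1], x[2], ph, slope) - e

    sol = optimize.least_squares(resid_free, x0, bounds=(lo, hi), method="trf")
    if not sol.success:
        raise RuntimeError(
            f"redox-Bohr fit did not converge: {sol.message}; best iterate {sol.x}"
        )
    ordering_refit = False
    if sol.x[2] < sol.x[1]:  # pKa_red < pKa_ox at the optimum
        warnings.warn("pKa ordering violated at optimum; refitting with "
                      "pKa_red = pKa_ox + separation >= 0 constraint")
        ordering_refit = True

        def resid_ord(y):  # y = (e_alk, pka_ox, sep)
            return _model_raw(y[0], y[1], y[1] + y[2], ph, slope) - e

        y0 = np.array([sol.x[0], min(sol.x[1], sol.x[2]), 0.0])
        lo2 = np.array([lo[0], lo[1], 0.0])
        hi2 = np.array([hi[0], hi[1], hi[2] - lo[1]])
        y0 = np.clip(y0, lo2, hi2)
        sol = optimize.least_squares(resid_ord, y0, bounds=(lo2, hi2),
                                     method="trf")
        if not sol.success:
            raise RuntimeError(f"constrained refit failed: {sol.message}")
        x = np.array([sol.x[0], sol.x[1], sol.x[1] + sol.x[2]])
    else:
        x = sol.x

    rss = float(np.sum(sol.fun ** 2))
    params = RedoxBohrParams(float(x[0]), float(min(x[1], x[2])),
                             float(max(x[1], x[2])), temperature)
    ci = _confidence_intervals(x, ph, e, slope, rss)
    flags = {
        "pka_ox": _bound_flag(x[1], bounds["pka"]),
        "pka_red": _bound_flag(x[2], bounds["pka"]),
    }
    # A pKa outside the measured pH window is confounded with E_alk: the
    # likelihood is flat on one side and the estimate is only a one-sided
    # bound.  Detect this by profiling each pKa one unit in each direction.
    for i, name in ((1, "pka_ox"), (2, "pka_red")):
        if flags[name] == "well_defined":
            flags[name] = _profile_flag(x, i, ph, e, slope, rss, bounds)
    return FitResult(params=params, rss=rss, ci=ci, bound_flags=flags,
                     n_points=len(data), ordering_refit=ordering_refit)


def _model_raw(e_alk, pka_ox, pka_red, ph, slope):
    ln10 = np.log(10.0)
    num = np.log1p(np.exp(ln10 * (pka_red - ph))) / ln10
    den = np.log1p(np.exp(ln10 * (pka_ox - ph))) / ln10
    return e_alk + slope * (num - den)


def _profile_flag(x, idx, ph, e, slope, rss_opt, bounds) -> str:
    """Profile-likelihood flatness check for one pKa.

    The probed pKa is fixed at each box bound in turn and the other two
    parameters refitted.  If the residual sum of squares stays within a
    1-dof chi-square threshold (at the fit's noise scale) all the way to a
    bound, the data do not constrain that side: flat up to the upper bound
    means the estimate is only a lower bound; flat down to the lower bound,
    only an upper bound.  This is the typical outcome when a pKa lies
    outside the measured pH window.
    """
    n = len(ph)
    s2 = max(rss_opt / max(n - 3, 1), 1e-12)
    threshold = 3.84 * s2  # chi2(1, 0.95)
    lo_pka, hi_pka = bounds["pka"]
    free = [j for j in (0, 1, 2) if j != idx]
    lo_free = np.array([bounds["e_alk"][0] if j == 0 else lo_pka for j in free])
    hi_free = np.array([bounds["e_alk"][1] if j == 0 else hi_pka for j in free])

    def profile_rss(fixed_value: float) -> float:
        def resid(y):
            full = np.empty(3)
            full[idx] = fixed_value
            full[free[0]], full[free[1]] = y
            return _model_raw(full[0], full[1], full[2], ph, slope) - e

        y0 = np.clip(x[free], lo_free + 1e-9, hi_free - 1e-9)
        sol = optimize.least_squares(resid, y0, bounds=(lo_free, hi_free),
                                     method="trf")
        return float(np.sum(sol.fun ** 2))

    flat_up = profile_rss(hi_pka) - rss_opt < threshold
    flat_down = profile_rss(lo_pka) - rss_opt < threshold
    if flat_up and not flat_down:
        return "lower_bound"
    if flat_down and not flat_up:
        return "upper_bound"
    return "well_defined"


def _bound_flag(value: float, bound: tuple[float, float]) -> str:
    if value <= bound[0] + BOUND_FLAG_TOL:
        return "lower_bound"
    if value >= bound[1] - BOUND_FLAG_TOL:
        return "upper_bound"
    return "well_defined"


def _confidence_intervals(x, ph, e, slope, rss):
    """95% Wald intervals from the numerical Jacobian at the optimum."""
    names = ("e_alk", "pka_ox", "pka_red")
    n, p = len(ph), 3
    eps = np.array([1e-3, 1e-5, 1e-5])
    jac = np.empty((n, p))
    for j in range(p):
        xp, xm = x.copy(), x.copy()
        xp[j] += eps[j]
        xm[j] -= eps[j]
        jac[:, j] = (_model_raw(xp[0], xp[1], xp[2], ph, slope)
                     - _model_raw(xm[0], xm[1], xm[2], ph, slope)) / (2 * eps[j])
    dof = max(n - p, 1)
    s2 = rss / dof
    try:
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        se = np.full(p, np.nan)
    return {nm: (float(x[i] - 1.96 * se[i]), float(x[i] + 1.96 * se[i]))
            for i, nm in enumerate(names)}


def et_driving_force(donor: RedoxBohrParams, acceptor_e_mv: float, ph):
    """Delta E (mV) = acceptor potential minus donor midpoint potential at pH.

    Positive values mean electron transfer from the donor to the acceptor is
    thermodynamically downhill.
    """
    return acceptor_e_mv - model_potential(donor, ph)
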