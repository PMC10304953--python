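"""Temperature dependence of paramagnetic hyperfine shifts.

The 4Fe-4S cluster of a reduced HiPIP is diamagnetic in its ground state
but paramagnetic excited states are thermally populated.  Hyperfine-shifted
1H signals from the cluster-coordinating cysteine beta-CH2 protons (outside
the ~0-15 ppm diamagnetic envelope) therefore move with temperature:

* Curie behaviour: the shift relaxes toward the diamagnetic position as T
  rises;
* anti-Curie behaviour: the shift moves further away (downfield signals
  shift further downfield), signalling growing population of paramagnetic
  excited states.

Each signal is fitted with an ordinary least-squares line delta = a + b*T
(a 1/T regression is available as an option) and classified from the slope
sign; slope sets from two proteins are compared to decide whether the
cluster electronic structure is the same.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

FLAT_THRESHOLD_DEFAULT = 0.005  # ppm/K
DIAMAGNETIC_ENVELOPE_PPM = 15.0


@dataclass
class HyperfineSeries:
    """(T, delta) points for one hyperfine-shifted signal (label A, B, ...)."""

    signal_label: str
    temperatures: np.ndarray
    shifts: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.temperatures.size != self.shifts.size:
            raise ValueError("temperature and shift arrays differ in length")
        if self.temperatures.size < 3:
            raise ValueError("need at least 3 temperature points")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def is_hyperfine(self, envelope: float = DIAMAGNETIC_ENVELOPE_PPM) -> bool:
        """True when the signal lies outside the diamagnetic envelope."""
        return bool(np.all(np.abs(self.shifts) > envelope))


@dataclass
class TempDepFit:
    signal_label: str
    slope: float          # ppm/K (or ppm*K if against_inverse_t)
    intercept: float      # ppm
    r_squared: float
    classification: str   # curie | anti_curie | flat
    against_inverse_t: bool = False


def fit_tempdep(series: HyperfineSeries,
                flat_threshold: float = FLAT_THRESHOLD_DEFAULT,
                against_inverse_t: bool = False) -> TempDepFit:
    """OLS line through one signal's (T, delta) points, with classification.

    For downfield signals (delta > 0) a positive slope vs T is anti-Curie
    and a negative slope Curie; the convention inverts for upfield signals
    (delta < 0), where anti-Curie means moving further upfield.  Slopes
    within ``flat_threshold`` of zero are classified flat.  With
    ``against_inverse_t`` the regressor is 1/T and the sign logic flips
    (a shift growing with T shrinks with 1/T).
    """
    x = 1.0 / series.temperatures if against_inverse_t else series.temperatures
    res = stats.linregress(x, series.shifts)
    r2 = float(res.rvalue ** 2) if not np.isnan(res.rvalue) else 1.0

    upfield = float(np.mean(series.shifts)) < 0.0
    # "away from the diamagnetic position as T rises" in the vs-T convention:
    eff = float(res.slope)
    if against_inverse_t:
        eff = -eff
    if upfield:
        eff = -eff
    if eff > flat_threshold:
        cls = "anti_curie"
    elif eff < -flat_threshold:
        cls = "curie"
    else:
        cls = "flat"
    return TempDepFit(signal_label=series.signal_label, slope=float(res.slope),
                      intercept=float(res.intercept), r_squared=r2,
                      classification=cls, against_inverse_t=against_inverse_t)


@dataclass
class SlopeComparison:
    mean_slope_a: float
    mean_slope_b: float
    ratio: float
    classifications_agree: bool
    verdict: str  # similar | not_similar | not_comparable
    rel_tol: float


def compare_slopes(fits_a: list[TempDepFit], fits_b: list[TempDepFit],
                   rel_tol: float = 0.25) -> SlopeComparison:
    """Compare two proteins' hyperfine slope sets.

    Verdict is ``similar`` iff the ratio of mean slopes is within
    ``rel_tol`` of 1 and all signals of both proteins share one
    classification; mixed classifications within either protein give
    ``not_comparable``.  Equal slopes with equal (anti-)Curie behaviour
    indicate the same cluster electronic structure in the two proteins.
    """
    if not fits_a or not fits_b:
        raise ValueError("both fit lists must be non-empty")
    cls_a = {f.classification for f in fits_a}
    cls_b = {f.classification for f in fits_b}
    ma = float(np.mean([f.slope for f in fits_a]))
    mb = float(np.mean([f.slope for f in fits_b]))
    ratio = ma / mb if mb != 0 else np.inf
    if len(cls_a) > 1 or len(cls_b) > 1:
        return SlopeComparison(ma, mb, ratio, False, "not_comparable", rel_tol)
    agree = cls_a == cls_b
    similar = agree and np.isfinite(ratio) and abs(ratio - 1.0) <= rel_tol
    return SlopeComparison(ma, mb, ratio, agree,
                           "similar" if similar else "not_similar", rel_tol)
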