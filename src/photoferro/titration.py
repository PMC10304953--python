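"""Chemical-shift-perturbation (CSP) mapping of protein-protein interfaces.

Adding an unlabeled binding partner to a 15N-labeled protein perturbs the
amide 1H/15N resonances of residues at (or allosterically coupled to) the
interface.  Two signatures are scored per residue between a free and a
bound HSQC peak list:

* a combined chemical-shift change d_comb = sqrt(dH^2 + (alpha*dN)^2)
  (Williamson weighting, alpha = 0.14, 0.20 for glycine), and
* an intensity ratio I_bound / I_free reporting exchange line broadening.

Residues are classified ``shifted`` / ``broadened`` / ``shifted+broadened``
/ ``unaffected`` against distribution-based thresholds (mean +/- k*sd over
all matched residues, k = 1 by default).  A residue whose bound peak has
vanished is classified ``missing`` and treated downstream as extreme
broadening.  Residues appearing as two bound peaks (slow-exchange
conformational doubling) are detected separately.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALPHA_DEFAULT = 0.14
ALPHA_GLYCINE = 0.20

CLASSES = ("shifted", "broadened", "shifted+broadened", "unaffected", "missing")


@dataclass
class Peak:
    residue_number: int
    residue_type: str
    delta_H: float
    delta_N: float
    height: float
    linewidth_H: float | None = None


@dataclass
class PeakList:
    """An assigned 2D 1H-15N peak list for one titration condition.

    ``condition`` is ``free`` or ``bound``; ``ligand_ratio`` and
    ``illumination`` (dark/light) are metadata only.
    """

    protein_id: str
    condition: str
    entries: list[Peak] = field(default_factory=list)
    ligand_ratio: float | None = None
    illumination: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("free", "bound"):
            raise ValueError("condition must be 'free' or 'bound'")
        for p in self.entries:
            if p.height <= 0:
                raise ValueError(
                    f"residue {p.residue_number}: peak height must be positive")
        counts = Counter(p.residue_number for p in self.entries)
        over = [r for r, c in counts.items() if c > 2]
        if over:
            raise ValueError(
                f"more than two peaks assigned to residue(s) {sorted(over)}")
        for p in self.entries:
            if not (5.0 <= p.delta_H <= 13.0) or not (100.0 <= p.delta_N <= 135.0):
                warnings.warn(
                    f"residue {p.residue_number}: shifts ({p.delta_H:.2f}, "
                    f"{p.delta_N:.2f}) outside the typical amide region")
                break

    def by_residue(self) -> dict[int, list[Peak]]:
        out: dict[int, list[Peak]] = {}
        for p in self.entries:
            out.setdefault(p.residue_number, []).append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.residue_number, p.residue_type, p.delta_H, p.delta_N,
              p.height, p.linewidth_H) for p in self.entries],
            columns=["residue_number", "residue_type", "delta_H_ppm",
                     "delta_N_ppm", "height", "linewidth_H_hz"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, protein_id: str = "", condition: str = "free",
                 **meta) -> "PeakList":
        df = pd.read_csv(path)
        entries = [
            Peak(int(r.residue_number), str(r.residue_type),
                 float(r.delta_H_ppm), float(r.delta_N_ppm), float(r.height),
                 None if pd.isna(r.linewidth_H_hz) else float(r.linewidth_H_hz))
            for r in df.itertuples()
        ]
        return cls(protein_id=protein_id, condition=condition,
                   entries=entries, **meta)


def combined_shift(dH, dN, alpha: float = ALPHA_DEFAULT):
    """Weighted combined 1H/15N shift change sqrt(dH^2 + (alpha*dN)^2), ppm."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return np.sqrt(np.square(dH) + np.square(alpha * np.asarray(dN, float)))


def match_peaks(free: PeakList, bound: PeakList) -> pd.DataFrame:
    """Pair free/bound peaks by residue number.

    Returns one row per free residue with columns ``dH``, ``dN``,
    ``height_free``, ``height_bound``, ``linewidth_free/bound`` and
    ``status`` in {paired, missing, doubled}.  For a doubled residue the
    major (taller) bound peak provides the shift columns.  Residues with
    more than two bound peaks raise at PeakList construction.
    """
    free_map = free.by_residue()
    bound_map = bound.by_residue()
    for r, peaks in free_map.items():
        if len(peaks) > 1:
            raise ValueError(f"free list has multiple peaks for residue {r}")
    rows = []
    for r in sorted(free_map):
        f = free_map[r][0]
        bpeaks = bound_map.get(r, [])
        if not bpeaks:
            rows.append((r, f.residue_type, np.nan, np.nan, f.height, np.nan,
                         f.linewidth_H, np.nan, "missing"))
            continue
        status = "doubled" if len(bpeaks) == 2 else "paired"
        b = max(bpeaks, key=lambda p: p.height)
        height_b = sum(p.height for p in bpeaks)
        rows.append((r, f.residue_type, b.delta_H - f.delta_H,
                     b.delta_N - f.delta_N, f.height, height_b,
                     f.linewidth_H, b.linewidth_H, status))
    return pd.DataFrame(rows, columns=[
        "residue_number", "residue_type", "dH", "dN", "height_free",
        "height_bound", "linewidth_free", "linewidth_bound", "status"])


@dataclass
class PerturbationTable:
    """Per-residue perturbation metrics and classification, sorted by residue."""

    table: pd.DataFrame
    alpha: float
    k: float
    thresholds: dict

    def residues_in(self, *classes: str) -> list[int]:
        mask = self.table["classification"].isin(classes)
        return [int(r) for r in self.table.loc[mask, "residue_number"]]

    @property
    def shifted(self) -> set[int]:
        return set(self.residues_in("shifted", "shifted+broadened"))

    @property
    def broadened(self) -> set[int]:
        return set(self.residues_in("broadened", "shifted+broadened"))

    @property
    def missing(self) -> set[int]:
        return set(self.residues_in("missing"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def classify_perturbations(
    paired: pd.DataFrame,
    alpha: float = ALPHA_DEFAULT,
    k: float = 1.0,
    use_linewidths: bool = False,
    glycine_alpha: float = ALPHA_GLYCINE,
) -> PerturbationTable:
    """Classify residues from a matched free/bound table.

    shifted:   d_comb > mean(d_comb) + k*sd(d_comb)
    broadened: I_bound/I_free < mean(ratio) - k*sd(ratio)
               (or a symmetric rule on linewidth increase when
               ``use_linewidths`` and linewidths are present)

    Statistics are taken over all matched residues without iterative
    pruning.  If d_comb has zero variance every residue is classified
    unaffected and a warning is emitted.  Missing residues keep the
    ``missing`` label (extreme broadening).
    """
    if len(paired) < 5:
        raise ValueError("need at least 5 paired residues for distribution "
                         "thresholds")
    df = paired.sort_values("residue_number").reset_index(drop=True).copy()
    alpha_vec = np.where(df["residue_type"].str.upper() == "G",
                         glycine_alpha, alpha)
    matched = df["status"].isin(["paired", "doubled"])
    # per-residue alpha (glycine gets its own weight)
    d_comb = np.sqrt(df["dH"].to_numpy(float) ** 2
                     + (alpha_vec * df["dN"].to_numpy(float)) ** 2)
    df["d_comb"] = np.where(matched, d_comb, np.nan)
    df["intensity_ratio"] = np.where(
        matched, df["height_bound"] / df["height_free"], np.nan)

    dc = df.loc[matched, "d_comb"].to_numpy(float)
    ir = df.loc[matched, "intensity_ratio"].to_numpy(float)
    shift_cut = float(np.mean(dc) + k * np.std(dc))
    broad_cut = float(np.mean(ir) - k * np.std(ir))

    zero_var = np.std(dc) < 1e-15
    if zero_var:
        warnings.warn("zero variance in combined shifts; all residues "
                      "classified unaffected")

    lw_cut = None
    have_lw = (use_linewidths
               and df.loc[matched, "linewidth_free"].notna().all()
               and df.loc[matched, "linewidth_bound"].notna().all())
    if have_lw:
        dlw = (df.loc[matched, "linewidth_bound"]
               - df.loc[matched, "linewidth_free"]).to_numpy(float)
        lw_cut = float(np.mean(dlw) + k * np.std(dlw))

    def label(row):
        if row["status"] == "missing":
            return "missing"
        if zero_var:
            return "unaffected"
        is_shift = row["d_comb"] > shift_cut
        if have_lw:
            is_broad = (row["linewidth_bound"] - row["linewidth_free"]) > lw_cut
        else:
            is_broad = row["intensity_ratio"] < broad_cut
        if is_shift and is_broad:
            return "shifted+broadened"
        if is_shift:
            return "shifted"
        if is_broad:
            return "broadened"
        return "unaffected"

    df["classification"] = df.apply(label, axis=1)
    thresholds = {"shift_cut": shift_cut, "broaden_cut": broad_cut,
                  "linewidth_cut": lw_cut, "k": k, "alpha": alpha,
                  "rule": "linewidths" if have_lw else "heights"}
    return PerturbationTable(table=df, alpha=alpha, k=k, thresholds=thresholds)


def detect_peak_doubling(bound: PeakList, tol_H: float = 0.02,
                         tol_N: float = 0.1) -> dict[int, float]:
    """Residues observed as two resolved bound peaks (slow-exchange doubling).

    Returns {residue: minor/major height ratio in (0, 1]} for residues whose
    two peaks are separated by more than ``tol_H`` ppm in 1H *or* ``tol_N``
    ppm in 15N; pairs within both tolerances are treated as one peak.
    """
    if tol_H <= 0 or tol_N <= 0:
        raise ValueError("tolerances must be positive")
    out: dict[int, float] = {}
    for r, peaks in bound.by_residue().items():
        if len(peaks) != 2:
            continue
        a, b = peaks
        if abs(a.delta_H - b.delta_H) > tol_H or abs(a.delta_N - b.delta_N) > tol_N:
            lo, hi = sorted((a.height, b.height))
            out[r] = lo / hi
    return out


def interacting_set(table: PerturbationTable) -> list[int]:
    """Union of shifted, broadened and missing residues, ascending.

    Missing bound peaks count as broadening beyond detection, so they are
    part of the reported interface.
    """
    residues = table.shifted | table.broadened | table.missing
    return sorted(residues)
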