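"""Seeded synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline has a generator here that emulates
its experimental input and records exactly what was planted, so that each
analysis can be scored as a recovery problem:

* HSQC titration pairs with planted shifted / broadened / doubled residues;
* E-pH midpoint-potential datasets from a redox-Bohr parameter set;
* anti-Curie (or Curie) hyperfine temperature series;
* toy PDB structures - a smooth CA trace carrying a 4-atom SF4 cluster
  placed against a chosen surface patch;
* two-state cytochrome UV-vis spectra series with known oxidized fractions.

All randomness flows from one integer seed per scenario through
``numpy.random.default_rng``; identical seeds reproduce identical outputs.
Zero-noise outputs satisfy the generating model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .redox import RedoxBohrParams, RedoxDataPoint, model_potential
from .spectra import Spectrum
from .structure import Atom, StructureModel
from .tempdep import HyperfineSeries
from .titration import ALPHA_DEFAULT, Peak, PeakList, combined_shift

# ---------------------------------------------------------------------------
# Synthetic HiPIP-like sequences.
#
# PIOC_LIKE_SEQUENCE is a synthetic 54-residue stand-in for a small HiPIP:
# it is NOT the real PioC sequence (which is not reproduced here), but it
# plants the experimentally named residue types at the named 1-based
# positions (K4, N17, A19, K20, R21, C22, C25, R26, C34, N44, R48, K53)
# plus a fourth cluster cysteine at 47.
PIOC_LIKE_SEQUENCE = "MSEKLVTDGAEVSLDGNSAKRCSGCREFVPGQSCTDLAGISEGNWDCRVLAEKA"

#: Residues reported to respond to each binding partner (1-based positions
#: in the PioC-like sequence): used as planted defaults.
PIOA_SHIFTED = (19, 25, 34)
PIOA_BROADENED = (4, 21, 26, 44, 53)
LHRC_SHIFTED = (19, 20, 48)
LHRC_BROADENED = (17, 19, 22)

#: Interface residues found not conserved in the paralogue comparison.
NONCONSERVED_INTERFACE = (17, 19, 20, 44, 48, 53)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic child stream: one global seed, split per generator.

    The stream key is derived from the generator name (stable across
    processes, unlike the built-in salted ``hash``).
    """
    key = int.from_bytes(stream.encode(), "little") % (2 ** 31)
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


# ---------------------------------------------------------------------------
# HSQC titration pairs


@dataclass
class TitrationScenario:
    """Planted perturbations for one free/bound HSQC peak-list pair.

    ``shifted`` maps residue -> (dH_ppm, dN_ppm); ``broadened`` maps
    residue -> intensity attenuation factor in (0, 1); ``doubled`` maps
    residue -> (sep_H_ppm, sep_N_ppm, minor/major intensity ratio).
    """

    residues: list[tuple[int, str]] = field(
        default_factory=lambda: [(i + 1, aa) for i, aa in
                                 enumerate(PIOC_LIKE_SEQUENCE)])
    shifted: dict[int, tuple[float, float]] = field(default_factory=dict)
    broadened: dict[int, float] = field(default_factory=dict)
    doubled: dict[int, tuple[float, float, float]] = field(default_factory=dict)
    noise_sigma_H: float = 0.0
    noise_sigma_N: float = 0.0
    noise_sigma_I: float = 0.0
    seed: int = 0
    protein_id: str = "synthetic-hipip"
    ligand_id: str = "ligand"

    def __post_init__(self) -> None:
        numbers = {n for n, _ in self.residues}
        for name, keys in (("shifted", self.shifted),
                           ("broadened", self.broadened),
                           ("doubled", self.doubled)):
            extra = set(keys) - numbers
            if extra:
                raise ValueError(f"{name} set not a subset of residues: "
                                 f"{sorted(extra)}")
        if any(not (0.0 < a < 1.0) for a in self.broadened.values()):
            raise ValueError("attenuation factors must lie in (0, 1)")
        if min(self.noise_sigma_H, self.noise_sigma_N, self.noise_sigma_I) < 0:
            raise ValueError("noise sigmas must be non-negative")

    # -- factory scenarios reproducing the reported interface maps ---------
    @classmethod
    def pioa_interface(cls, noise_sigma_H: float = 0.0,
                       noise_sigma_N: float = 0.0,
                       noise_sigma_I: float = 0.0, seed: int = 0,
                       shift_H: float = 0.06, shift_N: float = 0.35,
                       attenuation: float = 0.4) -> "TitrationScenario":
        """Scenario planting the PioA-binding signature: shifts at A19, C25,
        C34 and broadening at K4, R21, R26, N44, K53."""
        return cls(
            shifted={r: (shift_H, shift_N) for r in PIOA_SHIFTED},
            broadened={r: attenuation for r in PIOA_BROADENED},
            noise_sigma_H=noise_sigma_H, noise_sigma_N=noise_sigma_N,
            noise_sigma_I=noise_sigma_I, seed=seed, ligand_id="PioA-like")

    @classmethod
    def lhrc_interface(cls, noise_sigma_H: float = 0.0,
                       noise_sigma_N: float = 0.0,
                       noise_sigma_I: float = 0.0, seed: int = 0,
                       shift_H: float = 0.06, shift_N: float = 0.35,
                       attenuation: float = 0.4) -> "TitrationScenario":
        """Scenario planting the LH-RC-binding signature: shifts at A19,
        K20, R48 and broadening at N17, A19, C22 (A19 both)."""
        return cls(
            shifted={r: (shift_H, shift_N) for r in LHRC_SHIFTED},
            broadened={r: attenuation for r in LHRC_BROADENED},
            noise_sigma_H=noise_sigma_H, noise_sigma_N=noise_sigma_N,
            noise_sigma_I=noise_sigma_I, seed=seed, ligand_id="LH-RC-like")


def gen_titration_pair(scenario: TitrationScenario
                       ) -> tuple[PeakList, PeakList, dict]:
    """Free and bound peak lists plus the planted ground-truth record.

    Free-state peak positions are drawn once (seeded) in the amide region;
    the bound list applies the planted shifts, attenuations and doublings,
    then adds Gaussian noise (bound list only - the free list is the
    reference acquisition).  ``truth`` records the planted memberships and
    a ``recovery_uncertain`` flag when a planted combined shift falls below
    three times the combined noise floor.
    """
    rng = _rng(scenario.seed, "titration")
    free_entries, bound_entries = [], []
    for number, aa in scenario.residues:
        dh = float(rng.uniform(6.5, 10.0))
        dn = float(rng.uniform(105.0, 130.0))
        h = float(rng.uniform(0.8e5, 1.2e5))
        free_entries.append(Peak(number, aa, dh, dn, h))

        bh, bn, bheight = dh, dn, h
        if number in scenario.shifted:
            sh, sn = scenario.shifted[number]
            bh, bn = bh + sh, bn + sn
        if number in scenario.broadened:
            bheight *= scenario.broadened[number]

        def noisy(x, sigma):
            return x + float(rng.normal(0.0, sigma)) if sigma > 0 else x

        if number in scenario.doubled:
            sep_h, sep_n, ratio = scenario.doubled[number]
            major = bheight / (1.0 + ratio)
            minor = bheight * ratio / (1.0 + ratio)
            for pos_sign, height in ((+0.5, major), (-0.5, minor)):
                bound_entries.append(Peak(
                    number, aa,
                    noisy(bh + pos_sign * sep_h, scenario.noise_sigma_H),
                    noisy(bn + pos_sign * sep_n, scenario.noise_sigma_N),
                    height * (1.0 + (rng.normal(0.0, scenario.noise_sigma_I)
                                     if scenario.noise_sigma_I > 0 else 0.0))))
        else:
            bound_entries.append(Peak(
                number, aa,
                noisy(bh, scenario.noise_sigma_H),
                noisy(bn, scenario.noise_sigma_N),
                bheight * (1.0 + (rng.normal(0.0, scenario.noise_sigma_I)
                                  if scenario.noise_sigma_I > 0 else 0.0))))

    free = PeakList(protein_id=scenario.protein_id, condition="free",
                    entries=free_entries)
    bound = PeakList(protein_id=scenario.protein_id, condition="bound",
                     entries=bound_entries, ligand_ratio=1.0)

    noise_floor = combined_shift(scenario.noise_sigma_H,
                                 scenario.noise_sigma_N, ALPHA_DEFAULT)
    uncertain = any(
        combined_shift(sh, sn, ALPHA_DEFAULT) < 3.0 * noise_floor
        for sh, sn in scenario.shifted.values()) if scenario.shifted else False
    truth = {
        "shifted": sorted(scenario.shifted),
        "broadened": sorted(scenario.broadened),
        "doubled": sorted(scenario.doubled),
        "shift_magnitudes": {str(k): list(v)
                             for k, v in scenario.shifted.items()},
        "attenuations": {str(k): v for k, v in scenario.broadened.items()},
        "doubling": {str(k): list(v) for k, v in scenario.doubled.items()},
        "recovery_uncertain": bool(uncertain),
        "seed": scenario.seed,
    }
    return free, bound, truth


# ---------------------------------------------------------------------------
# Redox-Bohr E-pH datasets


@dataclass
class RedoxScenario:
    """E-pH simulation: replicate noisy measurements of a redox-Bohr curve."""

    params: RedoxBohrParams
    ph_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(4.0, 10.01, 0.2), 2))
    noise_sigma: float = 3.0   # mV, instrument-level scatter
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.ph_grid = np.asarray(self.ph_grid, dtype=float)
        if self.ph_grid.size == 0:
            raise ValueError("ph_grid must be non-empty")
        if np.any(np.diff(self.ph_grid) <= 0):
            raise ValueError("ph_grid must be strictly increasing")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @classmethod
    def pioc_like(cls, e_alk: float = 330.0, **kw) -> "RedoxScenario":
        """Small redox-Bohr effect: pKa_ox 7.6, pKa_red 8.0."""
        return cls(params=RedoxBohrParams(e_alk, 7.6, 8.0), **kw)

    @classmethod
    def rpal4085_like(cls, e_alk: float = 380.0, **kw) -> "RedoxScenario":
        """Pronounced redox-Bohr effect: pKa_ox 5.5, pKa_red 8.2."""
        return cls(params=RedoxBohrParams(e_alk, 5.5, 8.2), **kw)

    @classmethod
    def measured_window(cls, params: RedoxBohrParams, **kw) -> "RedoxScenario":
        """Emulate a protein-film voltammetry campaign: midpoints at 8 pH
        values across the experimentally accessible window 6.0-8.1, with
        8 mV scatter (typical film-voltammetry midpoint reproducibility)."""
        kw.setdefault("ph_grid", np.round(np.arange(6.0, 8.11, 0.3), 2))
        kw.setdefault("noise_sigma", 8.0)
        return cls(params=params, **kw)


def gen_redox_dataset(scenario: RedoxScenario) -> list[list[RedoxDataPoint]]:
    """Replicated E-pH datasets: E = model + N(0, sigma), reported vs SHE."""
    rng = _rng(scenario.seed, "redox")
    curve = model_potential(scenario.params, scenario.ph_grid)
    replicates = []
    for _ in range(scenario.n_replicates):
        noise = (rng.normal(0.0, scenario.noise_sigma, scenario.ph_grid.size)
                 if scenario.noise_sigma > 0 else np.zeros(scenario.ph_grid.size))
        replicates.append([
            RedoxDataPoint(float(p), float(e + n), "SHE")
            for p, e, n in zip(scenario.ph_grid, np.atleast_1d(curve), noise)])
    return replicates


# ---------------------------------------------------------------------------
# Hyperfine temperature series


def gen_hyperfine_series(slopes, intercepts, t_grid, noise_sigma: float = 0.0,
                         seed: int = 0) -> list[HyperfineSeries]:
    """Linear delta(T) = intercept + slope*T + N(0, sigma) series.

    Signals are labelled A, B, C, ... in order.  Temperatures must lie in
    273-330 K (the practical range for aqueous protein NMR) and at least
    two must be given.
    """
    slopes = np.asarray(slopes, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if slopes.size != intercepts.size:
        raise ValueError("slopes and intercepts differ in length")
    if t_grid.size < 2:
        raise ValueError("need at least 2 temperatures")
    if np.any(t_grid < 273.0) or np.any(t_grid > 330.0):
        raise ValueError("temperatures must lie within 273-330 K")
    rng = _rng(seed, "tempdep")
    out = []
    for i, (b, a) in enumerate(zip(slopes, intercepts)):
        label = chr(ord("A") + i)
        delta = a + b * t_grid
        if noise_sigma > 0:
            delta = delta + rng.normal(0.0, noise_sigma, t_grid.size)
        out.append(HyperfineSeries(signal_label=label,
                                   temperatures=t_grid.copy(), shifts=delta))
    return out


# ---------------------------------------------------------------------------
# Toy structures

HELIX_RADIUS = 8.0       # A
HELIX_RISE = 1.5         # A per residue
HELIX_STEP_DEG = 25.2    # deg per residue -> CA-CA ~3.8 A
CLUSTER_OFFSET = 3.5     # A, radially outward of the patch centroid


def gen_toy_structure(n_residues: int, patch_residues,
                      seed: int = 0) -> StructureModel:
    """Toy protein: CA + CB trace on a gentle helix with an SF4 heterogroup.

    The 4-atom cluster (HETATM, residue SF4) is placed just outside the
    backbone at the centroid of ``patch_residues``, so a contiguous-ish
    patch is guaranteed to be the cluster's nearest residues.  Geometry:
    helix radius 8 A, 25.2 deg/residue, 1.5 A rise (CA-CA ~3.8 A); CB
    proxies sit 1.5 A radially outward of each CA.  A small seeded jitter
    (0.05 A) avoids exact degeneracies.
    """
    if n_residues < 8:
        raise ValueError("need at least 8 residues")
    patch = sorted(set(int(r) for r in patch_residues))
    if any(r < 1 or r > n_residues for r in patch):
        raise ValueError("patch_residues must lie within 1..n_residues")
    rng = _rng(seed, "structure")
    step = np.deg2rad(HELIX_STEP_DEG)
    atoms: list[Atom] = []
    ca_positions = {}
    serial = 1
    for i in range(1, n_residues + 1):
        theta = (i - 1) * step
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = HELIX_RADIUS * radial + np.array([0.0, 0.0, HELIX_RISE * (i - 1)])
        ca = ca + rng.normal(0.0, 0.05, 3)
        cb = ca + 1.5 * radial
        ca_positions[i] = ca
        for name, pos in (("CA", ca), ("CB", cb)):
            atoms.append(Atom(serial=serial, atom_name=name,
                              residue_name="ALA", chain_id="A",
                              residue_number=i, x=round(float(pos[0]), 3),
                              y=round(float(pos[1]), 3),
                              z=round(float(pos[2]), 3),
                              element="C", record="ATOM"))
            serial += 1
    centroid = np.mean([ca_positions[r] for r in patch], axis=0)
    outward = centroid - np.array([0.0, 0.0, centroid[2]])
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
    center = centroid + CLUSTER_OFFSET * outward
    # 2.7 A-edge tetrahedron: alternating Fe/S corners of a cube
    half = 2.7 / np.sqrt(2.0) / 2.0
    corners = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) * half
    for j, (elem, corner) in enumerate(zip(("FE", "S", "FE", "S"), corners)):
        pos = center + corner
        atoms.append(Atom(serial=serial, atom_name=f"{elem}{j + 1}",
                          residue_name="SF4", chain_id="A",
                          residue_number=n_residues + 1,
                          x=round(float(pos[0]), 3), y=round(float(pos[1]), 3),
                          z=round(float(pos[2]), 3), element=elem,
                          record="HETATM"))
        serial += 1
    return StructureModel(atoms=atoms)


# ---------------------------------------------------------------------------
# UV-vis two-state spectra

#: (center nm, amplitude, sigma nm) Gaussian bands of the basis spectra:
#: reduced cytochrome c-type - Soret 420 plus beta 520 / alpha 550;
#: oxidized - Soret at 409, alpha/beta bleached.
REDUCED_BANDS = ((420.0, 1.00, 9.0), (520.0, 0.12, 9.0), (550.0, 0.16, 7.0))
OXIDIZED_BANDS = ((409.0, 0.85, 11.0),)


def _bands_spectrum(wavelengths: np.ndarray, bands) -> np.ndarray:
    ab = np.zeros_like(wavelengths, dtype=float)
    for center, amp, sigma in bands:
        ab += amp * np.exp(-0.5 * ((wavelengths - center) / sigma) ** 2)
    return ab


def default_wavelength_grid() -> np.ndarray:
    """250-700 nm at 1 nm, the usual cuvette scan range."""
    return np.arange(250.0, 700.0 + 0.5, 1.0)


def reduced_basis(wavelengths: np.ndarray | None = None) -> Spectrum:
    wl = default_wavelength_grid() if wavelengths is None else \
        np.asarray(wavelengths, float)
    return Spectrum(wl, _bands_spectrum(wl, REDUCED_BANDS))


def oxidized_basis(wavelengths: np.ndarray | None = None) -> Spectrum:
    wl = default_wavelength_grid() if wavelengths is None else \
        np.asarray(wavelengths, float)
    return Spectrum(wl, _bands_spectrum(wl, OXIDIZED_BANDS))


def gen_spectra_series(fractions, band_params=None, noise_sigma: float = 0.0,
                       seed: int = 0,
                       wavelengths: np.ndarray | None = None
                       ) -> tuple[list[Spectrum], dict]:
    """Linear mixtures (1-f)*reduced + f*oxidized with optional noise.

    ``fractions`` are oxidized fractions in [0, 1]; ``band_params`` may
    override the (reduced, oxidized) band tuples.  Returns the spectra and
    a truth record of the planted fractions.
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(fr < 0) or np.any(fr > 1):
        raise ValueError("fractions must lie in [0, 1]")
    wl = default_wavelength_grid() if wavelengths is None else \
        np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    red_bands, ox_bands = band_params or (REDUCED_BANDS, OXIDIZED_BANDS)
    red = _bands_spectrum(wl, red_bands)
    ox = _bands_spectrum(wl, ox_bands)
    rng = _rng(seed, "spectra")
    spectra = []
    for f in fr:
        ab = (1.0 - f) * red + f * ox
        if noise_sigma > 0:
            ab = ab + rng.normal(0.0, noise_sigma, wl.size)
        spectra.append(Spectrum(wl.copy(), ab))
    truth = {"fractions": [float(f) for f in fr], "seed": seed}
    return spectra, truth
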