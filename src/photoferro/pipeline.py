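"""Orchestration of the two headline analyses.

``run_interaction_mapping`` chains peak-list matching, perturbation
classification, doubling detection and the spatial patch test into a
per-ligand interface report; ``run_hipip_comparison`` combines redox-Bohr
fits, hyperfine slope comparison, sequence/structure comparison and
ET-feasibility scans into a two-protein comparison report.

Reports are plain JSON-serializable dicts carrying a schema version, the
thresholds used and SHA-256 digests of every input file, so any number in
a report can be traced to its inputs and settings.  Stages are isolated:
a failing optional stage is recorded under ``errors`` without corrupting
the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .redox import RedoxBohrParams, fit_redox_bohr
from .sequence import conservation_of_set, nw_align, percent_identity
from .spectra import et_feasibility
from .structure import kabsch_superpose, patch_permutation_test, read_pdb
from .tempdep import compare_slopes, fit_tempdep
from .titration import (PeakList, classify_perturbations, detect_peak_doubling,
                        interacting_set, match_peaks)

logger = logging.getLogger("photoferro")

SCHEMA_VERSION = 1

THRESHOLD_RANGES = {
    "alpha": (0.0, 1.0),
    "k": (0.0, 10.0),
    "flat_threshold": (0.0, 1.0),
    "rel_tol": (0.0, 2.0),
    "B": (99, 10 ** 7),
    "seed": (0, 2 ** 31 - 1),
    "envelope_cutoff": (0.0, 100.0),
    "acceptor_e_mv": (-1000.0, 1500.0),
}

DEFAULT_THRESHOLDS = {
    "alpha": 0.14, "k": 1.0, "flat_threshold": 0.005, "rel_tol": 0.25,
    "B": 999, "seed": 0, "envelope_cutoff": 15.0, "acceptor_e_mv": 430.0,
}

DEFAULT_CONVENTIONS = {
    "identity_denominator": "aligned_pairs",
    "reference_electrode": "SHE",
}


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    """Validated analysis configuration.

    ``inputs`` maps stage names to file paths (or nested dicts of paths);
    thresholds outside their documented ranges and missing files are
    rejected at load time.
    """

    inputs: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    conventions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.thresholds = {**DEFAULT_THRESHOLDS, **self.thresholds}
        self.conventions = {**DEFAULT_CONVENTIONS, **self.conventions}
        for name, value in self.thresholds.items():
            if name in THRESHOLD_RANGES:
                lo, hi = THRESHOLD_RANGES[name]
                if not (lo <= value <= hi):
                    raise ConfigError(
                        f"threshold {name}={value} outside [{lo}, {hi}]")
        for path in _iter_paths(self.inputs):
            if not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(inputs=raw.get("inputs", {}),
                   thresholds=raw.get("thresholds", {}),
                   conventions=raw.get("conventions", {}))

    def as_dict(self) -> dict:
        return {"inputs": self.inputs, "thresholds": self.thresholds,
                "conventions": self.conventions}


#: input keys whose values are metadata, not file paths
NON_PATH_KEYS = {"proteins", "interacting_residues", "ca_ranges"}


def _iter_paths(obj):
    if isinstance(obj, dict):
        for k, v in obj.items():
            if k in NON_PATH_KEYS:
                continue
            yield from _iter_paths(v)
    elif isinstance(obj, (list, tuple)):
        for v in obj:
            yield from _iter_paths(v)
    elif isinstance(obj, (str, Path)):
        yield obj


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _input_digests(inputs) -> dict:
    return {str(p): _digest(p) for p in _iter_paths(inputs)}


def run_interaction_mapping(config: AnalysisConfig) -> dict:
    """Per-ligand interface mapping report.

    ``config.inputs['titrations']`` maps ligand name -> {free, bound} CSV
    paths; optional ``config.inputs['structure']`` (a PDB path) enables the
    cluster-proximity patch test on each interacting set.  Without a
    structure the patch test is skipped with a logged notice.
    """
    titr = config.inputs.get("titrations")
    if not titr:
        raise ConfigError("interaction mapping requires inputs.titrations "
                          "({ligand: {free, bound}})")
    structure_path = config.inputs.get("structure")
    model = read_pdb(structure_path) if structure_path else None
    if model is None:
        logger.info("no structure configured; patch test skipped")

    thr = config.thresholds
    report = {
        "schema_version": SCHEMA_VERSION,
        "analysis": "interaction_mapping",
        "config": config.as_dict(),
        "input_digests": _input_digests(config.inputs),
        "ligands": {},
    }
    for ligand, paths in sorted(titr.items()):
        for key in ("free", "bound"):
            if key not in paths:
                raise ConfigError(
                    f"titration stage {ligand!r}: missing {key!r} peak list")
        free = PeakList.from_csv(paths["free"], condition="free")
        bound = PeakList.from_csv(paths["bound"], condition="bound")
        paired = match_peaks(free, bound)
        table = classify_perturbations(paired, alpha=thr["alpha"], k=thr["k"])
        doubling = detect_peak_doubling(bound)
        inter = interacting_set(table)
        entry = {
            "shifted": sorted(table.shifted),
            "broadened": sorted(table.broadened),
            "shifted_and_broadened": sorted(table.shifted & table.broadened),
            "missing": sorted(table.missing),
            "doubled": {str(r): ratio for r, ratio in sorted(doubling.items())},
            "interacting_set": inter,
            "thresholds_used": table.thresholds,
        }
        if model is not None and len(inter) >= 2:
            res = patch_permutation_test(model, inter, B=int(thr["B"]),
                                         seed=int(thr["seed"]))
            entry["patch_test"] = {
                "observed_mean_min_dist_A": res.observed,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "null_mean_A": res.null_mean,
            }
        else:
            entry["patch_test"] = None
        report["ligands"][ligand] = entry
    validate_report(report)
    return report


def run_hipip_comparison(config: AnalysisConfig) -> dict:
    """Two-protein comparison report (redox, hyperfine, sequence, structure, ET).

    Expected inputs (each optional except the pair of protein names under
    ``proteins``): ``redox`` {name: csv}, ``tempdep`` {name: csv},
    ``sequences`` (FASTA with both records), ``structures`` {name: pdb}
    with ``ca_ranges`` {name: [lo, hi]}, ``interacting_residues`` (list,
    on protein A numbering).  Stage failures are isolated under ``errors``.
    """
    names = config.inputs.get("proteins")
    if not names or len(names) != 2:
        raise ConfigError("hipip comparison requires inputs.proteins: "
                          "[name_a, name_b]")
    name_a, name_b = names
    thr = config.thresholds
    report = {
        "schema_version": SCHEMA_VERSION,
        "analysis": "hipip_comparison",
        "config": config.as_dict(),
        "input_digests": _input_digests(config.inputs),
        "proteins": [name_a, name_b],
        "errors": {},
    }

    fits = {}
    if "redox" in config.inputs:
        for name, path in config.inputs["redox"].items():
            try:
                fit = fit_redox_bohr(pio.read_redox_csv(path))
                fits[name] = fit
                report.setdefault("redox", {})[name] = pio.fit_result_record(fit)
                report["redox"][name]["bohr_amplitude_mv"] = \
                    _amplitude(fit.params)
            except Exception as exc:  # stage isolation
                report["errors"][f"redox:{name}"] = str(exc)

    if "tempdep" in config.inputs:
        tfits = {}
        for name, path in config.inputs["tempdep"].items():
            try:
                series = pio.read_hyperfine_csv(path)
                eligible = [s for s in series
                            if s.is_hyperfine(thr["envelope_cutoff"])]
                tfits[name] = [fit_tempdep(s, thr["flat_threshold"])
                               for s in eligible]
                report.setdefault("tempdep", {})[name] = [
                    {"signal": f.signal_label, "slope_ppm_per_k": f.slope,
                     "intercept_ppm": f.intercept, "r_squared": f.r_squared,
                     "classification": f.classification} for f in tfits[name]]
            except Exception as exc:
                report["errors"][f"tempdep:{name}"] = str(exc)
        if len(tfits) == 2:
            try:
                cmpres = compare_slopes(tfits[name_a], tfits[name_b],
                                        rel_tol=thr["rel_tol"])
                report["slope_comparison"] = {
                    "mean_slope_a": cmpres.mean_slope_a,
                    "mean_slope_b": cmpres.mean_slope_b,
                    "ratio": cmpres.ratio,
                    "verdict": cmpres.verdict,
                }
            except Exception as exc:
                report["errors"]["slope_comparison"] = str(exc)

    if "sequences" in config.inputs:
        try:
            records = pio.read_fasta(config.inputs["sequences"])
            seq_a, seq_b = records[name_a], records[name_b]
            aln = nw_align(seq_a, seq_b)
            conv = config.conventions["identity_denominator"]
            seq_report = {
                "score": aln.score,
                "identity": percent_identity(aln, conv),
                "identity_convention": conv,
            }
            inter = config.inputs.get("interacting_residues")
            if inter:
                part = conservation_of_set(aln, inter)
                seq_report["conservation"] = {
                    "conserved": sorted(part.conserved),
                    "substituted": sorted(part.substituted),
                    "unaligned": sorted(part.unaligned),
                    "n_not_conserved": len(part.not_conserved),
                }
            report["sequence"] = seq_report
        except Exception as exc:
            report["errors"]["sequence"] = str(exc)

    if "structures" in config.inputs:
        try:
            models = {n: read_pdb(p)
                      for n, p in config.inputs["structures"].items()}
            ranges = config.inputs.get("ca_ranges", {})
            ca_a = models[name_a].ca_coords(tuple(ranges.get(name_a)) if
                                            ranges.get(name_a) else None)
            ca_b = models[name_b].ca_coords(tuple(ranges.get(name_b)) if
                                            ranges.get(name_b) else None)
            n = min(len(ca_a), len(ca_b))
            sup = kabsch_superpose(ca_a[:n], ca_b[:n])
            report["superposition"] = {"rmsd_A": sup.rmsd,
                                       "n_atoms": sup.n_atoms}
        except Exception as exc:
            report["errors"]["superposition"] = str(exc)

    for name, fit in fits.items():
        try:
            scan = et_feasibility(fit.params, thr["acceptor_e_mv"],
                                  ph_range=(6.0, 8.0))
            report.setdefault("et_feasibility", {})[name] = {
                "acceptor_e_mv": thr["acceptor_e_mv"],
                "favorable_fraction": float(scan.favorable.mean()),
                "crossing_ph": scan.crossing_ph,
                "delta_e_at_ph7_mv": float(
                    scan.delta_e_mv[len(scan.ph_grid) // 2]),
            }
        except Exception as exc:
            report["errors"][f"et_feasibility:{name}"] = str(exc)

    validate_report(report)
    return report


def _amplitude(params: RedoxBohrParams) -> float:
    from .redox import bohr_amplitude
    return bohr_amplitude(params)


REQUIRED_KEYS = {
    "interaction_mapping": ("schema_version", "config", "input_digests",
                            "ligands"),
    "hipip_comparison": ("schema_version", "config", "input_digests",
                         "proteins", "errors"),
}


def validate_report(report: dict) -> None:
    """Minimal schema check: analysis kind known and required keys present."""
    kind = report.get("analysis")
    if kind not in REQUIRED_KEYS:
        raise ValueError(f"unknown analysis kind {kind!r}")
    missing = [k for k in REQUIRED_KEYS[kind] if k not in report]
    if missing:
        raise ValueError(f"report missing required keys: {missing}")


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
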