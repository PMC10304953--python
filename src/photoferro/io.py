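"""CSV / FASTA readers and writers for the pipeline's tabular dialects."""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO

from .redox import FitResult, RedoxDataPoint
from .tempdep import HyperfineSeries


def read_redox_csv(path) -> list[RedoxDataPoint]:
    """Read `pH,E_mV,reference` rows into data points."""
    df = pd.read_csv(path)
    return [RedoxDataPoint(float(r.pH), float(r.E_mV), str(r.reference))
            for r in df.itertuples()]


def write_redox_csv(points: list[RedoxDataPoint], path) -> None:
    pd.DataFrame(
        [(p.ph, p.e_mv, p.reference) for p in points],
        columns=["pH", "E_mV", "reference"],
    ).to_csv(path, index=False)


def fit_result_record(fit: FitResult) -> dict:
    """JSON-ready record of a redox-Bohr fit."""
    return {
        "e_alk_mv": fit.params.e_alk,
        "pka_ox": fit.params.pka_ox,
        "pka_red": fit.params.pka_red,
        "temperature_k": fit.params.temperature,
        "rss_mv2": fit.rss,
        "ci": {k: list(v) for k, v in fit.ci.items()},
        "bound_flags": dict(fit.bound_flags),
        "n_points": fit.n_points,
        "ordering_refit": fit.ordering_refit,
    }


def read_hyperfine_csv(path) -> list[HyperfineSeries]:
    """Read `signal_label,T_K,delta_ppm` rows, one series per label."""
    df = pd.read_csv(path)
    out = []
    for label, grp in df.groupby("signal_label", sort=True):
        grp = grp.sort_values("T_K")
        out.append(HyperfineSeries(
            signal_label=str(label),
            temperatures=grp["T_K"].to_numpy(float),
            shifts=grp["delta_ppm"].to_numpy(float)))
    return out


def write_hyperfine_csv(series: list[HyperfineSeries], path) -> None:
    rows = [(s.signal_label, t, d)
            for s in series for t, d in zip(s.temperatures, s.shifts)]
    pd.DataFrame(rows, columns=["signal_label", "T_K", "delta_ppm"]) \
        .to_csv(path, index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: sequence} (ordered)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
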