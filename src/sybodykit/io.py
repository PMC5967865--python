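"""File formats: FASTA for library members, CSV tables, JSON fit reports.

CSV schemas used throughout the package:

- qPCR:         sample_id, primer_pair, Ct, replicate
- ELISA plate:  row, col, absorbance, well_class
- sensorgram:   time, response, concentration, phase
- dose-response: x, y, replicate
- melt:         temperature, signal, condition
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import DoseResponse, FitResult, MeltCurve, Sensorgram
from .library import LibraryMember

__all__ = [
    "write_fasta",
    "read_fasta",
    "read_qpcr_csv",
    "read_elisa_csv",
    "read_sensorgram_csv",
    "read_dose_response_csv",
    "read_melt_csv",
    "write_fit_report",
]


def write_fasta(members: Iterable[LibraryMember], path: str | Path) -> int:
    """Write library members as a wrapped FASTA file; returns the record count."""
    records = [
        SeqRecord(Seq(m.dna), id=m.name, description=f"protein={m.protein}")
        for m in members
    ]
    return SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[LibraryMember]:
    """Read library members back from FASTA written by :func:`write_fasta`."""
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        protein = ""
        for token in rec.description.split():
            if token.startswith("protein="):
                protein = token[len("protein="):]
        dna = str(rec.seq)
        if not protein:
            protein = str(Seq(dna[: len(dna) - len(dna) % 3]).translate())
        members.append(LibraryMember(name=rec.id, dna=dna, protein=protein))
    return members


def _require_columns(df: pd.DataFrame, required: set[str], what: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{what} table is missing columns: {sorted(missing)}")


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, {"sample_id", "primer_pair", "Ct", "replicate"}, "qPCR")
    return df


def read_elisa_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, {"row", "col", "absorbance", "well_class"}, "ELISA")
    return df


def read_sensorgram_csv(path: str | Path) -> list[Sensorgram]:
    """Read per-concentration sensorgrams from a long-format table."""
    df = pd.read_csv(path)
    _require_columns(df, {"time", "response", "concentration", "phase"}, "sensorgram")
    grams = []
    for conc, grp in df.groupby("concentration", sort=True):
        grp = grp.sort_values("time")
        assoc = grp.loc[grp["phase"] == "association", "time"]
        t_assoc = float(assoc.max()) if len(assoc) else float(grp["time"].max())
        grams.append(
            Sensorgram(
                times=grp["time"].to_numpy(dtype=float),
                responses=grp["response"].to_numpy(dtype=float),
                concentration=float(conc),
                t_assoc=t_assoc,
            )
        )
    return grams


def read_dose_response_csv(path: str | Path) -> DoseResponse:
    df = pd.read_csv(path)
    _require_columns(df, {"x", "y"}, "dose-response")
    replicate = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return DoseResponse(
        x=df["x"].to_numpy(dtype=float), y=df["y"].to_numpy(dtype=float), replicate=replicate
    )


def read_melt_csv(path: str | Path) -> dict[str, MeltCurve]:
    """Read melt curves keyed by condition from a long-format table."""
    df = pd.read_csv(path)
    _require_columns(df, {"temperature", "signal"}, "melt")
    if "condition" not in df.columns:
        df = df.assign(condition="default")
    curves = {}
    for condition, grp in df.groupby("condition", sort=True):
        grp = grp.sort_values("temperature")
        curves[str(condition)] = MeltCurve(
            temperatures=grp["temperature"].to_numpy(dtype=float),
            signals=grp["signal"].to_numpy(dtype=float),
            condition=str(condition),
        )
    return curves


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_fit_report(
    path: str | Path,
    model: str,
    params: Mapping[str, float] | None,
    fit: FitResult,
    extra: Mapping[str, object] | None = None,
) -> dict:
    """Write a JSON fit report and return the written document."""
    doc = {
        "model": model,
        "converged": fit.converged,
        "params": _jsonable(dict(params)) if params is not None else None,
        "stderr": _jsonable(dict(fit.stderr)),
        "residual_norm": float(fit.residual_norm),
        "message": fit.message,
        "nfev": fit.nfev,
    }
    if extra:
        doc.update(_jsonable(dict(extra)))
    Path(path).write_text(json.dumps(doc, indent=2))
    return doc
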