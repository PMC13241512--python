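"""Plain-text readers and writers: peak-list CSV, traces, corpora, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import MoleculeRecord
from .codec import HSQCPeak, PeakList1D

__all__ = [
    "write_peaklist_csv",
    "read_peaklist_csv",
    "write_hsqc_csv",
    "read_hsqc_csv",
    "write_trace_csv",
    "read_trace_csv",
    "write_corpus_smiles",
    "read_corpus_smiles",
    "write_corpus_sdf",
    "write_manifest",
    "read_manifest",
]


def write_peaklist_csv(path, peaks: PeakList1D) -> None:
    pd.DataFrame(
        {"position": peaks.positions, "intensity": peaks.intensities,
         "width": peaks.widths}
    ).to_csv(path, index=False)


def read_peaklist_csv(path, modality: str) -> PeakList1D:
    df = pd.read_csv(path)
    return PeakList1D(modality, df["position"].to_numpy(),
                      df["intensity"].to_numpy(), df["width"].to_numpy())


def write_hsqc_csv(path, peaks: list[HSQCPeak]) -> None:
    pd.DataFrame(
        [
            {"c_centroid": p.c_centroid, "c_min": p.c_min, "c_max": p.c_max,
             "h_centroid": p.h_centroid, "h_min": p.h_min, "h_max": p.h_max}
            for p in peaks
        ],
        columns=["c_centroid", "c_min", "c_max", "h_centroid", "h_min", "h_max"],
    ).to_csv(path, index=False)


def read_hsqc_csv(path) -> list[HSQCPeak]:
    df = pd.read_csv(path)
    return [HSQCPeak(**row) for row in df.to_dict("records")]


def write_trace_csv(path, axis: np.ndarray, values: np.ndarray) -> None:
    pd.DataFrame({"axis": axis, "value": values}).to_csv(path, index=False)


def read_trace_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["axis"].to_numpy(), df["value"].to_numpy()


def write_corpus_smiles(path, records: list[MoleculeRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles}\t{rec.mol_id}\n")


def read_corpus_smiles(path) -> list[MoleculeRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        mol_id = parts[1].strip() if len(parts) > 1 else None
        records.append(MoleculeRecord.from_smiles(smiles, mol_id))
    return records


def write_corpus_sdf(path, records: list[MoleculeRecord]) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.MolFromSmiles(rec.smiles)
            mol.SetProp("_Name", rec.mol_id)
            writer.write(mol)
    finally:
        writer.close()


def write_manifest(path, entries: list[dict]) -> None:
    """Link molecule ids to their spectrum files (JSON)."""
    with open(path, "w") as fh:
        json.dump({"entries": entries}, fh, indent=1)


def read_manifest(path) -> list[dict]:
    with open(path) as fh:
        return json.load(fh)["entries"]
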