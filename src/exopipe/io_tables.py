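"""Readers and writers for the pipeline's tabular inputs and results.

All files are tab-separated UTF-8.  ``"NA"``, ``"Undetermined"`` and empty
cells are parsed as missing, matching qPCR instrument exports and R
conventions.  Two CT layouts are supported:

* wide — one row per miRNA, one column per sample (sample ids
  ``"<patient>:<timepoint>"``), first column named ``mirna``;
* long — columns ``sample`` (patient id), ``mirna``, ``timepoint``, ``ct``.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DRUGS,
    ChemoresistanceEntry,
    ChemoresistanceList,
    CTMatrix,
    make_sample_id,
    validate_clinical,
)

MISSING_TOKENS = ["NA", "Undetermined", "undetermined", ""]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        na_values=MISSING_TOKENS,
        keep_default_na=False,
        encoding="utf-8",
        **kwargs,
    )


def read_ct_matrix(path: str | Path, layout: str = "wide") -> CTMatrix:
    """Read a CT matrix from a TSV file.

    Parameters
    ----------
    path : file path
    layout : {"wide", "long"}

    Raises a ``ValueError`` naming the offending entry on duplicate
    (sample, miRNA) pairs or unknown timepoint labels.
    """
    if layout == "wide":
        df = _read_tsv(path)
        first = df.columns[0]
        if df[first].duplicated().any():
            dup = df.loc[df[first].duplicated(), first].iloc[0]
            raise ValueError(f"duplicate miRNA row {dup!r} in {path}")
        df = df.set_index(first)
        return CTMatrix(df.T.astype(float))
    if layout == "long":
        df = _read_tsv(path)
        required = {"sample", "mirna", "timepoint", "ct"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long CT table missing columns {sorted(missing)}")
        sample_ids = [
            make_sample_id(str(p), str(t))
            for p, t in zip(df["sample"], df["timepoint"])
        ]
        keys = pd.DataFrame({"sample_id": sample_ids, "mirna": df["mirna"]})
        dups = keys.duplicated()
        if dups.any():
            row = keys[dups].iloc[0]
            raise ValueError(
                f"duplicate entry for sample {row['sample_id']!r}, "
                f"miRNA {row['mirna']!r} in {path}"
            )
        wide = pd.DataFrame(
            {"sample_id": sample_ids, "mirna": df["mirna"], "ct": df["ct"].astype(float)}
        ).pivot(index="sample_id", columns="mirna", values="ct")
        wide.index.name = None
        wide.columns.name = None
        # preserve first-appearance order of assays
        order = list(dict.fromkeys(df["mirna"]))
        return CTMatrix(wide[order])
    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def write_ct_matrix(ct: CTMatrix, path: str | Path) -> None:
    """Write a CT matrix in the wide layout (rows = miRNAs)."""
    out = ct.ct.T
    out.index.name = "mirna"
    out.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8")


def read_clinical(path: str | Path) -> pd.DataFrame:
    return validate_clinical(_read_tsv(path))


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", na_rep="NA", index=False, encoding="utf-8")


def read_chemoresistance_list(path: str | Path) -> ChemoresistanceList:
    """Read a (mirna, drug, direction) TSV into a validated list.

    Unknown drug names and directions outside {up, down} are hard errors.
    A header-only file yields an empty list.
    """
    df = _read_tsv(path)
    required = {"mirna", "drug", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chemoresistance list missing columns {sorted(missing)}")
    entries = [
        ChemoresistanceEntry(str(r.mirna), str(r.drug), str(r.direction))
        for r in df.itertuples()
    ]
    return ChemoresistanceList(entries)


def write_chemoresistance_list(clist: ChemoresistanceList, path: str | Path) -> None:
    pd.DataFrame(
        [(e.mirna, e.drug, e.direction) for e in clist.entries],
        columns=["mirna", "drug", "direction"],
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")


def summarize_list_by_drug(clist: ChemoresistanceList) -> pd.DataFrame:
    """Count up/down resistance-associated miRNAs per drug.

    Returns one row per known drug (zero rows included), columns
    ``drug, n_up, n_down``.
    """
    rows = []
    for drug in DRUGS:
        directions = list(clist.by_drug(drug).values())
        rows.append(
            {
                "drug": drug,
                "n_up": sum(d == "up" for d in directions),
                "n_down": sum(d == "down" for d in directions),
            }
        )
    return pd.DataFrame(rows)


def _bundled(name: str) -> Path:
    return Path(str(importlib.resources.files("exopipe").joinpath("data", name)))


def load_reference_diffexpr() -> pd.DataFrame:
    """Bundled published summary of the 62 exo-miRNAs downregulated after
    induction chemotherapy (mean ΔCT per timepoint, RQ, fold change, BH p)."""
    df = _read_tsv(_bundled("downregulated_mirnas.tsv"))
    for col in df.columns[1:]:
        df[col] = df[col].astype(float)
    return df


def load_reference_chemoresistance_list() -> ChemoresistanceList:
    """Bundled literature-curated chemoresistance list (miRNA x drug x
    direction) for the six induction-regimen drugs."""
    return read_chemoresistance_list(_bundled("chemoresistance_list.tsv"))


def write_normalized(norm, path: str | Path) -> None:
    """Write a NormalizedMatrix as a wide ΔCT TSV (rows = miRNAs)."""
    masked = norm.delta_ct.where(norm.detected | norm.imputed, np.nan)
    out = masked.T
    out.index.name = "mirna"
    out.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8")
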