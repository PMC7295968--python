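"""Readers and writers for plate tables, GCT matrices, GMT gene sets and
potency tables, plus signature subsetting.

Formats
-------
long_csv
    One row per (well, gene) cell with columns ``well_id, plate_id, role,
    compound_id, concentration_uM, technical_replicate_id,
    biological_replicate_id, gene_symbol, probe_id, value``.
GCT
    Text GCT v1.3 (the two-header-row dialect used for L1000 level-4
    z-score matrices); rows = probes, columns = wells/samples.  Values read
    from GCT are tagged ``scale="z-score"``.
GMT
    Tab-separated gene sets: name, description, genes...
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    FormatError,
    GeneSignature,
    IntegrityError,
    PlateExpressionSet,
    ReferencePotency,
    Role,
    Scale,
    WELL_COLUMNS,
)

__all__ = [
    "read_plate_table",
    "write_plate_table",
    "read_gene_sets",
    "write_gene_sets",
    "subset_to_signature",
    "read_reference_potencies",
    "write_potency_table",
]

LONG_CSV_COLUMNS = (
    "well_id",
    "plate_id",
    "role",
    "compound_id",
    "concentration_uM",
    "technical_replicate_id",
    "biological_replicate_id",
    "gene_symbol",
    "probe_id",
    "value",
)


# ---------------------------------------------------------------------------
# plate tables
# ---------------------------------------------------------------------------
def read_plate_table(
    path, format: str = "long_csv", scale: str | None = None
) -> PlateExpressionSet:
    """Read a plate expression table.

    Parameters
    ----------
    path
        File path (long-format CSV or text GCT v1.3).
    format
        ``"long_csv"`` or ``"gct"``.
    scale
        Value scale tag; defaults to ``"counts"`` for long_csv and
        ``"z-score"`` for GCT.
    """
    if format == "long_csv":
        return _read_long_csv(path, scale=scale or Scale.COUNTS)
    if format == "gct":
        return _read_gct(path, scale=scale or Scale.ZSCORE)
    raise ValueError(f"unknown plate format {format!r}")


def _read_long_csv(path, scale: str) -> PlateExpressionSet:
    df = pd.read_csv(path)
    required = ("well_id", "role", "gene_symbol", "value")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    dup = df.duplicated(subset=["well_id", "gene_symbol", "probe_id"]
                        if "probe_id" in df.columns else ["well_id", "gene_symbol"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise IntegrityError(
            f"{path}: duplicate cell for well {row['well_id']!r} "
            f"gene {row['gene_symbol']!r}"
        )
    for col in WELL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col == "concentration_uM" else ""
    if "probe_id" not in df.columns:
        df["probe_id"] = df["gene_symbol"]

    values = df.pivot(index="well_id", columns="gene_symbol", values="value")
    if values.isna().any().any():
        well = values.index[values.isna().any(axis=1)][0]
        raise IntegrityError(f"{path}: well {well!r} is missing gene values")
    values.columns.name = None

    wells = (
        df.drop_duplicates("well_id")
        .set_index("well_id")[list(WELL_COLUMNS)]
        .loc[values.index]
    )
    wells["concentration_uM"] = pd.to_numeric(
        wells["concentration_uM"], errors="coerce"
    )
    for col in WELL_COLUMNS:  # text metadata: absent reads back as ""
        if col != "concentration_uM":
            wells[col] = wells[col].fillna("").astype(str)
    gene_meta = df.drop_duplicates("gene_symbol").set_index("gene_symbol")
    genes = pd.DataFrame(index=values.columns)
    genes["probe_id"] = gene_meta["probe_id"].reindex(values.columns)
    if "is_housekeeper" in df.columns:
        genes["is_housekeeper"] = (
            gene_meta["is_housekeeper"].reindex(values.columns).fillna(False).astype(bool)
        )
    else:
        genes["is_housekeeper"] = False
    return PlateExpressionSet(values=values, wells=wells, genes=genes, scale=scale)


def write_plate_table(pset: PlateExpressionSet, path) -> None:
    """Write a plate to long-format CSV (inverse of ``read_plate_table``)."""
    long = (
        pset.values.stack()
        .rename("value")
        .reset_index()
        .rename(columns={"level_0": "well_id", "level_1": "gene_symbol"})
    )
    long.columns = ["well_id", "gene_symbol", "value"]
    long = long.join(pset.wells, on="well_id")
    long = long.join(pset.genes[["probe_id", "is_housekeeper"]], on="gene_symbol")
    long[list(LONG_CSV_COLUMNS) + ["is_housekeeper"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GCT v1.3 (text)
# ---------------------------------------------------------------------------
def _read_gct(path, scale: str) -> PlateExpressionSet:
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.3"):
            raise FormatError(f"{path}: not a text GCT v1.3 file ({version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError(f"{path}: malformed GCT dimension line")
        nrow, ncol = int(dims[0]), int(dims[1])
        nrmeta = int(dims[2]) if len(dims) > 2 else 0
        ncmeta = int(dims[3]) if len(dims) > 3 else 0
        body = pd.read_csv(fh, sep="\t", header=0, dtype=str)

    sample_cols = body.columns[1 + nrmeta :]
    if len(sample_cols) != ncol:
        raise FormatError(
            f"{path}: header declares {ncol} samples, found {len(sample_cols)}"
        )
    col_meta = body.iloc[:ncmeta].set_index(body.columns[0])
    data = body.iloc[ncmeta:]
    if len(data) != nrow:
        raise FormatError(f"{path}: header declares {nrow} rows, found {len(data)}")

    probe_ids = data.iloc[:, 0].astype(str).values
    # first row-metadata column is conventionally the gene symbol
    if nrmeta >= 1:
        symbols = data.iloc[:, 1].astype(str).values
    else:
        symbols = probe_ids
    matrix = data[sample_cols].astype(float).values.T  # wells × probes

    # Duplicate symbols are kept at probe resolution (column label
    # "SYMBOL|probe") and flagged for collapse_probes.
    sym_series = pd.Series(symbols)
    dup_mask = sym_series.duplicated(keep=False).values
    columns = [
        f"{s}|{p}" if d else s for s, p, d in zip(symbols, probe_ids, dup_mask)
    ]
    values = pd.DataFrame(matrix, index=list(sample_cols), columns=columns)

    wells = pd.DataFrame(index=values.index)
    for col in WELL_COLUMNS:
        if col in col_meta.index:
            wells[col] = col_meta.loc[col, sample_cols].values
        else:
            wells[col] = np.nan if col == "concentration_uM" else ""
    if (wells["role"] == "").all():
        wells["role"] = Role.COMPOUND  # caller must annotate controls
        wells["concentration_uM"] = pd.to_numeric(
            wells["concentration_uM"], errors="coerce"
        ).fillna(1.0)
    wells["concentration_uM"] = pd.to_numeric(wells["concentration_uM"], errors="coerce")

    genes = pd.DataFrame(
        {"probe_id": probe_ids, "is_housekeeper": False}, index=columns
    )
    genes["gene_symbol"] = symbols
    pset = PlateExpressionSet(values=values, wells=wells, genes=genes, scale=scale)
    pset.attrs["duplicate_symbols"] = sorted(sym_series[dup_mask].unique())
    return pset


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------
def read_gene_sets(path) -> list[GeneSignature]:
    """Parse a GMT file into signatures, preserving file and gene order."""
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            try:
                signatures.append(GeneSignature(name=name, genes=tuple(genes)))
            except IntegrityError as err:
                raise IntegrityError(f"{path}:{lineno}: {err}") from err
    return signatures


def write_gene_sets(signatures: Sequence[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, "na", *sig.genes]) + "\n")


# ---------------------------------------------------------------------------
# signature subsetting
# ---------------------------------------------------------------------------
def subset_to_signature(
    pset: PlateExpressionSet, sig: GeneSignature
) -> PlateExpressionSet:
    """Restrict the plate to signature genes, in signature order.

    The number of mapped and unmapped genes is recorded in
    ``attrs["signature_mapping"]``.  Raises if no signature gene is present.
    """
    present = [g for g in sig.genes if g in pset.values.columns]
    unmapped = [g for g in sig.genes if g not in pset.values.columns]
    if not present:
        raise IntegrityError(
            f"no gene of signature {sig.name!r} is present on the plate"
        )
    out = pset.with_values(pset.values[present])
    out.attrs["signature_mapping"] = {
        "signature": sig.name,
        "n_signature_genes": len(sig),
        "n_mapped": len(present),
        "n_unmapped": len(unmapped),
        "unmapped": unmapped,
    }
    return out


# ---------------------------------------------------------------------------
# potency / reference tables
# ---------------------------------------------------------------------------
def read_reference_potencies(path) -> list[ReferencePotency]:
    """Read a reference potency CSV (compound_id, potency_uM[, grinf, flat_curve])."""
    df = pd.read_csv(path)
    if "compound_id" not in df.columns or "potency_uM" not in df.columns:
        raise FormatError(f"{path}: needs columns compound_id and potency_uM")
    refs = []
    for _, row in df.iterrows():
        refs.append(
            ReferencePotency(
                compound_id=str(row["compound_id"]),
                potency_uM=None if pd.isna(row["potency_uM"]) else float(row["potency_uM"]),
                grinf=float(row["grinf"]) if "grinf" in df.columns and pd.notna(row.get("grinf")) else None,
                flat_curve=bool(row["flat_curve"]) if "flat_curve" in df.columns and pd.notna(row.get("flat_curve")) else False,
            )
        )
    return refs


def write_potency_table(potencies: pd.DataFrame, path) -> None:
    """Write a fitted-potency table (one row per compound × method)."""
    potencies.to_csv(path, index=False)
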