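"""File I/O: TSV matrices ("NA" missing dialect), design tables, GMT,
FASTA, CETSA CSV and TOML configuration."""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    ExpressionMatrix,
    GeneLengths,
    PROTEIN_LAYERS,
    SampleDesign,
    ValidationError,
)
from .simdata import CetsaDataset

NA = "NA"


def read_expression_tsv(path, layer: str) -> ExpressionMatrix:
    """Read a features x samples TSV (first column = feature ids).

    "NA" cells are accepted only on protein layers; duplicate feature
    ids and ragged rows are errors.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA], keep_default_na=False,
        dtype=str,
    )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique()[0]
        raise ValidationError(f"duplicate feature id {dup!r} in {path}")
    if df.isna().any().any() and layer not in PROTEIN_LAYERS:
        raise ValidationError(
            f"'NA' cells are not allowed on layer {layer!r} ({path})"
        )
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    values.index.name = None  # exact round trip with in-memory matrices
    values.columns.name = None
    return ExpressionMatrix(values, layer=layer)


def write_expression_tsv(mat: ExpressionMatrix, path) -> None:
    mat.values.to_csv(path, sep="\t", na_rep=NA, index_label="feature_id")


def read_design_tsv(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t"))


def write_design_tsv(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_gene_lengths_tsv(path) -> GeneLengths:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GeneLengths(df.iloc[:, 0].astype(float))


def write_gene_lengths_tsv(lengths: GeneLengths, path) -> None:
    lengths.lengths.to_frame("length").to_csv(
        path, sep="\t", index_label="feature_id"
    )


def read_fasta_sequences(path) -> dict[str, str]:
    """Protein FASTA -> {record id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_cetsa_csv(path) -> CetsaDataset:
    """CETSA CSV with columns agonist_dose, antagonist_conc, replicate,
    signal; concentrations in molar."""
    return CetsaDataset(pd.read_csv(path))


def write_cetsa_csv(data: CetsaDataset, path) -> None:
    data.table.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)
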