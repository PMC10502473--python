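"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (gene rows, header row of sample ids),
clinical tables and results as CSV, plain gene sets as standard GMT, and
weighted/centroid signatures as the YAML registry format of
:mod:`tnbcsig.registry`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .scoring import validate_expression

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_clinical_csv",
    "write_clinical_csv",
    "CLINICAL_REQUIRED_COLUMNS",
]

ARM_LEVELS = {"carboplatin", "docetaxel"}
BRCA_LEVELS = {"BRCA1_mutated", "BRCA2_mutated", "BRCA1_methylated", "wildtype", "uncertain"}
TIMEPOINT_LEVELS = {"primary", "recurrence"}
CLINICAL_REQUIRED_COLUMNS = [
    "sample_id", "patient_id", "arm", "response", "pfs_time", "pfs_event",
    "tils", "brca_status", "prior_chemo", "timepoint",
]


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes-by-samples TSV expression matrix and validate it.

    First column holds gene ids, the header row sample ids. Non-numeric cells
    and duplicate identifiers are rejected with their coordinates.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        rows = [i + 2 for i, d in enumerate(raw.index.duplicated(keep=False)) if d]
        dupes = sorted(raw.index[raw.index.duplicated()].unique().tolist())
        raise ValueError(f"{path}: duplicate gene ids {dupes} (file rows {rows})")
    values = np.empty(raw.shape)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.argmax()]
            raise ValueError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna().argmax()]
            raise ValueError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        values[:, j] = converted.to_numpy()
    expr = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    return validate_expression(expr)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name TAB description TAB gene ids.

    Returns an ordered mapping name -> duplicate-free gene list. Duplicate set
    names are rejected; within-set duplicate genes are dropped with a warning.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = [g for g in fields[2:] if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning("%s:%d: set %r has duplicate genes (de-duplicated)",
                               path, lineno, name)
            sets[name] = deduped
    if not sets:
        logger.warning("%s: empty GMT file", path)
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_clinical_csv(path) -> pd.DataFrame:
    """Read and validate a clinical table.

    Enumerated columns (arm, brca_status, timepoint) are checked against their
    allowed levels; pfs_time must be strictly positive.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col, levels in (("arm", ARM_LEVELS), ("brca_status", BRCA_LEVELS),
                        ("timepoint", TIMEPOINT_LEVELS)):
        bad = set(df[col].dropna().unique()) - levels
        if bad:
            raise ValueError(
                f"{path}: column {col!r} has unknown values {sorted(bad)}; "
                f"allowed: {sorted(levels)}"
            )
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    nonpos = df.index[df["pfs_time"] <= 0]
    if len(nonpos):
        raise ValueError(f"{path}: pfs_time <= 0 at file row(s) {[i + 2 for i in nonpos]}")
    return df


def write_clinical_csv(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False)
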