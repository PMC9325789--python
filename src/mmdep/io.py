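"""Readers and writers for screen matrices, cohorts and gene-set files.

Screen matrices follow the DepMap gene-effect dialect: cell lines as rows,
gene columns labelled "SYMBOL (ENTREZID)", blank or "NA" cells for missing
values.  In memory everything is transposed to gene x line.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CohortSurvival, GeneSetCollection, ScreenMatrix

logger = logging.getLogger("mmdep")

_LABEL_RE = re.compile(r"^\s*(?P<symbol>\S+)\s*(?:\((?P<entrez>\d+)\))?\s*$")

_NA_VALUES = ["", "NA"]


def parse_gene_label(label: str) -> tuple[str, int | None]:
    """Split a DepMap column label into (symbol, entrez or None)."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse gene label {label!r}")
    entrez = m.group("entrez")
    return m.group("symbol"), (int(entrez) if entrez is not None else None)


def read_screen_matrix(path: str | Path, platform: str) -> ScreenMatrix:
    """Read a DepMap-style gene-effect CSV into a gene x line ScreenMatrix.

    The file has cell lines as rows (first column = line id) and genes as
    columns; blank or "NA" cells are missing.  Raises on duplicate line ids,
    duplicate gene symbols, or non-numeric cells.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, index_col=0, na_values=_NA_VALUES, keep_default_na=False
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate cell-line IDs: {dups[:5]}")

    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            if len(bad):
                line_id, val = bad.index[0], bad.iloc[0]
                raise ValueError(
                    f"{path}: non-numeric value {val!r} at line {line_id!r}, gene column {col!r}"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")

    symbols, entrez = [], {}
    for label in df.columns:
        sym, eid = parse_gene_label(str(label))
        symbols.append(sym)
        if eid is not None:
            entrez[sym] = eid
    if len(set(symbols)) != len(symbols):
        seen: set[str] = set()
        dups = [s for s in symbols if s in seen or seen.add(s)]
        raise ValueError(f"{path}: gene symbol collision: {sorted(set(dups))[:5]}")

    scores = df.T.astype(float)
    scores.index = pd.Index(symbols, name="gene")
    scores.columns.name = "line"
    return ScreenMatrix(scores=scores, platform=platform, entrez=entrez)


def write_screen_matrix(screen: ScreenMatrix, path: str | Path) -> None:
    """Write a ScreenMatrix back to the DepMap dialect (lines as rows)."""
    df = screen.scores.T.copy()
    df.columns = [
        f"{g} ({screen.entrez[g]})" if g in screen.entrez else g for g in df.columns
    ]
    df.index.name = "line"
    # repr-precision floats so a text round trip preserves values
    df.to_csv(path, float_format="%.17g", na_rep="")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a standard GMT gene-set file: term, description, members."""
    names: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            term, desc = fields[0], fields[1]
            if term in members:
                raise ValueError(f"{path}: line {lineno}: duplicate term {term!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: term {term!r} has no members")
            names[term] = desc
            members[term] = genes
    return GeneSetCollection(names=names, members=members)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term in sets:
            genes = "\t".join(sorted(sets.members[term]))
            fh.write(f"{term}\t{sets.names[term]}\t{genes}\n")


def read_line_metadata(path: str | Path) -> "pd.Series":
    """Read cell-line metadata CSV (columns: line_id, lineage) to a Series."""
    df = pd.read_csv(path)
    if not {"line_id", "lineage"} <= set(df.columns):
        raise ValueError(f"{path}: need columns line_id and lineage")
    if df["line_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate line_id entries")
    return pd.Series(df["lineage"].values, index=df["line_id"].values, name="lineage")


def read_cohort(
    expr_path: str | Path, clinical_path: str | Path, name: str | None = None
) -> CohortSurvival:
    """Load a cohort from an expression matrix (genes x samples, TSV or CSV)
    and a clinical CSV, inner-joined on patient id.

    Patients present in only one table are dropped with a logged count;
    zero overlap is a hard error.
    """
    expr_path = Path(expr_path)
    sep = "\t" if expr_path.suffix in {".tsv", ".txt"} else ","
    expression = pd.read_csv(expr_path, sep=sep, index_col=0)
    clinical = pd.read_csv(clinical_path, index_col="patient_id")

    expr_ids = list(expression.columns)
    common = [p for p in expr_ids if p in set(clinical.index)]
    if not common:
        raise ValueError(
            f"no overlapping patients between {expr_path} and {clinical_path}"
        )
    n_dropped = (len(expr_ids) - len(common)) + (len(clinical) - len(common))
    if n_dropped:
        logger.info("read_cohort(%s): dropped %d non-overlapping patients", name, n_dropped)
    expression = expression[common]
    clinical = clinical.loc[common]
    return CohortSurvival(
        name=name or expr_path.stem, expression=expression, clinical=clinical
    )


def write_cohort(cohort: CohortSurvival, expr_path: str | Path, clinical_path: str | Path) -> None:
    cohort.expression.to_csv(expr_path, sep="\t", float_format="%.17g")
    out = cohort.clinical.copy()
    out.index.name = "patient_id"
    out.to_csv(clinical_path, float_format="%.17g")
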