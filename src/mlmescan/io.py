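"""Readers and writers for expression matrices, marker panels and tables.

Dense matrices are TSV/CSV with gene ids in the first column and a header row
of cell ids.  Sparse matrices use MatrixMarket coordinate format with two
one-column sidecar files of gene and cell ids; absent entries are zeros.
Marker panels and simulation configs are YAML (JSON is a YAML subset).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .datamodel import (
    DEFAULT_MASTER_REGULATORS,
    DEFAULT_MIN_MARKERS_PER_LINEAGE,
    ExpressionMatrix,
    MarkerPanel,
    ParseError,
    PrevalenceRow,
    ValidationError,
)

_META_COLUMNS = ("embryo_id", "stage", "lineage", "dataset_id")


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "genes_by_cells",
    gene_ids_path: str | Path | None = None,
    cell_ids_path: str | Path | None = None,
    cell_meta_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix, normalising to genes x cells orientation.

    For ``format="mtx"`` the row/column id sidecar files are required; which
    axis is genes is set by ``orientation`` exactly as for dense input.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pandas raises various parser errors
            raise ParseError(f"cannot parse {path} as {format}: {exc}") from exc
        if df.empty and df.shape[0] == 0:
            raise ValidationError(f"{path}: matrix has no rows")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise ParseError(f"{path}: non-numeric entries in columns {list(bad)[:3]}")
        row_ids, col_ids = list(df.index), list(df.columns)
    elif format == "mtx":
        if gene_ids_path is None or cell_ids_path is None:
            raise ValueError("mtx format requires gene_ids_path and cell_ids_path")
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ParseError(f"cannot parse {path} as MatrixMarket: {exc}") from exc
        values = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        row_ids = _read_id_column(gene_ids_path)
        col_ids = _read_id_column(cell_ids_path)
    else:
        raise ValueError(f"unknown format {format!r}")

    if orientation == "cells_by_genes":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    elif orientation != "genes_by_cells":
        raise ValueError(f"unknown orientation {orientation!r}")

    cell_meta = None
    if cell_meta_path is not None:
        cell_meta = read_cell_meta(cell_meta_path)
    return ExpressionMatrix(
        gene_ids=row_ids, cell_ids=col_ids, values=values, cell_meta=cell_meta
    )


def _read_id_column(path: str | Path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    if not ids:
        raise ValidationError(f"{path}: empty id file")
    return ids


def write_expression_matrix(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: str = "tsv",
    gene_ids_path: str | Path | None = None,
    cell_ids_path: str | Path | None = None,
) -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        matrix.to_dataframe().to_csv(path, sep=sep, index_label="gene_id")
    elif format == "mtx":
        if gene_ids_path is None or cell_ids_path is None:
            raise ValueError("mtx format requires gene_ids_path and cell_ids_path")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
        Path(gene_ids_path).write_text("".join(g + "\n" for g in matrix.gene_ids))
        Path(cell_ids_path).write_text("".join(c + "\n" for c in matrix.cell_ids))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    return meta


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="cell_id")


def read_marker_panel(path: str | Path) -> MarkerPanel:
    """Load a marker panel from a YAML/JSON config.

    Expected keys: ``lineage_markers`` (mapping with EPI/TE/PE lists, or the
    three lineage keys at top level), optional ``master_regulators`` (default
    NANOG, POU5F1, SOX2) and ``min_markers_per_lineage`` (default 4).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: panel config must be a mapping")
    markers = cfg.get("lineage_markers")
    if markers is None:
        markers = {k: cfg[k] for k in ("EPI", "TE", "PE") if k in cfg}
    missing = {"EPI", "TE", "PE"} - set(markers or {})
    if missing:
        raise ValidationError(f"{path}: panel config missing lineages {sorted(missing)}")
    return MarkerPanel(
        lineage_markers=markers,
        master_regulators=cfg.get("master_regulators", list(DEFAULT_MASTER_REGULATORS)),
        min_markers_per_lineage=cfg.get(
            "min_markers_per_lineage", DEFAULT_MIN_MARKERS_PER_LINEAGE
        ),
    )


def write_marker_panel(panel: MarkerPanel, path: str | Path) -> None:
    cfg = {
        "lineage_markers": {k: list(v) for k, v in panel.lineage_markers.items()},
        "master_regulators": list(panel.master_regulators),
        "min_markers_per_lineage": panel.min_markers_per_lineage,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def format_p_value(p: float | None) -> str:
    if p is None:
        return "NA"
    if p < 1e-3:
        return f"{p:.4E}"
    return f"{p:.8g}"


def write_prevalence_table(rows: Sequence[PrevalenceRow], path: str | Path) -> None:
    """Write prevalence rows as TSV: one header line plus one line per row.

    Percent is printed to one decimal; p-values switch to scientific notation
    below 1e-3.  Degenerate (empty) strata print NA percent and are flagged.
    """
    if not rows:
        raise ValidationError("no prevalence rows to write")
    lines = ["label\tn_total\tn_positive\tpercent\tp_value\ttest\tflagged"]
    for r in rows:
        pct = "NA" if r.percent is None else f"{r.percent:.1f}"
        lines.append(
            f"{r.label}\t{r.n_total}\t{r.n_positive}\t{pct}\t"
            f"{format_p_value(r.p_value)}\t{r.test}\t{str(r.flagged).lower()}"
        )
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_signature(path: str | Path):
    """Read a two-column (gene, weight) TSV signature; provenance from a
    sibling ``<path>.json`` file when present."""
    from .datamodel import SignatureProfile

    df = pd.read_csv(path, sep="\t")
    if not {"gene", "weight"} <= set(df.columns):
        raise ParseError(f"{path}: signature TSV needs 'gene' and 'weight' columns")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SignatureProfile(
        genes=list(df["gene"].astype(str)),
        weights=df["weight"].to_numpy(dtype=float),
        numerator_label=meta.get("numerator_label", "numerator"),
        denominator_label=meta.get("denominator_label", "denominator"),
        pseudocount=meta.get("pseudocount", 1.0),
    )


def write_signature(signature, path: str | Path) -> None:
    pd.DataFrame({"gene": signature.genes, "weight": signature.weights}).to_csv(
        path, sep="\t", index=False
    )
    Path(str(path) + ".json").write_text(
        json.dumps(
            {
                "numerator_label": signature.numerator_label,
                "denominator_label": signature.denominator_label,
                "pseudocount": signature.pseudocount,
            },
            indent=2,
        )
    )


def write_run_manifest(path: str | Path, command: str, params: dict) -> None:
    """Record what produced an output file (command, parameters, seed)."""
    Path(path).write_text(json.dumps({"command": command, **params}, indent=2, default=str))
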