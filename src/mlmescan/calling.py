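"""Binary positivity calling, HPAT-phenotype segregation and prevalence stats.

A gene is called positive in a cell when its value strictly exceeds the
rule's threshold — either a fixed value (default 0: any detected signal) or
the gene's median over all cells of the matrix, the convention used for
validation-style FPKM data.  Ties at the threshold are negative.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .datamodel import (
    BinaryCallMatrix,
    CallRule,
    ExpressionMatrix,
    PrevalenceRow,
    ValidationError,
)

HPAT_GENES = ("HPAT21", "HPAT2", "HPAT15")

#: phenotype of a cell from its (HPAT21, HPAT2, HPAT15) positivity triple
HPAT_PHENOTYPES = {
    (True, False, False): "spHPAT21",
    (True, False, True): "dpHPAT15",
    (True, True, False): "HPAT2pos_double",
    (True, True, True): "HPAT2pos_triple",
    (False, False, False): "null_phenotype",
}


def call_positive(matrix: ExpressionMatrix, rule: CallRule) -> BinaryCallMatrix:
    """Apply a positivity rule; the realised thresholds are stored on the rule.

    ``population_median`` computes each gene's median over *all* cells in the
    matrix; a value equal to the median is negative (strict ``>``).
    """
    if rule.kind == "population_median":
        thresholds = np.median(matrix.values, axis=1)
        realized = CallRule(kind="population_median", threshold=thresholds)
    else:
        thr = np.asarray(rule.threshold, dtype=float)
        if thr.ndim == 0:
            thresholds = np.full(matrix.n_genes, float(thr))
        elif thr.shape == (matrix.n_genes,):
            thresholds = thr
        else:
            raise ValidationError(
                f"per-gene threshold length {thr.shape} does not match "
                f"{matrix.n_genes} genes"
            )
        realized = CallRule(kind="fixed_threshold", threshold=thresholds)
    calls = matrix.values > thresholds[:, None]
    return BinaryCallMatrix(
        gene_ids=list(matrix.gene_ids),
        cell_ids=list(matrix.cell_ids),
        calls=calls,
        rule=realized,
    )


def classify_hpat(calls: BinaryCallMatrix) -> dict[str, str]:
    """Assign each cell its HPAT-expression phenotype.

    The three informative lincRNAs HPAT21, HPAT2 and HPAT15 partition cells
    into single-positive HPAT21 (TE-like), double-positive HPAT15 (PE-like),
    HPAT2-positive double/triple (epiblast-like) and the null phenotype;
    combinations outside the observed patterns are labelled "other".
    """
    missing = [g for g in HPAT_GENES if g not in calls.gene_ids]
    if missing:
        raise ValidationError(f"call matrix lacks required HPAT genes: {missing}")
    idx = calls.gene_index(HPAT_GENES)
    out: dict[str, str] = {}
    for j, cell in enumerate(calls.cell_ids):
        triple = tuple(bool(calls.calls[i, j]) for i in idx)
        out[cell] = HPAT_PHENOTYPES.get(triple, "other")
    return out


def prevalence(
    calls: BinaryCallMatrix,
    groups: Mapping[str, Sequence[str]],
    target_genes: Sequence[str],
    semantics: str = "all",
) -> list[PrevalenceRow]:
    """Per-group counts of cells positive for a gene set.

    ``semantics="all"`` requires positivity for every listed gene (conjunction,
    the multi-marker convention); ``"any"`` requires at least one.  An empty
    group yields a flagged zero-total row rather than being dropped.
    """
    if semantics not in ("all", "any"):
        raise ValueError(f"unknown semantics {semantics!r}")
    gidx = calls.gene_index(target_genes)
    sub = calls.calls[gidx, :]
    positive = sub.all(axis=0) if semantics == "all" else sub.any(axis=0)
    cell_pos = {c: i for i, c in enumerate(calls.cell_ids)}
    rows = []
    for label, cells in groups.items():
        idx = [cell_pos[c] for c in cells if c in cell_pos]
        if len(idx) != len(cells):
            unknown = [c for c in cells if c not in cell_pos]
            raise KeyError(f"group {label!r} references unknown cells: {unknown[:5]}")
        n_total = len(idx)
        n_positive = int(positive[idx].sum()) if n_total else 0
        rows.append(PrevalenceRow(label=label, n_total=n_total, n_positive=n_positive))
    return rows


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sided by point-probability summation: all tables with the observed
    margins whose hypergeometric probability is at most that of the observed
    table contribute to p.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValidationError(f"table entries must be non-negative integers, got {v}")
    if a + b + c + d == 0:
        raise ValidationError("empty table")
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; p from chi2(k-1).

    For k identical groups scipy raises on zero variance; that situation is
    the no-separation case, returned here as (H=0, p=1).
    """
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis requires at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("kruskal_wallis groups must be nonempty")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)
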