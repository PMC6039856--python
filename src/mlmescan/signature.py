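"""Ratio-based gene signatures and per-cell correlation scoring.

A signature is the per-gene log2 ratio of mean expression between two cell
populations (e.g. telomerase-positive cells versus epiblast cells), with a
pseudocount guarding zeros.  A cell's score is the Pearson correlation of its
log-transformed, per-cell-centred expression profile over the signature genes
with the signature weights; cells whose score strictly exceeds a cutoff
(0.5 by default; 0.4 and 0.55 as named presets) are MLME-resembling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .datamodel import ExpressionMatrix, SignatureProfile, ValidationError

CUTOFF_PRESETS = {"lenient": 0.4, "default": 0.5, "stringent": 0.55}


def derive_ratio_signature(
    matrix: ExpressionMatrix,
    numerator_cells: Sequence[str],
    denominator_cells: Sequence[str],
    genes: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    numerator_label: str = "numerator",
    denominator_label: str = "denominator",
) -> SignatureProfile:
    """weight_g = log2((mean_g(numerator) + pc) / (mean_g(denominator) + pc))."""
    if not (pseudocount > 0):
        raise ValidationError("pseudocount must be positive")
    num = list(numerator_cells)
    den = list(denominator_cells)
    if not num or not den:
        raise ValidationError("numerator and denominator cell sets must be nonempty")
    if set(num) & set(den):
        raise ValidationError("numerator and denominator cell sets overlap")
    if genes is None:
        genes = list(matrix.gene_ids)
    gidx = matrix.gene_index(genes)
    num_idx = matrix.cell_index(num)
    den_idx = matrix.cell_index(den)
    mean_num = matrix.values[np.ix_(gidx, num_idx)].mean(axis=1)
    mean_den = matrix.values[np.ix_(gidx, den_idx)].mean(axis=1)
    weights = np.log2((mean_num + pseudocount) / (mean_den + pseudocount))
    return SignatureProfile(
        genes=list(genes),
        weights=weights,
        numerator_label=numerator_label,
        denominator_label=denominator_label,
        pseudocount=pseudocount,
    )


def _transform_profile(
    profile: np.ndarray, transform: str, pseudocount: float
) -> np.ndarray:
    if transform == "log2":
        x = np.log2(np.asarray(profile, dtype=float) + pseudocount)
    elif transform == "raw":
        x = np.asarray(profile, dtype=float)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return x - x.mean()


def correlation_score(
    profile: Sequence[float],
    signature: SignatureProfile,
    transform: str = "log2",
    method: str = "pearson",
) -> float | None:
    """Correlation of one expression profile (ordered as signature.genes)
    with the signature weights; ``None`` when the score is undefined
    (zero variance on either side)."""
    x = _transform_profile(np.asarray(profile, dtype=float), transform, signature.pseudocount)
    w = signature.weights
    if len(x) != len(w):
        raise ValidationError("profile length does not match signature")
    if len(x) < 3:
        raise ValidationError("need at least 3 signature genes")
    if np.ptp(x) == 0 or np.ptp(w) == 0:
        return None
    if method == "pearson":
        r = scipy.stats.pearsonr(x, w)[0]
    elif method == "spearman":
        r = scipy.stats.spearmanr(x, w)[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    return None if math.isnan(r) else float(r)


def score_cells(
    matrix: ExpressionMatrix,
    signature: SignatureProfile,
    cells: Sequence[str] | None = None,
    transform: str = "log2",
    method: str = "pearson",
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Score each cell against the signature.

    Returns a DataFrame indexed by cell id with columns ``score`` (NaN when
    undefined), ``defined``, ``rank`` (1 = highest score; undefined scores
    rank last; ties broken by cell id) and ``is_mlme_like`` (score strictly
    above ``cutoff``; undefined scores are never MLME-like).
    """
    cells = list(matrix.cell_ids) if cells is None else list(cells)
    gidx = matrix.gene_index(signature.genes)
    cidx = matrix.cell_index(cells)
    sub = matrix.values[np.ix_(gidx, cidx)]
    scores = np.full(len(cells), np.nan)
    for j in range(len(cells)):
        r = correlation_score(sub[:, j], signature, transform=transform, method=method)
        if r is not None:
            scores[j] = r
    df = pd.DataFrame({"score": scores}, index=pd.Index(cells, name="cell_id"))
    df["defined"] = ~df["score"].isna()
    order = sorted(
        range(len(cells)),
        key=lambda i: (-(scores[i] if not np.isnan(scores[i]) else -np.inf), cells[i]),
    )
    ranks = np.empty(len(cells), dtype=int)
    ranks[order] = np.arange(1, len(cells) + 1)
    df["rank"] = ranks
    df["is_mlme_like"] = df["defined"] & (df["score"] > cutoff)
    return df


def population_score(
    matrix: ExpressionMatrix,
    signature: SignatureProfile,
    cells: Sequence[str],
    transform: str = "log2",
    method: str = "pearson",
) -> float | None:
    """Population-based correlation score: the group-mean expression profile
    over the signature genes scored against the signature."""
    gidx = matrix.gene_index(signature.genes)
    cidx = matrix.cell_index(list(cells))
    mean_profile = matrix.values[np.ix_(gidx, cidx)].mean(axis=1)
    return correlation_score(mean_profile, signature, transform=transform, method=method)


def classify_by_score(scores: pd.DataFrame, cutoff: float | str = 0.5) -> pd.DataFrame:
    """Relabel ``is_mlme_like`` at a cutoff (strict >); presets by name."""
    if isinstance(cutoff, str):
        cutoff = CUTOFF_PRESETS[cutoff]
    if not (-1.0 <= cutoff <= 1.0):
        raise ValidationError(f"cutoff {cutoff} outside [-1, 1]")
    out = scores.copy()
    out["is_mlme_like"] = out["defined"] & (out["score"] > cutoff)
    return out


def refine_signature(
    matrix: ExpressionMatrix,
    scores: pd.DataFrame,
    signature: SignatureProfile,
    cutoff: float = 0.5,
    alpha: float = 0.05,
    test: str = "ranksum",
) -> SignatureProfile:
    """Keep signature genes that differ between high- and low-scoring cells.

    Cells with score > cutoff form the positive group, the rest the negative
    group; genes with a two-sided rank-sum (or Welch t) p < alpha are
    retained and their weights re-derived between the two groups.
    """
    defined = scores[scores["defined"]]
    pos_cells = list(defined.index[defined["score"] > cutoff])
    neg_cells = list(defined.index[defined["score"] <= cutoff])
    if not pos_cells or not neg_cells:
        raise ValidationError(
            f"score cutoff {cutoff} leaves an empty group "
            f"({len(pos_cells)} above, {len(neg_cells)} at-or-below); adjust the cutoff"
        )
    gidx = matrix.gene_index(signature.genes)
    pos = matrix.values[np.ix_(gidx, matrix.cell_index(pos_cells))]
    neg = matrix.values[np.ix_(gidx, matrix.cell_index(neg_cells))]
    keep: list[str] = []
    for i, gene in enumerate(signature.genes):
        a, b = pos[i], neg[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue  # identical constant -> no evidence of difference
        if test == "ranksum":
            p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")[1]
        elif test == "ttest":
            p = scipy.stats.ttest_ind(a, b, equal_var=False)[1]
        else:
            raise ValueError(f"unknown test {test!r}")
        if p < alpha:
            keep.append(gene)
    refined = derive_ratio_signature(
        matrix,
        numerator_cells=pos_cells,
        denominator_cells=neg_cells,
        genes=keep,
        pseudocount=signature.pseudocount,
        numerator_label=f"score>{cutoff}",
        denominator_label=f"score<={cutoff}",
    )
    return refined


@dataclass
class TopScoringSelection:
    cells: list[str]
    k: int
    satisfiable: bool
    missing_stages: list[str]


def select_top_scoring(
    scores: pd.DataFrame,
    cell_meta: pd.DataFrame,
    stages_required: Sequence[str],
) -> TopScoringSelection:
    """Smallest top-k prefix of the score ranking containing at least one
    cell from every required stage.

    Cells are ordered by descending score with ties (and the k-th boundary)
    broken by lexicographic cell id.  If some required stage has no scored
    cells the criterion is unsatisfiable: all cells are returned, flagged.
    """
    if scores.empty:
        raise ValidationError("no scores supplied")
    defined = scores[scores["defined"]]
    order = sorted(
        defined.index, key=lambda c: (-float(defined.loc[c, "score"]), str(c))
    )
    stage_of = cell_meta["stage"]
    available = {stage_of.get(c) for c in order}
    required = list(stages_required)
    missing = [s for s in required if s not in available]
    if missing:
        return TopScoringSelection(
            cells=list(order), k=len(order), satisfiable=False, missing_stages=missing
        )
    outstanding = set(required)
    for k, cell in enumerate(order, start=1):
        outstanding.discard(stage_of.get(cell))
        if not outstanding:
            return TopScoringSelection(
                cells=order[:k], k=k, satisfiable=True, missing_stages=[]
            )
    raise AssertionError("unreachable: required stages verified present")
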