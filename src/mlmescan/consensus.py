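"""Cross-dataset consensus signatures and maternal/embryonic origin summary.

Genes differentially expressed between MLME-like and other cells are computed
independently in two datasets; the consensus keeps genes significant in both
with the same direction of change.  Each consensus gene can carry a
maternal / embryonic transcriptional-origin label (supplied as annotation,
never inferred), summarised as the fraction of up-regulated genes of
embryonic origin and of down-regulated genes of maternal origin.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.stats.multitest

from .datamodel import ExpressionMatrix, ValidationError, round_half_up


def differential_genes(
    matrix: ExpressionMatrix,
    group_pos: Sequence[str],
    group_neg: Sequence[str],
    genes: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    test: str = "ranksum",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene effect (log2 mean ratio with pseudocount) and two-sided p.

    The rank-sum (Mann-Whitney) test is the default; Welch's t is available.
    ``fdr=True`` adds a Benjamini-Hochberg adjusted column ``p_adj``.
    """
    pos = list(group_pos)
    neg = list(group_neg)
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError("each group needs at least 2 cells")
    if set(pos) & set(neg):
        raise ValidationError("groups overlap")
    if genes is None:
        genes = list(matrix.gene_ids)
    gidx = matrix.gene_index(genes)
    a = matrix.values[np.ix_(gidx, matrix.cell_index(pos))]
    b = matrix.values[np.ix_(gidx, matrix.cell_index(neg))]
    effect = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    if test == "ranksum":
        with warnings.catch_warnings():
            # constant genes yield exact-tie warnings; their p is 1 as desired
            warnings.simplefilter("ignore")
            p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", axis=1)[1]
    elif test == "ttest":
        p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)[1]
    else:
        raise ValueError(f"unknown test {test!r}")
    p = np.where(np.isnan(p), 1.0, p)
    out = pd.DataFrame(
        {"effect": effect, "p": p}, index=pd.Index(genes, name="gene_id")
    )
    if fdr:
        out["p_adj"] = statsmodels.stats.multitest.multipletests(
            out["p"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def concordant_consensus(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    alpha: float = 0.05,
    origins: Mapping[str, str] | pd.Series | None = None,
    p_column: str = "p",
) -> pd.DataFrame:
    """Genes significant in both datasets with concordant direction of change.

    Returns one row per consensus gene: direction (up/down from the shared
    effect sign), per-dataset effects and p-values, and the origin label
    (maternal / embryonic / unknown) when an annotation is supplied.
    """
    shared = stats_a.index.intersection(stats_b.index)
    if shared.empty:
        warnings.warn("no shared genes between the two datasets", stacklevel=2)
    a = stats_a.loc[shared]
    b = stats_b.loc[shared]
    sig = (a[p_column] < alpha) & (b[p_column] < alpha)
    sign_a = np.sign(a["effect"])
    concordant = sig & (sign_a == np.sign(b["effect"])) & (sign_a != 0)
    keep = shared[concordant]
    out = pd.DataFrame(
        {
            "direction": np.where(a.loc[keep, "effect"] > 0, "up", "down"),
            "effect_a": a.loc[keep, "effect"],
            "effect_b": b.loc[keep, "effect"],
            "p_a": a.loc[keep, p_column],
            "p_b": b.loc[keep, p_column],
        },
        index=pd.Index(keep, name="gene_id"),
    )
    if origins is not None:
        origins = pd.Series(origins)
        out["origin"] = [
            origins.get(g, "unknown") if pd.notna(origins.get(g, None)) else "unknown"
            for g in out.index
        ]
    else:
        out["origin"] = "unknown"
    return out


def concordance_correlation(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame
) -> float | None:
    """Pearson r between the two datasets' per-gene effects over shared genes;
    None when fewer than 3 shared genes or no variance."""
    shared = stats_a.index.intersection(stats_b.index)
    if len(shared) < 3:
        return None
    x = stats_a.loc[shared, "effect"].to_numpy()
    y = stats_b.loc[shared, "effect"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(scipy.stats.pearsonr(x, y)[0])


def origin_summary(consensus: pd.DataFrame) -> dict:
    """Origin breakdown of a consensus table.

    Percentages are over origin-labelled genes only (unknowns surfaced as
    counts); an empty consensus or direction yields None for that fraction.
    """
    out: dict = {"n_genes": int(len(consensus))}
    table: dict[str, dict[str, int]] = {}
    for direction in ("up", "down"):
        sub = consensus[consensus["direction"] == direction]
        counts = {
            o: int((sub["origin"] == o).sum())
            for o in ("maternal", "embryonic", "unknown")
        }
        table[direction] = counts
        labelled = counts["maternal"] + counts["embryonic"]
        out[f"n_{direction}"] = int(len(sub))
        out[f"n_{direction}_unknown"] = counts["unknown"]
        focal = "embryonic" if direction == "up" else "maternal"
        out[f"pct_{direction}_{focal}"] = (
            round_half_up(100.0 * counts[focal] / labelled, 1) if labelled else None
        )
    out["table"] = table
    return out
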