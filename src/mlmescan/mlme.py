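"""The digital multi-lineage (MLME) classification rule and subset enrichment.

A cell carries the MLME phenotype when its binary expression calls show at
least ``min_markers_per_lineage`` positive markers of *each* of EPI, TE and
PE and all master regulators positive.  Enrichment of MLME cells within a
cell subset against a background is quantified with the hypergeometric
distribution, exactly, as a log-space sum of point probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .datamodel import (
    BinaryCallMatrix,
    ContingencyCounts,
    MarkerPanel,
    PrevalenceRow,
    ValidationError,
)


def call_mlme(calls: BinaryCallMatrix, panel: MarkerPanel) -> pd.Series:
    """Per-cell boolean MLME phenotype under the digital multi-marker rule.

    Master regulators are required positives for every MLME cell regardless
    of panel membership; they count toward a lineage's marker tally only when
    listed in that lineage's marker list.
    """
    missing = [g for g in panel.all_genes if g not in set(calls.gene_ids)]
    if missing:
        raise ValidationError(f"panel genes absent from call matrix: {missing}")
    ok = np.ones(len(calls.cell_ids), dtype=bool)
    for lineage in ("EPI", "TE", "PE"):
        gidx = calls.gene_index(panel.lineage_markers[lineage])
        tally = calls.calls[gidx, :].sum(axis=0)
        ok &= tally >= panel.min_markers_per_lineage
    if panel.master_regulators:
        midx = calls.gene_index(panel.master_regulators)
        ok &= calls.calls[midx, :].all(axis=0)
    return pd.Series(ok, index=pd.Index(calls.cell_ids, name="cell_id"), name="is_mlme")


def _log_tail_sum(N: int, K: int, n: int, k_from: int, k_to: int) -> float:
    """Exact hypergeometric tail P(k_from <= X <= k_to), summed in log space."""
    ks = np.arange(k_from, k_to + 1)
    if ks.size == 0:
        return 0.0
    logs = scipy.stats.hypergeom.logpmf(ks, N, K, n)
    return float(np.exp(scipy.special.logsumexp(logs)))


def hypergeom_enrichment(counts: ContingencyCounts, tail: str = "upper") -> float:
    """Hypergeometric probability that a subset of size n from a background
    of N cells (K of them labelled) contains k labelled members.

    tail="upper": P(X >= k), the enrichment test; tail="lower": P(X <= k),
    depletion; tail="point": the point probability P(X = k) — the quantity
    tabulated in the published prevalence tables (see docs/methods.md).

    The lower tail is evaluated as the upper tail of the complement subset
    (P(X <= k) = P(X' >= K - k) for the complementary n' = N - n cells), so a
    subset's enrichment p and its complement's depletion p are the *same*
    floating-point computation and agree exactly.
    """
    N, K, n, k = counts.N, counts.K, counts.n, counts.k
    if tail == "point":
        p = float(np.exp(scipy.stats.hypergeom.logpmf(k, N, K, n)))
    elif tail == "upper":
        p = _log_tail_sum(N, K, n, k, min(K, n))
    elif tail == "lower":
        comp = ContingencyCounts(N=N, K=K, n=N - n, k=K - k)
        return hypergeom_enrichment(comp, tail="upper")
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def rank_band_sizes(n: int, fractions: Sequence[float]) -> list[int]:
    """Generic top-x% band sizes: ceiling(n * x), at least 1."""
    return [max(1, int(np.ceil(n * x))) for x in fractions]


@dataclass
class Stratum:
    """A labelled cell subset evaluated against a declared background."""

    label: str
    cells: Sequence[str]
    background: Sequence[str]
    tail: str = "upper"


def top_rank_stratum(
    scores: pd.DataFrame,
    cells: Sequence[str],
    n_top: int,
    label: str,
    background: Sequence[str] | None = None,
    complement: bool = False,
) -> Stratum:
    """Stratum of the n_top highest-scoring cells (descending score, ties by
    cell id) within ``cells``, or its complement."""
    pool = [c for c in cells if c in scores.index]
    order = sorted(pool, key=lambda c: (-float(scores.loc[c, "score"]), str(c)))
    chosen = order[n_top:] if complement else order[:n_top]
    return Stratum(
        label=label,
        cells=chosen,
        background=list(background) if background is not None else list(cells),
    )


def build_prevalence_report(
    mlme_flags: pd.Series,
    strata: Sequence[Stratum],
    tail: str | None = None,
) -> list[PrevalenceRow]:
    """Prevalence rows with hypergeometric enrichment p-values.

    Each stratum is tested against its declared background; ``tail`` overrides
    every stratum's tail convention when given (``"point"`` reproduces the
    published tables).  Empty strata are flagged, not dropped.
    """
    rows = []
    for st in strata:
        bg = list(st.background)
        sub = list(st.cells)
        unknown = [c for c in sub + bg if c not in mlme_flags.index]
        if unknown:
            raise KeyError(f"stratum {st.label!r} references unknown cells: {unknown[:5]}")
        if not set(sub) <= set(bg):
            raise ValidationError(f"stratum {st.label!r} not contained in its background")
        N = len(bg)
        K = int(mlme_flags.loc[bg].sum())
        n = len(sub)
        k = int(mlme_flags.loc[sub].sum()) if sub else 0
        if n == 0 or N == 0:
            rows.append(
                PrevalenceRow(label=st.label, n_total=n, n_positive=k, flagged=True)
            )
            continue
        use_tail = tail if tail is not None else st.tail
        p = hypergeom_enrichment(ContingencyCounts(N=N, K=K, n=n, k=k), tail=use_tail)
        rows.append(
            PrevalenceRow(
                label=st.label,
                n_total=n,
                n_positive=k,
                p_value=p,
                test=f"hypergeometric:{use_tail}",
            )
        )
    return rows
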