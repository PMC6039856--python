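"""Eigen-spectrum gene filtering for heatmap preparation.

Pipeline: (1) a piecewise FPKM transform — log2(x) above 2, x/2 at or below
2 — plus a negligible positive uniform jitter (< 1e-5) that breaks ties;
(2) iterative removal of the least informative gene, defined as the gene
with the smallest contribution to the variance captured by the leading
eigenvectors that account for 95% of total variance; (3) a halting rule on
the Shannon entropy of the normalised covariance eigenvalue spectrum — when
a removal would change the entropy by at least the threshold (10% default,
7% for small datasets) relative to the unfiltered matrix, that gene is
restored and filtering stops.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ValidationError

JITTER_SCALE = 1e-5


def transform_fpkm(values: np.ndarray, jitter_seed: int | None = 0) -> np.ndarray:
    """Piecewise transform: log2(x) for x > 2, x/2 for x <= 2, plus uniform
    jitter in (0, 1e-5).  Jitter is drawn once per matrix under the seed;
    ``jitter_seed=None`` disables it."""
    values = np.asarray(values, dtype=float)
    if (values < 0).any():
        raise ValidationError("FPKM values must be non-negative")
    out = np.where(values > 2, np.log2(np.maximum(values, 1e-300)), values / 2.0)
    if jitter_seed is not None:
        rng = np.random.default_rng(jitter_seed)
        jitter = rng.uniform(0.0, JITTER_SCALE, size=values.shape)
        # open interval (0, 1e-5): resample exact zeros (probability ~0)
        while (jitter == 0).any():
            jitter[jitter == 0] = rng.uniform(0.0, JITTER_SCALE, int((jitter == 0).sum()))
        out = out + jitter
    return out


def _eigen_spectrum(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Descending eigenvalues and matching eigenvectors (columns) of the
    gene-gene covariance, cells as observations."""
    n_genes, n_cells = values.shape
    if n_genes < 2 or n_cells < 2:
        raise ValidationError("need at least 2 genes and 2 cells")
    centered = values - values.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / (n_cells - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    return evals, evecs[:, order]


def gene_contributions(
    values: np.ndarray,
    variance_fraction: float = 0.95,
    weighting: str = "eigenvalue",
) -> np.ndarray:
    """Per-gene contribution to the variance captured by the leading
    eigenvectors accounting for ``variance_fraction`` of total variance.

    With the default eigenvalue weighting, contribution_g = sum over the
    leading components j of lambda_j * loading_{g,j}^2, so contributions over
    genes sum to the captured variance.  ``weighting="unweighted"`` drops the
    lambda_j factor.
    """
    evals, evecs = _eigen_spectrum(np.asarray(values, dtype=float))
    total = evals.sum()
    if total <= 0:
        raise ValidationError("matrix has zero total variance")
    n_comp = int(np.searchsorted(np.cumsum(evals) / total, variance_fraction) + 1)
    n_comp = min(n_comp, len(evals))
    lead_vals = evals[:n_comp]
    lead_vecs = evecs[:, :n_comp]
    if weighting == "eigenvalue":
        contrib = (lead_vecs**2) @ lead_vals
    elif weighting == "unweighted":
        contrib = (lead_vecs**2).sum(axis=1)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return np.asarray(contrib)


def spectrum_entropy(values: np.ndarray) -> float:
    """Shannon entropy (natural log) of the covariance eigenvalue spectrum
    normalised to sum 1; lies in [0, ln(rank)]."""
    evals, _ = _eigen_spectrum(np.asarray(values, dtype=float))
    total = evals.sum()
    if total <= 0:
        raise ValidationError("matrix has zero total variance")
    p = evals / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _n_components(values: np.ndarray, variance_fraction: float) -> int:
    evals, _ = _eigen_spectrum(values)
    return int(np.searchsorted(np.cumsum(evals) / evals.sum(), variance_fraction) + 1)


def iterative_filter(
    values: np.ndarray,
    gene_ids: Sequence[str],
    entropy_change_threshold: float = 0.10,
    variance_fraction: float = 0.95,
    weighting: str = "eigenvalue",
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the least informative gene until the spectrum entropy
    has drifted by the threshold.

    At each step the gene with the smallest contribution (ties broken by
    lexicographically smallest gene id) is provisionally removed; if the
    entropy of the reduced matrix differs from the initial entropy by at
    least ``entropy_change_threshold`` (relative), the gene is restored and
    filtering halts.  Returns the retained gene ids (input order) and a trace
    with one row per executed removal: iteration, gene, contribution, entropy
    after removal, relative entropy change, and the number of leading
    components carrying 95% of variance at that step.
    """
    if not (0.0 < entropy_change_threshold < 1.0):
        raise ValidationError("entropy_change_threshold must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    gene_ids = [str(g) for g in gene_ids]
    if values.shape[0] != len(gene_ids):
        raise ValidationError("gene_ids length does not match matrix rows")
    if len(gene_ids) < 3:
        raise ValidationError("need at least 3 genes to filter")

    h0 = spectrum_entropy(values)
    if h0 <= 0:
        raise ValidationError("degenerate initial spectrum (zero entropy)")

    keep = np.ones(len(gene_ids), dtype=bool)
    trace_rows = []
    iteration = 0
    while keep.sum() > 2:
        sub = values[keep]
        contrib = gene_contributions(sub, variance_fraction, weighting)
        kept_idx = np.flatnonzero(keep)
        # smallest contribution; ties -> lexicographically smallest gene id
        order = sorted(range(len(kept_idx)), key=lambda i: (contrib[i], gene_ids[kept_idx[i]]))
        victim_local = order[0]
        victim = kept_idx[victim_local]

        trial = keep.copy()
        trial[victim] = False
        h = spectrum_entropy(values[trial])
        rel_change = abs(h - h0) / h0
        if rel_change >= entropy_change_threshold:
            break  # restore the crossing gene: stop before exceeding
        keep = trial
        iteration += 1
        trace_rows.append(
            {
                "iteration": iteration,
                "removed_gene": gene_ids[victim],
                "contribution": float(contrib[victim_local]),
                "entropy_after": h,
                "relative_entropy_change": rel_change,
                "n_components_95": _n_components(values[keep], variance_fraction),
            }
        )

    retained = [g for g, k in zip(gene_ids, keep) if k]
    trace = pd.DataFrame(
        trace_rows,
        columns=[
            "iteration",
            "removed_gene",
            "contribution",
            "entropy_after",
            "relative_entropy_change",
            "n_components_95",
        ],
    )
    return retained, trace
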