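"""Core data containers for embryonic single-cell expression analysis.

The central container is :class:`ExpressionMatrix`, a dense non-negative
genes x cells matrix (FPKM-like units) with per-cell metadata (embryo,
developmental stage, lineage, dataset) and per-gene metadata (maternal /
embryonic transcriptional origin, marker-panel tags).  All downstream maths
assumes the genes x cells orientation; readers normalise orientation on load.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STAGES = ("E3", "E4.early", "E4", "E5.early", "E5", "E6", "E7", "other")
LINEAGES = ("EPI", "PE", "TE", "pre-lineage", "unassigned")
ORIGINS = ("maternal", "embryonic", "unknown")

#: canonical master pluripotency regulators required by the MLME rule
DEFAULT_MASTER_REGULATORS = ("NANOG", "POU5F1", "SOX2")
DEFAULT_MIN_MARKERS_PER_LINEAGE = 4


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed in the declared dialect."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching how percentages are tabulated.

    Python/numpy bankers' rounding would print 0.25 -> 0.2; prevalence tables
    use conventional half-up rounding (0.25 -> 0.3).
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    cell_ids: list[str]
    values: np.ndarray  # genes x cells, non-negative
    cell_meta: pd.DataFrame | None = None  # indexed by cell id
    gene_meta: pd.DataFrame | None = None  # indexed by gene id

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValidationError("expression matrix has no genes")
        if len(self.cell_ids) == 0:
            raise ValidationError("expression matrix has no cells")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = _duplicates(self.cell_ids)
            raise ValidationError(f"duplicate cell ids: {dupes}")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")
        if (self.values < 0).any():
            g, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.gene_ids[g]!r}, "
                f"cell {self.cell_ids[c]!r}"
            )
        for meta, ids, what in (
            (self.cell_meta, self.cell_ids, "cell"),
            (self.gene_meta, self.gene_ids, "gene"),
        ):
            if meta is not None:
                unknown = set(meta.index.astype(str)) - set(ids)
                if unknown:
                    raise ValidationError(
                        f"{what}_meta keys not present in matrix: {sorted(unknown)[:5]}"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def cell_index(self, cells: Sequence[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in lookup]
        if missing:
            raise KeyError(f"cells not in matrix: {missing}")
        return np.array([lookup[c] for c in cells], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        cell_meta: pd.DataFrame | None = None,
        gene_meta: pd.DataFrame | None = None,
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(df.index.astype(str)),
            cell_ids=list(df.columns.astype(str)),
            values=df.to_numpy(dtype=float),
            cell_meta=cell_meta,
            gene_meta=gene_meta,
        )

    def to_anndata(self):
        """Export as an AnnData (cells as observations), for the scanpy world."""
        import anndata

        return anndata.AnnData(
            X=self.values.T.copy(),
            obs=(self.cell_meta.loc[self.cell_ids].copy()
                 if self.cell_meta is not None
                 else pd.DataFrame(index=self.cell_ids)),
            var=(self.gene_meta.loc[self.gene_ids].copy()
                 if self.gene_meta is not None
                 else pd.DataFrame(index=self.gene_ids)),
        )


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in ids:
        if x in seen:
            out.append(x)
        seen.add(x)
    return out[:5]


@dataclass
class MarkerPanel:
    """Lineage marker panel for the digital multi-lineage (MLME) rule.

    A cell carries the MLME phenotype when it is positive for at least
    ``min_markers_per_lineage`` markers of each of EPI, TE and PE *and* for
    every master regulator.  Master regulators count toward a lineage tally
    only when they are also listed in that lineage's marker list.
    """

    lineage_markers: Mapping[str, Sequence[str]]
    master_regulators: Sequence[str] = DEFAULT_MASTER_REGULATORS
    min_markers_per_lineage: int = DEFAULT_MIN_MARKERS_PER_LINEAGE

    def __post_init__(self) -> None:
        self.lineage_markers = {k: list(v) for k, v in dict(self.lineage_markers).items()}
        self.master_regulators = list(self.master_regulators)
        missing = {"EPI", "TE", "PE"} - set(self.lineage_markers)
        if missing:
            raise ValidationError(f"marker panel missing lineages: {sorted(missing)}")
        for lin, genes in self.lineage_markers.items():
            if not genes:
                raise ValidationError(f"empty marker list for lineage {lin!r}")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"duplicate genes in {lin!r} marker list: {_duplicates(genes)}")
        if len(set(self.master_regulators)) != len(self.master_regulators):
            raise ValidationError("duplicate master regulators")
        if int(self.min_markers_per_lineage) < 1:
            raise ValidationError("min_markers_per_lineage must be >= 1")
        self.min_markers_per_lineage = int(self.min_markers_per_lineage)

    @property
    def all_genes(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for lin in ("EPI", "TE", "PE"):
            for g in self.lineage_markers[lin]:
                if g not in seen:
                    out.append(g)
                    seen.add(g)
        for g in self.master_regulators:
            if g not in seen:
                out.append(g)
                seen.add(g)
        return out

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.gene_ids)
        missing = [g for g in self.all_genes if g not in known]
        if missing:
            raise ValidationError(f"panel genes absent from matrix: {missing}")


@dataclass
class CallRule:
    """Positivity rule: strictly-greater-than a fixed or per-gene threshold.

    ``population_median`` thresholds each gene at its median over *all* cells
    of the matrix the rule is applied to (a value tied with the median is
    called negative); the realised per-gene medians are stored back on the
    rule for provenance.
    """

    kind: str  # "fixed_threshold" | "population_median"
    threshold: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed_threshold", "population_median"):
            raise ValidationError(f"unknown call rule kind {self.kind!r}")
        if self.kind == "fixed_threshold":
            if self.threshold is None:
                self.threshold = 0.0
            thr = np.asarray(self.threshold, dtype=float)
            if (thr < 0).any():
                raise ValidationError("fixed threshold must be >= 0")


@dataclass
class BinaryCallMatrix:
    gene_ids: list[str]
    cell_ids: list[str]
    calls: np.ndarray  # bool, genes x cells
    rule: CallRule

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("call matrix shape does not match id lists")

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in call matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class SignatureProfile:
    """Ordered gene list with log2-ratio weights and derivation provenance."""

    genes: list[str]
    weights: np.ndarray
    numerator_label: str = "numerator"
    denominator_label: str = "denominator"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValidationError("signature genes and weights differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"duplicate signature genes: {_duplicates(self.genes)}")
        if not np.isfinite(self.weights).all():
            raise ValidationError("signature weights must be finite")
        if not (self.pseudocount > 0):
            raise ValidationError("pseudocount must be positive")

    def __len__(self) -> int:
        return len(self.genes)

    def subset(self, genes: Sequence[str]) -> "SignatureProfile":
        keep = [g for g in self.genes if g in set(genes)]
        idx = [self.genes.index(g) for g in keep]
        return SignatureProfile(
            genes=keep,
            weights=self.weights[idx],
            numerator_label=self.numerator_label,
            denominator_label=self.denominator_label,
            pseudocount=self.pseudocount,
        )


@dataclass
class PrevalenceRow:
    """One row of a prevalence table: a labelled population with counts."""

    label: str
    n_total: int
    n_positive: int
    p_value: float | None = None
    test: str = ""
    flagged: bool = False  # set for empty / degenerate strata

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_positive < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_positive > self.n_total:
            raise ValidationError("n_positive exceeds n_total")
        if self.n_total == 0:
            self.flagged = True

    @property
    def percent(self) -> float | None:
        if self.n_total == 0:
            return None
        return round_half_up(100.0 * self.n_positive / self.n_total, 1)


@dataclass
class ContingencyCounts:
    """(N, K, n, k): a subset of size n with k labelled members, drawn from a
    background of N cells of which K are labelled."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        for name in ("N", "K", "n", "k"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
            setattr(self, name, int(v))
        if self.K > self.N or self.n > self.N:
            raise ValidationError("K and n must not exceed N")
        if self.k > min(self.K, self.n) or self.k < max(0, self.n + self.K - self.N):
            raise ValidationError(
                f"k={self.k} outside hypergeometric support "
                f"[{max(0, self.n + self.K - self.N)}, {min(self.K, self.n)}]"
            )
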