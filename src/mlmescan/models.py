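"""High-level model/results interface over the MLME pipeline.

``MLMEAnalysis`` bundles an expression matrix, a marker panel and the
positivity rule; ``fit()`` runs binary calling, the digital MLME rule,
optional signature scoring, TERT+/TERT- prevalence with hypergeometric
enrichment, and the per-stage emergence timeline, returning an
``MLMEResults`` whose ``summary()`` is a printable report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from . import calling, mlme, signature as sigmod, timeline as tlmod
from .datamodel import (
    BinaryCallMatrix,
    CallRule,
    ExpressionMatrix,
    MarkerPanel,
    PrevalenceRow,
    SignatureProfile,
    ValidationError,
)
from .io import format_p_value


class MLMEAnalysis:
    """Digital MLME phenotyping of an expression matrix.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Genes x cells expression values with cell metadata.
    panel : MarkerPanel
        Lineage markers, master regulators and the per-lineage tally.
    rule : CallRule, optional
        Positivity rule; population median by default (the validation-data
        convention).
    signature : SignatureProfile, optional
        When given, cells are also scored against the signature and the
        prevalence report gains top-score-band rows.
    tert_gene : str
        Gene whose positivity defines telomerase status (default "TERT").
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        panel: MarkerPanel,
        rule: CallRule | None = None,
        signature: SignatureProfile | None = None,
        tert_gene: str = "TERT",
        cells_per_embryo: Mapping[str, int] | None = None,
        score_band_fractions: Sequence[float] = (0.03, 0.05, 0.10),
    ) -> None:
        panel.validate_against(matrix)
        self.matrix = matrix
        self.panel = panel
        self.rule = rule if rule is not None else CallRule(kind="population_median")
        self.signature = signature
        self.tert_gene = tert_gene
        self.cells_per_embryo = dict(cells_per_embryo) if cells_per_embryo else None
        self.score_band_fractions = tuple(score_band_fractions)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        panel: MarkerPanel,
        cell_meta: pd.DataFrame | None = None,
        **kwargs,
    ) -> "MLMEAnalysis":
        return cls(ExpressionMatrix.from_dataframe(df, cell_meta=cell_meta), panel, **kwargs)

    def fit(self, enrichment_tail: str | None = None) -> "MLMEResults":
        """Run the pipeline.

        ``enrichment_tail=None`` (default) tests each stratum with its natural
        tail (upper for enrichment rows, lower for the depleted complement);
        pass ``"point"`` for point probabilities as tabulated in published
        prevalence tables.
        """
        calls = calling.call_positive(self.matrix, self.rule)
        mlme_flags = mlme.call_mlme(calls, self.panel)

        tert_flags = None
        if self.tert_gene in calls.gene_ids:
            row = calls.gene_index([self.tert_gene])[0]
            tert_flags = pd.Series(
                calls.calls[row], index=pd.Index(calls.cell_ids, name="cell_id"),
                name="is_tert_positive",
            )

        scores = None
        if self.signature is not None:
            scores = sigmod.score_cells(self.matrix, self.signature)

        strata = self._build_strata(mlme_flags, tert_flags, scores)
        report = mlme.build_prevalence_report(mlme_flags, strata, tail=enrichment_tail)

        estimates = None
        if self.cells_per_embryo is not None and self.matrix.cell_meta is not None:
            estimates = tlmod.stage_timeline(
                mlme_flags, self.matrix.cell_meta, self.cells_per_embryo
            )

        return MLMEResults(
            model=self,
            calls=calls,
            mlme_flags=mlme_flags,
            tert_flags=tert_flags,
            scores=scores,
            prevalence=report,
            timeline=estimates,
            enrichment_tail=enrichment_tail or "per-stratum",
        )

    def _build_strata(self, mlme_flags, tert_flags, scores) -> list[mlme.Stratum]:
        all_cells = list(mlme_flags.index)
        strata = [mlme.Stratum("all cells", all_cells, all_cells)]
        if tert_flags is not None:
            pos = list(tert_flags.index[tert_flags])
            neg = list(tert_flags.index[~tert_flags])
            strata.append(mlme.Stratum(f"{self.tert_gene} positive", pos, all_cells))
            strata.append(
                mlme.Stratum(f"{self.tert_gene} negative", neg, all_cells, tail="lower")
            )
            if scores is not None and pos:
                for frac, n_top in zip(
                    self.score_band_fractions,
                    mlme.rank_band_sizes(len(pos), self.score_band_fractions),
                ):
                    strata.append(
                        mlme.top_rank_stratum(
                            scores, pos, n_top,
                            label=f"top {frac:.0%} {self.tert_gene}pos (n={n_top})",
                            background=all_cells,
                        )
                    )
        return strata


@dataclass
class MLMEResults:
    """Fitted MLME analysis: calls, phenotype flags, scores and enrichment."""

    model: MLMEAnalysis
    calls: BinaryCallMatrix
    mlme_flags: pd.Series
    tert_flags: pd.Series | None
    scores: pd.DataFrame | None
    prevalence: list[PrevalenceRow]
    timeline: list[tlmod.EmergenceEstimate] | None
    enrichment_tail: str

    @property
    def n_mlme(self) -> int:
        return int(self.mlme_flags.sum())

    def prevalence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": r.label,
                    "n_total": r.n_total,
                    "n_mlme": r.n_positive,
                    "percent": r.percent,
                    "p_value": r.p_value,
                    "test": r.test,
                }
                for r in self.prevalence
            ]
        ).set_index("label")

    def timeline_frame(self) -> pd.DataFrame | None:
        if self.timeline is None:
            return None
        return tlmod.timeline_frame(self.timeline)

    def summary(self) -> str:
        m = self.model
        head = [
            ("Cells", str(self.mlme_flags.size)),
            ("Genes", str(m.matrix.n_genes)),
            ("Positivity rule", m.rule.kind),
            ("Markers/lineage required", str(m.panel.min_markers_per_lineage)),
            ("Master regulators", ", ".join(m.panel.master_regulators)),
            ("MLME cells", f"{self.n_mlme} ({100.0 * self.n_mlme / self.mlme_flags.size:.1f}%)"),
            ("Enrichment tail", self.enrichment_tail),
        ]
        lines = ["MLME phenotype analysis", "=" * 60]
        lines += [f"{k:<28s}{v}" for k, v in head]
        rows = [
            [
                r.label,
                str(r.n_total),
                str(r.n_positive),
                "NA" if r.percent is None else f"{r.percent:.1f}",
                format_p_value(r.p_value),
            ]
            for r in self.prevalence
        ]
        table = SimpleTable(
            rows,
            headers=["population", "n", "MLME n", "MLME %", "p value"],
            title="Prevalence of the MLME phenotype",
        )
        lines += ["", str(table)]
        if self.timeline is not None:
            tl = self.timeline_frame()
            lines += ["", "Emergence timeline (>=1 MLME cell per embryo)",
                      tl.to_string(float_format=lambda x: f"{x:.4f}")]
        return "\n".join(lines)
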