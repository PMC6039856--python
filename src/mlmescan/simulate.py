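"""Synthetic embryo-structured single-cell expression data with planted truth.

The generator emulates the populations the pipeline is designed to analyse:
stage-structured preimplantation embryos (E3-E7), lineage-committed cells
(EPI / PE / TE), early pre-lineage cells that weakly co-express markers of
all lineages, a planted telomerase-positive subpopulation, and a planted
MLME subpopulation co-expressing at least ``min_markers_per_lineage`` markers
of every lineage plus the three master regulators.

Expression follows a two-state model: a gene that is "on" in a cell draws
from a log-normal on-state (optionally zeroed by dropout); a gene that is
"off" is an exact zero with high probability (``off_zero_prob``) and
otherwise draws from a low log-normal off-state.  The zero inflation of the
off state mirrors real FPKM matrices, where unexpressed genes are mostly
exact zeros — this is what makes the population-median positivity rule
meaningful downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DEFAULT_MASTER_REGULATORS,
    ExpressionMatrix,
    MarkerPanel,
    ValidationError,
)

LINEAGE_KEYS = ("EPI", "PE", "TE", "pre-lineage")


@dataclass
class SimulationConfig:
    seed: int = 0
    #: (stage label, n_embryos, cells_per_embryo)
    stages: Sequence[tuple[str, int, int]] = (
        ("E3", 5, 10),
        ("E4", 5, 18),
        ("E5", 8, 30),
        ("E6", 8, 40),
        ("E7", 6, 50),
    )
    lineage_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "E3": {"EPI": 0.0, "PE": 0.0, "TE": 0.0, "pre-lineage": 1.0},
            "E4": {"EPI": 0.0, "PE": 0.0, "TE": 0.0, "pre-lineage": 1.0},
            "E5": {"EPI": 0.20, "PE": 0.20, "TE": 0.35, "pre-lineage": 0.25},
            "E6": {"EPI": 0.25, "PE": 0.25, "TE": 0.50, "pre-lineage": 0.0},
            "E7": {"EPI": 0.25, "PE": 0.25, "TE": 0.50, "pre-lineage": 0.0},
        }
    )
    mlme_fraction: Mapping[str, float] = field(
        default_factory=lambda: {s: 0.12 for s in ("E3", "E4", "E5", "E6", "E7")}
    )
    tert_positive_prob: Mapping[str, float] = field(
        default_factory=lambda: {"MLME": 0.66, "non-MLME": 0.51}
    )
    n_background_genes: int = 200
    panel_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"EPI": 12, "PE": 12, "TE": 12}
    )
    #: (log-mean, log-sd) of the natural-log-normal expression states
    on_state: tuple[float, float] = (3.0, 0.8)
    off_state: tuple[float, float] = (-2.0, 0.5)
    dropout_prob: float = 0.1
    #: probability that an "off" gene is an exact zero (FPKM-like sparsity)
    off_zero_prob: float = 0.95
    #: per-gene probability that a pre-lineage cell switches a marker on
    bleed_through: float = 0.2
    dataset_id: str = "sim"

    def validate(self) -> None:
        if len(self.stages) == 0:
            raise ValidationError("at least one stage required")
        for stage, n_emb, n_cells in self.stages:
            if n_emb < 1 or n_cells < 1:
                raise ValidationError(f"stage {stage}: embryos and cells/embryo must be >= 1")
            if stage not in self.lineage_mix:
                raise ValidationError(f"stage {stage}: no lineage mix configured")
            if stage not in self.mlme_fraction:
                raise ValidationError(f"stage {stage}: no MLME fraction configured")
            mix = self.lineage_mix[stage]
            probs = [mix.get(k, 0.0) for k in LINEAGE_KEYS]
            if any(p < 0 or p > 1 for p in probs):
                raise ValidationError(f"stage {stage}: lineage probabilities outside [0,1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(f"stage {stage}: lineage mix sums to {sum(probs)}, not 1")
        for name, p in (
            ("dropout_prob", self.dropout_prob),
            ("off_zero_prob", self.off_zero_prob),
            ("bleed_through", self.bleed_through),
            *((f"mlme_fraction[{s}]", p) for s, p in self.mlme_fraction.items()),
            *((f"tert_positive_prob[{g}]", p) for g, p in self.tert_positive_prob.items()),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} = {p} outside [0,1]")
        for grp in ("MLME", "non-MLME"):
            if grp not in self.tert_positive_prob:
                raise ValidationError(f"tert_positive_prob missing group {grp!r}")
        if self.n_background_genes < 1:
            raise ValidationError("n_background_genes must be >= 1")
        for lin in ("EPI", "PE", "TE"):
            if self.panel_sizes.get(lin, 0) < 1:
                raise ValidationError(f"panel size for {lin} must be >= 1")

    @property
    def n_cells_total(self) -> int:
        return sum(n_emb * n_cells for _, n_emb, n_cells in self.stages)


@dataclass
class SimulatedDataset:
    matrix: ExpressionMatrix
    truth: pd.DataFrame  # indexed by cell id: is_mlme, is_tert_positive, lineage, stage, embryo_id
    panel: MarkerPanel


def default_panel(config: SimulationConfig) -> MarkerPanel:
    """Synthetic marker panel matching the config's panel sizes; the master
    regulators are included in the EPI list (they are epiblast genes)."""
    markers = {}
    masters = list(DEFAULT_MASTER_REGULATORS)
    for lin in ("EPI", "PE", "TE"):
        size = config.panel_sizes[lin]
        genes = [f"{lin}_M{i:02d}" for i in range(1, size + 1)]
        if lin == "EPI":
            genes = masters + genes[: max(size - len(masters), 0)]
        markers[lin] = genes
    return MarkerPanel(lineage_markers=markers, master_regulators=masters)


def simulate_dataset(
    config: SimulationConfig, panel: MarkerPanel | None = None
) -> SimulatedDataset:
    """Draw a reproducible stage/embryo-structured expression matrix.

    Non-MLME cells of lineage L draw L's markers from the on state and other
    markers from the off state; pre-lineage cells switch each marker on
    independently with probability ``bleed_through``; planted MLME cells draw
    every panel marker and master regulator from the on state.  TERT follows
    the per-cell telomerase status; background genes are always off.
    Dropout zeroes on-state values last.
    """
    config.validate()
    if panel is None:
        panel = default_panel(config)
    for lin in ("EPI", "PE", "TE"):
        if len(panel.lineage_markers[lin]) < panel.min_markers_per_lineage:
            raise ValidationError(
                f"panel for {lin} smaller than min_markers_per_lineage"
            )

    panel_genes = panel.all_genes
    master_set = set(panel.master_regulators)
    gene_ids = list(panel_genes)
    if "TERT" not in gene_ids:
        gene_ids.append("TERT")
    gene_ids += [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]

    lineage_sets = {lin: set(panel.lineage_markers[lin]) for lin in ("EPI", "PE", "TE")}
    marker_union = set(panel_genes)

    # one deterministic sub-stream per stage, all derived from the global seed
    root = np.random.SeedSequence(config.seed)
    stage_streams = root.spawn(len(config.stages))

    cols: list[np.ndarray] = []
    cell_ids: list[str] = []
    truth_rows: list[dict] = []
    n_genes = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    tert_idx = gene_pos["TERT"]

    for (stage, n_embryos, cells_per_embryo), stream in zip(config.stages, stage_streams):
        rng = np.random.default_rng(stream)
        mix = config.lineage_mix[stage]
        probs = np.array([mix.get(k, 0.0) for k in LINEAGE_KEYS])
        for emb in range(1, n_embryos + 1):
            embryo_id = f"{stage}.emb{emb:02d}"
            for ci in range(1, cells_per_embryo + 1):
                cell_id = f"{embryo_id}.c{ci:03d}"
                lineage = LINEAGE_KEYS[rng.choice(len(LINEAGE_KEYS), p=probs)]
                is_mlme = rng.random() < config.mlme_fraction[stage]
                tert_p = config.tert_positive_prob["MLME" if is_mlme else "non-MLME"]
                is_tert = rng.random() < tert_p

                on = np.zeros(n_genes, dtype=bool)
                if is_mlme:
                    for g in marker_union:
                        on[gene_pos[g]] = True
                elif lineage in ("EPI", "PE", "TE"):
                    for g in lineage_sets[lineage]:
                        on[gene_pos[g]] = True
                    if lineage == "EPI":
                        for g in master_set:
                            on[gene_pos[g]] = True
                else:  # pre-lineage: weak stochastic co-expression of all panels
                    for g in marker_union:
                        if rng.random() < config.bleed_through:
                            on[gene_pos[g]] = True
                on[tert_idx] = is_tert

                vals = np.zeros(n_genes)
                n_on = int(on.sum())
                if n_on:
                    v = np.exp(rng.normal(config.on_state[0], config.on_state[1], n_on))
                    if config.dropout_prob > 0:
                        v[rng.random(n_on) < config.dropout_prob] = 0.0
                    vals[on] = v
                off_idx = np.flatnonzero(~on)
                leak = rng.random(off_idx.size) >= config.off_zero_prob
                if leak.any():
                    vals[off_idx[leak]] = np.exp(
                        rng.normal(config.off_state[0], config.off_state[1], int(leak.sum()))
                    )

                cols.append(vals)
                cell_ids.append(cell_id)
                truth_rows.append(
                    {
                        "cell_id": cell_id,
                        "is_mlme": is_mlme,
                        "is_tert_positive": is_tert,
                        "lineage": lineage,
                        "stage": stage,
                        "embryo_id": embryo_id,
                    }
                )

    values = np.column_stack(cols)
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    cell_meta = truth[["embryo_id", "stage", "lineage"]].copy()
    cell_meta["dataset_id"] = config.dataset_id
    gene_meta = pd.DataFrame(
        {
            "origin": "unknown",
            "panel": [
                "master" if g in master_set
                else "EPI" if g in lineage_sets["EPI"]
                else "PE" if g in lineage_sets["PE"]
                else "TE" if g in lineage_sets["TE"]
                else "TERT" if g == "TERT"
                else "background"
                for g in gene_ids
            ],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        values=values,
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )
    return SimulatedDataset(matrix=matrix, truth=truth, panel=panel)


def empirical_truth_rates(dataset: SimulatedDataset) -> pd.DataFrame:
    """Exact per-stage planted MLME and TERT+ fractions from the truth table."""
    truth = dataset.truth
    out = truth.groupby("stage", sort=False).agg(
        n_cells=("is_mlme", "size"),
        n_mlme=("is_mlme", "sum"),
        n_tert_positive=("is_tert_positive", "sum"),
    )
    out["mlme_fraction"] = out["n_mlme"] / out["n_cells"]
    out["tert_fraction"] = out["n_tert_positive"] / out["n_cells"]
    return out


def simulate_enrichment_labels(
    n_cells: int,
    tert_prob: float,
    mlme_given_tert_pos: float,
    mlme_given_tert_neg: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Label-level draw of (TERT status, MLME status) per cell.

    Used to study the operating characteristics of the subset-enrichment test
    under a planted relative risk mlme_given_tert_pos / mlme_given_tert_neg,
    without simulating expression values.
    """
    for name, p in (
        ("tert_prob", tert_prob),
        ("mlme_given_tert_pos", mlme_given_tert_pos),
        ("mlme_given_tert_neg", mlme_given_tert_neg),
    ):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name} = {p} outside [0,1]")
    tert = rng.random(n_cells) < tert_prob
    p_mlme = np.where(tert, mlme_given_tert_pos, mlme_given_tert_neg)
    mlme = rng.random(n_cells) < p_mlme
    return pd.DataFrame(
        {"is_tert_positive": tert, "is_mlme": mlme},
        index=pd.Index([f"c{i:05d}" for i in range(n_cells)], name="cell_id"),
    )
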