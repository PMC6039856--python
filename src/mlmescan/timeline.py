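"""Per-stage likelihood that at least one MLME cell emerges in an embryo.

Under an independence (binomial) model, if a fraction f of a stage's cells
carry the MLME phenotype and an embryo at that stage has n cells, the chance
that an individual embryo contains at least one MLME cell is
p_emerge = 1 - (1 - f)^n.  The per-stage fraction f is pooled over embryos,
with a 95% Wilson score interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .datamodel import STAGES, ValidationError

_STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}


def emergence_probability(f: float, n: int) -> float:
    """1 - (1 - f)^n: chance of >= 1 MLME cell among n independent cells."""
    if not (0.0 <= f <= 1.0):
        raise ValidationError(f"fraction f = {f} outside [0, 1]")
    if n < 1 or int(n) != n:
        raise ValidationError(f"cells per embryo n = {n} must be a positive integer")
    return 1.0 - (1.0 - f) ** int(n)


@dataclass
class EmergenceEstimate:
    stage: str
    n_cells_analyzed: int
    n_mlme: int
    f: float | None
    ci_low: float | None
    ci_high: float | None
    cells_per_embryo: int
    p_emerge: float | None
    flagged: bool = False


def stage_timeline(
    mlme_flags: pd.Series,
    cell_meta: pd.DataFrame,
    cells_per_embryo: Mapping[str, int],
) -> list[EmergenceEstimate]:
    """Emergence estimates per developmental stage, ordered E3 -> E7.

    f is the pooled MLME fraction over all analysed cells of the stage; the
    interval is a 95% Wilson score CI; stages with no analysed cells are
    flagged rather than dropped.
    """
    stages_present = list(dict.fromkeys(cell_meta["stage"]))
    missing = [s for s in stages_present if s not in cells_per_embryo]
    if missing:
        raise ValidationError(f"no cells_per_embryo entry for stages: {missing}")
    out = []
    for stage in sorted(stages_present, key=lambda s: (_STAGE_ORDER.get(s, len(STAGES)), s)):
        cells = cell_meta.index[cell_meta["stage"] == stage]
        n_cells = len(cells)
        n_emb = int(cells_per_embryo[stage])
        if n_emb < 1:
            raise ValidationError(f"cells_per_embryo for {stage} must be >= 1")
        if n_cells == 0:
            out.append(
                EmergenceEstimate(
                    stage=stage, n_cells_analyzed=0, n_mlme=0, f=None,
                    ci_low=None, ci_high=None, cells_per_embryo=n_emb,
                    p_emerge=None, flagged=True,
                )
            )
            continue
        k = int(mlme_flags.loc[cells].sum())
        f = k / n_cells
        lo, hi = proportion_confint(k, n_cells, alpha=0.05, method="wilson")
        # boundary counts: the Wilson interval is exactly one-sided there,
        # but float round-off can leave ~1e-19 residues
        lo = 0.0 if k == 0 else lo
        hi = 1.0 if k == n_cells else hi
        out.append(
            EmergenceEstimate(
                stage=stage,
                n_cells_analyzed=n_cells,
                n_mlme=k,
                f=f,
                ci_low=float(lo),
                ci_high=float(hi),
                cells_per_embryo=n_emb,
                p_emerge=emergence_probability(f, n_emb),
            )
        )
    return out


def timeline_frame(estimates: Sequence[EmergenceEstimate]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in estimates]).set_index("stage")
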