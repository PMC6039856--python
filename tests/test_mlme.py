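from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlmescan import (
    BinaryCallMatrix,
    CallRule,
    ContingencyCounts,
    MarkerPanel,
    Stratum,
    ValidationError,
    build_prevalence_report,
    call_mlme,
    hypergeom_enrichment,
    rank_band_sizes,
    top_rank_stratum,
)


def hypergeom_oracle(N, K, n, k, tail):
    """Exact-rational tail/point probability by direct combinatorial sums."""
    denom = comb(N, n)
    lo, hi = max(0, n + K - N), min(K, n)

    def pmf(i):
        return Fraction(comb(K, i) * comb(N - K, n - i), denom)

    if tail == "point":
        return pmf(k)
    if tail == "upper":
        return sum((pmf(i) for i in range(k, hi + 1)), Fraction(0))
    return sum((pmf(i) for i in range(lo, k + 1)), Fraction(0))


class TestCallMlme:
    @staticmethod
    def _calls_for(panel, positive_genes_by_cell):
        genes = panel.all_genes
        cells = list(positive_genes_by_cell)
        calls = np.zeros((len(genes), len(cells)), dtype=bool)
        gpos = {g: i for i, g in enumerate(genes)}
        for j, cell in enumerate(cells):
            for g in positive_genes_by_cell[cell]:
                calls[gpos[g], j] = True
        return BinaryCallMatrix(
            gene_ids=genes, cell_ids=cells, calls=calls,
            rule=CallRule(kind="fixed_threshold"),
        )

    def test_rule_conjunction(self, toy_panel):
        full = {
            *toy_panel.lineage_markers["EPI"][:4],
            *toy_panel.lineage_markers["TE"][:4],
            *toy_panel.lineage_markers["PE"][:4],
            "NANOG", "POU5F1", "SOX2",
        }
        cases = {
            "mlme": full,
            "no_sox2": full - {"SOX2"},
            "three_pe": full - {toy_panel.lineage_markers["PE"][3]},
        }
        # NANOG/POU5F1/SOX2 are EPI markers in toy_panel, so removing a PE
        # marker drops that lineage below 4 while EPI stays satisfied
        calls = self._calls_for(toy_panel, cases)
        flags = call_mlme(calls, toy_panel)
        assert bool(flags["mlme"])
        assert not flags["no_sox2"]
        assert not flags["three_pe"]

    def test_master_regulators_required_even_outside_panels(self):
        panel = MarkerPanel(
            lineage_markers={
                "EPI": ["E1", "E2", "E3", "E4"],
                "TE": ["T1", "T2", "T3", "T4"],
                "PE": ["P1", "P2", "P3", "P4"],
            }
        )
        markers = {f"{L}{i}" for L in "ETP" for i in range(1, 5)}
        calls = self._calls_for(
            panel,
            {
                "with_masters": markers | {"NANOG", "POU5F1", "SOX2"},
                "markers_only": markers,
            },
        )
        flags = call_mlme(calls, panel)
        assert bool(flags["with_masters"]) and not flags["markers_only"]

    def test_missing_panel_gene_listed(self, toy_panel):
        calls = BinaryCallMatrix(
            gene_ids=["NANOG"], cell_ids=["c"], calls=np.ones((1, 1), dtype=bool),
            rule=CallRule(kind="fixed_threshold"),
        )
        with pytest.raises(ValidationError, match="T1"):
            call_mlme(calls, toy_panel)


class TestContingencyCounts:
    def test_support_bounds_enforced(self):
        with pytest.raises(ValidationError):
            ContingencyCounts(N=10, K=5, n=5, k=6)  # k > min(K, n)
        with pytest.raises(ValidationError):
            ContingencyCounts(N=10, K=8, n=8, k=2)  # k < n + K - N
        with pytest.raises(ValidationError):
            ContingencyCounts(N=10, K=11, n=5, k=2)


class TestHypergeomEnrichment:
    def test_whole_population_is_certain(self):
        c = ContingencyCounts(N=100, K=30, n=100, k=30)
        assert hypergeom_enrichment(c, "upper") == pytest.approx(1.0)

    def test_direct_combinatorial_value(self):
        # N=20, K=10, n=5, k=5: C(10,5)/C(20,5) = 252/15504
        c = ContingencyCounts(N=20, K=10, n=5, k=5)
        assert hypergeom_enrichment(c, "upper") == pytest.approx(
            252 / 15504, rel=1e-12
        )

    def test_upper_tail_decreasing_in_k(self):
        ps = [
            hypergeom_enrichment(ContingencyCounts(N=50, K=20, n=15, k=k), "upper")
            for k in range(0, 16)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_subset_complement_symmetry_is_exact(self):
        """Enrichment p of a subset equals depletion p of its complement,
        bit-for-bit (the same computation under the hood)."""
        c_pos = ContingencyCounts(N=1529, K=267, n=819, k=175)
        c_neg = ContingencyCounts(N=1529, K=267, n=710, k=92)
        assert hypergeom_enrichment(c_pos, "upper") == hypergeom_enrichment(
            c_neg, "lower"
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 40), st.data())
    def test_matches_exact_rational_oracle(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(1, N))
        lo, hi = max(0, n + K - N), min(K, n)
        k = data.draw(st.integers(lo, hi))
        c = ContingencyCounts(N=N, K=K, n=n, k=k)
        for tail in ("upper", "lower", "point"):
            expected = float(hypergeom_oracle(N, K, n, k, tail))
            assert hypergeom_enrichment(c, tail) == pytest.approx(
                expected, rel=1e-9, abs=1e-300
            )


class TestPrevalenceReport:
    @staticmethod
    def _flags(n_pos_in_subset, n_subset, n_pos_rest, n_rest):
        ids, vals = [], []
        for i in range(n_subset):
            ids.append(f"s{i:04d}")
            vals.append(i < n_pos_in_subset)
        for i in range(n_rest):
            ids.append(f"r{i:04d}")
            vals.append(i < n_pos_rest)
        return pd.Series(vals, index=pd.Index(ids, name="cell_id"))

    def test_printed_style_percent(self):
        flags = self._flags(36, 82, 267 - 36, 1529 - 82)
        sub = [c for c in flags.index if c.startswith("s")]
        rows = build_prevalence_report(
            flags, [Stratum("top 10%", sub, list(flags.index))]
        )
        assert rows[0].percent == 43.9

    def test_stratum_equal_to_background_p_one(self):
        flags = self._flags(5, 20, 0, 0)
        rows = build_prevalence_report(
            flags, [Stratum("all", list(flags.index), list(flags.index))]
        )
        assert rows[0].p_value == pytest.approx(1.0)

    def test_complementary_strata_share_p(self):
        flags = self._flags(30, 100, 20, 150)
        sub = [c for c in flags.index if c.startswith("s")]
        rest = [c for c in flags.index if c.startswith("r")]
        rows = build_prevalence_report(
            flags,
            [
                Stratum("subset", sub, list(flags.index), tail="upper"),
                Stratum("complement", rest, list(flags.index), tail="lower"),
            ],
        )
        assert rows[0].p_value == rows[1].p_value

    def test_empty_stratum_flagged(self):
        flags = self._flags(1, 4, 0, 0)
        rows = build_prevalence_report(flags, [Stratum("empty", [], list(flags.index))])
        assert rows[0].flagged

    def test_stratum_outside_background_rejected(self):
        flags = self._flags(1, 4, 1, 4)
        sub = [c for c in flags.index if c.startswith("s")]
        rest = [c for c in flags.index if c.startswith("r")]
        with pytest.raises(ValidationError, match="background"):
            build_prevalence_report(flags, [Stratum("bad", sub, rest)])


class TestRankBands:
    def test_generic_ceiling(self):
        assert rank_band_sizes(819, [0.03, 0.05, 0.10]) == [25, 41, 82]

    def test_top_rank_stratum_orders_by_score_then_id(self):
        scores = pd.DataFrame(
            {"score": [0.9, 0.9, 0.5], "defined": True},
            index=pd.Index(["b", "a", "c"], name="cell_id"),
        )
        st_ = top_rank_stratum(scores, ["a", "b", "c"], 1, "top1")
        assert list(st_.cells) == ["a"]
        comp = top_rank_stratum(scores, ["a", "b", "c"], 1, "rest", complement=True)
        assert list(comp.cells) == ["b", "c"]
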