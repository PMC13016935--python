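import itertools
import math

import numpy as np
import pandas as pd
import pytest

from safetyome.errors import ValidationError
from safetyome.panels import Panel, SafetyomeConfig
from safetyome.validate import (
    ValidateConfig,
    adjust_pvalues,
    cutoff_sweep,
    enrich_panels,
    hypergeom_test,
    load_disease_table,
    match_rate,
)


def enumeration_oracle(panel, disease, universe):
    """P(overlap >= observed) by enumerating every possible panel draw."""
    observed = len(panel & disease)
    n_hits = 0
    n_total = 0
    for draw in itertools.combinations(sorted(universe), len(panel)):
        n_total += 1
        if len(set(draw) & disease) >= observed:
            n_hits += 1
    return n_hits / n_total


class TestHypergeom:
    def test_zero_overlap_p_is_one(self):
        universe = {f"g{i}" for i in range(10)}
        assert hypergeom_test({"g0"}, {"g9"}, universe) == 1.0

    def test_worked_example_against_counting(self):
        # universe 10, panel 5, disease 4, overlap 4: C(5,4)*C(5,0)/C(10,4)
        universe = {f"g{i}" for i in range(10)}
        panel = {f"g{i}" for i in range(5)}
        disease = {f"g{i}" for i in range(4)}
        expected = math.comb(5, 4) * math.comb(5, 0) / math.comb(10, 4)
        assert hypergeom_test(panel, disease, universe) == pytest.approx(expected)

    def test_panel_equal_to_universe_is_certain(self):
        universe = {f"g{i}" for i in range(6)}
        assert hypergeom_test(universe, {"g0", "g1"}, universe) == 1.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_test({"g1"}, {"g1"}, set())

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exhaustive_enumeration(self, seed):
        """On every small universe the closed form equals brute-force draws."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 13))
        universe = {f"g{i}" for i in range(m)}
        panel = set(rng.choice(sorted(universe), rng.integers(1, m), replace=False))
        disease = set(rng.choice(sorted(universe), rng.integers(1, m), replace=False))
        assert hypergeom_test(panel, disease, universe) == pytest.approx(
            enumeration_oracle(panel, disease, universe)
        )


class TestAdjustment:
    def test_bonferroni_multiplies_and_caps(self):
        assert adjust_pvalues([0.01] * 5) == pytest.approx([0.05] * 5)
        assert adjust_pvalues([0.5] * 5) == pytest.approx([1.0] * 5)

    def test_bh_step_up_by_hand(self):
        assert adjust_pvalues([0.01, 0.02, 0.04], "bh") == pytest.approx(
            [0.03, 0.03, 0.04]
        )

    def test_bonferroni_significance_subset_of_unadjusted(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0, 1, 40)
        adj = np.asarray(adjust_pvalues(list(ps)))
        assert set(np.where(adj < 0.05)[0]) <= set(np.where(ps < 0.05)[0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            adjust_pvalues([0.1], "holm")


def _panel(panel_id, genes, level="SOC"):
    return Panel(panel_id, level, {g: {"s1", "s2"} for g in genes},
                 {g: {"genetic"} for g in genes})


def _disease_table(sets, indirect=()):
    rows = [(d, g, 1) for d, genes in sets.items() for g in genes]
    rows += [(d, g, 0) for d, g in indirect]
    return pd.DataFrame(rows, columns=["disease_term", "gene_symbol", "direct_evidence"])


class TestEnrichment:
    def test_direct_evidence_only(self):
        table = _disease_table({"d1": ["g1", "g2"]}, indirect=[("d1", "g3")])
        loaded = load_disease_table(table)
        assert set(loaded["gene_symbol"]) == {"g1", "g2"}

    def test_pt_panels_below_floor_excluded(self):
        big = _panel("PT_big", [f"g{i}" for i in range(50)], level="PT")
        small = _panel("PT_small", [f"g{i}" for i in range(49)], level="PT")
        table = _disease_table({"d1": [f"g{i}" for i in range(20)]})
        out = enrich_panels([big, small], table, {"d1": {"PT_big"}}, level="PT")
        assert set(out["panel_id"]) == {"PT_big"}

    def test_adjusted_p_not_below_raw(self):
        panels = [_panel(f"S{i}", [f"g{j}" for j in range(i, i + 6)]) for i in range(4)]
        table = _disease_table({"d1": ["g0", "g1", "g2"], "d2": ["g7", "g8"]})
        out = enrich_panels(panels, table, {}, level="SOC")
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        assert (out["overlap"] <= out[["panel_size", "disease_set_size"]].min(axis=1)).all()


class TestMatchRate:
    def _results(self, rows):
        return pd.DataFrame(
            rows,
            columns=["panel_id", "disease_term", "significant", "matched"],
        )

    def test_two_of_three_matching(self):
        res = self._results(
            [
                ("Cardiac", "d1", True, True),
                ("Cardiac", "d2", True, True),
                ("Cardiac", "d3", True, False),
                ("Cardiac", "d4", False, False),
            ]
        )
        per_panel, mean = match_rate(res, "SOC")
        assert per_panel["Cardiac"] == pytest.approx(200 / 3)
        assert mean == pytest.approx(200 / 3)

    def test_all_matching_is_hundred(self):
        res = self._results([("A", "d1", True, True), ("B", "d2", True, True)])
        _, mean = match_rate(res, "SOC")
        assert mean == 100.0

    def test_no_significant_results_warns(self, caplog):
        res = self._results([("A", "d1", False, True)])
        with caplog.at_level("WARNING"):
            per_panel, mean = match_rate(res, "SOC")
        assert per_panel.empty and math.isnan(mean)

    def test_duplicate_rows_forbidden(self):
        res = self._results([("A", "d1", True, True), ("A", "d1", True, True)])
        with pytest.raises(ValidationError):
            match_rate(res, "SOC")


class TestSweep:
    def _inputs(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i:03d}" for i in range(60)]
        links = pd.DataFrame(
            {
                "gene_symbol": genes,
                "pt_term": ["p1"] * 30 + ["p2"] * 30,
                "soc_term": ["SOC_A"] * 30 + ["SOC_B"] * 30,
                "source_id": ["s1"] * 60,
                "evidence_class": ["genetic"] * 60,
            }
        )
        scores = pd.DataFrame(
            {
                "gene_symbol": genes,
                "scaled": rng.permutation(60) / 6.0,
                "percentile": rng.permutation(60) * 100 / 60,
            }
        )
        table = _disease_table({"dA": genes[:20], "dB": genes[30:50]})
        labels = {"dA": {"SOC_A"}, "dB": {"SOC_B"}}
        return links, scores, table, labels

    def test_nine_rows_and_anti_monotone_sizes(self):
        links, scores, table, labels = self._inputs()
        sweep = cutoff_sweep(links, scores, table, labels, SafetyomeConfig())
        assert sweep["cutoff_percentile"].tolist() == list(range(10, 100, 10))
        sizes = sweep["n_targets"].tolist()
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_zero_noise_world_soc_match_rate_is_perfect(clean_world):
    """Diseases built from organ-exclusive truth genes can only be enriched
    in their own organ panel, so every significant hit matches."""
    from safetyome.pipeline import run_end_to_end

    report = run_end_to_end(clean_world)
    assert report["soc_match_rate_pct"] == pytest.approx(100.0)
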