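import numpy as np
import pandas as pd
import pytest

from safetyome.errors import ValidationError
from safetyome.panels import (
    Panel,
    SafetyomeConfig,
    build_pt_panels,
    build_soc_safetyome,
    panels_long_form,
    read_gmt,
    summarize,
    write_gmt,
)
from safetyome.scoring import scale_scores

LINK_COLS = ["gene_symbol", "pt_term", "soc_term", "source_id", "evidence_class"]


def _links(rows):
    frame = pd.DataFrame(rows, columns=LINK_COLS)
    frame["stage"] = "exact"
    frame["similarity"] = 1.0
    return frame


def _scores(genes_with_pct):
    return pd.DataFrame(
        {
            "gene_symbol": list(genes_with_pct),
            "scaled": [p / 10 for p in genes_with_pct.values()],
            "percentile": list(genes_with_pct.values()),
        }
    )


class TestSocSafetyome:
    def test_excluded_socs_dropped(self):
        links = _links(
            [
                ("g1", "p1", "SOC_A", "s1", "genetic"),
                ("g2", "p2", "SOC_X", "s1", "genetic"),
            ]
        )
        cfg = SafetyomeConfig(excluded_socs=frozenset({"SOC_X"}), cutoff_percentile=0)
        panels, safetyome = build_soc_safetyome(
            links, _scores({"g1": 90, "g2": 90}), cfg
        )
        assert [p.panel_id for p in panels] == ["SOC_A"]
        assert safetyome == {"g1"}

    def test_zero_cutoff_keeps_all_linked_genes(self):
        links = _links(
            [
                ("g1", "p1", "SOC_A", "s1", "genetic"),
                ("g2", "p1", "SOC_A", "s2", "genetic"),
            ]
        )
        _, safetyome = build_soc_safetyome(
            links, _scores({"g1": 0, "g2": 50}), SafetyomeConfig(cutoff_percentile=0)
        )
        assert safetyome == {"g1", "g2"}

    def test_cutoff_retention_is_inclusive(self):
        links = _links(
            [
                ("g1", "p1", "SOC_A", "s1", "genetic"),
                ("g2", "p1", "SOC_A", "s1", "genetic"),
            ]
        )
        _, safetyome = build_soc_safetyome(
            links, _scores({"g1": 50, "g2": 49}), SafetyomeConfig(cutoff_percentile=50)
        )
        assert safetyome == {"g1"}

    def test_half_cutoff_on_distinct_scores_keeps_exactly_half(self):
        """1,000 genes with distinct scaled scores and a 50% cutoff: the
        strictly-below rank definition retains exactly the top 500."""
        rng = np.random.default_rng(7)
        raws = rng.permutation(1000).astype(float)
        scores = scale_scores([(f"g{i:04d}", r) for i, r in enumerate(raws)])
        links = _links(
            [(f"g{i:04d}", "p1", "SOC_A", "s1", "genetic") for i in range(1000)]
        )
        _, safetyome = build_soc_safetyome(
            links, scores, SafetyomeConfig(cutoff_percentile=50)
        )
        assert len(safetyome) == 500
        top500 = set(scores.nlargest(500, "scaled")["gene_symbol"])
        assert safetyome == top500

    def test_raising_cutoff_never_adds_genes(self):
        rng = np.random.default_rng(3)
        genes = {f"g{i}": float(p) for i, p in enumerate(rng.permutation(40))}
        links = _links([(g, "p1", "SOC_A", "s1", "genetic") for g in genes])
        scores = _scores({g: p * 100 / 40 for g, p in genes.items()})
        previous = None
        for cutoff in (0, 25, 50, 75, 100):
            _, s = build_soc_safetyome(
                links, scores, SafetyomeConfig(cutoff_percentile=cutoff)
            )
            if previous is not None:
                assert s <= previous
            previous = s

    def test_union_of_panels_is_safetyome(self):
        links = _links(
            [
                ("g1", "p1", "SOC_A", "s1", "genetic"),
                ("g2", "p2", "SOC_B", "s1", "genetic"),
                ("g1", "p2", "SOC_B", "s2", "genetic"),
            ]
        )
        panels, safetyome = build_soc_safetyome(
            links, _scores({"g1": 60, "g2": 60}), SafetyomeConfig()
        )
        assert set().union(*(p.genes for p in panels)) == safetyome

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValidationError):
            SafetyomeConfig(cutoff_percentile=101)

    def test_unscored_linked_gene_rejected(self):
        links = _links([("ghost", "p1", "SOC_A", "s1", "genetic")])
        with pytest.raises(ValidationError, match="ghost"):
            build_soc_safetyome(links, _scores({"g1": 50}), SafetyomeConfig())


class TestPtPanels:
    def test_two_source_rule(self):
        links = _links(
            [
                ("g1", "p1", "SOC_A", "a", "genetic"),
                ("g2", "p1", "SOC_A", "a", "genetic"),
                ("g2", "p1", "SOC_A", "b", "genetic"),
                ("g3", "p1", "SOC_A", "a", "genetic"),
                ("g3", "p1", "SOC_A", "b", "genetic"),
                ("g3", "p1", "SOC_A", "c", "genetic"),
            ]
        )
        (panel,) = build_pt_panels(links, min_sources=2)
        assert panel.genes == {"g2", "g3"}
        assert all(len(s) >= 2 for s in panel.support.values())

    def test_min_sources_one_keeps_everything(self):
        links = _links([("g1", "p1", "SOC_A", "a", "genetic")])
        (panel,) = build_pt_panels(links, min_sources=1)
        assert panel.genes == {"g1"}

    def test_gene_joins_each_qualifying_pt(self):
        links = _links(
            [
                ("g1", "p1", "SOC_A", "a", "genetic"),
                ("g1", "p1", "SOC_A", "b", "genetic"),
                ("g1", "p2", "SOC_A", "a", "genetic"),
                ("g1", "p2", "SOC_A", "c", "genetic"),
            ]
        )
        panels = {p.panel_id: p for p in build_pt_panels(links)}
        assert set(panels) == {"p1", "p2"}
        assert all("g1" in p.genes for p in panels.values())

    def test_raising_min_sources_never_adds_genes(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"g{rng.integers(8)}", f"p{rng.integers(3)}", "SOC_A",
             f"s{rng.integers(4)}", "genetic")
            for _ in range(60)
        ]
        links = _links(rows)
        previous = None
        for k in (1, 2, 3, 4):
            members = {
                (p.panel_id, g) for p in build_pt_panels(links, k) for g in p.genes
            }
            if previous is not None:
                assert members <= previous
            previous = members

    def test_min_sources_below_one_rejected(self):
        with pytest.raises(ValidationError):
            build_pt_panels(_links([]), min_sources=0)

    def test_empty_panels_not_emitted(self):
        links = _links([("g1", "p1", "SOC_A", "a", "genetic")])
        assert build_pt_panels(links, min_sources=2) == []


def test_zero_noise_pt_panels_match_ground_truth(clean_world):
    """Panels rebuilt from clean links equal the planted >=2-source truth."""
    from safetyome.harmonize import FilterConfig, harmonize_all
    from safetyome.phenomap import Hierarchy, expand_links, map_cascade

    records = harmonize_all(clean_world.tables, clean_world.gene_universe, FilterConfig())
    hierarchy = Hierarchy.from_frame(clean_world.hierarchy)
    mapped, _, _ = map_cascade(records["trait_text"].tolist(), hierarchy)
    links = expand_links(records, mapped)
    built = {p.panel_id: p.genes for p in build_pt_panels(links, 2)}
    assert built == clean_world.truth.pt_panels(2)


class TestSummarize:
    def test_soc_count_histogram_and_class_split(self):
        links = _links(
            [
                ("g1", "p1", "SOC_A", "a", "genetic"),
                ("g1", "p2", "SOC_B", "a", "genetic"),
                ("g2", "p1", "SOC_A", "b", "pharmacological"),
                ("g2", "p1", "SOC_A", "a", "genetic"),
            ]
        )
        panels, _ = build_soc_safetyome(
            links, _scores({"g1": 60, "g2": 60}), SafetyomeConfig()
        )
        stats = summarize(panels, links)
        assert stats["soc_count_histogram"] == {1: 1, 2: 1}
        assert stats["evidence_class_split"] == {
            "genetic_only": 1,
            "pharmacological_only": 0,
            "both": 1,
        }
        assert stats["multi_source_gene_soc_fraction"] == pytest.approx(1 / 3)


def test_gmt_round_trip(tmp_path):
    panels = [
        Panel("SOC_A", "SOC", {"g1": {"a"}, "g2": {"a", "b"}},
              {"g1": {"genetic"}, "g2": {"genetic", "pharmacological"}}),
        Panel("SOC_B", "SOC", {"g3": {"c"}}, {"g3": {"pharmacological"}}),
    ]
    path = tmp_path / "panels.gmt"
    write_gmt(panels, path)
    sets = read_gmt(path)
    assert sets == {"SOC_A": {"g1", "g2"}, "SOC_B": {"g3"}}
    long_form = panels_long_form(panels)
    assert long_form.loc[long_form.gene_symbol == "g2", "sources"].item() == "a,b"
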