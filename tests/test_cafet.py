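"""Sample-axis coverage enrichment (CAFET)."""

import pandas as pd
import pytest
from scipy.stats import hypergeom

from cafet import (
    DysregulationFlags,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleGrouping,
    SynthConfig,
    cafet_all,
    cafet_gene,
    cafet_genes_all,
    cafet_group,
    flag_samples_per_gene,
    generate_cohort,
    tail_p,
)


def single_probe_matrix(values_by_sample: dict[str, float], gene="GENE"):
    df = pd.DataFrame([list(values_by_sample.values())], index=[f"{gene}_p1"],
                      columns=list(values_by_sample))
    return ExpressionMatrix(values=df, probe_to_gene={f"{gene}_p1": gene})


def flags(gene, samples, universe, direction="up"):
    return DysregulationFlags(gene=gene, direction=direction,
                              flagged_samples=frozenset(samples),
                              sample_universe=frozenset(universe))


class TestFlagSamplesPerGene:
    def test_strict_fold_rule_against_median(self):
        samples = {f"s{i}": 100.0 for i in range(1, 5)}
        up = flag_samples_per_gene(single_probe_matrix({**samples, "s5": 251.0}), "GENE", "up")
        assert up.flagged_samples == frozenset({"s5"})
        # 250 is exactly 2.5x the median of 100: strictly-greater rule, no flag
        boundary = flag_samples_per_gene(single_probe_matrix({**samples, "s5": 250.0}), "GENE", "up")
        assert boundary.flagged_samples == frozenset()
        down = flag_samples_per_gene(single_probe_matrix({**samples, "s5": 49.0}), "GENE", "down")
        assert down.flagged_samples == frozenset({"s5"})

    def test_any_probe_union(self):
        df = pd.DataFrame(
            [[100, 100, 300, 100, 100], [80, 80, 80, 80, 300]],
            index=["G_p1", "G_p2"], columns=[f"s{i}" for i in range(1, 6)],
        ).astype(float)
        m = ExpressionMatrix(values=df, probe_to_gene={"G_p1": "G", "G_p2": "G"})
        f = flag_samples_per_gene(m, "G", "up")
        assert f.flagged_samples == frozenset({"s3", "s5"})

    def test_zero_median_probe_semantics(self):
        m = single_probe_matrix({"s1": 0.0, "s2": 0.0, "s3": 5.0})
        assert flag_samples_per_gene(m, "GENE", "up").flagged_samples == frozenset({"s3"})
        assert flag_samples_per_gene(m, "GENE", "down").flagged_samples == frozenset()

    def test_reference_mean_baseline(self):
        m = single_probe_matrix({"s1": 100.0, "s2": 100.0, "s3": 100.0, "s4": 260.0})
        f = flag_samples_per_gene(m, "GENE", "up", reference_samples=["s1", "s2", "s3"])
        assert f.flagged_samples == frozenset({"s4"})

    def test_absent_gene_rejected(self, tiny_matrix):
        with pytest.raises(KeyError):
            flag_samples_per_gene(tiny_matrix, "NOPE", "up")


class TestCafetGene:
    def test_counts_and_tail(self):
        universe = [f"s{i}" for i in range(10)]
        g = SampleGrouping(group1=frozenset(universe[:4]), group2=frozenset(universe[4:]))
        res = cafet_gene(flags("G", universe[:3] + [universe[5]], universe), g)
        assert (res.S_T, res.S_G, res.S_P, res.S_C) == (10, 4, 4, 3)
        assert res.p_value == pytest.approx(tail_p(10, 4, 4, 3), rel=1e-12)

    def test_no_flags_is_certain(self):
        universe = [f"s{i}" for i in range(6)]
        g = SampleGrouping(group1=frozenset(universe[:3]), group2=frozenset(universe[3:]))
        assert cafet_gene(flags("G", [], universe), g).p_value == 1.0

    def test_sox2_worked_counts(self):
        # 61 samples with high expression, 54 in the 63-sample group 1, cohort 138
        universe = [f"s{i:03d}" for i in range(138)]
        g = SampleGrouping(group1=frozenset(universe[:63]), group2=frozenset(universe[63:]))
        flagged = universe[:54] + universe[63:70]
        res = cafet_gene(flags("SOX2", flagged, universe), g)
        assert (res.S_P, res.S_C) == (61, 54)
        assert res.p_value == pytest.approx(hypergeom.sf(53, 138, 63, 61), rel=1e-9)

    def test_universe_mismatch_rejected(self):
        universe = [f"s{i}" for i in range(6)]
        g = SampleGrouping(group1=frozenset(universe[:3]), group2=frozenset(universe[3:5]))
        with pytest.raises(ValueError, match="universe"):
            cafet_gene(flags("G", [], universe), g)


class TestCafetGroup:
    def _universe_grouping(self):
        universe = [f"s{i}" for i in range(12)]
        return universe, SampleGrouping(group1=frozenset(universe[:5]),
                                        group2=frozenset(universe[5:]))

    def test_union_counts(self):
        universe, g = self._universe_grouping()
        members = [
            flags("A", universe[:2], universe),
            flags("B", universe[1:4], universe),
            flags("C", universe[8:9], universe),
        ]
        res = cafet_group(members, g, min_contributing_genes=3)
        assert res.n_genes_contributing == 3
        assert res.S_FP == 5 and res.S_FC == 4
        assert res.p_value == pytest.approx(tail_p(12, 5, 5, 4), rel=1e-12)
        assert res.eligible

    def test_single_gene_group_equals_gene_result(self):
        universe, g = self._universe_grouping()
        f = flags("A", universe[:3], universe)
        group_res = cafet_group([f], g, min_contributing_genes=1)
        gene_res = cafet_gene(f, g)
        assert group_res.p_value == gene_res.p_value
        assert (group_res.S_FP, group_res.S_FC) == (gene_res.S_P, gene_res.S_C)

    def test_absorbed_member_changes_only_contribution_count(self):
        universe, g = self._universe_grouping()
        base = [flags("A", universe[:4], universe)]
        extra = base + [flags("B", universe[1:3], universe)]
        r1 = cafet_group(base, g, min_contributing_genes=1)
        r2 = cafet_group(extra, g, min_contributing_genes=1)
        assert (r1.S_FP, r1.S_FC, r1.p_value) == (r2.S_FP, r2.S_FC, r2.p_value)
        assert r2.n_genes_contributing == r1.n_genes_contributing + 1

    def test_eligibility_threshold(self):
        universe, g = self._universe_grouping()
        members = [flags(c, universe[:1], universe) for c in "ABC"]
        res = cafet_group(members, g, min_contributing_genes=5)
        assert not res.eligible

    def test_mixed_direction_and_empty_rejected(self):
        universe, g = self._universe_grouping()
        with pytest.raises(ValueError, match="empty"):
            cafet_group([], g)
        mixed = [flags("A", [], universe, "up"), flags("B", [], universe, "down")]
        with pytest.raises(ValueError, match="direction"):
            cafet_group(mixed, g)

    def test_union_bounds_invariant(self):
        universe, g = self._universe_grouping()
        members = [
            flags("A", universe[:3], universe),
            flags("B", universe[2:6], universe),
            flags("C", universe[5:7], universe),
        ]
        res = cafet_group(members, g, min_contributing_genes=1)
        sizes = [3, 4, 2]
        assert max(sizes) <= res.S_FP <= sum(sizes)
        assert res.S_FP <= res.S_T


class TestBatchedCafet:
    def test_cafet_all_bh_over_eligible_only(self):
        cfg = SynthConfig(n_genes=50, n_samples=30, planted_set_size=8,
                          planted_fold=6.0, regime="concentrated", seed=5, n_decoy_sets=3)
        matrix, grouping, coll = generate_cohort(cfg)
        results = cafet_all(matrix, grouping, coll, direction="up")
        assert results, "planted concentrated signal should produce eligible groups"
        assert results[0].set_id == "PLANTED"
        assert results[0].fdr < 0.05
        assert all(r.eligible for r in results)
        # doubled collection: identical p's, fdr reflects the larger m
        doubled = GeneSetCollection()
        for s in coll:
            doubled.add(GeneSet(s.set_id, s.name, s.genes))
            doubled.add(GeneSet(s.set_id + "_copy", s.name, s.genes))
        results2 = cafet_all(matrix, grouping, doubled, direction="up")
        p_by_id = {r.set_id: r.p_value for r in results2}
        for s in coll:
            if s.set_id in p_by_id:
                assert p_by_id[s.set_id] == p_by_id[s.set_id + "_copy"]

    def test_cafet_all_everything_ineligible(self, tiny_matrix):
        g = SampleGrouping(group1=frozenset({"s1", "s2"}), group2=frozenset({"s3", "s4"}))
        coll = GeneSetCollection()
        coll.add(GeneSet("S", "s", frozenset({"TP53", "MYC"})))
        assert cafet_all(tiny_matrix, g, coll, min_contributing_genes=5) == []

    def test_cafet_genes_all_dedupe_and_single_gene_fdr(self):
        cfg = SynthConfig(n_genes=30, n_samples=20, planted_set_size=5,
                          planted_fold=6.0, regime="concentrated", seed=2, n_decoy_sets=1)
        matrix, grouping, _ = generate_cohort(cfg)
        one = cafet_genes_all(matrix, grouping, ["G01"], direction="up")
        assert len(one) == 1 and one[0].fdr == pytest.approx(one[0].p_value)
        dup = cafet_genes_all(matrix, grouping, ["G01", "G01", "G02"], direction="up")
        assert [r.gene for r in sorted(dup, key=lambda r: r.gene)] == ["G01", "G02"]

    def test_planted_gene_wins_among_nulls(self):
        cfg = SynthConfig(n_genes=100, n_samples=60, planted_set_size=1,
                          planted_fold=6.0, regime="concentrated", seed=7, n_decoy_sets=1)
        matrix, grouping, _ = generate_cohort(cfg)
        results = cafet_genes_all(matrix, grouping, [f"G{i:03d}" for i in range(1, 101)],
                                  direction="up")
        best = min(results, key=lambda r: (r.fdr, r.p_value))
        assert best.gene == "G001"


def test_transpose_duality_with_fga():
    """Swapping the roles of genes and samples gives the same tail query, hence the same p."""
    from cafet import fga_enrich_set

    universe_samples = [f"s{i}" for i in range(15)]
    g = SampleGrouping(group1=frozenset(universe_samples[:6]),
                       group2=frozenset(universe_samples[6:]))
    f = flags("G", universe_samples[:4] + universe_samples[7:9], universe_samples)
    gene_res = cafet_gene(f, g)

    universe_genes = [f"g{i}" for i in range(15)]
    group = GeneSet("S", "s", frozenset(universe_genes[:6]))
    query = set(universe_genes[:4] + universe_genes[7:9])
    fga_res = fga_enrich_set(query, group, universe_genes)
    assert gene_res.p_value == pytest.approx(fga_res.p_value, rel=1e-12)
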