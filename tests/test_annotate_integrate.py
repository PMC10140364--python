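from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import hypergeom_tail_exact

from ploidymeth import annotate_integrate as ai
from ploidymeth import dmr_calling as dc
from ploidymeth.io_formats import (GeneFeature, GenomicInterval, TeFeature,
                                   make_promoter)


def gene(gid, start, end, strand="+", chrom="chr1"):
    body = GenomicInterval(chrom, start, end, strand)
    return GeneFeature(gid, body, (body,), make_promoter(body, 2000))


def dmr(start, end, context="CG", direction="hyper", chrom="chr1"):
    lo, hi = (0.1, 0.5) if direction == "hyper" else (0.5, 0.1)
    return dc.Dmr(chrom, start, end, context, 5, 4, lo, hi, direction)


class TestAnchoring:
    def test_dmr_spanning_tss_hits_body_and_promoter(self):
        g = gene("g1", 10000, 14000)
        assignments = ai.anchor_dmrs([dmr(9900, 10100)], [g])
        assert {(a.gene_id, a.region_type) for a in assignments} == {
            ("g1", "body"), ("g1", "promoter")}

    def test_gene_without_dmr_absent(self):
        genes = [gene("g1", 10000, 14000), gene("g2", 40000, 44000)]
        assignments = ai.anchor_dmrs([dmr(10500, 10600)], genes)
        assert {a.gene_id for a in assignments} == {"g1"}

    def test_related_set_is_union_not_sum(self):
        genes = [gene("g1", 10000, 14000), gene("g2", 40000, 44000)]
        dmrs = [dmr(9900, 10100), dmr(40500, 40600, "CHH")]
        assignments = ai.anchor_dmrs(dmrs, genes)
        assert ai.dmr_related_genes(assignments) == {"g1", "g2"}

    def test_printed_set_sizes_reproduce_reported_union(self):
        assert ai.two_set_union_size(1440, 2057, 142) == 3355

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            ai.two_set_union_size(5, 7, 6)


class TestVenn:
    def random_assignments(self, rng, n=200):
        out = []
        for i in range(n):
            out.append(ai.DmrGeneAssignment(
                f"g{rng.integers(0, 60)}",
                ("CG", "CHG", "CHH")[rng.integers(3)],
                ("body", "promoter")[rng.integers(2)], ("d",)))
        return out

    def test_exclusive_counts_match_brute_force_sets(self):
        rng = np.random.default_rng(8)
        assignments = self.random_assignments(rng)
        for by in ("context", "region_type"):
            sets = {}
            for a in assignments:
                sets.setdefault(getattr(a, by), set()).add(a.gene_id)
            counts = ai.venn_counts(assignments, by=by)
            labels = sorted(sets)
            for r in range(1, len(labels) + 1):
                for combo in combinations(labels, r):
                    exact = set.intersection(*(sets[c] for c in combo))
                    for other in labels:
                        if other not in combo:
                            exact -= sets[other]
                    assert counts[frozenset(combo)] == len(exact)

    def test_inclusion_exclusion_identity(self):
        rng = np.random.default_rng(9)
        assignments = self.random_assignments(rng)
        counts = ai.venn_counts(assignments, by="region_type")
        sets = {}
        for a in assignments:
            sets.setdefault(a.region_type, set()).add(a.gene_id)
        union = len(sets["body"] | sets["promoter"])
        a, b = len(sets["body"]), len(sets["promoter"])
        inter = len(sets["body"] & sets["promoter"])
        assert union == a + b - inter
        assert counts[frozenset({"body"})] + counts[frozenset({"promoter"})] \
            + counts[frozenset({"body", "promoter"})] == union

    def test_disjoint_sets_have_zero_intersections(self):
        assignments = [
            ai.DmrGeneAssignment("g1", "CG", "body", ("d1",)),
            ai.DmrGeneAssignment("g2", "CHH", "body", ("d2",)),
        ]
        counts = ai.venn_counts(assignments, by="context")
        assert counts[frozenset({"CG", "CHH"})] == 0

    def test_single_set_degenerates(self):
        assignments = [ai.DmrGeneAssignment("g1", "CG", "body", ("d1",))]
        counts = ai.venn_counts(assignments, by="context")
        assert counts == {frozenset({"CG"}): 1}


class TestExpressionClasses:
    def fpkm_table(self, values):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(values))],
            "sample": "s1", "group": "2X", "fpkm": values,
        })

    def test_all_zero_is_all_none(self):
        with pytest.warns(UserWarning, match="none-expressed"):
            classes = ai.classify_expression(self.fpkm_table([0.0] * 10))
        assert set(classes.values()) == {"none"}

    def test_expressed_genes_split_into_equal_tertiles(self):
        rng = np.random.default_rng(3)
        classes = ai.classify_expression(
            self.fpkm_table(list(rng.uniform(1, 100, 300))))
        counts = pd.Series(classes).value_counts()
        for cls in ("low", "medium", "high"):
            assert abs(counts[cls] - 100) <= 1

    def test_strict_quartile_scheme(self):
        classes = ai.classify_expression(
            self.fpkm_table(list(range(1, 101))), scheme="quartiles")
        counts = pd.Series(classes).value_counts()
        assert all(counts[c] == 25 for c in ("none", "low", "medium", "high"))

    def test_medium_class_carries_highest_body_cg_methylation(
            self, default_sim, default_calls):
        tiers = default_sim.truth.gene_tiers
        prof = ai.methylation_by_expression_class(
            default_calls["2X_1"], default_sim.genes, tiers)
        body_cg = {cls: np.nansum(p["CG"].m_sums["body"])
                   / np.nansum(p["CG"].cov_sums["body"])
                   for cls, p in prof.items()}
        assert body_cg["medium"] >= body_cg["high"]
        assert body_cg["none"] == min(body_cg.values())

    def test_chh_body_level_decreases_with_expression(
            self, default_sim, default_calls):
        tiers = default_sim.truth.gene_tiers
        prof = ai.methylation_by_expression_class(
            default_calls["2X_1"], default_sim.genes, tiers)
        body = {cls: np.nansum(p["CHH"].m_sums["body"])
                / np.nansum(p["CHH"].cov_sums["body"])
                for cls, p in prof.items()}
        assert body["none"] > body["low"] > body["medium"] > body["high"]

    def test_tiny_class_skipped_with_warning(self, default_calls, default_sim):
        classes = {g.gene_id: "high" for g in default_sim.genes}
        classes[default_sim.genes[0].gene_id] = "low"
        with pytest.warns(UserWarning, match="low"):
            prof = ai.methylation_by_expression_class(
                default_calls["2X_1"].head(1000), default_sim.genes, classes)
        assert "low" not in prof


class TestTeInsertion:
    def test_no_tes_means_all_none(self):
        genes = [gene("g1", 10000, 14000)]
        status = ai.te_insertion_status(genes, [])
        assert status == {"g1": "none"}

    def test_body_precedence_over_flank(self):
        g = gene("g1", 10000, 14000)
        tes = [TeFeature("t1", GenomicInterval("chr1", 11000, 11500), "Gypsy"),
               TeFeature("t2", GenomicInterval("chr1", 9000, 9500), "Copia")]
        assert ai.te_insertion_status([g], tes)["g1"] == "body"

    def test_flank_detected_within_2kb(self):
        g = gene("g1", 10000, 14000)
        te = TeFeature("t1", GenomicInterval("chr1", 14500, 15000), "LINE")
        assert ai.te_insertion_status([g], [te])["g1"] == "flank"
        far = TeFeature("t2", GenomicInterval("chr1", 17000, 18000), "LINE")
        assert ai.te_insertion_status([g], [far])["g1"] == "none"

    def test_planted_ordering_on_synthetic_data(self, default_sim):
        tab, pvals = ai.te_insertion_expression(
            default_sim.genes, default_sim.tes, default_sim.expression)
        means = tab.set_index("te_status")["mean_log1p_fpkm"]
        assert means["body"] < means["none"] < means["flank"]
        assert pvals["body_vs_none"] < 0.05


class TestOverlapDegDmr:
    def de_table(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])
        from ploidymeth.io_formats import de_status
        df["status"] = [de_status(fc, p) for fc, p in zip(df["log2fc"], df["padj"])]
        return df

    def test_empty_de_table_gives_empty_overlap(self):
        genes = [gene("g1", 10000, 14000)]
        assignments = ai.anchor_dmrs([dmr(10100, 10200)], genes)
        records, quadrants = ai.overlap_deg_dmr(
            self.de_table([]), assignments,
            {d.dmr_id: d.direction for d in [dmr(10100, 10200)]})
        assert records == []
        assert sum(quadrants.values()) == 0

    def test_quadrant_counts_partition_overlap(self):
        genes = [gene(f"g{i}", 10000 + 20000 * i, 14000 + 20000 * i)
                 for i in range(4)]
        dmrs = [dmr(10100, 10300, direction="hyper"),
                dmr(30100, 30300, direction="hypo"),
                dmr(50100, 50300, direction="hyper"),
                dmr(50400, 50600, direction="hypo"),  # g2 becomes mixed
                dmr(70100, 70300, direction="hyper")]
        assignments = ai.anchor_dmrs(dmrs, genes)
        de = self.de_table([("g0", -2.0, 0.001), ("g1", 1.5, 0.001),
                            ("g2", 1.0, 0.01), ("g3", 0.1, 0.9)])
        records, quadrants = ai.overlap_deg_dmr(
            de, assignments, {d.dmr_id: d.direction for d in dmrs})
        assert len(records) == 3
        assert quadrants["hyper-down"] == 1
        assert quadrants["hypo-up"] == 1
        assert quadrants["mixed"] == 1
        assert sum(quadrants.values()) == len(records)

    def test_namespace_mismatch_is_an_error(self):
        genes = [gene("g1", 10000, 14000)]
        assignments = ai.anchor_dmrs([dmr(10100, 10200)], genes)
        de = self.de_table([("other1", 2.0, 0.01)])
        with pytest.raises(ValueError, match="share no gene ids"):
            ai.overlap_deg_dmr(de, assignments,
                               {dmr(10100, 10200).dmr_id: "hyper"})

    def test_fully_coupled_simulation_lands_in_negative_quadrants(self):
        from ploidymeth.synthetic_data import SimulationConfig, run_full_simulation
        sim = run_full_simulation(SimulationConfig(
            seed=13, n_chroms=1, chrom_length=400_000, n_genes=48, n_tes=20,
            n_dmrs=30, coupled_fraction=1.0, dmr_promoter_fraction=0.5))
        g1 = [sim.reports[s] for s in ("2X_1", "2X_2", "2X_3")]
        g2 = [sim.reports[s] for s in ("4X_1", "4X_2", "4X_3")]
        tests = dc.test_all_sites(g1, g2)
        dmrs = []
        for ctx in ("CG", "CHG", "CHH"):
            dmrs += dc.call_dmrs(tests[tests["context"] == ctx])
        assignments = ai.anchor_dmrs(dmrs, sim.genes)
        records, quadrants = ai.overlap_deg_dmr(
            sim.de, assignments, {d.dmr_id: d.direction for d in dmrs})
        assert records
        negative = quadrants["hyper-down"] + quadrants["hypo-up"]
        positive = quadrants["hyper-up"] + quadrants["hypo-down"]
        assert negative >= 0.8 * (negative + positive)


class TestOverrepresentation:
    def term_map(self, pairs):
        return pd.DataFrame(pairs, columns=["gene_id", "term_id"])

    def test_term_covering_all_background_has_p_one(self):
        bg = [f"g{i}" for i in range(20)]
        tm = self.term_map([(g, "T1") for g in bg])
        (res,) = ai.overrepresentation(bg[:5], bg, tm)
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_hypergeometric_value(self):
        bg = [f"g{i}" for i in range(100)]
        tm = self.term_map([(f"g{i}", "T1") for i in range(5)])
        (res,) = ai.overrepresentation(bg[:10], bg, tm)
        want = hypergeom_tail_exact(5, 100, 5, 10)
        assert res.p_value == pytest.approx(want, rel=1e-10)
        # all five carriers in a 10-of-100 draw: C(95,5)/C(100,10)
        assert want == pytest.approx(3.3472e-6, rel=1e-4)

    def test_permuted_labels_give_calibrated_pvalues(self):
        """Random gene sets: P(p <= t) stays at or below t (the exact test is
        valid, i.e. super-uniform under the null at every threshold)."""
        rng = np.random.default_rng(17)
        bg = [f"g{i}" for i in range(400)]
        tm = self.term_map([(g, f"T{rng.integers(40)}") for g in bg
                            for _ in range(2)])
        pvals = []
        for _ in range(50):
            chosen = list(rng.choice(bg, size=100, replace=False))
            pvals += [r.p_value for r in ai.overrepresentation(chosen, bg, tm)]
        pvals = np.array(pvals)
        for t in (0.01, 0.05, 0.2, 0.5):
            se = np.sqrt(t * (1 - t) / len(pvals))
            assert (pvals <= t).mean() <= t + 3 * se
        # and not grossly conservative either
        assert (pvals <= 0.5).mean() > 0.25

    def test_gene_set_must_be_subset(self):
        with pytest.raises(ValueError):
            ai.overrepresentation(["x"], ["a", "b"], self.term_map([("a", "T")]))

    def test_empty_term_map_rejected(self):
        with pytest.raises(ValueError, match="empty term map"):
            ai.overrepresentation(["a"], ["a"], self.term_map([]))
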