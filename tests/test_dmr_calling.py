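import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import call_dmrs_naive, fisher_two_sided_exact

from ploidymeth import dmr_calling as dc
from ploidymeth.io_formats import GeneFeature, GenomicInterval, make_promoter


def make_tests_frame(positions, pvalues, signs, context="CG", chrom="chr1",
                m1=None, u1=None, m2=None, u2=None):
    n = len(positions)
    m1 = m1 if m1 is not None else [5] * n
    u1 = u1 if u1 is not None else [10] * n
    m2 = m2 if m2 is not None else [10] * n
    u2 = u2 if u2 is not None else [5] * n
    return pd.DataFrame({
        "chrom": chrom, "start": positions, "context": context,
        "m1": m1, "u1": u1, "m2": m2, "u2": u2,
        "p_value": pvalues, "level_diff": signs, "diff_sign": signs,
    })


class TestSiteTest:
    def test_identical_groups_give_p_one(self):
        res = dc.site_test([(10, 10)], [(10, 10)])
        assert res.p_value == pytest.approx(1.0)
        assert res.level_diff == 0.0

    def test_extreme_table_closed_form(self):
        # (0,20; 20,0): only the two corner tables are as unlikely
        from math import comb
        res = dc.site_test([(0, 20)], [(20, 0)])
        assert res.p_value == pytest.approx(2 / comb(40, 20), rel=1e-9)
        assert res.level_diff == 1.0

    def test_replicates_are_pooled(self):
        res = dc.site_test([(1, 4), (2, 3)], [(4, 1), (5, 0)])
        assert (res.m1, res.u1, res.m2, res.u2) == (3, 7, 9, 1)

    def test_zero_coverage_group_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            dc.site_test([(0, 0)], [(5, 5)])

    def test_matches_exact_enumeration_for_small_margins(self):
        rng = np.random.default_rng(0)
        tables = [(m1, u1, m2, u2)
                  for m1 in range(0, 7) for u1 in range(0, 7)
                  for m2 in range(0, 7) for u2 in range(0, 7)
                  if m1 + u1 > 0 and m2 + u2 > 0][::7]
        tables += [tuple(rng.integers(0, 26, 4)) for _ in range(300)]
        tables = [t for t in tables if t[0] + t[1] > 0 and t[2] + t[3] > 0]
        m1, u1, m2, u2 = map(np.array, zip(*tables))
        got = dc.fisher_two_sided(m1, u1, m2, u2)
        want = [fisher_two_sided_exact(*t) for t in tables]
        np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_matches_scipy_fisher(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            m1, u1, m2, u2 = (int(x) for x in rng.integers(0, 40, 4))
            if m1 + u1 == 0 or m2 + u2 == 0:
                continue
            ours = float(dc.fisher_two_sided(m1, u1, m2, u2)[0])
            ref = stats.fisher_exact([[m1, u1], [m2, u2]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-7)


class TestCallDmrs:
    def test_qualifying_run_becomes_one_dmr(self):
        pos = [0, 20, 40, 60, 79]            # spans 80 bp
        df = make_tests_frame(pos, [1e-6] * 5, [1.0] * 5)
        (d,) = dc.call_dmrs(df)
        assert (d.start, d.end, d.n_sites, d.n_sig_sites) == (0, 80, 5, 5)
        assert d.direction == "hyper"

    def test_short_span_fails_length_rule(self):
        df = make_tests_frame([0, 20, 39], [1e-6] * 3, [1.0] * 3)  # 40 bp
        assert dc.call_dmrs(df) == []

    def test_close_same_direction_regions_merge(self):
        # two qualifying regions 60 bp apart (clusters split by a small
        # site-gap cap so the <100 bp merge rule itself is exercised)
        pos = [0, 20, 40, 60, 79]
        far = [x + 140 for x in pos]          # gap 140-80 = 60 < 100
        df = make_tests_frame(pos + far, [1e-6] * 10, [1.0] * 10)
        (d,) = dc.call_dmrs(df, max_site_gap=40)
        assert (d.start, d.end) == (0, 220)
        assert (d.n_sites, d.n_sig_sites) == (10, 10)

    def test_distant_regions_stay_separate(self):
        pos = [0, 20, 40, 60, 79]
        far = [x + 230 for x in pos]          # gap 230-80 = 150 >= 100
        df = make_tests_frame(pos + far, [1e-6] * 10, [1.0] * 10)
        dmrs = dc.call_dmrs(df, max_site_gap=40)
        assert [(d.start, d.end) for d in dmrs] == [(0, 80), (230, 310)]

    def test_opposite_directions_never_merge(self):
        pos = [0, 20, 40, 60, 79]
        far = [x + 140 for x in pos]
        df = make_tests_frame(pos + far, [1e-6] * 10, [1.0] * 5 + [-1.0] * 5,
                         m2=[10] * 5 + [1] * 5, u2=[5] * 5 + [14] * 5)
        dmrs = dc.call_dmrs(df)
        assert len(dmrs) == 2
        assert {d.direction for d in dmrs} == {"hyper", "hypo"}

    def test_interior_nonsignificant_sites_dilute_proportion(self):
        pos = list(range(0, 110, 10))
        p = [1e-6 if i in (0, 5, 10) else 0.5 for i in range(11)]
        df = make_tests_frame(pos, p, [1.0] * 11)
        assert dc.call_dmrs(df) == []   # 3/11 significant < 50%

    def test_multi_context_input_rejected(self):
        df = make_tests_frame([0, 50], [1e-6, 1e-6], [1, 1])
        df.loc[1, "context"] = "CHH"
        with pytest.raises(ValueError, match="single context"):
            dc.call_dmrs(df)

    def test_unsorted_input_rejected(self):
        df = make_tests_frame([50, 0], [1e-6, 1e-6], [1, 1])
        with pytest.raises(ValueError, match="sorted"):
            dc.call_dmrs(df)

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(80):
            n = int(rng.integers(5, 31))
            pos = np.cumsum(rng.integers(5, 260, n))
            pvals = rng.choice([1e-7, 1e-3], n, p=[0.55, 0.45])
            signs = rng.choice([1.0, -1.0], n, p=[0.7, 0.3])
            m2 = rng.integers(0, 20, n)
            df = make_tests_frame(pos, pvals, signs, m2=m2,
                             u2=20 - m2)
            got = [(d.start, d.end, d.n_sites, d.n_sig_sites, d.direction)
                   for d in dc.call_dmrs(df)]
            want = call_dmrs_naive(list(pos), list(pvals), list(signs),
                                   df["m1"].tolist(), df["u1"].tolist(),
                                   df["m2"].tolist(), df["u2"].tolist())
            assert got == want, f"trial {trial}"

    def test_means_come_from_pooled_member_counts(self):
        pos = [0, 30, 79]
        df = make_tests_frame(pos, [1e-6] * 3, [1.0] * 3,
                         m1=[2, 3, 1], u1=[8, 7, 9], m2=[9, 8, 7], u2=[1, 2, 3])
        (d,) = dc.call_dmrs(df)
        assert d.mean_level_g1 == pytest.approx(6 / 30)
        assert d.mean_level_g2 == pytest.approx(24 / 30)


class TestDmrProperties:
    def test_every_called_dmr_satisfies_region_criteria(self, default_dmr_products):
        for d in default_dmr_products["dmrs"]:
            assert dc.check_dmr_criteria(d)
            assert d.direction == ("hyper" if d.mean_level_g2 > d.mean_level_g1
                                   else "hypo")

    def test_dmrs_within_context_never_overlap(self, default_dmr_products):
        by_ctx = {}
        for d in default_dmr_products["dmrs"]:
            by_ctx.setdefault((d.context, d.chrom), []).append(d)
        for group in by_ctx.values():
            group.sort(key=lambda d: d.start)
            for a, b in zip(group, group[1:]):
                assert a.end <= b.start

    def test_direction_counts_partition_total(self, default_dmr_products):
        summary = dc.dmr_summary(default_dmr_products["dmrs"])
        assert (summary["hyper"] + summary["hypo"]).equals(summary["total"])


class TestGenomicDistribution:
    def _genes(self):
        body = GenomicInterval("chr1", 10000, 16000, "+")
        exons = (GenomicInterval("chr1", 10000, 12000, "+"),
                 GenomicInterval("chr1", 14000, 16000, "+"))
        return [GeneFeature("g1", body, exons, make_promoter(body, 2000))]

    def dmr(self, start, end):
        return dc.Dmr("chr1", start, end, "CG", 5, 4, 0.1, 0.5, "hyper")

    def test_dmr_inside_exon(self):
        tab = dc.dmr_genomic_distribution([self.dmr(10500, 11000)], self._genes())
        assert tab.set_index(["context", "region_class"]).loc[
            ("CG", "exon"), "count"] == 1

    def test_maximal_overlap_wins_with_promoter_tiebreak(self):
        # 60 bp in promoter [8000,10000), 40 bp in exon
        tab = dc.dmr_genomic_distribution([self.dmr(9940, 10040)], self._genes())
        assert tab.set_index(["context", "region_class"]).loc[
            ("CG", "promoter"), "count"] == 1

    def test_intron_and_intergenic_assignment(self):
        dmrs = [self.dmr(12500, 13500), self.dmr(30000, 31000)]
        tab = dc.dmr_genomic_distribution(dmrs, self._genes())
        idx = tab.set_index(["context", "region_class"])["count"]
        assert idx[("CG", "intron")] == 1
        assert idx[("CG", "intergenic")] == 1

    def test_counts_sum_to_number_of_dmrs(self, default_dmr_products, default_sim):
        dmrs = default_dmr_products["dmrs"]
        tab = dc.dmr_genomic_distribution(dmrs, default_sim.genes)
        assert tab["count"].sum() == len(dmrs)
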