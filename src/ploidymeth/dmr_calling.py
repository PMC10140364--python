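"""Two-group differential methylation testing and DMR formation.

Region rules (fixed by the analysis protocol this pipeline implements): a
region qualifies as a DMR when the proportion of member loci with per-site
p < 1e-5 exceeds 50%, the region holds at least 3 tested loci and spans more
than 50 bp; same-direction regions closer than 100 bp are merged.

Per-site statistic.  The exact primitive is a two-sided Fisher test on the
2x2 table of pooled within-group counts (implemented here by direct
hypergeometric enumeration, vectorized).  At typical WGBS depth (~15x per
replicate, 3 replicates per group) a single site almost never reaches
p < 1e-5 even for a large true difference, so the pipeline default first
pools counts over a small moving window (DSS-style local smoothing) and
applies a Wald test on the smoothed proportions, with a genomic-control
correction that absorbs replicate overdispersion.  ``method="fisher"``
selects the unsmoothed exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from ._intervals import merge_intervals, overlap_length
from .io_formats import CONTEXTS, GenomicInterval

TEST_COLUMNS = [
    "chrom", "start", "context", "m1", "u1", "m2", "u2",
    "p_value", "level_diff", "diff_sign",
]

#: genomic control needs a reasonable number of (mostly null) sites
_MIN_SITES_FOR_GC = 500


@dataclass(frozen=True)
class Dmr:
    """A differentially methylated region (group 2 vs group 1, e.g. 4X - 2X)."""

    chrom: str
    start: int
    end: int
    context: str
    n_sites: int
    n_sig_sites: int
    mean_level_g1: float
    mean_level_g2: float
    direction: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("DMR must have positive length")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def level_diff(self) -> float:
        return self.mean_level_g2 - self.mean_level_g1

    @property
    def dmr_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.context}"


@dataclass(frozen=True)
class SiteTestResult:
    chrom: str
    start: int
    context: str
    m1: int
    u1: int
    m2: int
    u2: int
    p_value: float
    level_diff: float


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------


def fisher_two_sided(m1, u1, m2, u2):
    """Vectorized two-sided Fisher exact p for 2x2 tables (m1,u1; m2,u2).

    Enumerates the hypergeometric support and sums the probabilities of all
    tables no more likely than the observed one (relative tolerance 1e-7 for
    ties, the usual convention).
    """
    m1, u1, m2, u2 = (np.atleast_1d(np.asarray(x, dtype=np.int64))
                      for x in (m1, u1, m2, u2))
    N = m1 + u1 + m2 + u2
    K = m1 + m2          # methylated margin
    n = m1 + u1          # group-1 margin
    kmin = np.maximum(0, n - (N - K))
    kmax = np.minimum(n, K)
    width = int((kmax - kmin).max()) + 1 if len(m1) else 1
    ks = kmin[:, None] + np.arange(width)[None, :]
    valid = ks <= kmax[:, None]
    ksafe = np.where(valid, ks, kmin[:, None])

    def logpmf(k):
        return (
            gammaln(K + 1)[:, None] - gammaln(k + 1) - gammaln(K[:, None] - k + 1)
            + gammaln(N - K + 1)[:, None] - gammaln(n[:, None] - k + 1)
            - gammaln((N - K - n)[:, None] + k + 1)
            + gammaln(n + 1)[:, None] + gammaln(N - n + 1)[:, None]
            - gammaln(N + 1)[:, None]
        )

    lp = logpmf(ksafe)
    lp_obs = np.take_along_axis(lp, (m1 - kmin)[:, None], axis=1)
    keep = valid & (lp <= lp_obs + np.log1p(1e-7))
    p = np.exp(lp, where=keep, out=np.zeros_like(lp)).sum(axis=1)
    return np.minimum(p, 1.0)


def site_test(g1_counts, g2_counts, method: str = "fisher") -> SiteTestResult:
    """Test one site: replicate counts pooled within group, then compared.

    ``g*_counts``: sequence of (count_m, count_u) pairs, one per replicate.
    """
    m1 = int(sum(c[0] for c in g1_counts))
    u1 = int(sum(c[1] for c in g1_counts))
    m2 = int(sum(c[0] for c in g2_counts))
    u2 = int(sum(c[1] for c in g2_counts))
    if m1 + u1 == 0 or m2 + u2 == 0:
        raise ValueError("both groups need coverage > 0; skip untested sites")
    if method == "fisher":
        p = float(fisher_two_sided(m1, u1, m2, u2)[0])
    elif method == "wald":
        p = float(_wald_p(np.array([m1]), np.array([u1]),
                          np.array([m2]), np.array([u2]))[0])
    else:
        raise ValueError(f"unknown method {method!r}")
    diff = m2 / (m2 + u2) - m1 / (m1 + u1)
    return SiteTestResult("", -1, "", m1, u1, m2, u2, p, diff)


def _wald_p(m1, u1, m2, u2, phi: float = 1.0):
    """Two-sided two-proportion Wald p with optional variance inflation."""
    t1 = m1 + u1
    t2 = m2 + u2
    p1 = np.divide(m1, t1, out=np.zeros(len(m1)), where=t1 > 0)
    p2 = np.divide(m2, t2, out=np.zeros(len(m2)), where=t2 > 0)
    pp = (m1 + m2) / np.maximum(t1 + t2, 1)
    var = phi * pp * (1 - pp) * (1 / np.maximum(t1, 1) + 1 / np.maximum(t2, 1))
    z = np.divide(p2 - p1, np.sqrt(var), out=np.zeros(len(m1)), where=var > 0)
    return 2 * stats.norm.sf(np.abs(z)), z


def _pool_group(samples) -> pd.DataFrame:
    """Sum replicate counts per site for one group."""
    first = samples[0]
    keys = ["chrom", "start", "strand", "context"]
    if all(
        len(s) == len(first)
        and (s["start"].to_numpy() == first["start"].to_numpy()).all()
        and (s["chrom"].to_numpy() == first["chrom"].to_numpy()).all()
        for s in samples[1:]
    ):
        pooled = first[keys].copy()
        pooled["count_m"] = sum(s["count_m"].to_numpy() for s in samples)
        pooled["count_u"] = sum(s["count_u"].to_numpy() for s in samples)
        return pooled
    cat = pd.concat([s[keys + ["count_m", "count_u"]] for s in samples])
    return cat.groupby(keys, sort=False, observed=True).sum().reset_index()


def _smooth_counts(pos, m, t, span: int):
    """Moving-window sums of counts over positions within +-span/2."""
    half = span // 2
    lo = np.searchsorted(pos, pos - half, side="left")
    hi = np.searchsorted(pos, pos + half, side="right")
    cm = np.concatenate([[0], np.cumsum(m)])
    ct = np.concatenate([[0], np.cumsum(t)])
    return cm[hi] - cm[lo], ct[hi] - ct[lo]


def test_all_sites(group1, group2, method: str = "smoothed",
                   smooth_span: int = 600, min_coverage: int = 4) -> pd.DataFrame:
    """Per-site two-group tests over whole methylomes.

    ``group1`` / ``group2``: lists of per-replicate site tables (the raw
    cytosine-report DataFrames).  Counts are pooled within each group; sites
    with pooled coverage below ``min_coverage`` in either group are skipped.

    Methods: "smoothed" (default; moving-window pooled counts, Wald test,
    per-context genomic-control correction), "fisher" (exact, unsmoothed),
    "wald" (unsmoothed).  ``level_diff`` is always the raw pooled
    ML(group2) - ML(group1); ``diff_sign`` carries the sign used for run
    segmentation (the smoothed sign under the default method).
    """
    g1 = _pool_group(list(group1))
    g2 = _pool_group(list(group2))
    keys = ["chrom", "start", "context"]
    merged = g1.merge(g2, on=keys + ["strand"], suffixes=("_1", "_2"), how="inner")
    t1 = merged["count_m_1"] + merged["count_u_1"]
    t2 = merged["count_m_2"] + merged["count_u_2"]
    merged = merged.loc[(t1 >= min_coverage) & (t2 >= min_coverage)]
    merged = merged.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)

    m1 = merged["count_m_1"].to_numpy(dtype=np.int64)
    u1 = merged["count_u_1"].to_numpy(dtype=np.int64)
    m2 = merged["count_m_2"].to_numpy(dtype=np.int64)
    u2 = merged["count_u_2"].to_numpy(dtype=np.int64)
    level_diff = m2 / (m2 + u2) - m1 / (m1 + u1)

    if method == "fisher":
        p = np.empty(len(merged))
        for lo in range(0, len(merged), 20000):
            hi = min(lo + 20000, len(merged))
            p[lo:hi] = fisher_two_sided(m1[lo:hi], u1[lo:hi], m2[lo:hi], u2[lo:hi])
        diff_sign = np.sign(level_diff)
    elif method == "wald":
        p, z = _wald_p(m1, u1, m2, u2)
        diff_sign = np.sign(level_diff)
    elif method == "smoothed":
        p = np.ones(len(merged))
        diff_sign = np.zeros(len(merged))
        chrom_arr = merged["chrom"].to_numpy()
        ctx_arr = merged["context"].to_numpy()
        for ctx in CONTEXTS:
            zs = []
            slices = []
            for chrom in pd.unique(chrom_arr):
                sel = np.flatnonzero((chrom_arr == chrom) & (ctx_arr == ctx))
                if len(sel) == 0:
                    continue
                pos = merged["start"].to_numpy()[sel]
                sm1, st1 = _smooth_counts(pos, m1[sel], (m1 + u1)[sel], smooth_span)
                sm2, st2 = _smooth_counts(pos, m2[sel], (m2 + u2)[sel], smooth_span)
                _, z = _wald_p(sm1, st1 - sm1, sm2, st2 - sm2)
                zs.append(z)
                slices.append(sel)
            if not zs:
                continue
            z_all = np.concatenate(zs)
            nonzero = z_all[z_all != 0]
            phi = 1.0
            if len(z_all) >= _MIN_SITES_FOR_GC and len(nonzero) > len(z_all) / 2:
                phi = max(1.0, float(np.median(np.abs(nonzero)) / 0.674489750196) ** 2)
            z_all = z_all / np.sqrt(phi)
            pv = 2 * stats.norm.sf(np.abs(z_all))
            idx = np.concatenate(slices)
            p[idx] = pv
            diff_sign[idx] = np.sign(z_all)
    else:
        raise ValueError(f"unknown method {method!r}")

    return pd.DataFrame(
        {
            "chrom": merged["chrom"], "start": merged["start"],
            "context": merged["context"], "m1": m1, "u1": u1, "m2": m2, "u2": u2,
            "p_value": p, "level_diff": level_diff, "diff_sign": diff_sign,
        }
    )


# ---------------------------------------------------------------------------
# region formation
# ---------------------------------------------------------------------------


def call_dmrs(tests: pd.DataFrame, p_threshold: float = 1e-5,
              sig_proportion: float = 0.5, min_sites: int = 3,
              min_length: int = 50, merge_gap: int = 100,
              max_site_gap: int = 500, revalidate: bool = True):
    """Form DMRs from a sorted single-context site-test table.

    1. Candidate segments: maximal runs of significant sites (p below
       threshold, consistent sign, adjacent significant sites no more than
       ``max_site_gap`` apart), extended to include interior tested sites.
    2. Filter on the three region criteria (site count, length, significant
       fraction).
    3. Merge surviving same-direction regions separated by < ``merge_gap``.
    4. Optionally re-validate the criteria post-merge; failing merged regions
       are dropped.
    5. Boundaries span the first to last member site; group means come from
       pooled member-site counts.
    """
    contexts = tests["context"].unique()
    if len(contexts) > 1:
        raise ValueError("call_dmrs expects a single context per invocation")
    if len(tests) == 0:
        return []
    context = contexts[0]
    starts = tests["start"].to_numpy()
    chroms = tests["chrom"].to_numpy()
    order_ok = True
    for chrom in pd.unique(chroms):
        s = starts[chroms == chrom]
        if (np.diff(s) <= 0).any():
            order_ok = False
    if not order_ok:
        raise ValueError("site tests must be sorted by position within chromosomes")

    sign_col = "diff_sign" if "diff_sign" in tests.columns else None
    out = []
    for chrom in pd.unique(chroms):
        sub = tests[chroms == chrom]
        pos = sub["start"].to_numpy()
        p = sub["p_value"].to_numpy()
        sign = (sub[sign_col].to_numpy() if sign_col
                else np.sign(sub["level_diff"].to_numpy()))
        m1 = sub["m1"].to_numpy()
        u1 = sub["u1"].to_numpy()
        m2 = sub["m2"].to_numpy()
        u2 = sub["u2"].to_numpy()
        sig_idx = np.flatnonzero((p < p_threshold) & (sign != 0))

        # 1. runs of significant sites
        runs = []
        for i in sig_idx:
            if (runs and sign[i] == sign[runs[-1][-1]]
                    and pos[i] - pos[runs[-1][-1]] <= max_site_gap):
                runs[-1].append(i)
            else:
                runs.append([i])

        def region(i0, i1, run_sign):
            n_sites = i1 - i0 + 1
            in_span = slice(i0, i1 + 1)
            n_sig = int(((p[in_span] < p_threshold) & (sign[in_span] == run_sign)).sum())
            return {
                "i0": i0, "i1": i1, "sign": run_sign,
                "start": int(pos[i0]), "end": int(pos[i1]) + 1,
                "n_sites": n_sites, "n_sig": n_sig,
            }

        def passes(r):
            return (
                r["n_sites"] >= min_sites
                and (r["end"] - r["start"]) > min_length
                and r["n_sig"] / r["n_sites"] > sig_proportion
            )

        # 2. filter candidates
        candidates = [region(run[0], run[-1], sign[run[0]]) for run in runs]
        candidates = [r for r in candidates if passes(r)]

        # 3. merge same-direction neighbours closer than merge_gap
        merged = []
        for r in candidates:
            prev = merged[-1] if merged else None
            if (prev is not None and r["sign"] == prev["sign"]
                    and r["start"] - prev["end"] < merge_gap):
                fused = region(prev["i0"], r["i1"], r["sign"])
                fused["was_merged"] = True
                merged[-1] = fused
            else:
                r.setdefault("was_merged", False)
                merged.append(r)

        # 4. re-validate post-merge
        for r in merged:
            if revalidate and r["was_merged"] and not passes(r):
                continue
            sl = slice(r["i0"], r["i1"] + 1)
            t1 = int(m1[sl].sum() + u1[sl].sum())
            t2 = int(m2[sl].sum() + u2[sl].sum())
            mean1 = m1[sl].sum() / t1
            mean2 = m2[sl].sum() / t2
            out.append(
                Dmr(
                    chrom=str(chrom), start=r["start"], end=r["end"],
                    context=str(context), n_sites=r["n_sites"],
                    n_sig_sites=r["n_sig"], mean_level_g1=float(mean1),
                    mean_level_g2=float(mean2),
                    direction="hyper" if mean2 > mean1 else "hypo",
                )
            )
    return out


def check_dmr_criteria(dmr: Dmr, min_sites: int = 3, min_length: int = 50,
                       sig_proportion: float = 0.5) -> bool:
    """Do the stored fields of a DMR satisfy the three region criteria?"""
    return (
        dmr.n_sites >= min_sites
        and dmr.length > min_length
        and dmr.n_sig_sites / dmr.n_sites > sig_proportion
    )


def dmr_summary(dmrs) -> pd.DataFrame:
    """Hyper/hypo counts per context."""
    rows = []
    for ctx in CONTEXTS:
        sub = [d for d in dmrs if d.context == ctx]
        rows.append(
            {
                "context": ctx,
                "hyper": sum(d.direction == "hyper" for d in sub),
                "hypo": sum(d.direction == "hypo" for d in sub),
                "total": len(sub),
            }
        )
    return pd.DataFrame(rows)


def dmr_genomic_distribution(dmrs, genes) -> pd.DataFrame:
    """Assign each DMR to promoter/exon/intron/intergenic by maximal overlap.

    Ties break in the order promoter > exon > intron > intergenic.
    """
    classes = {"promoter": {}, "exon": {}, "intron": {}}
    genic = {}
    for g in genes:
        chrom = g.body.chrom
        if g.promoter is not None:
            classes["promoter"].setdefault(chrom, []).append(
                (g.promoter.start, g.promoter.end)
            )
            genic.setdefault(chrom, []).append((g.promoter.start, g.promoter.end))
        for ex in g.exons:
            classes["exon"].setdefault(chrom, []).append((ex.start, ex.end))
        for s, e in g.introns():
            classes["intron"].setdefault(chrom, []).append((s, e))
        genic.setdefault(chrom, []).append((g.body.start, g.body.end))
    for d in (*classes.values(), genic):
        for chrom in d:
            d[chrom] = merge_intervals(d[chrom])

    priority = ["promoter", "exon", "intron", "intergenic"]
    counts = {(ctx, cls): 0 for ctx in CONTEXTS for cls in priority}
    for dmr in dmrs:
        ov = {
            cls: overlap_length(dmr.start, dmr.end, classes[cls].get(dmr.chrom, []))
            for cls in classes
        }
        ov["intergenic"] = dmr.length - overlap_length(
            dmr.start, dmr.end, genic.get(dmr.chrom, [])
        )
        best = max(priority, key=lambda c: (ov[c], -priority.index(c)))
        counts[(dmr.context, best)] += 1
    rows = [
        {"context": ctx, "region_class": cls, "count": counts[(ctx, cls)]}
        for ctx in CONTEXTS
        for cls in priority
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery evaluation against a planted truth
# ---------------------------------------------------------------------------


def match_planted(called, planted, min_fraction: float = 0.5):
    """Match called DMRs to planted intervals at reciprocal-overlap >= frac.

    Both sides need matching context and direction.  Returns a dict with
    per-context recall, overall precision and the match pairs.
    """
    matched_planted = set()
    matched_called = set()
    for ci, c in enumerate(called):
        for pi, t in enumerate(planted):
            if (c.context != t.context or c.direction != t.direction
                    or c.chrom != t.chrom):
                continue
            ov = max(0, min(c.end, t.end) - max(c.start, t.start))
            if (ov >= min_fraction * (c.end - c.start)
                    and ov >= min_fraction * (t.end - t.start)):
                matched_planted.add(pi)
                matched_called.add(ci)
    recall = {}
    for ctx in CONTEXTS:
        idx = [i for i, t in enumerate(planted) if t.context == ctx]
        recall[ctx] = (
            sum(i in matched_planted for i in idx) / len(idx) if idx else float("nan")
        )
    precision = len(matched_called) / len(called) if called else float("nan")
    return {
        "recall_by_context": recall,
        "precision": precision,
        "n_called": len(called),
        "n_planted": len(planted),
        "n_recovered": len(matched_planted),
    }
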