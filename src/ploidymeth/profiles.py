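"""Context-stratified methylation profiles over genomic feature classes.

Two views: (1) mean levels per region class (promoter, exon, intron, gene
body, TE, intergenic) and (2) metagene/meta-TE profiles — feature bodies
scaled to a fixed number of bins plus fixed-width flanking bins, pooled over
features.  Pooling is always count-weighted (sum of methylated reads over sum
of total reads per bin), matching the windowed-level convention and keeping
sparse CHH bins stable; a site overlapping several classes contributes to
each of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import membership, merge_intervals
from .io_formats import CONTEXTS

REGION_CLASSES = ("promoter", "exon", "intron", "genebody", "TE", "intergenic")


@dataclass
class MetaProfile:
    """Binned mean-level profile over a feature set for one context.

    ``upstream``/``body``/``downstream`` hold count-weighted mean levels
    (NaN where no site contributed); the ``*_counts`` vectors hold the
    (fractional) number of contributing sites per bin.  The raw read-count
    sums are kept so profiles of disjoint feature sets can be combined
    exactly.
    """

    feature_set: str
    context: str
    upstream: np.ndarray = field(default=None)
    body: np.ndarray = field(default=None)
    downstream: np.ndarray = field(default=None)
    upstream_counts: np.ndarray = field(default=None)
    body_counts: np.ndarray = field(default=None)
    downstream_counts: np.ndarray = field(default=None)
    m_sums: dict = field(default_factory=dict)
    cov_sums: dict = field(default_factory=dict)
    n_features: int = 0

    def segment(self, name):
        return {"upstream": self.upstream, "body": self.body,
                "downstream": self.downstream}[name]


def _scatter_fractional(a0, a1, weights, n_bins, m_acc, cov_acc, site_acc,
                        m_w, cov_w):
    """Distribute each site's weight over the bins its scaled span covers.

    ``a0``/``a1`` are scaled coordinates in [0, n_bins]; a span narrower than
    one bin lands (possibly split) in one or two bins, a span wider than one
    bin (feature shorter than the bin count) is spread fractionally.
    """
    a0 = np.clip(a0, 0.0, n_bins)
    a1 = np.clip(a1, 0.0, n_bins)
    ok = a1 > a0
    if not ok.all():
        a0, a1, weights, m_w, cov_w = (x[ok] for x in (a0, a1, weights, m_w, cov_w))
    if len(a0) == 0:
        return
    span = a1 - a0
    b0 = np.minimum(a0.astype(np.int64), n_bins - 1)
    cut = b0 + 1.0
    wide = a1 > cut + 1.0          # span covers > 2 bins (short features)
    # first-bin share (vectorized; covers the one- and two-bin cases)
    frac1 = np.where(a1 <= cut, 1.0, (cut - a0) / span)
    frac1 = np.where(wide, 0.0, frac1)
    np.add.at(m_acc, b0, m_w * frac1)
    np.add.at(cov_acc, b0, cov_w * frac1)
    np.add.at(site_acc, b0, weights * frac1)
    # second-bin share
    two = np.flatnonzero(~wide & (a1 > cut))
    if len(two):
        b1 = np.minimum(b0[two] + 1, n_bins - 1)
        frac2 = (a1[two] - cut[two]) / span[two]
        np.add.at(m_acc, b1, m_w[two] * frac2)
        np.add.at(cov_acc, b1, cov_w[two] * frac2)
        np.add.at(site_acc, b1, weights[two] * frac2)
    # rare wide spans: exact fractional spread, plain loop
    for i in np.flatnonzero(wide):
        lo, hi = a0[i], a1[i]
        for b in range(int(lo), min(int(np.ceil(hi)), n_bins)):
            frac = (min(hi, b + 1) - max(lo, b)) / span[i]
            if frac > 0:
                m_acc[b] += m_w[i] * frac
                cov_acc[b] += cov_w[i] * frac
                site_acc[b] += weights[i] * frac


def _index_calls(calls: pd.DataFrame):
    """Per-(chrom, context) sorted position/count arrays for fast slicing."""
    out = {}
    for (chrom, ctx), sub in calls.groupby(["chrom", "context"], sort=False,
                                           observed=True):
        sub = sub.sort_values("start")
        out[(chrom, ctx)] = (
            sub["start"].to_numpy(),
            sub["count_m"].to_numpy(dtype=float),
            (sub["count_m"] + sub["count_u"]).to_numpy(dtype=float),
        )
    return out


def metagene_profile(calls: pd.DataFrame, features, flank: int = 2000,
                     body_bins: int = 60, flank_bins: int = 20,
                     feature_set: str = "features"):
    """Average methylation over length-normalized feature bodies + flanks.

    Bodies are scaled to ``body_bins`` equal fractions, flanks use
    fixed-width bins; '-' strand features are reversed so bin 0 is always the
    5' end.  Returns ``{context: MetaProfile}``.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    index = _index_calls(calls)
    acc = {
        ctx: {
            seg: (np.zeros(n), np.zeros(n), np.zeros(n))
            for seg, n in (("upstream", flank_bins), ("body", body_bins),
                           ("downstream", flank_bins))
        }
        for ctx in CONTEXTS
    }
    flank_width = flank / flank_bins
    n_feat = 0
    for feat in features:
        body = getattr(feat, "body", feat)
        strand = body.strand if body.strand in "+-" else "+"
        n_feat += 1
        for ctx in CONTEXTS:
            got = index.get((body.chrom, ctx))
            if got is None:
                continue
            pos, m_arr, cov_arr = got
            lo = np.searchsorted(pos, body.start - flank)
            hi = np.searchsorted(pos, body.end + flank)
            if hi <= lo:
                continue
            p = pos[lo:hi]
            m_w = m_arr[lo:hi]
            cov_w = cov_arr[lo:hi]
            ones = np.ones(len(p))
            for seg, seg_start, seg_len, n_bins in (
                ("upstream", body.start - flank, flank, flank_bins),
                ("body", body.start, body.end - body.start, body_bins),
                ("downstream", body.end, flank, flank_bins),
            ):
                inside = (p + 1 > seg_start) & (p < seg_start + seg_len)
                if not inside.any():
                    continue
                scale = n_bins / seg_len
                a0 = (p[inside] - seg_start) * scale
                a1 = (p[inside] + 1 - seg_start) * scale
                if strand == "-":
                    a0, a1 = n_bins - a1, n_bins - a0
                    tgt = {"upstream": "downstream",
                           "downstream": "upstream"}.get(seg, seg)
                else:
                    tgt = seg
                m_acc, cov_acc, site_acc = acc[ctx][tgt]
                _scatter_fractional(a0, a1, ones[inside], n_bins,
                                    m_acc, cov_acc, site_acc,
                                    m_w[inside], cov_w[inside])
    profiles = {}
    for ctx in CONTEXTS:
        prof = MetaProfile(feature_set=feature_set, context=ctx,
                           n_features=n_feat)
        for seg in ("upstream", "body", "downstream"):
            m_acc, cov_acc, site_acc = acc[ctx][seg]
            with np.errstate(invalid="ignore", divide="ignore"):
                level = np.where(cov_acc > 0, m_acc / np.maximum(cov_acc, 1e-300),
                                 np.nan)
            setattr(prof, seg, level)
            setattr(prof, f"{seg}_counts", site_acc)
            prof.m_sums[seg] = m_acc
            prof.cov_sums[seg] = cov_acc
        profiles[ctx] = prof
    return profiles


def combine_profiles(a: MetaProfile, b: MetaProfile) -> MetaProfile:
    """Count-weighted combination of two profiles over disjoint feature sets."""
    if a.context != b.context:
        raise ValueError("profiles must share a context")
    out = MetaProfile(feature_set=f"{a.feature_set}+{b.feature_set}",
                      context=a.context, n_features=a.n_features + b.n_features)
    for seg in ("upstream", "body", "downstream"):
        m = a.m_sums[seg] + b.m_sums[seg]
        cov = a.cov_sums[seg] + b.cov_sums[seg]
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(cov > 0, m / np.maximum(cov, 1e-300), np.nan)
        setattr(out, seg, level)
        setattr(out, f"{seg}_counts",
                getattr(a, f"{seg}_counts") + getattr(b, f"{seg}_counts"))
        out.m_sums[seg] = m
        out.cov_sums[seg] = cov
    return out


def region_levels(calls: pd.DataFrame, genes, tes) -> pd.DataFrame:
    """Count-weighted mean level per region class and context.

    Introns are gene bodies minus exons; a site overlapping several classes
    counts in each.  Intergenic = outside every gene body, promoter and TE.
    """
    by_class: dict[str, dict[str, list]] = {c: {} for c in REGION_CLASSES[:-1]}
    for g in genes:
        chrom = g.body.chrom
        if g.promoter is not None:
            by_class["promoter"].setdefault(chrom, []).append(
                (g.promoter.start, g.promoter.end))
        by_class["genebody"].setdefault(chrom, []).append(
            (g.body.start, g.body.end))
        for ex in g.exons:
            by_class["exon"].setdefault(chrom, []).append((ex.start, ex.end))
        for s, e in g.introns():
            by_class["intron"].setdefault(chrom, []).append((s, e))
    for te in tes:
        by_class["TE"].setdefault(te.body.chrom, []).append(
            (te.body.start, te.body.end))
    merged = {
        cls: {c: merge_intervals(v) for c, v in chroms.items()}
        for cls, chroms in by_class.items()
    }

    rows = []
    for (chrom, ctx), sub in calls.groupby(["chrom", "context"], sort=False,
                                           observed=True):
        pos = sub["start"].to_numpy()
        m = sub["count_m"].to_numpy(dtype=float)
        cov = (sub["count_m"] + sub["count_u"]).to_numpy(dtype=float)
        genic = np.zeros(len(pos), dtype=bool)
        for cls in ("promoter", "genebody", "TE"):
            genic |= membership(pos, merged[cls].get(chrom, []))
        for cls in REGION_CLASSES:
            if cls == "intergenic":
                mask = ~genic
            else:
                mask = membership(pos, merged[cls].get(chrom, []))
            if mask.any():
                rows.append((chrom, cls, ctx, m[mask].sum(), cov[mask].sum(),
                             int(mask.sum())))
    if not rows:
        return pd.DataFrame(columns=["region_class", "context", "mean_level",
                                     "n_sites"])
    df = pd.DataFrame(rows, columns=["chrom", "region_class", "context",
                                     "m", "cov", "n_sites"])
    agg = (df.groupby(["region_class", "context"], sort=False)
             .agg(m=("m", "sum"), cov=("cov", "sum"), n_sites=("n_sites", "sum"))
             .reset_index())
    agg = agg[agg["cov"] > 0]
    agg["mean_level"] = agg["m"] / agg["cov"]
    order = {c: i for i, c in enumerate(REGION_CLASSES)}
    agg = agg.sort_values(["region_class", "context"],
                          key=lambda s: s.map(order).fillna(s.map(
                              {c: i for i, c in enumerate(CONTEXTS)})))
    return agg[["region_class", "context", "mean_level", "n_sites"]].reset_index(drop=True)


def te_order_profiles(calls: pd.DataFrame, tes, orders=None,
                      min_features: int = 5, **profile_kwargs):
    """Metagene profiles per TE order; orders with too few elements skipped."""
    import warnings

    if orders is None:
        orders = sorted({te.order for te in tes})
    out = {}
    for order in orders:
        subset = [te for te in tes if te.order == order]
        if len(subset) < min_features:
            warnings.warn(
                f"TE order {order!r} has {len(subset)} elements "
                f"(< {min_features}); skipped"
            )
            continue
        out[order] = metagene_profile(calls, subset,
                                      feature_set=f"TE:{order}",
                                      **profile_kwargs)
    return out


def profiles_to_table(profiles: dict, feature_set: str) -> pd.DataFrame:
    """Flatten {context: MetaProfile} into a tidy TSV-ready table."""
    rows = []
    for ctx, prof in profiles.items():
        for seg in ("upstream", "body", "downstream"):
            levels = prof.segment(seg)
            counts = getattr(prof, f"{seg}_counts")
            for i, (lv, n) in enumerate(zip(levels, counts)):
                rows.append((feature_set, ctx, seg, i, lv, n))
    return pd.DataFrame(rows, columns=["feature_set", "context", "segment",
                                       "bin", "mean_level", "n_sites"])
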