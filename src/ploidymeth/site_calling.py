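"""Spike-in-calibrated methylation-site calling and genome-wide summaries.

A cytosine is tested against the null that all of its methylated reads are
bisulfite non-conversion artefacts: with non-conversion rate ``r`` estimated
from an unmethylated lambda-phage spike-in, the one-sided p-value is
``P(X >= count_m)`` for ``X ~ Binomial(count_m + count_u, r)``.  Sites with a
Benjamini-Hochberg q-value below ``alpha`` (one family per sample, all
contexts pooled) are flagged methylated.  The methylation level of a site,
window or region is always the count-weighted ratio ``ML = mC / (mC + umC)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CONTEXTS

CALL_COLUMNS = [
    "chrom", "start", "strand", "context", "count_m", "count_u",
    "level", "p_value", "q_value", "methylated",
]


@dataclass(frozen=True)
class ConversionEstimate:
    """Pooled lambda non-conversion rate r = sum(mC) / sum(mC + umC)."""

    rate_r: float
    n_sites: int
    n_reads: int

    def __post_init__(self):
        if not (0 < self.rate_r < 1):
            raise ValueError("non-conversion rate must lie strictly in (0, 1)")


def estimate_nonconversion(lambda_report: pd.DataFrame) -> ConversionEstimate:
    """Estimate the non-conversion rate from a lambda spike-in site table.

    The spike-in is fully unmethylated, so every methylated read is a failed
    conversion.  A raw ratio of exactly 0 or 1 is clamped into (0, 1) by a
    pseudocount (0.5 on the numerator, 1 on the denominator) so the binomial
    null is never degenerate.
    """
    m = int(lambda_report["count_m"].sum())
    total = m + int(lambda_report["count_u"].sum())
    if total == 0:
        raise ValueError("lambda report has zero total coverage")
    ratio = m / total
    if ratio == 0.0 or ratio == 1.0:
        ratio = (m + 0.5) / (total + 1)
    covered = int(
        ((lambda_report["count_m"] + lambda_report["count_u"]) > 0).sum()
    )
    return ConversionEstimate(rate_r=ratio, n_sites=covered, n_reads=total)


def methylation_level(count_m: int, count_u: int) -> float:
    """ML = mC / (mC + umC); undefined (raises) at zero coverage."""
    total = count_m + count_u
    if total <= 0:
        raise ValueError("methylation level undefined at zero coverage")
    return count_m / total


def binomial_site_pvalue(count_m, coverage, rate_r: float):
    """Upper-tail binomial p-value P(X >= count_m), vectorized."""
    if not (0 < rate_r < 1):
        raise ValueError("rate_r must lie strictly in (0, 1)")
    return stats.binom.sf(np.asarray(count_m) - 1, np.asarray(coverage), rate_r)


def call_sites(records: pd.DataFrame, conv: ConversionEstimate,
               alpha: float = 0.05, min_coverage: int = 4) -> pd.DataFrame:
    """Test every sufficiently covered site of one sample.

    Returns a call table (one row per tested site) with per-site level,
    binomial p-value, BH q-value over all tested sites of the sample, and the
    methylated flag ``q_value < alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    cov = records["count_m"] + records["count_u"]
    calls = records.loc[cov >= min_coverage].reset_index(drop=True).copy()
    coverage = (calls["count_m"] + calls["count_u"]).to_numpy()
    if len(calls) == 0:
        calls[["level", "p_value", "q_value"]] = np.nan
        calls["methylated"] = pd.Series([], dtype=bool)
        return calls
    p = binomial_site_pvalue(calls["count_m"].to_numpy(), coverage, conv.rate_r)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    calls["level"] = calls["count_m"].to_numpy() / coverage
    calls["p_value"] = p
    calls["q_value"] = q
    calls["methylated"] = q < alpha
    return calls


def windowed_levels(calls: pd.DataFrame, bin_size: int = 10000) -> pd.DataFrame:
    """Count-weighted methylation level per (chrom, window, context).

    The level of a window is ``sum(mC) / sum(mC + umC)`` over its member
    sites — the sum of read counts in the window, not a mean of per-site
    ratios.  Windows with zero coverage are omitted.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(calls) == 0:
        return pd.DataFrame(
            columns=["chrom", "bin_start", "bin_end", "context", "level",
                     "n_sites", "count_m", "coverage"]
        )
    df = calls[["chrom", "start", "context", "count_m", "count_u"]].copy()
    df["bin_start"] = (df["start"] // bin_size) * bin_size
    grouped = (
        df.groupby(["chrom", "bin_start", "context"], sort=True, observed=True)
        .agg(n_sites=("start", "size"), count_m=("count_m", "sum"),
             count_u=("count_u", "sum"))
        .reset_index()
    )
    grouped["coverage"] = grouped["count_m"] + grouped["count_u"]
    grouped = grouped[grouped["coverage"] > 0].reset_index(drop=True)
    grouped["level"] = grouped["count_m"] / grouped["coverage"]
    grouped["bin_end"] = grouped["bin_start"] + bin_size
    return grouped[["chrom", "bin_start", "bin_end", "context", "level",
                    "n_sites", "count_m", "coverage"]]


@dataclass
class GlobalMethylationStats:
    """Per-sample genome-wide summary of methylated-site calls.

    ``pct_mC`` and ``pct_by_context`` are percentages of covered (tested)
    sites flagged methylated; ``proportion_of_mC_by_context`` distributes the
    methylated sites over the three contexts (sums to 1); the histogram bins
    methylated-site levels into ten 10%-wide bins.
    """

    pct_mC: float
    pct_by_context: dict = field(default_factory=dict)
    proportion_of_mC_by_context: dict = field(default_factory=dict)
    level_histogram: dict = field(default_factory=dict)
    n_covered: int = 0
    n_methylated: int = 0


def global_stats(calls: pd.DataFrame) -> GlobalMethylationStats:
    """Summarize one sample's calls (Table-1-style percentages, histograms)."""
    if len(calls) == 0:
        raise ValueError("no covered sites")
    n_meth = int(calls["methylated"].sum())
    pct_by_context = {}
    prop = {}
    hist = {}
    edges = np.linspace(0.0, 1.0, 11)
    for ctx in CONTEXTS:
        sub = calls[calls["context"] == ctx]
        meth = sub[sub["methylated"]]
        pct_by_context[ctx] = (
            100.0 * len(meth) / len(sub) if len(sub) else float("nan")
        )
        prop[ctx] = len(meth) / n_meth if n_meth else float("nan")
        counts, _ = np.histogram(
            np.clip(meth["level"].to_numpy(), 0, 1 - 1e-12), bins=edges
        )
        hist[ctx] = counts
    return GlobalMethylationStats(
        pct_mC=100.0 * n_meth / len(calls),
        pct_by_context=pct_by_context,
        proportion_of_mC_by_context=prop,
        level_histogram=hist,
        n_covered=len(calls),
        n_methylated=n_meth,
    )


# ---------------------------------------------------------------------------
# TSV writers (External Interfaces)
# ---------------------------------------------------------------------------


def write_calls(calls: pd.DataFrame, path, header: str | None = None):
    from .io_formats import write_headed_tsv

    out = calls[CALL_COLUMNS].copy()
    out["end"] = out["start"] + 1
    out = out[["chrom", "start", "end", "strand", "context", "count_m",
               "count_u", "level", "p_value", "q_value", "methylated"]]
    write_headed_tsv(out, path, header)


def write_windowed(windows: pd.DataFrame, path, header: str | None = None):
    from .io_formats import write_headed_tsv

    write_headed_tsv(windows, path, header)


def write_summary(stats_by_sample: dict, path, header: str | None = None):
    """Table-1-style summary TSV keyed by sample."""
    from .io_formats import write_headed_tsv

    rows = []
    for sample, st in stats_by_sample.items():
        rows.append(
            {
                "sample": sample,
                "pct_mC": st.pct_mC,
                "pct_mCG": st.pct_by_context["CG"],
                "pct_mCHG": st.pct_by_context["CHG"],
                "pct_mCHH": st.pct_by_context["CHH"],
                "prop_mC_CG": st.proportion_of_mC_by_context["CG"],
                "prop_mC_CHG": st.proportion_of_mC_by_context["CHG"],
                "prop_mC_CHH": st.proportion_of_mC_by_context["CHH"],
                "n_covered": st.n_covered,
                "n_methylated": st.n_methylated,
            }
        )
    write_headed_tsv(pd.DataFrame(rows), path, header)
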