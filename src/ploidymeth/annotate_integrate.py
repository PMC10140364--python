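"""DMR-to-gene anchoring and methylation/expression/TE integration.

A gene is DMR-related when a DMR overlaps its body (TSS..TES) or its 2-kb
upstream promoter by at least one base; the DMR-related gene set is the
*union* of body- and promoter-anchored genes, never their sum.  Downstream
integration joins that set with expression classes, TE-insertion status and
the differential-expression table, and tests gene sets for term
over-representation with a one-sided hypergeometric test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import metagene_profile


@dataclass(frozen=True)
class DmrGeneAssignment:
    gene_id: str
    context: str
    region_type: str               # "body" or "promoter"
    dmr_ids: tuple = ()

    def __post_init__(self):
        if self.region_type not in ("body", "promoter"):
            raise ValueError(f"bad region_type {self.region_type!r}")


@dataclass(frozen=True)
class IntegrationRecord:
    gene_id: str
    methylation_direction: str     # hyper | hypo | mixed | none
    de_status: str                 # up | down | ns
    expression_class: str = "none"
    te_status: str = "none"

    @property
    def quadrant(self) -> str:
        if self.methylation_direction in ("mixed", "none"):
            return self.methylation_direction
        if self.de_status == "ns":
            return "ns"
        return f"{self.methylation_direction}-{self.de_status}"


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int     # set genes carrying the term
    K: int     # background genes carrying the term
    n: int     # set size
    N: int     # background size
    p_value: float
    q_value: float = float("nan")


# ---------------------------------------------------------------------------
# anchoring and set logic
# ---------------------------------------------------------------------------


def anchor_dmrs(dmrs, genes):
    """Assign DMRs to genes via >= 1 bp overlap with body or promoter."""
    trees: dict[tuple, IntervalTree] = {}
    for g in genes:
        trees.setdefault(("body", g.body.chrom), IntervalTree()).addi(
            g.body.start, g.body.end, g.gene_id)
        if g.promoter is not None:
            trees.setdefault(("promoter", g.promoter.chrom), IntervalTree()).addi(
                g.promoter.start, g.promoter.end, g.gene_id)
    hits: dict[tuple, list] = {}
    for d in dmrs:
        for region_type in ("body", "promoter"):
            tree = trees.get((region_type, d.chrom))
            if tree is None:
                continue
            for iv in tree.overlap(d.start, d.end):
                hits.setdefault((iv.data, d.context, region_type), []).append(
                    d.dmr_id)
    return [
        DmrGeneAssignment(gene_id, context, region_type, tuple(sorted(ids)))
        for (gene_id, context, region_type), ids in sorted(hits.items())
    ]


def dmr_related_genes(assignments) -> set:
    """Union of body- and promoter-anchored gene ids."""
    return {a.gene_id for a in assignments}


def two_set_union_size(size_a: int, size_b: int, size_intersection: int) -> int:
    """|A ∪ B| by inclusion-exclusion from printed set sizes."""
    if size_intersection > min(size_a, size_b):
        raise ValueError("intersection larger than a set")
    return size_a + size_b - size_intersection


def venn_counts(assignments, by: str = "context") -> dict:
    """Exclusive Venn-region gene counts, keyed by frozenset of set labels.

    ``by="context"`` builds one gene set per methylation context,
    ``by="region_type"`` one per anchoring region (body / promoter).
    """
    if by not in ("context", "region_type"):
        raise ValueError("by must be 'context' or 'region_type'")
    sets: dict[str, set] = {}
    for a in assignments:
        sets.setdefault(getattr(a, by), set()).add(a.gene_id)
    labels = sorted(sets)
    counts = {}
    from itertools import combinations

    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[label] for label in combo))
            outside = set.union(set(), *(sets[label] for label in labels
                                         if label not in combo))
            counts[frozenset(combo)] = len(inside - outside)
    return counts


# ---------------------------------------------------------------------------
# expression classes and methylation profiles per class
# ---------------------------------------------------------------------------


def classify_expression(fpkm_table: pd.DataFrame, group: str | None = None,
                        min_expr: float = 0.1,
                        scheme: str = "none+tertiles") -> dict:
    """Class per gene: none-expressed, then low/medium/high.

    Default scheme: genes with mean FPKM below ``min_expr`` are
    "none"; the remaining genes split at the tertiles of their mean-FPKM
    distribution (a none-expressed gene cannot be a quantile member of the
    distribution that contains it).  ``scheme="quartiles"`` instead cuts all
    genes at the FPKM quartiles into none/low/medium/high.
    """
    df = fpkm_table
    if group is not None:
        df = df[df["group"] == group]
    mean_fpkm = df.groupby("gene_id")["fpkm"].mean()
    classes = {}
    if scheme == "quartiles":
        ranks = mean_fpkm.rank(method="first")
        cut = pd.qcut(ranks, 4, labels=["none", "low", "medium", "high"])
        return dict(zip(mean_fpkm.index, cut.astype(str)))
    if scheme != "none+tertiles":
        raise ValueError(f"unknown scheme {scheme!r}")
    expressed = mean_fpkm[mean_fpkm >= min_expr]
    for gid in mean_fpkm.index[mean_fpkm < min_expr]:
        classes[gid] = "none"
    if len(expressed) == 0:
        warnings.warn("all genes are none-expressed; tertiles are empty")
        return classes
    ranks = expressed.rank(method="first")
    cut = pd.qcut(ranks, 3, labels=["low", "medium", "high"])
    classes.update(dict(zip(expressed.index, cut.astype(str))))
    return classes


def methylation_by_expression_class(calls: pd.DataFrame, genes, classes: dict,
                                    min_genes: int = 5, **profile_kwargs):
    """Metagene profile per expression class: {class: {context: MetaProfile}}."""
    out = {}
    for cls in ("none", "low", "medium", "high"):
        subset = [g for g in genes if classes.get(g.gene_id) == cls]
        if len(subset) < min_genes:
            warnings.warn(f"expression class {cls!r} has {len(subset)} genes "
                          f"(< {min_genes}); skipped")
            continue
        out[cls] = metagene_profile(calls, subset, feature_set=f"class:{cls}",
                                    **profile_kwargs)
    return out


# ---------------------------------------------------------------------------
# TE insertion vs expression
# ---------------------------------------------------------------------------


def te_insertion_status(genes, tes, flank: int = 2000) -> dict:
    """body if a TE overlaps TSS..TES, else flank if within 2 kb, else none."""
    trees: dict[str, IntervalTree] = {}
    for te in tes:
        trees.setdefault(te.body.chrom, IntervalTree()).addi(
            te.body.start, te.body.end, te.te_id)
    status = {}
    for g in genes:
        tree = trees.get(g.body.chrom)
        st = "none"
        if tree is not None:
            if tree.overlap(g.body.start, g.body.end):
                st = "body"
            elif tree.overlap(max(0, g.body.start - flank), g.body.end + flank):
                st = "flank"
        status[g.gene_id] = st
    return status


def te_insertion_expression(genes, tes, fpkm_table: pd.DataFrame,
                            flank: int = 2000):
    """Mean log expression per TE-insertion status + rank-sum comparisons.

    Returns ``(summary_df, pvalues)`` where pvalues holds two-sided
    Mann-Whitney p for body-vs-none and flank-vs-none on log1p(FPKM).
    """
    status = te_insertion_status(genes, tes, flank)
    mean_fpkm = fpkm_table.groupby("gene_id")["fpkm"].mean()
    values = {st: [] for st in ("body", "flank", "none")}
    for gid, st in status.items():
        if gid in mean_fpkm.index:
            values[st].append(np.log1p(mean_fpkm[gid]))
    rows = [
        {"te_status": st, "n_genes": len(v),
         "mean_log1p_fpkm": float(np.mean(v)) if v else float("nan")}
        for st, v in values.items()
    ]
    pvalues = {}
    for st in ("body", "flank"):
        if values[st] and values["none"]:
            pvalues[f"{st}_vs_none"] = float(
                stats.mannwhitneyu(values[st], values["none"],
                                   alternative="two-sided").pvalue
            )
    return pd.DataFrame(rows), pvalues


# ---------------------------------------------------------------------------
# DEG x DMR integration
# ---------------------------------------------------------------------------


def gene_methylation_direction(assignments, dmr_directions: dict) -> dict:
    """Majority DMR direction per gene ("mixed" on a tie)."""
    tallies: dict[str, list] = {}
    for a in assignments:
        for dmr_id in a.dmr_ids:
            tallies.setdefault(a.gene_id, []).append(dmr_directions[dmr_id])
    out = {}
    for gid, dirs in tallies.items():
        hyper = dirs.count("hyper")
        hypo = dirs.count("hypo")
        out[gid] = "hyper" if hyper > hypo else "hypo" if hypo > hyper else "mixed"
    return out


def overlap_deg_dmr(de_table: pd.DataFrame, assignments, dmr_directions: dict,
                    expression_classes: dict | None = None,
                    te_status: dict | None = None):
    """Join DEGs with DMR-related genes into quadrant-labelled records.

    The overlap set is (DE status != ns) ∩ (DMR-related genes); each gene is
    labelled hyper-down, hypo-up, hyper-up or hypo-down ("mixed" genes are
    listed but excluded from quadrant counts).  Raises when the two inputs
    share no gene ids at all (a namespace mismatch, not an empty result).
    """
    related = dmr_related_genes(assignments)
    de_genes = set(de_table["gene_id"])
    if len(de_table) and related and not (de_genes & related):
        raise ValueError("DE table and DMR assignments share no gene ids")
    direction = gene_methylation_direction(assignments, dmr_directions)
    status_by_gene = dict(zip(de_table["gene_id"], de_table["status"]))
    overlap = sorted(
        g for g in related if status_by_gene.get(g, "ns") != "ns"
    )
    records = [
        IntegrationRecord(
            gene_id=g,
            methylation_direction=direction.get(g, "none"),
            de_status=status_by_gene[g],
            expression_class=(expression_classes or {}).get(g, "none"),
            te_status=(te_status or {}).get(g, "none"),
        )
        for g in overlap
    ]
    quadrants = {q: 0 for q in ("hyper-down", "hypo-up", "hyper-up", "hypo-down")}
    mixed = 0
    for r in records:
        if r.methylation_direction == "mixed":
            mixed += 1
        else:
            quadrants[r.quadrant] += 1
    quadrants["mixed"] = mixed
    return records, quadrants


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------


def overrepresentation(gene_set, background, term_map: pd.DataFrame):
    """One-sided hypergeometric over-representation test per term.

    ``term_map``: DataFrame with gene_id, term_id[, term_name].  Terms with
    no gene in the set (k = 0) are not tested.  BH q-values are computed over
    the tested terms.
    """
    if len(term_map) == 0:
        raise ValueError("empty term map")
    background = set(background)
    gene_set = set(gene_set)
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    tm = term_map[term_map["gene_id"].isin(background)]
    names = dict(zip(tm["term_id"], tm.get("term_name", tm["term_id"])))
    N = len(background)
    n = len(gene_set)
    results = []
    for term_id, sub in tm.groupby("term_id"):
        carriers = set(sub["gene_id"])
        K = len(carriers)
        k = len(carriers & gene_set)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id, names.get(term_id, term_id),
                                        k, K, n, N, p))
    if not results:
        return []
    _, q, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    results = [
        EnrichmentResult(r.term_id, r.term_name, r.k, r.K, r.n, r.N,
                         r.p_value, float(qv))
        for r, qv in zip(results, q)
    ]
    results.sort(key=lambda r: r.p_value)
    return results
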