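"""Synthetic bisulfite data with the statistical structure of a diploid vs
autotetraploid leaf methylome comparison.

The generator emulates the assumed structure of the real experiment: a
CpG-depleted genome so that most cytosines sit in CHH context; bimodal
per-site methylation (a context-specific fraction of sites methylated, with
methylated-site levels drawn from context-specific Beta distributions,
calibrated so the pooled mean level per context matches ``baseline_levels``);
elevated methylation in TE bodies; gene-body methylation tied to expression
tier; planted hyper/hypo DMRs between the groups; beta-binomial replicate
counts at Poisson ~15x depth; a fully unmethylated lambda spike-in
chromosome; and FPKM/differential-expression tables coupled to promoter
methylation and TE insertion.

All outputs are deterministic functions of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .io_formats import (
    CONTEXTS,
    GeneFeature,
    GenomicInterval,
    TeFeature,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: sub-seeds so each stage draws an independent, reproducible stream
_STAGE_KEYS = {"genome": 11, "methylome": 23, "expression": 37, "terms": 53}

_CLASS_I_ORDERS = ("Copia", "Gypsy", "LINE", "LTR")
_CLASS_II_ORDERS = ("Helitron", "TIR", "MITE")

_TIERS = ("none", "low", "medium", "high")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment (defaults = the emulated design)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 240
    n_tes: int = 200
    depth_mean: float = 15.0
    baseline_levels: dict = field(
        default_factory=lambda: {"CG": 0.40, "CHG": 0.28, "CHH": 0.10}
    )
    dispersion: float = 0.05
    n_dmrs: int = 120
    dmr_length_range: tuple = (500, 1500)
    dmr_effect: float = 0.3
    hyper_fraction: float = 0.6
    conversion_failure: float = 0.005
    replicates_per_group: int = 3
    groups: tuple = ("2X", "4X")

    # genome composition
    gc_content: float = 0.36
    cpg_suppression: float = 0.50   # CG dinucleotide retention factor
    chg_suppression: float = 0.6
    lambda_length: int = 48_502
    promoter_length: int = 2000
    flank: int = 2000
    gene_length_range: tuple = (800, 3000)

    # methylation architecture
    methylated_level_beta: dict = field(
        default_factory=lambda: {"CG": (18.0, 2.0), "CHG": (18.0, 3.0),
                                 "CHH": (3.0, 6.0)}
    )
    te_methylated_fraction: dict = field(
        default_factory=lambda: {"CG": 0.90, "CHG": 0.85, "CHH": 0.70}
    )
    tier_multipliers: dict = field(
        default_factory=lambda: {
            "CG": {"none": 0.6, "low": 1.1, "medium": 1.5, "high": 1.2},
            "CHG": {"none": 1.0, "low": 0.7, "medium": 0.5, "high": 0.3},
            "CHH": {"none": 1.0, "low": 0.7, "medium": 0.5, "high": 0.3},
        }
    )

    # planted-DMR placement (context proportions mirror the CHH-dominated
    # composition of the emulated comparison)
    dmr_context_proportions: dict = field(
        default_factory=lambda: {"CG": 0.045, "CHG": 0.095, "CHH": 0.860}
    )
    dmr_promoter_fraction: float = 0.30
    dmr_body_fraction: float = 0.25
    dmr_min_separation: int = 2000

    # TE-gene geometry
    body_te_fraction: float = 0.15
    flank_te_fraction: float = 0.15

    # expression model
    none_expressed_fraction: float = 0.10
    tier_log2_fpkm: dict = field(
        default_factory=lambda: {"low": 1.0, "medium": 3.5, "high": 6.0}
    )
    expression_rep_sd: float = 0.3
    body_te_penalty: float = 0.3    # multiplicative FPKM factor
    flank_te_boost: float = 2.0
    coupled_fraction: float = 0.5
    coupling_log2fc: float = 2.0

    def __post_init__(self):
        # YAML round trips deliver lists; normalize back to tuples
        for name in ("dmr_length_range", "gene_length_range", "groups"):
            val = getattr(self, name)
            if isinstance(val, list):
                setattr(self, name, tuple(val))
        self.methylated_level_beta = {
            k: tuple(v) for k, v in self.methylated_level_beta.items()
        }

    def validate(self):
        for name in ("conversion_failure", "hyper_fraction", "dispersion",
                     "coupled_fraction", "body_te_fraction", "flank_te_fraction",
                     "none_expressed_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if not (0 <= self.dmr_effect <= 1):
            raise ValueError("dmr_effect must lie in [0, 1]")
        for ctx in CONTEXTS:
            lvl = self.baseline_levels[ctx]
            if not (0 <= lvl <= 1):
                raise ValueError("baseline levels must lie in [0, 1]")
            a, b = self.methylated_level_beta[ctx]
            if lvl > 0 and lvl / (a / (a + b)) > 1:
                raise ValueError(
                    f"baseline level {lvl} for {ctx} exceeds the mean "
                    "methylated-site level; lower it or raise the Beta mean"
                )
        lo, hi = self.dmr_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad dmr_length_range")
        return self

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STAGE_KEYS[stage]])

    def sample_names(self):
        return [
            f"{g}_{i + 1}" for g in self.groups
            for i in range(self.replicates_per_group)
        ]


@dataclass(frozen=True)
class PlantedDmr:
    chrom: str
    start: int
    end: int
    context: str
    direction: str    # hyper = elevated in group 2 (4X), hypo = elevated in 2X
    placement: str = "intergenic"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthSet:
    """Ground truth recorded while simulating, for recovery tests."""

    planted_dmrs: list = field(default_factory=list)
    te_gene_links: dict = field(default_factory=dict)   # gene -> body|flank|none
    coupled_genes: dict = field(default_factory=dict)   # gene -> (meth, expr) signs
    gene_tiers: dict = field(default_factory=dict)      # gene -> expression tier
    promoter_dmr_genes: dict = field(default_factory=dict)  # gene -> meth sign

    def to_json(self, path):
        payload = {
            "planted_dmrs": [asdict(d) for d in self.planted_dmrs],
            "te_gene_links": self.te_gene_links,
            "coupled_genes": {k: list(v) for k, v in self.coupled_genes.items()},
            "gene_tiers": self.gene_tiers,
            "promoter_dmr_genes": self.promoter_dmr_genes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted_dmrs=[PlantedDmr(**d) for d in payload["planted_dmrs"]],
            te_gene_links=payload["te_gene_links"],
            coupled_genes={k: tuple(v) for k, v in payload["coupled_genes"].items()},
            gene_tiers=payload["gene_tiers"],
            promoter_dmr_genes=payload["promoter_dmr_genes"],
        )


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def _random_sequence(rng, length, gc, cpg_keep, chg_keep):
    """Random sequence with CpG (and C-H-G) dinucleotide depletion.

    Depletion shifts most cytosines into CHH context, the hallmark of plant
    genomes that makes CHH the most populous context.
    """
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(np.arange(4), size=length, p=probs).astype(np.uint8)
    c, g = 1, 2
    # break a fraction of CG dinucleotides (G -> T)
    cg = np.flatnonzero((seq[:-1] == c) & (seq[1:] == g))
    kill = cg[rng.random(len(cg)) > cpg_keep]
    seq[kill + 1] = 3
    # break a fraction of C-H-G trinucleotides (G -> A)
    chg = np.flatnonzero((seq[:-2] == c) & (seq[1:-1] != g) & (seq[2:] == g))
    kill = chg[rng.random(len(chg)) > chg_keep]
    seq[kill + 2] = 0
    return seq


def _seq_to_str(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


def simulate_genome(config: SimulationConfig):
    """Generate a genome with non-overlapping stranded genes and placed TEs.

    Genes sit in equal-width slots with enough margin for promoters and
    flanks; TEs are placed inside gene bodies, in 2-kb flanks, and
    intergenically, recording the gene-TE link for each gene.
    Returns ``(sequences, genes, tes)`` where ``sequences`` maps chromosome
    name to string.
    """
    config.validate()
    rng = config.rng("genome")
    sequences = {}
    genes = []
    tes = []
    te_links = {}

    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    glo, ghi = config.gene_length_range
    margin = max(config.promoter_length, config.flank) + 200

    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = _random_sequence(
            rng, config.chrom_length, config.gc_content,
            config.cpg_suppression, config.chg_suppression,
        )
        sequences[chrom] = _seq_to_str(seq)
        n_here = per_chrom[ci]
        if n_here == 0:
            continue
        slot = config.chrom_length // n_here
        if slot < ghi + 2 * margin:
            raise ValueError(
                "chrom_length too small to place the requested genes with "
                "promoter/flank margins"
            )
        for gi in range(n_here):
            length = int(rng.integers(glo, ghi + 1))
            lo = gi * slot + margin
            hi = (gi + 1) * slot - margin - length
            start = int(rng.integers(lo, hi + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, start, start + length, strand)
            exons = _random_exons(rng, body)
            gene_id = f"g{ci + 1:02d}{gi + 1:04d}"
            from .io_formats import make_promoter

            promoter = make_promoter(body, config.promoter_length,
                                     config.chrom_length)
            genes.append(GeneFeature(gene_id, body, exons, promoter))
            te_links[gene_id] = "none"

    # --- TE placement -----------------------------------------------------
    n_body = min(int(round(config.body_te_fraction * len(genes))), config.n_tes)
    n_flank = min(int(round(config.flank_te_fraction * len(genes))),
                  config.n_tes - n_body)
    eligible = [g for g in genes if g.body.length >= 500]
    chosen = list(rng.choice(len(eligible), size=min(n_body + n_flank, len(eligible)),
                             replace=False))
    body_genes = [eligible[i] for i in chosen[:n_body]]
    flank_genes = [eligible[i] for i in chosen[n_body:]]
    tid = 0

    def draw_order():
        if rng.random() < 0.6:
            return _CLASS_I_ORDERS[rng.integers(len(_CLASS_I_ORDERS))]
        return _CLASS_II_ORDERS[rng.integers(len(_CLASS_II_ORDERS))]

    for g in body_genes:
        max_len = min(1500, g.body.length - 100)
        length = int(rng.integers(300, max(301, max_len + 1)))
        start = int(rng.integers(g.body.start, g.body.end - length + 1))
        tid += 1
        tes.append(TeFeature(f"te{tid:04d}",
                             GenomicInterval(g.body.chrom, start, start + length),
                             draw_order()))
        te_links[g.gene_id] = "body"
    for g in flank_genes:
        length = int(rng.integers(300, 1501))
        if rng.random() < 0.5:
            end = int(g.body.start - rng.integers(0, config.flank - length + 1))
            start = end - length
        else:
            start = int(g.body.end + rng.integers(0, config.flank - length + 1))
            end = start + length
        start = max(0, start)
        tid += 1
        tes.append(TeFeature(f"te{tid:04d}",
                             GenomicInterval(g.body.chrom, start, start + length),
                             draw_order()))
        te_links[g.gene_id] = "flank"

    # intergenic TEs: keep clear of gene bodies +- flank
    from ._intervals import merge_intervals, overlap_length

    blocked = {}
    for g in genes:
        blocked.setdefault(g.body.chrom, []).append(
            (max(0, g.body.start - config.flank), g.body.end + config.flank)
        )
    blocked = {c: merge_intervals(v) for c, v in blocked.items()}
    chrom_names = list(sequences)
    remaining = config.n_tes - tid
    attempts = 0
    while remaining > 0 and attempts < 200 * config.n_tes:
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        length = int(rng.integers(300, 3001))
        start = int(rng.integers(0, config.chrom_length - length))
        if overlap_length(start, start + length, blocked.get(chrom, [])):
            continue
        tid += 1
        tes.append(TeFeature(f"te{tid:04d}",
                             GenomicInterval(chrom, start, start + length),
                             draw_order()))
        remaining -= 1
    if remaining > 0:
        raise ValueError("chrom_length too small to place the requested TEs")

    tes.sort(key=lambda t: (t.body.chrom, t.body.start))
    return sequences, genes, tes, te_links


def _random_exons(rng, body: GenomicInterval):
    """Split a gene body into 1-5 exons with intervening introns."""
    k = int(rng.integers(1, 6))
    if k == 1 or body.length < 60 * (2 * k - 1):
        return (body,)
    w = rng.dirichlet(np.ones(2 * k - 1)) * (body.length - 60 * (2 * k - 1))
    widths = (w + 60).astype(int)
    widths[-1] += body.length - int(widths.sum())
    bounds = np.concatenate([[0], np.cumsum(widths)])
    exons = []
    for j in range(k):
        s = body.start + int(bounds[2 * j])
        e = body.start + int(bounds[2 * j + 1])
        exons.append(GenomicInterval(body.chrom, s, min(e, body.end), body.strand))
    return tuple(exons)


# ---------------------------------------------------------------------------
# cytosine site grid
# ---------------------------------------------------------------------------


def site_table(sequences: dict) -> pd.DataFrame:
    """All cytosines of both strands with their context, position-sorted."""
    frames = []
    for chrom, s in sequences.items():
        seq = np.frombuffer(s.encode(), dtype=np.uint8)
        A, C, G, T = 65, 67, 71, 84
        n = len(seq)
        # forward-strand cytosines (need two downstream bases)
        fwd = np.flatnonzero(seq[:-2] == C)
        nxt1, nxt2 = seq[fwd + 1], seq[fwd + 2]
        fwd_ctx = np.where(nxt1 == G, 0, np.where(nxt2 == G, 1, 2))
        # reverse-strand cytosines are reference Gs (two upstream bases)
        rev = np.flatnonzero(seq[2:] == G) + 2
        prv1, prv2 = seq[rev - 1], seq[rev - 2]
        rev_ctx = np.where(prv1 == C, 0, np.where(prv2 == C, 1, 2))
        pos = np.concatenate([fwd, rev])
        strand = np.concatenate([
            np.full(len(fwd), "+"), np.full(len(rev), "-")
        ])
        ctx = np.concatenate([fwd_ctx, rev_ctx])
        order = np.argsort(pos, kind="mergesort")
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": pos[order].astype(np.int64),
            "strand": strand[order],
            "context": np.array(CONTEXTS)[ctx[order]],
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def _assign_tiers(rng, genes, config):
    """Expression tier per gene: a none-expressed slice, then equal tertiles."""
    ids = [g.gene_id for g in genes]
    perm = rng.permutation(len(ids))
    n_none = int(round(config.none_expressed_fraction * len(ids)))
    tiers = {}
    rest = perm[n_none:]
    third = len(rest) // 3
    for j, gi in enumerate(perm):
        if j < n_none:
            tiers[ids[gi]] = "none"
    for j, gi in enumerate(rest):
        tiers[ids[gi]] = _TIERS[1 + min(2, j // max(1, third))]
    return tiers


def _plant_dmrs(rng, config, genes, sites, region_mean=None,
                expressed_genes=None):
    """Choose non-overlapping planted DMR intervals (promoter/body/intergenic).

    Every planted interval must cover >= 3 cytosines of its context, and —
    when ``region_mean`` is supplied — have headroom for the full
    ``dmr_effect`` mean shift (regions already near saturation, e.g. TE
    bodies, cannot gain 0.3 in mean level and are re-drawn).
    """
    n_by_ctx = {
        ctx: int(round(config.dmr_context_proportions[ctx] * config.n_dmrs))
        for ctx in CONTEXTS
    }
    # rounding drift goes to CHH, the dominant context
    n_by_ctx["CHH"] += config.n_dmrs - sum(n_by_ctx.values())

    pos_by = {}
    for (chrom, ctx), sub in sites.groupby(["chrom", "context"], observed=True):
        pos_by[(chrom, ctx)] = sub["start"].to_numpy()

    placed = {c: [] for c in {g.body.chrom for g in genes} | set(pos_by_c[0] for pos_by_c in pos_by)}

    def conflicts(chrom, start, end):
        for s, e in placed.get(chrom, []):
            if start < e + config.dmr_min_separation and s < end + config.dmr_min_separation:
                return True
        return False

    lo, hi = config.dmr_length_range
    planted = []
    promoter_genes = {}
    n_promoter = int(round(config.dmr_promoter_fraction * config.n_dmrs))
    n_body = int(round(config.dmr_body_fraction * config.n_dmrs))
    placements = (["promoter"] * n_promoter + ["body"] * n_body
                  + ["intergenic"] * (config.n_dmrs - n_promoter - n_body))
    rng.shuffle(placements)
    contexts = [c for c in CONTEXTS for _ in range(n_by_ctx[c])]
    rng.shuffle(contexts)

    gene_pool = list(genes)
    chrom_names = sorted({g.body.chrom for g in genes}) or sorted(
        {k[0] for k in pos_by}
    )
    used_promoters = set()

    for placement, ctx in zip(placements, contexts):
        direction = "hyper" if rng.random() < config.hyper_fraction else "hypo"
        ok = False
        for _ in range(400):
            length = int(rng.integers(lo, hi + 1))
            if placement == "promoter" and gene_pool:
                g = gene_pool[int(rng.integers(len(gene_pool)))]
                if g.promoter is None or g.gene_id in used_promoters:
                    continue
                # promoter DMRs couple to expression; silent genes carry none
                if expressed_genes is not None and g.gene_id not in expressed_genes:
                    continue
                if g.promoter.length < length:
                    length = g.promoter.length
                start = int(rng.integers(g.promoter.start,
                                         g.promoter.end - length + 1))
                chrom = g.promoter.chrom
            elif placement == "body" and gene_pool:
                g = gene_pool[int(rng.integers(len(gene_pool)))]
                if g.body.length < length + 100:
                    continue
                start = int(rng.integers(g.body.start, g.body.end - length + 1))
                chrom = g.body.chrom
            else:
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                start = int(rng.integers(0, config.chrom_length - length))
            end = start + length
            if conflicts(chrom, start, end):
                continue
            pos = pos_by.get((chrom, ctx))
            if pos is None:
                continue
            n_sites = int(np.searchsorted(pos, end) - np.searchsorted(pos, start))
            if n_sites < 3:
                continue
            if region_mean is not None:
                if region_mean(chrom, start, end, ctx) + config.dmr_effect > 0.95:
                    continue
            placed.setdefault(chrom, []).append((start, end))
            planted.append(PlantedDmr(chrom, start, end, ctx, direction, placement))
            if placement == "promoter":
                used_promoters.add(g.gene_id)
                promoter_genes[g.gene_id] = 1 if direction == "hyper" else -1
            ok = True
            break
        if not ok:
            raise ValueError(
                "could not place all requested DMRs; genome too small or "
                "separation too strict"
            )
    return planted, promoter_genes


def simulate_methylomes(sequences, genes, tes, config: SimulationConfig,
                        te_links=None):
    """Simulate replicate cytosine reports for both groups plus the spike-in.

    Returns ``(reports, lambda_reports, truth)``; reports map sample name
    (e.g. "2X_1") to a site table.  Group 2 (4X) carries the planted hyper
    DMRs; hypo DMRs are regions where the diploid is elevated instead, so
    every planted DMR has the same absolute group difference regardless of
    the context baseline.
    """
    config.validate()
    rng = config.rng("methylome")
    sites = site_table(sequences)
    ctx_arr = sites["context"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["start"].to_numpy()

    # chromosome blocks are contiguous and position-sorted: index by slices
    chrom_ofs = {}
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        chrom_ofs[chrom] = (int(idx[0]), int(idx[-1]) + 1)

    def span(chrom, start, end):
        lo, hi = chrom_ofs[chrom]
        sub = pos_arr[lo:hi]
        return lo + np.searchsorted(sub, start), lo + np.searchsorted(sub, end)

    tiers = _assign_tiers(rng, genes, config)

    # per-site probability of being a methylated site
    pi = np.empty(len(sites))
    ctx_masks = {ctx: ctx_arr == ctx for ctx in CONTEXTS}
    beta_mean = {c: a / (a + b) for c, (a, b) in config.methylated_level_beta.items()}
    for ctx in CONTEXTS:
        pi[ctx_masks[ctx]] = config.baseline_levels[ctx] / beta_mean[ctx]
    # gene bodies: tier-dependent multiplier
    for g in genes:
        tier = tiers[g.gene_id]
        lo, hi = span(g.body.chrom, g.body.start, g.body.end)
        for ctx in CONTEXTS:
            sel = ctx_masks[ctx][lo:hi]
            pi[lo:hi][sel] *= config.tier_multipliers[ctx][tier]
    # TE bodies override (highly methylated in every context)
    for te in tes:
        lo, hi = span(te.body.chrom, te.body.start, te.body.end)
        for ctx in CONTEXTS:
            sel = ctx_masks[ctx][lo:hi]
            pi[lo:hi][sel] = config.te_methylated_fraction[ctx]
    np.clip(pi, 0.0, 1.0, out=pi)

    methylated = rng.random(len(sites)) < pi
    levels = np.zeros(len(sites))
    for ctx in CONTEXTS:
        a, b = config.methylated_level_beta[ctx]
        sel = methylated & ctx_masks[ctx]
        levels[sel] = rng.beta(a, b, size=int(sel.sum()))

    def region_mean(chrom, start, end, ctx):
        lo, hi = span(chrom, start, end)
        sel = np.flatnonzero(ctx_masks[ctx][lo:hi]) + lo
        return float(levels[sel].mean()) if len(sel) else 1.0

    planted, promoter_genes = ([], {})
    if config.n_dmrs > 0:
        expressed = {gid for gid, t in tiers.items() if t != "none"}
        planted, promoter_genes = _plant_dmrs(rng, config, genes, sites,
                                              region_mean, expressed)
    levels_g2 = levels.copy()
    levels_g1 = levels          # modified in place for hypo (2X-elevated) DMRs
    for d in planted:
        lo, hi = span(d.chrom, d.start, d.end)
        sel = np.flatnonzero(ctx_masks[d.context][lo:hi]) + lo
        target_arr = levels_g2 if d.direction == "hyper" else levels_g1
        _raise_region_mean(rng, target_arr, sel, config.dmr_effect,
                           config.methylated_level_beta[d.context])

    coupled = {}
    if promoter_genes:
        gene_ids = sorted(promoter_genes)
        take = rng.random(len(gene_ids)) < config.coupled_fraction
        for gid, t in zip(gene_ids, take):
            if t:
                coupled[gid] = (promoter_genes[gid], -promoter_genes[gid])

    truth = TruthSet(
        planted_dmrs=planted,
        te_gene_links=dict(te_links or {}),
        coupled_genes=coupled,
        gene_tiers=tiers,
        promoter_dmr_genes=promoter_genes,
    )
    if not truth.te_gene_links:
        truth.te_gene_links = _geometry_links(genes, tes, config.flank)

    reports = {}
    k = (1 - config.dispersion) / config.dispersion if config.dispersion > 0 else None
    for group, lv in zip(config.groups, (levels_g1, levels_g2)):
        p_success = lv + (1 - lv) * config.conversion_failure
        for rep in range(config.replicates_per_group):
            depth = rng.poisson(config.depth_mean, size=len(sites))
            if k is not None:
                interior = (p_success > 0) & (p_success < 1)
                p_rep = p_success.copy()
                p_rep[interior] = rng.beta(
                    p_success[interior] * k, (1 - p_success[interior]) * k
                )
            else:
                p_rep = p_success
            m = rng.binomial(depth, p_rep)
            df = sites.copy()
            df["count_m"] = m.astype(np.int64)
            df["count_u"] = (depth - m).astype(np.int64)
            reports[f"{group}_{rep + 1}"] = df
    lambda_reports = _simulate_lambda(rng, config)
    return reports, lambda_reports, truth


def _raise_region_mean(rng, levels_arr, sel, effect, beta_params):
    """Raise a region's mean level by ``effect`` in one group.

    Unmethylated sites are switched to the methylated state (levels drawn
    from the context's Beta distribution) until the regional mean reaches the
    target; any residual deficit is spread as a uniform clamped shift.  This
    realizes the full planted effect regardless of how methylated the region
    already is, mirroring how differential methylation mostly arises by
    gain/loss of methylated sites.
    """
    if effect <= 0 or len(sel) == 0:
        return
    cur = levels_arr[sel]
    target_sum = cur.sum() + effect * len(sel)
    unmeth = sel[cur == 0]
    order = rng.permutation(len(unmeth))
    a, b = beta_params
    draws = rng.beta(a, b, size=len(unmeth))
    total = cur.sum()
    converted = 0
    for j in order:
        if total >= target_sum:
            break
        levels_arr[unmeth[j]] = draws[j]
        total += draws[j]
        converted += 1
    if total < target_sum:
        deficit = (target_sum - total) / len(sel)
        levels_arr[sel] = np.clip(levels_arr[sel] + deficit, 0.0, 1.0)


def _geometry_links(genes, tes, flank):
    links = {}
    for g in genes:
        status = "none"
        for te in tes:
            if te.body.chrom != g.body.chrom:
                continue
            if te.body.start < g.body.end and g.body.start < te.body.end:
                status = "body"
                break
            if (te.body.start < g.body.end + flank
                    and g.body.start - flank < te.body.end):
                status = "flank"
        links[g.gene_id] = status
    return links


def _simulate_lambda(rng, config: SimulationConfig):
    """Unmethylated spike-in chromosome: every methylated read is a
    conversion failure."""
    seq = _random_sequence(rng, config.lambda_length, 0.50, 1.0, 1.0)
    lam_sites = site_table({"lambda": _seq_to_str(seq)})
    out = {}
    for name in config.sample_names():
        depth = rng.poisson(config.depth_mean, size=len(lam_sites))
        m = rng.binomial(depth, config.conversion_failure)
        df = lam_sites.copy()
        df["count_m"] = m.astype(np.int64)
        df["count_u"] = (depth - m).astype(np.int64)
        out[name] = df
    return out


# ---------------------------------------------------------------------------
# expression + DE tables
# ---------------------------------------------------------------------------


def simulate_expression(genes, truth: TruthSet, config: SimulationConfig):
    """FPKM and differential-expression tables coupled to the planted truth.

    Body-TE genes get a multiplicative penalty, flank-TE genes a boost;
    coupled genes shift expression in group 2 with the sign opposite to
    their promoter methylation change.  The DE table is constructed directly
    from the planted shifts (log2fc = shift + noise, small padj), because
    the differential-expression fit itself is an upstream tool whose output
    this pipeline consumes.
    """
    config.validate()
    rng = config.rng("expression")
    rows = []
    de_rows = []
    samples = {
        g: [f"{g}_{i + 1}" for i in range(config.replicates_per_group)]
        for g in config.groups
    }
    for g in genes:
        tier = truth.gene_tiers.get(g.gene_id, "medium")
        link = truth.te_gene_links.get(g.gene_id, "none")
        if tier == "none":
            for grp in config.groups:
                for s in samples[grp]:
                    rows.append((g.gene_id, s, grp, float(rng.uniform(0, 0.05))))
            de_rows.append((g.gene_id, 0.0, 1.0))
            continue
        base = config.tier_log2_fpkm[tier] + rng.normal(0, 0.5)
        if link == "body":
            base += np.log2(config.body_te_penalty)
        elif link == "flank":
            base += np.log2(config.flank_te_boost)
        shift = 0.0
        if g.gene_id in truth.coupled_genes:
            shift = truth.coupled_genes[g.gene_id][1] * config.coupling_log2fc
        group_mean = {config.groups[0]: base, config.groups[1]: base + shift}
        for grp in config.groups:
            for s in samples[grp]:
                x = group_mean[grp] + rng.normal(0, config.expression_rep_sd)
                rows.append((g.gene_id, s, grp, float(2.0 ** x)))
        if shift != 0.0:
            log2fc = shift + rng.normal(0, 0.2)
            padj = float(10 ** (-rng.uniform(2, 6)))
        else:
            log2fc = rng.normal(0, 0.15)
            padj = float(rng.uniform(0.1, 1.0))
        de_rows.append((g.gene_id, float(log2fc), padj))

    expr = pd.DataFrame(rows, columns=["gene_id", "sample", "group", "fpkm"])
    de = pd.DataFrame(de_rows, columns=["gene_id", "log2fc", "padj"])
    from .io_formats import de_status

    de["status"] = [de_status(fc, p) for fc, p in zip(de["log2fc"], de["padj"])]
    return expr, de


def simulate_term_map(genes, truth: TruthSet, config: SimulationConfig,
                      n_terms: int = 30):
    """Random gene->term map with one term enriched in the coupled genes."""
    rng = config.rng("terms")
    rows = []
    for g in genes:
        for t in rng.choice(n_terms, size=int(rng.integers(1, 5)), replace=False):
            rows.append((g.gene_id, f"T{t:03d}", f"term {t}"))
    for gid in sorted(truth.coupled_genes):
        rows.append((gid, "T900", "planted coupled-gene term"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"]).drop_duplicates()


def run_full_simulation(config: SimulationConfig) -> SimpleNamespace:
    """Convenience wrapper: genome -> methylomes -> expression in one call."""
    sequences, genes, tes, te_links = simulate_genome(config)
    reports, lambda_reports, truth = simulate_methylomes(
        sequences, genes, tes, config, te_links
    )
    expression, de = simulate_expression(genes, truth, config)
    term_map = simulate_term_map(genes, truth, config)
    return SimpleNamespace(
        config=config, sequences=sequences, genes=genes, tes=tes,
        reports=reports, lambda_reports=lambda_reports, truth=truth,
        expression=expression, de=de, term_map=term_map,
    )
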