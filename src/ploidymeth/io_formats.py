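"""Readers and writers for every external format the methylome pipeline touches.

One coordinate convention rules the package: 0-based half-open intervals on the
forward reference strand.  Converters live at the file boundary only — cytosine
reports and GFF3 arrive 1-based inclusive and are shifted on the way in, BED is
already 0-based half-open and passes through unchanged.

TSV dialect: UTF-8, tab-separated, ``##``-prefixed provenance lines, a single
``#``-prefixed column-header line.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")
CONTEXT_ALIASES = {"CPG": "CG", "CG": "CG", "CHG": "CHG", "CHH": "CHH"}
STRANDS = ("+", "-", ".")

#: Fixed transposable-element order -> class lookup.  Class I are
#: retrotransposons (copy-and-paste), class II DNA transposons (cut-and-paste).
ORDER_TO_CLASS = {
    "Copia": "I",
    "Gypsy": "I",
    "LINE": "I",
    "SINE": "I",
    "LTR": "I",
    "TIR": "II",
    "Helitron": "II",
    "MITE": "II",
    "hAT": "II",
    "Mutator": "II",
    "CACTA": "II",
}

REPORT_COLUMNS = ["chrom", "start", "strand", "context", "count_m", "count_u"]


class FormatError(ValueError):
    """Malformed external file (carries the offending line number if known)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; ``strand`` is '+', '-' or '.'."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CytosineRecord:
    """A single cytosine: width-1 interval plus context and read counts."""

    interval: GenomicInterval
    context: str
    count_m: int
    count_u: int

    def __post_init__(self):
        if self.interval.length != 1:
            raise ValueError("cytosine interval must have width 1")
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")
        if self.count_m < 0 or self.count_u < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def coverage(self) -> int:
        return self.count_m + self.count_u


@dataclass(frozen=True)
class GeneFeature:
    """A gene: stranded body (TSS..TES), exons, and derived promoter.

    The promoter abuts the TSS on the 5' side: for '+' genes it lies left of
    ``body.start``, for '-' genes right of ``body.end``.  It may be truncated
    (or empty, represented as ``None``) at chromosome bounds.
    """

    gene_id: str
    body: GenomicInterval
    exons: tuple = ()
    promoter: GenomicInterval | None = None

    def __post_init__(self):
        for ex in self.exons:
            if not (self.body.start <= ex.start and ex.end <= self.body.end):
                raise ValueError(
                    f"exon {ex} of {self.gene_id} not nested within body"
                )

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        """TSS as a reference coordinate (position of the first base)."""
        return self.body.start if self.strand == "+" else self.body.end - 1

    def introns(self):
        """Body minus merged exons, as plain (start, end) tuples."""
        from ._intervals import complement, merge_intervals

        merged = merge_intervals([(e.start, e.end) for e in self.exons])
        shifted = [(s - self.body.start, e - self.body.start) for s, e in merged]
        return [
            (s + self.body.start, e + self.body.start)
            for s, e in complement(shifted, self.body.length)
        ]


@dataclass(frozen=True)
class TeFeature:
    """A transposable element with order label and derived class (I or II)."""

    te_id: str
    body: GenomicInterval
    order: str
    te_class: str = ""

    def __post_init__(self):
        if not self.te_class:
            object.__setattr__(
                self, "te_class", te_class_for_order(self.order)
            )
        if self.te_class not in ("I", "II"):
            raise ValueError(f"bad TE class {self.te_class!r}")


def te_class_for_order(order: str) -> str:
    cls = ORDER_TO_CLASS.get(order)
    if cls is None:
        warnings.warn(f"unknown TE order {order!r}; assigning class I")
        cls = "I"
    return cls


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    sample: str
    group: str
    fpkm: float

    def __post_init__(self):
        if self.fpkm < 0:
            raise ValueError("FPKM must be non-negative")


@dataclass(frozen=True)
class DeRecord:
    gene_id: str
    log2fc: float
    padj: float
    status: str = field(default="")

    def __post_init__(self):
        if not (0 <= self.padj <= 1):
            raise ValueError("padj must lie in [0, 1]")
        if not self.status:
            object.__setattr__(self, "status", de_status(self.log2fc, self.padj))
        if self.status not in ("up", "down", "ns"):
            raise ValueError(f"bad DE status {self.status!r}")


def de_status(log2fc: float, padj: float, de_alpha: float = 0.05) -> str:
    if padj <= de_alpha and log2fc > 0:
        return "up"
    if padj <= de_alpha and log2fc < 0:
        return "down"
    return "ns"


# ---------------------------------------------------------------------------
# cytosine reports (Bismark CX-style dialect)
# ---------------------------------------------------------------------------


def _normalize_context(raw: pd.Series, path) -> pd.Series:
    ctx = raw.str.upper().map(CONTEXT_ALIASES)
    if ctx.isna().any():
        line = int(np.flatnonzero(ctx.isna().to_numpy())[0]) + 1
        raise FormatError(f"{path}: bad context {raw.iloc[line - 1]!r} at line {line}")
    return ctx


def read_cytosine_report(path, genome=None, on_context_mismatch: str = "warn"):
    """Read a Bismark-style cytosine report into a site table.

    Columns of the dialect: chrom, 1-based position, strand, methylated count,
    unmethylated count, context, trinucleotide (optional).  Returns a
    DataFrame with columns chrom, start (0-based), strand, context, count_m,
    count_u.  Zero-coverage sites are retained; coverage filtering belongs to
    the analysis stages.

    ``genome``: optional pyfaidx.Fasta (or path to FASTA).  When given, the
    context of each site is re-derived from the reference triplet and
    mismatches are reported (``on_context_mismatch``: "warn", "error" or
    "fix").
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            dtype={0: str, 2: str, 5: str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise _locate_bad_line(path) from exc
    if df.shape[1] < 6:
        raise FormatError(f"{path}: expected >= 6 columns")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "pos", "strand", "count_m", "count_u", "context"]
    for col in ("pos", "count_m", "count_u"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise _locate_bad_line(path)
    for col, ok in (("strand", df["strand"].isin(["+", "-"])),
                    ("pos", df["pos"] >= 1),
                    ("count_m", df["count_m"] >= 0),
                    ("count_u", df["count_u"] >= 0)):
        if not ok.all():
            line = int(np.flatnonzero(~ok.to_numpy())[0]) + 1
            raise FormatError(f"{path}: invalid {col} value at line {line}")
    df["context"] = _normalize_context(df["context"], path)
    # sortedness per chromosome, chromosomes in contiguous blocks
    chrom_codes, chrom_labels = pd.factorize(df["chrom"])
    if (np.diff(chrom_codes) < 0).any():
        raise FormatError(f"{path}: chromosome blocks are not contiguous")
    pos = df["pos"].to_numpy()
    same = np.diff(chrom_codes) == 0
    if (np.diff(pos)[same] <= 0).any():
        raise FormatError(f"{path}: positions not sorted within a chromosome")
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": pos - 1,
            "strand": df["strand"],
            "context": df["context"],
            "count_m": df["count_m"].astype(np.int64),
            "count_u": df["count_u"].astype(np.int64),
        }
    )
    if genome is not None:
        _check_contexts(out, genome, on_context_mismatch, path)
    return out


def _locate_bad_line(path) -> FormatError:
    """Scan for the first malformed line to report a line number."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                return FormatError(f"{path}: expected >= 6 columns at line {i}")
            try:
                int(parts[1]), int(parts[3]), int(parts[4])
            except ValueError:
                return FormatError(f"{path}: non-integer field at line {i}")
    return FormatError(f"{path}: malformed cytosine report")


def derive_context(seq: str, start: int, strand: str) -> str | None:
    """Context of the cytosine at 0-based ``start`` from its reference triplet.

    Returns None when the triplet runs off the sequence end.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    if strand == "+":
        if start + 2 >= n:
            return None
        if seq[start + 1] == "G":
            return "CG"
        if seq[start + 2] == "G":
            return "CHG"
        return "CHH"
    if start - 2 < 0:
        return None
    nxt = comp.get(seq[start - 1], "N")
    nxt2 = comp.get(seq[start - 2], "N")
    if nxt == "G":
        return "CG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def _check_contexts(df, genome, action, path):
    import pyfaidx

    if not isinstance(genome, pyfaidx.Fasta):
        genome = pyfaidx.Fasta(str(genome))
    mismatches = 0
    fixed = df["context"].to_numpy(copy=True)
    for chrom, sub in df.groupby("chrom", sort=False):
        seq = str(genome[chrom][:]).upper()
        for idx, start, strand, ctx in zip(
            sub.index, sub["start"], sub["strand"], sub["context"]
        ):
            derived = derive_context(seq, int(start), strand)
            if derived is not None and derived != ctx:
                mismatches += 1
                fixed[idx] = derived
    if mismatches:
        msg = f"{path}: {mismatches} context labels disagree with the reference"
        if action == "error":
            raise FormatError(msg)
        warnings.warn(msg)
        if action == "fix":
            df["context"] = fixed


def iter_cytosine_report(path, genome=None):
    """Stream CytosineRecord objects from a report file."""
    df = read_cytosine_report(path, genome=genome)
    for row in df.itertuples(index=False):
        yield CytosineRecord(
            GenomicInterval(row.chrom, row.start, row.start + 1, row.strand),
            row.context,
            int(row.count_m),
            int(row.count_u),
        )


def write_cytosine_report(df, path, header: str | None = None):
    """Write a site table back to the 1-based report dialect."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"] + 1,
            "strand": df["strand"],
            "count_m": df["count_m"],
            "count_u": df["count_u"],
            "context": df["context"],
        }
    )
    with open(path, "w") as fh:
        if header:
            fh.write(f"## {header}\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene / TE annotations
# ---------------------------------------------------------------------------


def make_promoter(body: GenomicInterval, promoter_length: int,
                  chrom_length: int | None = None) -> GenomicInterval | None:
    """Strand-aware promoter: the ``promoter_length`` bases 5' of the TSS.

    '+' genes: [TSS - L, TSS); '-' genes: [TES_coord, TES_coord + L) in
    reference coordinates.  Truncated at chromosome bounds; fully
    off-chromosome promoters yield None with a warning.
    """
    if body.strand == "+":
        start, end = body.start - promoter_length, body.start
        start = max(0, start)
    elif body.strand == "-":
        start, end = body.end, body.end + promoter_length
        if chrom_length is not None:
            end = min(chrom_length, end)
    else:
        raise FormatError(f"gene on {body.chrom} has no strand")
    if start >= end:
        warnings.warn(
            f"promoter of gene at {body.chrom}:{body.start} falls entirely "
            "off the chromosome; using zero-width promoter"
        )
        return None
    return GenomicInterval(body.chrom, start, end, body.strand)


def read_gene_annotation(path, promoter_length: int = 2000,
                         chrom_sizes: dict | None = None):
    """Read genes (GFF3 or BED12) into GeneFeature objects with promoters."""
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _read_bed12_genes(path, promoter_length, chrom_sizes)
    return _read_gff3_genes(path, promoter_length, chrom_sizes)


def _read_gff3_genes(path, promoter_length, chrom_sizes):
    from gffutils.iterators import DataIterator

    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    deferred_exons = []
    for feat in DataIterator(path):
        ftype = feat.featuretype
        if ftype == "gene":
            gid = feat.attributes.get("ID", [f"{feat.seqid}:{feat.start}"])[0]
            if feat.strand not in ("+", "-"):
                raise FormatError(f"{path}: gene {gid} has no strand")
            genes[gid] = {
                "body": GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                                        feat.strand),
                "exons": [],
            }
        elif ftype in ("mRNA", "transcript"):
            tid = feat.attributes.get("ID", [None])[0]
            parent = feat.attributes.get("Parent", [None])[0]
            if tid and parent:
                tx_parent[tid] = parent
        elif ftype == "exon":
            parent = feat.attributes.get("Parent", [None])[0]
            deferred_exons.append(
                (parent, GenomicInterval(feat.seqid, feat.start - 1, feat.end,
                                         feat.strand))
            )
    for parent, iv in deferred_exons:
        gid = tx_parent.get(parent, parent)
        if gid in genes:
            genes[gid]["exons"].append(iv)
    return _assemble_genes(genes, promoter_length, chrom_sizes)


def _read_bed12_genes(path, promoter_length, chrom_sizes):
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: expected >= 6 BED columns at line {i}")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: gene {name} has no strand (line {i})")
            body = GenomicInterval(chrom, start, end, strand)
            exons = []
            if len(parts) >= 12:
                sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
                offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
                for sz, off in zip(sizes, offsets):
                    exons.append(
                        GenomicInterval(chrom, start + off, start + off + sz, strand)
                    )
            genes[name] = {"body": body, "exons": exons}
    return _assemble_genes(genes, promoter_length, chrom_sizes)


def _assemble_genes(genes, promoter_length, chrom_sizes):
    out = []
    for gid, rec in genes.items():
        body = rec["body"]
        exons = rec["exons"] or [body]
        size = (chrom_sizes or {}).get(body.chrom)
        promoter = make_promoter(body, promoter_length, size)
        out.append(GeneFeature(gid, body, tuple(sorted(exons, key=lambda e: e.start)),
                               promoter))
    out.sort(key=lambda g: (g.body.chrom, g.body.start))
    return out


def read_te_annotation(path):
    """Read a TE BED (chrom, start, end, te_id, score, strand, order[, class])."""
    tes = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise FormatError(f"{path}: expected >= 7 columns at line {i}")
            body = GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                   parts[5] if parts[5] in STRANDS else ".")
            cls = parts[7] if len(parts) > 7 else ""
            tes.append(TeFeature(parts[3], body, parts[6], cls))
    return tes


def write_te_bed(tes, path, header: str | None = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"## {header}\n")
        for te in tes:
            fh.write(
                "\t".join(
                    [te.body.chrom, str(te.body.start), str(te.body.end),
                     te.te_id, "0", te.body.strand, te.order, te.te_class]
                )
                + "\n"
            )


def write_gff3(genes, path, header: str | None = None):
    """Write GeneFeature objects as GFF3 (gene + exon records)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header:
            fh.write(f"## {header}\n")
        for g in genes:
            b = g.body
            fh.write(
                f"{b.chrom}\tploidymeth\tgene\t{b.start + 1}\t{b.end}\t.\t"
                f"{b.strand}\t.\tID={g.gene_id}\n"
            )
            for k, ex in enumerate(g.exons, start=1):
                fh.write(
                    f"{ex.chrom}\tploidymeth\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\tID={g.gene_id}.exon{k};Parent={g.gene_id}\n"
                )


def write_fasta(sequences: dict, path, line_width: int = 70):
    """Write {name: sequence} to FASTA."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# DMR BED
# ---------------------------------------------------------------------------

_DMR_BED_COLUMNS = [
    "chrom", "start", "end", "context", "score", "strand",
    "n_sites", "n_sig_sites", "mean_2x", "mean_4x", "direction",
]


def write_dmr_bed(dmrs, path, header: str | None = None):
    """Write DMRs as BED6+ (name=context, score=1000*|level diff| clamped).

    Extra columns: n_sites, n_sig_sites, mean_2x, mean_4x, direction.  Floats
    are written with 17 significant digits so a write -> read round trip is
    lossless.
    """
    with open(path, "w") as fh:
        if header:
            fh.write(f"## {header}\n")
        fh.write("#" + "\t".join(_DMR_BED_COLUMNS) + "\n")
        for d in dmrs:
            score = int(min(1000, round(1000 * abs(d.mean_level_g2 - d.mean_level_g1))))
            fh.write(
                "\t".join(
                    [
                        d.chrom, str(d.start), str(d.end), d.context, str(score),
                        ".", str(d.n_sites), str(d.n_sig_sites),
                        format(d.mean_level_g1, ".17g"),
                        format(d.mean_level_g2, ".17g"),
                        d.direction,
                    ]
                )
                + "\n"
            )


def read_dmr_bed(path):
    """Read a DMR BED written by :func:`write_dmr_bed`."""
    from .dmr_calling import Dmr

    dmrs = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_DMR_BED_COLUMNS):
                raise FormatError(f"{path}: expected {len(_DMR_BED_COLUMNS)} "
                                  f"columns at line {i}")
            dmrs.append(
                Dmr(
                    chrom=parts[0], start=int(parts[1]), end=int(parts[2]),
                    context=parts[3], n_sites=int(parts[6]),
                    n_sig_sites=int(parts[7]),
                    mean_level_g1=float(parts[8]), mean_level_g2=float(parts[9]),
                    direction=parts[10],
                )
            )
    return dmrs


# ---------------------------------------------------------------------------
# plain TSV tables (expression, DE, term map)
# ---------------------------------------------------------------------------


def _read_headed_tsv(path, required: tuple) -> pd.DataFrame:
    lines = []
    header = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if header is None:
                if not line.startswith("#"):
                    raise FormatError(f"{path}: missing '#'-prefixed header line")
                header = line[1:].rstrip("\n").split("\t")
                continue
            lines.append(line)
    if header is None:
        raise FormatError(f"{path}: empty table")
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", names=header)
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_headed_tsv(df, path, header: str | None = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"## {header}\n")
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format="%.6g")


def read_expression_table(path) -> pd.DataFrame:
    """Long-format FPKM table: gene_id, sample, group, fpkm."""
    df = _read_headed_tsv(path, ("gene_id", "sample", "group", "fpkm"))
    if (df["fpkm"] < 0).any():
        raise FormatError(f"{path}: negative FPKM")
    return df


def read_de_table(path, de_alpha: float = 0.05) -> pd.DataFrame:
    """Differential-expression table: gene_id, log2fc, padj (+derived status)."""
    df = _read_headed_tsv(path, ("gene_id", "log2fc", "padj"))
    if ((df["padj"] < 0) | (df["padj"] > 1)).any():
        raise FormatError(f"{path}: padj outside [0, 1]")
    df["status"] = [
        de_status(fc, p, de_alpha) for fc, p in zip(df["log2fc"], df["padj"])
    ]
    return df


def read_term_map(path) -> pd.DataFrame:
    """Gene -> term annotation table: gene_id, term_id[, term_name]."""
    df = _read_headed_tsv(path, ("gene_id", "term_id"))
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    return df
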