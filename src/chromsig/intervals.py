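"""Genomic interval and peak handling.

Per-sample peak calls are modelled as sorted collections of half-open
0-based intervals (BED convention throughout; GTF input is converted on
read). The module builds consensus peak sets across samples ("found in
at least k samples"), annotates peaks against gene models
(promoter/exon/intron/downstream/distal, CEAS-like midpoint scheme),
tests per-chromosome enrichment of a peak group against a background
with a one-sided binomial test, computes RPKM, and assigns peaks to
proximal target genes (gene body or a strand-oriented window upstream
of the TSS, 20 kb by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import binomial_upper_tail

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneModel",
    "GenomeLayout",
    "AnnotationParams",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_bed12_genes",
    "read_gtf_genes",
    "consensus_peaks",
    "annotate_peak",
    "genomic_distribution",
    "chromosome_enrichment",
    "rpkm_matrix",
    "assign_peaks_to_genes",
]

CATEGORIES = ("promoter", "exon", "intron", "downstream", "distal_intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic region [start, end) on ``chrom``; 0-based."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError("score must be nonnegative")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class PeakSet:
    """Sorted, deduplicated peak calls for one sample (or a consensus)."""

    sample_id: str
    intervals: list[GenomicInterval]

    def __post_init__(self):
        uniq = {(iv.chrom, iv.start, iv.end): iv for iv in self.intervals}
        self.intervals = sorted(
            uniq.values(), key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
            }
        )


@dataclass
class GeneModel:
    """A gene body with strand and optional exon structure.

    TSS is ``tx_start`` on '+' and ``tx_end`` on '-' (half-open
    convention: the upstream window of a '-' gene extends to higher
    coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"tx_start < tx_end violated for {self.gene_id}")
        self.exons = sorted(self.exons)
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(
                    f"exons of {self.gene_id} must be non-overlapping and "
                    "inside the gene body"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass
class GenomeLayout:
    """Chromosome name -> length (bp)."""

    chrom_sizes: dict[str, int]

    def __post_init__(self):
        for c, n in self.chrom_sizes.items():
            if n <= 0:
                raise ValueError(f"chromosome {c} has nonpositive length {n}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())


@dataclass
class AnnotationParams:
    """Windows for peak annotation and target-gene assignment.

    promoter_upstream_bp/promoter_downstream_bp define the strand-
    oriented promoter window around the TSS; downstream_bp the region
    past the 3' end still labelled "downstream"; upstream_window_bp the
    proximity window for target-gene assignment.
    """

    promoter_upstream_bp: int = 3000
    promoter_downstream_bp: int = 0
    downstream_bp: int = 3000
    upstream_window_bp: int = 20000
    precedence: tuple[str, ...] = ("promoter", "exon", "intron", "downstream")

    def __post_init__(self):
        for name in (
            "promoter_upstream_bp",
            "promoter_downstream_bp",
            "downstream_bp",
            "upstream_window_bp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class BedParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# I/O


def read_bed(path, sample_id: str | None = None) -> PeakSet:
    """Read a BED3+ file into a sorted :class:`PeakSet`.

    Column 5 (if present and numeric) populates the interval score.
    Malformed records raise :class:`BedParseError` naming the line.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            try:
                intervals.append(GenomicInterval(chrom, start, end, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(sample_id or path.stem, intervals)


def write_bed(peakset: PeakSet, path, *, score_in_col5: bool = True) -> None:
    """Write a PeakSet as BED (name column = sample id, score column 5)."""
    with open(path, "w") as fh:
        for iv in peakset:
            score = iv.score if (score_in_col5 and iv.score is not None) else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peakset.sample_id}\t{score:g}\n"
            )


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column <chrom>\\t<length> TSV."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected two columns")
            sizes[parts[0]] = int(parts[1])
    return GenomeLayout(sizes)


def read_bed12_genes(path) -> list[GeneModel]:
    """Read gene models from a BED12 file (blocks become exons)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise BedParseError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def read_gtf_genes(path) -> list[GeneModel]:
    """Read gene models from a GTF (exon features grouped by gene_id).

    GTF 1-based inclusive coordinates are converted to 0-based
    half-open on read.
    """
    import re

    gid_re = re.compile(r'gene_id\s+"([^"]+)"')
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            m = gid_re.search(f[8])
            if not m:
                raise BedParseError(f"GTF exon record without gene_id: {line!r}")
            exons.setdefault(m.group(1), []).append(
                (f[0], f[6], int(f[3]) - 1, int(f[4]))
            )
    genes = []
    for gid, recs in sorted(exons.items()):
        chrom, strand = recs[0][0], recs[0][1]
        starts = [r[2] for r in recs]
        ends = [r[3] for r in recs]
        merged = _merge_plain(sorted(zip(starts, ends)))
        genes.append(GeneModel(gid, chrom, strand, min(starts), max(ends), merged))
    return genes


def _merge_plain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in pairs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Consensus


def consensus_peaks(
    peaksets: Sequence[PeakSet], min_samples: int
) -> PeakSet:
    """Merge peak calls across samples and keep regions seen in >= k samples.

    The union of all peaks is merged by single-linkage overlap (>= 1 bp;
    bookended intervals are not merged) into disjoint regions; the
    occupancy of a merged region is the number of distinct samples with
    at least one original peak overlapping it, stored in the score
    column. Regions with occupancy >= ``min_samples`` are returned
    sorted. k larger than the number of samples yields an empty result.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if not peaksets:
        raise ValueError("peaksets must be nonempty")
    rows = []
    for si, ps in enumerate(peaksets):
        for iv in ps:
            rows.append((iv.chrom, iv.start, iv.end, si))
    out: list[GenomicInterval] = []
    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample"])
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values(["start", "end"], kind="stable")
            cur_s = cur_e = None
            members: set[int] = set()
            for s, e, si in zip(sub["start"], sub["end"], sub["sample"]):
                if cur_s is None:
                    cur_s, cur_e, members = s, e, {si}
                elif s < cur_e:  # >= 1 bp overlap with the growing region
                    cur_e = max(cur_e, e)
                    members.add(si)
                else:
                    occ = len(members)
                    if occ >= min_samples:
                        out.append(GenomicInterval(chrom, cur_s, cur_e, occ))
                    cur_s, cur_e, members = s, e, {si}
            if cur_s is not None:
                occ = len(members)
                if occ >= min_samples:
                    out.append(GenomicInterval(chrom, cur_s, cur_e, occ))
    return PeakSet(f"consensus_ge{min_samples}", out)


# ---------------------------------------------------------------------------
# Annotation


def _promoter_window(gene: GeneModel, params: AnnotationParams) -> tuple[int, int]:
    if gene.strand == "+":
        return (
            gene.tss - params.promoter_upstream_bp,
            gene.tss + params.promoter_downstream_bp,
        )
    return (
        gene.tss - params.promoter_downstream_bp,
        gene.tss + params.promoter_upstream_bp,
    )


def _downstream_window(gene: GeneModel, params: AnnotationParams) -> tuple[int, int]:
    if gene.strand == "+":
        return (gene.tx_end, gene.tx_end + params.downstream_bp)
    return (gene.tx_start - params.downstream_bp, gene.tx_start)


def annotate_peak(
    interval: GenomicInterval,
    gene_models: Sequence[GeneModel],
    params: AnnotationParams | None = None,
) -> str:
    """Assign a peak's midpoint to exactly one genomic category.

    Precedence: promoter > exon > intron > downstream > distal
    intergenic. A chromosome absent from the gene models yields
    ``distal_intergenic``.
    """
    if not gene_models:
        raise ValueError("gene_models must be nonempty")
    params = params or AnnotationParams()
    mid = interval.midpoint
    hit = {cat: False for cat in CATEGORIES}
    for gene in gene_models:
        if gene.chrom != interval.chrom:
            continue
        lo, hi = _promoter_window(gene, params)
        if lo <= mid < hi:
            hit["promoter"] = True
        if gene.tx_start <= mid < gene.tx_end:
            in_exon = any(s <= mid < e for s, e in gene.exons)
            hit["exon" if in_exon else "intron"] = True
        lo, hi = _downstream_window(gene, params)
        if lo <= mid < hi:
            hit["downstream"] = True
    for cat in params.precedence:
        if hit[cat]:
            return cat
    return "distal_intergenic"


def genomic_distribution(
    peakset: PeakSet,
    gene_models: Sequence[GeneModel],
    params: AnnotationParams | None = None,
) -> dict[str, float]:
    """Fraction of peaks per genomic category (fractions sum to 1)."""
    if len(peakset) == 0:
        raise ValueError("peakset must be nonempty")
    counts = {cat: 0 for cat in CATEGORIES}
    for iv in peakset:
        counts[annotate_peak(iv, gene_models, params)] += 1
    n = len(peakset)
    return {cat: c / n for cat, c in counts.items()}


# ---------------------------------------------------------------------------
# Chromosome enrichment


def chromosome_enrichment(
    group_peaks: PeakSet,
    background_peaks: PeakSet | None = None,
    genome: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Per-chromosome one-sided binomial enrichment of a peak group.

    For each chromosome, p = P(X >= k) with X ~ Binomial(n, p0), where
    n is the total number of group peaks, k the group count on the
    chromosome and p0 the background fraction — from
    ``background_peaks`` (default: the consensus set the group was
    drawn from) or, if ``genome`` is given instead, the chromosome's
    genome-length fraction. A chromosome with group peaks but zero
    background peaks gets p0 floored at 1/(|background|+1) and is
    flagged.
    """
    if len(group_peaks) == 0:
        raise ValueError("group_peaks must be nonempty")
    if (background_peaks is None) == (genome is None):
        raise ValueError("provide exactly one of background_peaks or genome")
    n = len(group_peaks)
    group_counts: dict[str, int] = {}
    for iv in group_peaks:
        group_counts[iv.chrom] = group_counts.get(iv.chrom, 0) + 1
    if background_peaks is not None:
        if len(background_peaks) == 0:
            raise ValueError("background_peaks must be nonempty")
        bg_counts: dict[str, int] = {}
        for iv in background_peaks:
            bg_counts[iv.chrom] = bg_counts.get(iv.chrom, 0) + 1
        bg_total = len(background_peaks)
        chroms = sorted(set(group_counts) | set(bg_counts))
        p0s = {c: bg_counts.get(c, 0) / bg_total for c in chroms}
        floor = 1.0 / (bg_total + 1)
    else:
        chroms = sorted(set(group_counts) | set(genome.chrom_sizes))
        total = genome.total_length
        p0s = {c: genome.chrom_sizes.get(c, 0) / total for c in chroms}
        floor = min(genome.chrom_sizes.values()) / total / 10.0
    rows = []
    for c in chroms:
        k = group_counts.get(c, 0)
        p0 = p0s[c]
        flagged = False
        if p0 <= 0.0:
            if k == 0:
                continue
            p0 = floor
            flagged = True
        p0 = min(p0, 1.0 - 1e-12)
        p = binomial_upper_tail(k, n, p0)
        rows.append((c, k, n, p0, p, flagged))
    return pd.DataFrame(
        rows, columns=["chrom", "k", "n", "p0", "p_value", "flagged"]
    ).set_index("chrom")


# ---------------------------------------------------------------------------
# RPKM


def rpkm_matrix(count_matrix, peak_lengths, library_sizes):
    """RPKM[i, j] = count[i, j] / (length_i/1e3) / (libsize_j/1e6)."""
    counts = np.asarray(count_matrix, dtype=float)
    lengths = np.asarray(peak_lengths, dtype=float)
    libs = np.asarray(library_sizes, dtype=float)
    if counts.ndim != 2 or counts.shape != (lengths.size, libs.size):
        raise ValueError(
            f"dimension mismatch: counts {counts.shape}, "
            f"{lengths.size} lengths, {libs.size} library sizes"
        )
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if (lengths <= 0).any() or (libs <= 0).any():
        raise ValueError("lengths and library sizes must be positive")
    return counts / (lengths[:, None] / 1e3) / (libs[None, :] / 1e6)


# ---------------------------------------------------------------------------
# Target genes


def _target_window(gene: GeneModel, params: AnnotationParams) -> tuple[int, int]:
    """Gene body extended by the upstream window on the TSS side."""
    if gene.strand == "+":
        return (gene.tx_start - params.upstream_window_bp, gene.tx_end)
    return (gene.tx_start, gene.tx_end + params.upstream_window_bp)


def assign_peaks_to_genes(
    peaks: PeakSet | Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    params: AnnotationParams | None = None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Map peaks to proximal genes and return the induced gene list.

    A peak is assigned to a gene iff it overlaps (>= 1 bp) the gene
    body [tx_start, tx_end) or the strand-oriented window of
    ``upstream_window_bp`` ending at the TSS. Many peaks may map to one
    gene and one peak to many genes; the returned gene list is
    deduplicated and sorted.
    """
    params = params or AnnotationParams()
    ivs = list(peaks)
    mapping: dict[str, list[str]] = {}
    genes: set[str] = set()
    for iv in ivs:
        hits = []
        for gene in gene_models:
            if gene.chrom != iv.chrom:
                continue
            lo, hi = _target_window(gene, params)
            if iv.start < hi and lo < iv.end:
                hits.append(gene.gene_id)
        mapping[iv.key()] = sorted(hits)
        genes.update(hits)
    return mapping, sorted(genes)
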