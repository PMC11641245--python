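"""Direct-target triage from ChIP peaks over intronic/intergenic territories.

Cardiac cis-regulatory modules are typically clusters of binding sites for
several heart-development transcription factors, located in the introns of
the regulated gene or in the intergenic regions immediately flanking it.
A candidate gene is therefore triaged as a *likely direct target* of the
focal TF (Jumu) when, inside its search territory — introns plus the two
intergenic intervals bounded by the nearest neighboring genes — a focal-TF
ChIP peak is clustered with a peak for at least one partner cardiogenic TF
(Myb, Tin, Tup, Twi, Su(H), Pnt, Mad or Hand).  A gene whose territory has
no focal-TF peak at all is called indirectly regulated.

Coordinates are 0-based half-open throughout (BED convention); GFF3 input
(1-based inclusive) is converted on read.  "Clustered" means the gap between
two peaks is at most ``max_gap`` bases (overlapping peaks have gap 0); the
default ``max_gap=0`` requires overlap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_TFS",
    "FOCAL_TF",
    "GenomicInterval",
    "PeakRecord",
    "GeneModel",
    "TriageCall",
    "gene_territory",
    "clustered",
    "classify_direct_target",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_gene_models_bed12",
    "read_gene_models_gff3",
]

logger = logging.getLogger(__name__)

#: Cardiogenic TFs whose embryonic ChIP peaks are scanned.
FOCAL_TF = "Jumu"
DEFAULT_TFS = ("Jumu", "Myb", "Tin", "Tup", "Twi", "Su(H)", "Pnt", "Mad", "Hand")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bases between the intervals; 0 if they overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class PeakRecord:
    interval: GenomicInterval
    tf: str


@dataclass(frozen=True)
class GeneModel:
    """Gene span with (optionally) its exon structure."""

    name: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        prev_end = self.span.start
        for ex in self.exons:
            if ex.chrom != self.span.chrom:
                raise ValueError("exon on a different chromosome than the gene span")
            if ex.start < prev_end and prev_end != self.span.start:
                raise ValueError("exons must be sorted and non-overlapping")
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValueError("exon outside gene span")
            prev_end = ex.end

    def introns(self) -> list[GenomicInterval]:
        """Gene span minus exons.

        Without exon structure the whole gene body is returned as a
        conservative stand-in for the introns (with a warning).
        """
        if not self.exons:
            warnings.warn(
                f"gene {self.name}: no exon structure; using the whole gene body "
                "as the intronic territory",
                stacklevel=2,
            )
            return [self.span]
        out = []
        cursor = self.span.start
        for ex in self.exons:
            if ex.start > cursor:
                out.append(GenomicInterval(self.span.chrom, cursor, ex.start))
            cursor = max(cursor, ex.end)
        if cursor < self.span.end:
            out.append(GenomicInterval(self.span.chrom, cursor, self.span.end))
        return out


@dataclass(frozen=True)
class TriageCall:
    gene: str
    status: str  # direct | jumu_only | no_jumu_peak
    supporting_tfs: tuple[str, ...] = ()
    evidence: tuple[tuple[PeakRecord, PeakRecord, int], ...] = ()
    best_gap: int | None = None


def gene_territory(
    gene: GeneModel,
    upstream_neighbor: GeneModel | None = None,
    downstream_neighbor: GeneModel | None = None,
) -> list[GenomicInterval]:
    """Intronic + flanking-intergenic search territory of a gene.

    The territory is the union of the gene's introns, the interval between
    the end of the upstream neighbor and the gene start, and the interval
    between the gene end and the start of the downstream neighbor.  Strand
    is ignored; "upstream" means lower coordinates.  Zero-length intergenic
    gaps (abutting neighbors) contribute nothing.
    """
    chrom = gene.span.chrom
    territory: list[GenomicInterval] = []
    if upstream_neighbor is not None:
        nb = upstream_neighbor.span
        if nb.chrom != chrom:
            raise ValueError("upstream neighbor on a different chromosome")
        if nb.end > gene.span.start:
            raise ValueError("upstream neighbor overlaps or is on the wrong side of the gene")
        if nb.end < gene.span.start:
            territory.append(GenomicInterval(chrom, nb.end, gene.span.start))
    territory.extend(gene.introns())
    if downstream_neighbor is not None:
        nb = downstream_neighbor.span
        if nb.chrom != chrom:
            raise ValueError("downstream neighbor on a different chromosome")
        if nb.start < gene.span.end:
            raise ValueError("downstream neighbor overlaps or is on the wrong side of the gene")
        if nb.start > gene.span.end:
            territory.append(GenomicInterval(chrom, gene.span.end, nb.start))
    return sorted(territory)


def clustered(peak_a: GenomicInterval, peak_b: GenomicInterval, max_gap: int = 0) -> bool:
    """Whether two peaks form a cluster: gap between them at most ``max_gap``."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    return peak_a.gap_to(peak_b) <= max_gap


def classify_direct_target(
    territory: Sequence[GenomicInterval],
    peaks: Iterable[PeakRecord],
    max_gap: int = 0,
    gene: str = "",
    focal_tf: str = FOCAL_TF,
) -> TriageCall:
    """Triage one gene from the peaks intersecting its territory.

    Peaks partially overlapping a territory interval count as inside.
    Status is ``no_jumu_peak`` if the territory contains no focal-TF peak,
    ``direct`` if a focal-TF peak is clustered (gap <= max_gap) with at
    least one partner-TF peak, and ``jumu_only`` otherwise.
    """
    territory = list(territory)
    if not territory:
        raise ValueError("empty territory")
    inside = [
        p for p in peaks if any(p.interval.overlaps(t) for t in territory)
    ]
    focal = [p for p in inside if p.tf == focal_tf]
    partners = [p for p in inside if p.tf != focal_tf]
    if not focal:
        return TriageCall(gene=gene, status="no_jumu_peak")
    evidence = []
    best: int | None = None
    for f in focal:
        for q in partners:
            gap = f.interval.gap_to(q.interval)
            best = gap if best is None else min(best, gap)
            if gap <= max_gap:
                evidence.append((f, q, gap))
    if evidence:
        tfs = tuple(sorted({q.tf for _, q, _ in evidence}))
        return TriageCall(
            gene=gene,
            status="direct",
            supporting_tfs=tfs,
            evidence=tuple(evidence),
            best_gap=min(g for *_, g in evidence),
        )
    return TriageCall(gene=gene, status="jumu_only", best_gap=best)


# ---------------------------------------------------------------------------
# BED / GFF3 I/O


def read_peaks_bed(path: str | Path, tf: str | None = None) -> list[PeakRecord]:
    """Read ChIP peaks from a BED file.

    If ``tf`` is given it labels every peak (per-TF files); otherwise the
    BED name column (4th) carries the TF label (pooled file).
    """
    rows = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    peaks = []
    for row in rows.itertuples(index=False):
        label = tf if tf is not None else str(row[3])
        strand = str(row[5]) if len(row) > 5 and str(row[5]) in "+-" else None
        peaks.append(
            PeakRecord(
                interval=GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand),
                tf=label,
            )
        )
    return peaks


def write_peaks_bed(peaks: Sequence[PeakRecord], path: str | Path) -> None:
    """Write peaks as BED6 (name column = TF, score 0)."""
    with open(path, "w") as fh:
        for p in peaks:
            strand = p.interval.strand or "."
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.tf}\t0\t{strand}\n"
            )


def read_gene_models_bed12(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (blocks = exons)."""
    rows = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    genes = []
    for row in rows.itertuples(index=False):
        chrom, start, end, name = str(row[0]), int(row[1]), int(row[2]), str(row[3])
        strand = str(row[5]) if str(row[5]) in "+-" else None
        span = GenomicInterval(chrom, start, end, strand)
        sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row[11]).rstrip(",").split(",")]
        exons = tuple(
            GenomicInterval(chrom, start + off, start + off + size, strand)
            for off, size in zip(offsets, sizes)
        )
        genes.append(GeneModel(name=name, span=span, exons=exons))
    return genes


def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from GFF3, converting to 0-based."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        name = g.attributes.get("Name", [g.id])[0]
        span = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand if g.strand in "+-" else None)
        exon_ivs: set[tuple[int, int]] = set()
        for ex in db.children(g, featuretype="exon"):
            exon_ivs.add((ex.start - 1, ex.end))
        merged: list[GenomicInterval] = []
        for s, e in sorted(exon_ivs):
            if merged and s <= merged[-1].end:
                last = merged.pop()
                merged.append(GenomicInterval(span.chrom, last.start, max(last.end, e)))
            else:
                merged.append(GenomicInterval(span.chrom, s, e))
        genes.append(GeneModel(name=name, span=span, exons=tuple(merged)))
    return genes
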