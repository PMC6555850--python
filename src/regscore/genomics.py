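"""Genomic interval data model: peaks, gene models, promoter/distal annotation.

Coordinates are 0-based half-open everywhere (BED native).  A peak's
reference point for all TSS distances is its midpoint, ``(start + end) // 2``
(fractional midpoints floored).  Promoters are the strand-agnostic window
``[tss - 3000, tss + 3000)``; distal means a midpoint more than 3 kb but at
most 1 Mb from the nearest TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

PROMOTER_BP = 3000
DISTAL_MAX_BP = 1_000_000


class BedFormatError(ValueError):
    """Raised for malformed BED records; carries the 1-based line number."""


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its strand-aware transcription start site."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tss: int  # 0-based

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


@dataclass(frozen=True)
class Peak:
    """Accessible-chromatin interval with signal (RPKM) and significance."""

    chrom: str
    start: int  # inclusive
    end: int  # exclusive
    signal_rpkm: float = 0.0
    q_value: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"q_value must be in [0, 1], got {self.q_value}")
        if self.signal_rpkm < 0:
            raise ValueError(f"signal_rpkm must be >= 0, got {self.signal_rpkm}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PeakAnnotation:
    """Category of a peak relative to the gene annotation."""

    peak: Peak
    category: str  # 'promoter' | 'distal' | 'other'
    gene_id: str | None
    distance_to_tss: int | None  # signed bp, upstream negative


class PeakSet:
    """Sorted, non-overlapping collection of peaks on one genome.

    Overlapping input peaks are merged on construction (interval union;
    merged signal is the maximum, merged q-value the minimum), matching
    post-merge peak-caller output.
    """

    def __init__(self, peaks: Iterable[Peak], label: str = ""):
        self.label = label
        self.peaks: list[Peak] = _merge(sorted(peaks, key=lambda p: (p.chrom, p.start)))
        # per-chrom coordinate arrays for fast overlap queries
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[Peak]] = {}
        for p in self.peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        for chrom, ps in by_chrom.items():
            self._index[chrom] = (
                np.array([p.start for p in ps]),
                np.array([p.end for p in ps]),
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares >= 1 bp with any peak on chrom."""
        if chrom not in self._index:
            return False
        starts, ends = self._index[chrom]
        # peaks are disjoint and sorted: the only candidate is the first
        # peak whose end exceeds `start`
        i = int(np.searchsorted(ends, start, side="right"))
        return i < len(starts) and starts[i] < end


def _merge(sorted_peaks: list[Peak]) -> list[Peak]:
    merged: list[Peak] = []
    for p in sorted_peaks:
        if merged and p.chrom == merged[-1].chrom and p.start < merged[-1].end:
            q = merged[-1]
            merged[-1] = Peak(
                chrom=q.chrom,
                start=q.start,
                end=max(q.end, p.end),
                signal_rpkm=max(q.signal_rpkm, p.signal_rpkm),
                q_value=min(q.q_value, p.q_value),
                name=q.name or p.name,
            )
        else:
            merged.append(p)
    return merged


# ---------------------------------------------------------------------------
# I/O


def read_bed(path, q_threshold: float = 0.05, label: str = "") -> PeakSet:
    """Read a BED6+2 peak file, keeping peaks with q_value < q_threshold.

    Columns: chrom, start, end, name, score, strand, signal_rpkm, q_value.
    Malformed lines raise :class:`BedFormatError` naming the line.
    """
    peaks: list[Peak] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise BedFormatError(
                    f"{path}:{lineno}: expected 8 tab-separated columns "
                    f"(BED6 + signal_rpkm + q_value), got {len(fields)}"
                )
            try:
                peak = Peak(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    signal_rpkm=float(fields[6]),
                    q_value=float(fields[7]),
                )
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
            if peak.q_value < q_threshold:
                peaks.append(peak)
            else:
                dropped += 1
    log.info("read_bed(%s): kept %d peaks, dropped %d at q >= %g",
             path, len(peaks), dropped, q_threshold)
    return PeakSet(peaks, label=label or str(path))


def write_bed(peakset: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peakset):
            name = p.name or f"peak_{i:05d}"
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t.\t"
                f"{p.signal_rpkm:.6g}\t{p.q_value:.6g}\n"
            )


def read_gene_annotation(path) -> list[GeneModel]:
    """Read a gene annotation TSV: gene_id, chrom, strand, tss (0-based)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (lineno == 1 and line.startswith("gene_id")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            gene = GeneModel(fields[0], fields[1], fields[2], int(fields[3]))
            if gene.gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene.gene_id}")
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def write_gene_annotation(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


# ---------------------------------------------------------------------------
# Interval operations


def call_enriched_peaks(target: PeakSet, references: Sequence[PeakSet]) -> PeakSet:
    """Target peaks absent (no >= 1 bp overlap) from every reference set.

    This is the presence/absence definition of cell-type-enriched
    accessible regions: open in the target cell type, closed in all
    reference cell types.
    """
    kept = [
        p
        for p in target
        if not any(ref.overlaps(p.chrom, p.start, p.end) for ref in references)
    ]
    log.info("call_enriched_peaks: %d of %d target peaks enriched "
             "(vs %d reference sets)", len(kept), len(target), len(references))
    return PeakSet(kept, label=f"{target.label}.enriched")


def _signed_distance(gene: GeneModel, midpoint: int) -> int:
    """TSS -> midpoint distance, negative upstream of the gene."""
    d = midpoint - gene.tss
    return d if gene.strand == "+" else -d


def annotate_peaks(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    promoter_bp: int = PROMOTER_BP,
    distal_max_bp: int = DISTAL_MAX_BP,
) -> list[PeakAnnotation]:
    """Classify each peak as promoter / distal / other relative to TSSs.

    A peak is a promoter peak iff it overlaps [tss - promoter_bp,
    tss + promoter_bp) of some gene; it is assigned to the gene with the
    nearest TSS (midpoint distance; ties broken by gene_id).  Otherwise it
    is distal iff its midpoint lies within (promoter_bp, distal_max_bp] of
    the nearest TSS.  Peaks on chromosomes absent from the annotation are
    'other' (with a warning).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[PeakAnnotation] = []
    warned: set[str] = set()
    for p in peaks:
        cands = by_chrom.get(p.chrom)
        if not cands:
            if p.chrom not in warned:
                log.warning("annotate_peaks: chromosome %r not in annotation", p.chrom)
                warned.add(p.chrom)
            out.append(PeakAnnotation(p, "other", None, None))
            continue
        mid = p.midpoint
        # nearest TSS by midpoint distance, tie-broken lexicographically
        nearest = min(cands, key=lambda g: (abs(mid - g.tss), g.gene_id))
        promoter_genes = [
            g for g in cands
            if p.start < g.tss + promoter_bp and g.tss - promoter_bp < p.end
        ]
        if promoter_genes:
            g = min(promoter_genes, key=lambda g: (abs(mid - g.tss), g.gene_id))
            out.append(PeakAnnotation(p, "promoter", g.gene_id, _signed_distance(g, mid)))
        elif promoter_bp < abs(mid - nearest.tss) <= distal_max_bp:
            out.append(
                PeakAnnotation(p, "distal", nearest.gene_id, _signed_distance(nearest, mid))
            )
        else:
            out.append(
                PeakAnnotation(p, "other", nearest.gene_id, _signed_distance(nearest, mid))
            )
    return out


def distal_window(
    gene: GeneModel,
    peaks: PeakSet,
    promoter_bp: int = PROMOTER_BP,
    distal_max_bp: int = DISTAL_MAX_BP,
) -> list[tuple[Peak, int]]:
    """Peaks whose midpoint is within (promoter_bp, distal_max_bp] of the TSS.

    Distances are returned unsigned, ready for exponential-decay scoring.
    """
    out: list[tuple[Peak, int]] = []
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        d = abs(p.midpoint - gene.tss)
        if promoter_bp < d <= distal_max_bp:
            out.append((p, d))
    return out


def write_annotations(annots: Sequence[PeakAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcategory\tgene_id\tdistance_to_tss\n")
        for a in annots:
            gid = a.gene_id if a.gene_id is not None else "."
            dist = a.distance_to_tss if a.distance_to_tss is not None else "."
            fh.write(f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t"
                     f"{a.category}\t{gid}\t{dist}\n")
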