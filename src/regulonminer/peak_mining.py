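"""Candidate-selection cascade for ChIP peaks.

Stages: enrichment/p-value threshold filter -> intersection with intergenic
regions -> sigma-54 orientation filter (the element must face a downstream
ORF on the same strand within a bounded distance of its ATG) -> +/-100 bp
fragment extension.  Each stage is an independently testable function;
:func:`mine_candidates` chains them and reports survivor counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

from intervaltree import IntervalTree

from .config import PipelineConfig
from .core_io import (
    GeneAnnotation,
    GenomicInterval,
    GenomicSequence,
    Peak,
    revcomp,
)
from .motif_scan import SigmaPromoterHit, find_sigma54

logger = logging.getLogger("regulonminer")


@dataclass(frozen=True)
class CandidateFragment:
    """An extended peak fragment facing a gene through a sigma-54 element."""

    fragment: GenomicInterval
    source_peak: Peak
    intergenic_hits: tuple[GenomicInterval, ...]
    facing_gene: GeneAnnotation
    sigma_center_genomic: float      # fractional genomic centre of the element
    sigma_to_atg: float              # bp from element centre to the ATG (>0)


def filter_peaks(
    peaks: Sequence[Peak], min_enrichment: float = 2.0, max_p: float = 1e-10
) -> list[Peak]:
    """Retain peaks with enrichment >= ``min_enrichment`` AND p < ``max_p``.

    The enrichment comparison is inclusive ("at least 2-fold") and the
    p-value comparison strict; input order is preserved.
    """
    if min_enrichment <= 0 or max_p <= 0:
        raise ValueError("thresholds must be positive")
    return [p for p in peaks if p.enrichment >= min_enrichment and p.p_value < max_p]


def intersect_intergenic(
    peaks: Sequence[Peak], intergenic: Sequence[GenomicInterval]
) -> list[tuple[Peak, tuple[GenomicInterval, ...]]]:
    """Peaks overlapping (by >= 1 bp) at least one intergenic interval.

    Every overlapping interval is listed per peak, sorted by start.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intergenic:
        trees.setdefault(iv.seq_id, IntervalTree()).addi(iv.start, iv.end, iv)
    out: list[tuple[Peak, tuple[GenomicInterval, ...]]] = []
    for peak in peaks:
        tree = trees.get(peak.interval.seq_id)
        if tree is None:
            continue
        hits = sorted(
            (node.data for node in tree.overlap(peak.interval.start, peak.interval.end)),
            key=lambda iv: iv.start,
        )
        if hits:
            out.append((peak, tuple(hits)))
    return out


def extend_fragment(
    interval: GenomicInterval, extension: int, genome: GenomicSequence
) -> GenomicInterval:
    """Widen an interval by ``extension`` bp on each side, clipped to the genome."""
    if extension < 0:
        raise ValueError("extension must be >= 0")
    start = max(0, interval.start - extension)
    end = min(len(genome), interval.end + extension)
    if interval.start - extension < 0 or interval.end + extension > len(genome):
        logger.debug(
            "fragment %s:%d-%d clipped at sequence bounds",
            interval.seq_id,
            interval.start,
            interval.end,
        )
    return GenomicInterval(interval.seq_id, start, end, interval.strand)


def orient_filter(
    peaks_with_intergenic: Sequence[tuple[Peak, tuple[GenomicInterval, ...]]],
    genes: Sequence[GeneAnnotation],
    genome: GenomicSequence,
    scan_fn: Callable[[str], list[SigmaPromoterHit]] | None = None,
    max_promoter_to_atg: int = 500,
    extension: int = 100,
) -> list[CandidateFragment]:
    """Keep fragments whose sigma-54 element faces a downstream ORF.

    A fragment qualifies for a gene when it contains at least one sigma-54
    element on the gene's strand whose centre lies upstream of -- and within
    ``max_promoter_to_atg`` bp of -- the gene's start codon.  A fragment
    between divergent genes may yield one candidate per direction; the
    element nearest each ATG is recorded.
    """
    if scan_fn is None:
        scan_fn = find_sigma54

    candidates: list[CandidateFragment] = []
    for peak, intergenic_hits in peaks_with_intergenic:
        frag = extend_fragment(peak.interval, extension, genome)
        fseq = genome.residues[frag.start : frag.end]
        plus_centers = [frag.start + h.center for h in scan_fn(fseq)]
        minus_centers = [frag.end - 1 - h.center for h in scan_fn(revcomp(fseq))]
        for gene in genes:
            if gene.interval.seq_id != frag.seq_id:
                continue
            atg = gene.atg_position
            if gene.interval.strand == "+":
                dists = [atg - c for c in plus_centers if 0 < atg - c <= max_promoter_to_atg]
            else:
                dists = [c - atg for c in minus_centers if 0 < c - atg <= max_promoter_to_atg]
            if not dists:
                continue
            best = min(dists)
            center = atg - best if gene.interval.strand == "+" else atg + best
            candidates.append(
                CandidateFragment(
                    fragment=frag,
                    source_peak=peak,
                    intergenic_hits=intergenic_hits,
                    facing_gene=gene,
                    sigma_center_genomic=center,
                    sigma_to_atg=best,
                )
            )
    candidates.sort(
        key=lambda c: (c.fragment.seq_id, c.fragment.start, c.facing_gene.gene_id)
    )
    return candidates


def mine_candidates(
    genome: GenomicSequence,
    genes: Sequence[GeneAnnotation],
    peaks: Sequence[Peak],
    intergenic: Sequence[GenomicInterval],
    config: PipelineConfig | None = None,
) -> tuple[list[CandidateFragment], dict[str, int]]:
    """Run the full cascade; returns candidates and per-stage survivor counts."""
    cfg = config or PipelineConfig()

    def sigma_scan(seq: str) -> list[SigmaPromoterHit]:
        return find_sigma54(seq, anchor_mm=cfg.sigma54_anchor_mm)

    passed = filter_peaks(peaks, cfg.min_enrichment, cfg.max_p)
    with_intergenic = intersect_intergenic(passed, intergenic)
    candidates = orient_filter(
        with_intergenic,
        genes,
        genome,
        scan_fn=sigma_scan,
        max_promoter_to_atg=cfg.max_promoter_to_atg,
        extension=cfg.extension,
    )
    counts = {
        "total_peaks": len(peaks),
        "pass_threshold": len(passed),
        "with_intergenic": len(with_intergenic),
        "oriented_candidates": len(candidates),
    }
    logger.info(
        "peak funnel: %(total_peaks)d total -> %(pass_threshold)d pass thresholds -> "
        "%(with_intergenic)d with intergenic -> %(oriented_candidates)d oriented",
        counts,
    )
    return candidates, counts
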