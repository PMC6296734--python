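"""ATG-relative promoter-architecture assembly and in-silico mutagenesis.

A promoter fragment is analysed in the coding orientation of its downstream
gene (genomic minus-strand genes are reverse-complemented on extraction).
Positions are reported relative to the start codon: position -1 is the base
immediately 5' of the A of ATG; fractional motif centres are rounded half
away from zero for reporting only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import PipelineConfig
from .core_io import GeneAnnotation, GenomicSequence, ValidationError, revcomp
from .motif_scan import (
    CompositeSite,
    IHFHit,
    SigmaPromoterHit,
    SubsiteHit,
    assemble_composites,
    composite_score,
    find_ihf,
    find_sigma54,
    find_subsites,
)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (-126.5 -> -127)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def atg_relative_center(center: float, atg_offset: int) -> float:
    """ATG-relative coordinate of a fractional centre (negative = upstream)."""
    return center - atg_offset


def atg_relative_position(pos: int, atg_offset: int) -> int:
    """ATG-relative coordinate of an integer base position.

    The base immediately 5' of the ATG is -1; the A of ATG is +1 (there is
    no position 0).
    """
    return pos - atg_offset if pos < atg_offset else pos - atg_offset + 1


def fragment_position(rel: int, atg_offset: int) -> int:
    """Inverse of :func:`atg_relative_position` (bijection on base positions)."""
    return rel + atg_offset if rel < 0 else rel + atg_offset - 1


@dataclass(frozen=True)
class SubstitutionSpec:
    """A 6-bp replacement applied at a subsite locus on the analysed strand."""

    target_start: int
    replacement: str

    def __post_init__(self) -> None:
        if len(self.replacement) != 6 or set(self.replacement.upper()) - set("ACGT"):
            raise ValidationError(
                f"replacement {self.replacement!r} must be a 6-mer over ACGT"
            )


@dataclass
class PromoterArchitecture:
    """The assembled promoter picture for one gene, in ATG-relative terms."""

    gene_id: str
    atg_offset: int
    sigma: SigmaPromoterHit | None = None
    sigma_rel_center: int | None = None
    ihf: IHFHit | None = None
    ihf_rel_span: tuple[int, int] | None = None
    composite: CompositeSite | None = None
    composite_rel_centers: tuple[int, ...] = ()
    orphans: tuple[SubsiteHit, ...] = ()
    orphan_rel_centers: tuple[int, ...] = ()
    composite_to_sigma_distance: float | None = None
    warnings: tuple[str, ...] = ()


def extract_promoter(
    genome: GenomicSequence, gene: GeneAnnotation, upstream: int = 500
) -> tuple[str, int]:
    """Upstream region plus start codon, oriented so the ORF reads left->right.

    Returns ``(sequence, atg_offset)`` where ``atg_offset`` is the index of
    the A of the start codon within the returned sequence.
    """
    iv = gene.interval
    if iv.strand == "+":
        start = max(0, iv.start - upstream)
        seq = genome.residues[start : iv.start + 3]
        return seq, iv.start - start
    end = min(len(genome), iv.end + upstream)
    region = genome.residues[iv.end - 3 : end]
    seq = revcomp(region)
    return seq, len(region) - 3


def annotate_promoter(
    seq: str,
    atg_offset: int,
    config: PipelineConfig | None = None,
    gene_id: str = "",
) -> PromoterArchitecture:
    """Scan a promoter fragment and assemble its architecture.

    The sigma-54 element is the hit nearest the ATG within
    ``max_promoter_to_atg``; the composite is the best-scoring subsite chain
    whose downstream-most subsite centre lies ``sigma_to_uas_min``..
    ``sigma_to_uas_max`` bp upstream of the chosen element's centre.  Perfect
    subsites outside the chosen composite (such as a distal F' copy) are
    reported as orphans.
    """
    cfg = config or PipelineConfig()
    if not 0 <= atg_offset <= len(seq):
        raise ValidationError(f"atg_offset {atg_offset} outside fragment")
    warnings: list[str] = []

    arch = PromoterArchitecture(gene_id=gene_id, atg_offset=atg_offset)

    sigma_hits = [
        h
        for h in find_sigma54(seq, anchor_mm=cfg.sigma54_anchor_mm)
        if 0 < atg_offset - h.center <= cfg.max_promoter_to_atg
    ]
    if sigma_hits:
        sigma = max(sigma_hits, key=lambda h: h.center)  # nearest the ATG
        arch.sigma = sigma
        arch.sigma_rel_center = round_half_away(
            atg_relative_center(sigma.center, atg_offset)
        )
    else:
        warnings.append("no sigma-54 element found upstream of the ATG")

    subsites = find_subsites(
        seq, cfg.per_site_mm, motif_f=cfg.motif_f, motif_r=cfg.motif_r
    )
    composites = assemble_composites(
        subsites,
        min_sites=cfg.min_sites,
        spacing=(cfg.spacing_min, cfg.spacing_max),
        budget=cfg.mismatch_budget,
        phase_period=cfg.phase_period,
        phase_tol=cfg.phase_tol,
    )

    chosen: CompositeSite | None = None
    if arch.sigma is not None:
        eligible = []
        for comp in composites:
            nearest = max(s.center for s in comp.subsites)
            dist = arch.sigma.center - nearest
            if cfg.sigma_to_uas_min <= dist <= cfg.sigma_to_uas_max:
                eligible.append((comp, dist))
        if eligible:
            chosen, dist = max(
                eligible,
                key=lambda cd: (
                    composite_score(cd[0], cfg.mismatch_budget),
                    -cd[0].start,
                ),
            )
            arch.composite = chosen
            arch.composite_rel_centers = tuple(
                round_half_away(atg_relative_center(s.center, atg_offset))
                for s in chosen.subsites
            )
            arch.composite_to_sigma_distance = dist

    # IHF: nearest hit upstream of the sigma-54 element (between UAS and
    # promoter when a composite is present)
    ihf_hits = find_ihf(seq, cfg.ihf_consensus, cfg.ihf_max_mm)
    if arch.sigma is not None:
        region_hits = [h for h in ihf_hits if h.center < arch.sigma.center]
        if chosen is not None:
            downstream_of_uas = [
                h for h in region_hits if h.center > max(s.center for s in chosen.subsites)
            ]
            region_hits = downstream_of_uas or region_hits
        if region_hits:
            ihf = max(region_hits, key=lambda h: h.center)
            arch.ihf = ihf
            arch.ihf_rel_span = (
                atg_relative_position(ihf.start, atg_offset),
                atg_relative_position(ihf.end - 1, atg_offset),
            )

    in_composite = set()
    if chosen is not None:
        in_composite = {(s.kind, s.start) for s in chosen.subsites}
    orphans = tuple(
        s
        for s in subsites
        if s.mismatches == 0 and (s.kind, s.start) not in in_composite
    )
    arch.orphans = orphans
    arch.orphan_rel_centers = tuple(
        round_half_away(atg_relative_center(s.center, atg_offset)) for s in orphans
    )
    arch.warnings = tuple(warnings)
    return arch


def mutate_subsite(seq: str, spec: SubstitutionSpec) -> str:
    """Replace the 6 bp at ``spec.target_start`` with ``spec.replacement``.

    Length and all other positions are preserved; applying the inverse
    substitution restores the original sequence exactly.
    """
    start = spec.target_start
    if not 0 <= start <= len(seq) - 6:
        raise ValidationError(f"substitution start {start} outside sequence")
    return seq[:start] + spec.replacement.upper() + seq[start + 6 :]


def architecture_report(arch: PromoterArchitecture) -> str:
    """Deterministic, byte-stable text rendering of an architecture."""
    lines = [f"# gene\t{arch.gene_id or '-'}"]
    if arch.sigma is not None:
        lines.append(
            f"sigma54\tcenter\t{arch.sigma_rel_center}\tanchor_mm\t{arch.sigma.anchor_mismatches}"
        )
    if arch.ihf is not None and arch.ihf_rel_span is not None:
        lines.append(
            f"ihf\tspan\t{arch.ihf_rel_span[0]}\t{arch.ihf_rel_span[1]}\tmm\t{arch.ihf.mismatches}"
        )
    if arch.composite is not None:
        for site, rel in zip(arch.composite.subsites, arch.composite_rel_centers):
            lines.append(
                f"subsite\t{site.kind}\tcenter\t{rel}\tmm\t{site.mismatches}\tobs\t{site.observed}"
            )
        if arch.composite.spacings:
            joined = "\t".join(f"{d:.1f}" for d in arch.composite.spacings)
            lines.append(f"spacing\t{joined}")
        if arch.composite_to_sigma_distance is not None:
            lines.append(
                f"uas_to_sigma\t{arch.composite_to_sigma_distance:.1f}"
            )
    for orphan, rel in zip(arch.orphans, arch.orphan_rel_centers):
        lines.append(f"orphan\t{orphan.kind}\tcenter\t{rel}")
    for w in arch.warnings:
        lines.append(f"warning\t{w}")
    return "\n".join(lines) + "\n"
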