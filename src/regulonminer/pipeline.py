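"""End-to-end mining: candidate cascade plus promoter-architecture annotation.

A gene becomes a *predicted target* when a filtered, intergenic,
sigma-54-oriented peak faces it AND its promoter carries a composite subsite
chain in the configured window upstream of the chosen sigma-54 element.  The
composite requirement is what rejects loci whose subsites have the wrong
spacing; the earlier stages reject weak peaks and wrongly oriented elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .core_io import GeneAnnotation, GenomicSequence, Peak, intergenic_regions
from .peak_mining import CandidateFragment, mine_candidates
from .promoter_annotation import (
    PromoterArchitecture,
    annotate_promoter,
    extract_promoter,
)


@dataclass
class MiningResult:
    candidates: list[CandidateFragment]
    architectures: dict[str, PromoterArchitecture]   # keyed by facing gene id
    predicted_targets: list[str]                     # genes with a composite
    stage_counts: dict[str, int] = field(default_factory=dict)


def run_mine(
    genome: GenomicSequence,
    genes: list[GeneAnnotation],
    peaks: list[Peak],
    config: PipelineConfig | None = None,
) -> MiningResult:
    """Run the complete cascade and annotate every oriented candidate."""
    cfg = config or PipelineConfig()
    intergenic = intergenic_regions(genes, genome)
    candidates, counts = mine_candidates(genome, genes, peaks, intergenic, cfg)

    architectures: dict[str, PromoterArchitecture] = {}
    for cand in candidates:
        gid = cand.facing_gene.gene_id
        if gid in architectures:
            continue
        seq, atg_offset = extract_promoter(genome, cand.facing_gene, cfg.upstream_window)
        architectures[gid] = annotate_promoter(seq, atg_offset, cfg, gene_id=gid)

    predicted = sorted(
        gid for gid, arch in architectures.items() if arch.composite is not None
    )
    counts["with_composite"] = len(predicted)
    return MiningResult(
        candidates=candidates,
        architectures=architectures,
        predicted_targets=predicted,
        stage_counts=counts,
    )


def candidate_table(result: MiningResult) -> pd.DataFrame:
    """Candidate report with 1-based fragment coordinates."""
    rows = []
    for cand in result.candidates:
        start1, end1 = cand.fragment.to_1based()
        gid = cand.facing_gene.gene_id
        arch = result.architectures.get(gid)
        rows.append(
            {
                "seq_id": cand.fragment.seq_id,
                "fragment_start": start1,
                "fragment_end": end1,
                "enrichment": round(cand.source_peak.enrichment, 3),
                "p_value": f"{cand.source_peak.p_value:.3g}",
                "facing_gene": gid,
                "category": cand.facing_gene.category,
                "sigma54_position": int(round(cand.sigma_center_genomic)) + 1,
                "sigma54_to_atg": round(cand.sigma_to_atg, 1),
                "has_composite": arch is not None and arch.composite is not None,
                "n_subsites": (
                    arch.composite.n_subsites
                    if arch is not None and arch.composite is not None
                    else 0
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id",
            "fragment_start",
            "fragment_end",
            "enrichment",
            "p_value",
            "facing_gene",
            "category",
            "sigma54_position",
            "sigma54_to_atg",
            "has_composite",
            "n_subsites",
        ],
    )
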