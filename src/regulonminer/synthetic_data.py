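"""Seeded generator of genomes with planted promoter architectures.

The generator produces everything the pipeline consumes -- a bacterial-like
genome with annotated ORFs, planted promoter architectures (F/R subsite
chains at 20-25 bp centre spacing, a GG-N10-GC sigma-54 element centred at
-127, an IHF site upstream), simulated ChIP peaks and replicate expression
values -- together with a planting ledger that fully determines the expected
pipeline output.  Everything is a pure function of (config, seed).

Background cleanliness
----------------------
Hexamer subsites within 1-2 mismatches occur recurrently in random DNA, and
a bare GG-N10-GC screen fires about once per 256 bp per strand.  On a truly
i.i.d. background no mining pipeline could achieve exact ledger recovery, so
after drawing the background the generator *scrubs* it: chance sigma-54
anchor pairs (both strands), subsite hits within 1 mismatch genome-wide
(within 2 mismatches inside planted promoter regions) and chance IHF
consensus hits are destroyed by minimal base edits that respect the target
GC content.  Planted elements are protected.  The resulting genomes are
deliberately cleaner than real ones; see docs/methods.md for what this does
and does not demonstrate.

Decoy classes make each filter's rejection behaviour individually testable:

``decoy_orientation``
    full architecture planted element-wise reverse-complemented, so the
    sigma-54 element faces away from the ORF (rejected by the orientation
    filter);
``decoy_spacing``
    subsites planted 30 bp apart (no composite can assemble);
``decoy_subthreshold``
    correct architecture but a sub-threshold peak (rejected by the
    enrichment/p filter).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .config import PipelineConfig
from .core_io import (
    GeneAnnotation,
    GenomicInterval,
    GenomicSequence,
    Peak,
    revcomp,
    write_fasta,
    write_gff3,
    write_peaks_tsv,
)
from .motif_scan import scan_hexamer, find_ihf
from .promoter_annotation import round_half_away

_BASES = np.array(list("ACGT"))

_SIGMA_FWD_ANCHORS = {0: "G", 1: "G", 12: "G", 13: "C"}
_SIGMA_REV_ANCHORS = {0: "G", 1: "C", 12: "C", 13: "C"}  # revcomp of GG-N10-GC


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic datasets."""

    genome_length: int = 100_000
    n_genes: int = 50
    gc: float = 0.5
    gene_length: tuple[int, int] = (600, 1000)
    gap_length: tuple[int, int] = (500, 800)

    n_targets: int = 8
    n_decoy_orientation: int = 3
    n_decoy_spacing: int = 3
    n_decoy_subthreshold: int = 3
    n_background_peaks: int = 12

    # peak simulation: lognormal fold enrichment (median ~3, matching the
    # 2.1-7.5 range of real CbrB peaks) with a floor comfortably above the
    # 2-fold screening threshold at true loci
    enrichment_median: float = 3.0
    enrichment_sigma: float = 0.2
    enrichment_floor: float = 2.2
    target_log10p: tuple[float, float] = (-30.0, -12.0)
    decoy_spacing_value: int = 30

    # expression simulation
    expression_cv: float = 0.2
    n_reps: int = 9

    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


@dataclass
class PlantSpec:
    """How to plant one promoter architecture."""

    label: str = "target"
    n_subsites: int = 3
    spacings: tuple[int, ...] | None = None       # centre-to-centre, bp
    total_mismatches: int | None = None           # 0..2, drawn if None
    sigma_center_rel: int = -127
    ihf_region_rel: tuple[int, int] = (-189, -165)
    uas_anchor_center_rel: float = -240.5         # downstream-most subsite centre
    orphan_f_prime: bool = False


@dataclass
class PlantedLocus:
    """Ledger entry: the ground truth for one planted promoter."""

    gene_id: str
    label: str
    strand: str
    atg_genomic: int
    sigma_rel_center: int
    subsite_kinds: tuple[str, ...]
    subsite_rel_centers: tuple[int, ...]
    subsite_mismatches: tuple[int, ...]
    spacings: tuple[int, ...]
    ihf_rel_span: tuple[int, int]
    orphan_rel_center: int | None
    span_genomic: tuple[int, int]
    peak_enrichment: float | None = None
    peak_p: float | None = None


@dataclass
class PlantingLedger:
    loci: list[PlantedLocus] = field(default_factory=list)

    def by_label(self, label: str) -> list[PlantedLocus]:
        return [l for l in self.loci if l.label == label]

    @property
    def target_gene_ids(self) -> set[str]:
        return {l.gene_id for l in self.by_label("target")}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump([dataclasses.asdict(l) for l in self.loci], fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantingLedger":
        with open(path) as fh:
            raw = json.load(fh)
        loci = []
        for entry in raw:
            for key in (
                "subsite_kinds",
                "subsite_rel_centers",
                "subsite_mismatches",
                "spacings",
            ):
                entry[key] = tuple(entry[key])
            entry["ihf_rel_span"] = tuple(entry["ihf_rel_span"])
            entry["span_genomic"] = tuple(entry["span_genomic"])
            loci.append(PlantedLocus(**entry))
        return cls(loci)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def make_genome(
    length: int,
    gc: float = 0.5,
    n_genes: int = 50,
    seed: int | None = None,
    gene_length: tuple[int, int] = (600, 1000),
    gap_length: tuple[int, int] = (500, 800),
    seq_id: str = "chr",
    rng: np.random.Generator | None = None,
    strand_persistence: float = 0.7,
) -> tuple[GenomicSequence, list[GeneAnnotation]]:
    """i.i.d. background with non-overlapping genes on both strands.

    Every gene starts with ATG on its strand (written as CAT on the plus
    strand for minus-strand genes).  Consecutive genes share a strand with
    probability ``strand_persistence`` (bacterial genomes are organised in
    co-oriented runs).  Deterministic for a fixed seed.  Raises when the
    requested genes cannot be packed into ``length``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_genes * (gene_length[1] + gap_length[1]) > length:
        raise ValueError(
            f"infeasible packing: {n_genes} genes of up to {gene_length[1]} bp "
            f"with gaps up to {gap_length[1]} bp cannot fit in {length} bp"
        )
    arr = rng.choice(_BASES, size=length, p=_base_probs(gc))
    genes: list[GeneAnnotation] = []
    pos = 0
    strand = "+" if rng.random() < 0.5 else "-"
    for i in range(n_genes):
        gap = int(rng.integers(gap_length[0], gap_length[1] + 1))
        glen = int(rng.integers(gene_length[0], gene_length[1] + 1))
        start, end = pos + gap, pos + gap + glen
        if i > 0 and rng.random() >= strand_persistence:
            strand = "+" if strand == "-" else "-"
        if strand == "+":
            arr[start : start + 3] = list("ATG")
        else:
            arr[end - 3 : end] = list("CAT")
        genes.append(
            GeneAnnotation(
                gene_id=f"gene{i + 1:03d}",
                interval=GenomicInterval(seq_id, start, end, strand),
            )
        )
        pos = end
    return GenomicSequence(id=seq_id, residues="".join(arr)), genes


def _start_codon_mask(genes: list[GeneAnnotation], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for g in genes:
        iv = g.interval
        if iv.strand == "+":
            mask[iv.start : iv.start + 3] = True
        else:
            mask[iv.end - 3 : iv.end] = True
    return mask


# ---------------------------------------------------------------------------
# background scrubbing
# ---------------------------------------------------------------------------

def _anchor_hits(seq: str, anchors: dict[int, str], length: int, max_mm: int) -> list[int]:
    """Starts of windows whose anchor positions match within ``max_mm``."""
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    if arr.size < length:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, length)
    mm = np.zeros(windows.shape[0], dtype=np.int64)
    for pos, base in anchors.items():
        mm += windows[:, pos] != base.encode("ascii")
    return [int(s) for s in np.nonzero(mm <= max_mm)[0]]


def scrub_background(
    arr: np.ndarray,
    rng: np.random.Generator,
    gc: float = 0.5,
    protected: np.ndarray | None = None,
    allowed_subsites: set[int] | frozenset[int] = frozenset(),
    allowed_sigma: set | frozenset = frozenset(),
    allowed_ihf: set | frozenset = frozenset(),
    strict_mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    max_iter: int = 100,
) -> int:
    """Destroy chance motif hits in-place; returns the number of edits.

    Removes sigma-54 anchor pairs on both strands, F/R subsite hits within 1
    mismatch genome-wide (within 2 mismatches wherever ``strict_mask`` is
    true at the window start) and IHF consensus hits on both strands, except
    windows registered as planted (``allowed_*``; sigma/IHF keys are
    ``(strand, plus_strand_window_start)``).  Edits never touch ``protected``
    positions; replacement bases are drawn from the GC-weighted distribution
    restricted to bases that actually break the match.
    """
    cfg = config or PipelineConfig()
    n = arr.size
    if protected is None:
        protected = np.zeros(n, dtype=bool)
    probs_full = _base_probs(gc)
    edits = 0
    ihf_rev = revcomp(cfg.ihf_consensus)

    def pick_base(current: str, excluded: set[str]) -> str:
        options = [b for b in "ACGT" if b != current and b not in excluded]
        w = np.array([probs_full["ACGT".index(b)] for b in options])
        if w.sum() == 0:
            w = np.ones(len(options))
        return str(rng.choice(np.array(options), p=w / w.sum()))

    for _ in range(max_iter):
        seq = "".join(arr)
        # each fix: (position, bases that must NOT be used at that position)
        fixes: list[tuple[int, set[str]]] = []

        for motif in (cfg.motif_f, cfg.motif_r):
            for s, mm in scan_hexamer(seq, motif, 2):
                if s in allowed_subsites:
                    continue
                strict = strict_mask is not None and bool(strict_mask[s])
                if mm > (2 if strict else 1):
                    continue
                fixable = [
                    s + k
                    for k in range(6)
                    if seq[s + k] == motif[k] and not protected[s + k]
                ]
                if fixable:
                    p = int(rng.choice(np.array(fixable)))
                    fixes.append((p, set()))

        for strand, anchors in (("+", _SIGMA_FWD_ANCHORS), ("-", _SIGMA_REV_ANCHORS)):
            for s in _anchor_hits(seq, anchors, 14, cfg.sigma54_anchor_mm):
                if (strand, s) in allowed_sigma:
                    continue
                fixable = [
                    s + pos
                    for pos, base in anchors.items()
                    if seq[s + pos] == base and not protected[s + pos]
                ]
                if fixable:
                    p = int(rng.choice(np.array(fixable)))
                    fixes.append((p, set()))

        for strand, consensus in (("+", cfg.ihf_consensus), ("-", ihf_rev)):
            for hit in find_ihf(seq, consensus, cfg.ihf_max_mm):
                if (strand, hit.start) in allowed_ihf:
                    continue
                candidates: list[tuple[int, set[str]]] = []
                for k, code in enumerate(consensus):
                    bases = set(ambiguous_dna_values[code])
                    if len(bases) == 4:
                        continue
                    p = hit.start + k
                    if seq[p] in bases and not protected[p]:
                        candidates.append((p, bases))
                if candidates:
                    idx = int(rng.integers(len(candidates)))
                    fixes.append(candidates[idx])

        if not fixes:
            return edits
        for p, excluded in fixes:
            arr[p] = pick_base(str(arr[p]), excluded - {str(arr[p])})
            edits += 1
    raise RuntimeError("background scrubbing did not converge")


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

class PlantingError(ValueError):
    """A planted element would not fit in the gene's upstream region."""


def _write_element(
    arr: np.ndarray,
    gene: GeneAnnotation,
    rel_start: int,
    element: str,
    reverse: bool,
    protect: np.ndarray,
    protect_offsets: list[int],
) -> tuple[int, int]:
    """Write ``element`` (coding orientation, ATG-relative start) into the genome.

    Returns the genomic ``[start, end)`` span.  ``protect_offsets`` are the
    element positions (coding frame) whose identity is constrained and must
    survive scrubbing; the rest (e.g. sigma-54 interior Ns) stay mutable.
    ``reverse=True`` writes the element reverse-complemented in place
    (decoy orientation).
    """
    m = len(element)
    iv = gene.interval
    if rel_start + m > 0:
        raise PlantingError(f"element at {rel_start} would cross the ATG")
    if iv.strand == "+":
        gstart = iv.start + rel_start
        text = element
        offsets = protect_offsets
    else:
        gstart = iv.end - rel_start - m
        text = revcomp(element)
        offsets = [m - 1 - k for k in protect_offsets]
    if reverse:
        text = revcomp(text)
        offsets = [m - 1 - k for k in offsets]
    gend = gstart + m
    if gstart < 0 or gend > arr.size:
        raise PlantingError(f"element at rel {rel_start} outside genome")
    arr[gstart:gend] = list(text)
    for k in offsets:
        protect[gstart + k] = True
    return gstart, gend


def _upstream_gap(gene: GeneAnnotation, genes: list[GeneAnnotation], length: int) -> tuple[int, int]:
    """Genomic extent of the intergenic gap upstream of ``gene``."""
    iv = gene.interval
    if iv.strand == "+":
        left_ends = [g.interval.end for g in genes if g.interval.end <= iv.start]
        return (max(left_ends, default=0), iv.start)
    right_starts = [g.interval.start for g in genes if g.interval.start >= iv.end]
    return (iv.end, min(right_starts, default=length))


def plant_promoter(
    arr: np.ndarray,
    gene: GeneAnnotation,
    spec: PlantSpec,
    rng: np.random.Generator,
    protect: np.ndarray,
    genes: list[GeneAnnotation],
    config: PipelineConfig | None = None,
) -> tuple[PlantedLocus, dict]:
    """Write one promoter architecture upstream of ``gene``; returns the
    ledger entry plus the allowed-window registry for the scrubber.

    Elements are positioned so that *reported* (half-away-rounded)
    ATG-relative centres equal the spec values: the sigma-54 element centre
    lands on ``sigma_center_rel`` (default -127), the downstream-most subsite
    centre on ``uas_anchor_center_rel`` and the IHF 13-mer at the upstream
    edge of ``ihf_region_rel``.
    """
    cfg = config or PipelineConfig()
    reverse = spec.label == "decoy_orientation"

    n_sites = spec.n_subsites
    if n_sites not in (2, 3):
        raise PlantingError("n_subsites must be 2 or 3")
    if spec.spacings is None:
        spacings = tuple(int(rng.integers(20, 26)) for _ in range(n_sites - 1))
    else:
        spacings = tuple(spec.spacings)
    if len(spacings) != n_sites - 1:
        raise PlantingError("need n_subsites - 1 spacings")
    total_mm = (
        int(rng.integers(0, 3)) if spec.total_mismatches is None else spec.total_mismatches
    )

    kinds = ("F", "R", "R")[:n_sites] if n_sites == 3 else ("F", "R")
    # subsite centres, left(upstream) to right(downstream)
    centers = [spec.uas_anchor_center_rel - sum(spacings[i:]) for i in range(n_sites - 1)]
    centers.append(spec.uas_anchor_center_rel)
    rel_starts = [int(c - 2.5) for c in centers]

    # realise the subsite sequences with the planted mismatches.  Because
    # GTAACA is the reverse complement of TGTTAC the two motifs overlap
    # heavily with themselves shifted by 1-2 bp: certain substitutions
    # (e.g. TGTTAC -> TGTAAC) would *create* a near-perfect subsite of the
    # other kind one base away, making the planted architecture ambiguous.
    # Those specific substitutions are excluded.
    forbidden = {"F": {2: "G", 3: "A", 5: "A"}, "R": {0: "T", 2: "T", 3: "C"}}
    motifs = [cfg.motif_f if k == "F" else cfg.motif_r for k in kinds]
    realised = [list(m) for m in motifs]
    site_mm = [0] * n_sites
    if total_mm:
        slots = rng.choice(n_sites * 6, size=total_mm, replace=False)
        for slot in slots:
            si, pos = divmod(int(slot), 6)
            original = realised[si][pos]
            banned = {original, forbidden[kinds[si]].get(pos, "")}
            choices = [b for b in "ACGT" if b not in banned]
            realised[si][pos] = str(rng.choice(np.array(choices)))
            site_mm[si] += 1

    sigma_rel_start = spec.sigma_center_rel - 6  # centre at sigma_center_rel - 0.5
    interior = "".join(rng.choice(_BASES, size=10))
    sigma_element = "GG" + interior + "GC"

    ihf_rel_start = spec.ihf_region_rel[0]
    ihf_element = "".join(
        str(rng.choice(np.array(list(ambiguous_dna_values[c]))))
        for c in cfg.ihf_consensus
    )

    gap = _upstream_gap(gene, genes, arr.size)
    gap_len = gap[1] - gap[0]
    furthest = rel_starts[0] if not spec.orphan_f_prime else -413
    if -furthest > gap_len - 5:
        raise PlantingError(
            f"gene {gene.gene_id}: upstream gap of {gap_len} bp too short for "
            f"elements reaching {furthest}"
        )

    spans = []
    allowed_subsites: set[int] = set()
    for rel, site in zip(rel_starts, realised):
        s, e = _write_element(arr, gene, rel, "".join(site), reverse, protect, list(range(6)))
        spans.append((s, e))
        allowed_subsites.add(s)

    orphan_center = None
    if spec.orphan_f_prime:
        s, e = _write_element(arr, gene, -413, cfg.motif_f, reverse, protect, list(range(6)))
        spans.append((s, e))
        allowed_subsites.add(s)
        orphan_center = round_half_away(-413 + 2.5)

    s, e = _write_element(
        arr, gene, sigma_rel_start, sigma_element, reverse, protect, [0, 1, 12, 13]
    )
    spans.append((s, e))
    element_on_plus = (gene.interval.strand == "+") != reverse
    allowed_sigma = {("+" if element_on_plus else "-", s)}

    protect_ihf = [k for k, c in enumerate(cfg.ihf_consensus) if c != "N"]
    s, e = _write_element(arr, gene, ihf_rel_start, ihf_element, reverse, protect, protect_ihf)
    spans.append((s, e))
    allowed_ihf = {("+" if element_on_plus else "-", s)}

    locus = PlantedLocus(
        gene_id=gene.gene_id,
        label=spec.label,
        strand=gene.interval.strand,
        atg_genomic=gene.atg_position,
        sigma_rel_center=spec.sigma_center_rel,
        subsite_kinds=kinds,
        subsite_rel_centers=tuple(round_half_away(c) for c in centers),
        subsite_mismatches=tuple(site_mm),
        spacings=spacings,
        ihf_rel_span=(ihf_rel_start, ihf_rel_start + len(cfg.ihf_consensus) - 1),
        orphan_rel_center=orphan_center,
        span_genomic=(min(s for s, _ in spans), max(e for _, e in spans)),
    )
    registry = {
        "subsites": allowed_subsites,
        "sigma": allowed_sigma,
        "ihf": allowed_ihf,
        "gap": gap,
    }
    return locus, registry


# ---------------------------------------------------------------------------
# peak and expression simulation
# ---------------------------------------------------------------------------

def simulate_peaks(
    genome: GenomicSequence,
    ledger: PlantingLedger,
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> list[Peak]:
    """One peak per planted locus plus background peaks, MACS-style.

    Loci labelled ``target``, ``decoy_orientation`` and ``decoy_spacing``
    receive enrichments from a floored lognormal (they are all genuinely
    bound in the simulation) and p-values at or below 1e-12;
    ``decoy_subthreshold`` loci fail either threshold; background peaks
    always fail at least one.  Enrichment/p are recorded in the ledger.
    """
    cfg = config or GeneratorConfig()
    length = len(genome)

    def target_enrichment() -> float:
        while True:
            value = float(
                np.exp(np.log(cfg.enrichment_median) + cfg.enrichment_sigma * rng.standard_normal())
            )
            if value >= cfg.enrichment_floor:
                return value

    peaks: list[Peak] = []
    for locus in ledger.loci:
        start = max(0, locus.span_genomic[0] - int(rng.integers(30, 121)))
        end = min(length, locus.span_genomic[1] + int(rng.integers(30, 121)))
        if locus.label == "decoy_subthreshold":
            if rng.random() < 0.5:
                enrichment = float(rng.uniform(1.3, 1.9))
                p_value = 10.0 ** float(rng.uniform(*cfg.target_log10p))
            else:
                enrichment = target_enrichment()
                p_value = 10.0 ** float(rng.uniform(-8.0, -4.0))
        else:
            enrichment = target_enrichment()
            p_value = 10.0 ** float(rng.uniform(*cfg.target_log10p))
        locus.peak_enrichment = enrichment
        locus.peak_p = p_value
        peaks.append(
            Peak(GenomicInterval(genome.id, start, end), enrichment, p_value)
        )

    for _ in range(cfg.n_background_peaks):
        width = int(rng.integers(200, 401))
        start = int(rng.integers(0, max(1, length - width)))
        peaks.append(
            Peak(
                GenomicInterval(genome.id, start, start + width),
                float(rng.uniform(1.0, 1.95)),
                10.0 ** float(rng.uniform(-8.0, -0.5)),
            )
        )
    peaks.sort(key=lambda p: (p.interval.seq_id, p.interval.start, p.interval.end))
    return peaks


def simulate_expression(
    effects: dict[str, tuple[float, float]],
    cv: float = 0.2,
    n_reps: int = 9,
    seed: int | None = None,
    condition: str = "OAA",
    rng: np.random.Generator | None = None,
    wt_strain: str = "KT2442",
    mut_strain: str = "MPO401",
) -> pd.DataFrame:
    """Replicate expression draws per gene x strain.

    ``effects`` maps gene id to (wild-type mean, mutant mean); each replicate
    is Normal(mean, cv*mean) truncated at zero (redrawn when negative).
    Deterministic per seed; returns a long-format replicate table.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rows = []
    for gene_id in sorted(effects):
        wt_mean, mut_mean = effects[gene_id]
        if wt_mean <= 0 or mut_mean <= 0:
            raise ValueError(f"gene {gene_id}: means must be positive")
        for strain, mean in ((wt_strain, wt_mean), (mut_strain, mut_mean)):
            for rep in range(1, n_reps + 1):
                value = mean if cv == 0 else -1.0
                while value < 0:
                    value = float(rng.normal(mean, cv * mean))
                rows.append(
                    {
                        "gene_id": gene_id,
                        "strain": strain,
                        "condition": condition,
                        "replicate": rep,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def _ledger_consistent(
    genome: GenomicSequence,
    genes: list[GeneAnnotation],
    ledger: PlantingLedger,
    cfg: PipelineConfig,
) -> bool:
    """True when every planted locus annotates back to its ledger entry.

    Because the two subsite motifs are reverse complements of each other,
    a planted subsite always carries near-miss 'shadow' windows of the
    opposite kind 1-2 bp away; for a small fraction of random mismatch
    placements a shadow ties the planted site and the recovered architecture
    becomes ambiguous.  The generator rejection-samples those placements so
    the ledger is always the unique best reading of the planted sequence.
    """
    from .promoter_annotation import annotate_promoter, extract_promoter

    by_id = {g.gene_id: g for g in genes}
    for locus in ledger.loci:
        seq, atg = extract_promoter(genome, by_id[locus.gene_id], cfg.upstream_window)
        arch = annotate_promoter(seq, atg, cfg, gene_id=locus.gene_id)
        if locus.label == "decoy_orientation":
            if arch.sigma is not None:
                return False
            continue
        if locus.label == "decoy_spacing":
            if arch.sigma_rel_center != locus.sigma_rel_center or arch.composite is not None:
                return False
            continue
        comp = arch.composite
        if comp is None:
            return False
        ok = (
            arch.sigma_rel_center == locus.sigma_rel_center
            and tuple(s.kind for s in comp.subsites) == locus.subsite_kinds
            and arch.composite_rel_centers == locus.subsite_rel_centers
            and tuple(s.mismatches for s in comp.subsites) == locus.subsite_mismatches
            and tuple(int(round(d)) for d in comp.spacings) == locus.spacings
            and arch.ihf_rel_span == locus.ihf_rel_span
            and (
                locus.orphan_rel_center is None
                or locus.orphan_rel_center in arch.orphan_rel_centers
            )
        )
        if not ok:
            return False
    return True


@dataclass
class SyntheticDataset:
    genome: GenomicSequence
    genes: list[GeneAnnotation]
    ledger: PlantingLedger
    peaks: list[Peak]
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.genome], outdir / "genome.fasta")
        write_gff3(self.genes, outdir / "genes.gff3")
        write_peaks_tsv(self.peaks, outdir / "peaks.tsv")
        self.ledger.to_json(outdir / "ledger.json")


def build_dataset(config: GeneratorConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Generate a complete, self-consistent synthetic study.

    Planted loci are assigned to *tandem* intergenic gaps (both flanking
    genes co-oriented), so each planted architecture faces exactly one gene
    and a mirrored decoy cannot legitimately face the opposite flank.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    labels = (
        ["target"] * cfg.n_targets
        + ["decoy_orientation"] * cfg.n_decoy_orientation
        + ["decoy_spacing"] * cfg.n_decoy_spacing
        + ["decoy_subthreshold"] * cfg.n_decoy_subthreshold
    )

    # tandem gaps: the gap upstream of gene i is between gene i-1 and gene i
    # (plus strand) or between gene i and gene i+1 (minus strand); it is
    # usable when the other flanking gene points the same way.  Redraw the
    # gene layout (still deterministic in the seed) in the rare case it
    # yields too few tandem gaps for the requested loci.
    def tandem_genes(genes: list[GeneAnnotation], length: int) -> list[GeneAnnotation]:
        out = []
        for i, gene in enumerate(genes):
            if gene.interval.strand == "+":
                neighbour = genes[i - 1] if i > 0 else None
            else:
                neighbour = genes[i + 1] if i + 1 < len(genes) else None
            if neighbour is None or neighbour.interval.strand == gene.interval.strand:
                gap = _upstream_gap(gene, genes, length)
                if gap[1] - gap[0] >= 480:
                    out.append(gene)
        return out

    for attempt in range(20):
        genome, genes = make_genome(
            cfg.genome_length,
            cfg.gc,
            cfg.n_genes,
            gene_length=cfg.gene_length,
            gap_length=cfg.gap_length,
            rng=rng,
        )
        eligible = tandem_genes(genes, len(genome))
        if len(eligible) < len(labels):
            if attempt == 19:
                raise ValueError(
                    f"only {len(eligible)} plantable tandem gaps for {len(labels)} "
                    "loci; increase genome_length/n_genes"
                )
            continue

        arr = np.array(list(genome.residues))
        protect = _start_codon_mask(genes, len(genome))
        scrub_background(arr, rng, gc=cfg.gc, protected=protect, config=cfg.pipeline)
        order = rng.permutation(len(eligible))
        ledger = PlantingLedger()
        allowed_subsites: set[int] = set()
        allowed_sigma: set = set()
        allowed_ihf: set = set()
        strict_mask = np.zeros(len(genome), dtype=bool)

        for label, idx in zip(labels, order):
            gene = eligible[int(idx)]
            if label == "decoy_spacing":
                n_sites = int(rng.choice([2, 3]))
                spec = PlantSpec(
                    label=label,
                    n_subsites=n_sites,
                    spacings=(cfg.decoy_spacing_value,) * (n_sites - 1),
                )
            else:
                n_sites = int(rng.choice([2, 3], p=[0.3, 0.7]))
                spec = PlantSpec(
                    label=label,
                    n_subsites=n_sites,
                    orphan_f_prime=bool(n_sites == 3 and rng.random() < 0.3),
                )
            locus, registry = plant_promoter(
                arr, gene, spec, rng, protect, genes, cfg.pipeline
            )
            ledger.loci.append(locus)
            allowed_subsites |= registry["subsites"]
            allowed_sigma |= registry["sigma"]
            allowed_ihf |= registry["ihf"]
            lo = max(0, registry["gap"][0] - 100)
            hi = min(len(genome), registry["gap"][1] + 100)
            strict_mask[lo:hi] = True

        scrub_background(
            arr,
            rng,
            gc=cfg.gc,
            protected=protect,
            allowed_subsites=allowed_subsites,
            allowed_sigma=allowed_sigma,
            allowed_ihf=allowed_ihf,
            strict_mask=strict_mask,
            config=cfg.pipeline,
        )

        genome = GenomicSequence(id=genome.id, residues="".join(arr))
        if _ledger_consistent(genome, genes, ledger, cfg.pipeline):
            break
    else:
        raise RuntimeError("could not generate an identifiable planted dataset")

    peaks = simulate_peaks(genome, ledger, rng, cfg)
    return SyntheticDataset(genome=genome, genes=genes, ledger=ledger, peaks=peaks, config=cfg)
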