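"""Generator contracts: determinism, planted-truth recovery, simulation stats."""

import dataclasses

import numpy as np
import pytest

from regulonminer.config import PipelineConfig
from regulonminer.core_io import GenomicInterval
from regulonminer.peak_mining import filter_peaks
from regulonminer.promoter_annotation import annotate_promoter, extract_promoter
from regulonminer.synthetic_data import (
    GeneratorConfig,
    PlantedLocus,
    PlantingLedger,
    build_dataset,
    make_genome,
    simulate_expression,
    simulate_peaks,
)


class TestMakeGenome:
    def test_deterministic(self):
        a = make_genome(10_000, 0.5, 5, seed=1)
        b = make_genome(10_000, 0.5, 5, seed=1)
        assert a[0].residues == b[0].residues
        assert [g.interval for g in a[1]] == [g.interval for g in b[1]]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            make_genome(2_000, 0.5, 5, seed=1)

    def test_genes_start_with_atg_on_their_strand(self):
        genome, genes = make_genome(20_000, 0.5, 8, seed=3)
        for g in genes:
            iv = g.interval
            if iv.strand == "+":
                assert genome.residues[iv.start : iv.start + 3] == "ATG"
            else:
                assert genome.residues[iv.end - 3 : iv.end] == "CAT"

    def test_genes_disjoint_and_sorted(self):
        _, genes = make_genome(30_000, 0.5, 12, seed=5)
        for a, b in zip(genes, genes[1:]):
            assert a.interval.end <= b.interval.start

    def test_observed_gc_within_3_se(self):
        length = 100_000
        genome, genes = make_genome(length, 0.62, 10, seed=7)
        codon = np.zeros(length, dtype=bool)
        for g in genes:
            iv = g.interval
            sl = slice(iv.start, iv.start + 3) if iv.strand == "+" else slice(iv.end - 3, iv.end)
            codon[sl] = True
        bases = np.array(list(genome.residues))[~codon]
        gc = np.isin(bases, list("GC")).mean()
        se = np.sqrt(0.62 * 0.38 / bases.size)
        assert abs(gc - 0.62) <= 3 * se

    def test_gc_one_limit_has_no_at_outside_codons(self):
        length = 20_000
        genome, genes = make_genome(length, 1.0, 6, seed=9)
        codon = np.zeros(length, dtype=bool)
        for g in genes:
            iv = g.interval
            sl = slice(iv.start, iv.start + 3) if iv.strand == "+" else slice(iv.end - 3, iv.end)
            codon[sl] = True
        bases = set(np.array(list(genome.residues))[~codon])
        assert bases <= {"G", "C"}


class TestPlantedRecovery:
    def test_targets_annotate_back_to_ledger_exactly(self, small_dataset):
        cfg = PipelineConfig()
        by_id = {g.gene_id: g for g in small_dataset.genes}
        checked = 0
        for locus in small_dataset.ledger.loci:
            if locus.label not in ("target", "decoy_subthreshold"):
                continue
            seq, atg = extract_promoter(small_dataset.genome, by_id[locus.gene_id])
            arch = annotate_promoter(seq, atg, cfg)
            assert arch.sigma_rel_center == locus.sigma_rel_center
            comp = arch.composite
            assert comp is not None
            assert tuple(s.kind for s in comp.subsites) == locus.subsite_kinds
            assert arch.composite_rel_centers == locus.subsite_rel_centers
            assert tuple(s.mismatches for s in comp.subsites) == locus.subsite_mismatches
            assert tuple(int(d) for d in comp.spacings) == locus.spacings
            assert arch.ihf_rel_span == locus.ihf_rel_span
            if locus.orphan_rel_center is not None:
                assert locus.orphan_rel_center in arch.orphan_rel_centers
            checked += 1
        assert checked >= 4

    def test_spacing_decoys_yield_no_composite(self, small_dataset):
        cfg = PipelineConfig()
        by_id = {g.gene_id: g for g in small_dataset.genes}
        for locus in small_dataset.ledger.by_label("decoy_spacing"):
            seq, atg = extract_promoter(small_dataset.genome, by_id[locus.gene_id])
            arch = annotate_promoter(seq, atg, cfg)
            assert arch.sigma_rel_center == locus.sigma_rel_center
            assert arch.composite is None

    def test_orientation_decoys_show_no_facing_sigma(self, small_dataset):
        cfg = PipelineConfig()
        by_id = {g.gene_id: g for g in small_dataset.genes}
        for locus in small_dataset.ledger.by_label("decoy_orientation"):
            seq, atg = extract_promoter(small_dataset.genome, by_id[locus.gene_id])
            arch = annotate_promoter(seq, atg, cfg)
            assert arch.sigma is None


class TestBuildDataset:
    def test_same_seed_identical_outputs(self, small_generator_config):
        a = build_dataset(small_generator_config, seed=4)
        b = build_dataset(small_generator_config, seed=4)
        assert a.genome.residues == b.genome.residues
        assert dataclasses.asdict(PlantingLedger(a.ledger.loci)) == dataclasses.asdict(
            PlantingLedger(b.ledger.loci)
        )
        assert [
            (p.interval.start, p.interval.end, p.enrichment, p.p_value) for p in a.peaks
        ] == [(p.interval.start, p.interval.end, p.enrichment, p.p_value) for p in b.peaks]

    def test_written_files_round_trip(self, small_dataset, tmp_path):
        from regulonminer.core_io import read_fasta, read_gff3, read_peaks

        small_dataset.write(tmp_path)
        (genome,) = read_fasta(tmp_path / "genome.fasta")
        assert genome.residues == small_dataset.genome.residues
        genes = read_gff3(tmp_path / "genes.gff3")
        assert [g.gene_id for g in genes] == [g.gene_id for g in small_dataset.genes]
        peaks = read_peaks(tmp_path / "peaks.tsv")
        assert len(peaks) == len(small_dataset.peaks)
        ledger = PlantingLedger.from_json(tmp_path / "ledger.json")
        assert ledger.loci == small_dataset.ledger.loci


def _dummy_locus(i, label="target"):
    return PlantedLocus(
        gene_id=f"g{i}",
        label=label,
        strand="+",
        atg_genomic=1000 + i,
        sigma_rel_center=-127,
        subsite_kinds=("F", "R"),
        subsite_rel_centers=(-262, -241),
        subsite_mismatches=(0, 0),
        spacings=(21,),
        ihf_rel_span=(-189, -177),
        orphan_rel_center=None,
        span_genomic=(400 + i, 700 + i),
    )


class TestSimulatePeaks:
    def test_all_target_peaks_pass_filter(self, rng):
        from regulonminer.core_io import GenomicSequence

        genome = GenomicSequence("chr", "A" * 5000)
        ledger = PlantingLedger([_dummy_locus(i) for i in range(10)])
        cfg = GeneratorConfig(n_background_peaks=0)
        peaks = simulate_peaks(genome, ledger, rng, cfg)
        assert len(peaks) == 10
        assert len(filter_peaks(peaks)) == 10

    def test_background_only_all_filtered(self, rng):
        from regulonminer.core_io import GenomicSequence

        genome = GenomicSequence("chr", "A" * 5000)
        cfg = GeneratorConfig(n_background_peaks=40)
        peaks = simulate_peaks(genome, PlantingLedger([]), rng, cfg)
        assert len(peaks) == 40
        assert filter_peaks(peaks) == []

    def test_subthreshold_decoys_fail_filter(self, rng):
        from regulonminer.core_io import GenomicSequence

        genome = GenomicSequence("chr", "A" * 5000)
        ledger = PlantingLedger(
            [_dummy_locus(i, "decoy_subthreshold") for i in range(20)]
        )
        cfg = GeneratorConfig(n_background_peaks=0)
        peaks = simulate_peaks(genome, ledger, rng, cfg)
        assert filter_peaks(peaks) == []

    def test_enrichment_median_within_5_percent(self, rng):
        from regulonminer.core_io import GenomicSequence

        genome = GenomicSequence("chr", "A" * 5000)
        ledger = PlantingLedger([_dummy_locus(i) for i in range(2000)])
        cfg = GeneratorConfig(n_background_peaks=0)
        peaks = simulate_peaks(genome, ledger, rng, cfg)
        median = np.median([p.enrichment for p in peaks])
        assert abs(median - cfg.enrichment_median) / cfg.enrichment_median <= 0.05


class TestSimulateExpression:
    def test_zero_cv_reproduces_ratio_exactly(self):
        frame = simulate_expression({"g": (8.0, 2.0)}, cv=0.0, seed=0)
        wt = frame[frame.strain == "KT2442"]["value"]
        mut = frame[frame.strain == "MPO401"]["value"]
        assert wt.mean() / mut.mean() == 4.0

    def test_same_seed_identical_frame(self):
        a = simulate_expression({"g": (5.0, 1.0)}, seed=42)
        b = simulate_expression({"g": (5.0, 1.0)}, seed=42)
        assert a.equals(b)

    def test_values_truncated_at_zero(self):
        frame = simulate_expression({"g": (0.5, 0.5)}, cv=3.0, seed=1)
        assert (frame["value"] >= 0).all()

    def test_replicate_counts(self):
        frame = simulate_expression({"a": (1.0, 1.0), "b": (2.0, 1.0)}, n_reps=6, seed=0)
        assert len(frame) == 2 * 2 * 6
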