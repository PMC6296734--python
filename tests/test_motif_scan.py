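"""Motif scanners and composite assembly against brute-force oracles."""

import itertools

import numpy as np
import pytest

from regulonminer.core_io import ConfigError
from regulonminer.motif_scan import (
    F_MOTIF,
    R_MOTIF,
    SubsiteHit,
    assemble_composites,
    composite_score,
    find_ihf,
    find_sigma54,
    find_subsites,
    phase_deviation,
    scan_hexamer,
)
from regulonminer.core_io import revcomp


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def hamming_oracle(seq, motif, max_mm):
    out = []
    for s in range(len(seq) - len(motif) + 1):
        mm = sum(a != b for a, b in zip(seq[s : s + len(motif)], motif))
        if mm <= max_mm:
            out.append((s, mm))
    return out


class TestScanHexamer:
    def test_exact_hit(self):
        assert scan_hexamer("AATGTTACGG", F_MOTIF, 0) == [(2, 0)]

    def test_single_substitution(self):
        assert scan_hexamer("TGTTAG", F_MOTIF, 1) == [(0, 1)]

    def test_n_counts_as_mismatch(self):
        assert scan_hexamer("TGTTNC", F_MOTIF, 0) == []
        assert scan_hexamer("TGTTNC", F_MOTIF, 1) == [(0, 1)]

    def test_short_sequence_empty(self):
        assert scan_hexamer("ACGT", F_MOTIF, 2) == []

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    @pytest.mark.parametrize("motif", [F_MOTIF, R_MOTIF])
    def test_matches_bruteforce_on_seeded_sequence(self, rng, motif, max_mm):
        seq = random_dna(rng, 1000)
        assert scan_hexamer(seq, motif, max_mm) == hamming_oracle(seq, motif, max_mm)

    def test_invalid_motif_rejected(self):
        with pytest.raises(ConfigError):
            scan_hexamer("ACGTACGT", "ACGTN", 0)


class TestFindSubsites:
    def test_r_hit_with_fractional_center(self):
        (hit,) = find_subsites("GTAACA")
        assert (hit.kind, hit.center, hit.mismatches) == ("R", 2.5, 0)

    def test_revcomp_duality(self, rng):
        for _ in range(20):
            seq = random_dna(rng, 300)
            fwd = find_subsites(seq)
            rev = find_subsites(revcomp(seq))
            mirrored = sorted(
                (len(seq) - 6 - h.start, "R" if h.kind == "F" else "F", h.mismatches)
                for h in fwd
            )
            assert mirrored == sorted((h.start, h.kind, h.mismatches) for h in rev)

    @pytest.mark.parametrize("mutated", ["TACCGT", "GACTCT", "AGCCTC"])
    def test_printed_knockout_hexamers_score_no_hit(self, mutated):
        # each substitution sequence is >2 mismatches from both subsite motifs
        assert find_subsites(mutated, max_mm_per_site=2) == []


class TestFindSigma54:
    def test_perfect_element(self):
        (hit,) = find_sigma54("GG" + "A" * 10 + "GC")
        assert (hit.start, hit.center, hit.anchor_mismatches) == (0, 6.5, 0)

    def test_broken_gc_anchor(self):
        assert find_sigma54("GGAAAAAAAAAAGA", anchor_mm=0) == []
        (hit,) = find_sigma54("GGAAAAAAAAAAGA", anchor_mm=1)
        assert hit.anchor_mismatches == 1

    @pytest.mark.parametrize("anchor_mm", [0, 1, 2])
    def test_matches_bruteforce(self, rng, anchor_mm):
        seq = random_dna(rng, 2000)
        oracle = []
        for s in range(len(seq) - 13):
            w = seq[s : s + 14]
            mm = (w[0] != "G") + (w[1] != "G") + (w[12] != "G") + (w[13] != "C")
            if mm <= anchor_mm:
                oracle.append((s, mm))
        got = [(h.start, h.anchor_mismatches) for h in find_sigma54(seq, anchor_mm)]
        assert got == oracle


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "W": "AT", "R": "AG", "Y": "CT",
    "S": "GC", "K": "GT", "M": "AC", "N": "ACGT",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


class TestFindIhf:
    def test_consensus_match(self):
        (hit,) = find_ihf("AATCAAGGGGTTA")
        assert (hit.start, hit.end, hit.mismatches) == (0, 13, 0)

    def test_w_violation_is_one_mismatch(self):
        assert find_ihf("CATCAAGGGGTTA", max_mm=0) == []
        (hit,) = find_ihf("CATCAAGGGGTTA", max_mm=1)
        assert hit.mismatches == 1

    def test_invalid_code_rejected(self):
        with pytest.raises(ConfigError):
            find_ihf("ACGT", consensus="WATZ")

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_matches_bruteforce(self, rng, max_mm):
        consensus = "WATCAANNNNTTR"
        seq = random_dna(rng, 3000)
        oracle = []
        for s in range(len(seq) - len(consensus) + 1):
            mm = sum(
                seq[s + k] not in IUPAC[c] for k, c in enumerate(consensus)
            )
            if mm <= max_mm:
                oracle.append((s, mm))
        got = [(h.start, h.mismatches) for h in find_ihf(seq, consensus, max_mm)]
        assert got == oracle


def hit(kind, start, mm=0):
    motif = F_MOTIF if kind == "F" else R_MOTIF
    return SubsiteHit(kind, start, mm, motif)


def chain_oracle(hits, smin=20.0, smax=25.0, budget=2, period=10.5, tol=4.0,
                 min_sites=2):
    """Independent exhaustive chain enumeration (iterative, stack-based)."""
    hits = sorted(hits, key=lambda h: (h.center, h.kind))
    n = len(hits)
    ok_pair = [
        [
            smin <= hits[j].center - hits[i].center <= smax
            and phase_deviation(hits[j].center - hits[i].center, period) <= tol
            for j in range(n)
        ]
        for i in range(n)
    ]
    all_chains = set()
    stack = [((i,), hits[i].mismatches) for i in range(n)
             if hits[i].mismatches <= budget]
    while stack:
        path, mm = stack.pop()
        grew = False
        for j in range(path[-1] + 1, n):
            if ok_pair[path[-1]][j] and mm + hits[j].mismatches <= budget:
                stack.append((path + (j,), mm + hits[j].mismatches))
                grew = True
        if not grew and len(path) >= min_sites:
            all_chains.add(path)
    # maximal = not a contiguous slice of another chain
    def is_subchain(a, b):
        return len(a) < len(b) and any(
            b[k : k + len(a)] == a for k in range(len(b) - len(a) + 1)
        )

    maximal = {c for c in all_chains if not any(is_subchain(c, o) for o in all_chains)}
    return {tuple((hits[i].kind, hits[i].start) for i in c) for c in maximal}


class TestAssembleComposites:
    def test_three_site_architecture(self):
        hits = [hit("F", 8), hit("R", 29), hit("R", 50)]  # centres 10.5/31.5/52.5
        (comp,) = assemble_composites(hits)
        assert comp.n_subsites == 3
        assert comp.total_mismatches == 0
        assert comp.spacings == (21.0, 21.0)
        assert comp.phase_deviations == (0.0, 0.0)
        assert comp.span == (8, 56)

    def test_too_far_apart(self):
        assert assemble_composites([hit("F", 0), hit("R", 30)]) == []

    @pytest.mark.parametrize(
        "gap,expected", [(19, 0), (20, 1), (25, 1), (26, 0)]
    )
    def test_spacing_boundaries_exact(self, gap, expected):
        comps = assemble_composites([hit("F", 0), hit("R", gap)])
        assert len(comps) == expected

    def test_budget_is_global(self):
        assert assemble_composites([hit("F", 0, 2), hit("R", 21, 1)]) == []
        (comp,) = assemble_composites([hit("F", 0, 2), hit("R", 21, 0)])
        assert comp.total_mismatches == 2

    def test_strict_phase_tolerance_rejects_non_integral_turns(self):
        # 23 bp is 2 bp off two helical turns: rejected at tol 1.5, kept at 4.0
        hits = [hit("F", 0), hit("R", 23)]
        assert assemble_composites(hits, phase_tol=1.5) == []
        assert len(assemble_composites(hits, phase_tol=4.0)) == 1

    def test_overlapping_chains_ranked_deterministically(self):
        # two 2-chains sharing the middle subsite: better (fewer-mm) chain primary
        hits = [hit("F", 0, 2), hit("R", 21, 0), hit("R", 42, 1)]
        comps = assemble_composites(hits)
        primaries = [c for c in comps if c.rank == "primary"]
        secondaries = [c for c in comps if c.rank == "secondary"]
        assert len(primaries) == 1 and len(secondaries) == 1
        assert primaries[0].total_mismatches <= secondaries[0].total_mismatches

    def test_matches_chain_enumeration_oracle_on_seeded_sequences(self, rng):
        for _ in range(6):
            seq = random_dna(rng, 2500)
            hits = find_subsites(seq, max_mm_per_site=2)
            got = {
                tuple((s.kind, s.start) for s in c.subsites)
                for c in assemble_composites(hits)
            }
            assert got == chain_oracle(hits)


class TestCompositeScore:
    def test_formula(self):
        c3 = assemble_composites([hit("F", 0), hit("R", 21), hit("R", 42)])[0]
        assert composite_score(c3) == 3.0
        (c2,) = assemble_composites([hit("F", 0, 1), hit("R", 21, 1)])
        assert composite_score(c2) == pytest.approx(2 - 2 / 3)

    def test_order_agrees_with_lexicographic(self, rng):
        comps = []
        for _ in range(30):
            n = int(rng.integers(2, 4))
            mms = rng.integers(0, 2, size=n)
            while mms.sum() > 2:
                mms = rng.integers(0, 2, size=n)
            hits = [hit("F" if k % 2 == 0 else "R", 21 * k, int(mms[k])) for k in range(n)]
            got = assemble_composites(hits)
            if got:
                comps.append(got[0])
        scored = sorted(comps, key=lambda c: composite_score(c), reverse=True)
        lex = sorted(comps, key=lambda c: (c.n_subsites, -c.total_mismatches), reverse=True)
        assert [(c.n_subsites, c.total_mismatches) for c in scored] == [
            (c.n_subsites, c.total_mismatches) for c in lex
        ]


class TestMonotonicity:
    def test_hits_grow_with_budget(self, rng):
        seq = random_dna(rng, 1500)
        for motif in (F_MOTIF, R_MOTIF):
            prev = set()
            for mm in range(0, 3):
                cur = {s for s, _ in scan_hexamer(seq, motif, mm)}
                assert prev <= cur
                prev = cur
        prev = set()
        for mm in range(0, 3):
            cur = {h.start for h in find_sigma54(seq, mm)}
            assert prev <= cur
            prev = cur
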