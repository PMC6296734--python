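# Methods

## The problem

CbrB is a σ^N^ (sigma-54 / RpoN)-dependent enhancer-binding protein of
*Pseudomonas*. Unlike the palindrome-binding activators typical of this
family, it recognises a chain of short non-palindromic subsites: the 6-bp
element TGTTAC read directly (type F) or as its reverse complement GTAACA
(type R), with centre-to-centre spacings of 20–25 bp that keep successive
sites on roughly the same face of the helix. Transcription additionally
requires a σ^N^ promoter element (consensus GG-N₁₀-GC) downstream of the
subsite cluster and is assisted by IHF binding in between. This package
turns that promoter model into a reusable mining pipeline: given ChIP peak
calls, a genome and its gene annotation, it selects candidate regulon
members and reports each candidate's promoter architecture in ATG-relative
coordinates, with in-silico subsite mutagenesis and RT-qPCR-style
expression-validation statistics.

## Coordinate conventions

Internally every interval is 0-based, half-open; report output is 1-based
inclusive. Promoter positions are counted from the start codon on the
gene's strand: position −1 is the base immediately 5′ of the A of ATG (the
A itself is +1; there is no 0). Even-length motifs have fractional centres
(a hexamer starting at *s* is centred at *s* + 2.5); spacing is measured
centre-to-centre, and fractional centres are rounded half away from zero
for reporting only — internal arithmetic stays fractional. A σ^N^ element
whose reported centre is −127 therefore spans −133…−120.

## The mining cascade

1. **Threshold filter** — keep peaks with fold enrichment ≥ 2 (inclusive)
   and p-value < 10⁻¹⁰ (strict), both configurable.
2. **Intergenic intersection** — keep peaks overlapping ≥ 1 bp of the
   complement of the merged gene annotation (no minimum overlap fraction
   is imposed).
3. **Orientation filter** — extend the peak by 100 bp on each side and keep
   fragments containing at least one σ^N^ element on the strand of, and
   within 500 bp upstream of, a downstream gene's ATG. A fragment between
   divergent genes can qualify once per direction. The GG/GC anchors are
   matched exactly by default (`sigma54_anchor_mm` widens them).
4. **Architecture annotation** — extract 500 bp upstream of each facing
   gene (minus-strand genes are reverse-complemented so the ORF reads
   left-to-right), choose the σ^N^ hit nearest the ATG, assemble subsite
   composites, and accept the best-scoring composite whose downstream-most
   subsite centre lies 30–250 bp upstream of the σ^N^ centre. A locus is a
   *predicted target* only when such a composite exists; this last step is
   what rejects subsite clusters with non-functional spacing, which the
   first three stages cannot see.

The funnel counts logged at each stage mirror the narrative of a real
screen (total → pass thresholds → intergenic → oriented → with composite)
so real-data runs can be compared against published counts.

## Composite assembly

Subsite hits (each within `per_site_mm` = 2 mismatches; an N never matches)
are chained left-to-right. A chain is valid when every consecutive
centre-to-centre distance lies in [20, 25] bp, each distance is within
`phase_tol` of an integer number of helical turns (`phase_period` =
10.5 bp), and the *summed* mismatches stay within the global budget of 2
("2 mismatches overall"). Only maximal chains are reported; overlapping
chains are ranked by more subsites, then fewer total mismatches, then
leftmost start — the winner is primary, the rest secondary. The ranking
score `n_subsites − total_mismatches/(budget+1)` is a reporting aid only.

**Phase tolerance.** The stated spacing range 20–25 bp itself spans
deviations of 0–4 bp from the nearest helical repeat (21 bp = two turns),
so a strict ±1.5 bp same-face rule would contradict the spacing rule it is
meant to accompany. The default is therefore permissive (`phase_tol` =
4.0 bp): it never rejects a spacing the 20–25 bp window accepts, but does
reject near-anti-phase distances if the window is reconfigured wider. Set
`phase_tol: 1.5` for a strict same-face screen.

**Orphan subsites.** Perfect subsites outside the selected composite (such
as a distal F′ copy a further ~150 bp upstream, whose deletion does not
affect activation) are reported separately and never joined into a
composite.

**IHF.** The IHF site is matched against a degenerate IUPAC consensus,
default WATCAANNNNTTR — the classic *E. coli* consensus, supplied because
no organism-specific sequence is established for this system — and the hit
reported is the one nearest the σ^N^ element on its upstream side,
preferring hits between the composite and the promoter.

## Expression validation

Fold change is the ratio of mean wild-type (KT2442) to mean *cbrB*-mutant
(MPO401) expression, reported half-up to one decimal. Group comparison is
the unpaired t-test without assuming equal variances (Welch), two-sided,
computed via `scipy.stats.ttest_ind_from_stats`, with stars at p < 0.05 /
0.01 / 0.005. A gene is called activated (repressed) when the unrounded
fold change is above (below) 1 at p < 0.05, otherwise "no difference".
When only summary statistics are supplied the replicate count defaults to
9 — three biological replicates, each in technical triplicate; because the
true per-gene replicate counts in such tables are ambiguous, printed
p-values are reproduced only qualitatively (star thresholds), while fold
changes reproduce exactly. The packaged table
`data/rtqpcr_validation_oaa.tsv` transcribes published wild-type/mutant
summaries for eleven genes grown on oxaloacetate; running `validate` on it
yields 6 activated, 3 repressed and 2 no-difference calls.

## Synthetic data

The generator emulates the study conditions end to end and is a pure
function of (config, seed):

* **Genome** — i.i.d. background at configurable GC content (default 0.5)
  with 50 non-overlapping genes in 100 kb (desk scale), gene lengths
  600–1000 bp, intergenic gaps 500–800 bp, both strands, consecutive genes
  co-oriented with probability 0.7 (operon-like runs). Every gene starts
  with ATG on its strand.
* **Planted promoters** — per locus: 2 or 3 subsites with spacings drawn
  uniformly from {20…25} bp and 0–2 total planted mismatches, the
  downstream-most subsite centred at −240.5 (inside the −210…−270 region
  protected in footprinting experiments); a σ^N^ element centred at −127;
  an IHF consensus instance at −189…−177; optionally a perfect orphan F′
  centred at −411. Decoy classes isolate each filter: `decoy_orientation`
  plants the architecture element-wise reverse-complemented (σ^N^ faces
  away), `decoy_spacing` uses 30-bp spacings, `decoy_subthreshold` keeps
  the architecture but weakens the peak.
* **Peaks** — one peak per planted locus with lognormal fold enrichment
  (median 3, σ 0.2, floored at 2.2 so genuinely bound loci always clear
  the 2-fold screen; the floor is raised to 4 in the acceptance runs) and
  p ≤ 10⁻¹²; sub-threshold decoys fail one threshold; background peaks
  always fail at least one.
* **Expression** — replicates drawn per gene × strain from a normal with
  constant coefficient of variation (default 0.2), truncated at zero;
  published summary tables show standard deviations roughly proportional
  to means, which this is the simplest model matching.

**Background scrubbing.** Hexamers within 1–2 mismatches of a 6-bp motif
occur about every 13 bp in random DNA, and a bare GG-N₁₀-GC screen fires
about once per 256 bp per strand, so on a raw i.i.d. background chance
composites (~0.5 per 500-bp fragment at budget 2) and chance σ^N^ elements
would make exact planted-truth recovery impossible for *any* scanner. The
generator therefore scrubs the background with minimal, GC-respecting base
edits: σ^N^ anchor pairs on both strands and IHF consensus hits are
destroyed genome-wide, subsite hits within 1 mismatch genome-wide, and
within 2 mismatches inside planted promoter regions (±100 bp). Planted
elements are protected. Because the two subsite motifs are reverse
complements of each other, a planted subsite unavoidably carries 1–2
mismatch "shadow" windows of the opposite kind 1–2 bp away whose matching
bases lie inside the protected element; mismatch placements that would
make such a shadow indistinguishable from the planted site are excluded,
and the generator verifies that every ledger entry is the unique best
reading of its locus, redrawing the layout (still deterministically) in
the rare ambiguous case.

**What passing tests do and do not show.** On these scrubbed genomes the
cascade achieves 100% sensitivity and 0 false positives by construction of
the study conditions. Real genomes are not scrubbed: there, near-miss
subsites and σ^N^-like anchors are abundant — the very reason the original
screen could not distil a consensus by motif discovery — so on real data
the pipeline is a candidate generator whose specificity depends on the
ChIP evidence, not a classifier with these error rates.

## Problem sizes and numerical choices

Tests and the acceptance script use 30-kb / 14-gene genomes (3 targets + 6
decoys + 5 background peaks per seed, 20 seeds), 10 × 2–5 kb sequences for
scanner-vs-brute-force checks, 10⁵ permutations for the Welch cross-check
and 10⁴ null replicates (n = 9 per group, threefold variance ratio) for
type-I calibration — sizes chosen so the whole suite runs on a laptop in
well under a minute per component while keeping every Monte-Carlo margin
(3 SE, 5%, [0.04, 0.06]) comfortably powered. Ties anywhere in ranking are
broken deterministically (score, then leftmost). Degenerate inputs fail
loudly: empty sequences, non-ACGTN residues, p-values outside (0, 1],
non-positive qPCR means and zero-variance comparisons with unequal means
all raise typed errors rather than propagating.

## Known limitations

* The funnel counts of a genome-wide screen (hundreds of peaks, dozens of
  intergenic candidates) are reproducible only with the original deposited
  reads and the manual curation that followed; the package substitutes
  property-based recovery on planted genomes for those counts.
* Composite detection is a hard-threshold scanner, not a statistical
  model: no PWM, information content or binding free energy. This mirrors
  the screening procedure it implements.
* The IHF consensus is a cross-species default, and the σ^N^ screen uses
  only the GG/GC anchor pair of the full −24/−12 element; both widen to
  mismatches via configuration but have no organism-specific calibration.
* A middle-subsite knockout splits a 3-subsite chain into a pair more than
  25 bp apart, which the spacing rule rejects even though such promoters
  retain partial activity in vivo; partial-function concordance is
  therefore tested with terminal knockouts.
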