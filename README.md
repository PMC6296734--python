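# regulonminer

Mining the direct regulon of a σ^N^-dependent enhancer-binding protein from
ChIP peak calls.

CbrB, the response regulator of the *Pseudomonas* CbrAB two-component
system, activates σ^N^ (sigma-54) promoters through an unusual upstream
activating sequence: not a palindrome, but a chain of 6-bp subsites —
TGTTAC in direct orientation (type F) or its reverse complement GTAACA
(type R) — whose centres sit 20–25 bp apart, keeping successive sites on
the same face of the DNA helix, upstream of a GG-N₁₀-GC promoter element
and an IHF bending site. `regulonminer` implements the corresponding
candidate-selection and promoter-dissection procedure as a tested,
reusable pipeline:

* **peak mining** — enrichment ≥ 2-fold at p < 10⁻¹⁰, intersection with
  intergenic regions, σ^N^-orientation filtering ("facing an ORF"), and
  ±100 bp fragment extension;
* **motif scanning** — mismatch-tolerant hexamer subsite search, σ^N^
  (GG-N₁₀-GC) and IHF (WATCAANNNNTTR) consensus detection, and assembly of
  composite sites from ≥ 2 subsites with proper spacing, helical phasing
  and at most 2 mismatches overall;
* **promoter annotation** — ATG-relative architecture reports (σ^N^ centre,
  IHF span, subsite chain, orphan subsites) and in-silico 6-bp subsite
  substitutions;
* **expression validation** — wild-type/mutant fold change, Welch's
  unequal-variance t-test, significance stars, activated/repressed calls;
* **synthetic data** — a seeded generator of genomes with planted promoter
  architectures, decoy loci, simulated peaks and replicate expression,
  plus a planting ledger that makes the whole pipeline testable offline.

## Worked example

Generate a synthetic study, mine it, and validate expression:

```sh
regulonminer fixtures --out demo --seed 5
regulonminer mine demo/genome.fasta demo/genes.gff3 demo/peaks.tsv --out demo/mined
# peak funnel: 29 total -> 14 pass thresholds -> 14 with intergenic -> 11 oriented -> 8 with composite
```

`demo/mined/predicted_targets.txt` lists exactly the genes whose promoters
were planted with a complete architecture (the ledger in
`demo/ledger.json` is the ground truth), and
`demo/mined/architectures.txt` holds one report per candidate. Scanning a
single promoter fragment (ORF-oriented FASTA, start codon as the last
three bases) prints the architecture directly:

```
# gene	PP2810_like
sigma54	center	-127	anchor_mm	0
ihf	span	-189	-177	mm	0
subsite	F	center	-283	mm	0	obs	TGTTAC
subsite	R	center	-262	mm	0	obs	GTAACA
subsite	R	center	-241	mm	1	obs	GTAACG
spacing	21.0	21.0
uas_to_sigma	114.0
orphan	F	center	-411
```

Read: the σ^N^ element is centred 127 bp upstream of the ATG, an IHF site
spans −189…−177, three subsites (F, R, R; the last with one mismatch) form
a composite with 21-bp centre spacings whose downstream edge lies 114 bp
upstream of the σ^N^ centre, and a distal perfect F copy centred at −411
is reported as an orphan, never joined into the composite.

Validating the packaged wild-type (KT2442) vs *cbrB*-mutant (MPO401)
RT-qPCR summary table:

```sh
regulonminer validate src/regulonminer/data/rtqpcr_validation_oaa.tsv
```

```
gene_id	fold_change	t	df	p	stars	call
PP0952	0.1	-7.187	8.14	8.58e-05	***	repressed
PP1206	0.3	-6.594	12.01	2.55e-05	***	repressed
PP3009	1.0	0.0	15.4	1		no_difference
PP3074	5.7	6.323	10.04	8.5e-05	***	activated
PP3420	11.7	11.907	8.25	1.75e-06	***	activated
PP3656	1.1	0.447	11.76	0.663		no_difference
PP4050	0.7	-3.721	12.72	0.00266	***	repressed
PP4391	4.7	14.782	8.55	2.21e-07	***	activated
PP4486	2.8	5.895	10.08	0.000147	***	activated
PP4643	3.4	7.06	8.64	7.27e-05	***	activated
crcZ	43.5	12.749	8.0	1.35e-06	***	activated
# 11 genes: 6 activated, 3 repressed, 2 no difference
```

The fold-change column is the ratio of mean mRNA levels (wild type over
mutant) to one decimal — crcZ at 43.5 is the strongest activation, the
σ^N^-factor gene PP0952 the strongest repression — and the call column
applies the p < 0.05 direction rule.

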