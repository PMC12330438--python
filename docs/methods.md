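# Methods

`svsieve` implements the post-assembly half of a long-read structural-variant
(SV) discovery workflow for simplex families, together with a synthetic-cohort
generator that reproduces the statistical structure the workflow assumes. This
note records the models, the parameters that matter, and the design choices
made where the procedure was genuinely open.

## The discovery model

SVs are deletions (DEL) and insertions (INS) of ≥50 bp. A call is a locus,
type, length, optional sequence, quality and the set of callers reporting it.
Two calls are *the same allele* when

* they are of the same type,
* their breakpoints are within `refdist` (default 500 bp),
* their sizes agree reciprocally to `pctsize` (default 0.90), and
* when both carry sequence, their global-alignment identity
  `1 − edit/max(len)` is at least `pctseq` (default 0.90).

The sequence test is skipped when either side lacks sequence (DEL records
routinely do); the identity metric itself is a package choice — merge tools do
not publish theirs — and is isolated in one function.

**Callerset validation.** Per sample, assembly-based calls are kept only when
matched by ≥1 alignment-based caller; output keeps assembly coordinates. With
per-aligner sensitivity *s* the expected validated fraction of true calls is
`1 − (1−s)²`, which the simulator reproduces and the tests check.

**Collapse.** Calls from all samples are clustered greedily in (chrom, pos)
order: a call joins the first cluster whose current representative it matches,
else founds one. Representative selection is `maxqual` within samples and
most-shared-signature ("common") across the cohort. This reproduces the
order-dependent behaviour of the conventional tools; the test suite compares
cluster counts against an exhaustive transitive-closure oracle on instances
constructed to be order-independent (well-separated loci, jitter below half
`refdist`). One sample with two genuinely distinct het calls in a cluster
becomes hom-alt; repeated reports of one allele by *different* callers are a
single call and stay het; phase-unknown het/het merges are flagged in
provenance.

**Mendelian concordance** is the fraction of a child's carried loci whose
genotype is drawable one-allele-from-each-parent (mother-only for male chrX,
father-only for chrY). A missing parental genotype makes a locus *unknown* —
it leaves the concordance denominator and routes the call into the curation
chain instead of being declared a violation. This two-tier treatment is why
error-free simulations show concordance 1.0.

## Pangenome filtering and classification

A child locus is *common* when it matches any control locus carried by ≥1
control — presence/absence, not an AF threshold. On chrX/chrY only controls of
the child's sex count. Control loci whose genotypes are all missing do not
count as carried. Survivors are partitioned into six categories (autosomal
het/hom, X het/hom, male hemizygous X/Y) and labelled:

* **de novo** — no parental support after the full curation chain;
* **private inherited** — allele carried by exactly one parent among all
  cohort parents, transmitted to the child (counted per carrier parent, so a
  multi-child family consumes one "observation");
* **biparental homozygous** — child hom-alt, both parents het, autosomal,
  never homozygous in any control, configuration present in one family only;
* **rare other** — everything else (e.g. female X hom from a carrier father
  plus het mother, which is inherited but not private).

## Transmission curation

Mendelian-consistent rare SVs are high-confidence. The rest run a fixed chain,
stopping at the first resolving step:

1. **relaxed re-match** against the parents' *raw* (pre-validation) callsets
   at pctseq/pctsize 0.9 — recovers inheritance lost at validation;
2. **callable-region score**: `logistic(−2 + 1.5·log1p(reads) + mapq/60 −
   2·clip)` with threshold 0.5. This is a fixed, documented logistic rule over
   read support, mapping quality and clipping — the published workflow uses a
   trained classifier here whose weights are not public; the rule preserves
   the inputs, the 0.5 threshold and monotonicity (score non-decreasing in
   reads and mapq), and the weights are configuration;
3. **re-genotyper support**: a parental alt call at the locus;
4. **TR allele lengths** (TR-flagged loci): inherited if a parental allele is
   within `max(10 bp, 10%·child_len)`; larger child alleles are expanded de
   novo. Both tolerances are package defaults, exposed in config;
5. **read-support tiers**: ≥3 reads → moderate, 1–2 → low confidence
   (2 reads is unstated upstream; it is grouped with "single read" here),
   0 → no support.

Steps 1–4 resolve to status *moderate* (the source procedure states statuses
only for step 5). A candidate with no support anywhere is de novo. Manual
inspection (the original step 6) is out of scope, so zero-support candidates
become de novo directly.

## Burden statistics

The headline "OR" is the per-individual **rate ratio** `(k1/n1)/(k2/n2)`: with
the published counts (26 de novo SVs among 51 probands, 20 among 36 siblings)
it gives 0.92 and the Yates-corrected chi-square on the 2×2 carrier table
gives p = 0.84, both matching the printed values, whereas the classical 2×2
odds ratio does not. The classical odds ratio is still emitted alongside. For
strata where events outnumber individuals (per-child counts summed over
thousands of SVs) the carrier table is undefined and the statistic falls back
to a Yates-corrected goodness-of-fit of the event split (k1, k2) against
expectations proportional to (n1, n2). Per-child count distributions are
compared with a two-sided Mann–Whitney U (normal approximation, tie
correction, Z signed probands-minus-siblings). Bonferroni adjustment spans all
strata tested in one run; the family size is logged with the results.

The **discovery curve** counts nonredundant loci carried by ≥1 of the first k
controls; the **rare-pool curve** recomputes each child's rare count against
every panel prefix (a locus leaves the pool at the earliest prefix containing
a matching carrier). Both are monotone by construction and checked against
brute-force union recomputation.

## Annotation

SV footprints are `[pos−1, pos+svlen)` for DEL (anchor base plus deleted
stretch) and the single insertion-site base for INS; overlap is ≥1 bp.
Primary class precedence is Exon > UTR > Intron > Inter (UTR can be folded
into Exon for burden counting, as the published figure groups them); NDD, REG,
brainREG, TR and SegDup are independent flags. Whether TF clusters count as
REG is track configuration, not code.

## Sex-chromosome statistics

**Window coverage.** Chromosomes are cut into 1 Mbp windows; a window
qualifies when the union of contig alignment blocks covers ≥95% of its
unmasked length and ≤3 distinct contigs overlap it. The contig-count
condition is read as a per-window disqualifier (the alternative — dropping
contigs — is not what the workflow measures). Windows fully inside the
exclusion mask (PAR, centromere, Yq12) leave the denominator. Coverage uses
the union of aligned blocks, so splitting one alignment into abutting
sub-blocks of the same contig changes nothing (tested).

**XCI skew.** Per CpG island (±5 kbp flank, 889-island scale in real data),
the mean methylated fraction is computed per haplotype; islands lacking
coverage on either haplotype are excluded from chromosome summaries. A
chromosome is called skewed when |mean difference| ≥ 0.25 *and* ≥80% of
islands agree in direction — both thresholds are package choices (the source
analysis is qualitative) and configurable. The hypermethylated haplotype is
the preferentially inactivated one.

## The synthetic cohort

The generator emulates the study conditions, not the genome:

* **Panel**: 100 controls (default) with Beta(0.15, 8) allele frequencies.
  The Beta parameters were chosen from the closed form for the expected
  fraction of a child's common SVs matched by an N-control panel, ≈97% at
  N = 100 — mirroring the published filtering fraction as a soft calibration.
  African-superpopulation samples get a ×2 AF boost (capped), reproducing
  their higher SV counts.
* **Sizes**: 0.5·N(300, 50) + 0.1·N(6000, 800) + 0.4·LogNormal(5, 1),
  floored at 50 bp — Alu-like and LINE-like modes fixed by observation,
  weights free.
* **Families**: 4 quads + 2 trios. Genotypes follow sex-aware
  Hardy–Weinberg/Mendelian sampling (male X from mother, Y from father,
  hemizygous outside 1 Mbp PARs). Planted per child: 2 de novo, 3 autosomal
  private-inherited, 1 chrX private (maternal), 1 chrY private for males;
  per female child 1 X-homozygous event; per family 1 biparental-homozygous
  event whose sibling is drawn Mendelian-conditioned on not being hom-alt.
* **Callsets**: three callers (one assembly-based, two alignment-based) with
  sensitivities (1.0, 0.9, 0.9), breakpoint jitter N(0, 30 bp) truncated to
  ±(refdist−2)/2 so all representations of one locus stay mutually matchable,
  INS sequence divergence 1% capped at (1−pctseq)/2 per copy, genotype error
  2% (het↔hom flips). Loci are placed in disjoint 4 kbp slots, so distinct
  loci can never merge — cluster recovery is exact by design.
* **Evidence tables**: parental read support Poisson(10) for carriers,
  Poisson(0) for non-carriers (so a planted de novo has zero parental reads);
  TR allele-length tables with ±2 bp jitter; re-genotyper calls equal to true
  parental genotypes.
* **Truth ledger**: every emitted record id embeds its true locus
  (`truth@sample@caller`), and class labels are derived from the realized
  true genotypes by the same definitions the pipeline applies — an
  independent oracle for recovery tests (a common locus that happens to be
  carried by one cohort parent and zero controls *is* private-inherited, and
  both sides agree on it).

What the simulation does **not** model: real repeat structure (TR loci are a
ledger flag over uniform-random sequence), alignment artefacts, reference
bias, breakpoint ambiguity in tandem repeats, assembly errors, or linkage
between loci. Passing recovery tests therefore demonstrates the logic of
merging/filtering/curation, not caller accuracy on real genomes.

## Scales and determinism

Default desk scale is ~5,000 common loci, 100 controls, 22 family members
(~11,000 caller records); the full pipeline runs in a few seconds, and the
test suite uses 150–5,000-locus cohorts. All randomness flows from one seed
through tagged `numpy` SeedSequences; identical config+seed gives
byte-identical output files (checksummed in the run manifest and tested).
Positions use VCF 1-based coordinates on records and 0-based half-open
intervals everywhere else, converted in exactly one place.

## Known limitations

* The greedy collapse is order-dependent by design (faithfulness to the
  conventional tools); the oracle equivalence holds on order-independent
  instances only, and disagreements elsewhere are possible.
* The callable-region score is a fixed logistic stand-in with documented
  weights, not a trained model; its absolute scores are only meaningful
  relative to the 0.5 threshold.
* Inversions, duplications and translocations are rejected at parse time with
  a warning; only DEL/INS flow through the analysis.
* The rate-ratio chi-square treats each SV as independent; no per-gene or
  regression modelling is provided.
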