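# Methods

## Scope and shape

`eclemap` implements the desk-scale pipeline for mapping a fully penetrant
autosomal-recessive variant in a closed breed: array QC → mixed-model
association → shared-homozygosity (autozygosity) mapping → private-variant
cascade → consequence annotation → exact genotype–phenotype association,
plus a synthetic study generator that stands in for cohort data that
cannot be redistributed. All genomic coordinates are 1-based inclusive
throughout; BED files are converted at the I/O boundary. PLINK transposed
*text* (`.tped/.tfam`) is the canonical array format — fixtures stay
human-readable — and binary PLINK/BGEN/CRAM are deliberately out of scope.
Multi-allelic VCF records are split per alt allele on read; array no-calls
and VCF `./.` share one missing state.

## Quality control

One fixed-order pass: sample call rate ≥ 0.90 → marker call rate ≥ 0.90 →
minor allele frequency ≥ 0.10 (both phenotypes pooled, computed after
sample removal) → exact Hardy–Weinberg test in controls at a 10⁻⁵ floor,
with control-monomorphic markers exempt. The order itself is a design
choice (tools differ; the rule set does not), fixed so that removal counts
are auditable; the pass is idempotent. Every removal is logged with the
triggering rule and value.

The Hardy–Weinberg test conditions on allele counts and sums the
probabilities of all heterozygote counts no more probable than the
observed one; log-space accumulation keeps it exact for any cohort size.

## Kinship and the association scan

Two estimators: pairwise IBS (mean shared-allele proportion over
co-called markers) and the centered GRM (cross-product of mean-centered
dosages scaled by Σ2p(1−p), missing dosages set to the marker mean). The
GRM is the default random-effect covariance; which flavour a given study
used is rarely knowable, so both are first-class.

The scan fits `y = 1α + xβ + u + ε`, cov(u) = σg²K, by REML. One
eigendecomposition of K rotates the model to independent errors; per
marker, δ = σe²/σg² is re-optimized on a 64-point log₁₀ grid spanning
[10⁻⁵, 10⁵] with two local refinement passes (final resolution ≈ 1.6×10⁻⁴
decades), vectorized across markers. The Wald statistic (β̂/se)² is
referred to F(1, n−2), which makes the K = I case *exactly* ordinary least
squares — the invariant the tests pin down — and matches the common
Wald-test convention of mixed-model GWAS tools. Binary phenotypes are
treated quantitatively, as those tools do. Missing genotypes are
mean-imputed for the regression only. Monomorphic markers are flagged and
given p = 1.

Calibration caveat: with a binary 14/29 outcome at n = 43, even exact OLS
deviates slightly from the F reference (KS p ≈ 0.005–0.05 across seeds in
our measurements); this is a property of least squares on binary data, not
of the mixed model. The null-calibration test therefore permutes an
exchangeable Gaussian phenotype, and the binary case is covered exactly by
the OLS-equivalence test.

λ is reported as median(χ²₁)/0.4549 — from the uncorrected allelic χ² scan
("before") and the mixed-model p-values ("after"). We report λ but never
rescale p-values by it. Thresholds: suggestive 5×10⁻⁵ (passed through)
and Bonferroni α/m. Classical (Torgerson) MDS over 1−IBS distances
provides the relatedness display; coordinates are eigenvector-scaled and
sign-arbitrary.

## Autozygosity mapping

A marker is *segment-compatible* for a case set when no case is
heterozygous, all non-missing calls agree on one homozygous state, and at
most `max_missing_fraction` (default 0.2) of cases are missing. Segments
are maximal runs of compatible markers with at least `min_markers`
(default 25 — long enough that chance runs are negligible at array
density). The critical interval runs from the first flanking discordant
marker on the left to the first on the right (chromosome-terminal markers
when no flank exists), closed, because boundary coordinates in this field
are marker positions. Discordance tolerance is strict (zero heterozygous
non-missing calls) by default, matching the first-flanking-heterozygote
interval definition; the missing-fraction knob exists for noisy arrays.
Segments are ranked by the best contained association p-value, ties broken
by marker count then position.

## The prioritization cascade

Five steps over VariantSets: shared homozygous-alt across all sequenced
cases genome-wide; private against the panel; step 1 restricted to the
critical interval; private within the interval; protein-changing.
"Private" means the alt allele is observed in **zero** panel genomes, a
heterozygous carrier disqualifying (strict mode, default); a lenient mode
requires a homozygous panel carrier. Step 3 is recomputed from step 1, so
counts are monotone only against their applicable predecessor — the
five-row table's own layout. Per-step survivor identities are retained for
audit.

## Consequence annotation

A minimal transcript-aware annotator: genomic → CDS coordinates through
the exon structure (minus-strand transcripts count from the genomic CDS
end with complemented alleles), codon lookup in the transcript's stored
reference CDS (no genome FASTA needed; a declared-ref/CDS disagreement is
a hard error), translation via the standard genetic code (Biopython), and
HGVS-style strings `c.<pos><ref>><alt>` and `p.(<Ref3><idx><Alt3>)` with
the predicted-consequence parentheses convention. Splice-site = within 2
intronic bases of an exon boundary (the canonical GT/AG positions). Indels
get a `frameshift-proxy` class with no protein notation. Protein-changing
= missense, nonsense, splice-site or frameshift-proxy.

## Exact genotype–phenotype association

Counts are tabulated per (breed, phenotype); missing calls are tallied but
excluded from n. The headline test is the recessive collapse (hom-alt vs
everything else) — the natural coding for a recessive disease model, and
the one that reproduces the published cohort-scale p-value 1.2×10⁻³⁹ from
counts 23/1 vs 0/520 (verified against both an exact enumeration oracle
and an independent implementation). Dominant, allelic and genotypic
codings are provided; the genotypic 2×3 test enumerates all tables with
the observed margins exactly up to a size limit, then falls back to a
seeded Monte-Carlo estimate. The two-sided p uses the probability-mass
rule with a 10⁻⁷ relative tolerance on the comparison; everything is
computed in log space so 10⁻⁴⁰-scale values survive. Odds ratios with a
zero cell use the Haldane–Anscombe +0.5 correction and are flagged.
Breed subsets whose phenotype margin is below 5 (configurable) are
reported but refused as stand-alone tests — a single-case breed is never
tested by itself.

## The synthetic study generator

What it emulates: a closed breed population founded by a small haplotype
pool (8 founder haplotypes), bred at random for 24 generations at 1 cM/Mb
over two 50 Mb chromosomes — enough meioses to erode shared haplotypes to
the megabase scale a mapping study resolves, consistent with a disease
allele that predates breed formation (it segregates in several related
breeds). Sites: 12,000 per chromosome at the sequence tier; every third
site is an array marker (12.5 kb spacing, the density of a ~220k canine
array on a 2.4 Gb genome), with 0.5% per-call missingness (BeadChips
deliver >99% call rates once low-quality samples are dropped). Cohort: 14
cases and 29 controls on the array, 2 sequenced cases, 654 panel genomes.

Construction guarantees, chosen so the truth is auditable:

* founder haplotype 0 carries the causal allele (C>A at the configured
  position); gametes transmitting it inherit an intact 1 Mb core segment
  (crossovers inside the core are resolved by copying the carrier
  parent's whole core), so every causal homozygote is autozygous across
  at least that core;
* the recorded truth interval is the *realized* region over which all
  true cases are homozygous and concordant at the sequence tier — it
  contains the core and extends by whatever sharing recombination left,
  typically to 1–3 Mb;
* the panel founder pool is the study pool with founder 0 replaced by its
  ancestral, mutation-free copy: every standing allele of the study
  population is represented in the panel, so the causal allele (plus any
  planted neutral private variants) is exactly what the cascade should
  find, and the panel provably never carries it (asserted every run);
* cases are offspring of carrier×carrier matings accepted when homozygous
  (the study-design conditioning: affected dogs exist because such
  matings happen); controls are random offspring rejected only if causal
  homozygotes; allele loss by drift triggers a bounded, seeded redrop —
  the study conditions on the allele having survived;
* a toy protein-coding gene inside the core covers the causal position at
  CDS coordinate 1438 with a CC-initial codon, making the causal variant
  a guaranteed Pro→Thr missense; one neutral non-coding private variant
  is planted in the truth interval by default, so the cascade's last two
  rows are 2 → 1;
* phenotype error (default rate 0) replaces a case with a mislabelled
  non-homozygote, emulating a clinically misdiagnosed dog.

One seeded generator (`numpy.random.default_rng`) drives every draw;
identical configs reproduce byte-identical studies.

What it does **not** model: genotyping error (only missingness), sequencing
noise or read-level artefacts (the cascade consumes called genotypes, as
the real analysis consumes variant tables), population structure beyond a
single breed, selection, sex chromosomes, recombination hotspots, and
structural variants. Passing tests therefore demonstrate correct
*machinery* and realistic interval-scale behaviour, not robustness to
platform artefacts in real arrays.

## Numerical choices and degenerate inputs

Exact tests accumulate in log space with a 1+10⁻⁷ tie tolerance (the
convention shared with standard implementations). The REML grid bounds
[10⁻⁵, 10⁵] act as soft variance-component limits; rank-deficient marker
fits fall back to p = 1. Kinship matrices must be symmetric and PSD to
1e-8 relative tolerance (the error names the offending eigenvalue); a
sample pair with no co-called marker is an error for IBS. Zero genotype
counts, empty p-value vectors, zero markers, all-samples-removed QC, and
infeasible simulation configs all raise typed, explicit errors rather
than degrade.

## Problem sizes used in the tests

The default simulated genome is scaled to two chromosomes so that a full
study simulates in ~3 s and the complete pipeline runs in ~5 s; the
recovery properties are measured over 50 replicate seeds. The exhaustive
oracle sweeps cover all Hardy–Weinberg triples with n ≤ 30 and all 2×2
tables with total ≤ 60; the genotypic 2×3 enumeration is cross-checked at
totals ≤ 40. Segment detection is verified against a quadratic
all-windows scan up to 10 cases × 200 markers.

## Known limitations

The per-marker REML Wald test shares the mild small-sample liberality of
its field-standard counterpart (variance-ratio estimation noise is not
propagated into the test); the interval detector's ends overshoot the
sequence-level truth boundary by a short run of chance-concordant markers
(≈ array resolution, measured ≤ 150 kb under defaults); and the
genotypic exact test's Monte-Carlo fallback yields a seeded estimate, not
an exact value, above the enumeration limit.
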