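# Methods

## Variant model and normalization

All analyses operate on *decomposed, trimmed allele-level records*.  A raw
VCF site with k alternate alleles becomes k records; each record's per-sample
genotype counts copies of the focal alternate only, with other alternates
treated as reference for that record and any missing index making the whole
call missing (so half-missing calls like `./1` are classed *missing*, the
conservative reading when only 0/0, 1/1 and ./. semantics are defined).
Phase is ignored throughout: genotypes compare as unordered index multisets.

Normalization removes shared trailing bases first, then shared leading bases
(incrementing the position), always leaving at least one base per allele.
There is **no reference-FASTA left-alignment**: the package is deliberately
self-contained, and for indels inside short tandem repeats two callers may
emit right- vs left-aligned representations that trimming alone cannot
reconcile.  Such keys fail to intersect and count as caller-unique — a known
divergence risk of reference-free matching, acceptable at the ~0.1% level it
affects and documented here rather than hidden.

Contig names are opaque strings; no "chr" harmonization is attempted.  Two
call sets with disjoint contig namespaces intersect to the empty set, and
`intersect_callsets` warns loudly when it sees that situation.

Coordinates are 1-based inclusive internally (VCF convention); BED input is
converted from 0-based half-open on read.

## Benchmarking conventions

A sample's variant set is the allele keys at which its genotype class is het
or hom-alt; hom-ref and missing calls are excluded from both truth and query
before the key intersection.  Derived rates:

- precision = TP/(TP+FP), recall (= recovery) = TP/(TP+FN), F1 harmonic mean;
- FN rate = FN / truth total;
- FP rate = FP / (TP+FP), i.e. over *query* positives;
- genotype concordance = concordant / TP, comparing genotype *class*
  (het vs hom-alt), which equals exact allele-multiset comparison for
  decomposed biallelic keys.

The FP-rate, FN-rate and concordance denominators are not arbitrary: they
are the unique conventions under which the reference study's printed counts
reproduce its printed percentages (verified as exact identities in the test
suite, e.g. 648,346/(3,921,247+648,346) = 14.19%).  Any ratio with a zero
denominator is reported as `None`, distinct from 0.  Percentages in reports
are rounded to two decimals; full precision is always available from
`performance_metrics`.

SNV and indel strata are separated before comparison; MNV records (equal
multi-base allele lengths) belong to neither stratum and are only reported
when explicitly requested.

## Call-set statistics and spectra

Transitions are A↔G and C↔T; all other substitutions are transversions.
Singletons are defined *within the analyzed cohort* (exactly one sample
carries the allele) — an external-database definition would need resources
the package deliberately does not depend on.  Multiallelic sites are counted
as distinct (contig, pos, ref) triples whose records carry the
multiallelic-origin flag, which survives VCF round trips via an INFO flag.

Substitution spectra use the 12 raw ref>alt classes (not the 6
strand-collapsed ones) so that C>T and G>A — the classes produced by cytosine
and 5-methylcytosine deamination in fixed tissue — remain separately visible.
Rates are calls per 10 Mb with Poisson standard errors √count on the same
scale; the genome size used as denominator is a required parameter with no
default, since no single value is defensible across genomes.

For an inflated spectrum *b* versus baseline *a*, the deamination enrichment
estimator is

    m̂ = mean(ratio_c − 1 over C>T, G>A) / mean(ratio_c − 1 over the rest)

which is exact in expectation under the injection model below and robust to
the overall extra-FP level.

## Hard filtering

Thresholds default to the standard GATK germline short-variant values (see
README table).  A record fails a criterion only when the annotation is
present and *strictly* violates the inequality; boundary values pass, and
absent annotations are skipped rather than failed (failing on absence would
mass-fail records that merely lack rank-sum annotations).  MNVs are evaluated
with SNV thresholds.  Each failure is recorded under its criterion name in
the FILTER column for auditability.  Filtering can be disabled wholesale for
callers that ship model-filtered output.

## Prioritization

The cascade is: case hom-alt → private (no control carries the alternate;
control genotypes 0/0 or ./. are acceptable, and keys absent from the control
call set count as missing everywhere, the permissive choice forced by not
having joint genotypes) → protein-changing (impact MODERATE or HIGH; missing
impact drops) → autosomes (an explicitly configured contig list; there is no
safe default) → critical interval (1-based inclusive ends).  Each case is
filtered against the controls independently; the shared column intersects
across cases per tier.  Tier counts are therefore monotonically
non-increasing, and adding controls can only shrink private tiers — both
asserted as properties in the tests.

The number of controls is a free parameter throughout (reference cohorts in
this design space run to ~1500 genomes; the simulations here use hundreds).

## Synthetic data generator

The generator emulates the statistical structure the analyses consume, not
sequencing physics: no reads, no coverage model, no reference FASTA.
Positions are abstract coordinates on a toy genome (default: 5 autosomes +
chrX + one unplaced scaffold, 10 Mb each — small enough for seconds-scale
tests); reference bases are drawn uniformly and are consistent only per
record.

- **Substitution classes**: transition with probability t/(1+t) for target
  Ts/Tv t (default 2.1), uniform within the transition/transversion groups.
  Second alternates at multiallelic sites (default fraction 0.1%, the level
  seen in genome-wide shared call sets) are drawn under the same law so the
  realized Ts/Tv stays on target.
- **Indels**: anchored 1–3 bp insertions/deletions, deletion probability
  d/(1+d) for target del/ins d (default 1.04).
- **Genotypes**: per-site Hardy–Weinberg with allele frequency f ~ Beta(a, b).
  The cohort het/hom-alt ratio is E[2f(1−f)]/E[f²] = 2b/(a+1), and
  conditioning on the site segregating in the sampled cohort cancels from the
  ratio, so the calibration b = target·(a+1)/2 (default target 1.35, a = 1)
  is exact in closed form; a quadrature check of this identity is in the test
  suite.  Non-segregating sites are rejection-resampled jointly with their
  frequency, i.e. drawn from the correctly conditioned model.
- **Caller errors**: records dropped with probability fn_rate; surviving
  genotypes class-flipped (het↔hom-alt) with probability genotype_error_rate
  per sample; round(fp_rate·n) false positives at fresh positions, SNV
  classes drawn at fp_ts_tv (default 1.0, matching the near-1 Ts/Tv that
  caller-unique calls show in practice).  False positives never collide with
  truth positions (a simplification; collisions would be rare and would blur
  the configured rates) and are genotyped het in every sample so per-sample
  precision is predictable from the configuration.
- **FFPE artifacts**: per substitution class c with current count n_c, extra
  false positives are Poisson with mean e·n_c for the ten non-deamination
  classes and m·e·n_c for C>T and G>A (defaults e = 0.08, m = 2.5, chosen to
  reproduce the 15–20% transition inflation reported for hard-filtered FFPE
  call sets against matched FF data).  Under this proportional design each
  class ratio satisfies ratio−1 = e (or m·e), making the enrichment estimator
  above exact.  With e = 0 the call set is returned unchanged regardless
  of m.
- **Cohorts**: background variants share Beta-drawn frequencies between cases
  and controls; controls are additionally missing at 2% per genotype.  The
  planted variant is hom-alt in every case, hom-ref or missing in every
  control, HIGH impact, and placed inside the requested interval.

Everything is deterministic given its seed, down to byte-identical VCF
output (headers carry no timestamps).

### What passing tests do and do not show

Because genotypes, error processes and artifact injection are exactly the
models the analyses assume, parameter-recovery tests validate the *bookkeeping
and estimators*, not robustness to real FFPE data: real artifacts cluster by
fragment end and sequence context, callers' errors correlate with depth and
mappability, and real multiallelic/repeat-region representation differences
are richer than suffix/prefix trimming covers.  Conclusions about real data
should rest on the arithmetic reproduction of the published benchmark counts
plus the structural properties, with the synthetic recovery showing internal
consistency.

## Numerical and reporting choices

- Undefined ratios are `None` end to end (JSON `null`), never 0 or NaN.
- QUAL and INFO floats survive VCF round trips at float32 precision
  (htslib storage); tests compare at rel. tolerance 1e−5.
- Problem sizes: statistical recovery runs at 100k variants (SE small enough
  that 3-sigma bounds are meaningful), cohort recovery at 100 seeds × 3 cases
  × 220 controls × 800 background variants; both complete in seconds on one
  core.
- Duplicate allele keys on read (two raw sites trimming to the same key) keep
  the first record and warn; at most one record per key is an invariant.

## Known limitations

- No haplotype-aware comparison (vcfeval/hap.py semantics) — a caller
  representing one event as two adjacent keys scores as FP+FN here.
- No reference-based left-alignment (above).
- Structural variants, CNVs and symbolic alleles are skipped on read.
- The FF concordance denominator for caller-vs-caller comparison is assumed
  to be TP, consistent with every verifiable table; one published cell could
  not be verified either way and is documented in `reference_tables`.
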