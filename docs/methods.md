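# Methods

## Scope and data model

`amplicall` models a multiplexed amplicon assay for ctDNA: a panel of short
amplicons (intended outer length 69–157 bp, matching cell-free DNA fragment
sizes) grouped into PCR pools of 7–8 primer pairs from distinct genes. All
internal genomic coordinates are 0-based half-open; conversion to 1-based
happens only when writing VCF. Panel files declare their coordinate dialect
in a header directive (`#coords=1-based-inclusive` or the default
`#coords=0-based-half-open`) and are normalised on load, so the same panel
expressed in either dialect yields identical in-memory coordinates.

Panel design rules (amplicon length range, pool size, one gene per pool)
are enforced as warnings, not errors: published panels contain edge cases
and a validation report is more useful than a refusal to load. The length
rule is applied to the *outer* span (forward-primer start to reverse-primer
end); assays quote amplicon sizes as final product length, which is the
outer span. Blacklisting every amplicon yields an empty active panel with a
warning rather than an error, so automated parameter sweeps do not crash.

## Read processing

Read pairs become *fragments* (the assignable unit — a PCR product maps as
one molecule, so assignment is per pair, not per read). Fragments are kept
iff properly paired with insert size strictly > 60 bp; shorter products are
primer dimers. Each mate is hard-trimmed to its first 80 bases from the 5′
sequencing end, discarding the error-prone 3′ tail. A fragment is assigned
to the amplicon whose outer coordinates both its ends match within a ±5 bp
tolerance; ties (overlapping amplicons) break by smallest total end
distance, then lexicographic amplicon id, so assignment is deterministic.
Fragments matching no amplicon are off-target and excluded.

Where the two trimmed mates overlap (overlap = 160 − fragment length, so
3 bp on a 157 bp amplicon, more on shorter ones) both mates contribute to
the pileup independently. This double-counts molecules at overlap positions
but leaves allele fractions unbiased, and fixes the VAF denominator
convention once for the whole pipeline. Base-quality recalibration is not
performed; qualities are taken as given from the aligner.

## Calling cascade

Candidate emission is pileup thresholding: ≥ 3 alt reads **and** alt
fraction ≥ 0.5% in a replicate. These two knobs sit well below the 1%
average-VAF gate that dominates final specificity and well above the
simulated noise floor (~0.11% per specific alternative allele at default
error rates); both are configurable. Pair filters (coverage > 100× in both
samples, normal VAF < 1%, plasma/normal ratio > 5) *flag* candidates rather
than delete them, mirroring how external-caller rescues re-enter the
cascade. A normal VAF of exactly zero gives an infinite ratio, which
passes: the ratio test is a contamination guard and zero normal evidence is
the cleanest possible case.

Consensus requires passing candidates in ≥ 2 of 3 replicates. The average
VAF is the mean of the pileup alt fraction re-measured in **all**
replicates (called or not), so a replicate that narrowly missed the
candidate thresholds still contributes its signal. The post-consensus
filter keeps variants with average VAF ≥ 1% **and** average ratio ≥ 5; the
removal clause could also be read as an OR of the two keep-conditions, so
`FilterConfig(avg_filter_mode="or")` provides the alternative reading. The
FFPE filter removes C>T/G>A transitions with average VAF < 15% (strictly
below; 15% exactly is kept) and is identity for non-FFPE samples. The
average-VAF and FFPE filters are independent predicates on a fixed record,
hence commute (property-tested).

The internal caller emits substitutions only. The record model carries
deletion/insertion allele classes, and indels from ingested external VCFs
flow through the same pair filters, but v1 does not discover indels itself.
VCF ingestion retains records whose FILTER is PASS or whose failing filters
are *all* within the rescue whitelist; any non-whitelisted token drops the
record.

## Longitudinal tracking

Per-sample calling is repeated unchanged for every timepoint (FFPE flag per
sample); the union of surviving variants is then force-genotyped — mean
depth and mean alt fraction across a sample's replicates at the exact
site/allele — in every timepoint. Sites with zero depth report a missing
VAF, not zero. The group filter keeps variants strictly exceeding 5%
replicate-mean VAF in at least one sample (replicate-mean rather than
best-replicate: the mean is what the per-sample cascade reports, and using
it keeps the single-sample reduction exact). When overlapping amplicons
cover a site, the amplicon with the higher mean depth supplies the
measurement, recorded in the VCF `INFO/AMP` field; pooling counts across
amplicons was the alternative and would double-weight the overlap region.
Output is one multi-sample VCF with `DP`/`AF`/`CL` per timepoint plus a
long-format monitoring table; collection day is metadata only.

## Simulator

The generator emulates a two-genome dilution benchmark: a "tumour" line
heterozygous at a few panel sites absent from the matched "normal" line,
mixed by volume across 12 points (defaults 100, 66, 50, 25, 10, 6, 4, 2, 1,
0.6, 0.4, 0.2%, spanning expected VAF 50% → 0.1%; the fractions are
configuration, never hard-coded in logic). Expected VAF is fraction/2
exactly (heterozygous site, linear volume mixing).

Sampling is two-stage, which is what makes low-input behaviour realistic:

1. **Template subsampling.** Input mass sets haploid copies at 303/ng
   (3.3 pg per haploid genome), so 10 ng ≈ 3030 copies. Per amplicon,
   amplifiable templates are Poisson around copies × a log-normal
   efficiency factor (σ = 0.15, mean 1), and alt templates are a binomial
   draw at the expected VAF. At 2 ng (~600 copies) this reproduces the
   stochastic coverage and VAF scatter low-input assays show.
2. **Read resampling.** Reads per amplicon are Poisson around
   target_depth × the same efficiency factor (zero if no templates); each
   read draws its allele at the *realised* template fraction.

Errors are substitutions only: an effective PCR error (per-cycle rate
3 × 10⁻⁶ × 30 cycles, a high-fidelity polymerase) applied once to the
amplified molecule so both mates inherit it, plus a per-mate sequencing
error (10⁻³, ~Q30). Together ≈ 0.11% per position, i.e. ~0.04% per specific
alternative allele — consistent with the ≤ 0.3% per-position background
noise that such assays report for 99% of targeted positions. An optional
`jackpot_rate` injects early-cycle template-level errors that propagate to
VAF-correlated false positives; it defaults to off.

What the simulator does **not** model: cfDNA fragment-length variation
(inserts equal the outer amplicon span), indel errors, strand bias,
position-dependent quality decay, index hopping, and alignment ambiguity
(simulated fragments have exact coordinates, so amplicon assignment is
trivially perfect — assignment tolerance is exercised by constructed
offsets in tests, not by the simulator). Passing benchmarks on simulated
data therefore demonstrate the correctness and calibration of the pipeline
logic, not performance on real sequencing artefacts.

Determinism: every stochastic step draws from one `numpy` Generator, so a
fixed seed reproduces byte-identical reads, SAM and FASTQ output.

## Benchmark machinery and problem sizes

The self-contained benchmark simulates the series on a 24-amplicon
synthetic panel (4 truth-site amplicons + 20 background amplicons, ~2100
targeted positions), 3 replicates, target depth 3000×, and evaluates:

- **Noise profile** — per-position mean non-reference fraction across
  replicates at truth-negative positions; zero-depth positions are missing,
  excluded from quantiles.
- **VAF linearity** — OLS of observed (re-genotyped per replicate) on
  expected VAF pooling all 12 points × 4 sites × 3 replicates, fitted with
  an intercept (the quoted "estimated coefficient" of such analyses is the
  slope; a through-the-origin option exists since the model form is a
  choice). Pooling replicates rather than averaging them uses all 144
  observations and is recorded as the package's convention.
- **Sensitivity/FP** — per point, detected truth sites; a false positive is
  any surviving call at a non-truth (position, allele), summarised at the
  3% and 5% VAF thresholds.
- **Germline-pair protocol** — two germline-identical samples run through
  the cascade in both role orders; every call is a false positive by
  construction.

These problem sizes keep a full 12-point benchmark under ~10 s on one core
while leaving per-site binomial noise small relative to the acceptance
margins; unit tests use further reduced depths (50–1500×) chosen so that
3-standard-deviation bounds still discriminate.

## Known limitations

- No indel discovery in the internal caller (ingestion only).
- No unique-molecular-identifier support; replicate consensus is the only
  duplicate-noise control, as in the assay modelled.
- The naive exact-geometry SAM round-trip assumes simulator-style fragments;
  real aligned BAMs with soft-clips or variable spans flow through the
  per-fragment (slower) pileup path.
- Background-noise and FP behaviour inherit the uniform error model; real
  panels show position- and context-specific error (e.g. the occasional
  amplicon with an extreme mismatch rate, handled here by the blacklist
  mechanism rather than modelled).
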