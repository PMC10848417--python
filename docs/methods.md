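# Methods

This note documents the statistical models, the defaults and why they were
chosen, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Detection power

A site covered by `n` effective independent observations (molecular tags
for the UMI assay, reads for WES) and called when at least `m` alternate
observations appear has detection probability `P[Binomial(n, v) ≥ m]` for a
variant at true allele fraction `v`. The package defines minVAF₉₅% as the
smallest `v` whose tail reaches the confidence target (default 0.95), found
by bisection on the exact binomial survival function to an absolute
tolerance of 1e-6. The tail is continuous and strictly increasing in `v`,
so bisection is exact up to tolerance; unit tests verify that the tail at
the returned value meets the target and at `v − 2e-6` does not.

minCCF₉₅% is minVAF₉₅% pushed through the CCF conversion at the site's
purity and copy number, evaluated at multiplicity `s = 1`. This is the
conservative choice — a mutation on more than one allele is easier to see —
and per-`s` values remain available through the CCF engine.

**Calling-rule defaults.** Upstream UMI callers do not expose a single
closed-form threshold, so the package models calling as "`m` alternate
molecular tags". `m = 8` for the UMI model places the median minCCF₉₅% at
~3% of tumor cells for ~1200× MT coverage and typical (~0.7) purity, and
~0.9% above 4000×, matching the sensitivity profile this class of assay
reports. The WES model uses 50× coverage with `m = 5` alternate reads,
which puts the WES median minCCF₉₅% at ~0.5 — the familiar statement that
WES cannot reliably call mutations below roughly half of tumor cells — and
yields a ~15-fold UMI-over-WES sensitivity ratio at these depths. `m = 4`
was considered for WES and rejected during calibration: it implies a WES
floor of ~0.42 and a ~13-fold ratio, both farther from the reported
behavior of 50× exomes. Both models are plain dataclasses and fully
configurable.

## CCF estimation and multiplicity

For purity `p`, locus tumor copy number `n_t`, normal copy number `n_n`
(default 2) and multiplicity `s`:

    CCF = VAF · (p·n_t + (1−p)·n_n) / (p·s)

`n_t` is the per-segment `major_cn + minor_cn`, not a ploidy average.
Because `s` is unknown, the engine enumerates `s ∈ {1..major_cn}` and
reports the median across candidates; a single candidate is flagged
unambiguous (only one allele could carry the mutation), which is also the
gate for the pigeonhole test. CCFs above 1 are reported unclamped with a
flag — truncation would hide exactly the inconsistencies (purity or CN
mis-estimates) a reviewer needs to see.

Posterior draws use a Jeffreys Beta(½, ½) prior on VAF: with molecular-tag
counts in the hundreds to thousands the prior's influence is negligible,
and Jeffreys is the standard objective default at low counts. Only count
uncertainty is propagated; purity and copy number are treated as fixed
inputs, so posterior widths understate total uncertainty when those are
poorly known.

## FFPE artifact burden and UDG depletion

Rare-subclonal burden counts called variants with VAF strictly below 0.10
(the boundary value is excluded, following the rare-subclone definition) at
covered panel sites, panel-wide and per trinucleotide context. Contexts use
the 96-class pyrimidine-centered convention; a context the panel does not
cover has an *undefined* rate (NaN), never 0.

Deamination is specific to C>T, so the artifact signal is isolated as an
*excess*: the C>T per-site rate minus the mean per-site rate of the five
non-C>T substitution types in the same sample. UDG depletion is

    1 − excess_treated / excess_untreated

with counts pooled across matched treated/untreated pairs before the ratio
(mean-of-ratios is unstable at the low counts a 2.4-kb panel produces).
Uncertainty comes from a seeded bootstrap (default 1000 iterations) that
resamples covered sites with replacement; the estimator is invariant to
uniform rescaling of covered-site counts by construction. When the
untreated samples show no positive C>T excess the depletion is undefined
and the package raises an explicit error rather than returning a number.

## Clonal strata and pigeonhole co-clonality

Mutations are assigned to strata: **major** (called, median CCF ≥ 0.50),
**minor** (called, CCF < 0.50), **rare** (called, VAF < 0.10), and
**undetected** (covered but not called; annotated with the site's
minCCF₉₅%, the strongest available statement about its abundance). When low
purity makes a VAF < 0.10 mutation exceed CCF 0.50, *rare* takes precedence
— the rare definition is VAF-based and only approximately maps to CCF — and
the conflict is flagged. Sites with fewer than 100 MTs are excluded from
detection tallies as inadequately covered.

Two mutations whose CCFs sum to more than 1 must share cells, placing them
in one clonal lineage (the pigeonhole principle). The test reports
`P(CCF_a + CCF_b ≤ 1)` by Monte-Carlo over independently resampled
posterior draws (default 10⁷ draws, seeded, with a Wilson interval). When
the Monte-Carlo count is 0 the analytic Gaussian tail — matched to the
posterior moments — is reported instead, since genuine co-clonality tails
can sit below Monte-Carlo resolution; both numbers are exposed. The test
refuses loci with ambiguous multiplicity. By the same principle, all
mutations at CCF > 0.50 in one sample form a sequentially acquired lineage;
the size `k` of that set feeds the likelihood framework. For a patient's
undetected mutations, the size of a hypothetical nested ancestral subclone
carrying all of them is bounded by min(ancestral CCF, smallest minCCF₉₅%
among the undetected sites).

## False-positive significance

The artifact model sets each assayed site's false-detection probability
`q` from the same sample's background burden — panel-wide, or per
trinucleotide context with fallback to the panel-wide rate where the
context is uncovered (fallbacks are recorded). Background burden excludes
the assayed target sites themselves to avoid contamination. The number of
artifactual detections is then Binomial (panel-wide) or Poisson-binomial
(per-context), whose exact tail is computed by the standard O(n²) dynamic
programming convolution; the DP reduces to the scipy binomial closed form
when all `q` are equal (tested to 1e-12).

Per-patient tails are combined by Fisher's method (the default, because it
yields a calibrated combined P); the raw likelihood product is emitted
alongside in log10 for comparison with product-style summaries. Because
the per-patient tails are discrete, both are conservative — the null
distribution of the combined P is stochastically larger than uniform —
which the calibration tests check as "type-I error at most nominal", the
property that actually matters for the claim.

The sample-permutation test reassigns each patient's assayed
metastasis-specific site list to unrelated primaries and recomputes the
total detection count (a per-patient indicator statistic is available).
Site/primary combinations lacking adequate coverage are counted
unassayable and recorded. Small cohorts are enumerated exhaustively (≤ 8!
assignments); larger ones use Monte-Carlo with the add-one estimator
`P = (#{stat ≥ observed} + 1)/(n_perm + 1)`, n_perm defaulting to 10 000.

## Sequential-acquisition likelihood framework

The probability (up to a proportionality constant that cancels in every
comparison) that a series of `k` mutations, `d` of them drivers, arises
sequentially in one clonal lineage of a `T`-cell tumor at per-site
per-division mutation probability `μ`, each driver expanding its clone to a
fraction `c` of the tumor:

    P_sequence(k, d) ∝ (1 − (1−μ)^{Tc})^d · μ^{k−d−1} · (1 − (1−μ)^T)

Each driver factor is the probability that a Poisson hit lands in the
expanded pool; passengers do not expand, forcing each remaining mutation
into the same cell (a bare factor μ). Setting `d = 0` gives the passenger
model, bounded by `μ^{k−1}`; the passenger:driver ratio is
`(μ / (1−(1−μ)^{Tc}))^d`, which saturates to `μ^d` when `Tcμ ≫ 1`.
Everything is computed with `log1p`/`expm1` in log space; values whose
exponents undershoot double precision report `value = 0.0` with a finite
`log10`. `k` and `d` may be fractional, since cohort averages are legal
inputs. A series required to stay below a CCF ceiling `f` (a sub-majority
lineage, or the assay's ~3% detection floor) is evaluated with `c = f`.

Two defaults are deliberately named config values rather than constants in
science code: `μ = 10^−4.5`, the per-site rate at which the saturated
ratio `μ^d` reproduces the cohort-scale relative likelihoods this framework
is used to report; and a pipeline pool size `T = 10⁶` cells for the
bounded-expansion stage, the magnitude at which a bounded per-step hit
probability `1 − e^{−μTf}` is meaningfully below 1 (at `T ≫ 10⁶` the
bounded model saturates and discriminates nothing). Both are exposed on
`RunConfig`.

Deliberate omissions: no birth/death rates, no time-varying μ or T, no
acquisition-order modeling — the framework compares models that share these
simplifications, so they cancel to first order.

## Synthetic-data generator

The generator emulates the statistical structure of a 21-patient paired
primary/metastasis UMI panel study; its defaults are the study conditions
and are not tuned per test:

* panel of 204 regions of 11–22 bp (~2.4 kb covered), random reference
  sequence for trinucleotide contexts; one CN segment per chromosome,
  (major, minor) = (2, 1) with probability 0.2, else (1, 1);
* per-patient purity Uniform(0.55, 0.85) — archival breast FFPE material
  centers near 0.7; ploidy 2;
* MT depth log-normal with median 1160× and σ = 1.1 (reproducing an IQR of
  roughly 600–2600×), clipped to the assayable range [100, 6000];
  metastasis blocks at median ~400×; WES at 50×;
* per-patient assayed metastasis-specific driver counts log-normal with
  median 3 (IQR ~1–8), capped at 33; a fraction 0.925 of them
  post-dissemination (true primary CCF = 0), the remainder in rare primary
  subclones with CCF log-uniform on [0.015, 0.30];
* metastasis CCFs of those drivers log-uniform on [0.5, 1.0]; 4 truncal
  mutations per patient at CCF 1; background somatic rare variants at
  2×10⁻³ per covered site;
* FFPE C>T artifacts at 0.03 per covered C-context site in untreated
  blocks, thinned by (1 − UDG efficiency) in treated ones (efficiency
  default 0.9), with VAF ~ Uniform(1/depth, 0.05);
* calling simulated as "≥ 8 alternate MTs" (WES: ≥ 5 alternate reads),
  matching the detection-power defaults.

Counts are binomial given true VAF; everything is deterministic under the
config seed. Subclone CCFs are assigned, not grown — the pipeline's tests
need controlled clone sizes, not growth kinetics (the likelihood framework
has its own simulation oracle).

**What passing tests show, and what they do not.** The generator produces
independent binomial sampling at known truth, so the tests demonstrate
calibration and correctness of the estimators *under the stated model*:
detection at minCCF₉₅% lands at 95% ± 2%, CCF recovery error is small at
depth ≥ 1000, UDG depletion recovers injected efficiencies, the
significance tests are conservative on nulls. Real data add features the
generator does not emulate — site-specific error rates, UMI family-size
artifacts, purity/CN mis-estimation, spatial heterogeneity between blocks,
kataegis — so passing here does not certify performance on those axes.

## Reconstructed rare-subclone input table

`raresub/data/rare_subclone_inputs_reconstructed.tsv` is a synthetic
stand-in, not measured data: molecular-tag counts, purities and
allele-specific copy numbers for the nine rare-subclone driver detections
of the motivating cohort, constructed once so that the CCF engine
reproduces the per-patient point estimates reported for that cohort (PEAK1
at VAF 0.062 → CCF 0.24 with one mutable allele; the cohort median across
mutations 0.073; minimum 0.019; maximum ~0.28). It lets worked examples
and summary recomputations run without the original per-site supplementary
tables. The reconstruction pins per-patient point values, not the full
per-site uncertainty, so cohort dispersion statistics other than
min/median/max are not faithful.

## Numerical and engineering choices

* Coordinates: variant tables are 1-based; BED is 0-based half-open and
  converted on read. Contexts always on the pyrimidine strand.
* Required variant-table columns: patient_id, sample_id, chrom, pos, ref,
  alt, mt_alt, mt_total, called; everything else optional and preserved,
  so supplementary-style exports with extra columns read cleanly.
* Validation errors carry row numbers; schema errors name the missing
  column.
* Degenerate inputs are explicit signals, not silent defaults: homozygous
  deletions (no mutable allele), depth below the calling threshold
  (detection impossible), empty spectra, undefined depletion, undefined
  metspec:truncal ratio (no truncal mutation above the floor).
* Acceptance-scale summaries pool detection-power tables over replicate
  cohorts drawn from the same conditions: the estimand is a property of
  the depth/purity/CN distributions, and pooling shrinks only the
  Monte-Carlo error of its estimate. Problem sizes used: one 21-patient
  cohort for detection fractions (~100–130 assayed sites), ~2000 pooled
  site draws for power medians, 5 matched block pairs (~24 000 site
  observations) for UDG depletion.

## Known limitations

* The binomial detection model ignores site-specific substitution error
  rates and UMI consensus errors; the calling rule is a single-threshold
  abstraction of a more complex caller.
* CCF posteriors omit purity/CN uncertainty.
* The permutation test conditions on observed coverage patterns; with very
  uneven panels the "unassayable" accounting can make permuted statistics
  non-exchangeable in the extreme.
* The likelihood framework treats mutation generation events as
  independent and unordered; ordering arguments would only widen the
  driver-vs-passenger gap, so the reported ratios are conservative in that
  direction.
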