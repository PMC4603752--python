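# Methods

This note records the statistical model behind `speccount`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for reproducing its
output.

## Identification model

PSM-level filtering keeps charge ≥ 2 and peptide length ≥ 6 — short and
singly charged peptides identify unreliably on ion-trap instruments.

**Target-decoy FDR.** With targets and decoys searched together, the error
of the set accepted at score threshold s is estimated as
FDR(s) = D(s)/max(1, T(s)), the simple concatenated-search convention
(not 2D/(T+D)). Per-PSM q-values are the running minimum of FDR over
thresholds at or below the PSM's score, so q never increases with score,
and the accepted threshold is the lowest score with q strictly below the
cutoff (default 0.01). This is provably the threshold that maximizes
accepted targets subject to the estimated-FDR bound, and the test suite
checks it against exhaustive threshold search on small instances. Ties at
the threshold are accepted together. Zero decoys give q = 0 everywhere.

**Protein grouping.** Accessions with identical distinct-peptide sets merge
into one group (id = sorted accessions joined with `;`). Each peptide is
*counted* toward exactly one group — the one with more distinct peptides,
ties broken by lexicographically smaller group id (razor rule) — so counted
peptides partition and no spectrum is double-counted. The group probability
is the noisy-OR of its peptides' best PSM probabilities,
P = 1 − ∏ᵢ(1 − pᵢ): the chance that at least one supporting peptide is
correct, assuming independent peptide-level errors. It is monotone in both
the number of peptides and each probability. Peptide probabilities are
taken from the input as produced upstream; no rescoring model is fit here.
Groups are retained with ≥ 2 peptides and probability ≥ 0.7. The noisy-OR
is a deliberate modeling choice standing in for the proprietary "group
probability" of commercial validation tools, which do not publish a
formula; any monotone combination rule would order groups similarly at the
high-probability operating point used here.

## Quantification

Raw counts are integers (spectra per razor group per injection).
Normalization is total-spectral-count scaling: sample s is multiplied by
mean(totals)/total(s), so every normalized total equals the grand mean, the
grand total is conserved to 1e-9 relative, and within-sample ranks are
unchanged. A sample with zero total is an error (corrupt input), never
silently dropped. NSAF-style length normalization is intentionally out of
scope: protein lengths are not part of the input contract.

## QC metrics and fold-change calibration

Reproducibility of repeated QC injections is computed on ln N-SC over
proteins nonzero in every compared run: pairwise Pearson R, and
RSD% = 100·sd(ln N-SC)/mean(ln N-SC) per protein (sample sd, n−1),
averaged over proteins with positive mean. Under a multiplicative model
ln N-SC = ln a + ε with between-protein spread σ_a and per-run technical
noise σ_e, the expected pairwise R is σ_a²/(σ_a² + σ_e²).

Calibration uses replicate runs of a control experiment. Eligible proteins
are nonzero in all runs with mean ln N-SC inside the interquartile range of
the per-protein mean distribution ("inner-quartile"), trimming both the
noisy low-abundance tail and saturated high abundance. Over all unordered
run pairs, d = |Δ ln N-SC| is collected; the cutoff is exp of the
*inclusive* empirical quantile (smallest d with ≥ coverage of points ≤ d),
which guarantees achieved coverage ≥ requested on every input. Pairs with a
zero in either member are excluded rather than pseudocounted: ln is
undefined and calibration should reflect measurable signal. For Gaussian
ln-noise, d ~ |N(0, σ_e√2)| and the 99% cutoff converges to
exp(2.576·σ_e√2); at σ_e = 0.10 that is ≈ 1.44, and ≈ 99.6% of points fall
within ±1.5-fold — the rationale for the operational 1.5-fold threshold.
The calibration's Pearson R is reported on the IQR-restricted points by
default (`iqr_restrict`); note range restriction lowers R relative to the
all-protein QC report, and both are exposed.

In the full pipeline the calibration runs on QC injections in the control
depot when present, else on the control group's biological samples. The
calibrated cutoff only replaces the operational 1.5 when
`use_calibrated_fc` is set, because at ordinary spectral-counting depths
counting noise dominates run-level noise and the empirical cutoff is much
wider than 1.5 (the demo run calibrates to ≈ 8 at median expected counts of
~5); the 1.5 value corresponds to the high-depth, low-noise control regime.

## Differential calling

Per protein and depot, with diabetic as the case group:

- **Commonality** on *raw* counts ("observed" = at least one spectrum):
  pass if the nonzero fraction is strictly > 0.5 in at least one group.
- **Wilcoxon** rank-sum on N-SC, two-sided. For ≤ 14 total observations the
  p-value is exact by full enumeration of the C(n, n₁) group assignments of
  the observed multiset using midranks, so ties are handled exactly; above
  that, the tie-corrected normal approximation without continuity
  correction. All-identical input returns p = 1.
- **Fold change** on pseudocount-adjusted group means of N-SC,
  c = 0.5 by default: FC = +r if r = (m̄_d + c)/(m̄_n + c) ≥ 1 else −1/r, so
  |FC| ≥ 1 always and FC(a,b) = −FC(b,a) away from the r = 1 boundary.
  Means (not medians) are the spectral-counting norm; a median estimator
  would be available by operating on the same matrix externally.

Significance is the conjunction of the three flags and is order-invariant.
**No multiple-testing correction is applied**: the operating rule is a
per-protein p ≤ 0.05 guarded by the fold-change and commonality filters.
This matches the study design the pipeline implements, and users screening
large panels for discovery should treat the output as a ranked candidate
list, not an error-controlled set.

Cross-depot overlap intersects identified and significant sets and counts a
shared significant protein as concordant when its fold-change signs agree.

## Cohort statistics

Binary traits: Pearson chi-square on the 2×2 table *without* Yates
correction, χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1 — the variant
that reproduces standard clinical-table p-values for moderate n.
Continuous traits from summaries (n, mean, sd per group): Welch's t with
Satterthwaite df, preferred over the pooled test because group variances in
clinical tables are routinely unequal.

## Synthetic data

The generator emulates the target study's structure: ~600 protein groups,
20 vs 22 subjects, two depots, ~5000 expected spectra per sample, 9 QC
injections of one high-abundance omental specimen.

- Baseline abundances aᵢ ~ LogNormal(0, σ_a = 1.0).
- A fraction (default 0.05) of proteins is differential; the diabetic mean
  is multiplied (sign +) or divided (sign −) by |FC| ~ U(2, 8). A quarter
  of each depot's differential set is shared between depots with identical
  signed FC, to exercise concordance.
- Per-sample depth varies lognormally (sd 0.25) around `mean_depth`;
  expected counts are depth × normalized abundance.
- Counts are negative binomial with var = μ + dμ² (d = 0.2 by default;
  spectral counts are overdispersed Poisson). **d = 0 is the deterministic
  rounded-expectation limit**, not Poisson: it removes counting noise
  entirely, which is the regime in which the QC closed forms above hold and
  in which noiseless replicates yield cutoff = 1, R = 1, RSD = 0
  simultaneously. Near-Poisson behavior is available with small positive d.
- The QC experiment (`simulate_qc_experiment`) scales its base abundances
  to `qc_mean_depth` = 5×10⁵ expected spectra so that rounding error is
  second-order relative to the per-run ln noise (σ_e = 0.10); the in-study
  QC columns instead reuse a realized biological column at study depth,
  which is why their R (~0.77) and RSD (~25%) resemble noisy real QC data.
- PSM expansion gives each protein 2–10 unique random peptides (lengths
  6–30, charges 2–3), probabilities Beta(20, 1), target scores N(6, 0.8);
  decoys (0.3 per target) score N(1, 0.4), well below targets, so 1% FDR
  filtering recovers essentially all target spectra and the
  expand→identify→count round trip is exact when protein-level filters are
  non-binding.
- All randomness derives from `rng_seed` through numpy's PCG64
  (`np.random.default_rng`); outputs are bit-reproducible for a fixed numpy
  version.

What the generator does **not** emulate: peptide-level detectability and
length/charge biases, shared peptides between unrelated proteins (razor
behavior is tested on hand-built cases instead), missingness mechanisms
beyond sampling zeros, batch drift across injections, and subject-level
covariates (medication, lipid status). Passing tests therefore demonstrate
correctness of the statistical machinery under the stated count model, not
robustness to every artifact of real LC-MS data.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale simulations chosen to estimate each
quantity to useful precision: 2000 proteins for null-rate and calibration
experiments (binomial se ≈ 0.5% at p = 0.05), 600 proteins for parameter
recovery, 10⁵-point Gaussian samples for quantile closed-form checks.
Wilcoxon exactness is enumerated to 10 observations against an independent
U-statistic oracle; the implementation switches from enumeration to the
asymptotic form at 14. Fold changes are written with 2 decimals and an
ASCII leading `-` for decreases, p-values with 3 decimals; files are
tab-separated UTF-8 with headers. Ties in the razor rule and in FDR
thresholds are broken deterministically (lexicographic id; accept-together),
so reruns are byte-identical.

## Known limitations

- The noisy-OR group probability is a stand-in for upstream tools'
  unpublished group-probability models.
- Total-count normalization assumes most proteins are not changing; strong
  compositional shifts bias fold changes (mitigated but not removed by the
  commonality and FC guards).
- The exact reference normalization and ratio estimator of legacy
  commercial pipelines cannot be verified; TSC-to-mean scaling and group
  means are declared choices.
- Under the default generator (overdispersed counts at median expected
  count ≈ 5), the three-filter conjunction flags ≈ 2.3–2.5% of null
  proteins: the Wilcoxon stage is calibrated at 5%, but at low counts the
  fold-change estimate is positively correlated with the rank statistic, so
  the conjunction rate exceeds the α·P(|FC| ≥ 1.5) product that independence
  would suggest. Deeper sampling or a variance-stabilized FC estimator
  would lower it.
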