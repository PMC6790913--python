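# Methods

## Data model and conventions

The pipeline consumes MaxQuant `proteinGroups`-dialect tables: one row
per protein group with per-sample `Intensity <label>` (and optionally
`iBAQ <label>`) columns and `+`-encoded `Reverse` / `Potential
contaminant` flags. An intensity of 0 — including an empty cell —
means *not detected*; no downstream computation treats 0 as a measured
abundance, and no imputation is performed anywhere. Decimal separator
is `.`, fields are tab-separated; there is no locale sniffing.

Keratins are identified by gene symbol (default pattern: `KRT`
followed by a digit, case-insensitive, matched against each
semicolon-separated symbol), with a user-supplied explicit list as an
override. This matters because keratins are simultaneously genuine
epidermal proteins and the canonical laboratory contaminant: rows
*flagged* as contaminants are removed outright, while unflagged
keratin rows are retained and corrected by blank-run subtraction.

## Preprocessing

Order is fixed: **filter → blank-subtract → normalize**.

1. *Filtering.* Rows flagged reverse (decoy) or contaminant are
   removed; a row with both flags is counted once, under reverse.
2. *Blank subtraction.* The keratin background estimated from blank
   instrument runs is subtracted from every sample of each keratin
   row, flooring at 0 (a background estimate exceeding the signal
   yields "not detected", not a negative abundance). A single
   per-protein blank value applied to all samples is the default; a
   per-sample blank table is accepted, since runs may differ.
   Subtraction precedes normalization so that blank keratin mass
   cannot distort the per-sample scale factors.
3. *Normalization.* Each sample is scaled by
   `target / total`, where `total` is its summed intensity and
   `target` the smallest such total across samples ("adjust to the
   lowest total protein yield"). All factors are ≤ 1; within-sample
   ratios are preserved exactly; iBAQ columns are scaled by the same
   factor so the two quantifications remain mutually consistent.

iBAQ is summed tryptic-peptide intensity divided by the number of
theoretically observable peptides; a zero peptide count yields NaN
with a warning rather than an error, since such rows can still carry
raw intensity.

QC follows the study's two instruments: per-sample histograms of log2
iBAQ over detected proteins (bin width 1.0 log2 unit by default,
optionally normalised counts), and pairwise Pearson correlation of
log2 quantities computed over proteins detected in *both* members of
a pair (complete-case, because 0 means undetected); pairs sharing
fewer than 3 detected proteins report NA. Whether the original QC
used iBAQ or raw intensity is not documented; log2 iBAQ is the
default and raw intensity is available via `use="intensity"`.

## Differential analysis

*Technical aggregation.* Quadruplicate runs are collapsed per
(protein, donor, condition) to the arithmetic mean of the runs in
which the protein was detected (0 if none). The aggregation rule is a
package choice — the original analysis reports donor-level ratios
without stating one — and the detected-run mean avoids diluting a
real signal with censored zeros.

*Ratios.* r_d = KD_d / NT_d is defined only when both sides are
detected. Donors missing an entire condition are excluded with a
warning.

*Eligibility.* A protein enters the volcano and the classifier when
detected (in either condition) in ≥ 3 donors. The alternative
ordering — classify first, filter later — is available by applying
`classify_all` to the unfiltered ratio table, but filter-first is the
default.

*Consistency classification* (defaults: down_ratio 0.5, up_ratio 1.2,
max_undetectable 2, min_qualifying 3):

- DOWN requires every defined ratio < 1 (direction agreement in all
  donors), ≥ 3 qualifying reductions, and ≤ 2 KD-undetectable donors.
  A donor with the protein detected in NT but lost in KD counts as a
  qualifying reduction — the cap on undetectable donors only makes
  sense if such donors can otherwise qualify.
- UP is symmetric on defined ratios (> 1 everywhere, ≥ 3 donors at
  ≥ 1.2) with two asymmetries that the undetectable cases force:
  a KD-lost donor is an *observed reduction* and disqualifies UP,
  whereas a donor with the protein absent from NT gives no usable
  ratio and neither qualifies nor disqualifies (so a protein absent
  from every NT sample is ineligible rather than infinitely
  up-regulated — the conservative reading).

These thresholds produce mutually exclusive calls for any
configuration with down_ratio < 1 < up_ratio, and they are monotone:
tightening a magnitude threshold can only remove calls. Both
properties, and exhaustive agreement with an independently coded
brute-force transliteration of the rule over a grid of ratio vectors,
are enforced by the test suite.

*Volcano.* x = mean over defined donors of log2 r_d; y = two-sided
paired t-test on log10-transformed donor-level aggregates over donors
with both sides detected, df = pairs − 1, *unadjusted* — the
classification deliberately never uses p, so no multiplicity
correction is applied or needed. Zero-variance differences are
flagged and reported as NA rather than ±inf. Ratios are computed on
normalized raw intensity; iBAQ serves QC (configurable).

## Over-representation analysis

For query size n inside a universe of N genes, a set with K members
in the universe and k in the query scores p = P(X ≥ k),
X ~ Hypergeometric(N, K, n) (scipy's survival function; exactness
against rational-arithmetic enumeration is tested to 1e-12 for all
N ≤ 30). One-sided over-representation only. q-values are
Benjamini–Hochberg across all tested sets (statsmodels). The
recommended universe is the post-filter quantified proteome, not the
genome — enrichment against the genome mostly rediscovers what is
expressed. Gene identity is by upper-cased symbol; multi-symbol
protein groups contribute each symbol once. External database
statistics (network enrichment, hierarchy-aware pathway tests) are
out of scope; this module supplies the generic ORA math for
user-provided GMT collections.

## Assay statistics

- qPCR: ΔCt = Ct_target − Ct_reference per condition; ΔΔCt =
  ΔCt_KD − ΔCt_NT per matched replicate; fold = 2^−ΔΔCt. Fold changes
  are computed per replicate and then summarised (mean ± SEM); the
  alternative of exponentiating the mean ΔΔCt is a one-liner away but
  not the default.
- Histology: each slide's layer thickness is the mean of three
  positions (right, middle, left — order-invariant); per replicate
  and layer the KD/NT ratio; per layer mean ± SEM of ratios plus a
  paired t-test on the per-replicate means. SEM is sd/√n with the
  sample (n−1) standard deviation throughout the package.
- Lipids / functional measurements: element-wise KD/NT ratios with a
  t-based 95% CI (on the ratio scale by default; a log2-scale
  geometric option exists), and mean-of-k for repeated probe
  measurements.

## Synthetic data generator

log2 intensity of protein p in sample (d, c, t):

    mu_p + delta_d + beta_p * 1[c = KD] + eps,
    mu_p ~ U(20, 30),  delta_d ~ N(0, donor_sd),  eps ~ N(0, tech_sd)

censored to 0 below the detection limit. Defaults encode the study
design: 4 donors × 2 conditions × 4 technical runs, 9000 proteins, 5%
planted DOWN at beta = −2.0 and 5% UP at +0.5 (chosen near the
1.2-fold threshold so UP calling is genuinely hard), donor_sd 0.5 and
tech_sd 0.25 log2 units, detection limit at the 2nd percentile of the
baseline means. The donor effect is shared between a donor's KD and
NT samples, which is exactly why the paired design cancels it. On
top: 10 contaminant keratins with condition- and donor-independent
means (lab background), 100 reversed decoys drawn from the null model
so decoy removal is exercised non-trivially, and 6 endogenous
keratins among the null proteins so blank subtraction acts on
retained rows. The blank run returns a fixed fraction (default 0.3)
of each keratin row's mean intensity. All outputs are pure functions
of the configuration seed.

Assay fixtures plant a ΔΔCt of 3.0 cycles (strong mRNA knockdown)
over 8 replicates with 0.15-cycle technical noise, and a
stratum-corneum thinning ratio of 0.83 (viable cell layer 1.0) over
10 replicates, with log2-scale replicate ratio noise (sd 0.25) sized
so the SEM of the mean ratio is about 0.05, plus 10% per-position
measurement noise. Gene-set fixtures emit one set enriched for each
planted class at configurable purity plus uniform null sets.

What the generator does *not* emulate: peptide-level effects and
shared-peptide protein grouping, intensity-dependent missingness
beyond hard left-censoring, batch effects other than donor,
correlated proteins (regulated modules), or heavy-tailed measurement
error. Passing tests therefore demonstrate correctness of the
*computations* under a clean version of the design, not robustness to
every pathology of real LC-MS/MS data.

## Numerical and degenerate-case choices

- Post-subtraction negatives floor at 0; a sample with zero total
  intensity is a hard error naming the sample.
- Normalization equality of totals holds to ~1e-15 relative; the
  contract demands 1e-9.
- Paired t with < 2 usable pairs or zero-variance differences returns
  NaN (flagged) instead of raising, so one degenerate protein cannot
  abort a 9000-protein run.
- Hypergeometric p is clipped into (0, 1]; k = 0 short-circuits to 1.
- ORA rows sort by p with ties broken by set name, making output
  order deterministic; BH q-values are computed before sorting, over
  all tested sets.
- Result tables serialise NaN as `NA` and round-trip through the
  matching readers to 1e-12 relative.

## Known limitations and an honest benchmark note

A protein whose knockdown abundance falls below the detection limit
in three or more donors cannot be called DOWN: the undetectable cap
of the published rule excludes it, by design. Under the default
generator settings (baseline means spanning 10 log2 units, a −2
planted effect, censoring at the 2nd percentile) this puts roughly a
fifth of the planted-DOWN proteins out of reach, so DOWN sensitivity
plateaus near 0.8 — every miss in the benchmark is a fully censored
protein, not a classification error, and the recovered effect size
for called proteins is unbiased. Raising the planted effect or
lowering the detection limit would cosmetically raise sensitivity;
the defaults are kept because they mirror the intended study
conditions. Acceptance-script problem sizes (9000-protein main run,
100 small tables for the normalization sweep, 2000 calibration
simulations, exhaustive N ≤ 30 hypergeometric sweep) are the
package's chosen benchmark sizes and complete in well under a minute
each on one CPU.
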