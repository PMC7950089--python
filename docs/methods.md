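# Methods

This note documents the statistical models, conventions and design choices
behind `prosal`, stage by stage, together with what the synthetic-data
generator does and does not emulate.

## Study design assumed throughout

A two-group observational design: saliva samples from patients without
(pN0) and with (pN+) pathologically confirmed lymph-node metastasis,
measured once each by label-free LC-MS/MS at the discovery stage, and a
separate verification cohort measured as technical triplicates by SRM
against heavy-labeled internal standards. Defaults reflect a small
discovery cohort (12 vs 13 samples) and a 14 vs 26 verification cohort.

## Quantitative filtering and differential analysis (`quantops`)

* **Missing ≠ zero.** An absent cell (``.`` or empty in TSV) is a missing
  measurement; a recorded 0 is a present value and counts as valid. All
  filters and statistics use present values only; no imputation anywhere.
* **Quality filter.** Search-engine exports carry a per-feature quality
  score; rows below the threshold (default 8, read as the minimum
  acceptable score, so quality = 8.0 is kept) are dropped. The score's
  internal definition is proprietary to the upstream software; the
  synthetic generator emits a stand-in proxy on [0, 20] whose only modeled
  property is the fraction falling below the threshold.
* **Valid-value rule.** A peptide must have at least one present value in
  *both* groups (configurable). Quality and valid-value filters are pure
  row predicates, hence idempotent and commuting; a test asserts this.
* **Normalization.** Per-sample median equalization by default (each
  sample's median of present values scaled to the across-sample mean of
  medians); total-sum normalization optional. The upstream "normalized
  precursor intensity" algorithm is unspecified, so the conventional
  median method is used. Pipeline order is fixed and logged: quality →
  valid-value → normalize → test.
* **Differential test.** Per-feature one-way ANOVA on log2 intensities
  (two groups, so F = t² for the pooled t statistic — asserted
  numerically). Intensities are log2(x + 1); the pseudocount only matters
  for literal zeros, which are ~20 orders of magnitude below typical
  intensities here. No multiplicity correction at the discovery stage, by
  design: downstream correlation/ROC/SRM stages act as the consistency
  check. A Benjamini–Hochberg q-value column is available but off by
  default and never drives the `significant` flag. Rows with fewer than
  two present values in either group are reported `tested=False`; rows
  with zero variance in both groups and equal means get p = 1 and a
  `degenerate` flag.
* **Exclusivity partition.** A feature is exclusive to a group iff it has
  ≥1 present value there and none in the other group; total counts every
  feature detected at least once.
* **Protein-level shifts.** Per protein, mean log2(pN+) − mean log2(pN0)
  over present values; a functional class's shift is the unweighted mean
  over its proteins. Reverse-sequence and identified-only-by-site rows are
  removed first.

## Cleavage-site reconstruction (`cleavemap`)

Peptides are located on full-length proteins by exact substring match
(case-sensitive, no I/L equivalence — an `il_equivalent` relaxation was
considered and rejected because enrichment statistics would then need a
19-letter alphabet). All matches are reported; ambiguity (more than one
distinct (protein, start)) is flagged, and unmatched peptides are returned
explicitly rather than dropped.

Each located peptide contributes up to two cleavage windows: the bond that
released its N terminus (absent if the peptide starts at residue 1) and
the bond at its C terminus (absent at the protein end). Windows carry the
residues P3 P2 P1 | P1′ P2′ P3′ read from the *protein*; positions beyond
either protein terminus are padded with the marker ``-`` and excluded from
all counts. Coordinates are 1-based inclusive; the cut position is the
1-based index of P1. A wide mode (P4–P4′) exists for rule sets that
constrain P4/P4′.

**Enrichment statistic.** For each position and residue, the observed
frequency over the N usable windows is compared with the residue's
frequency in the whole proteome background via the one-proportion z-test
z = (f_obs − f_bg)/√(f_bg(1 − f_bg)/N), two-sided normal p-value,
direction assigned at p ≤ α. This is the parametric score family used by
sequence-logo enrichment tools; an exact binomial alternative is provided
and a test asserts that both produce the same rejection set away from a
narrow band around α. Duplicate windows from the same peptide (multiple
occurrences in homologous proteins) are collapsed so a peptide is counted
once — enrichment is peptide-level, not occurrence-level. Excluding an
accession list (used to remove the dominant salivary proline-rich
proteins) is equivalent to removing those peptides before extraction;
asserted by a test.

## Protease prediction (`proteasepred`)

Observed-mode prediction: a window is attributed to a protease iff every
constrained position of the protease's rule admits the window's residue at
the same position. Terminus markers never satisfy a constraint, and rules
constraining P4/P4′ fail closed on standard-width windows. N- and C-side
windows are matched independently; either attributes the peptide.
Matching is monotone by construction (adding rules never removes matches,
restricting residue sets never adds them) and every reported match
re-verifies against the raw protein sequence — both are tested.

Substrate abundance per protease and sample is the sum (or mean) of
present substrate-peptide intensities; group means and a log2 pN+/pN0
ratio summarize each protease. Ranking is deterministic: substrate count,
then total abundance, then lexicographic id.

The packaged rule table (19 proteases) is *illustrative*: literature-style
specificities for proteases relevant to salivary proteolysis, not a
reconstruction of any curated cleavage-site database. Real analyses should
supply their own table; the TSV schema accepts exact-site octamers
(``XXXQ|GXXX``) or per-position residue sets, both normalized internally
to positional sets.

## Clinical association and ROC (`clinstats`)

Clinical covariates are coded numerically (binary 0/1; ordinal stages as
small integers — the coding is the caller's choice and is deliberately not
inferred). Per (peptide, covariate) pair, pairwise-complete observations
feed an OLS regression and Pearson correlation. The default filter is the
conjunction: regression p ≤ 0.05, R² > 0.5, |R| > 0.7, ≥6 valid peptide
values per patient group; the stringent tier adds ≥3 paired observations
per clinical level. Both |R| > 0.7 and R² > 0.5 are enforced even though
nearly redundant (0.7² = 0.49), exactly as stated by the cascade's
definition. As a conjunction of predicates the cascade is order-free.
Pairs with a constant covariate after pairing are reported untestable.

**ROC.** Single features: univariate logistic regression; the fitted
probability is monotone in the feature, so the AUC equals the Mann–Whitney
U/(n₁n₂) rank statistic when the slope is positive (identity asserted).
CIs by DeLong. Random forest: 500 trees, seeded, scored by out-of-bag
probabilities (OOB chosen over resubstitution because RF resubstitution
probabilities are near-degenerate), CI by seeded percentile bootstrap of
the (score, label) pairs (2000 reps). Panels: multivariate binary
logistic regression; the *in-sample* (resubstitution) AUC of the fitted
linear predictor is the primary readout, matching how small-cohort panel
AUCs are conventionally reported, with an optional seeded stratified
k-fold AUC as a clearly-labeled extra. Complete-case rows only. Perfect
separation triggers a ridge-regularized fallback and a `separation` flag.
The optimal cutoff maximizes sensitivity subject to specificity ≥ 0.70
(the conventional decision threshold).

## SRM design and statistics (`srmtools`)

* **Proteotypic selection.** Fully tryptic in-silico digest (cleave after
  K/R; the standard not-before-proline exception is the default and can be
  disabled), length in [6, 20), C-terminal K/R (protein C-terminal peptide
  exempt), and substring-unique across the proteome.
* **Mass arithmetic.** Monoisotopic residue masses, water 18.010565 Da,
  proton 1.007276 Da. Heavy labels: C-terminal [¹³C₆,¹⁵N₂]-Lys
  (+8.0142 Da) and [¹³C₆,¹⁵N₄]-Arg (+10.0083 Da), *derived* from
  ¹³C−¹²C = 1.003355 and ¹⁵N−¹⁴N = 0.997035 rather than hard-coded.
  y ions contain the C terminus and shift by the label; b ions never do;
  precursors always do. The identity b_k + y_(L−k) − 2·proton = M holds to
  1e-9 and is property-tested. Report rounding is decimal half-up to two
  places. Two printed literature values for these peptides (FSVVYAK
  precursor 407.22, FFQSLDGIMFINK y2 261.15) are 0.01 below the computed
  round-half-up values, consistent with truncation at the source; they are
  noted here and not "corrected".
* **Quantification.** Per replicate, ratio = Σ light / Σ heavy over the
  peptide's transitions; replicates with zero total heavy signal are
  excluded and logged. Ratios are invariant to a common detector gain.
  Replicates are retained, not averaged, so the group test sees the
  nesting.
* **Group comparison.** Two-level nested ANOVA (samples within groups,
  replicates within samples); the group factor is tested against the
  among-sample mean square, which correctly treats the sample, not the
  injection, as the unit of inference. With one replicate per sample this
  reduces exactly to one-way ANOVA (asserted). The Mann–Whitney test runs
  on per-sample replicate means. Both at α = 0.05; type-I error of both is
  verified ≈ 5 % by simulation.

## Synthetic-data generator (`syndata`)

The generator defines the study conditions the tests run under:

* Proteome: i.i.d. sequences from a 20-residue background (uniform by
  default), 40 proteins of 150–400 residues.
* Digest: each planted protease has a positional-set rule and an event
  count (default 120 events each for a cathepsin-D-like P1 ∈ {F,W,Y,L}
  rule and a Q|G rule); each event emits a peptide whose N- or C-terminal
  boundary sits exactly at a rule-satisfying bond, plus 50 % background
  peptides cut at uniform random positions. Rules with no admissible site
  raise an error naming the rule.
* Intensities: log2 ~ Normal(baseline, σ) with baselines uniform on
  [20, 30] — a six-order-of-magnitude dynamic range — and σ derived from
  the intensity CV (default 0.3 → σ ≈ 0.42 log2 units). A fraction
  (default 0.11) of peptides is shifted by the effect size (default
  +2 log2 units) in pN+. Missingness is completely at random (default
  10 %); real LFQ missingness is intensity-dependent, which is *not*
  modeled, so passing tests say nothing about MNAR behavior.
* Clinical covariates: each feature shares a latent standard Gaussian with
  its linked peptides; binary features are the latent's sign, ordinal
  features its terciles. `target_correlation` refers to the *coded*
  covariate: thresholding attenuates a latent correlation by √(2/π) ≈ 0.80
  (binary) or ≈ 0.89 (tercile ordinal), so the latent link strength is
  back-computed through that factor (clipped at 0.99 latent). Targeting
  the latent scale instead would make a planted 0.9 link hover exactly at
  the |R| > 0.7 cascade threshold, which defeats the purpose of planting
  it.
* Panel calibration: for k independent unit-variance features with a
  common group shift d, the optimal linear combination has
  AUC = Φ(d√k/√2); `simulate_panel` inverts this in closed form
  (d = Φ⁻¹(AUC)·√2/√k) — calibration is analytic, not tuned. The default
  100 + 100 samples keep the resubstitution bias of the 5-feature logistic
  fit small so the measured in-sample AUC sits near the analytic target.
* SRM: per-sample true ratios log-normal around 1.0 (N0) or the planted
  effect (N+) with 25 % between-sample and 10 % within-sample CV, three
  transitions per peptide with heavy areas ~10⁵.
* Determinism: all randomness flows from `numpy.random.default_rng`
  seeded by the config; identical config + seed gives byte-identical
  outputs (tested).

Problem sizes in the test-suite simulations (e.g. 20 seeds for protease
recovery, 1000 features for null calibration, 400 runs for SRM type-I
error) were chosen as the smallest sizes at which the binomial 3σ
tolerances stated alongside each check are meaningful.

## Known limitations

* No spectrum- or retention-time-level modeling; the pipeline starts from
  identification + quantification tables.
* No imputation, batch correction, or match-between-runs emulation.
* Missingness is MCAR in the generator; conclusions about
  intensity-dependent missingness cannot be drawn from these tests.
* Observed-mode prediction only; specificity-matrix scoring
  ("predicted mode") and curated cleavage-database access are out of
  scope, and the shipped rule table is illustrative.
* Exopeptidase processivity is not modeled; exopeptidase-style rules are
  matched like endopeptidase rules.
* Survival analysis and external-database validation are out of scope.
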