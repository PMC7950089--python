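# prosal — proteolysis profiling of the saliva peptidome

`prosal` is a Python toolkit for analysing endogenous peptidomics data from
saliva (or any biofluid) in a two-group clinical design, built around the
question: *which proteases are active, and do their products carry
prognostic information?* It targets studies comparing oral-cancer patients
with (pN+) and without (pN0) pathologically confirmed lymph-node
metastasis, but every stage is generic.

The pipeline covers, in the order the analysis runs:

1. **Label-free quantification hygiene** (`prosal.quantops`) — quality-score
   filtering (keep quality ≥ 8 by default), the at-least-one-valid-value-per-
   group rule, median normalization, group-exclusivity (Venn) partitioning,
   and per-peptide one-way ANOVA on log2 intensities (α = 0.05, no
   multiplicity correction at the discovery stage).
2. **Cleavage-site reconstruction** (`prosal.cleavemap`) — exact mapping of
   peptides onto full-length proteins, extraction of the P3–P3′ residue
   window around each peptide terminus (Schechter–Berger numbering), and
   position-specific residue enrichment against the proteome background
   using z = (f_obs − f_bg) / √(f_bg (1 − f_bg)/N) with two-sided normal
   p-values (exact binomial optional).
3. **Observed-mode protease prediction** (`prosal.proteasepred`) — matching
   reconstructed windows against literature cleavage-site rules
   (e.g. cathepsin D: P1 ∈ {F, W, Y, L}), substrate-abundance aggregation
   per protease per sample, and deterministic ranking.
4. **Clinical association and ROC panels** (`prosal.clinstats`) — OLS +
   Pearson filter cascade (regression p ≤ 0.05, |R| > 0.7, R² > 0.5, ≥6
   valid values per group; stringent tier adds ≥3 per clinical level),
   detection-rate filtering (≥85 % per group), and single-feature /
   multivariate logistic or random-forest ROC with DeLong or bootstrap
   confidence intervals.
5. **SRM assay design and verification** (`prosal.srmtools`) — proteotypic
   tryptic peptide selection, monoisotopic precursor/y/b fragment m/z with
   [¹³C₆,¹⁵N₂]-Lys / [¹³C₆,¹⁵N₄]-Arg heavy labels, light/heavy ratio
   quantification over technical triplicates, and nested ANOVA +
   Mann–Whitney group comparison.

A first-class synthetic-study generator (`prosal.syndata`) plants proteases
with known specificity, differential abundance, and clinical correlations
into simulated peptidomes, so every downstream stage is testable against
ground truth without access to raw mass-spectrometry data.

## Worked example

Transition m/z values for the fetuin-A (AHSG) surrogate peptide FSVVYAK,
computed from sequence alone:

```python
>>> from prosal.srmtools import peptide_mz, fragment_mz, round_half_up
>>> round_half_up(peptide_mz("FSVVYAK", charge=2))
407.23
>>> [round_half_up(fragment_mz("FSVVYAK", "y", k)) for k in (3, 4, 5)]
[381.21, 480.28, 579.35]
```

A full synthetic-study run (two planted proteases — a cathepsin-D-like
P1 ∈ {F,W,Y,L} endopeptidase and a Q|G glutamine endopeptidase — 12 pN0 vs
13 pN+ samples):

```python
>>> from prosal.pipeline import run_pipeline
>>> summary = run_pipeline(seed=1, outdir="out")
>>> summary["n_quantified"], summary["n_differential"]
(248, 63)
>>> summary["protease_ranking"]
['CTSD', 'QGEP']
>>> summary["panel_auc"]
0.88
```

248 of 360 simulated peptides survive the quality and valid-value filters;
63 are called differential at α = 0.05; both planted proteases are
recovered from the cleavage windows with the higher-activity one ranked
first; and a 5-peptide logistic panel separates the groups with an
in-sample AUC of 0.88. The SRM arm (`summary["srm"]`) recovers the planted
two-fold reduction of the N+ light/heavy ratio with nested-ANOVA and
Mann–Whitney p-values ≪ 0.05.

The same stages are scriptable from the shell: `prosal simulate`,
`prosal quantfilter`, `prosal differential`, `prosal cleavage`,
`prosal predict`, `prosal clinical`, `prosal roc`, `prosal srm design`,
`prosal srm quantify`, `prosal pipeline` (see `prosal --help`).

## Scientific background

See `docs/methods.md` for the models and assumptions behind each stage,
the synthetic-data generating process and what it does and does not
emulate, numerical conventions (missing ≠ zero, log2 pseudocount, rounding,
tie-breaks), and known limitations.
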