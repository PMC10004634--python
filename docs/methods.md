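# Methods

## Scope

`phosreg` packages the quantitative analysis chain used to characterize a
selective covalent BTK inhibitor end to end: calling regulated phosphosites
from two label-swapped SILAC replicates against an empirical Gaussian null,
kinase-panel selectivity arithmetic and competition-binding hit calling,
logistic concentration-response fitting, microarray differential expression
with gene-wise-permutation GSEA and 2^-ddCt quantification, and xenograft
efficacy/pharmacodynamics statistics. A synthetic-data module generates every
input with the statistical structure the downstream analysis assumes, so the
whole chain is testable offline.

## SILAC regulation calling

**Model.** Each class-I phosphosite (S/T/Y with localization probability
>= 0.75; the boundary is inclusive) carries two treatment/control ratios, one
per replicate. The second replicate uses an inverted labeling scheme, so its
as-measured heavy/light ratio is the reciprocal of the treatment/control
ratio; `harmonize_label_swap` inverts it once, with the presence of the
harmonized column acting as the idempotency flag. The mass of unregulated
sites makes the histogram of log2 ratios approximately Gaussian; a
three-parameter Gaussian (amplitude, mu, sigma) is fitted to the bin counts by
unweighted least squares (Freedman-Diaconis bins by default, overridable).
Significance thresholds are `2^(mu +/- k*sigma)` with k = 2.5; for a centered
null the up and down cutoffs are exact reciprocals (up_thr * down_thr = 1). A
site is called regulated only when **both** replicate ratios exceed the same
cutoff strictly; discordant, single-replicate, or partially missing sites are
"unchanged".

**Which log2 sample is fitted.** Two modes are exposed. The default,
`pooled_single_ratios`, pools log2 of all single-replicate ratios; the fitted
sigma then lives on the same scale the thresholds are applied to, and at
sigma_log2 = 0.223 reproduces cutoffs of 1.472/0.679 at 2.5 sigma.
`ratio_of_ratios` fits log2(rep1/rep2) per site, which isolates
between-replicate disagreement: under the generator's noise model its sigma is
sqrt(2) times the technical replicate noise, not the marginal null sigma, so a
2.5-sigma cutoff derived from it would not match the published scale. Both
modes are deterministic given the input.

**Reporting.** Summaries count sites and distinct proteins (keyed on gene
symbol, falling back to protein name) per direction, with percentages of all
quantified sites rounded to one decimal and thresholds printed to three, the
precision conventions of the source tables.

## Synthetic SILAC generator

The generator emulates the study design rather than raw spectra. Per site:

- Null sites: a shared per-site biological component with sd
  `sqrt(null_sigma_log2^2 - replicate_noise_log2^2)` plus independent
  technical noise `replicate_noise_log2` per replicate, giving a marginal
  per-replicate sd of exactly `null_sigma_log2` (default 0.223, the value
  implied by the 1.472/0.679 cutoffs) and correlated replicates — the
  reproducibility premise of the label-swap design.
- Regulated sites (`frac_regulated`, split up/down by `prob_up`): the log2
  ratio sits exactly at the planted effect `+/- effect_log2` plus technical
  replicate noise only. The planted value **is** the site's biology, which
  keeps the ground-truth contract exact and makes the caller's operating
  characteristics interpretable: at effect = 4 sigma and replicate noise 0.1,
  per-replicate detection is Phi(3.35) and dual-replicate sensitivity ~0.999.
  Had regulated sites carried the same biological spread as null sites, no
  caller could exceed Phi(1.5) ~ 0.93 sensitivity at a 2.5-sigma cutoff with a
  4-sigma effect — an information bound, not an implementation property.
- Replicate 2 is stored as a raw heavy/light ratio (reciprocal) when
  `label_swap_rep2` is set.
- Residues are drawn at 84.6/14.4/1.0% Ser/Thr/Tyr; localization
  probabilities are bimodal with ~15% mass below 0.75 so the class-I filter is
  exercised; sites share proteins at a mean multiplicity of 1.9, in line with
  deep phosphoproteome surveys.

Defaults: `replicate_noise_log2 = 0.1`. The within- vs between-replicate
variance split of the original data is not recoverable from the published
numbers; 0.1 (about 7% ratio scatter between replicates for a truly regulated
site) is a realistic technical reproducibility for SILAC ratios, and both
components are exposed as parameters. What the generator does **not** emulate:
heavy-tailed ratio noise, missingness correlated with intensity, sequence
composition of real proteomes, or peptide-level quantification artifacts —
passing tests demonstrate the pipeline's arithmetic and calibration on
Gaussian-null data, not robustness to those pathologies. Under the defaults
the dual-replicate 2.5-sigma rule has a per-site false-call probability of
~0.4%, so a study-scale cohort (9,497 sites) accrues a few dozen false calls
on top of the planted sites; the regulated-site counts the acceptance script
reports are measurements of that operating point, not re-assertions of the
planted numbers.

## Pharmacology

- Percent inhibition is `[1 - (A-B)/(C-B)] * 100` (compound well A, no-enzyme
  background B, vehicle C); it is affine-invariant and may exceed [0, 100].
- Logistic fits run on log10 concentration via least squares (`curve_fit`),
  parameterized in log10(IC50) for stable intervals. Vehicle rows
  (concentration 0) evaluate to the zero-dose asymptote — the algebraic limit
  of the model at -infinity on the log axis — rather than being dropped.
  Variants: 4PL (free top/bottom/hill/IC50), 2PL (top = 100, bottom = 0), and
  sigmoid-Emax (baseline 0, free Emax). The 95% CI is a t-interval on
  log10(IC50) from the fit covariance, back-transformed; simulation places its
  coverage at ~95-97% under 3%-of-range Gaussian noise. A fit whose response
  falls with concentration (negative Hill, or swapped asymptotes in the 4PL's
  symmetric re-parameterization) is flagged unconverged rather than silently
  reported.
- Fold selectivity divides a kinase's IC50 by the reference kinase's.
  Formatting follows the source table: ratios >= 1 round half-up to integers,
  ratios < 1 to one decimal; a right-censored ">x" numerator propagates to a
  censored fold. The raw float is always retained. Two fold cells of the
  published zanubrutinib column are internally inconsistent with their printed
  IC50 inputs (no rounding scheme reproduces them); tests assert the
  recomputed values there and exact string matches everywhere else.
- Competition-binding hits are kinases with `100 - %CTRL` strictly above the
  cutoff (default 65%), sorted by descending inhibition.
- Biomarker-profile annotation requires two consecutive concentrations outside
  the significance envelope, same direction, with at least one
  |log10 ratio| > 0.1; antiproliferative readouts need one qualifying point.
  The envelope itself is an input, not estimated here.

## Transcriptomics

- 75th-percentile normalization scales each sample so its upper-quartile
  intensity equals a common target — by default the geometric mean of the
  per-sample 75th percentiles (scale changes of single samples then shift the
  whole cohort by a common factor), or a fixed constant for exact per-sample
  scale invariance. The operation is idempotent.
- Welch's t runs on log2 intensities (`scipy.stats.ttest_ind`,
  `equal_var=False`); fold change is the ratio of linear-scale geometric
  means; q-values are Benjamini-Hochberg (`statsmodels`). Up/down
  classification uses strict cutoffs (fold change > 2 or < 0.5, nominal
  p < 0.01 — the counts are defined on nominal p, with q reported alongside).
- 2^-ddCt: dCt = Ct_target - Ct_reference per sample, ddCt = group mean minus
  control-group mean, fold = 2^-ddCt. Folds are multiplicative in ddCt.
- GSEA: genes ranked by signal-to-noise on log2 values with the conventional
  variance floor (each group's sd bounded below by 0.2|mean|, 0.2 when the
  mean is 0). The enrichment score is the extremum of the weighted
  running sum (weight |metric|^p, p = 1; magnitude tie-breaks prefer the
  maximum). The null is **gene-wise**: membership of each set is re-drawn at
  random against the fixed ranked list, which keeps calibration when many
  genes respond to treatment and phenotype permutation would anti-conservatively
  mix signal into the null. NES divides ES by the mean same-sign |null ES|;
  p is the same-sign exceedance fraction (resolution 1/n_perm); FDR q compares
  pooled-null and observed NES tail fractions per sign, clipped to [0, 1]. The
  permutation stream is owned by a single seeded generator, so results are
  bit-reproducible.

## In-vivo statistics

- Tumor volume `V = L * W^2 / 2` (the standard ellipsoid approximation; the
  source does not state its formula, so this is a documented convention), with
  swapped diameters auto-ordered under a warning. TGI compares absolute mean
  volumes at the chosen day, `(1 - mean(V_t)/mean(V_v)) * 100`, without
  baseline adjustment.
- Dunnett's two-sided many-to-one test uses the pooled error term and
  evaluates `P(max_j |T_j| <= q)` by deterministic numerical integration:
  conditioning on the shared control variate (Gauss-Hermite, 80 nodes) and the
  chi-distributed scale (adaptive quadrature), with plug-in correlations
  `lambda_j^2 = n_j/(n_j + n_0)` for unbalanced designs (equicorrelation 0.5
  when balanced). Accuracy is ~1e-6; with a single treated group it reduces to
  the pooled two-sample t-test exactly, and it agrees with an independent
  implementation to <2e-4. Null simulation (5,000 replicates) puts the
  familywise error at alpha = 0.05 within [0.04, 0.06].
- The dose trend is OLS of final-day volume on dose over treated groups with
  the usual two-sided slope test.
- Pharmacodynamic inhibition excludes animals with > 30% dead (7-AAD-positive)
  tumor cells — strictly above; 30% is retained — and compares group means of
  stimulated-minus-unstimulated MFI to the vehicle group.

## Problem sizes and numerical choices

Calibration tests and the acceptance script use 20,000-site null cohorts
(sigma recovery within 2%), 9,497-site study-scale cohorts, 20,000-probe
expression cohorts at 8-vs-9 samples, 1,000 permutations for GSEA, 200
simulations for CI coverage, and 5,000 replicates for the Dunnett familywise
calibration — sizes at which the sampling error of each check is comfortably
below its tolerance. All randomness flows through `numpy.random.default_rng`
seeds surfaced in configs, function arguments and CLI flags. Degenerate inputs
fail loudly: constant ratio samples, censored reference IC50s, sets covering
the whole ranked list, all-excluded control groups and C = B plates all raise
`ValueError` rather than returning defaults.

## Known limitations

- The Gaussian-null fit assumes a unimodal, roughly symmetric log2 ratio
  histogram; heavily skewed or multi-modal nulls (e.g. incomplete label
  incorporation) would bias sigma.
- Censoring algebra covers only right-censored numerators over an uncensored
  reference — the only case the panel format produces.
- GSEA reports set-level statistics without leading-edge gene lists.
- The PD and growth simulators model lognormal noise only; no dropout,
  body-weight toxicity, or measurement-day jitter.
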