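# Methods

`seropanel` implements a biomarker-panel discovery analysis for serum
multi-omics case-control studies: a cohort of breast-cancer patients with and
without sentinel-lymph-node metastasis, profiled with targeted MRM proteomics
(protein concentrations, fmol/µL serum) and untargeted LC–MS/MS lipidomics
(peak areas normalized to total ion current). This note records the models,
conventions and numerical choices the package commits to, and what its
synthetic benchmark does and does not demonstrate.

## Statistical model and procedure

**Univariate screen.** Group differences in analyte abundance are tested with
the two-sided Mann–Whitney U test (metastatic vs non-metastatic) and the
Kruskal–Wallis test across multi-level clinical factors (biological subtype,
grade). Categorical clinical variables are compared by Pearson chi-square —
with the Yates continuity correction on 2×2 tables, matching the convention
of standard R `chisq.test` defaults — or by Fisher's exact test (two-sided by
the sum-of-smaller-probability rule). Monotone association between analytes
and the integer count of lymph-node metastases uses Spearman rank correlation
with the t-approximation p-value. A feature is *differential* at raw
p < 0.05 and *count-correlated* when p < 0.05 and |ρ| > 0.3. The screen
reports raw p-values; Benjamini–Hochberg adjustment is applied where FDR
control is the stated criterion (pathway enrichment) and available as an
optional column elsewhere.

Mann–Whitney uses the exact null when the pooled sample is ≤ 16 and tie-free,
otherwise the normal approximation with tie and continuity corrections (the
continuity correction is a documented choice; the rank tests are invariant to
monotone transforms, so no pre-transformation of abundances is needed).

**Second-order design.** The candidate design space contains every base
analyte plus all pairwise products including squares, p(p+1)/2 product
columns for p base features (87 proteins → 3915 columns; 295 lipids →
43 955). Products are formed on the raw measurement scale: a logistic
coefficient of order 10⁻¹² on a product of two ~10⁶-scale lipid intensities
is then directly interpretable. Protein and lipid blocks are expanded
separately by default (a whitelist argument covers other splits).

**OPLS-DA / VIP pre-selection.** A NIPALS OPLS-DA with autoscaled columns
(mean-centred, unit variance — the standard chemometric choice for
mixed-magnitude omics blocks) and the class vector coded ±1 and centred. The
predictive weight is w ∝ Xᵀy (unit norm); each orthogonal component removes
variation uncorrelated with the class contrast before the predictive
component is re-estimated; one orthogonal component is the default for a
two-class model. With a single response and a single predictive component the
classical VIP collapses to VIP_j = √p·|w_j|, so ΣVIP² = p exactly and VIP > 1
marks above-average contributors; candidates are the features with VIP
strictly above 1, in descending VIP order (ties broken by column order).
Selection happens in the autoscaled space; the panel itself is fitted on raw
values.

**Constrained stepwise logistic panel.** Logistic regression is fitted by
damped-Newton IRLS; convergence at max|score| < 1e-8 or relative
log-likelihood change < 1e-10, at most 100 iterations. Internally the design
is standardized (an exact reparametrization, needed for conditioning when
columns span twelve orders of magnitude); reported coefficients, standard
errors and covariance are transformed back to the measurement scale.
Separation is flagged when estimates diverge with still-improving likelihood
or prediction becomes numerically perfect; flagged fits are returned with a
warning, not repaired (no Firth correction).

Panel building is forward-then-backward: starting from intercept-only, each
forward step fits all single-term additions and keeps only *admissible* ones
— converged, non-separated, and (by default) with every non-intercept
two-sided Wald p < 0.05 — choosing the admissible addition with minimal AIC;
the phase stops when no admissible addition lowers AIC. The backward phase
then removes, one at a time, the term with the largest Wald p until all
non-intercept p < 0.05. The significance constraint is attached to the
addition step by default (`constraint_phase="forward_and_backward"`);
`"backward_only"` preserves the alternative reading in which only the
elimination phase enforces it. Forward AIC ties break by smaller worst-case
p, then candidate order, making runs deterministic. The intercept is exempt
from the constraint. A `max_terms` cap (default 12) guards feasibility at
n = 50. For speed the forward ranking uses a vectorized batched Newton
screen over all candidate additions; the chosen term is always refitted on
the exact IRLS path, and the batch serves only to rank.

Confidence intervals default to Wald; profile-likelihood intervals (deviance
increase of the χ²₁ 0.95 quantile, bracketed Brent root-finding, 1e-6–1e-8
tolerance) are available and are the appropriate choice for the asymmetric
intervals a small-n panel produces. Slope profiles are computed on the
standardized scale and mapped back exactly; the intercept is profiled on the
raw scale directly. When the profile deviance never reaches the cutoff the
bound is left one-sided with a warning.

**Evaluation.** The selected term set is held fixed and leave-one-out
cross-validation refits the coefficients on each n−1 subset, yielding one
out-of-fold probability per sample. The ROC is built over thresholds at
every unique probability plus sub-minimum/supra-maximum sentinels, with the
decision rule "positive iff probability ≥ threshold". AUC is the trapezoidal
area (ties contribute ½), which equals the Mann–Whitney U statistic divided
by n₁n₀ exactly. The operating threshold maximizes sensitivity + specificity
(Youden), ties resolved to the smallest threshold. Accuracy is reported at
that threshold, alongside the resubstitution (in-sample) accuracy, which is
labelled separately because the two answer different questions.

Fixed-set LOOCV is optimistically biased whenever the selection stage saw
the held-out sample. The package therefore also provides fully nested LOOCV
(`nested_loocv_probabilities` + `make_panel_selector`), in which VIP
pre-selection and the stepwise search are re-run inside every fold; on null
cohorts this variant's AUC is calibrated near 0.5 while the fixed-set
variant is not (the acceptance suite measures both behaviours rather than
hiding the gap). Folds with an empty selection predict 0.5 rather than the
training class rate: under leave-one-out the training prevalence always
tilts against the held-out class, and the rate would encode that artifact as
anti-signal.

**Pathway enrichment.** Over-representation of selected analytes in
user-supplied pathway sets (GMT-like file) uses the upper hypergeometric
tail P[X ≥ hits] with the universe defaulting to the quantified analytes —
the screening context — rather than a global database; BH-FDR across
pathways. Impact is the mean normalized degree centrality (degree/(n−1) in
the pathway-induced subgraph) of the hit nodes. How lipid species map to
pathway nodes is the user's modelling decision via the pathway file; ids are
treated opaquely.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable without patient data:

- **Design:** 25 metastatic + 25 non-metastatic samples; 87 protein and 295
  lipid features (the quantified universe of the motivating study design).
- **Abundances:** log-normal; Gaussian latents are equicorrelated (ρ = 0.6)
  within consecutive blocks of 5 features, reflecting the observation that
  marker analytes co-vary; protein scale 50 (fmol/µL regime), lipid scale
  10⁶ (TIC-normalized intensity regime), with a per-feature magnitude spread
  (log-normal σ = 0.5 around each block scale).
- **Planted markers:** 2 proteins + 9 lipids receive a +0.5 natural-log mean
  shift in the metastatic arm (the study reports two proteins and nine
  lipids as differential; effect sizes are not reported, and 0.5 is a
  moderate, recoverable choice at n = 50, not an estimate of the study's
  truth).
- **Metastasis count:** 0 in controls; in cases 1 + Poisson(exp(0.3 + 0.9·s))
  with s a latent severity score, giving a case median near 2 with an upper
  quartile near 4–5 without claiming the count's exact distribution.
- **Severity link:** marker latents are blended with s so the full-cohort
  Spearman correlation between marker abundance and the count tracks the
  `count_link` target (default 0.4, the "weak correlation, |r| ≈ 0.3–0.5"
  regime). The blend weight is 0.6·count_link, calibrated once at n = 500:
  the full-cohort correlation mixes the within-case severity channel
  (attenuated by Poisson noise) with the between-arm channel (controls at
  count 0, markers mean-shifted), so the weight needed is below the target
  itself.
- **Product effects:** 2 planted marker pairs define a second-order logit
  (β = 1.5 per standardized log-product by default); labels are then
  re-assigned as the top-25 of logit + logistic noise, a balanced
  case-control labelling that keeps the 25/25 design exact while making
  products, not single analytes, the dominant separators.
- **Clinical covariates** (age, subtype, grade, stage, receptor scores …)
  have realistic marginals but are group-independent: they exercise the
  screening and crosstab code, not clinical confounding.

Determinism: one `numpy` Generator seeded from the config; identical config
and seed give bit-identical tables.

What the generator does **not** emulate: batch/drift artefacts, censoring at
the limit of detection, missingness mechanisms, heavy-tailed contamination,
confounded clinical covariates, and any real biological pathway structure.
Passing recovery and calibration tests on these cohorts shows the pipeline's
machinery is correct and honestly calibrated under its own assumptions — not
that the discovered panels would replicate on real serum.

## Quartile convention

Displayed "Me (Q1; Q3)" summaries use linear interpolation between closest
ranks (type 7, the numpy default). This matters at n = 25 per group, where
conventions differ in the second decimal.

## Problem sizes used in the acceptance suite

Monte-Carlo sizes were chosen to keep the whole suite fast while leaving the
conclusions stable across seeds: 200 null cohorts for screen type-I
calibration (pooled over 76 400 feature tests, 99% binomial bounds), 100
cohorts at n = 500 for stepwise recovery (planted pairs plus a pool of six
noise products drawn from marker-free correlation blocks), 100 seeds at
n = 2000 for logistic parameter recovery, 1000 random score vectors for the
AUC/U identity, 100 random fits for the VIP identity, and 100 (60 in the
acceptance script) null cohorts for nested-LOOCV calibration with a
49-sample-fold selector capped at 30 candidates and 4 terms.

## Known limitations

- Exact Mann–Whitney p-values are not computed in the presence of ties (the
  tie-corrected normal approximation is used instead).
- OPLS-DA component count is fixed by configuration; no Q²-based
  auto-selection or permutation validation of the OPLS model.
- No penalized or Firth-corrected logistic alternatives; separation is
  flagged, not repaired.
- No bootstrap confidence intervals for AUC and no ROC-comparison tests.
- The enrichment impact score is plain degree centrality; topology-weighted
  variants used by web tools are out of scope, so named-pathway results
  depend entirely on the user-supplied pathway file.
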