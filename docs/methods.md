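# Methods

`mrtri` implements a two-sample summary-data Mendelian randomization (MR)
triangulation workflow: instrument selection from GWAS summary statistics,
allele harmonization, seven univariable estimators, four multivariable (MVMR)
estimators with conditional instrument strength, and mediation arithmetic.
A seeded synthetic generator with known causal structure makes every stage
testable without external data.

## Model and assumptions

For SNP j, let γ̂_j (SE σ_Xj) be its estimated per-allele effect on an
exposure and Γ̂_j (SE σ_Yj) its effect on the outcome, from non-overlapping
samples, all oriented to a common effect allele.  If the SNP is a valid
instrument (relevance, independence, exclusion restriction), Γ_j = β γ_j
with β the causal effect of one SD of the exposure (log-odds per SD for
binary outcomes).  Horizontal pleiotropy adds a direct term α_j:
Γ_j = β γ_j + α_j; the estimators differ in what they assume about the α_j.

### Univariable estimators

- **IVW** — weighted regression of Γ̂ on γ̂ through the origin, weights
  1/σ_Yj².  Multiplicative random effects: the reported SE is the
  fixed-effect SE times max(φ, 1), φ² = RSS/(k−1).  Flooring φ at 1 means
  under-dispersion never shrinks the interval.  Cochran's Q = RSS is
  reported.  k = 1 degenerates to the Wald ratio Γ̂/γ̂.
- **MR-Egger** — same regression with an intercept, rows oriented so every
  γ̂_j > 0.  The slope is consistent under InSIDE (pleiotropy independent of
  instrument strength); the intercept estimates mean directional pleiotropy.
  SEs use the freely estimated residual scale φ² = RSS/(k−2) and t p-values
  on k−2 df — no flooring, which keeps the intercept test exactly calibrated
  in clean data (flooring makes it conservative; this was measured directly).
  The intercept is unbiased only when exposure-side noise is negligible
  (NOME); with finite instrument strength it attenuates slightly.
- **Weighted median** — ordered Wald ratios interpolated at cumulative
  weight 0.5 using weight midpoints; weights are inverse first-order ratio
  variances γ̂²/σ_Y².  Consistent while >50% of weight is valid.  SE from a
  parametric bootstrap (γ̂, Γ̂ resampled from their normals), default 1000
  draws, seeded.  Under strictly one-sided contamination at fraction ε the
  estimator converges to the 0.5/(1−ε) quantile of the valid-ratio
  distribution — a small bias that the 3-SE recovery test must respect.
- **Weighted mode** — weighted normal-kernel density over ratios, bandwidth
  0.9·min(SD, MAD)·k^(−1/5) times a `bandwidth_factor` (default 1); estimate
  is the density argmax on a fine grid.  SE is the MAD (normal-consistent)
  of bootstrap re-estimates: the mode hops between density bumps across
  draws, so a robust scale is the appropriate convention.
- **MR-RAPS** — profile-score estimation under γ̂_j ~ N(γ_j, σ_Xj²),
  Γ̂_j ~ N(βγ_j, σ_Yj² + τ²).  The objective Σ ρ(t_j) with
  t_j = (Γ̂_j − βγ̂_j)/σ_j(β), σ_j² = σ_Yj² + β²σ_Xj² + τ², is minimized in
  β; the β-dependence of σ_j is what removes weak-instrument dilution, and
  the solver minimizes the objective on an expanding bracket (the score
  decays to zero in the tails, so root-bracketing alone is unreliable).
  ρ is quadratic or Huber (c = 1.345); τ² ≥ 0 solves the moment condition
  Σ t_j² = k−1, alternated with β to convergence.  SE by sandwich variance.
- **Contamination mixture** — each SNP is valid (ratio ~ N(β, v_j)) or
  invalid (ratio ~ N(0, v_j + ψ²)); the profile log-likelihood takes the
  per-SNP maximum and is maximized over a grid.  ψ defaults to 1.5× the
  precision-weighted SD of the ratios.  The search range is a *bounded*
  plausible-effect window (robust center ± max(1, 3ψ)) with grid points
  seeded at the in-range ratio estimates and iterative refinement around the
  maximum: a grid wide enough to cover every weak-instrument ratio admits
  spurious distant maxima, because a far-off β can "rescue" one extreme
  ratio that the invalid component explains poorly.  The 95% confidence set
  is the grid region within χ²₁(0.95)/2 of the maximum; a disconnected set
  is reported as its spanning interval with a multimodality flag.
- **MR-PRESSO** — global test: observed leave-one-out weighted residual sum
  of squares versus a parametric simulation null (p with +1/(n_sim+1)
  smoothing); outlier test: per-SNP observed versus simulated residuals
  using the *raw* empirical exceedance — smoothing would floor p at
  1/(n_sim+1), which can never clear the Bonferroni α/k bar at large k —
  and Bonferroni correction; distortion test: shift between all-SNP and
  outlier-corrected IVW versus random same-size removals.  Returns the
  outlier-corrected IVW when outliers are found.  Limitation (observed
  directly in simulation): at contamination fractions around 30% the anchor
  fit is itself biased, so outlier selection masks/swamps and the corrected
  estimate reduces but does not eliminate the bias.

### Multivariable estimators

With m exposures, the k×m matrix γ̂ is regressed jointly on Γ̂ (weights
1/σ_Y²), giving each exposure's **direct** effect conditional on the others.

- **MVMR-IVW**: no intercept; SE inflation max(φ, 1), φ² = RSS/(k−m).
  Reduces exactly to univariable IVW at m = 1.  Rank-deficient exposure
  matrices raise an explicit collinearity error.
- **MVMR-Egger**: adds an intercept after orienting rows to the designated
  primary exposure; residual scale unfloored as in the univariable case.
- **MVMR-median**: weighted least-absolute-deviations, solved as median
  regression on weight-scaled rows; bootstrap SEs.
- **MVMR-Lasso**: per-SNP intercepts θ_0j penalized by λΣ|θ_0j|, coordinate
  descent (weighted LS for β, soft-thresholding for θ_0).  λ is the largest
  value on a descending logarithmic grid whose retained (zero-intercept) set
  passes Q ≤ χ²₀.₉₅(k_valid − m); final estimates are MVMR-IVW on that set.
  "Largest λ" retains the most SNPs consistent with homogeneity and gives
  the λ→∞ (all retained, equals MVMR-IVW) limit on clean data; selecting the
  smallest qualifying λ would degenerate to λ→0.
- **Conditional F**: for exposure j, its effect vector is regressed on the
  other exposures' vectors with weights 1/σ_Xj² (cross-exposure sampling
  covariance 0 by default; a supplied covariance is honored); conditional
  F = Q_xj/(k − m + 1) with Q_xj the weighted residual sum of squares.
  Values below 10 are warned about, never gated on: results with weak
  conditional instruments are reported with the caveat.

### Instruments

Selection keeps p < 5×10⁻⁸ (strictly; a lenient 5×10⁻⁶ mode exists for
sparse-instrument exposures).  Clumping is greedy: the lowest-p unclaimed
SNP indexes a clump and claims same-chromosome SNPs within the window
(default 10 Mb each side, configurable) at r² ≥ 0.001.  Three
high-pleiotropy regions (HLA 6:28909037–30913661, ABO 9:135130951–137150617,
APOE 19:44409011–46412650, GRCh37; spans already include a 2 Mb pad) are
excluded.  Missing outcome SNPs may be replaced by the highest-r² proxy with
r² > 0.6 (strict); the proxy's own alleles are harmonized, with EAF-side
orientation.  MVMR pooling scores the union of per-exposure instrument sets
by the minimum p across exposures (or a fixed exposure's p) *before*
clumping, so each LD clump is represented by its best SNP for any exposure.

Variance explained per SNP is 2·EAF·(1−EAF)·β² on the SD scale; for binary
traits the log-OR is mapped to the liability scale by
r = β·sqrt(2·EAF·(1−EAF))·K(1−K)/z(K), with K the prevalence and z the
normal density at the liability threshold — a standard linear threshold-model
conversion satisfying the required contract (monotone in |β|, → 0 at β = 0).
F = ((n−k−1)/k)·(R²/(1−R²)).

### Harmonization

The first exposure's reported alleles define the reference per SNP; other
traits are matched directly, after swapping (beta negated, EAF → 1−EAF), or
after strand complement; unresolvable pairs are dropped with a log.
Palindromic (A/T, C/G) SNPs: default policy keeps them when the EAF is
decisive (outside [0.42, 0.58]) and orients by minor-allele side, drops them
otherwise; `strict` drops all; `keep` trusts forward-strand reporting.  The
configurable policy reflects that forward-strand input files make the strict
rule unnecessary, while user-supplied data may need it.

### Mediation

With θ_t the total effect (univariable IVW) and θ_2 the direct effect
(MVMR-IVW adjusted for the mediator), the proportion mediated is
1 − θ_2/θ_t, reported as a percentage.  For binary outcomes both effects are
log-odds — the only scale on which this ratio is coherent with odds-ratio
inputs.  Values outside [0, 1] are flagged, not clipped.  No SE is attached
by default.  The effect-size comparison between two direct effects is their
log-scale ratio.

## Synthetic generator

`simulate_sumstats` draws, per SNP: EAF ~ U(0.05, 0.5); per-allele exposure
effects with within-LD-block correlation √r²_within, scaled so instruments
explain `exposure_h2` of each exposure (default 0.05, the scale of the real
anthropometric instruments); the second exposure's effects are
`shared_loading` times the first's plus an orthogonalized residual, so the
variance budget is exact.  Pleiotropic direct effects α_j occur with
probability `pleiotropy_prob` and are drawn N(mean, sd) *oriented to the
exposure-raising allele* — "directional" is only meaningful in that frame,
since effect-allele coding is otherwise sign-symmetric.  True marginal
outcome effects are Σ_i β_i γ_ij + α_j.  Estimated effects add sampling
noise with SE = 1/sqrt(2n·EAF(1−EAF)) on the standardized scale; binary
outcomes use the log-odds normal approximation
SE = 1/sqrt(2n·EAF(1−EAF)·v(1−v)) above n = 50,000 and individual-level
logistic simulation (HWE genotypes, liability through a logistic link with
the intercept solved for the target prevalence, per-SNP Newton logistic
fits) below.  Sample overlap correlates exposure-1 and outcome noise with
coefficient `overlap_fraction`.  Within-block effects and noise are
correlated so that clumping visibly changes estimates — an approximation to
LD, not a genotype-level simulation.

What the generator does **not** emulate: realistic LD (block structure with
constant within-block r² only), population structure, allele-frequency
spectra, binary exposures, INDELs, or the real studies' cohorts.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated noise model, not performance on real GWAS data.

## Study conditions used in tests

- Parameter recovery: k = 150 instruments, two exposures (h² = 0.05 each,
  shared loading 0.7), UK-Biobank-scale n (460k/500k), effects (0, 0.5),
  fixed seed; all 11 estimators within 3 SE of truth.
- Robustness: 30% of instruments pleiotropic with α ~ N(0.02, 0.025)
  oriented to the exposure-raising allele — directional on average with both
  signs present, offsets large enough to be separable.  Under this regime
  the weighted median, weighted mode, contamination mixture, and
  outlier-corrected PRESSO stay within 3 SE while naive IVW does not; the
  PRESSO margin is modest, consistent with its masking limitation above.
- Calibration: 200 clean replicates at k = 30 strong instruments; Egger
  intercept p and PRESSO global p (n_sim = 200) tested for uniformity.
- MVMR attribution: 100 replicates of the correlated-exposure design where
  only the second exposure is causal; MVMR-IVW must null the first and
  retain the second in ≥90%.
- The analysis scripts simulate one full cohort set with true direct
  log-odds effects ln(3.27) and ln(1.31) and exposure-to-mediator loading
  0.43 (implying ~8.9% mediation), binary outcome at prevalence 0.0825 —
  problem sizes chosen to keep the whole workflow at desk scale.

## Numerical choices

Strict inequalities at all published thresholds (p < 5e−8, r² > 0.6,
r² < 0.001); clumping ties on p broken by (chromosome, position); proxy ties
by nearest position then lexicographic id.  Bootstrap sizes and every
stochastic routine take explicit seeds; fixed seeds make pipeline reports
byte-identical across runs.  Degenerate instrument counts return tagged
fallbacks (k = 1 → Wald ratio, k = 2 → IVW) for the median/mode/RAPS rather
than erroring, since real analyses (e.g. sparse binary-trait exposures) can
have very few instruments.  Wald-ratio variances are first-order by default;
a second-order term is available by flag.

## Known limitations

No Steiger filtering, correlated-instrument (generalized) IVW, CAUSE-style
Bayesian models, GWAS-VCF input, or build liftover.  The conditional-F
normalization follows one convention from a literature with several;
equivalence with other implementations is not claimed.  The binary-trait
liability r² is a linear approximation, not the exact threshold-model
integral.  MVMR assumes uncorrelated instruments after clumping.
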