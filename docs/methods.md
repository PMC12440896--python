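# Methods

## Data model

Each ego names exactly four peers; ties among {ego, peer 1..4} are binary,
undirected, and recorded in a 5×5 adjacency matrix with the ego at node 0.
The name generator itself establishes every ego–peer tie, so row 0 must be
all ones off-diagonal; a zero there is treated as a data error rather than
a missing tie, and an asymmetric matrix is rejected rather than
symmetrized. The peer–peer block is taken as fully observed — the survey
instrument offers no DK/NA option we could model for tie reports — and
this assumption is stated here rather than patched over.

Egos naming fewer than four peers are flagged and excluded before
analysis: the constraint index depends on network size, so the analysis
sample is restricted to uniform size-4 networks, where every ego row of
the proportion matrix is (0, ¼, ¼, ¼, ¼) and the constraint varies only
with the peer–peer block. Egos with missing outcome or covariate data are
likewise excluded, with the single exception of income, which keeps a
dedicated *missing* category.

## Constraint and structural-hole categories

Proportional tie strength divides each node's ties by its total tie
strength over its *whole* neighbourhood — for peer rows this includes the
tie back to the ego (Burt's original whole-network normalization; e.g. a
peer tied only to the ego and one other peer has row weights ½, ½). The
dyadic constraint is

    C_ij = (P_ij + Σ_{q≠i,j} P_iq P_qj)²,

its reciprocal the structural-hole index. Useful closed forms for
four-peer networks: star C = 1/16, two disjoint peer pairs C = 9/64,
complete C = 49/256; every C_ij of a four-peer ego lies in [1/16, 49/256].

Categories come from pooled tertiles of 1/C over all dyads in the sample
(not per-ego): cut points are the ⌈n/3⌉-th and ⌈2n/3⌉-th order statistics,
values at or below a cut point go to the lower category, so heavily tied
distributions produce unequal group sizes. Categorizing on 1/C with this
tie rule is equivalent to reverse-labelled tertiles of C; the suite
asserts the equivalence on tie-free data. The categorization is computed
directly on the structural-hole index.

## Peer health behavior score

Four peer behaviors reported by the ego are coded 1 = healthy (exercises,
non-smoker, non-drinker, non-obese), with any missing report coded 0 so
the score exists for every peer. Pairwise tetrachoric correlations use
the two-step maximum-likelihood estimator: thresholds fixed at the normal
quantiles of the observed margins, then a one-dimensional likelihood
maximization over the latent correlation. Because the fixed thresholds
reproduce the observed margins exactly, the likelihood is maximized where
the model (1,1)-cell probability equals the observed proportion, so the
estimate is obtained by bracketed root-finding of Φ₂(h, k, ρ) = p₁₁ on
ρ ∈ (−0.999, 0.999); Φ₂ is evaluated through Owen's T function, with
exact special cases at zero thresholds (both zero: ¼ + arcsin(ρ)/2π).
Tables with a zero cell receive a 0.5 continuity correction on all four
cells; a degenerate margin (constant indicator) raises rather than
returning ±1. If the assembled 4×4 matrix is not positive semidefinite,
eigenvalues are clipped at 1e−6 and the matrix rescaled to unit diagonal,
with a flag recording the smoothing.

Scores are the standardized indicators (column mean 0, variance 1)
projected on the leading eigenvector of the tetrachoric matrix, oriented
so the healthy direction is positive. Binary-data PCA has no single
scoring convention; this one is a monotone linear transform of the
plausible alternatives (raw 0/1 projection, covariance-scale loadings),
which leaves the logistic-regression fit invariant up to coefficient
rescaling. A consequence worth noting: the score variance equals the top
eigenvalue of the *Pearson* correlation of the indicators, not of the
tetrachoric matrix — exact equality holds when the decomposed matrix is
the Pearson one, and the suite asserts it there. Correlations and scores
are pooled over all peers jointly. The simple 0–4 healthy-behavior count
is also exported for descriptive comparability.

## Covariates

Equivalent income divides household income by the OECD-modified scale
1 + 0.5·(adults − 1) + 0.3·children (weights configurable); individual
income substitutes when household income is missing, and egos lacking
both fall into the explicit *missing* income category. Tertiles are
computed on observed values only, with the same order-statistic rule as
above. The exercise recode has three variants: at least 1–2 days/week
(main), at least 3–4 days/week (sens_high), and at least a few times per
month (sens_low). Non-smoking codes former and never smokers as 1;
regular drinking requires 3–4 days/week or more. Diffusion stages follow
the cumulative adopter shares (innovators 2.5%, early adopters 13.5%,
early majority 34%, late majority 34%, laggards 16%): prevalence ≤ 16% is
early, ≤ 50% intermediate, above that later, with boundaries inclusive on
the lower stage.

## Regression and inference

Fits use iteratively reweighted least squares from a zero start, stopping
when the sup-norm of the score drops below 1e−8 (at most 100 iterations);
a coefficient norm above 30 is flagged as likely complete separation and
returned non-converged with a warning. The classical covariance is the
inverse observed information (equal to the expected information for the
logit link). Cluster-robust covariance sums score contributions within
egos: V = B⁻¹(Σ_g s_g s_gᵀ)B⁻¹ · M/(M−1). The small-sample factor M/(M−1)
is the minimal degrees-of-freedom correction for clustered ML estimators;
other software multiplies by an additional (n−1)/(n−k), which matters
little at these sizes — the factor is exposed and the cross-check test
accounts for it. With every cluster a singleton the estimator collapses
to the heteroskedasticity-robust sandwich times n/(n−1); with rows
perfectly replicated within egos (the dyad design), the cluster-robust
standard errors reproduce the classical standard errors of the collapsed
one-row-per-ego fit, which is the property that justifies dyad-level
estimation here.

Odds-ratio tables are Wald-based (exp(β ± 1.96·se), two-sided normal
p-values), so an interval excludes 1 exactly when p < 0.05. Predicted
probabilities fix non-focal columns at their sample means — continuous
covariates at means, dummies at sample proportions, read literally — and
vary only the focal category dummies; intervals use the delta method on
the probability scale, se_p = p(1−p)·se_lp with se_lp from the
cluster-robust covariance, clipped to [0, 1]. The Hosmer–Lemeshow test
groups observations into g = 10 near-equal groups of predicted risk
(stable sort for ties), χ² = Σ(O−E)²/(E(1−E/n_g)) on g−2 degrees of
freedom. Pseudo-R²: McFadden 1 − L₁/L₀ and Nagelkerke
(1 − e^{2(L₀−L₁)/n})/(1 − e^{2L₀/n}). VIFs come from ordinary
least-squares regressions of each design column on the others (with
intercept), as is conventional even for logistic models. The non-smoking
model drops the ego-smoking covariate; the reference levels are the
middle structural-hole category, the low income tertile, and the first
municipality. An optional per-dyad peer-smoker term supports the
peer-smoking sensitivity adjustment, off by default.

## Synthetic populations

The generator emulates the study conditions: 1,705 egos by default, with
the published covariate margins (male 0.42, college 0.74, married 0.74,
working 0.87, age N(45.7, 6.9²), alcohol ≥3–4/wk 0.37, income missing
0.13, four municipalities at 0.19/0.21/0.30/0.30), raw answer-category
distributions chosen so the binary recodes hit those margins, and peer
margins near the published pooled peer table (coded healthy-indicator
rates ≈ 0.19/0.74/0.20/0.78 arising as latent prevalence × (1 −
missingness)). Peer behaviors are thresholded from a latent 4-variate
normal with configurable correlation (default equicorrelation 0.2).
Household income is lognormal with an OECD-modified scale applied to a
generated adults/children split; the *children* definition is the
generator's explicit household composition, since no age cutoff is
inherent in the scale.

Network density classes — star, paired (two disjoint peer pairs),
partial (i.i.d. Bernoulli(p) peer–peer block, p ~ U(0.2, 0.8) per ego),
complete — are allocated by largest-remainder rounding with ties broken
toward the denser class, so an equal star/paired/complete mixture makes
the pooled tertiles coincide with the density classes for any number of
egos. Outcomes are generated at the ego level from a logistic model on
the structural-hole category shares of the ego's four dyads plus
covariates, then replicated across the dyad rows — reproducing the
within-ego dependence that motivates clustered standard errors.
Covariate contributions are centered at their sample means, so the
configured prevalence is the prevalence at covariate means and the
configured log odds ratios are the exact generating slopes. Default
effect sizes follow the published association table; the smoking
covariate is derived from the generated non-smoking outcome (current
smoker margin 0.13), keeping the two internally consistent. Raw answer
categories (exercise frequency, smoking status) are back-sampled
conditional on the generated binary outcome, so re-reading the emitted
files through the recode pipeline reproduces the outcomes exactly.

Randomness flows from a single seed through counter-derived spawned
substreams per component (networks, covariates, peers, outcomes), with
vectorized draws inside each component; identical config and seed give
byte-identical files.

What the generator does *not* emulate: homophily between ego and peer
attributes, correlation between network density and covariates,
item-nonresponse outside income and peer behaviors, and realistic
topology beyond the four density classes. Passing tests therefore
validate the estimators and the pipeline plumbing under the stated
model, not the substantive findings on restricted survey data.

## Validation experiments and problem sizes

The recovery experiment uses category-homogeneous networks (equal thirds
star/paired/complete, 2,000 egos, 500 replicates) with a generating
OR(high vs middle) of 1.35 and all covariate effects off; homogeneity
makes the dyad-level coefficient's generating counterpart exact, since
logistic aggregation across mixed-category networks would otherwise bias
a naive comparison. The clustered-inference collapse check uses 10,000
egos with small coefficients (fitted probabilities near ½), where the
robust and classical variances agree closely in expectation. Tetrachoric
recovery uses 10,000 peers at latent equicorrelation 0.5.
Hosmer–Lemeshow calibration uses 1,000 correctly specified fits of
n = 1,000. These sizes keep the full suite around five minutes on one
CPU while leaving comfortable Monte Carlo margins.

## Known limitations

- The tetrachoric estimator is the two-step variant; joint estimation of
  thresholds and correlation would differ slightly in small samples.
- Constraint tertiles assume the pooled sample; per-stratum tertiles are
  not implemented.
- The main pipeline requires uniform network size 4 (the metrics module
  itself is size-generic).
- No GEE or mixed-model alternatives to the sandwich estimator, no Firth
  correction under separation, and no multiple-testing adjustment.
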