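# Methods

## Data model

A balanced MET is g genotypes × e environments × r replicates, one
trait value per plot. An *environment* is a location × year
combination; the default coding enumerates locations within year
(ENV1…ENVl = year 1, ENVl+1… = year 2, …) and can be overridden with an
explicit location order. Balance is enforced at validation: every
genotype × location × year cell must carry the same replicate count.
Isolated missing plots can optionally be imputed with the cell mean of
the remaining replicates (logged); whole missing cells are never
imputed — an unbalanced trial needs a mixed-model analysis this package
deliberately does not provide.

All models operate on the sufficient statistics of the balanced design:
the g × e matrix of cell means x_ij and the pooled within-cell error
mean square MSE = SS(within) / (g·e·(r−1)). Replicate blocks are pooled
into error; no separate block term is reported. All arithmetic is in
double precision; rounding (4 decimals for stability tables, 2 for
ANOVA) happens only in the presentation layer.

## ANOVA

`pooled_anova` computes the classical balanced factorial partition
G, L, Y, G×Y, G×L, Y×L, G×Y×L on plot data. Everything is treated as a
fixed effect: only SS/MS/F arithmetic is reported, and for a balanced
design those quantities coincide with what a random-environment
formulation would print; readers who need variance components or
BLUPs should fit a mixed model instead. All terms are tested against
pooled error by default because MET reports rarely state denominators;
`env_collapsed_anova` accepts `test_g_over_ge=True` to test genotypes
against the interaction instead.

`env_collapsed_anova` gives the G / E / G×E partition of the two-way
table on either basis:

* **plot** — means-based SS × r, error row from the pooled MSE
  (df g·e·(r−1)); this is the scale at which trial reports print their
  interaction tables;
* **means** — cell-mean scale, no F tests.

The identity SS_E(collapsed) = SS_L + SS_Y + SS_L×Y (and likewise for
the interaction) is asserted in the tests. Percent explained for
G, E, G×E is relative to their sum (error excluded), the convention
used when reports say "the environment explained x% of variation".

## Univariate stability

The environment index is I_j = X_.j − X.. (sums to zero). Per genotype:

* **Eberhart–Russell**: b_i = Σ_j x_ij I_j / Σ_j I_j², deviation MS
  Σ_j δ̂²_ij/(e−2). The default S²d_i subtracts MSE/r (the classical
  error-corrected estimator); `error_correction=False` gives the raw
  deviation MS. Both are exposed because published tables mix the two
  conventions — the corrected and raw values differ by the constant
  MSE/r across all genotypes.
* **Perkins–Jinks**: regression of the interaction residual on I_j.
  Algebraically B_i = b_i − 1 and the residuals coincide with the ER
  residuals, so DJ_i equals the raw ER deviation MS; this is asserted,
  not assumed.
* **Wricke**: W_i = Σ_j (x_ij − X_i. − X_.j + X..)². ΣW_i = SS_GE on
  the means basis (tested).
* **Francis–Kannenberg**: sd (ddof = 1) and CV% of the genotype's e
  environment means. Note that CV is computed over environment means,
  not plots, so it excludes replicate error.

Balanced-design identities mean(b_i) = 1 and mean(B_i) = 0 hold exactly
and are property-tested. Adaptation classes use a slope tolerance of
0.05 around 1 (configurable): above → adapted to favorable (high-index)
environments, below → unfavorable, else average responsiveness; crossed
with above/below grand-mean performance. t (H0: b_i = 1, e−2 df, using
the genotype's own deviation variance) and F (H0: S²d_i = 0, against
MSE/r) statistics are computed but not used in classification.

## AMMI

The double-centered interaction matrix is decomposed by SVD. Design
choices:

* **Sign convention** — each component's environment-score vector is
  flipped so its largest-magnitude element is positive; biplots are
  then deterministic across BLAS/LAPACK builds. All reported geometry
  (AMMI2 distances, subspaces) is invariant to this choice.
* **Axis df** — Gollob: g + e − 1 − 2n for axis n; they sum to
  (g−1)(e−1). F tests use pooled error (the Gollob approach); this is
  liberal relative to resampling-based tests and is flagged as such.
* **Basis** — the decomposition always acts on cell means; `basis="plot"`
  scales the ANOVA SS by r so they sit on the same scale as the
  plot-level tables. Coordinates are means-based.
* **Scaling** — biplot coordinates use symmetric scaling
  (λ^0.5 to each side) by default; the exponent is configurable in
  [0, 1].

AMMI1 plots main effects (μ + α_g, μ + β_e) against scaled IPCA1;
AMMI2 plots the first two scaled score pairs, and a genotype's Euclidean
distance from the origin is its instability measure (rank 1 = most
stable).

## GGE

Columns (environments) are centered, removing E and keeping G + GE;
optional division by the per-environment sd is available but off by
default, since contribution percentages in trial reports are computed
from unscaled SS. Rank-2 markers come from the SVD with singular-value
partitioning: symmetric for which-won-where, genotype-focused for
mean-vs-stability and ranking, environment-focused for
discriminativeness — standard biplot practice; every view accepts an
override. The rank-2 goodness of fit (share of Σλ²) is always exposed
so users can judge whether the 2-D geometry is adequate.

Which-won-where: the winner of an environment is the genotype
maximizing the marker inner product — exactly the argmax of the rank-2
reconstruction of the centered table, and necessarily a convex-hull
vertex. Sectors are reported per hull vertex (counterclockwise);
boundary ties go to the counterclockwise-first vertex. Collinear
genotype markers (relative second-singular-value below 1e−5) raise a
degenerate-geometry error rather than produce arbitrary sectors.

The AEC direction is the normalized mean environment marker; genotype
mean performance is the signed projection on it, instability the
perpendicular component. The ideal point for ranking sits on the
positive AEC at the largest genotype projection. Discriminativeness is
the environment marker norm, representativeness the cosine with the
AEC; the "ideal test environment" flag uses the product of the two —
a documented, simple combined score, not a canonical statistic.

## Correlation

Pearson r between traits on the pooled g·e cell means by default
(genotype-means and plot bases by flag), p from the t transform with
n − 2 df, unadjusted (Bonferroni by flag). Zero-variance traits yield
NaN with a warning. The genetic-correlation label sometimes attached to
this quantity in trial reports is avoided: without a variance-component
decomposition this is a phenotypic correlation.

## Synthetic trials

The generator draws Y_ijr = μ + g_i + e_j + Σ_k λ_k γ_ik δ_jk + ε_ijr
with centered main effects and score vectors QR-orthogonalized against
the intercept — exactly the identifiability constraints AMMI assumes,
so implanted λ are recovered to numerical precision at zero noise. In
slope mode the interaction is (b_i − 1)·e_j with slopes recentered to
mean 1 (the joint-regression constraint). One seeded stream drives all
draws in a fixed order, so datasets and truth records are reproducible.

Defaults emulate a wheat grain-yield MET: 13 genotypes, 4 locations × 2
years, 3 replicates, grand mean 2.6 kg/plot, genotype sd 0.20 and
environment sd 0.63 kg/plot, a rank-2 interaction with singular values
5.5 and 3.3 on the cell-mean scale (interaction comparable to the main
effects in total SS), and plot error sd 0.30 kg/plot (CV ≈ 11%, a
typical well-run yield trial). What the generator does **not** emulate:
spatial field trend, heteroscedastic or correlated plot errors, and any
genuine three-way genotype × location × year structure beyond what the
environment coding induces. Passing recovery tests therefore show the
estimators are correct under the stated model, not that real trials
satisfy that model.

Test and acceptance runs use trials between 4 × 4 × 2 and the full
13 × 8 × 3 design, with 50–200 Monte-Carlo replicates for the
stochastic recovery checks — sizes at which every identity in this
document is exercised while the whole suite stays fast.

## Numerical notes and limitations

* Balance identities are asserted at 1e−10; SS partitions at 1e−8
  relative; oracle comparisons at 1e−10.
* Singular values of order machine-epsilon inflate to ~1e−8 after the
  λ^0.5 biplot scaling; zero-ness tests for scaled coordinates use 1e−6.
* Degenerate inputs: an additive table is a valid AMMI model with all
  λ = 0; a zero environment index, a zero-variance environment under
  sd-scaling, and an origin-centered mean environment marker raise
  explicit errors.
* Out of scope: REML/mixed models for unbalanced data, spatial
  adjustment, variance components and heritability, Shukla/Lin–Binns/
  nonparametric stability measures, AMMI stability value indices, and
  genotype-by-trait biplots.
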