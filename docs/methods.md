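# Methods

## The scientific question

When one brood-parasitic bird species exploits several host species through
specialist host-races, each host is under selection to move its egg
phenotype away from its own mimic — but moving into phenotypic space
occupied by another host risks parasitism by that host's mimic. The
prediction is that sympatric hosts of a shared parasite should *partition*
egg phenotypic space among species more strongly than related,
unparasitized species, and that parasitic host-races should match their own
host better than other local hosts. This package implements the full
analysis chain for that question — phenotype quantification, discriminant
classification with a sample-size chance null, host-race mimicry
differentials, and phylogenetic-signal estimation — and, because the
underlying museum egg collection has no public digital archive, a synthetic
community generator that reproduces the statistical structure the analyses
assume.

## Phenotype space

Each egg is a 10-vector: a double-cone luminance index; UV, SW, MW and LW
single-cone photon catches; and five pattern metrics.

**Photon catches.** `Q_i = ∫ R(λ) I(λ) S_i(λ) dλ` (trapezoid rule on the
visual system's wavelength grid, reflectance linearly interpolated), where
`R` is egg reflectance, `I` the illuminant and `S_i` the receptor
sensitivity. By default catches are normalized by the perfect-white catch,
so `R ≡ 1` scores exactly 1 for every receptor and catches are
dimensionless indices. No chromatic-adaptation or receptor-noise modelling
is applied: catches are used directly as luminance and colour indices.
`VisualSystem.idealized()` supplies *synthetic* Gaussian receptor templates
(UV 370/25, SW 445/30, MW 508/35, LW 565/40, double 560/80 nm peak/width)
with a flat illuminant; the analyses require a plausible tetrachromatic
system, not a particular species' measured curves.

**Granularity pattern metrics.** The masked egg image is mean-padded,
DC-removed, Fourier-transformed, and partitioned into octave bands of
Euclidean spatial frequency. The coarsest band covers structure sizes down
to half the smaller image dimension; each band halves the size; the finest
band absorbs everything to Nyquist, so the bands tile the frequency plane
and (for a full mask) band energies sum exactly to the image variance.
Band energy is the mean squared band-passed value inside the mask. From the
band profile and the image:

| metric | definition |
|---|---|
| `marking_size` | band scale (px) with maximal energy |
| `main_contribution` | max band energy / total energy |
| `contrast` | √(total energy) — RMS pattern amplitude |
| `coverage` | fraction of mask pixels darker than an Otsu threshold |
| `dispersion` | CV of coverage over 5 equal-length zones along the egg's long axis |

These five operationalizations are this package's own concrete choices for
metric families that the literature describes at varying levels of detail;
each sits behind a single function and can be replaced independently. Otsu
thresholding was chosen because it is parameter-free and deterministic; a
patternless image (zero total energy) reports `main_contribution = 0`,
`contrast = 0` and a missing `marking_size`. For two-valued images the
threshold falls between the two values, so a half-dark egg has coverage
exactly 0.5.

## Preprocessing

Applied in this order (configurable): random selection of one egg per
clutch (uniform, seeded — avoids pseudoreplication from correlated clutch
mates); Mahalanobis outlier removal; Pearson collinearity screen; arcsine-
square-root transform.

* **Outliers** are rows whose squared Mahalanobis distance to the pooled
  trait mean, under the pooled covariance, exceeds the chi-square(d) upper
  0.001 quantile. The cutoff is exposed as `alpha`; 0.001 flags only gross
  errors and makes the screen idempotent on clean data. Distances are
  computed on the pooled family table, not per species, so a species far
  from the family centroid can lose eggs — the dial that controls this in
  the generator is the between-species separation.
* **Collinearity**: all trait pairs with |r| above 0.8 are reported. When
  the flagged pairs are exactly UV–MW and SW–LW (the structure real cone
  catches show, which the generator reproduces with r = 0.9), the suggested
  drops are MW and LW; otherwise the later trait of each pair.
* **Transform**: traits are min-max scaled to [0, 1] (parameters recorded,
  transform invertible) then mapped through asin(√x). Min-max scaling was
  chosen because photon catches are not proportions; rank order is
  preserved. The headline analyses run on untransformed data with
  correlated traits retained; the transform and the trait drops are
  sensitivity switches, and the pipeline test verifies the group contrast
  keeps its direction and significance under both.

## Classification machinery

Written from first principles (no classifier library in the analysis path):

* **Discriminant axes** solve `B v = θ W v`, with `B` the size-weighted
  between-group scatter of group means and `W` the pooled within-group
  scatter, via the symmetric generalized eigensolver; axes are scaled to
  unit pooled within-group variance (so one-SD ellipses in discriminant
  space are comparable across groups). `min(k − 1, d)` axes are kept. A
  singular `W` is ridge-stabilized (`1e-8·tr(W)/d`) with a warning.
* **Assignment** maximizes the Gaussian equal-covariance discriminant score
  `μ_g'Σ⁻¹x − ½μ_g'Σ⁻¹μ_g + log π_g` with `Σ = W/(n − k)`; priors default
  to group sample-size proportions, consistent with the chance null below;
  ties break toward the lowest group index for deterministic reruns.
* **Jack-knife (leave-one-out)** is exact but incremental: removing row x
  from group g shifts that group's mean and subtracts the rank-one term
  `(n_g/(n_g − 1)) (x − m_g)(x − m_g)'` from `W`, so the inverse follows
  from the Sherman–Morrison identity. Leave-one-out priors track the
  reduced group sizes. The test suite proves equality with a literal
  refit-per-row loop.
* **Monte-Carlo sample splitting** (default 100 stratified 75/25 splits)
  is the confirmatory accuracy estimate; on Gaussian data it tracks the
  jack-knife within a few points.
* **Multinomial logistic regression** is the assumption-lean cross-check:
  full k-class softmax fit by damped Newton steps on the ridge-penalized
  log-likelihood (ridge `1e-6·n` on non-intercept coefficients — needed
  because separable groups, which do occur, make the unpenalized MLE
  diverge). Convergence is declared at gradient norm < 1e-8. Groupwise
  logistic accuracy is resubstitution accuracy; a jack-knifed variant
  exists but is not the default.

## Partitioning inference

If eggs were assigned to species purely in proportion to species sample
sizes, accuracy would be `Σ(n_i/N)²` and the expected number correct
`Σn_i²/N` — the chance null. Groupwise: the observed jack-knifed (or
logistic) correct count is compared to the rounded expected count by a
two-sided Fisher's exact test (table rows = correct/incorrect, columns =
expected/observed; the construction is configurable because it is a
convention), with a Wald binomial CI (`1.96·√(p(1−p)/n)`, in percentage
points) and the improvement over chance (accuracy − expected accuracy).
Fisher's exact p sums hypergeometric probabilities of all tables no more
probable than the observed one (1e-7 relative tolerance on the comparison,
as in standard implementations). Groups are contrasted by Fisher's exact
test on their observed rates. Pairwise: every within-group species pair
gets a two-group jack-knifed accuracy and a pair chance expectation
`(n_i² + n_j²)/(n_i + n_j)²`; the two groups' pair distributions are
compared by Welch's unequal-variance t on pooled midranks
(Welch–Satterthwaite df). The ranked-Welch statistic is reported as
`statistic` with its df. No multiple-testing correction is applied — each
pairwise value is a discriminant rate, not a significance test.

## Mimicry analysis

For each parasitic host-race: two-group jack-knifed accuracy against its
own host and against every other parasitized host of the same family. Low
accuracy = good mimicry. The specialization signal is own-host accuracy
minus the mean of other-host accuracies, per race; significance comes from
a paired t-test with one pair per race (df = races − 1), equivalent to a
one-sample t on the per-race differences. Races with fewer than
`min_race_n = 3` eggs (two-group DFA needs ≥ 3 per side and a race of 1–2
eggs estimates nothing) are reported, flagged, and excluded from the test.

## Phylogenetic signal

Species-level trait values are per-species means of the cleaned egg table.
Under Brownian motion the tip covariance C has root-to-tip depths on the
diagonal and shared-path lengths off it; Pagel's λ multiplies the
off-diagonal. For fixed λ, the root state and rate have closed-form GLS ML
estimates, so the likelihood is profiled over λ ∈ [0, 1] by bounded scalar
search (xatol 1e-8), with both boundaries always evaluated and ties
resolved toward the boundary. p0 and p1 are likelihood-ratio tests against
λ = 0 and λ = 1 referred to chi-square(1) — the standard convention even
though λ̂ sits on a boundary under the null, making p0 conservative and p1
anticonservative. Estimates are aggregated over a set of candidate trees
(mean ± SD of λ̂, p0, p1 per trait); trees missing species are skipped and
counted. The implementation matches phytools::phylosig to ~1e-4 in λ̂ and
log-likelihood on simulated data, and λ̂ is invariant to rescaling all
branch lengths.

## The synthetic generator

What it emulates: multivariate-normal species with a per-trait
between/within separation dial; r = 0.9 correlations within the UV–MW and
SW–LW catch pairs; host-races drawn from a fidelity-weighted mixture of
their own host's fitted Gaussian and the pooled-host Gaussian (fidelity 1 =
perfect specialist, 0 = generalist — a single dial spanning the
specialist/generalist contrast between the two families); λ-scaled Brownian
traits on pure-birth trees rescaled to unit depth (branch lengths clamped
to ≥ 1e-3 because simultaneous-split branches can be zero); spotted egg
images with elliptical masks, 8-bit quantized.

Preset conditions (chosen once, as the study conditions the analyses are
exercised under):

* Group sizes: warbler-like 5 parasitized species/205 clutches and 6
  unparasitized/219; weaver-like 10/339 and 4/46. Per-species counts are
  not published, so each total is split with moderate inequality —
  [60,45,40,32,28], [63,45,35,30,25,21], [85,52,40,35,30,26,23,18,16,14],
  [15,12,11,8] — such that the chance expectation `Σn_i²/N` reproduces the
  published expected-correct counts 44, 42, 46 and 12.
* Separation dials calibrated once so preset jack-knifed accuracies land in
  the published regimes: warbler parasitized 0.55 (~80%), warbler
  unparasitized 0.25 (~55%), weaver parasitized 0.45 (~64%), weaver
  unparasitized 1.0 (~95%; large enough to be near-perfectly classified,
  small enough that the pooled outlier screen strips at most a few eggs
  rather than whole species).
* Host-race fidelity 0.95 (warbler-like specialists; two races have 2 and 1
  eggs, exercising the low-n exclusion rule) and 0.3 (weaver-like
  near-generalists, 12–25 eggs each).

What it does **not** emulate: real reflectance spectra of particular taxa,
egg 3-D geometry, non-Gaussian trait distributions, clutch-level signature
polymorphism beyond a simple within-clutch variance split, or any true
phylogenetic structure in species means (species means are drawn
independently of the trees, which is why low λ is the expected outcome).
Passing tests therefore demonstrate that the machinery recovers planted
structure under the model's own assumptions — not that real egg data meet
those assumptions.

## Numerical choices and problem sizes

Default test and validation sizes: parameter recovery for λ uses 200-tip
trees with 100 replicates per true value (recovery bias < 0.1 for λ ∈ {0,
0.5, 1}); the sign-reproduction experiment uses 50 seeded two-group
communities of 4 + 4 species × 25 clutches; the fidelity sweep uses 3-host
communities of 60 clutches per species with 30-egg races. Multivariate
draws use the `eigh` method of numpy's Generator for cross-platform
determinism. Degenerate inputs fail loudly: non-PSD covariances name the
offending species, constant traits and singular covariances raise, a group
of one names the group, and an empty candidate-tree set after skipping
raises rather than returning an empty summary.

## Known limitations

The paired mimicry t-test assumes the per-race differences are roughly
normal — with 3–5 races the test is coarse, exactly as in the motivating
study design. The Wald binomial CI degenerates to ±0 at 0% or 100%
accuracy. The chance-null Fisher table treats the expected count as if it
were an observed count, which is a modelling convention, not exact
inference. Logistic "accuracy" is resubstitution and therefore optimistic
relative to the jack-knifed DFA column it sits beside.
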