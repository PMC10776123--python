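# Methods

This note documents the statistical procedures, their tunable
parameters, the synthetic-data model, and the numerical and design
choices behind `metaboaging`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Trend typing

Each metabolite's abundances are log2-transformed and tested across the
three ordered groups A < B < C (e.g. 22, 37 and 52 weeks of age) with a
one-way fixed-effects ANOVA followed by all-pairs Tukey HSD. The
Tukey–Kramer form is used so unequal group sizes (dropped samples) stay
legal: for groups i, j with means m_i, m_j and sizes n_i, n_j,

    q_ij = |m_i − m_j| / sqrt( MSE/2 · (1/n_i + 1/n_j) ),

referred to the studentized range distribution with k = 3 and
df = N − 3. A single significance level α (default 0.05) serves both
tests; there is no multiplicity correction across metabolites by
default (a BH option exists), matching the per-metabolite p < 0.05
convention of comparative metabolomics.

**Taxonomy.** With d1 = m_B − m_A and d2 = m_C − m_B, the sign pattern
(d1, d2) gives the direction: (+,+) up, (−,−) down, (+,−) bell-shaped
inversion, (−,+) U-shaped inversion. Within a direction the
significance pattern of the Tukey triple gives four subtypes: A–B
significant (`early`), B–C significant (`late`), both (`both`), or
neither consecutive comparison but the A–C endpoint comparison
significant (`gradual`). Profiles with no significant comparison are
`no_change`. 4 × 4 + 1 = 17 types in 5 groups; the classifier is a
total function (enumeration-tested), bell always has the middle peak,
and raising α can only move calls out of `no_change`. Exact mean ties
(d = 0) take the sign of the A–C difference; all-equal means combined
with a significant comparison is rejected as an impossible state.

**Degenerate inputs.** Zero within-group variance with equal means
yields F = 0, p = 1; with unequal means F = ∞, p = 0 (the limiting
behaviour), and pairwise p-values 0 or 1 by mean equality.

**Numerics.** The studentized-range survival function is evaluated by
a vectorized 160-node Gauss–Legendre quadrature of the classical
double integral (scale mixture over the χ distribution of the pooled
SD, range probability inside). It matches `scipy.stats
.studentized_range.sf` to ~1e-14 while being ~10³× faster on arrays,
which is what makes simulation-scale testing (thousands of Tukey
triples) practical. scipy's implementation remains the oracle in the
test suite.

## Co-abundance network and modules

Pearson correlations are computed between all metabolite pairs across
all samples of all time points on the log10 scale (the comparative
scale; a log2 flag exists). Two-sided p-values use the t transform
with df = n_samples − 2 (at least 4 samples required); adjustment is
Benjamini–Hochberg over all unique pairs (Bonferroni available).
Edges require **r > 0.7 strictly** and adjusted p < 0.01; only
positive correlations qualify by default (absolute-value mode behind a
flag) — the network is one of co-abundance, not co-variation.
Constant metabolites are excluded from pairing with a warning but kept
as isolated nodes.

**MCL** is implemented from scratch on the column-stochastic
transition matrix with unit self-loops: expansion (matrix power 2),
inflation (elementwise power 2.0 with column renormalization), pruning
(entries < 1e-5 zeroed, renormalized), iterated until the maximum
entry change falls below 1e-6 or 100 iterations (non-convergence
returns the current clustering with a flag). Clusters follow the
attractor interpretation — rows with overlapping nonzero support are
merged — and isolated nodes become singletons. The partition is
invariant to node relabeling.

## Integrated Value of Influence

Per node: degree DC; neighborhood connectivity NC (mean neighbor
degree, 0 for isolates); unnormalized shortest-path betweenness BC
(only relative ranks matter after normalization, so the normalization
convention is inert); local H-index LH = h(i) + Σ_{j∈N(i)} h(j), with
h the neighbor-degree H-index; ClusterRank CR = 10^(−c_i) ·
Σ_{j∈N(i)} (deg j + 1), with c_i the local clustering coefficient and
c := 0 for degree ≤ 1 nodes (the limiting convention, maximizing the
CR weight); collective influence CI = (deg − 1) · Σ (deg_j − 1) over
the frontier exactly ℓ = 3 steps away (an empty frontier contributes
0; ℓ is configurable). Each raw vector is range-normalized to
[1, 100] via 1 + 99·(x − min)/(max − min), a constant vector mapping
to all-ones; then

    Hubness   = DC' + LH'
    Spreading = (NC' + CR') · (BC' + CI')
    IVI       = range-normalize(Hubness · Spreading).

Regular graphs therefore score IVI = 1 everywhere, and the most
influential node scores exactly 100. Because composite-score
conventions drift between implementations, the package's guarantees
about IVI are rank-based (hub recovery, brute-force equality of each
centrality on small graphs), not value-based. Top-k ranking breaks
ties by degree, then node id.

## Cumulative mortality and ESE inflections

M(t) = deaths(≤ t)/N on integer census weeks; the log10 curve starts
at the first death (M = 0 has no logarithm). Censored animals count
toward N but never toward deaths — standard life-table bookkeeping.

The **extremum surface estimator** computes, for each interior point
i, the left surface a_i = T(1,i) − C(1,i) and right surface
b_i = T(i,n) − C(i,n), where T is the trapezoidal integral of the
data polyline and C the chord trapezoid. For a convex-then-concave
curve the inflection estimate is the midpoint of argmin a and
argmax b; concave-then-convex swaps the extrema. **Orientation** is
chosen by comparing the joint strength of the two candidate extremum
pairs (|min a| + max b versus max a + |min b|): the sign of the
full-span surface alone is unreliable because an asymmetric sigmoid
can have either curvature regime dominate the total signed area (the
quartic with y″ = (x−10)(x−30)/3000 is a concrete counterexample — its
convex-then-concave left half has a positive total surface). Exactly
straight data are recognized via a scale-aware tolerance on the second
divided differences (float fuzz is not curvature) and return a
"no inflection" result distinct from an error.

**Multiple inflections** are found by bounded-depth (4) recursive
bisection: ESE on the full series, split at the estimate, recurse on
both sides. A candidate is kept only when a sign change of the second
differences of the 3-point-smoothed curve lies within three median
grid steps of it, and at most one candidate — the closest — survives
per sign-change location. A sliding-window mode exists behind a flag.
Weeks without census are not interpolated.

## Synthetic data: what it emulates, what it does not

**Abundance.** Intensities are 2^(base + trend offset + noise) with
base log2 mean 20 (~10⁶ counts, a typical LC–MS peak), effect size
2.0 log2 units between adjacent groups, and noise SD 0.3 log2 units.
The default mixture plants 72.1 % no-change and 12.8 % bell-shaped
metabolites (the two proportions the killifish study reports), the
remaining 15.1 % split evenly across up, down and U-shape — the split
is a free choice, documented as such. Correlated modules use a latent
factor per module: x = λ·z + sqrt(1 − λ²)·ε in the noise term, so
within-module correlation is λ² (default λ = 0.9 → r ≈ 0.81). Modules
spanned by a hub share a group factor (inter-module factor correlation
ρ = 0.75) and the hub loads (0.98) on the normalized mean of its
spanned modules' realized factors, giving hub–member correlations near
0.80. A hub loading on k orthogonal factors would correlate with
members at only loading/√k (0.52 for k = 3) — below any useful edge
threshold — which is why the group factor exists. Not emulated: batch
effects, missingness, m/z or retention-time structure, heteroscedastic
intensity-dependent noise. A green planted-truth test therefore
establishes statistical correctness of the pipeline, not robustness to
instrument artifacts.

**Survival.** Discrete weekly sampling: each animal alive at week t
dies with probability 1 − exp(−(H(t) − H(t−1))) under the hazard
h(t) = a·e^(bt) for t < plateau_week and the constant plateau_hazard
afterwards. Defaults: n = 39 (the study's cohort size), a = 1e-4,
b = 0.2 /week, plateau at 45 weeks, plateau hazard 0.1 /week — a
decelerated late-life level chosen so that survivors at plateau onset
die out over roughly a dozen weeks, consistent with a ~60-week maximum
lifespan. The closed-form expected log10 M(t) is available for
noise-free checks.

**Known limitation (mortality-deceleration detection).** Within this
two-piece hazard family the expected log10 cumulative-mortality curve
is *strictly concave*: u′ = H′/((e^H − 1)·ln 10) decreases on both
segments (on the Gompertz segment H′ = bH + a > bH, on the plateau
H″ = 0), so the curve has a concave corner at plateau onset but no
true inflection, and area-based surface extrema drift toward the span
boundaries rather than the corner. A genuine convex bend in log M
requires super-exponential growth of the cumulative hazard — i.e. a
near-zero early-life hazard followed by an onset, which is how real
cohorts produce the classic S-shaped log-mortality curve with an
early-life inflection before the late-life plateau. The ESE machinery
itself is verified on curves that do possess inflections; recovering a
plateau onset from a pure Gompertz-plateau cohort is outside what this
hazard family can express, and the corresponding planted-truth check
documents that gap rather than papering over it.

**Known limitation (hub recovery).** With 21 samples, the realized
variance of shared latent factors fluctuates enough that a hub blob
occasionally saturates into a near-complete subgraph — where all
centralities tie and the hub disappears into symmetry — or fragments.
Dense blobs can also fall below graph diameter 3, zeroing the
collective-influence term for every member. Hub recovery by IVI rank
is therefore strong but not certain at this sample size.

**Fibers.** Lognormal mixtures parameterized by (weight, median μm²,
log-SD); the default three-component mixture produces a realistic
small/medium/large split across the 1000 and 2600 μm² cut points
(boundaries inclusive for medium, as "between 1000 and 2600" reads).

## Other conventions and decisions

- **Deduplication** keys on the putative name (IDs are unique by
  construction; names collide): keep the highest identification
  confidence, break ties by maximum intensity — by default the mean
  across all samples, with a max-single-peak option, since "maximum
  intensity" is ambiguous; final ties fall back to input order.
  Idempotent, and performed on the raw scale.
- **Zeros before log transform**: default is per-metabolite half-minimum
  imputation (half the smallest positive value of that metabolite),
  with an error mode; imputation counts are logged. An all-zero
  metabolite is an error.
- **Lipid parsing** is deliberately minimal — `CLASS(C:D)` shorthand
  plus `…carnitine Cn` text forms; anything else is `OTHER` and
  parsing never raises. Annotations can also be supplied directly,
  bypassing parsing. Class totals sum raw peak intensities (not log
  values) of species with ANOVA p < α, per group; a per-group-mean
  flag exists.
- **Pipeline determinism**: every stage's randomness flows from the
  config seed; a manifest (config hash + seed) is written next to the
  outputs; rerunning a config byte-reproduces the result bundle.
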