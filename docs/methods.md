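# Methods

## Study design being modelled

The package analyses a nested 2×2 between-animal factorial: fluid (chronic
binge-like EtOH drinking vs H₂O) crossed with chemogenetic treatment (CNO
activating an excitatory Gq DREADD vs vehicle).  Several Golgi-stained
medium spiny neurons are reconstructed per animal (cells nested in brains),
and one bulk RNA-seq library is collected per animal.  The scientific
pattern of interest is *amelioration*: an EtOH-induced increase in
dendritic branching, and EtOH-induced expression changes, that are present
in EtOH(VEH) animals but absent when CNO is on board.

## Morphometry conventions

An SWC reconstruction is a rooted tree of 3-D points.  Soma points carry no
length; a *stem* (primary dendrite) is a dendrite point whose parent is a
soma point, and the soma centroid (mean of soma points) is the origin for
all radial measures.  The eight per-neuron parameters are:

- `n_dendrites` — number of stems;
- `n_nodes` — points with ≥ 2 dendritic children (a multifurcation is one
  node);
- `n_ends` — tips;
- `total_length` — Σ Euclidean lengths of dendrite-to-dendrite segments
  (µm); zero-length segments are dropped with a warning;
- `avg_dendrite_length` — total_length / n_dendrites;
- `sum_terminal_orders` — for each tip, the number of sister branches
  passed walking back to the soma (a point with c children contributes
  c − 1 to every descendant tip), summed over tips; an unbranched
  dendrite's tip has order 0.  Whether commercial tracing software starts
  this count at 0 or 1 is not standardised; the sister-counting definition
  above is used consistently and is flagged here rather than guessed at.
- `branch_sum` — number of maximal unbranched segments (equivalently
  n_nodes + n_ends, verified both ways);
- `complexity` — (sum_terminal_orders + n_ends) × avg_dendrite_length, µm.

Units are fixed to µm; no unit inference is attempted.

## Sholl analysis

Radial distance is 3-D Euclidean distance from the soma centroid (tracings
are 3-D; a 2-D projection convention would not conserve length).  Shells
are half-open `[k·w, (k+1)·w)` with w = 10 µm by default; a point exactly
on a boundary belongs to the outer shell.  Along a straight segment the
squared distance is quadratic in the path parameter, so boundary crossings
are the real roots of that quadratic in (0, 1): re-entrant segments count
one crossing per sign change, tangencies count zero, and an endpoint
exactly on the sphere counts only if the segment's other endpoint is
strictly inside (ties are thus exact and testable).  Shell lengths are
apportioned by cutting every segment at its crossing parameters, which
makes Σ shell length equal total dendritic length to machine precision.
AUC uses the trapezoid rule — on the boundary-radius grid for
intersections and on shell midpoints for binned measures; the rule is a
fixed convention since "area under the curve" alone does not pin one down.

## Mixed-model inference

Each response (one morphometric parameter, one Sholl AUC, or one per-radius
Sholl value) follows

y_ij = x_ij′β + u_i + ε_ij,  u_i ~ N(0, σ_u²), ε_ij ~ N(0, σ_e²),

with animal i random and treatment-coded fixed effects for fluid,
treatment and their interaction.  Estimation is maximum likelihood — not
REML — so likelihood-ratio tests between nested fixed-effect
specifications are valid.  For fixed λ = σ_u²/σ_e², β̂ and σ̂_e² are exact
GLS/profile solutions using the block structure of V = I + λZZ′; the
profiled log-likelihood is maximised over λ ∈ [0, ∞) on a log grid
(41 points, 10⁻⁴–10⁴) refined by golden-section search, with the boundary
λ = 0 permitted.  Perfectly-fitting degenerate responses are floored at a
relative residual variance of 10⁻¹², which makes the LRT of two saturated
models exactly zero.  Main effects are tested by dropping each term from
the additive model; the interaction by full vs additive (a type-II
convention — the alternative of testing mains from the full model is noted
as an open choice and not mixed in).  Each single-term LRT uses χ²(1).
Variance components are never tested, avoiding the boundary-null χ²
mixture problem.

FDR families: the eight morphometric parameters form one BH family per
effect; Sholl radii form one family per (measure, effect); the four Sholl
AUCs one family per effect.  Results carry three tiers: q < α, nominal
p < α only, or neither.  The family definitions are stated in the report
header since different groupings are defensible.

Small-sample behaviour: the fluid effect is a between-animal contrast, so
with ~32 animals the ML likelihood-ratio test is mildly anticonservative —
measured type-I error ≈ 0.06 at α = 0.05 in the calibration the acceptance
script reruns, and indistinguishable from lme4/statsmodels ML fits (the
implementation agrees with statsmodels MixedLM to < 10⁻⁴ in log-likelihood).
This is a property of ML LRTs at this design size, not of the
implementation; users who need exact small-sample control should increase
animal counts or apply a parametric bootstrap outside this package.

## Expression screen

log-CPM is log₂((count + 0.5)/(libsize + 1)·10⁶); genes with mean plain
CPM < 1 are removed before testing.  A gene-wise cell-means model over the
four groups yields residual variances s_g² on d_g df; the empirical-Bayes
prior (d₀, s₀²) is estimated by moment matching of log s_g² (digamma/
trigamma equations solved by Newton), and posterior variances
s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g) give moderated t statistics on
d₀ + d_g df.  d₀ = 0 recovers the ordinary t-test; d₀ = ∞ pools all
variances; estimation failure falls back to a configurable fixed d₀ with a
warning.  Precision weights (voom) are deliberately not applied — the
moderated t is computed on unweighted log-CPM — which leaves a small,
measured anticonservativeness on negative-binomial data (null DEG rate
≈ 0.047–0.052 at p < 0.05 in the acceptance reruns).

DEGs are called at unadjusted p < 0.05 per contrast against H₂O(VEH) (an
optional BH mode exists but is off by default, matching the screen's
permissive discovery stage).  The three DEG lists are partitioned into
their seven disjoint Venn regions.  The amelioration score of a gene is,
by default, the Euclidean distance between its EtOH(VEH) and EtOH(CNO)
contrast effects, |lfc_EV − lfc_EC| — large when CNO removes a binge
response; a documented `all_pairs` switch uses the full pairwise distance
among the three contrast effects, since the phrase "pairwise distance in
expression patterns" admits both readings.  Ranking is restricted, as in
the screen's intended use, to the DEGs unique to EtOH(VEH); ties break by
gene id.  The mediator panel report evaluates a curated list of
structural-plasticity genes (11 core members shipped; the published panel
has 57, the remainder user-supplied) under the two within-treatment
EtOH vs H₂O contrasts, with p-value stars and explicit missing-gene flags.

## Synthetic data: what it emulates, and what it does not

**Neurons.**  Growth is a stochastic binary branching process: a segment of
branch order o has lognormal length (mean 35 µm, SD 12 µm), is traced in
2 µm steps with Gaussian heading jitter (SD 0.15 rad per step), and
bifurcates with probability `branch_prob` while o < `max_order`.  Defaults
(5 stems, branch_prob 0.45, max_order 6) give trees with roughly 5–15
nodes and several hundred µm of dendrite — medium-spiny-neuron-like scale.
This growth model was chosen because it produces exactly the statistics
the morphometry stage measures; it does not emulate tortuosity profiles,
diameters/taper, spines, or tissue boundary effects of real Golgi
material, so passing recovery tests demonstrates correctness of the
pipeline, not realism of any particular biological effect size.

**Cohorts.**  Group sizes default to 4 animals per design cell and 7 cells
per animal, the scale of the morphology cohort in the packaged accounting
table (4–5 animals, ~7 cells/brain, 117 cells from 17 animals).  Animal
heterogeneity is a shared lognormal multiplier on branch_prob (log-SD
0.075); EtOH multiplies branch_prob by 1 + e (default e = 0.60) in
EtOH(VEH) and by 1 + e(1 − a) in EtOH(CNO), so the amelioration fraction
a = 1 (default) makes the two CNO groups identically distributed.  No
published effect-size estimates exist for these morphometric responses, so
e and the animal SD are free parameters; they were fixed once by a power
calibration so that the planted effect is detected (q < 0.05) for the
complexity / terminal-order / branch-sum trio with ≥ 90% power at the
default cohort size while keeping a clearly nonzero within-animal
intraclass correlation — i.e. the generator represents a strong,
unambiguous binge effect of the kind the inference stage is meant to
resolve, not a marginal one.  Per-animal and per-cell random streams are
split from the master seed with counter-based `SeedSequence` keys, so
growing the cohort never changes existing animals' draws.

**Counts.**  Genes get lognormal baseline abundances (log₂ mean 5, SD 2),
samples get lognormal library sizes (mean 2×10⁷, CV 0.3), and counts are
gamma-Poisson with dispersion 0.08 — typical bulk-brain values.  600 binge
genes carry log₂ fold changes ~ N(0, 1) in EtOH(VEH); half of them
(amelioration fraction 0.5) lose the effect in EtOH(CNO)
(*binge-ameliorated*) while the rest keep it (*binge-only*); 600 further
genes respond to CNO in both fluids; group-wise abundances are
renormalised so effects are compositionally consistent.  Twelve samples
per group match the sequencing cohort's n = 11–12.  The simulator omits
batch effects, gene–gene correlation, GC/length biases and outlier
samples, so screen-recovery results bound what the method does under its
own assumptions only.

## Numerical and degenerate-input choices

- λ-search grid 10⁻⁴–10⁴ (41 points) + golden-section to 10⁻⁹ on log₁₀λ;
  boundary λ = 0 always evaluated and allowed to win.
- Singular fixed-effect designs (confounded factors) raise a dedicated
  error rather than returning pseudo-inverse estimates.
- Zero-variance responses are skipped with a warning; a manifest cell
  missing from an input table is a hard error naming the cell.
- Sholl tie-breaks (boundary membership, endpoint-on-sphere crossings) are
  fixed as described so tests can assert exact integers.
- BH is step-up with enforced monotonicity, returned in input order;
  single p-values pass through unchanged.
- The trigamma inverse uses Newton iteration with the standard asymptotic
  endpoints (1/√y for large y, 1/y for small).

## Problem sizes used by the validation scripts

The acceptance rerun uses 500 replicates for LRT type-I error (32 animals,
192 cells each), 200 replicates for effect recovery (160 animals), 20
cohort replicates per power arm, a full default-size count simulation
(20 000 genes × 48 samples) for screen recovery, and 20 × 500-gene null
simulations for the DEG rate — sizes chosen to keep Monte-Carlo error
comfortably below the decision margins they feed.

## Known limitations

- ML-LRT anticonservativeness at small animal counts (quantified above);
  no Satterthwaite/Kenward–Roger or bootstrap correction is provided.
- No voom precision weights; moderated t on log-CPM only.
- WGCNA-style network construction, GO/TF enrichment, behavioural ANOVAs
  and image-based tracing are out of scope.
- The amelioration distance is an effect-pattern heuristic, not a test; it
  carries no error control.
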