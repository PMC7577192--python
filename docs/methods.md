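# Methods

## Overview

`metabonet` infers two networks from a cross-sectional biomarker
cohort, per age group, and characterises their structure. The
pipeline is: read/validate → cell-level cleaning → age stratification
→ pathological-state assessment → network inference (continuous and
dichotomous) → graph metrics → conditional-uniform-graph null tests →
age-trend statistics. Every stage is deterministic given its seed.

## Cohort handling

The analytic substrate is a participants × {age, sex, 15 biomarkers}
table. Cleaning masks *cells*, never drops participants: a value
outside a permissive plausibility range (e.g. axillary temperature
outside 30–43 °C, glucose outside 1–40 mmol/L, systolic pressure
outside 60–260 mmHg) is treated as a recording error "incompatible
with life" and set missing, with every masked cell reported and
logged. A cross-field rule masks waist values whose waist/height
ratio falls outside a configurable window (default 0.25–1.0): such
pairs are mutually inconsistent, and waist is by far the more
error-prone measurement. Cleaning is total and idempotent.

Age strata are half-open `[lower, upper)` bins; the defaults are
<25, 25–34, 35–44, 45–54, 55–64 and 65+ (open top bin). The bins
partition the cohort for any boundary choice; ages below the first
boundary are a hard error, since adult thresholds do not apply.

## Pathological states

Twelve binary states are derived from threshold rules in a fixed
order. Comparisons with a cut-off are strict (`>` / `<`); a state is
missing whenever any input is missing. Two derived indices feed the
rules:

* **HOMA-IR** = glucose [mmol/L] × insulin [µU/mL] / 22.5, with basal
  insulin converted from pmol/L by a configurable factor (default
  6.945; the literature uses 6.0–6.945). Cut-offs 1.7 (M) / 1.8 (F).
* **eGFR**: CKD-EPI 2009 creatinine equation without the race
  coefficient (configurable to include 1.159), creatinine converted
  µmol/L → mg/dL by ÷ 88.4. Cut-off < 90 mL/min/1.73 m².

High blood pressure is true when *either* systolic > 120 or
diastolic > 80 mmHg. The harmonized metabolic-syndrome flag is a
separate construct with its own conventions: at least 3 of 5
criteria, each with `≥` (waist M > 90 / F > 80 cm is the exception,
matching the waist state), blood pressure at the lower prevention
threshold 130/85, and no medication criterion (biomarker-only data).
The two blood-pressure thresholds (120/80 state vs 130/85 MetS)
deliberately coexist.

Age trends are reported two ways: per variable, the OLS slope of the
raw value on continuous age (units/year, two-sided *t* test); per
state, a Cochran–Armitage chi-square test for trend across the
ordered strata with **midpoint-age scores** ((lower+upper)/2; the open
top bin is scored lower + 5, i.e. 70 for the 65+ bin, matching its
observed mean age). With two strata the statistic reduces exactly to
the uncorrected Pearson chi-square of the 2×2 table, which is how it
is unit-tested.

## Network inference

**Physiological network.** Spearman correlations are computed on
pairwise-complete observations with average ranks for ties; the
two-sided p-value uses the *t* approximation
t = ρ√((n−2)/(1−ρ²)). An edge is kept when p < α (default 0.001 —
at n = 2572 this corresponds to |ρ| ≳ 0.065); the weight is ρ², the
signed ρ is kept as an edge attribute. Squaring makes weights valid
capacities/strengths while discarding sign; no multiple-testing
correction beyond the fixed gate is applied. Rank-based inference
makes the network invariant under strictly monotone transforms of any
variable (a tested property).

**Pathological-states network.** For each ordered pair (X, C) of
states, computed over participants non-missing for both,

    ε(C|X) = N_x (P(c|x) − P(c)) / sqrt(N_x · P(c) · (1 − P(c)))

is the z-score of the observed co-occurrence count against the
binomial Binom(N_x, P(c)) expected under independence. The arc X→C is
kept when ε > 1.96, the two-sided 95% normal quantile, with ε as the
weight. ε is undefined (and logged) when P(c) ∈ {0, 1} or N_x = 0.
Because the denominator scales with the conditioning set, ε(C|X) and
ε(X|C) differ in magnitude though never in sign — the source of the
network's directionality.

## Graph metrics

* **Eigencentrality** (undirected): principal eigenvector of the
  weighted adjacency by power iteration (tolerance 1e-10) from the
  uniform start vector, with a diagonal shift so that bipartite
  spectra cannot oscillate; nonnegative, rescaled to max = 1.
* **Hub / authority** (directed): principal eigenvectors of A·Aᵀ and
  Aᵀ·A (the HITS fixed point), computed by dense symmetric
  eigendecomposition, rescaled to max = 1. Nodes without outgoing
  arcs get hub score 0.
* **Flow betweenness**: edge weights act as capacities; a node's
  score is the total all-pairs max-flow lost when it is removed
  (unordered pairs for undirected networks, ordered for directed;
  directed max-flow uses directed capacities). Exhaustively
  cross-checked against an independent max-flow implementation on
  random graphs with n ≤ 8.
* **Largest cliques**: Bron–Kerbosch with pivoting on the undirected
  (symmetrised) view, keeping all maximum-size cliques; membership
  frequency counts, per node, in how many of the supplied networks it
  belongs to at least one largest clique (0..7 for the study design of
  pooled + six strata).
* **Communities**: Louvain (weighted modularity) for undirected
  networks; the Reichardt–Bornholdt spinglass annealer (via igraph,
  25 spins max, seed-reproducible) on the symmetrised weighted graph
  for directed ones, run per connected component. Components of ≤ 2
  nodes are assigned directly — a connected pair is necessarily one
  community, and the annealer does not terminate on 2-node graphs.
  Reported Q is always recomputed from scratch on the final
  assignment with the package's own modularity function.
* **Topology**: density m/[n(n−1)/2] (undirected) or m/[n(n−1)]
  (directed); reciprocity = reciprocated arcs / arcs; characteristic
  path length L = mean *unweighted* shortest-path length over
  connected ordered pairs (disconnected pairs excluded and logged;
  weighted-distance L is deliberately not the default, matching the
  conventional hop-count definition); global transitivity = 3 ×
  triangles / connected triples on the binarized, symmetrised graph.
* **Weighted clustering**: Barrat's local coefficient
  C_i = [1/(s_i(k_i−1))] Σ (w_ij + w_ih)/2 · a_ij a_ih a_jh for
  undirected networks (reduces exactly to the unweighted coefficient
  at unit weights), and the Clemente–Grassi total coefficient with
  W̃ = (W + Wᵀ)/2 and total degrees for directed ones (reduces to
  Barrat on a symmetric digraph — both reductions are tested, plus a
  cross-check against igraph's Barrat implementation). Nodes with
  fewer than two neighbours are undefined and excluded from the
  network mean ± SEM.
* **Small-world index**: SWI = (CC/CC_rand)/(L/L_rand) on the
  binarized (symmetrised) graph with the Humphries–Gurney closed-form
  references CC_rand = density and L_rand = ln(n)/ln(mean degree),
  chosen over rewired-null Monte Carlo because they are deterministic
  and directly testable (Erdős–Rényi graphs score ≈ 1); undefined for
  mean degree ≤ 1. Both the binarized and the weighted clustering
  means are emitted, labelled, since "clustering coefficient" is
  ambiguous between the two.

## Null models (CUG tests)

A CUG test redraws the binarized structure R times (default 1000)
under one of three conditionings — *size* (each tie Bernoulli(1/2)),
*edges* (uniform over graphs with the observed tie count), or
*dyad census* (mutual/asymmetric/null counts preserved; directed
only) — recomputes the statistic per draw, and reports two one-sided
p-values (ties counted on both sides, so p_greater + p_less ≥ 1).
Observed weights are reassigned uniformly at random to the drawn
ties, preserving the weight distribution while randomising structure.
Draws are reproducible from the seed, and the conditioning invariants
(exact edge count, exact dyad census) are asserted in tests on every
draw. Calibration is verified empirically: when the observed graph is
itself drawn from the null, p_greater is uniform. Note the ≥ tie
convention makes p-values slightly conservative for coarsely discrete
statistics; the calibration experiment therefore uses dense 12-node
graphs (40 of 66 edges), where the transitivity support is fine
enough for a Kolmogorov–Smirnov comparison to apply.

## Synthetic cohorts

The generator exists because the downstream analysis consumes exactly
two features of the data: rank correlations and threshold
exceedances. A Gaussian copula controls both directly: a latent
multivariate normal with correlation 2·sin(π·ρ_s/6) — the exact
latent Pearson correlation that produces a target Spearman ρ_s — is
pushed through each variable's marginal quantile function. Marginal
families are normal by default and moment-matched lognormal for the
right-skewed labs whose reported SD is comparable to their mean
(insulin, triglycerides, creatinine). The elementwise sine transform
can break positive semi-definiteness slightly; eigenvalues are
clipped at 1e-8 and the matrix rescaled to unit diagonal, with a hard
error (reporting the smallest eigenvalue) below −0.05.

The default specification reproduces the study conditions: six strata
of sizes 680/528/445/468/352/99 (total 2572), ages uniform within
each stratum's range (18–24 … 65–81), 65% female, and the published
per-stratum means ± SD for all 15 variables. The default dependence
matrix is a documented package fixture, not an estimate from the
study: moderate positive blocks among adiposity, glycaemic, lipid,
renal and pressure variables with physiologic cross-links and
negative HDL couplings, chosen so that threshold states co-occur
above chance at study-like sample sizes.

What the generator does *not* emulate: within-stratum age gradients
(marginals are constant inside a stratum), age-varying dependence
(one copula serves all strata, so the "transitivity peaks in
mid-life" pattern of real cohorts is not reproduced — a flat curve is
in fact used as a negative control in the tests), measurement error
structure, and any longitudinal within-person correlation. Passing
tests therefore demonstrate correctness of the machinery under known
truth, not epidemiological realism. One source-table inconsistency is
inherited knowingly: taking the printed temperature marginals at face
value (e.g. 37.2 ± 0.5 °C in the youngest stratum) puts roughly half
the synthetic cohort above the 37 °C cut-off, where the study reports
~1% prevalence — the published mean/SD and the published prevalence
are not jointly reproducible by any unimodal marginal. Several other
low-precision printed SDs ("5 ± 2") similarly inflate synthetic state
prevalences relative to the study's.

## Problem sizes and tolerances

The test suite verifies the copula at n = 5000–10000 (dependence
recovery within 0.05 elementwise), planted two-block recovery over 50
seeds (≥ 95% exact recovery), CUG calibration with 500 × 500
replicates, the type-I error of the α = 0.001 edge gate over 500
independent cohorts at n = 2572, and all oracle equivalences at
1e-8–1e-12. The acceptance script runs the full pipeline at the
default study size (n = 2572, CUG R = 200); the whole suite and the
script each complete in a few minutes on one core.

## Known limitations

* ε is computed on complete pairs per state pair; with informative
  missingness this basis differs between pairs.
* L excludes disconnected pairs rather than penalising them, which can
  flatter very sparse networks (and inflate their SWI).
* The spinglass annealer is stochastic; only its seed-fixed runs are
  reproducible, and its Q can fall marginally below Louvain's.
* No partial-correlation or lagged network variants; associations are
  marginal and cross-sectional, so no causal reading is warranted.
* Degree-sequence-preserving (configuration-model) nulls are not
  provided; the CUG families are size, edges, and dyad census.
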