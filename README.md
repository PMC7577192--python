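# metabonet

Age-stratified **metabolic physiological network** analysis: from a
participant-level biomarker table to two inferred networks per age
group, their centrality/community/topology characterisation, and
null-model tests.

Metabolic homeostasis emerges from the coupling of many regulatory
subsystems — glycaemic, lipid, renal, adiposity, blood pressure.
`metabonet` models that coupling in a cross-sectional cohort in two
complementary ways:

* **Physiological network** (undirected): nodes are 15 continuous
  biomarkers (fasting glucose, HbA1c, basal insulin, HDL, LDL,
  triglycerides, uric acid, urea, creatinine, waist, weight, height,
  axillary temperature, systolic and diastolic pressure). An edge
  joins variables whose Spearman rank correlation is significant at
  *p* < 0.001 (two-sided, *t* approximation); the edge weight is
  ρ² so that weights are positive while the signed ρ is retained.
* **Pathological-states network** (directed): nodes are 12 binary risk
  states derived by literature cut-offs (hyperglycemia, high HbA1c,
  insulin resistance via HOMA-IR, low HDL, high LDL,
  hypertriglyceridemia, hyperuricemia, azotemia, low eGFR via CKD-EPI,
  overweight, high temperature, high blood pressure). For an ordered
  pair (X, C) the arc weight is the binomial z-score

  ε(C|X) = N<sub>x</sub>(P(c|x) − P(c)) / √(N<sub>x</sub> P(c)(1 − P(c)))

  comparing observed co-occurrence among the N<sub>x</sub> carriers of
  X with its expectation under independence; an arc is kept when
  ε > 1.96 (the 95% normal quantile). ε is not symmetric, which gives
  the network its directionality.

Both networks are built for the pooled sample and for six age strata
(<25, 25–34, 35–44, 45–54, 55–64, 65+) and characterised by
eigencentrality, HITS hub/authority scores, flow betweenness
(all-pairs max-flow lost when a node is removed — a gatekeeping
measure), largest cliques, Louvain and spinglass communities,
density, reciprocity, characteristic path length, weighted transitivity
(Barrat / Clemente–Grassi), and the Humphries–Gurney small-world
index. Conditional uniform graph (CUG) tests compare every statistic
against random graphs of the same size, edge count, or dyad census.

A Gaussian-copula **synthetic cohort generator** reproduces the study
conditions (six strata of sizes 680/528/445/468/352/99, 65% female,
published per-stratum biomarker means ± SD, configurable Spearman
dependence), so the whole pipeline is testable without access to the
original data.

## Worked example

```python
import metabonet as mn

spec = mn.default_study_spec(seed=42)
cohort, report = mn.clean_cohort(mn.generate_cohort(spec))

assoc = mn.spearman_matrix(cohort)
physio = mn.build_physio_network(assoc, alpha=0.001)

states = mn.assess_states(cohort)
patho = mn.build_patho_network(states, threshold=1.96)

ec = mn.eigencentrality(physio)
fb = mn.flow_betweenness(physio)
part = mn.louvain(physio, seed=0)
topo = mn.topology_summary(patho)
mets = mn.mets_harmonized(cohort)
```

prints (via the obvious `print` statements):

```
cohort: 2572 participants, 125 cells masked
physiological network: 59 edges, density 0.56
pathological network: 79 arcs
most influential variables: waist, weight, triglycerides
top gatekeepers: uric_acid, weight, waist
louvain: 4 communities, Q = 0.302
patho topology: density 0.60, transitivity 0.77, L 1.28, SWI 1.31
MetS prevalence: 33.6%
```

Reading the output: 125 synthetic cells fell outside the plausibility
ranges and were masked (never whole participants). Of the 105 possible
biomarker pairs, 59 correlate significantly — adiposity (waist,
weight) is the most *influential* node set (eigencentrality), while
uric acid is the strongest *gatekeeper* (flow betweenness): removing
it disconnects the most correlation flow between subsystems. Louvain
recovers four physiologic modules (glycaemic, renal, adiposity/lipid,
blood pressure). The directed states network is dense and transitive,
with a harmonized metabolic-syndrome prevalence of 33.6% in this
synthetic cohort.

## Command line

```sh
metabonet simulate --seed 42 --out cohort.csv      # synthetic cohort
metabonet run --input cohort.csv --seed 42 --out report/
metabonet metrics --graph report/physio_total.graphml
```

`metabonet run` writes GraphML and edge-list CSVs for all 14 networks
(2 kinds × 7 groups), tidy CSV tables (topology, centralities, trend
statistics, prevalences, clique/cluster membership frequencies), CUG
results as JSON, and a manifest with a hash of the analytic
configuration; re-running with the same configuration and seed
reproduces identical numeric content.

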