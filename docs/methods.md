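# Methods

## Model and procedure

The pipeline predicts a future disease diagnosis (the running example is
Parkinson's disease) from coded EHR history alone, years before the first
diagnostic code, by projecting patients onto a typed biomedical knowledge
graph.

**Graph and transition structure.**  The graph is a set of typed nodes
(Disease, Symptom, Gene, Compound, SideEffect) and labelled edges.
Propagation runs on a column-stochastic transition matrix in which column
*j* spreads mass uniformly over the neighbors of node *j*.  Edges are
traversed bidirectionally by default — the source relations are semantic,
not causal, and the method's intent is information flow in both directions;
a directed mode exists behind a flag.  Edges are unweighted because no
weighting scheme is part of the method definition.  Nodes are ordered
lexicographically by id so all matrices are reproducible across runs.
Columns with no out-edges (possible in directed mode) are flagged dangling;
their mass is redistributed onto the restart vector during propagation, the
standard PageRank convention.

**Propagated entry vectors.**  For a mapped EHR concept *c*, the embedding
is the fixed point of

    v ← d·(T·v + m·r) + (1 − d)·r

where *r* is the restart distribution, *d* the damping factor and *m* the
mass currently on dangling nodes.  The restart distribution is
cohort-weighted: weight at entry node *y* equals the number of cohort
patients carrying *c* who also have an event mapping to *y*, normalized to
sum 1; a concept with no carriers falls back to unit mass on its own node.
This couples the embedding to the cohort's co-occurrence structure, which is
the point of the construction: concepts that travel together in the cohort
restart into overlapping neighborhoods.  Because the restart weighting
depends on the cohort, embeddings are recomputed per cohort per horizon.

**Patient signatures.**  A patient's signature is the L1-normalized sum of
the embedding rows of their *distinct* mapped concepts.  Multiplicity is
deliberately ignored (a concept is a fact about the patient, not a count);
a count-weighted mode exists behind a flag.  Rows therefore live on the
probability simplex, and every feature is a graph node.

**Cohort rules.**  Case index date t0 is the first PD diagnostic code, or
the first PD medication when that is earlier.  Cases need ≥2 PD codes with
one at least 182 days after t0.  Cases with a neuroleptic medication in the
half-open window (first code − 182 d, first code] are excluded (drug-induced
parkinsonism look-alikes); the look-back anchors on the first diagnostic
code even when a medication defines t0, following the rule's clinical
rationale.  Everyone under 40 years at index is excluded.  Controls anchor
at last visit − 182 days.  The horizon-*h* model sees events strictly before
t0 − 365·h, so windows nest (−5 ⊆ −3 ⊆ −1).  Calendar phrases are fixed-day
arithmetic throughout: 6 months = 182 days, 1 year = 365 days.  Training
populations are rebalanced to a prevalence-matched case:control ratio
(default 572 per 100,000, i.e. floor(n_cases·100000/572) controls sampled
without replacement); experiments on small synthetic cohorts override this
to use all generated controls.

**Classification and evaluation.**  A random forest (200 trees, class
weights n/(2·n_class)) or logistic regression is fit on an 80:20 stratified
split.  Test-set AUC is bootstrapped: 100 replicates of 50 patients drawn
with replacement, redrawn until both classes are present (the source
procedure does not say how mixed replicates are enforced; rejection
resampling is the simplest mechanism).  The 95% CI is the 2.5/97.5
percentile pair.  Method AUC distributions are compared by Welch's t-test
(two-sided) or the two-sample Kolmogorov–Smirnov test.  Per-feature
screening uses the two-sided Mann–Whitney U test, exact when n1·n2 ≤ 200 and
tie-free, otherwise the tie-corrected normal approximation; constant columns
are assigned p = 1 and flagged.  Benjamini–Hochberg q-values are reported
alongside raw p.  Feature importances are reported as midrank percentiles,
100·(midrank − 0.5)/N, so an all-equal distribution sits at 50.

**Baselines.**  (1) Raw codes: binary patient × mapped-concept indicators,
restricted to graph-mappable concepts for a fair comparison.  (2) MDS
prodromal criteria: posterior odds = prior odds(age band) × ∏ marker LRs,
with LR+ for present markers, LR− for assessable-but-absent markers and 1
for markers not assessable from codes.  The shipped marker LRs and age
priors are editable defaults seeded from the published criteria literature;
the 40–49 band (prior 0.002) is extrapolated below the published range so
the default synthetic age span is covered.  The EHR-code→marker map is
dataset-specific configuration; the synthetic pipeline assigns one prodromal
concept to each leading assessable marker.

**Explanatory subnetworks.**  A prediction is explained by the subgraph
linking the patient's entry nodes to a focus node: relay candidates are
nodes *v* with dist(entries, v) + dist(v, focus) ≤ 2, ranked by the
patient's signature value with node-id tie-break and truncated to the top
25.  This deterministic rule replaces manual figure curation; both
parameters are exposed.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any real vocabulary or schema.

*Graph*: 80 nodes (15 Disease, 25 Symptom, 20 Gene, 12 Compound, 8
SideEffect), a deterministic path backbone over sorted node ids (keeps the
graph connected and gives it large diameter), 8 designated prodromal entry
nodes wired directly to one target disease node, and independent background
edges at probability 0.02 per remaining pair.  40 Disease/Symptom/Compound
nodes are EHR-mappable entry concepts.

*Cohort*: every patient emits each entry concept as a Poisson process at a
shared background rate totalling 3 events/patient-year.  Cases receive an
index day uniform in the central 60% of a 5475-day observation span (so all
horizons have support), two PD codes 183 days apart from t0, and elevated
prodromal-concept rates: for horizon h ∈ {1, 3, 5} the rate multiplier
(defaults 6, 4, 2) applies in the year immediately preceding t0 − 365·h.
The −h model's window therefore contains the signal epochs of horizons
h, …, 5: nearer horizons see strictly more signal, the synthetic analogue of
prodromal symptoms becoming more numerous as diagnosis nears.  Ages at index
are uniform on 45–90 years.  Controls receive a pseudo-index from the same
distribution and stop being observed 182 days later, so that the control
anchoring rule reproduces it and windowed-history lengths match between
arms; without this, a classifier would separate the arms on follow-up length
alone and a null run would not calibrate.  Setting all multipliers to 1
makes the arms exchangeable by construction.

*Relayed mode* constructs the scenario where graph enrichment is necessary:
prodromal concepts are split into halves A and B, train-fold cases express
only A, test-fold cases only B, and prodromal concepts are excluded from
everyone's background, so test-case raw vectors have zero mass on train-case
concepts by construction while both halves remain graph neighbors of the
target.

What the generator does **not** emulate: realistic code vocabularies and
hierarchies, coding-habit and billing artifacts, visit clustering and
irregular observation, informative censoring, comorbidity correlation
structure, lab values (labs enter as presence only).  Passing tests
therefore demonstrate that the machinery recovers the planted structure
under its own assumptions — they do not certify performance on real EHR
data, where the published headline AUCs (computed on private data) remain
the only reference.

## Numerical choices

Damping 0.85, L1 convergence tolerance 1e-8, max 1000 iterations (the
method definition states none of these; 0.85 is the conventional PageRank
value).  Power iteration is validated against an independent dense linear
solve, v = (1−d)(I − d·M)⁻¹r, to L1 1e-8.  Probability conservation
(embedding and signature rows summing to 1 within 1e-9) is asserted
throughout.  Control subsampling uses floor rounding.  The window boundary
is strict (< t0 − 365·h) and the neuroleptic window half-open; the source
rules state neither, and fixed conventions are preferable to ambiguity.
Patients windowed to an empty history are dropped from modelling and counted
in the report.  The experiment driver derives per-stage seeds by hashing the
global seed with the stage name (blake2s, 4 bytes, mod 2³¹), so any stage
can be re-run independently and identically.

## Experiment sizes

Library defaults and the analysis drivers use 200 cases and 200 controls per
arm with five seeded replicates per condition — large enough for the
qualitative contrasts of interest (signal specificity, enrichment advantage,
horizon ordering) to be stable, and small enough that the complete study
re-runs from scratch in well under a minute on one CPU.  At these sizes a
single test split holds 80 patients, so any individual AUC carries a
standard error of roughly 0.06; conclusions are drawn from seed-averaged
contrasts, not single runs.

## Known limitations

The restart-weighting scheme is one reading of the method's
"cohort-weighted" construction (the exact modification of topic-sensitive
PageRank used by production knowledge-graph systems is not public); it is
isolated behind `build_restart_vector` so alternatives can be swapped.  The
MDS marker table is a defaults file, not a reproduction of any study's
mapping.  L1 normalization couples signature features: strong planted signal
slightly depresses unrelated nodes, so feature-level specificity claims
should cite FDR-adjusted values.  The raw-code baseline can match or beat
the propagated representation when the same informative codes appear in
train and test — the enrichment advantage is specific to regimes (like the
relayed design) where test-time evidence is absent from training, which is
precisely the generalization claim of interest.
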