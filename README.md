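# kgprodromal

Early, pre-diagnostic identification of Parkinson's disease (PD) from coded
electronic health records (EHR), by enriching a patient's diagnosis,
medication and lab codes with a heterogeneous biomedical knowledge graph.
The package is aimed at methods researchers in clinical informatics and
network medicine: it implements the full analysis pipeline — propagation
embeddings, cohort rules, classification, baselines — as a tested library,
driven by a synthetic data generator with controllable planted signal, since
real EHR data of this kind cannot be redistributed.

## The method

Patients enter a typed knowledge graph (Disease, Symptom, Gene, Compound,
SideEffect nodes) through the graph nodes their EHR codes map to.  For every
mapped concept *c* the pipeline computes a **propagated entry vector** — the
stationary distribution of a personalized PageRank walk

&nbsp;&nbsp;&nbsp;&nbsp;*v* ← *d*·(*T v* + *m·r*) + (1 − *d*)·*r*

with column-stochastic transition *T*, damping *d* = 0.85, dangling mass *m*
redistributed onto the restart vector *r*.  The restart distribution is
cohort-weighted: mass at entry node *y* is proportional to the number of
cohort patients who carry *c* and also have an event mapping to *y*.  A
patient's **signature** is the L1-normalized sum of the propagated vectors of
their distinct mapped concepts — one value per graph node, so every feature
is an interpretable biomedical concept.

Cohorts follow pre-diagnostic rules: case index date t0 = first PD code (or
earlier first PD medication), ≥2 PD codes ≥182 days apart, neuroleptic
exposure within 182 days before the first code excluded, age ≥ 40 at index,
control t0 = last visit − 182 days.  Each model at horizon *h* ∈ {1, 3, 5}
years sees only events strictly before t0 − 365·*h*.  A class-weighted
random forest (weight ∝ n/(2·n_class)) is trained on an 80:20 stratified
split and evaluated by bootstrap AUC: 100 resamples of 50 patients with
replacement, 95% CI from the 2.5/97.5 percentiles.  Two baselines are
compared on identical patients: binary raw-code vectors restricted to
mappable concepts, and the MDS prodromal-criteria score, posterior odds =
prior odds(age) × ∏ marker likelihood ratios.

## Worked example

The numbered drivers under `analysis/` run the study end to end on synthetic
data and write their tables under `results/`:

```
$ python analysis/02_feature_analysis.py
patients modelled: 400
target disease DIS001: p = 6.2e-25 (rank 1 among 15 diseases)
most distant disease DIS015: p = 0.0328 (BH q = 0.075)
```

Although no pre-index record ever contains the target-disease code, the
target node ranks first among all disease features: propagation has routed
the cases' prodromal codes onto it.  The disease node farthest from the
target barely moves — the signal is specific, not a global shift.

```
$ python analysis/04_relayed_comparison.py
seed 0: propagated AUC 0.944, raw AUC 0.554
...
mean enrichment advantage over 5 seeds: 0.391
```

In the relayed design, training cases express one set of prodromal codes and
test cases a disjoint set (both wired to the target disease).  A raw binary
model has no usable feature at test time (AUC ≈ 0.5); the propagated
representation transfers through the shared graph neighborhood (AUC ≈ 0.88).
This is the regime where knowledge-graph enrichment is necessary rather than
merely convenient.

`analysis/03_horizon_experiment.py` reports mean bootstrap AUC per horizon
and method; with the default generator the AUC of every method falls as the
horizon recedes from the index date, and `analysis/05_patient_network.py`
exports a GraphML subnetwork explaining one patient's prediction (entry
codes → relay nodes → target disease).

A thin CLI mirrors the drivers: `kgprodromal simulate|cohort|run-all`.

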