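# netpharm

Network-pharmacology analysis of multi-herb formulas: from raw per-herb
ingredient tables to disease-relevant target networks and enriched
biological terms, in one reproducible pipeline.

Multi-herb preparations contain hundreds of chemical ingredients, most
of which have no experimentally measured protein targets. `netpharm`
addresses the question a systems-pharmacology study asks of such a
formula: *which proteins does the ingredient ensemble plausibly act on,
which of those are relevant to a disease of interest, how is that
activity distributed over the member herbs, and which biological
processes does it concentrate in?* It is aimed at computational
pharmacologists and bioinformaticians who have ingredient tables
(SDF/CSV), a curated drug–target interaction database, binary
substructure fingerprints, disease gene lists, and GMT annotations — and
who want the whole chain to run deterministically on a desk machine.

## The core method

Candidate targets are ranked by **substructure–drug–target network
diffusion**. Build a tripartite graph with drug nodes, target nodes, and
substructure (fingerprint-bit) nodes; a drug is linked to its known
targets and to its set fingerprint bits. For each drug, place unit
resource on its attribute neighbours — a fraction *α* spread equally
over its known targets and 1 − *α* over its bits — then run *k* rounds
of two-pass diffusion. In the attribute→drug pass, an attribute node
sends its mass to adjacent drugs with shares ∝ deg<sup>γ</sup>; in the
drug→attribute pass a drug sends a fraction *β* of its mass to its
target neighbours and 1 − *β* to its bit neighbours, again with
deg<sup>γ</sup> shares inside each class (degrees are total degrees in
the union graph, and each share is normalised over the eligible
neighbours, so every round conserves mass exactly). The score of
(drug, target) is the mass on the target after *k* rounds. Negative *γ*
damps promiscuous hubs; a new chemical entity with no known targets is
scored purely through its substructure bits. Defaults: α = β = 0.1,
γ = −0.5, k = 2.

Downstream, the pipeline intersects predicted+known targets with a
disease gene set, attributes disease targets to herbs (a Venn partition
by the exact herb subset hitting each target), builds compound–target
and herb–target bipartite networks with degree/hub reports, and tests
high-degree targets for term over-representation with an exact
hypergeometric tail and Benjamini–Hochberg adjustment.

## Worked example

Everything runs from a seeded synthetic bundle, so no downloads are
needed:

```python
from netpharm import SDTNBI, SimConfig, simulate, run_pipeline

bundle = simulate(SimConfig(seed=1), "scratch/bundle")
model = SDTNBI.from_files(bundle.observed["known_dti"],
                          bundle.observed["fingerprints"])
print(model.evaluate_holdout(holdout_fraction=0.2, L=10, seed=1).summary())
```

prints

```
Held-out ranking evaluation
===========================
drugs evaluated : 42
list length L   : 10
precision @ L   : 0.1024
recall @ L      : 0.9167
eP (vs random)  : 1.79
eR (vs random)  : 1.79
AUC (macro)     : 0.8506
params          : alpha=0.1 beta=0.1 gamma=-0.5 k=2
```

Read: with 20 % of the known drug–target edges hidden, the diffusion
ranking places a hidden target in a drug's top-10 list about 1.8× more
often than random ranking would (eP), recovers 92 % of each drug's
hidden targets within the top 10, and orders hidden targets above
non-targets with probability 0.85 (macro AUC).

Running the full chain and the enrichment stage:

```python
result = run_pipeline("scratch/bundle", "scratch/out")
top = result.enrichment.results[0]
print(top.term, top.k, top.K, f"p_adj={top.p_adj:.3g}")
```

```
TERM_PLANTED 10 10 p_adj=4.96e-09
```

The generator plants one annotation term containing exactly the
disease-relevant targets; the pipeline recovers it as the top enriched
term. The same steps are exposed on the command line
(`netpharm simulate|merge|predict|evaluate|network|enrich|pipeline`).

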