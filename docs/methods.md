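# Methods

## The diffusion model

The target predictor operates on a tripartite graph with drug nodes and
two classes of *attribute* nodes: protein targets (from a known
interaction table) and binary substructure-fingerprint bits. Write
`A` (drugs × targets) and `S` (drugs × bits) for the two binary
adjacencies and deg(·) for total degree in the union graph `[A | S]`,
fixed once at build time.

For a drug *u* the initial resource vector over attribute nodes is

- mass α split equally over *u*'s known targets and 1 − α split equally
  over *u*'s bits, when both classes are non-empty;
- all mass on the single non-empty class otherwise (in particular, a
  new chemical entity with no known targets starts with all mass on its
  bits, independent of α).

One diffusion round is two passes:

1. **attribute → drug.** Attribute node *v* sends its mass to its drug
   neighbours; drug *u* receives a share deg(u)^γ / Σ_{u′∈N(v)} deg(u′)^γ.
2. **drug → attribute.** Drug *u* splits its mass β : (1 − β) between
   its target-neighbour class and its bit-neighbour class (if one class
   is empty the other takes weight 1); within a class, neighbour *v*
   receives a share ∝ deg(v)^γ, normalised within the class.

Because every outgoing distribution is normalised per node, each round
is exactly mass-conserving for *any* γ — the 1e-12 conservation bound in
the tests is floating-point error only, not model slack. The
(drug, target) score is the mass on the target node after k rounds;
k = 0 returns the initial allocation. Scores for one drug sum to at
most 1 (the remainder sits on bit nodes), so rankings are per-drug and
scale-free.

γ is applied identically in both passes — one uniform hub rule. This
makes γ provably irrelevant on degree-regular graphs (all hub weights
equal, normalisation cancels), which the tests exploit as a symmetry
check. Negative γ down-weights promiscuous nodes; the defaults
α = β = 0.1, γ = −0.5, k = 2 favour substructure evidence (most initial
mass and most drug out-flow go through bits) with mild hub damping.

Implementation: the two passes are assembled once per (β, γ) as a pair
of sparse row/column-stochastic transfer matrices and cached on the
network object; prediction is then k sparse matrix products per drug
batch. Iteration order is fixed (sorted ids) and all arithmetic is
double precision, so scores are bit-reproducible. The test suite
checks the sparse iterative path against an independently written dense
`f0·(W1W2)^k` oracle at 1e-10 over a 4×4×4×4 parameter grid on 100
random graphs.

## Held-out evaluation

`evaluate_holdout` removes a seeded random fraction (default 20 %) of
known interaction edges, rebuilds the network on the remainder (drugs
losing every target are scored as NCEs), and for each drug with at
least one rankable held-out target ranks all targets of the rebuilt
network except the drug's training targets. Reported at list length L:

- P = mean over drugs of hits@L / L, R = mean of hits@L / |held-out|;
- eP = P / P_rand with P_rand = mean |held-out| / |candidates| — the
  expected precision of a random ranking; eR = R / R_rand with
  R_rand = L / mean |candidates|;
- AUC = macro-averaged per-drug ROC area, midrank tie handling.

Under random scores eP, eR → 1 and AUC → 0.5; the suite verifies this
calibration by simulation. A held-out pair whose target loses all its
remaining training edges drops out of the rebuilt network and cannot be
ranked; such pairs are ignored and drugs left without rankable held-out
targets are excluded from all means (with the default synthetic
conditions this affects at most a handful of edges). Leave-one-out
evaluation is available behind a flag; the default is a single random
holdout because it is an order of magnitude cheaper at equal power for
the property checks used here. Top-L tie-breaks are by target id, so
evaluation is deterministic given the seed.

## Ingredient catalogs

Per-herb tables (SDF V2000 or CSV with SMILES) are merged on the full
27-character standard InChIKey, so stereoisomers stay distinct. Records
whose structure is absent or unparseable are *kept* under a flagged
normalised-name key (`NAME:` + case-folded, whitespace-collapsed name):
traditional-medicine tables are name-rich and structure-poor, and
dropping such rows would silently shrink the catalog. Name-keyed and
structure-keyed records never merge. Compound ids `M1..Mn` follow the
lexicographic order of the canonical keys, making the catalog
independent of input order and the merge idempotent — both are tested
byte-for-byte on the CSV export. No salt stripping or other
standardisation beyond the toolkit's SMILES canonicalisation is
applied, and no ADME filtering.

## Disease overlap, attribution, networks

Gene symbols are normalised by upper-casing and whitespace removal
only; alias and ortholog resolution are out of scope and a documented
caveat. A herb is credited with a disease target if *any* of its
compounds hits it through a known or predicted edge; the Venn partition
assigns each target to the exact herb subset hitting it, so regions are
disjoint and cover the target set (tested as a partition identity).
The compound–target and herb–target graphs are typed bipartite
networkx graphs with edge provenance (`known`/`predicted`); degree
reports use strict thresholds (defaults: compound hubs > 5 edges,
target hubs > 100 compounds — scale-dependent, configurable).

Exports: GraphML (node `type`, edge `provenance` attributes), edge-list
CSV, and SIF. Plain three-column SIF cannot carry node types or
provenance, so the writer emits the standard body (relation tokens
`targets` / `contains`) plus `#`-prefixed metadata lines that the
package's own importer reads and other tools skip; with them, all three
formats round-trip to an identical network. Node order in every export
is (type, id), so repeated exports are byte-identical.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P(X ≥ k) for k query hits in a K-gene term, query size n, background
N (computed via the survival function in log space; verified against
exhaustive enumeration for every valid configuration with N ≤ 12).
The background defaults to all genes of the annotation collection.
Multiple testing uses Benjamini–Hochberg; only terms overlapping the
query are reported but every term with at least one background gene
counts toward the BH family, which can only inflate adjusted p-values
(conservative). Retention follows the top-20 / adjusted-p < 0.05 rule.
Note that hypergeometric p-values are discrete: the rejection rate at
nominal 0.05 equals the largest achievable level below 0.05, which for
small terms can sit well under the nominal rate. The null-calibration
simulation therefore uses a configuration (background 500, term 35,
query 50) whose achievable level, computed analytically beforehand, is
0.049 — close enough to nominal for the check to be informative.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not real chemistry or biology. Mechanism: each of T targets owns a
small pharmacophore of m fingerprint bits (sampled without replacement
per target; overlaps across targets allowed). Each drug truly binds
1 + Poisson(0.5) targets (truncated at 4) and sets the pharmacophore
bits of its true targets with probability p_on = 0.9 against a
background bit rate p_bg = 0.05; every drug keeps at least one bit.
Drugs sharing targets therefore share bits — the minimal generative
mechanism under which substructure diffusion provably carries signal,
and setting p_on = p_bg yields an exact null (tested: AUC ≈ 0.5). The
observed interaction file is a seeded 80 % subsample of the true pairs;
herb membership is uniform with a 10 % second-herb duplication rate;
the disease set is half the targets plus 30 decoy symbols; 50 random
annotation terms (size 5–25 over the target+decoy universe) are joined
by one planted term equal to the disease targets that truly bind at
least one drug. Defaults: 4 herbs, 200 drugs, 20 targets, 256 bits.

All symbols are synthetic (`CPD0001`, `T001`, `DEC001`), ground truth
is written under `truth/` strictly apart from `observed/`, and bundles
regenerate byte-identically from (config, seed).

What passing on this generator does **not** show: robustness to alias
ambiguity in gene symbols, to fingerprint families whose bits are
correlated in chemically realistic ways, to the heavy-tailed degree
distributions of real interaction databases, or to annotation terms
with hierarchical (GO-like) dependence. Results on real inputs depend
on the curation quality of those inputs.

## Problem sizes and defaults used in checks

The standard study conditions are the generator defaults above with
seed 1; evaluation uses a 20 % holdout at L = 10 and the default
diffusion parameters. The oracle-equivalence sweep uses 100 random
graphs with up to 20 drugs, 10 targets and 30 bits; calibration
simulations use 50 repeats (ranking) and 1000 draws (hypergeometric
null). These sizes give stable means while keeping the whole suite
fast on a single CPU.

## Known limitations

- The predicted-edge threshold (default top-10 novel targets per drug)
  is a reporting choice, not an estimated quantity; change it with the
  `top_L` / `--top-l` options.
- Macro-averaged AUC weights every evaluated drug equally regardless of
  how many targets it hides.
- The enrichment test is the plain hypergeometric, not a modified
  (EASE-style) score, and terms are treated as independent gene sets.
- Herb attribution is binary (a herb hits a target or not); edge scores
  are not propagated to the herb level.
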