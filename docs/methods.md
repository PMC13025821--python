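# Methods

## The multiscale interactome and its walk

The network joins three layers over two walkable node kinds. Proteins carry
undirected physical-interaction edges (PPI layer) and directed annotation
edges to biological-function terms; function terms form a hierarchy stored
as child→parent edges. Herbs, compounds, and the disease are deliberately
*not* nodes: each enters the walk only as a restart distribution over its
associated proteins. This keeps a single transition system shared by every
entity, which is what makes profile correlations comparable — all profiles
live on the same node index (sorted proteins followed by sorted functions).

The transition matrix is built per node. A node's outgoing mass is divided
among its *populated* transition classes (protein→protein,
protein→function, function→protein, function→parent, function→child)
proportionally to the class weights, then uniformly across the edges within
a class. A class with weight but no edges at a node cedes its share to the
populated classes rather than leaking mass; a node with no out-edges at all
becomes a sink. Default class weights are all 1 (an unbiased walk); they are
exposed through `DiffusionConfig.layer_weights` and a YAML config on the
CLI because tuned layer weights are data-dependent and no defensible
universal values exist.

The walk iterates

    r(k+1) = (1 − α) s + α ( r(k) M + s · Σ_{j∈J} r_j(k) )

to convergence in L1. Sink mass is collected as a scalar each step and
re-injected through the seed inside the walk term, so every iterate sums to
exactly 1; profiles are conserved distributions by construction, not by
renormalization. α is the walk-continuation weight — the probability of
*not* restarting at a given step. The term "restart probability" is
sometimes attached to the symbol α in this family of methods even when the
update weights the walk term by α; we implement the update rule literally,
with α = 0.85, and the two-node closed form (r_A = 0.15/0.2775 for A→B with
B a sink and a δ_A seed) pins the semantics down unambiguously.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.85 | walk-continuation weight; 1−α is the restart rate |
| `epsilon` | 1e-6 | L1 convergence tolerance between iterates |
| `max_iterations` | 500 | guard; exceeding it flags the profile non-converged |
| `layer_weights` | all 1.0 | per-class bias of the transition split |

ε = 1e-6 is a conventional choice for restart walks of this size; at
α = 0.85 the iteration contracts with rate ≤ α, so ~80 iterations suffice
and the 500-iteration guard is generous. Correctness of the fixed point is
checked against a direct dense linear solve of
(I − α Mᵀ − α s 1_Jᵀ) r = (1 − α) s on randomized systems, including
sink-heavy and disconnected ones.

Profile similarity is the Pearson correlation computed as the cosine of the
mean-centered profiles, over the full protein+function index. Degenerate
(zero-variance) profiles raise rather than return a silent 0.

## Assembly and curation choices

Herbs with fewer than six annotated compounds are excluded (the boundary is
"five or fewer are dropped", so count ≥ 6 keeps). After merging
herb–compound with compound–target records on the shared compound id, each
herb's targets are ranked by the number of its own compounds supporting the
target, ties broken lexicographically, and the top 50 are retained. The
support-count criterion is our choice: it is computable from the assembled
tables alone, it rewards targets that many constituents converge on, and it
gives a prefix-stable ordering (raising the cap never reorders a prefix).

Disease genes pass three filters — source allow-list (when set),
association-type exclusion (always including "therapeutic", which describes
treatment rather than pathogenesis), and evidence-class exclusion
(animal-model-only, text-mining) — then are restricted to proteins present
in the network. An empty post-filter set is a hard error because the
disease seed would be undefined.

## Screening

Overlap significance uses the hypergeometric upper tail P(X ≥ k) with
N = interactome protein count, K = disease-set size, n = entity target
count. The tail is summed in log space (gammaln + logsumexp) so that the
extreme overlaps the screen produces (p ≪ 1e-300 territory on large
networks) remain finite and ordered. BH correction is applied across all
screened entities of one kind in one family (herbs separately from
compounds); the retained flag is q < 0.05. Correlation carries no cutoff —
it only orders the table — because any threshold on it would be arbitrary,
while the overlap test has a calibrated null. Ties in the ordering break by
smaller raw p, then id, making the output deterministic.

Two enrichment summaries are reported for every overlap test because both
conventions are used in practice under the same column name:
fold-enrichment (k/n)/(K/N) and −log10 p.

A herb reaches the final top-10 list only when retained *and* at least
three of its constituent compounds independently pass the identical screen
at compound level ("active compounds"). This guards against herbs whose
aggregate target set looks disease-like without any single constituent
plausibly carrying the effect.

## Subnetworks

A candidate's mechanism subnetwork takes its targets, the k = 20 nodes most
visited in *its own* profile (proteins and functions ranked jointly; a
per-kind quota is available by flag), and the disease proteins among them;
induces all multiscale-layer edges on that node set plus entity→target
links; and prunes targets lacking a direct edge to a disease protein or a
retained function, iterating to a fixed point. Driving top-k from the
entity profile (with disease proteins overlaid) centers the picture on the
candidate's mechanism; single-step adjacency — not path reachability —
defines "connected" so that every retained target is visibly anchored in
the drawn graph. Exports are GraphML and a two-file TSV with role labels
(compound/target/disease_protein/function/disease).

## Over-representation analysis

Per term: hypergeometric upper-tail p, odds ratio from the 2×2 table with
Haldane 0.5 correction when any cell is zero, a z-score of the observed
overlap under the hypergeometric null, combined score −ln(p)·z, and BH q
across the library's terms. The z-score is a documented approximation: web
enrichment services compute z as a deviation from precomputed expected
*ranks* on their server-side background, which cannot be reproduced
offline. Ranking by p and the BH significance set do not depend on this
choice; odds ratios and combined scores are therefore comparative, not
reference values. The background defaults to the interactome protein set
and is overridable per library.

## The synthetic study

The generator emulates the statistical structure the analysis depends on,
not any particular organism's interactome:

| parameter | default | emulates |
|---|---|---|
| `n_proteins` / `n_functions` | 500 / 120 | desk-scale proteome + term set |
| `ppi_attachment` | 3 | preferential attachment → heavy-tailed PPI degrees |
| `annotation_rate` | 2.0 | mean GO annotations per protein |
| `hierarchy_branching` | 3 | children per term in the balanced-tree DAG |
| `disease_module_size` | 30 | curated disease gene set |
| `module_extra_density` | 0.2 | within-module edge boost (disease cohesion) |
| `n_active_herbs` / `n_decoy_herbs` | 10 / 40 | planted signal vs background panel |
| `targets_per_herb` | 25 | herb target-set size (under the top-50 cap) |
| `active_overlap_fraction` | 0.6 | share of an active herb's targets in-module |
| `compounds_per_herb` | 6–15 | constituents per herb (all pass the ≥6 filter) |

Active herbs draw 60% of their targets from the module; decoys sample
uniformly from the whole proteome, so their module overlap follows the
hypergeometric null (mean n·K/N = 1.5 at defaults) — verified against that
expectation over large decoy panels. Each herb's targets are distributed
over its compounds with full coverage in both directions. Truth labels are
written beside, never inside, the network bundle.

What passing the recovery benchmark shows: the pipeline separates herbs
with genuine module-concentrated targets from background samplers, at
planted effect sizes a curated pharmacology database plausibly exhibits.
What it does not show: robustness to identifier noise, annotation bias
toward well-studied proteins, correlated target sets between herbs sharing
compounds across herbs, or interactome false-edge rates — real exports
have all of these and the generator deliberately models none of them.

Problem sizes throughout (620-node walks, 50-herb and ~500-compound
screens, 100 randomized solver checks of ≤50 nodes) were chosen so the full
suite and the acceptance run each complete in seconds while leaving the
planted-recovery margins wide.

## Numerical and degenerate-input conventions

- Undirected PPI edges canonicalize as sorted id pairs; duplicates collapse
  on load. The function hierarchy is verified acyclic (Kahn) at validation.
- Non-sink transition rows must sum to 1 within 1e-12; profiles to 1 within
  1e-9 (they are exact to machine precision in practice).
- All rankings break ties deterministically (probability/correlation
  descending, then raw p, then lexicographic id), so repeated runs emit
  byte-identical TSVs.
- Entities whose seeds cannot be resolved are skipped with a warning at
  screen level but are a hard error when addressed directly; an
  unresolvable disease seed is always fatal.
- BH-adjusted values are step-up q-values; note that re-adjusting q-values
  is not a no-op (the step-up rescales by m/rank), so q-values are computed
  once per family, from raw p-values only.

## Known limitations

- Layer weights are not learned; the unbiased default is a neutral choice,
  not an optimum.
- The enrichment combined score is not comparable to server-computed
  values (see above).
- The generator's function hierarchy is a balanced tree, a simpler shape
  than real ontologies (no multiple parenthood).
- Real-scale interactomes (hundreds of thousands of edges) are loadable
  through the same TSV interface but the dense solver cross-check is only
  feasible at test scale; the iterative path itself is sparse and scales.
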