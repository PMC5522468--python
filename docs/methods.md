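# Methods

## Problem setting

`grnpipe` reconstructs a signed, modular gene regulatory network (GRN) from
a small-panel perturbation time-course screen: ~126 probes measured by a
digital counting assay in two conditions (e.g. with/without an FGF ligand,
or a vehicle control vs an FGFR inhibitor) at three timepoints (6, 12, 24 h)
with three biological replicates per cell of the design. At this scale a
full count-model analysis is neither possible nor needed; the pipeline
follows the analysis conventions of such screens: mean-ratio fold changes
with unpaired t-tests, hierarchical clustering of log profiles, tree-
ensemble edge ranking, gold-standard threshold calibration, and graph-
theoretic downstream analysis.

## Normalization

Two successive per-sample geometric-mean scalings, the standard recipe for
nCounter-style panels: positive-control probes first, then housekeeping
genes. For reference-probe set R and sample s the factor is
`geomean_grand(R) / geomean_s(R)`; each step is a pure per-sample rescaling,
so normalization is idempotent and removes multiplicative library-size
effects up to one global constant (the grand geometric mean of the injected
factors). Either step can be disabled; with no reference probes configured
the pipeline passes values through with a warning rather than guessing.

Values strictly below a detection floor (default 4e-5 on the normalized
scale — the level below which in situ hybridization cannot confirm a
transcript) are set to 0; genes whose whole row becomes 0 are flagged
absent and excluded from both regulator and target sets downstream. The
comparison is strict (`< floor`), so a value exactly at the floor is kept.

## Differential expression

Per gene and timepoint: fold change = ratio of arithmetic means of
normalized linear-scale values (treatment/control); p-value from a
two-sided unpaired t-test (pooled-variance Student by default; Welch
optional). A gene is `up` when FC ≥ fc_up and p < α, `down` when
FC ≤ fc_down and p < α. Two preset threshold pairs are built in, `figure`
(1.5 / 0.25, the default) and `methods` (1.25 / 0.75), both at α = 0.05 —
both sets circulate in the literature for this assay and the headline
transcript counts follow the stricter pair. Raw p-values are used by
default (matching practice for a 126-probe panel); Benjamini–Hochberg
adjustment is available via config. Zero-variance degenerate groups return
p = 1 (equal means) or p = 0 with a warning (unequal means); a zero control
mean yields an explicit `inf`/`nan` fold-change sentinel.

Note on calibration: the t-test's null p-values are uniform when its
normality assumption holds. The simulated observation model is log-normal,
so calibration checks are run on log-scale values (where the model is
exactly Gaussian); on linear-scale values with n = 3 the test is mildly
anti-conservative in the tails, which is a property of the t-test, not of
this implementation.

## Hierarchical clustering

Euclidean distance between (log2-transformed, pseudocount 1) gene profiles,
agglomerative linkage (complete by default; average and Ward available),
tree cut into exactly k clusters (default k = 11, the typical number of
response classes resolved on panels of this size). Genes are sorted
lexicographically before distances are computed, making the result
invariant to input row order; cluster ids are relabelled 1..k by first
occurrence in that order. The merge tree is exported as Newick with branch
lengths from merge heights.

## Network inference

GENIE3-style tree-ensemble inference: for each target gene, a Random Forest
(default 1000 trees, √p candidate features per split) regresses the
target's profile on all candidate regulators (the TF list) excluding the
target itself, with all samples from all conditions/timepoints pooled into
one observation matrix. The importance measure (IM) of a regulator for a
target is the mean over trees of the *unnormalized* impurity (variance)
reduction attributed to splits on that regulator. Target profiles are
standardized to unit variance by default, so each target's incoming IMs sum
to roughly 1 and an absolute IM threshold is comparable across targets.
All regulator→target pairs are ranked globally by IM, ties broken by
(regulator, target) lexicographic order.

Determinism: samples are put in a canonical order (lexicographic by full
expression profile) before fitting, so results are invariant to sample
arrival order even with bootstrap resampling; each target's forest seed is
derived from the run seed and the target's position in the sorted gene
list, so results are invariant to gene order as well. A fixed seed gives
bit-identical rankings with a fixed version of the tree library
(scikit-learn). Zero-variance targets receive zero incoming IMs with a
warning.

Known behaviour at small panel sizes: a pure-noise target distributes its
(standardized) unit variance across its few candidate regulators, so false
incoming edges of noise targets carry IMs of order 1/#regulators. With ~60
regulators this floor is ~0.016 and discrimination is good; with ~5
regulators it materially overlaps weak true edges. Recovery benchmarks are
therefore most meaningful at panel scale.

## Threshold calibration

The ranked list is scored against a literature gold standard (directed,
exact matching; undirected matching optional): for each IM threshold, the
number of retained predictions and the fraction of gold-standard edges
among them (sensitivity). Threshold selection modes: `manual` (a value
chosen by inspection — the faithful mode for reproducing a published
network), `knee` (automated default: the curve point maximizing
perpendicular distance from the chord of the axis-normalized
(n_predictions, sensitivity) curve, ties to the larger threshold) and
`top_k` (IM of the k-th ranked edge; k = 500 mirrors the "analyse the top
predictions in detail" convention). Edges tied with the threshold are kept
(≥ comparison), so nested thresholds give nested networks.

## Downstream network analysis

- **Communities**: Newman-style modularity clustering on the undirected
  projection of the network with IM weights (antiparallel edges sum).
  Default is greedy agglomerative modularity maximization; Girvan–Newman
  edge-betweenness division (keeping the maximal-modularity cut of the
  dendrogram) is the alternative. Module ids are contiguous from 1, ordered
  by each module's lexicographically smallest member. An edgeless graph
  yields singletons with Q = 0.
- **Centrality**: betweenness as unnormalized shortest-path counts
  (unweighted paths), computed on the directed graph by default (ordered
  pairs) or the undirected projection (unordered pairs); plus in/out
  degree. Out-degree sums to the edge count exactly.
- **Edge signing**: Pearson correlation between regulator and target
  profiles over the same samples used for inference; r > 0 → activating,
  r < 0 → repressive, r = 0 or undefined → unsigned with a warning.
- **Subcircuits**: induced subgraph on a gene and its first neighbours
  (in-, out- or both directions), retaining all edges among them.
- **Enrichment**: hypergeometric upper tail P(X ≥ k) per (module, term)
  with the probe panel as the universe (not the genome — the panel was
  curated, so genome-scale background would overstate enrichment); raw
  p < 0.05 by default, BH optional.

## Synthetic-data generator

The generator emulates the screen's statistical structure so that every
stage has a known-answer test bed; it is not a mechanistic simulator.

- **Truth networks**: each (TF, gene) ordered pair becomes an edge with
  probability `density`; weight magnitudes uniform on [0.8, 1.2], negative
  with probability `p_negative` (default 0.3). Motifs (mutual activation or
  repression pairs) can be planted verbatim. The first TF is the signal
  gene — the condition-driven exogenous input standing in for the pathway
  ligand. `allow_cycles=False` restricts edges to a fixed topological
  order, producing an acyclic truth.
- **Dynamics**: latent log-expression per sample is propagated
  (default 20 steps) through `x ← basal + b + W·x`, with the signal gene
  held at `basal + b + level` (default level 2 natural-log units under
  treatment, 0 under control), and values clipped at ±12 to tame unstable
  feedback; clipping triggers a warning because clipped genes saturate and
  lose identifiable regulatory signal. `b` is a per-gene per-sample
  biological perturbation (Gaussian, sd `biological_sd` = 0.5 ≈ 1.6-fold
  explant-to-explant spread) — without intrinsic regulator variation a
  screen carries no propagated signal off the perturbation path and
  network recovery would be impossible by construction.
- **Observation**: `y = exp(x + ε) · L_s` with measurement noise ε
  (sd 0.1) and per-sample library factor `L_s` (log-sd 0.2 by default).
  Housekeeping probes are network-independent noise-free constants, so
  geometric-mean normalization removes library factors exactly. An
  optional Poisson layer produces integer counts for I/O tests.
- **Defaults mirror the screen design**: 2 conditions × {6, 12, 24} h ×
  3 replicates = 18 samples; recovery benchmarks scale replicates up
  (34 per cell ≈ 200 samples) for statistical power.
- **Gold standards** are sampled uniformly without replacement from the
  true edges (default emulated size 76, the scale of a curated literature
  list for such a panel).

What the generator does *not* emulate: mRNA degradation kinetics and
time-lagged responses (timepoints differ only through the signal profile),
count overdispersion, probe-specific efficiency, batch structure, or
spatial heterogeneity. Passing recovery tests therefore demonstrates
correctness of the inference machinery on monotone signed dependencies with
realistic noise, not performance guarantees on any particular biological
dataset.

### Stability caveat

With cycles allowed and |weights| ≥ 0.8 the random truth typically has
spectral radius > 1; the clipped linear propagation then saturates a
sizeable minority of genes at the bound, which destroys their identifiable
signal (the generator warns when this happens). Recovery benchmarks
therefore use acyclic truths, which stay in the linear regime; cyclic
motifs remain available for targeted tests via `motif_injection`.

## Problem sizes used in the shipped benchmarks

- Recovery benchmark: 126 genes (63 TFs), density 0.02 (~150 true edges),
  204 samples, 1000 trees — AUROC and sign-recovery are computed at this
  size.
- Screen-design pipeline: 126 genes + 4 housekeeping probes, 18 samples,
  1000 trees, knee-calibrated threshold and top-500 community structure.
- Oracle equivalence checks (betweenness, modularity, sensitivity counting,
  hypergeometric p) run on graphs ≤ 8 nodes / lists ≤ 60 edges where
  exhaustive enumeration is exact and fast.

## Numerical and design choices

- Inference input scale: normalized linear values after flooring (log2
  optional), matching how such screens are conventionally fed to GENIE3.
- Forest count interpretation: "n = 1000" is read as one forest of 1000
  trees per target (the reference GENIE3 usage); `n_forest_replicates`
  exposes the alternative reading (averaging 1000 single-forest runs).
- Student (pooled-variance) t-test as the unmarked meaning of "unpaired
  t-test"; Welch via config.
- Knee selection normalizes both curve axes to [0, 1] before the
  chord-distance computation, since predictions (thousands) and
  sensitivity (unit interval) are on incommensurate scales.
- All randomness flows through explicit integer seeds; no global RNG state
  is used anywhere.

## Limitations

- Edge signs come from marginal Pearson correlation; a repressor acting on
  a target that is simultaneously strongly activated by a correlated
  regulator can be mis-signed.
- Importance-based rankings cannot distinguish direct from strongly
  correlated indirect regulation (chains inflate grandparent edges).
- Community structure from greedy modularity is a heuristic; on real data
  different Newman-family algorithms may return different module counts.
- The hypergeometric enrichment treats terms independently (no ontology
  DAG propagation).
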