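# Methods

`remitt` reconstructs putative T cell migration trails on spatial
transcriptomics slides and provides the statistical machinery to interrogate
them. This note documents the model, the parameters that matter, the
synthetic data used for validation, and the numerical choices made where the
design was genuinely open.

## Model and procedure

**Premise.** Effector T cells entering a tumor progressively exhaust. A
stream of T cells moving along a physical corridor should therefore leave a
spatial footprint: a chain of adjacent T-cell-containing spots whose
exhaustion level trends upward. The method searches for such chains and
validates them against matched spatial permutations.

**Exhaustion score (z).** T-cell-infiltrated spots are those with any
detected transcript of the pan-T surface markers (CD8A, CD8B, CD4, CD3D,
CD3E, CD3G; threshold configurable). Across T spots, the summed expression
of seven exhaustion markers (PDCD1, LAG3, HAVCR2, TIGIT, CTLA4, ENTPD1, TOX)
is regressed by ordinary least squares on the summed T-marker expression —
both sums scale with the number of T cells in a spot, so the residual
reflects how exhausted those cells are rather than how many there are.
Residuals are shifted so the smallest is 0. By default both sums are
computed on per-spot TPM-normalized expression (counts / total UMI × 1e6) so
that z is comparable across sequencing depths; raw count sums are available
by option.

**Node graph.** Analysis units are nodes: single spots on standard Visium,
or region-grown groups of adjacent pixels with similar z on Visium HD
(radius 5 × pixel pitch, score tolerance defaulting to 5% of the observed z
range, seeds visited in descending T-marker signal for determinism). Nodes
closer than `d_max` = 130 µm (one hex-lattice step of ~110 µm plus slack)
are joined by a directed edge pointing from lower to higher z, weighted by
the z difference; ties orient by node id, keeping the graph acyclic.

**Candidate trails.** Potential starts are the lowest-z third of nodes and
potential ends the highest-z third. Two searches run over all start–end
pairs at least 0.5 mm apart:

1. *Minimum-spanning path*: Dijkstra's algorithm on the directed graph.
   Because every directed path between two nodes telescopes to the same
   total weight (z_end − z_start), ties are resolved deterministically by
   fewest hops, then lexicographic node ids — effectively the most direct
   monotone route.
2. *3D line*: x and y are rescaled affinely onto the z range; nodes within a
   small perpendicular distance of the 3D segment joining the pair are
   collected and ordered by their projection onto it. The default capture
   distance is 5% of the z range, capped at 0.6 × `d_max` in rescaled units
   so the capture cylinder stays narrower than one lattice pitch — without
   the cap, lateral lattice neighbors of a trail fall inside the cylinder
   and corrupt the projection ordering. Trails with a z *drawback* between
   consecutive nodes exceeding 10% of the trail's z span are rejected, as
   are trails with a 2D gap ≥ `d_max`.

Candidates shorter than 6 nodes or spanning under 0.5 mm are excluded;
identical node sequences found by both methods are reported once with both
method tags.

**Trail selection.** For each candidate, 5–15 *alternative routes* between
the same endpoints are drawn by self-avoiding random walks on the undirected
T-node graph (uniform choice among unvisited neighbors, restart on dead
ends, walk capped at 3 × the trail length, at most 200 walks). Alternatives
must satisfy every trail constraint except z-monotonicity. Coherence of a
route is the mean Pearson correlation of normalized stage-gene expression
between all node pairs; stage genes are the panel candidates significantly
positively correlated with T-marker level (Pearson, p < 0.05), falling back
to the top three by correlation on degenerate slides so the statistic stays
defined. A candidate becomes a trail only if its coherence beats every one
of its own alternatives and the 85th percentile of all alternatives pooled
across candidates. Candidates with fewer than 5 alternatives are dropped
conservatively (criterion (a) is undefined on an empty set) and reported.

**Matched controls.** Nodes are clustered (log1p, PCA to 30 components,
k-means with k = 6, fixed seed) on the 3,000 most variable genes (variance
of log1p TPM). For each trail, a control is a self-avoiding walk confined to
T nodes of the trail's majority cluster with the same length, adjacency and
≥ 0.5 mm span; the trail's own path (either orientation) is excluded. One
control per trail forms a control set; 5,000 sets (configurable) form the
empirical null. A trail whose cluster cannot host any admissible control is
excluded from control-based analyses with a logged warning rather than
aborting the run.

**Systematic statistics.**

- *Trend tests*: summed panel expression (CXCL9/10/11; CCL4/5; CXCL16;
  macrophage CD68/CD163/CD80/CD14) on the 1-based trail index, linear mixed
  model with a random intercept per trail, ML fit, two-sided Wald p for the
  fixed slope. Singular or non-converging fits fall back to per-trail OLS
  slopes with a one-sample t test (logged).
- *Differential expression*: per gene, mean TPM over all on-trail spots
  versus the same statistic per control set; two-sided empirical p
  (plain-proportion convention, so p = 0 is reportable; add-one available),
  Benjamini–Hochberg across genes; up-called at adjusted p < 0.05 and fold
  change > 1.2 against the mean of the null means.
- *Shared V genes*: a TCR/BCR variable gene (name prefixes TRAV/TRAJ/TRBV,
  IGHV/IGKV/IGLV) is shared by a consecutive spot pair when its raw count is
  nonzero in both. Per trail the mean over consecutive pairs; the observed
  statistic is the median over trails, tested against the control sets.
- *Over-representation*: one-sided Fisher exact tests of up-called genes in
  GMT gene sets over the variable-gene universe, BH-adjusted.
- *Phenotype ranking*: given a cluster × gene table of single-cell means,
  each up-called gene ranks the clusters (ascending, average ties); clusters
  are ordered by their median rank, descending.

## Synthetic slides

The generator plants known structure so every stage is testable without
external downloads. A slide is a hexagonal lattice (default 30 × 30 spots,
110 µm pitch) with 60% T-cell-infiltrated spots and 5 planted trails of 8
adjacent spots each. Planted trails are directionally persistent
self-avoiding lattice walks (60° turns with probability 0.2) constrained to
span ≥ 0.5 mm so the ground truth itself satisfies the method's trail
definition.

Counts are negative-binomial (dispersion 20) thinned by 10% dropout. Per-T
spot, a lognormal abundance factor (σ = 0.15) scales all T-cell-derived
genes, mimicking variable T-cell content — exactly the nuisance the
exhaustion regression is designed to remove. Along a planted trail the
exhaustion-marker mean rises log-linearly (0.5 per step, ~30× over a trail),
centered on the off-trail baseline: trails run from well below the resident
exhaustion level (newly entered cells) to well above it. Chemokine and
macrophage panels rise log-linearly along trails (0.25 and 0.15 per step);
stage genes share a trail-level lognormal profile (σ = 0.6) that creates
the coherence signal selection relies on; each trail carries a 4-gene TCR
"clone" detected on all its spots. Six horizontal tissue domains carry
compositional 50-gene signatures (background rescaled so expected library
size is identical across domains), giving the expression clusters a
spatially contiguous footprint as on real slides without distorting the
TPM-based exhaustion score.

These are deliberately *strong-signal* conditions: the planted gradient is
many times the per-spot score noise. Passing recovery tests under them shows
the machinery finds what it is designed to find; it does not show the method
is sensitive on weak-infiltration or high-dropout slides — the score's
dynamic range and T-spot density are its known sensitivity limits. The
generator also omits histology, cell-type mixtures beyond the planted
structure, and spatial autocorrelation beyond the planted domains and
trails.

## Numerical choices and degenerate inputs

- All geometry is in microns; array coordinates convert once at load
  (x = col × pitch/2, y = row × pitch × √3/2, pitch 110 µm) when scale-factor
  metadata is absent.
- Zero-UMI spots are dropped at normalization with a warning; an all-zero
  matrix is an error.
- Variable genes: variance of log1p TPM, ties broken by gene name, so
  selection is deterministic and permutation-invariant.
- Zero-variance stage vectors contribute correlation 0 to a route's
  coherence instead of propagating NaN.
- Equal exhaustion scores orient their edge by node id; equal projections in
  the 3D-line ordering break ties by node id.
- Empirical p-values use the plain proportion 2·min(#≥, #≤)/n by default
  (p = 0 possible); the (count+1)/(n+1) convention is available.
- Every random stage (alternative routes, controls, clustering, simulation)
  is driven by explicit seeds through `numpy` `SeedSequence` spawning; runs
  are bit-reproducible from their manifest.

## Problem sizes used in validation

The test suite and the acceptance script run the method end to end on
synthetic slides of 900 spots with ~580 genes; the suite uses 20 replicate
slides for recovery and 8 gradient-free slides for the false-trail rate
(the acceptance script 14 and 6), 200–500 replicates for test calibration,
and 200 control sets for empirical-null checks. These
sizes make the whole validation run in minutes on one CPU while keeping
every statistic's sampling error well inside the asserted margins. A full
production run (5,000 control sets) uses the same code paths.

## Known limitations

- The directed-graph formulation makes all monotone routes between two nodes
  weight-equivalent (telescoping), so the minimum-spanning-path search is in
  effect a most-direct-monotone-route search; this matches the published
  construction but means edge weights do not differentiate routes.
- The 3D-line search assumes trails are approximately straight in (x, y, z);
  strongly curved or convex-profile trails are only found by the graph
  search.
- A single non-monotone step with no adjacent detour breaks the directed
  chain; sensitivity therefore degrades quickly as score noise approaches
  the per-step gradient.
- Control matching requires the trail's expression cluster to host
  length-matched walks; on slides where clusters isolate the trail spots
  themselves, such trails are excluded from control-based analyses.
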