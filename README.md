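# remitt

Reconstruction of T cell migration trails from spatial transcriptomics data.

Tumor-infiltrating T cells exhaust as they move through the tumor
microenvironment. On a 10x Visium or Visium HD slide, a stream of T cells
that followed the same physical corridor leaves a recognizable footprint: a
chain of adjacent T-cell-containing spots whose exhaustion level trends
upward. `remitt` finds these chains and subjects them to a full battery of
permutation-based validation statistics. It is aimed at computational
biologists analyzing tumor ST data who want to go beyond domain clustering
and ask *directional* questions about immune cell movement.

## Method at a glance

Per T-cell spot, the exhaustion score is the OLS residual

    z_i = E_i − (β̂ · T_i + α̂),   shifted so min(z) = 0,

where `E_i` is the summed expression of PDCD1, LAG3, HAVCR2, TIGIT, CTLA4,
ENTPD1, TOX and `T_i` the summed expression of CD8A, CD8B, CD4, CD3D, CD3E,
CD3G — controlling exhaustion for T-cell content. Nodes closer than 130 µm
form a directed graph G(V, E) with edges pointing up the score gradient,
weighted w(u→v) = z_v − z_u. Candidate trails between low-score starts and
high-score ends (terciles) come from Dijkstra's algorithm and from a
3D-line search in (x, y, z) after rescaling xy onto the score range. Trails
shorter than 6 nodes or spanning < 0.5 mm are discarded. A candidate is
reported only if the mean pairwise correlation of stage-gene expression
along it beats all of its own 5–15 alternative same-endpoint routes and the
85th percentile of all alternatives pooled.

Reported trails are then compared against 5,000 matched control sets
(length-, cluster-, adjacency- and span-matched random walks): mixed-model
trend tests for chemokine panels along the trail index, empirical
differential expression with BH correction, shared TCR/BCR variable-gene
statistics, Fisher-exact gene-set enrichment, and phenotype ranking against
single-cell cluster means. Details and assumptions: `docs/methods.md`.

## Worked example

Simulate a slide with planted migration trails, then run the full chain:

```bash
remitt simulate slide/ --seed 4
remitt run slide/ --out out/ --seed 4 --n-control-sets 200
```

which prints (abridged):

```
... remitt.pipeline INFO dataset: 900 spots x 575 genes
... remitt.scoring INFO exhaustion regression: slope=0.3915 intercept=3.525e+04 R2=0.006
... remitt.pipeline INFO 24 candidate trails
... remitt.pipeline INFO 13 trails retained (11 dropped)
13 trails -> out
```

`out/trails.csv` lists each reported trail's ordered spot ids, 1-based
indices, exhaustion profile and span; `out/trend_tests.csv` holds the
mixed-model slopes — a positive `beta` with `p < 0.05` means the panel
rises along the trails; on this simulated slide the CXCL9/10/11 panel gives
`beta = 444.0` (TPM per index step) at `p = 4.7e-16`, matching the planted
per-step gradient; `out/de_table.csv`
contains the empirical differential-expression calls against the matched
controls, and `out/manifest.json` records the full configuration and seeds
needed to reproduce the run byte for byte.

The same API is available from Python:

```python
from remitt import SynthConfig, simulate_dataset, RunConfig, run_pipeline

ds, truth = simulate_dataset(SynthConfig(rng_seed=4))
result = run_pipeline(RunConfig(seed=4, n_control_sets=200), ds=ds)
print(len(result.trails), result.trend_results["cxcl9_10_11"].beta)
```

On real data, point `remitt run` at a spaceranger output directory
(MTX matrix + barcodes/features + tissue positions + scale factors; both
spaceranger position dialects are accepted).

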