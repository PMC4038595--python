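# coexpredict

Transcriptome prediction and in-silico gene perturbation via gene
co-expression networks of chained affine regressions.

Given an RMA-scale (log2-intensity) expression matrix, `coexpredict` builds
an undirected co-expression network in which every edge connects a gene pair
with `|Pearson r|` above a threshold (default 0.75) and carries the
ordinary-least-squares slope/intercept in both directions. From there it can:

- **Select a source-gene panel** — candidates from strongly correlated edges
  (`|r| > 0.95` or `r² > 0.95`), reduced by greedy maximum-marginal-coverage
  set cover within a jump limit (default 4), optionally supplemented with
  high-degree genes from the uncovered remainder.
- **Predict reachable targets** from source-gene values by composing the
  per-edge affine models along all simple paths up to 4 edges (capped at
  10,000 paths per pair, deterministic lexicographic enumeration), reporting
  mean and SD over paths. *Single-pass* mode assigns each target its nearest
  source (ties by source-list order); *multi-pass* pools paths across all
  reaching sources.
- **Simulate perturbations** (over-expression ratio > 1, knockdown < 1,
  knockout = 0) with a two-pass prediction over the perturbed genes'
  reachable neighborhood; affected genes are classified by fold ratio
  (1-jump, default threshold 3×) or a Bonferroni-corrected two-sample z-test
  (2–4 jumps, default α = 0.05).
- **Find expression buffers**: sweep one gene's ratio across a grid, fit a
  quadratic to the affected-gene response, and solve its roots for the ratio
  interval around 1 with no predicted effect.
- **Evaluate** predictions by within-threshold accuracy (actual within
  ±X% of predicted), percent differences, and correlation, stratified by
  jump count; estimate intra-array variation from duplicate-probe genes as
  the mean `|average ratio − 1|`.
- **Simulate data** with known ground truth (latent-factor modules, layered
  chains, random-walk chains, duplicate probes) so everything is testable
  offline.

## Command-line usage

All subcommands hang off one entry point; option precedence is CLI flag >
`--config` YAML file > built-in default, and the resolved configuration is
logged to stderr.

```sh
# simulate a compendium with 5 modules of 20 genes
coexpredict simulate --modules 5x20 --samples 600 --target-r 0.85 --seed 42 --out sim/

# build the network (GraphML or JSON-lines by output extension)
coexpredict build-net --matrix sim/matrix.tsv --threshold 0.75 --out net.graphml

# pick a source panel: candidates at |r| > 0.95, greedy cover, +10 hubs
coexpredict select-sources --net net.graphml --criterion abs_r --cutoff 0.95 \
    --max-jumps 4 --supplement 10 --out sources.txt

# predict all genes reachable within 4 jumps from measured source values
coexpredict predict --net net.graphml --sources sources.tsv --mode single \
    --max-jumps 4 --max-paths 10000 --out pred.tsv

# two-pass perturbation prediction (spec.tsv: gene<TAB>ratio)
coexpredict perturb --net net.graphml --background bg.tsv --spec spec.tsv \
    --alpha 0.05 --fold 3 --out perturbed.tsv

# expression-buffer sweep, 10% steps from knockout to 2x over-expression
coexpredict buffer --net net.graphml --background bg.tsv --gene M0G003 \
    --grid 0:2:0.1 --out buffer.tsv

# score predictions against a held-out sample column
coexpredict evaluate --pred pred.tsv --truth matrix.tsv \
    --thresholds 10,20,30,40 --out report.tsv
```

File formats are plain TSV: the expression matrix has an `id` header column
followed by sample ids; probe maps, source values, and perturbation specs
are 2-column TSV without headers.

## Python API

```python
from coexpredict import (
    build_network, predict_single_pass, PathEnumerationPolicy,
    SourceValues, load_expression_matrix,
)

matrix = load_expression_matrix("matrix.tsv")
net = build_network(matrix, threshold=0.75)
values = SourceValues({"gene1": 8.4, "gene2": 7.1})
results = predict_single_pass(net, values, PathEnumerationPolicy(max_len=4))
```

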