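# signgrn

Gene regulatory network inference from **pseudo time-series** and
**steady-state** single-cell expression data, using the *signs* of
expression time derivatives as class labels.

Pseudo time-series data order cells along a cellular process but carry no
real measurement times, so time derivatives cannot be estimated — but
their signs can. `signgrn` smooths each gene along pseudotime, labels
every cell `+`, `-`, `0` or `X` (excluded) per target gene, trains small
GENIE3-style forests of weighted regression trees on the `0`-labeled
(steady-state) cells, and repeatedly selects the tree most consistent
with the `+`/`-` labeled cells under a class-balanced hinge penalty. The
selected ensemble is scored with permutation ("random input") variable
importance, averaged over repeated randomizations, to rank candidate
regulator→target edges.

## Modules

| module | contents |
|---|---|
| `signgrn.labeling` | dataset container, tricube local-linear smoothing, sign-label rules, per-gene subproblem construction |
| `signgrn.forest` | weighted CART regression trees (numba-jitted), shared-sample inner forests, variance-reduction and permutation importances |
| `signgrn.ensemble` | bootstrap / weight-mass under-sampling / hinge penalty / tree selection loop; full network inference |
| `signgrn.evaluation` | precision-recall curves, AUPRC, candidate-count and expected-overlap arithmetic |
| `signgrn.synthetic` | seeded Hill-kinetics network generator and Euler–Maruyama single-cell simulator; named fixture profiles |
| `signgrn.io`, `signgrn.cli` | TSV readers/writers and the `signgrn` command line |

## CLI

```bash
# generate a synthetic benchmark (expression.tsv, metadata.tsv, gold.tsv)
signgrn simulate --profile tiny --seed 1 --out-dir out/

# assign sign-of-derivative labels
signgrn label --expression out/expression.tsv --metadata out/metadata.tsv \
    --out out/labels.tsv

# infer a ranked network (reduced profile by default; --profile paper
# switches to N_tree=1000 / N_subtree=50 / N_rnd=100)
signgrn infer --expression out/expression.tsv --metadata out/metadata.tsv \
    --seed 1 --out out/edges.tsv

# score against a gold standard
signgrn eval --edges out/edges.tsv --gold out/gold.tsv --out out/report.json
```

Expression TSV: header `cell_id` + gene names, one row per cell.
Metadata TSV: `cell_id`, `pseudotime` (empty for steady-state cells),
`condition`. All outputs start with `#` comment headers recording the
package version, seed and configuration hash.

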