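# pagmix

Constraint-based causal discovery on mixed continuous/categorical data in the
presence of latent confounders. The package implements:

- **graph_core** — endpoint-labelled mixed graphs (DAGs, skeletons, partial
  ancestral graphs), ancestry and d-separation queries, moralization, and
  plain-text graph/dataset I/O;
- **ci_tests** — a regression-based conditional-independence test for mixed
  data (partial-correlation t test for continuous pairs, multinomial-logistic
  likelihood-ratio test when a categorical variable is involved) and a
  d-separation oracle test;
- **mgm** — a pairwise mixed graphical model fitted by proximal-gradient
  minimization of the penalized negative log pseudolikelihood (l1 on
  continuous-continuous weights, group-l2 on continuous-discrete vectors,
  Frobenius on discrete-discrete blocks), used as a constraining skeleton;
- **fci_engine** — FCI-Stable (order-independent skeleton + Possible-D-Sep
  phase + complete orientation-rule closure), FCI-MAX (max-p-value separating
  sets for collider orientation), CFCI (conservative collider classification),
  their MGM-constrained hybrids, a collider-retention optimization and a
  load-balanced collider-job scheduler whose parallel output is bitwise equal
  to the serial one;
- **synthetic_data** — random mixed DAGs with linear / log-linear structural
  equations, non-monotone categorical effects, latent-variable selection and
  ground-truth PAG construction via the oracle search;
- **evaluation** — adjacency and endpoint-orientation precision/recall
  (with fractional circle penalties and DAG-ancestry consultation), stratified
  by CC/CD/DD edge type;
- **cli_io** — the `pagmix` command-line interface and a `replicate` driver
  chaining simulate → learn → evaluate across seed/parameter grids.

## CLI

```sh
# simulate a mixed dataset with latent confounding + ground truth
pagmix simulate --nodes 15 --edges-mean 22 --edges-sd 5 --latents 2 \
    --samples 800 --seed 7 -o data.tsv --true-pag truth.pag --dag dag.graph

# undirected skeleton from the mixed graphical model
pagmix mgm data.tsv --lambda 0.15 -o skeleton.graph

# any of: fci, fci-max, cfci, mgm-fci, mgm-fci-max, mgm-cfci
pagmix learn data.tsv --algorithm mgm-fci-max --alpha 0.05 --depth 3 \
    --skeleton skeleton.graph -o out.pag
pagmix learn data.tsv --algorithm fci-max --alpha 0.05 -o out2.pag

# score an estimate against the truth
pagmix evaluate --est out.pag --truth truth.pag --dag dag.graph -o report.tsv

# full grid: simulate -> learn -> evaluate, long-format TSV out
pagmix replicate --algorithms fci,fci-max --alpha 0.01,0.05 --seeds 0,1,2 \
    --nodes 15 --latents 2 --samples 800 -o results.tsv
```

Datasets are TSV/CSV with a header row; categorical columns are detected
(non-numeric, or integer-valued with few distinct values) and can be forced
with a sidecar type file (`name<TAB>continuous|categorical`). Graphs use a
line-oriented edge list with endpoint tokens (`A o-> B`, `A --- B`, `A <-> B`,
…) beneath a node-declaration block.

## Notes

- Ground-truth PAGs use the oracle search at unlimited conditioning depth;
  that search is exponential in the Possible-D-Sep set size and practical to
  roughly 15 observed nodes. `true_pag(..., pdsep_depth=k)` caps the phase
  for larger graphs.
- All searches are deterministic given the data and configuration; variable
  order never affects results.
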