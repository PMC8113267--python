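# clseq

Analysis toolkit for **cluster RNA-seq**: sequencing libraries made from
small, partially dissociated multi-cell clumps alongside ordinary single
cells.  Because a clump's transcriptome is the sum of its members, a clump
whose correlation profile supports *two* cell states is evidence that those
states are physical neighbors in the tissue.  `clseq` turns that idea into a
pipeline:

1. **simulate** — generate a synthetic 1D tissue (state domains with soft
   boundaries, negative-binomial expression, marker blocks, multi-cell
   clusters, a rare "sticky-cell" artifact mode, optional knockout with a
   hybrid two-state program) with complete ground truth.
2. **qc** — split libraries into singles / clusters / excluded middle by
   total UMI (defaults: clusters > 35,000, singles < 9,500), drop
   low-complexity (< 200 genes) and high-mitochondrial (> 5%) libraries,
   estimate cells per cluster, blacklist genes, score gene sets against
   expression-matched controls, regress out covariates, gate on markers.
3. **signatures** — log-normalize, one-vs-rest Wilcoxon marker detection
   (logFC > 0.25, BH-adjusted p < 0.05), top-20 markers per state, and
   row-z-scored signature profiles.
4. **assign** — Pearson-correlate each cluster library against every
   reference single cell over the signature gene set, group queries,
   test group-by-state mean correlations with a barcode-shuffle permutation
   null (1000 shuffles), and call pure / mixed / unassigned identities
   (defaults r > 0.6, p < 0.01).
5. **graph** — count pair support from mixed calls into a state-adjacency
   graph (min support 2 guards against sticky artifacts), seriate states by
   exhaustive search for 1D orders that keep supported pairs adjacent, and
   validate against simulation truth.

## CLI

One entry point with stage subcommands:

```bash
clseq simulate --config model.yaml --n-singles 700 --n-clusters 700 --seed 7 --out sim/
clseq qc --in sim/ --out qc/
clseq signatures --in qc/ --labels sim/labels.tsv --top-n 20 --out sigs/
clseq assign --query qc/ --reference qc/ --labels sim/labels.tsv \
             --markers sigs/marker_lists.json --n-perm 1000 --seed 7 --out assign/
clseq graph --assignments assign/assignments.tsv --min-support 2 --out graph/
clseq report --assignments assign/assignments.tsv --out report.json
```

or the whole pipeline from one YAML config:

```bash
clseq run --config run.yaml --seed 7 --out run/
```

`run` executes simulate → qc → signatures → assign → graph, records a
manifest with a config hash and per-artifact checksums, is deterministic
under a fixed seed, and resumes by regenerating only missing artifacts.
Exit codes: 0 success, 2 validation error, 3 dependency error, 4 I/O error.

Count matrices are exchanged as MatrixMarket triplets
(`matrix.mtx` + `features.tsv` + `barcodes.tsv`, 1-based indices on disk),
with annotations, truth tables and marker tables as TSV.

## Package layout

```
src/clseq/
  model.py       count-matrix / annotation / gene-table types, dataset merging
  io.py          MatrixMarket triplet + TSV readers/writers
  simulate.py    synthetic tissue model with ground truth
  qc.py          library and gene QC
  signatures.py  normalization, marker detection, signature profiles
  identity.py    correlation assignment, permutation test, composition tests
  spatial.py     state-adjacency graph, seriation, truth evaluation
  evaluation.py  end-to-end benchmarks against simulation truth
  config.py      validated YAML run configuration
  pipeline.py    staged runner with manifest + resume
  cli.py         click CLI
```
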