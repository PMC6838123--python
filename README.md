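# hicsub

Subcompartment inference from moderate-coverage inter-chromosomal Hi-C.

Nuclear chromatin partitions into five primary spatial subcompartments —
A1, A2 (active) and B1, B2, B3 (repressed) — originally defined by
clustering the inter-chromosomal Hi-C contact matrix of deeply sequenced
GM12878 (billions of read pairs). Most Hi-C experiments are far
shallower, so those definitions cannot be transferred directly.
`hicsub` is for genome-organization researchers who want 100 kb
subcompartment annotations from Hi-C runs with tens of millions of
inter-chromosomal read pairs rather than billions.

## Method

The input is the inter-chromosomal contact matrix `C` (rows = 100 kb bins
on odd-numbered autosomes, columns = bins on even-numbered autosomes),
mapped elementwise to contact probabilities

    P_ij = exp(−1 / C_ij),   P = 0 at C = 0,

which bounds heavy-tailed counts in [0, 1) so networks can train with
binary cross-entropy. Two models then operate on rows of `P`:

1. **Denoising autoencoder** — 9 affine layers of widths
   `N_loci, 1024, 512, 256, 128, 256, 512, 1024, N_loci`; ReLU hidden
   layers (25% dropout after the 1024- and 256-unit layers), a linear
   128-d latent layer, sigmoid output. Trained for 25 epochs
   (RMSProp, batch 32, lr 0.001) to map rows of a downsampled matrix to
   the corresponding rows of the dense matrix. Its encoder turns each
   bin's genome-wide contact profile into a 128-d embedding; its decoder
   imputes the dense contact probabilities.
2. **Balanced MLP classifier** — layers `128, 64, 16, 5` with a sigmoid
   squash on the input embedding, ReLU + 25% dropout on hidden layers,
   and softmax output over the five subcompartments. Before training,
   each class is brought to the same size N by sampling synthetic
   embeddings `r = x + (y − x)·rand(0,1)` on segments between same-class
   pairs.

Independent model pairs are trained for the odd and even parities (the
even pipeline runs on the transposed matrix). Across multiple cell
types, per-bin annotation entropy `S_i = Σ_c −p_{i,c} log p_{i,c}`
(with `p_{i,c}` the fraction of cell types labelling bin `i` as `c`)
defines 13 conservation states — 12 entropy-ordered states plus a
non-conserved state for bins where no label reaches a majority — and
per-label information content `|p log(p/q)|`, `q = 0.2`.

Everything is plain NumPy; training is bitwise reproducible for a fixed
seed.

## Worked example

No real Hi-C download is required: the package ships a planted-truth
simulator that generates block-structured inter-chromosomal matrices
with Poisson noise and known labels.

```sh
hicsub simulate --n-odd 400 --n-even 400 --depth 2e6 --keep-rate 0.1 \
    --seed 0 --out fixture/
hicsub train --dense fixture/dense.triplets.tsv --reference fixture/truth.bed \
    --chrom-sizes fixture/chrom.sizes --keep-rate 0.1 --seed 0 --out models/
hicsub annotate --model-dir models/ --contacts fixture/sparse.triplets.tsv \
    --chrom-sizes fixture/chrom.sizes --out annotated/
hicsub evaluate --pred annotated/subcompartments.bed --reference fixture/truth.bed \
    --chrom-sizes fixture/chrom.sizes --out eval/
```

The same run through the library:

```python
from hicsub.experiments import recovery_experiment
print(recovery_experiment(seed=0))
```

prints

```
{'held_out_accuracy': 1.0, 'spearman_imputed': 0.864..., 'spearman_sparse': 0.765...}
```

meaning: training on half the chromosomes at 10% coverage, every held-out
100 kb bin received its planted subcompartment label, and the imputed
probability matrix tracks the dense matrix better (row-averaged Spearman
0.86) than the sparse input does (0.77). A coverage titration
(`hicsub coverage-sweep`, or `hicsub.experiments.coverage_trend`) shows
accuracy holding ≥ 0.99 down to 5% coverage on the same fixture and
degrading at 2%.

Real data workflow (optional): export inter-chromosomal 100 kb counts
from a `.hic`/cooler store to triplet text with your extractor of
choice, supply a chromosome-sizes file, and use the same commands; a
reference annotation BED on the identical grid is needed for training.

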