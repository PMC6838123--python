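# Methods

## Model overview

`hicsub` treats subcompartment inference as representation learning on
the inter-chromosomal Hi-C matrix. Each 100 kb bin is described by its
vector of contacts with every bin of the opposite chromosome parity;
bins in the same spatial subcompartment have near-identical such
vectors, which is what makes the inter-chromosomal block (rather than
the distance-dominated intra-chromosomal maps) the right substrate.
The method assumes (i) contact propensity between two bins depends
mainly on their subcompartment identities, (ii) a low-coverage matrix
is a read-level thinning of the dense one, and (iii) the reference
labels used for training are transferable across the genome within a
cell type.

### Contact probabilities

Raw counts are mapped through `P = exp(−1/C)` with `P(0) = 0`, the
analytic `C → 0⁺` limit; no pseudocount is added, so sparsity is
preserved exactly. The map is strictly increasing, bounded in `[0, 1)`,
and compresses outliers toward 1, which keeps extreme cells from
dominating gradients and lets both networks train under binary
cross-entropy. Whether counts were previously matrix-balanced is
deliberately left to the caller: pre-normalized matrices are accepted
unchanged, raw counts are the default.

### Denoising autoencoder

Widths `N_loci, 1024, 512, 256, 128, 256, 512, 1024, N_loci`; ReLU
hidden layers; the 128-d latent layer is linear to leave the embedding
space unconstrained; the output layer is sigmoid to match the target
range. Dropout (rate 0.25) follows the 1024- and 256-unit hidden layers
on both sides of the bottleneck. Training: binary cross-entropy (a
mean-squared-error mode is provided and behaves similarly), RMSProp
(decay 0.9, epsilon 1e-7 — conventional values), 25 epochs, batch 32,
learning rate 0.001. Inputs are rows of the downsampled probability
matrix restricted to the training chromosomes (by default the first
half of each parity's chromosome list, ≈ 50% of rows); targets are the
corresponding dense rows. The even-parity model is trained on the
transposed matrices with the same recipe.

For small synthetic grids every interior width is capped at
`4·N_loci`, preserving the hourglass shape at desk scale.

Two numerical choices matter at small sample sizes and are therefore
explicit:

- **Initialization** is seeded He-uniform, `W ~ U(−s, s)` with
  `s = sqrt(6/fan_in)`. With unit-gain fan-in scaling the 25-epoch
  budget on a few hundred rows reliably stalls in the "predict the
  column means" basin — the reconstruction ignores its input entirely —
  whereas the ReLU-variance-preserving gain escapes it.
- **All floats are float32**, and every random choice (init, shuffling,
  dropout masks, thinning) flows through one seeded generator, so runs
  are bitwise reproducible on a given platform.

### Classifier

Layers `128, 64, H, 5` with `H = 16` by default and 32 as a supported
alternative (both train successfully; the published description is
ambiguous between them). The input embedding is passed through a fixed
sigmoid squash; hidden layers are ReLU with 25% dropout; the output is
softmax, and `predict` takes the argmax with ties broken toward A1.
Loss is categorical cross-entropy under the same RMSProp settings.
Because the balanced training sets here are orders of magnitude smaller
than a genome's worth of bins, the classifier gets its own epoch budget,
default 50 (the autoencoder keeps 25); both are configurable.

### Training-set balancing

For each class, N synthetic embeddings are generated as uniform random
points on segments between two randomly chosen same-class originals,
with N strictly greater than the largest class count (default
`3 × largest class + 1`, which gives the optimizer enough samples per
epoch at desk scale). The output is exactly `5N` rows with a uniform
label marginal; provenance (generating pair indices) is retained so the
segment-membership invariant is checkable.

### Coverage handling at inference

A model pair is trained at one input coverage. Inputs substantially
denser than that sit off the training distribution and measurably
degrade annotations, so `annotate_cell` by default thins any input whose
total count exceeds the training coverage down to it (binomial thinning
with a manifest-derived seed — deterministic). This mirrors how the
training input itself is produced from denser data, and the
complementary deployment rule `select_parameter_set` chooses between
10%- and 5%-trained bundles by the target's inter-chromosomal read-pair
count (default boundary 45 million pairs). The coverage-titration
utility (`coverage_sweep`) consequently defaults to a fixed model pair
trained at 10% applied across input coverages; `retrain=True` instead
retrains the whole pipeline per rate. At desk scale the retraining
variant is noticeably less stable at high keep-rates: with little
corruption the 25-epoch denoising task is too easy to force
class-structured latents out of a few hundred rows.

### Conservation states

Across N cell types, each fully annotated bin has a count vector over
the five labels; entropy uses natural log with `0·log 0 = 0` (state
identities are invariant to the log base, which only rescales the
ordering — tested). Count multisets are partitions of N into at most
five parts, so entropy takes finitely many values: 23 for N = 9, of
which 11 lack a strict-majority label and merge into the non-conserved
state, leaving 12 numbered states + NC. The majority rule generalizes
as `2·max_count > N`. Bins with any NA annotation are excluded from
state assignment and flagged separately. B2 and B3 are kept distinct
throughout. Information content is `|p·log(p/q)|` with uniform
background `q = 0.2`, bounded by `ln 5`.

### Evaluation conventions

Accuracy is the fraction of co-annotated bins whose labels match;
per-class accuracy is the confusion-matrix diagonal over its row sum.
AUPR is one-vs-rest with step-wise precision-recall integration (linear
interpolation is optimistic for PR curves). Enrichment fold change is
the median signal within a class over the median across all annotated
bins, computed over full-width bins only (terminal short bins excluded,
so bin medians equal base-pair medians). Boundary profiles average a
signal at 100 kb offsets in ±400 kb around ordered label switches of
adjacent bins; windows that leave the chromosome or touch an NA bin are
dropped. Cross-validation is stratified k-fold with a per-fold balanced
retrain, falling back to unstratified folds (and to unbalanced training)
when a class is too small.

## Synthetic data

The planted model emulates exactly the structure the method relies on:
five labels laid out in contiguous domain-like runs (geometric lengths,
mean 8 bins, minimum 3 — roughly megabase-scale domains) over two
parities of 400 bins each by default; counts are independent Poisson
draws with mean `depth · R[l_i, l_j] / Z`, normalized so the expected
total equals the target depth (2×10⁶ read pairs by default, i.e. a mean
of ~12 pairs per 100 kb × 100 kb cell before thinning). The affinity
matrix R is diagonal-dominant with strong A1–A1, A2–A2, B3–B3
self-affinity, an A1–A2 cross term, moderate B-family terms, B1
intermediate, and weak A–B contacts. Its contrast is chosen so that
label-pair classes are actually separated in probability space after
the `exp(−1/C)` map at the default depth; with weak contrast all dense
probabilities collapse into a narrow high band where cross-entropy
cannot distinguish reconstruction from a constant predictor. The
magnitudes are simulation knobs, not estimates of real contact
frequencies.

What the simulator does **not** model: genomic distance effects
(irrelevant inter-chromosomally), mappability/GC/fragment biases,
copy-number and structural variation, matrix balancing artifacts, or
mixtures of cell states. Tests passing on these fixtures demonstrate
that the implementation recovers planted structure under Poisson +
thinning noise at realistic sparsity — not that real-data accuracy will
match.

Signal tracks for enrichment/boundary tests are Gaussian draws around
per-label means (defaults 4, 3, 2, 1, 0.5 — an active-to-repressed
gradient) with configurable noise.

## Problem sizes used in the shipped experiments

The canned experiments (`hicsub.experiments`) run the full pipeline on
the 400×400-bin default fixture (4 chromosomes per parity, train on the
first two), which takes a few seconds per seed on one CPU; the test
suite's shared fixture uses 200×200 bins at the same per-cell depth.
These sizes were chosen as the smallest at which the pipeline's
behaviour is stable across seeds.

## Known limitations

- Desk-scale training (hundreds of rows) is far below the regime the
  protocol's hyperparameters were designed for; the He initialization
  and the classifier's larger epoch budget compensate, but per-seed
  variance remains visible (one seed in ten typically lands just below
  0.9 held-out accuracy at 10% coverage).
- Binary `.hic`/cooler stores are not parsed natively; contacts enter as
  triplet text.
- Bins are fixed-width on one assembly; no lift-over or SV-aware
  correction.
- Probability outputs are not calibrated; the softmax scores rank labels
  but are not validated as frequencies.
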