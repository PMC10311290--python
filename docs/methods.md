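# Methods

## Model and assumptions

`crosstype` matches cell types between two species' scRNA-seq datasets by
(i) building a weighted bipartite gene-match graph from protein-embedding
cosine distances or BLAST bitscores, (ii) imputing a shared feature space
over the union of matched genes, (iii) training a shared-weight cell
encoder with per-species softmax classifiers, and (iv) transferring labels
by classifier swapping. The central assumptions are that homologous genes
have nearby protein embeddings, that matched cell types have similar
(z-scored, log-normalized) expression over matched genes, and that a
linear-softmax head over a shared nonlinear embedding can separate the
types within each species.

The matching score between two types is the average of the two directional
transfer fractions. It summarizes classifier agreement, not absolute
transcriptional similarity: scores change if the type composition of either
dataset changes, and the classifiers have no rejection option, so genuinely
species-specific types can only be recognized by their low scores.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `tau` | 0.005 | cosine-distance threshold for candidate gene matches |
| `k_max` | 5 | per-gene cap on retained partners |
| `n_hvg` | 2000 | highly variable genes per species (seurat-flavor dispersion) |
| `norm_scale` | 1e4 | library-size target per cell before log |
| `hidden_dim`, `embed_dim` | 64, 32 | encoder layer widths |
| `epochs`, `lr` | 200, 0.001 | Adam training run (one batch pair per epoch) |
| `batch_per_species` | 5000 | cells sampled per species per epoch |
| `smoothing` | 0.1 | label-smoothing mass spread over non-target types |
| `weight_alpha` | 9 | dynamic class weights `w_t=(1-acc_t)α+1 ∈ [1,10]` |
| `k_align` | 20 | cross-species neighbours in the alignment loss |
| `l2_gamma` | 0.01 | L2 penalty on all parameters |

The distance threshold is tied to the embedding model that produced the
vectors; 0.005 is appropriate for 1024-dimensional protein-language-model
embeddings and is exposed as configuration for other embedding sources.

## Design choices where the design was open

- **Edge weights** are `1 − d/τ`, clamped to [0, 1]: weight 1 at distance
  0, weight 0 at the threshold. In BLAST mode the (average) bitscore is the
  edge score; the stored [0, 1] weight divides by the maximum retained
  bitscore, which is equivalent under imputation because each imputed
  column normalizes by its incident weight sum.
- **Top-k rule.** The per-gene closest-k cut is directional. An edge is
  retained if it survives the cut for *at least one* endpoint (union rule,
  default); an intersection rule is available. The union keeps asymmetric
  matches where a gene is important to its partner but not vice versa.
  Ties at the k-th position break lexicographically by partner gene id for
  determinism.
- **Isoforms.** When a gene has several protein isoforms, gene–gene
  distance is the minimum over isoform pairs (one similar isoform is
  evidence enough for homology); a mean mode is available.
- **Soft alignment neighbours.** With hard nearest-neighbour selection and
  fixed shared features, the alignment term is piecewise constant in the
  parameters and contributes no gradient. The default therefore weights
  the K nearest opposite-species cells by a softmax over negative squared
  embedding distances, the minimal differentiable relaxation; a
  paper-literal `hard` mode is kept for ablation. Neighbours are found
  within the batch, not globally.
- **Class-weight accuracy** is the training-batch accuracy accumulated per
  epoch, per species, with the species' own classifier; weights start at 1
  (no accuracy exists before the first epoch) and types absent from an
  epoch's batch keep their previous weight.
- **Scoring conventions.** Transfer argmax ties break to the lowest type
  index; recall requires *strict* row-and-column maxima (ties count as
  failure); types absent from one species appear as all-zero rows/columns
  rather than being dropped. The combined matrix has species-A types as
  rows.
- **Normalization order.** Each species is restricted to its matched gene
  set, then z-scored (population sd, `ddof=0`); imputation consumes the
  z-scored values. Zero-variance genes z-score to 0 instead of NaN. A
  zero-count cell is an error (upstream QC is out of scope). An imputation
  group whose weights sum to zero (possible only at distance exactly τ)
  yields a zero column with a warning — the "no information" baseline on
  the z-scale.

## Numerical details

- Cross-entropy clamps probabilities at 1e−12 inside the logarithm.
- Parameters initialize with uniform Kaiming-style fan-in scaling from the
  run seed; biases start at zero. Batch sampling, initialization, and all
  other randomness draw from one seeded generator, so two runs with the
  same seed produce identical trajectories on one machine.
- All gradients (weighted smoothed cross-entropy, soft-neighbour alignment,
  L2) are derived analytically and verified against central finite
  differences in the test suite.
- Adam uses β = (0.9, 0.999), eps = 1e−8.

## Synthetic data

The generator emulates exactly the structure the method assumes: homology
latents give each one-to-one (or duplicated) gene pair nearby embeddings
(latent + independent noise, default sd 0.02, i.e. cosine distances
~1e−4 — well inside τ — while unrelated genes sit near distance 1);
matched types share per-gene log-normal mean profiles up to a small
divergence factor (default sd 0.05); counts are negative-binomial
(dispersion 2) with 10% dropout. Defaults: 5 matched types, 60 vs 45
cells per type (a deliberate species proportion imbalance), 150 shared
homology latents, 40 species-specific genes per species, embedding
dimension 32. A BLAST-style table with bitscores decreasing in embedding
distance (plus decoy hits above the E-value cutoff) is emitted so all
three matching modes run against the same known homology.

What passing on these fixtures shows: the pipeline's machinery — matching,
imputation, optimization, transfer, scoring — recovers a known ground
truth under its own assumptions. What it does not show: performance on
real atlases, where type boundaries are ambiguous, homology is partly
many-to-many, batch effects exist, and embeddings come from a real protein
language model. No claim of splatter-grade biological fidelity is made.

Recovery tests and the worked example train with 150 epochs and batches of
512 — sized to the ~525-cell fixtures (larger batches than the dataset
only resample it) — while the published defaults (200 epochs, 5000 per
batch) remain the configuration defaults.

## Limitations

- Only coding genes with available protein embeddings participate in
  embedding-mode matching; genes without an embedding are dropped (logged).
- No rejection option: every cell receives an opposite-species label, so
  species-specific types are detected only through low matching scores.
- The alignment loss encourages type-level proximity, not per-cell mixing;
  it is not a batch-integration method.
- Computing protein embeddings and running BLAST are outside the package:
  both are consumed as precomputed inputs.
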