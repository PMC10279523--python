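# Methods

## Model and assumptions

omicfuse assumes that the omics layers of one cohort share a single latent
partition of the patients: every layer measures a different molecular facet
of the same subtypes. Each layer v contributes two complementary signals —
its expression matrix X⁽ᵛ⁾ and the neighbourhood structure of its samples,
encoded as a binary kNN graph A⁽ᵛ⁾ (edge when either sample is among the
other's k nearest Euclidean neighbours; self excluded; ties at the k-th
distance broken deterministically by lower row index). The graph enters the
model twice: as the propagation operator T⁽ᵛ⁾ = D^{-1/2}(A⁽ᵛ⁾+I)D^{-1/2} of
the graph-convolutional encoder/decoder layers, and as a reconstruction
target of the bilinear graph decoder. Reconstructing both the attributes and
the graphs from one shared embedding H forces H to preserve expression
content *and* sample-similarity relations simultaneously.

Patients missing a layer are handled structurally, not by imputation: the
indicator matrix G⁽ᵛ⁾ (N_v × N, one 1 per row) maps omics-local rows to the
intact patient universe, fusion averages only the embeddings that exist, and
G⁽ᵛ⁾·H selects the relevant rows of H for each decoder. When every layer is
complete all G⁽ᵛ⁾ are identities and the machinery reduces — bit-exactly, by
construction (row indexing and scatter-adds rather than matrix products) —
to the plain full-data computation.

All activations are tanh; consequently reconstructed attributes and graph
entries lie in (−1, 1). On z-scored inputs this is adequate (most entries
fall inside the range), but a binary adjacency with edges can never be
reconstructed exactly — L_gsr has a positive infimum whenever A has edges.
We regress the raw tanh output against the binary adjacency with a squared
Frobenius loss; no sigmoid/cross-entropy variant is used.

## Training schedule

1. **Pre-training** minimizes L_nar + α·L_gsr full-batch.
2. **Cluster initialization**: the cluster count C is chosen by the plain
   eigengap rule on the normalized Laplacian of a Gaussian-on-kNN similarity
   over the rows of H, searching C ∈ [2, 15]; μ is set to the centroids of
   the spectral labels. Empty initial clusters trigger up to five re-seeded
   k-means retries.
3. **Fine-tuning** minimizes L = L_nar + α·L_gsr + β·KL(P‖Q) with μ updated
   by gradient (the deep-embedded-clustering convention). The target P is
   recomputed from the current Q every `p_refresh_interval` epochs
   (default 5), and training stops early once the fraction of samples whose
   argmax-Q cluster changed between refreshes falls below `convergence_tol`
   (default 0.001). C stays frozen after initialization: re-estimating it
   every refresh would destabilize μ.
4. Final labels come from spectral clustering of the final H with the
   frozen C.

Because the cohorts this tool targets are small (hundreds of patients),
training is full-batch with a numpy implementation of Adam at the default
learning rate 0.001; plain SGD is available via `optimizer="sgd"`. Gradients
of every term — through the tanh GCN stacks, the indicator fusion, the
bilinear graph decoder, and the Student-t/KL self-supervision — are derived
analytically and verified against central finite differences in the test
suite. With a fixed seed, two runs are bit-identical.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| learning rate | 0.001 | stated operating point of the method |
| α, β | 1, 1 | the loss is reported to be robust to these trade-offs |
| d (embedding dim) | 0.8 × min(D_v) if min(D_v) < 2000, else 1600 | dimension rule of the method |
| encoder depth M | 2 | two propagation steps; hidden width min(256, D_v) |
| k (GCN graphs) | ⌈log₂ N_v⌉ + 1, clamped to [2, N_v−1] | slowly growing: sparse but (empirically) connected |
| eigengap range | [2, 15] | stated search range for the cluster count |
| pretrain / fine-tune epochs | 200 / 100 | enough for the reconstruction loss to reach its cluster-structure floor on cohorts of this size |
| similarity bandwidth t | auto: mean squared distance over retained neighbour pairs | scale-free local bandwidth |

Weights are Glorot-uniform initialized (tanh-appropriate scaling), seeded.
A numerical floor of 1e-12 guards the soft-assignment and target-distribution
denominators in degenerate collapsed states; normal values are untouched.

## Design choices that were genuinely open

* **Decoder indexing.** The attribute decoder mirrors the encoder with M
  weight matrices: the first applied row-wise to G⁽ᵛ⁾H without propagation,
  the remaining M−1 with T⁽ᵛ⁾, ending at D_v columns. This is the only
  arrangement consistent with the stated loss shapes for partial cohorts.
* **Connectivity of the clustering graph.** The eigengap heuristic counts
  near-zero Laplacian eigenvalues, and a disconnected similarity graph
  contributes one exact zero per component — so on a disconnected graph the
  rule returns the component count of the *neighbourhood graph* rather than
  the cluster count of the data. This matters for partial cohorts: fusion
  averages a patient's available embeddings, so patients covered by
  different omics subsets can occupy systematically offset regions of
  H-space, and a small-k graph then falls apart into cluster × coverage
  strata. Following standard spectral-clustering practice, the similarity
  builder doubles k until the graph is connected; on full cohorts the
  default k already yields a connected graph and nothing changes.
* **Eigengap form.** The plain gap argmax_i (λ_{i+1} − λ_i) is the default;
  an index-weighted variant (maximizing i·gap) is available via
  `index_weighted_eigengap`. Ties break toward the smaller count.
* **Discretization.** The trace relaxation is completed conventionally:
  row-normalized bottom-C eigenvectors, k-means with 20 seeded restarts.
* **μ as a parameter.** Centers are trained by gradient during fine-tuning
  rather than re-estimated from hard assignments.
* **KL base.** Natural logarithm; only the relative scale against β depends
  on this choice.

## What the synthetic generator emulates — and what it does not

`generate_multiomics` plants one balanced C-cluster partition shared by all
layers: per layer, C centroids separated by `separation × noise_sd` along
mutually orthogonal random directions, plus i.i.d. Gaussian noise.
`apply_missingness` deletes a uniformly sampled fraction θ of rows from one
layer — whole patients missing one platform, the partial-cohort regime.

This captures the consensus-structure assumption and the missingness
mechanism, but not real omics marginals: no methylation beta-value bounds,
no count overdispersion, no correlated features, no batch effects, and no
block missingness across several layers. Passing the recovery tests
therefore shows the pipeline is a correct and robust implementation of the
model under its own assumptions — not that it will resolve subtypes in any
particular clinical cohort, where separations are far weaker and clusters
are unbalanced.

Study conditions used by the test suite and `scripts/acceptance.py`: N = 300
patients, V = 2 layers with 50 and 80 features, C = 3 subtypes, separation 8,
noise SD 1, θ ∈ {0, 0.1, 0.3, 0.5}, five generator/training seeds per
condition; the pretraining-efficacy measurement uses a 120-patient version
(dims 20 and 30). These sizes keep a complete run around a minute on one
CPU while leaving the recovery task non-trivial for a wrong implementation
(a mis-specified fusion, loss, or eigengap reliably breaks them).

## Degenerate inputs and numerical notes

* Zero-variance features are dropped (with a warning) before z-scoring; an
  all-constant layer is an error.
* An intact patient absent from every layer makes fusion undefined and is an
  error; an isolated node in the similarity graph is an error advising a
  larger k.
* An empty soft cluster (a Q column summing to 0) is an error in the target
  distribution; KL is infinite (error) if Q is 0 where P is positive, with
  0·log 0 ≡ 0.
* Everything is float64 and dense; eigendecompositions use
  `scipy.linalg.eigh`. The brute-force oracle tests hold to 1e-10.

## Known limitations

* Full-batch dense training: fine for N up to a few thousand, not for
  atlas-scale data (no minibatch graph sampling).
* No out-of-sample assignment; clustering is transductive.
* Hyperparameter search is out of scope: the CLI reports silhouette so users
  can compare settings, but no grid search is built in.
* Survival and clinical-enrichment analyses of discovered subtypes are left
  to downstream tools (the labels TSV joins cleanly on sample IDs).
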