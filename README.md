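# omicfuse

Multi-omics integration and cancer-subtype discovery for **full and partial
cohorts**: a graph-convolutional autoencoder that embeds V omics expression
matrices into one consensus latent space by jointly reconstructing each
omics' expression matrix *and* its sample-similarity graph, refines the
embedding with deep-embedded-clustering self-supervision, and assigns
subtypes by eigengap-guided spectral clustering.

It is aimed at computational biologists who have per-patient expression
matrices from several platforms (e.g. DNA methylation, mRNA, miRNA) where
some patients were never profiled on some platforms. Missing patients are
handled by indicator matrices rather than imputation, so partial cohorts run
through exactly the same pipeline as complete ones.

## Model

For omics v with matrix X⁽ᵛ⁾ (N_v × D_v), a binary kNN graph A⁽ᵛ⁾ connects
samples that are mutual-or-one-way k-nearest Euclidean neighbours. With the
renormalized operator T⁽ᵛ⁾ = D^{-1/2}(A⁽ᵛ⁾+I)D^{-1/2}:

* **Encoder** — Z_m = tanh(T⁽ᵛ⁾ Z_{m−1} W_m), Z_0 = X⁽ᵛ⁾, giving a per-omics
  embedding Z⁽ᵛ⁾ with shared width d.
* **Consensus fusion** — a binary indicator G⁽ᵛ⁾ (N_v × N) maps omics rows to
  the intact patient universe; h_j = Σ_v Σ_i G⁽ᵛ⁾_ij z⁽ᵛ⁾_i / Σ_v Σ_i G⁽ᵛ⁾_ij,
  the mean of each patient's available embeddings.
* **Attribute decoder** — tanh layers mirror the encoder back to D_v columns,
  loss L_nar = Σ_v ‖X⁽ᵛ⁾ − X̂⁽ᵛ⁾‖²_F.
* **Graph decoder** — Â⁽ᵛ⁾ = tanh(G⁽ᵛ⁾H W̃⁽ᵛ⁾ (G⁽ᵛ⁾H)ᵀ), one bilinear matrix
  per omics, loss L_gsr = Σ_v ‖A⁽ᵛ⁾ − Â⁽ᵛ⁾‖²_F.
* **Self-supervision** — Student-t soft assignment Q of H to trainable
  centers μ, sharpened target P_ij ∝ Q²_ij / Σ_i Q_ij, loss L_ss = KL(P‖Q).

Total loss L = L_nar + α·L_gsr + β·L_ss (defaults α = β = 1, learning rate
0.001). Training pre-trains on L_nar + αL_gsr, initializes C and μ by
eigengap spectral clustering of H (C searched over [2, 15]), then fine-tunes
on the full loss with periodic target refresh. Final subtypes come from
spectral clustering of the final H.

## Worked example

```python
import omicfuse as of
from sklearn.metrics import adjusted_rand_score

spec = of.SyntheticSpec(n_samples=300, n_omics=2, n_clusters=3,
                        dims=(50, 80), separation=8.0, noise_sd=1.0, seed=0)
ds = of.generate_multiomics(spec)            # full cohort
ds = of.apply_missingness(ds, 0, 0.3, seed=1)  # drop 30% of patients from omics 0

res = of.fit_predict(ds, of.TrainConfig(seed=0))
print(res.n_clusters, adjusted_rand_score(ds.true_labels, res.labels))
```

prints

```
3 1.0
```

i.e. even with 30% of patients missing one omics, the pipeline selects the
correct number of subtypes by the eigengap rule and recovers the planted
partition exactly (adjusted Rand index 1.0) on this well-separated cohort.

The same pipeline is scriptable from a shell:

```bash
omicfuse simulate --n-samples 300 --dims 50,80 --n-clusters 3 --outdir data/
omicfuse fit data/omics_0.tsv data/omics_1.tsv --seed 0 --outdir run/
omicfuse evaluate --labels run/labels.tsv --truth data/true_labels.tsv \
                  --embedding run/embedding.tsv
```

`fit` writes per-sample cluster labels, the consensus embedding, a per-epoch
loss log and internal quality metrics.

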