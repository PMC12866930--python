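# scdropgan

Selective dropout imputation for single-cell RNA sequencing expression
matrices.

scRNA-seq count matrices are dominated by zeros of two kinds: biological
zeros (the gene is genuinely silent in that cell) and technical dropouts
(the transcript was present but not captured). Imputing indiscriminately
corrupts biological zeros; not imputing at all leaves downstream analyses
(clustering, differential expression, trajectories) working on damaged
data. `scdropgan` addresses both failure modes:

1. **Dropout identification.** For each gene *j* within each cell
   subpopulation *k*, preprocessed expression is modeled as a
   two-component mixture

   f(x) = λ·Gamma(x; α, β) + (1 − λ)·Normal(x; μ, σ),

   where the Gamma component (mass near the zero level) represents
   dropout and the Normal component genuine expression. Parameters are
   fit by EM; a zero is flagged as a dropout when its posterior dropout
   probability d = λĝ(x) / (λĝ(x) + (1 − λ)n̂(x)) exceeds a threshold
   ρ (default 0.5). Subpopulations come from provided cell-type labels or
   from K-means pre-clustering (model order via silhouette + elbow).

2. **Generative imputation.** A variational autoencoder with a learnable
   Gaussian-mixture latent prior (one component per cell type) is
   pretrained on its evidence lower bound

   ELBO = E_q[log p(x|z)] − KL(q(z, k|x) ‖ p(z, k)),

   then trained adversarially against a multi-task discriminator: a
   shared embedder feeds (i) an adversarial real/fake head, (ii) a
   cell-level contrastive head scored with the NT-Xent loss whose
   positive pair is (observed cell, its reconstruction), and (iii) a
   cell-type-level head scored with the supervised contrastive loss.
   The contrastive heads push the generator to keep individual cells and
   cell types distinguishable — the defense against over-smoothing.
   Finally, the decoder's noise-free reconstruction replaces **only** the
   flagged zeros; every other entry is returned bit-identical.

A Splatter-style simulator (Gamma gene means, log-normal library sizes,
per-type DE factors, Poisson counts, mean-dependent logistic dropout)
provides paired (complete, observed) matrices with the exact dropout
mask, so the whole method is testable without any download. Presets
`sim42` … `sim91` target observed zero rates of 42–91% over a
dropout-free base rate of ~27%.

The networks run on a compact reverse-mode autodiff engine included in
the package (`scdropgan.tensor`, `scdropgan.nn`) — plain numpy, CPU-only,
sized for desk-scale matrices.

## Worked example

```python
import numpy as np
from scdropgan import (RunConfig, preprocess, preset, recovery_metrics,
                       run_pipeline, simulate)

truth = simulate(preset("sim71", seed=1, n_cells=500, n_genes=300))
cfg = RunConfig(seed=1, hidden_dims=(128, 64), latent_dim=16,
                warmup_epochs=5, pretrain_epochs=10, joint_epochs=10,
                batch_size=128)
result, manifest = run_pipeline(truth.observed, cfg, labels=truth.labels)

complete = preprocess(truth.complete, cfg)
imputed = recovery_metrics(result.values, complete,
                           positions=truth.true_dropout_mask)
print(imputed["rmse"], imputed["pcc"])
```

Running this (it is `examples/03_impute_pipeline.py`) prints

```
imputed 86,612 flagged zeros
RMSE at true-dropout positions: 0.941 (leaving them at zero: 1.447)
PCC at true-dropout positions:  0.744
```

i.e. at the positions where the simulator deleted real expression, the
imputed values are substantially closer to the hidden truth than the
zeros they replace (RMSE 0.94 vs 1.45 on the log scale) and correlate
well with it (Pearson r = 0.74). `examples/` contains one short script
per capability: simulation, dropout identification, the full pipeline,
the clustering gain, and the ablation benchmark.

A thin CLI mirrors the library:

```sh
scdropgan simulate --preset sim71 --seed 1 --out sim/
scdropgan identify --input sim/observed.mtx --labels sim/labels.txt --out id/
scdropgan train --input sim/observed.mtx --labels sim/labels.txt --out run/
scdropgan evaluate --imputed run/imputed.csv --truth truth.csv --out report.tsv
scdropgan benchmark --presets sim42,sim71,sim91 --seeds 1,2 --out bench.tsv
```

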