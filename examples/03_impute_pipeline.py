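"""Run the full selective-imputation pipeline and measure recovery.

The pipeline preprocesses the counts, flags dropouts, pretrains the
mixture-prior variational generator on its ELBO, adversarially trains it
against the multi-task discriminator, and imputes only the flagged zeros.
"""

import numpy as np

from scdropgan import (RunConfig, preprocess, preset, recovery_metrics,
                       run_pipeline, simulate)

truth = simulate(preset("sim71", seed=1, n_cells=500, n_genes=300))
cfg = RunConfig(seed=1, hidden_dims=(128, 64), latent_dim=16,
                warmup_epochs=5, pretrain_epochs=10, joint_epochs=10,
                batch_size=128)
result, manifest = run_pipeline(truth.observed, cfg, labels=truth.labels)

complete = preprocess(truth.complete, cfg)
observed = preprocess(truth.observed, cfg)
at_dropout = truth.true_dropout_mask
imputed = recovery_metrics(result.values, complete, positions=at_dropout)
print(f"imputed {manifest['n_dropouts_flagged']:,} flagged zeros")
print(f"RMSE at true-dropout positions: {imputed['rmse']:.3f} "
      f"(leaving them at zero: "
      f"{np.sqrt(np.mean((observed.values[at_dropout] - complete.values[at_dropout])**2)):.3f})")
print(f"PCC at true-dropout positions:  {imputed['pcc']:.3f}")

# Lower RMSE than the left-at-zero baseline and a high Pearson correlation
# mean the generator reconstructs the missing expression rather than
# filling in noise; entries outside the dropout mask are untouched.
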