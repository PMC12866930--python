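"""Flag dropout events with the per-subpopulation Gamma-Normal mixture.

Each gene's preprocessed expression within a cell type is modeled as
lambda * Gamma + (1 - lambda) * Normal; a zero is called a dropout when
its posterior probability of coming from the Gamma (dropout) component
exceeds rho = 0.5.
"""

from scdropgan import (dropout_id_metrics, identify_dropouts, preprocess,
                       preset, simulate)

truth = simulate(preset("sim71", seed=1, n_cells=500, n_genes=300))
x = preprocess(truth.observed)
d, mask, fits = identify_dropouts(x, truth.labels, rho=0.5, seed=1)

report = dropout_id_metrics(mask, truth.true_dropout_mask, truth.observed)
print(f"fitted {len(fits)} (gene, subpopulation) mixtures")
print(f"flagged {mask.mask.sum():,} of {int((truth.observed.values == 0).sum()):,} zeros")
for metric in ("f1", "precision", "recall", "fpr"):
    print(f"{metric}: {report[metric]:.3f}")

# F1/precision/recall compare flagged zeros against the simulator's true
# dropout positions; FPR is the fraction of biological zeros incorrectly
# flagged (the over-imputation risk).
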