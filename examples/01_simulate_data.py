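"""Simulate paired (complete, dropout-corrupted) scRNA-seq counts.

The presets span observed zero rates from ~42% to ~91% on top of a
dropout-free zero rate near 27%, matching the sparsity regimes the method
is evaluated in.
"""

from scdropgan import preset, simulate, zero_fraction

for name in ("sim42", "sim71", "sim91"):
    truth = simulate(preset(name, seed=1, n_cells=500, n_genes=300))
    print(f"{name}: complete zeros {zero_fraction(truth.complete):.1%}, "
          f"observed zeros {zero_fraction(truth.observed):.1%}, "
          f"dropout events {truth.true_dropout_mask.sum():,}")

# Each printed line pairs a dropout-free matrix with its corrupted version;
# the dropout-event count is exactly the number of positives the dropout
# identifier should recover.
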