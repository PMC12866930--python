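"""Two-stage training and selective imputation.

Stage one pretrains the variational generator on its ELBO.  Stage two
jointly trains generator and multi-task discriminator with alternating
updates: per mini-batch the discriminator minimizes

    L_D = lambda_adv * L_Dis + lambda_cell * L_cell + lambda_type * L_type

against detached generated samples, then the generator minimizes

    L_G_total = -ELBO + lambda_adv * L_G + lambda_cell * L_cell
                + lambda_type * L_type

with gradients flowing through the (frozen) discriminator into the
generator.  Setting a lambda to zero (or dropping a head) reproduces the
ablation variants; with all three at zero the stage reduces to continued
ELBO training.

Imputation is deterministic: the decoder is evaluated at the posterior
mean and its output replaces the expression value only at positions the
dropout mask flags — every other entry is returned bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .discriminator import (ContrastiveConfig, DiscriminatorState,
                            adversarial_losses, cell_contrastive_loss,
                            type_contrastive_loss)
from .dropout import DropoutMask, identify_dropouts, precluster
from .generator import (GeneratorConfig, GeneratorState, decode, elbo,
                        encode, pretrain_generator, reparameterize)
from .io import (CellLabels, ExpressionMatrix, RunConfig, derive_seed,
                 preprocess, write_manifest, write_matrix, zero_level)
from .nn import Adam
from .tensor import Tensor, concat

logger = logging.getLogger("scdropgan")

__all__ = ["TrainingSchedule", "ImputedMatrix", "joint_train", "impute",
           "run_pipeline"]


@dataclass
class TrainingSchedule:
    pretrain_epochs: int = 20
    warmup_epochs: int = 10
    joint_epochs: int = 10
    batch_size: int = 128
    lr_generator: float = 1e-3
    lr_discriminator: float = 1e-3
    seed: int = 0
    lambda_adv: float = 1.0
    lambda_cell: float = 1.0
    lambda_type: float = 1.0

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if min(self.pretrain_epochs, self.joint_epochs) < 0:
            raise ValueError("epoch counts must be nonnegative")
        for name in ("lambda_adv", "lambda_cell", "lambda_type"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ImputedMatrix:
    values: ExpressionMatrix
    mask: DropoutMask


@dataclass
class JointTrace:
    generator: list = field(default_factory=list)
    discriminator: list = field(default_factory=list)
    elbo: list = field(default_factory=list)


def _check_finite(value: float, term: str, epoch: int, batch: int) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(
            f"{term} became non-finite at epoch {epoch}, batch {batch}")


def joint_train(x: ExpressionMatrix, labels: CellLabels,
                gstate: GeneratorState, dstate: DiscriminatorState | None,
                schedule: TrainingSchedule,
                contrastive: ContrastiveConfig | None = None) -> JointTrace:
    """Alternating adversarial/contrastive training; mutates both states.

    ``dstate`` may be None when all lambda weights are zero (the
    no-discriminator ablation), in which case the loop is plain continued
    ELBO training.
    """
    cc = contrastive or ContrastiveConfig()
    lam_adv, lam_cell, lam_type = (schedule.lambda_adv, schedule.lambda_cell,
                                   schedule.lambda_type)
    use_disc = (lam_adv > 0 or lam_cell > 0 or lam_type > 0)
    if use_disc and dstate is None:
        raise ValueError("discriminator state required when any lambda > 0")

    values = x.values
    codes = labels.codes()
    n = values.shape[0]
    rng = np.random.default_rng(derive_seed(schedule.seed, "shuffle"))
    g_opt = Adam(gstate.parameters(), lr=schedule.lr_generator)
    d_opt = Adam(dstate.parameters(), lr=schedule.lr_discriminator) \
        if use_disc else None
    trace = JointTrace()
    noise_counter = 0

    for epoch in range(schedule.joint_epochs):
        g_losses, d_losses, elbos = [], [], []
        order = rng.permutation(n)
        for bi, lo in enumerate(range(0, n, schedule.batch_size)):
            idx = order[lo:lo + schedule.batch_size]
            if len(idx) < 2:
                continue
            xb = values[idx]
            tb = codes[idx]
            types2n = np.concatenate([tb, tb])
            noise_seed = derive_seed(schedule.seed, f"noise{noise_counter}")
            noise_counter += 1

            # --- discriminator step (generated samples detached) ---
            if use_disc:
                mean, logvar = encode(xb, gstate)
                z = reparameterize(mean, logvar, noise_seed)
                fake = decode(z, gstate).data.copy()
                real_emb = dstate.embed(xb)
                fake_emb = dstate.embed(fake)
                d_loss = Tensor(0.0)
                if lam_adv > 0:
                    l_dis, _ = adversarial_losses(real_emb, fake_emb, dstate)
                    _check_finite(l_dis.item(), "L_Dis", epoch, bi)
                    d_loss = d_loss + lam_adv * l_dis
                if lam_cell > 0:
                    l_cell = cell_contrastive_loss(real_emb, fake_emb, dstate, cc)
                    _check_finite(l_cell.item(), "L_cell", epoch, bi)
                    d_loss = d_loss + lam_cell * l_cell
                if lam_type > 0:
                    l_type = type_contrastive_loss(
                        concat([real_emb, fake_emb], axis=0), types2n,
                        dstate, cc)
                    _check_finite(l_type.item(), "L_type", epoch, bi)
                    d_loss = d_loss + lam_type * l_type
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()
                d_losses.append(d_loss.item())

            # --- generator step (discriminator frozen) ---
            value, recon, kl = elbo(xb, gstate, noise_seed)
            g_loss = -value
            _check_finite(g_loss.item(), "-ELBO", epoch, bi)
            if use_disc:
                mean, logvar = encode(xb, gstate)
                z = reparameterize(mean, logvar, noise_seed)
                fake = decode(z, gstate)
                real_emb = dstate.embed(xb)
                fake_emb = dstate.embed(fake)
                if lam_adv > 0:
                    _, l_g = adversarial_losses(real_emb, fake_emb, dstate)
                    _check_finite(l_g.item(), "L_G", epoch, bi)
                    g_loss = g_loss + lam_adv * l_g
                if lam_cell > 0:
                    l_cell = cell_contrastive_loss(real_emb, fake_emb, dstate, cc)
                    _check_finite(l_cell.item(), "L_cell", epoch, bi)
                    g_loss = g_loss + lam_cell * l_cell
                if lam_type > 0:
                    l_type = type_contrastive_loss(
                        concat([real_emb, fake_emb], axis=0), types2n,
                        dstate, cc)
                    _check_finite(l_type.item(), "L_type", epoch, bi)
                    g_loss = g_loss + lam_type * l_type
            g_opt.zero_grad()
            if use_disc:
                for p in dstate.parameters():
                    p.grad = None
            g_loss.backward()
            g_opt.step()
            g_losses.append(g_loss.item())
            elbos.append(value.item())

        trace.generator.append(float(np.mean(g_losses)))
        trace.elbo.append(float(np.mean(elbos)))
        if d_losses:
            trace.discriminator.append(float(np.mean(d_losses)))
    return trace


def impute(x: ExpressionMatrix, mask: DropoutMask,
           gstate: GeneratorState) -> ImputedMatrix:
    """Replace mask-flagged entries with the noise-free reconstruction.

    The latent code is the posterior mean (no sampling), so imputation is
    deterministic given a trained state.  Unflagged entries are returned
    bit-identical; imputed entries are floored at the preprocessed zero
    level.
    """
    if mask.mask.shape != x.values.shape:
        raise ValueError("mask shape does not match matrix")
    mean, _ = encode(x.values, gstate)
    x_hat = decode(mean, gstate).data
    z0 = zero_level()
    filled = np.where(mask.mask, np.maximum(x_hat, z0), x.values)
    out = ExpressionMatrix(filled, list(x.cell_ids), list(x.gene_ids))
    return ImputedMatrix(out, mask)


def run_pipeline(raw: ExpressionMatrix, cfg: RunConfig,
                 labels: CellLabels | None = None,
                 out_dir=None):
    """preprocess -> labels/precluster -> identify -> pretrain -> joint -> impute.

    Returns ``(ImputedMatrix, dict)`` where the dict is the run manifest
    (also written to ``out_dir`` with the output matrices when given).
    """
    x = preprocess(raw, cfg)
    if labels is None:
        labels = precluster(x, cfg.k_max, derive_seed(cfg.seed, "kmeans"))
    elif len(labels) != x.n_cells:
        raise ValueError("labels must cover all cells")

    d, mask, fits = identify_dropouts(
        x, labels, rho=cfg.rho, seed=cfg.seed, max_iter=cfg.em_max_iter,
        tol=cfg.em_tol, n_restarts=cfg.em_restarts)

    n_comp = cfg.n_components or labels.k
    gcfg = GeneratorConfig(input_dim=x.n_genes,
                           hidden_dims=tuple(cfg.hidden_dims),
                           latent_dim=min(cfg.latent_dim, x.n_genes - 1),
                           n_components=max(n_comp, 1), prior=cfg.prior)
    gstate, pre_trace = pretrain_generator(
        x.values, gcfg, warmup_epochs=cfg.warmup_epochs,
        elbo_epochs=cfg.pretrain_epochs, batch_size=cfg.batch_size,
        lr=cfg.lr_generator, seed=derive_seed(cfg.seed, "network"))

    schedule = TrainingSchedule(
        pretrain_epochs=cfg.pretrain_epochs, warmup_epochs=cfg.warmup_epochs,
        joint_epochs=cfg.joint_epochs, batch_size=cfg.batch_size,
        lr_generator=cfg.lr_generator, lr_discriminator=cfg.lr_discriminator,
        seed=cfg.seed,
        lambda_adv=cfg.lambda_adv if cfg.use_adv else 0.0,
        lambda_cell=cfg.lambda_cell if cfg.use_cell else 0.0,
        lambda_type=cfg.lambda_type if cfg.use_type else 0.0)
    use_disc = (schedule.lambda_adv > 0 or schedule.lambda_cell > 0
                or schedule.lambda_type > 0)
    dstate = DiscriminatorState(
        x.n_genes, np.random.default_rng(derive_seed(cfg.seed, "network") + 1),
        embed_dims=tuple(cfg.embed_dims), head_hidden=cfg.head_hidden,
        proj_dim=cfg.proj_dim) if use_disc else None
    cc = ContrastiveConfig(tau_cell=cfg.tau_cell, tau_type=cfg.tau_type)
    joint_trace = joint_train(x, labels, gstate, dstate, schedule, cc)

    result = impute(x, mask, gstate)
    manifest = {
        "label_source": labels.source,
        "n_subpopulations": int(labels.k),
        "n_dropouts_flagged": int(mask.mask.sum()),
        "stages": {
            "pretrain_elbo_trace": pre_trace.elbo,
            "joint_generator_trace": joint_trace.generator,
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_matrix(result.values, out_dir / "imputed.csv", format="csv")
        mask_em = ExpressionMatrix(mask.mask.astype(float), list(x.cell_ids),
                                   list(x.gene_ids))
        write_matrix(mask_em, out_dir / "mask.mtx", format="mtx")
        fits.to_csv(out_dir / "fits.tsv", sep="\t", index=False)
        write_manifest(out_dir / "manifest.json", cfg, extra=manifest)
    return result, manifest
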