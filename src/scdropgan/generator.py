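"""Variational generator with a Gaussian-mixture latent prior.

The generator is a VAE whose latent prior p(z, k) is a mixture of K
diagonal Gaussians with trainable weights pi, means mu_c and variances
sigma_c^2 (the VaDE construction).  The encoder outputs the posterior mean
and log-variance of q(z|x); component responsibilities q(k|x) are the GMM
posterior of the sampled latent code.  Setting ``prior='standard_normal'``
collapses the model to a plain VAE (single fixed N(0, I) component), the
ablation variant.

The decoder likelihood is Gaussian with fixed unit variance on the
preprocessed log-expression scale, so the reconstruction term of the ELBO
is -0.5 * ||x - x_hat||^2 (additive constants dropped).  The final decoder
activation is a softplus, keeping reconstructions nonnegative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .nn import MLP, Adam
from .tensor import Tensor

logger = logging.getLogger("scdropgan")

__all__ = ["GeneratorConfig", "GeneratorState", "encode", "reparameterize",
           "decode", "elbo", "pretrain_generator"]

_LOG2PI = float(np.log(2 * np.pi))


@dataclass
class GeneratorConfig:
    input_dim: int
    hidden_dims: tuple = (512, 256)
    latent_dim: int = 32
    n_components: int = 1
    prior: str = "gmm"                    # "gmm" | "standard_normal"
    decoder_likelihood: str = "gaussian_fixed_var"

    def __post_init__(self):
        if self.latent_dim >= self.input_dim:
            raise ValueError("latent_dim must be smaller than input_dim")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.prior not in ("gmm", "standard_normal"):
            raise ValueError(f"unknown prior {self.prior!r}")
        if self.prior == "standard_normal":
            # the plain-VAE ablation has a single fixed component
            self.n_components = 1


class GeneratorState:
    """Encoder/decoder networks plus the (trainable) mixture prior."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        dims = [cfg.input_dim, *cfg.hidden_dims]
        self.enc_trunk = MLP(dims, rng, activation="relu",
                             out_activation="relu")
        self.enc_mean = MLP([cfg.hidden_dims[-1], cfg.latent_dim], rng)
        # zero-init so the posterior starts at unit variance
        self.enc_logvar = MLP([cfg.hidden_dims[-1], cfg.latent_dim], rng,
                              zero_init_last=True)
        self.decoder = MLP([cfg.latent_dim, *reversed(cfg.hidden_dims),
                            cfg.input_dim], rng, activation="relu",
                           out_activation="softplus")
        K, D = cfg.n_components, cfg.latent_dim
        self.pi_logits = Tensor(np.zeros(K), requires_grad=cfg.prior == "gmm")
        self.prior_means = Tensor(np.zeros((K, D)),
                                  requires_grad=cfg.prior == "gmm")
        self.prior_logvars = Tensor(np.zeros((K, D)),
                                    requires_grad=cfg.prior == "gmm")

    def parameters(self) -> list[Tensor]:
        ps = (self.enc_trunk.parameters() + self.enc_mean.parameters()
              + self.enc_logvar.parameters() + self.decoder.parameters())
        if self.cfg.prior == "gmm":
            ps += [self.pi_logits, self.prior_means, self.prior_logvars]
        return ps

    def log_pi(self) -> np.ndarray:
        logits = self.pi_logits.data
        return logits - np.log(np.sum(np.exp(logits - logits.max()))) \
            - logits.max()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in (self.enc_trunk.parameters()
                                 + self.enc_mean.parameters()
                                 + self.enc_logvar.parameters()
                                 + self.decoder.parameters())] + \
               [self.pi_logits.data, self.prior_means.data,
                self.prior_logvars.data]


def save_generator(state: GeneratorState, path) -> None:
    arrays = {f"arr{i}": a for i, a in enumerate(state.state_arrays())}
    np.savez(path, n_arrays=len(arrays), input_dim=state.cfg.input_dim,
             hidden_dims=np.asarray(state.cfg.hidden_dims),
             latent_dim=state.cfg.latent_dim,
             n_components=state.cfg.n_components,
             prior=state.cfg.prior, **arrays)


def load_generator(path) -> GeneratorState:
    with np.load(path, allow_pickle=False) as z:
        cfg = GeneratorConfig(input_dim=int(z["input_dim"]),
                              hidden_dims=tuple(int(h) for h in z["hidden_dims"]),
                              latent_dim=int(z["latent_dim"]),
                              n_components=int(z["n_components"]),
                              prior=str(z["prior"]))
        state = GeneratorState(cfg, np.random.default_rng(0))
        arrays = [z[f"arr{i}"] for i in range(int(z["n_arrays"]))]
    targets = (state.enc_trunk.parameters() + state.enc_mean.parameters()
               + state.enc_logvar.parameters() + state.decoder.parameters()
               + [state.pi_logits, state.prior_means, state.prior_logvars])
    for p, a in zip(targets, arrays):
        p.data = a.astype(np.float64)
    return state


# ---------------------------------------------------------------------------
# forward pieces

def encode(x, state: GeneratorState):
    """Map a batch of cells to posterior (mean, logvar); deterministic."""
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float64))
    if x.shape[-1] != state.cfg.input_dim:
        raise ValueError(f"expected {state.cfg.input_dim} genes, "
                         f"got {x.shape[-1]}")
    h = state.enc_trunk(x)
    return state.enc_mean(h), state.enc_logvar(h)


def reparameterize(mean: Tensor, logvar: Tensor, noise_seed: int) -> Tensor:
    """z = mean + exp(logvar / 2) * eps with seeded standard-normal eps."""
    rng = np.random.default_rng(int(noise_seed))
    eps = Tensor(rng.standard_normal(mean.shape))
    return mean + (logvar * 0.5).exp() * eps


def decode(z, state: GeneratorState) -> Tensor:
    if not isinstance(z, Tensor):
        z = Tensor(np.asarray(z, dtype=np.float64))
    if z.shape[-1] != state.cfg.latent_dim:
        raise ValueError(f"expected latent width {state.cfg.latent_dim}, "
                         f"got {z.shape[-1]}")
    return state.decoder(z)


def _gmm_log_responsibilities(z_data: np.ndarray,
                              state: GeneratorState) -> np.ndarray:
    """log q(k|x) as the prior posterior of the sampled z (constants)."""
    mu = state.prior_means.data          # K x D
    lv = state.prior_logvars.data
    log_pi = state.log_pi()
    # B x K log-density of z under each component
    diff = z_data[:, None, :] - mu[None, :, :]
    log_comp = -0.5 * np.sum(_LOG2PI + lv[None] + diff ** 2 / np.exp(lv)[None],
                             axis=2)
    logits = log_pi[None, :] + log_comp
    logits -= logits.max(axis=1, keepdims=True)
    return logits - np.log(np.exp(logits).sum(axis=1, keepdims=True))


def elbo(x, state: GeneratorState, noise_seed: int):
    """Single-sample ELBO of a batch, averaged over cells.

    Returns ``(elbo, reconstruction_term, kl_term)`` as scalars on the
    computation graph; ``elbo = recon - kl`` with additive constants of the
    Gaussian likelihood dropped.
    """
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float64))
    mean, logvar = encode(x, state)
    z = reparameterize(mean, logvar, noise_seed)
    x_hat = decode(z, state)
    if not np.all(np.isfinite(x_hat.data)):
        bad = int(np.flatnonzero(~np.isfinite(x_hat.data).all(axis=1))[0])
        raise FloatingPointError(f"non-finite reconstruction at batch index {bad}")
    recon = ((x - x_hat) ** 2).sum(axis=1).mean() * (-0.5)

    if state.cfg.prior == "standard_normal":
        kl = ((mean ** 2 + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1).mean()
    else:
        gamma = np.exp(_gmm_log_responsibilities(z.data, state))   # B x K, const
        g = Tensor(gamma)
        lv_c = state.prior_logvars                                  # K x D
        mu_c = state.prior_means
        # E_q[-log p(z|c)] per (cell, component):
        #   0.5 * sum_d [log 2 pi + lv_c + (s^2 + (m - mu_c)^2) / exp(lv_c)]
        s2 = logvar.exp()                                           # B x D
        m = mean
        B = m.shape[0]
        quad = (s2.reshape(B, 1, -1) + (m.reshape(B, 1, -1) - mu_c.reshape(
            1, *mu_c.shape)) ** 2) / lv_c.exp().reshape(1, *lv_c.shape)
        e_neglogp = ((quad + lv_c.reshape(1, *lv_c.shape) + _LOG2PI) * 0.5
                     ).sum(axis=2)                                  # B x K
        log_pi_t = state.pi_logits - Tensor(
            np.log(np.sum(np.exp(state.pi_logits.data
                                 - state.pi_logits.data.max())))
            + state.pi_logits.data.max())
        # KL = sum_c gamma_c * [E_q(-log p(z|c)) - log pi_c] + sum gamma log gamma
        #      - entropy of q(z|x)
        cross = (g * (e_neglogp - log_pi_t.reshape(1, -1))).sum(axis=1)
        ent_cat = Tensor((gamma * np.log(np.maximum(gamma, 1e-300))).sum(axis=1))
        ent_q = ((logvar + 1.0 + _LOG2PI) * 0.5).sum(axis=1)
        kl = (cross + ent_cat - ent_q).mean()

    value = recon - kl
    if not np.isfinite(value.data):
        raise FloatingPointError("non-finite ELBO")
    return value, recon, kl


# ---------------------------------------------------------------------------
# pretraining

@dataclass
class PretrainTrace:
    warmup_loss: list = field(default_factory=list)
    elbo: list = field(default_factory=list)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        idx = order[lo:lo + batch_size]
        if len(idx) >= 2:
            yield idx


def pretrain_generator(x_values: np.ndarray, cfg: GeneratorConfig,
                       warmup_epochs: int = 10, elbo_epochs: int = 20,
                       batch_size: int = 128, lr: float = 1e-3,
                       seed: int = 0) -> tuple[GeneratorState, PretrainTrace]:
    """Three-phase pretraining of the generator.

    (a) deterministic autoencoder warm-up on the reconstruction error;
    (b) for the mixture prior, a GMM fit on the warm latent means to
        initialize (pi, mu_c, sigma_c^2) — skipped for the plain-VAE prior;
    (c) gradient ascent on the ELBO for ``elbo_epochs`` epochs.

    Returns the trained state and the per-epoch loss trace.
    """
    x = np.asarray(x_values, dtype=np.float64)
    rng = np.random.default_rng(int(seed))
    state = GeneratorState(cfg, rng)
    opt = Adam(state.parameters(), lr=lr)
    trace = PretrainTrace()
    n = x.shape[0]

    for epoch in range(warmup_epochs):
        losses = []
        for idx in _batches(n, batch_size, rng):
            xb = Tensor(x[idx])
            mean, _ = encode(xb, state)
            x_hat = decode(mean, state)
            loss = ((xb - x_hat) ** 2).sum(axis=1).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.warmup_loss.append(float(np.mean(losses)))

    if cfg.prior == "gmm":
        mean, _ = encode(Tensor(x), state)
        gm = GaussianMixture(n_components=cfg.n_components,
                             covariance_type="diag", reg_covar=1e-4,
                             random_state=int(seed)).fit(mean.data)
        state.pi_logits.data = np.log(np.maximum(gm.weights_, 1e-10))
        state.prior_means.data = gm.means_.copy()
        state.prior_logvars.data = np.log(np.maximum(gm.covariances_, 1e-6))

    noise_counter = 0
    for epoch in range(elbo_epochs):
        vals = []
        for idx in _batches(n, batch_size, rng):
            value, _, _ = elbo(x[idx], state,
                               noise_seed=seed * 1000003 + noise_counter)
            noise_counter += 1
            loss = -value
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"pretraining diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            vals.append(value.item())
        trace.elbo.append(float(np.mean(vals)))
    return state, trace
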