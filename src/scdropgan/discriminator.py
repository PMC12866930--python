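"""Multi-task discriminator: shared embedder plus three heads.

The embedder f_e maps expression profiles to a shared representation,
which feeds

* an adversarial head (sigmoid probability that a sample is real),
* a cell-level projection head scored with the normalized
  temperature-scaled cross-entropy (NT-Xent) loss, where the positive
  pair is an observed cell and its generated counterpart, and
* a cell-type-level projection head scored with the supervised
  contrastive loss, where all same-type samples are positives.

Projections are L2-normalized inside the losses, so the dot products are
cosine similarities; denominators are computed with max-subtracted
log-sum-exp and excluded entries masked with a large negative constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import MLP
from .tensor import Tensor, concat, logsumexp

__all__ = ["ContrastiveConfig", "DiscriminatorState", "cosine_sim",
           "adversarial_losses", "cell_contrastive_loss",
           "type_contrastive_loss"]

_P_EPS = 1e-7       # probability clamp before logs in the adversarial loss
_NEG = -1e9         # mask value excluding an entry from a log-sum-exp


@dataclass
class ContrastiveConfig:
    tau_cell: float = 0.5
    tau_type: float = 0.1

    def __post_init__(self):
        if self.tau_cell <= 0 or self.tau_type <= 0:
            raise ValueError("temperatures must be > 0")


class DiscriminatorState:
    def __init__(self, input_dim: int, rng: np.random.Generator,
                 embed_dims: tuple = (256, 128), head_hidden: int = 64,
                 proj_dim: int = 64):
        self.embedder = MLP([input_dim, *embed_dims], rng, activation="relu",
                            out_activation="relu")
        e = embed_dims[-1]
        self.h_adv = MLP([e, head_hidden, 1], rng, activation="relu")
        self.h_cell = MLP([e, head_hidden, proj_dim], rng, activation="relu")
        self.h_type = MLP([e, head_hidden, proj_dim], rng, activation="relu")

    def embed(self, x) -> Tensor:
        return self.embedder(x)

    def adv_prob(self, emb: Tensor) -> Tensor:
        return self.h_adv(emb).sigmoid()

    def parameters(self) -> list[Tensor]:
        return (self.embedder.parameters() + self.h_adv.parameters()
                + self.h_cell.parameters() + self.h_type.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


def cosine_sim(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two vectors; errors on a zero vector."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def _normalize_rows(t: Tensor) -> Tensor:
    norm = ((t ** 2).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    return t / norm


def adversarial_losses(real_emb, fake_emb, state: DiscriminatorState):
    """Non-saturating-free original GAN losses on embedded batches.

    L_Dis = -E[log H(real)] - E[log(1 - H(fake))];
    L_G   =  E[log(1 - H(fake))].
    Probabilities are clamped to [1e-7, 1 - 1e-7] before the logarithms.
    """
    p_real = state.adv_prob(real_emb).clip(_P_EPS, 1.0 - _P_EPS)
    p_fake = state.adv_prob(fake_emb).clip(_P_EPS, 1.0 - _P_EPS)
    log_one_minus_fake = (1.0 - p_fake).log().mean()
    l_dis = -(p_real.log().mean()) - log_one_minus_fake
    l_g = log_one_minus_fake
    return l_dis, l_g


def cell_contrastive_loss(obs_emb, gen_emb, state: DiscriminatorState,
                          cfg: ContrastiveConfig) -> Tensor:
    """NT-Xent loss over 2N projections; positives are (x_i, x_hat_i).

    Row i of ``gen_emb`` must be the generated counterpart of row i of
    ``obs_emb``.  For each anchor the denominator ranges over the other
    2N - 1 projections; the loss averages the 2N anchor terms.
    """
    t_obs = state.h_cell(obs_emb)
    t_gen = state.h_cell(gen_emb)
    n = t_obs.shape[0]
    if t_gen.shape[0] != n:
        raise ValueError("observed and generated batches must match")
    if n < 2:
        raise ValueError("need at least 2 cells (no negatives otherwise)")
    u = _normalize_rows(concat([t_obs, t_gen], axis=0))    # 2N x P
    sims = (u @ u.T) / cfg.tau_cell                        # 2N x 2N
    m = 2 * n
    diag_mask = np.where(np.eye(m, dtype=bool), _NEG, 0.0)
    denom = logsumexp(sims + Tensor(diag_mask), axis=1)    # 2N
    pos_idx = np.concatenate([np.arange(n) + n, np.arange(n)])
    pos_onehot = np.zeros((m, m))
    pos_onehot[np.arange(m), pos_idx] = 1.0
    pos = (sims * Tensor(pos_onehot)).sum(axis=1)
    return (denom - pos).mean()


def type_contrastive_loss(all_emb, types, state: DiscriminatorState,
                          cfg: ContrastiveConfig) -> Tensor:
    """Supervised contrastive loss over the 2N projections.

    ``types`` gives one label per row (generated cells inherit the label
    of their observed counterpart).  Anchors whose label appears only once
    have no positives and are skipped with a warning.  The anchor terms
    are summed, following the multi-positive supervised formulation.
    """
    v = state.h_type(all_emb)
    types = np.asarray(types)
    m = v.shape[0]
    if len(types) != m:
        raise ValueError("one type label per embedding row required")
    v = _normalize_rows(v)
    sims = (v @ v.T) / cfg.tau_type
    same = types[:, None] == types[None, :]
    np.fill_diagonal(same, False)
    n_pos = same.sum(axis=1)
    anchors = n_pos > 0
    if not anchors.all():
        warnings.warn(f"{int((~anchors).sum())} anchor(s) without positives "
                      "skipped in the type-level contrastive loss")
    if not anchors.any():
        return Tensor(0.0)
    diag_mask = np.where(np.eye(m, dtype=bool), _NEG, 0.0)
    denom = logsumexp(sims + Tensor(diag_mask), axis=1)    # over A(i)
    pos_weight = np.where(same, 1.0, 0.0)
    pos_weight[anchors] /= n_pos[anchors, None]
    pos_mean = (sims * Tensor(pos_weight)).sum(axis=1)     # mean over P(i)
    per_anchor = denom - pos_mean
    keep = np.where(anchors, 1.0, 0.0)
    return (per_anchor * Tensor(keep)).sum()
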