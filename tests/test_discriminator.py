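"""Adversarial and contrastive losses against closed forms and brute force."""

import math

import numpy as np
import pytest

from scdropgan.discriminator import (ContrastiveConfig, DiscriminatorState,
                                     adversarial_losses,
                                     cell_contrastive_loss, cosine_sim,
                                     type_contrastive_loss)
from scdropgan.nn import Adam
from scdropgan.tensor import Tensor, concat


@pytest.fixture
def dstate():
    return DiscriminatorState(12, np.random.default_rng(4), embed_dims=(16,),
                              head_hidden=8, proj_dim=6)


@pytest.fixture
def cc():
    return ContrastiveConfig(tau_cell=0.5, tau_type=0.1)


def test_cosine_sim_basic_identities(rng):
    v = rng.normal(size=5)
    assert cosine_sim(v, v) == pytest.approx(1.0)
    assert cosine_sim(v, -v) == pytest.approx(-1.0)
    assert cosine_sim([1, 0], [0, 1]) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        cosine_sim([0, 0], [1, 2])


def constant_adv_state(dstate):
    for p in dstate.h_adv.layers[-1].parameters():
        p.data[:] = 0.0           # sigmoid(0) = 0.5 for every input
    return dstate


def test_adversarial_fixed_point_half(dstate, rng):
    constant_adv_state(dstate)
    real = dstate.embed(rng.gamma(2, 1, size=(16, 12)))
    fake = dstate.embed(rng.gamma(2, 1, size=(16, 12)))
    l_dis, l_g = adversarial_losses(real, fake, dstate)
    assert l_dis.item() == pytest.approx(2 * math.log(2), abs=1e-12)
    assert l_g.item() == pytest.approx(-math.log(2), abs=1e-12)


def test_adversarial_perfect_discriminator_near_zero(dstate, rng):
    # head output saturated at a clamp bound keeps the logs finite
    real = dstate.embed(rng.gamma(2, 1, size=(4, 12)))
    fake = dstate.embed(rng.gamma(2, 1, size=(4, 12)))
    dstate.h_adv.layers[-1].W.data[:] = 0.0
    dstate.h_adv.layers[-1].b.data[:] = 100.0
    l_dis, _ = adversarial_losses(real, fake, dstate)
    assert np.isfinite(l_dis.item())
    # a head separating real (p at the upper clamp) from fake (lower clamp)
    # drives its loss to ~0
    p_real = Tensor(np.full((4, 1), 1 - 1e-7))
    p_fake = Tensor(np.full((4, 1), 1e-7))
    l = -(p_real.log().mean()) - (1.0 - p_fake).log().mean()
    assert l.item() == pytest.approx(0.0, abs=1e-6)


def test_adversarial_asymmetric_in_real_fake(dstate, rng):
    real = dstate.embed(rng.gamma(2, 1, size=(8, 12)))
    fake = dstate.embed(rng.normal(size=(8, 12)) ** 2)
    l1, _ = adversarial_losses(real, fake, dstate)
    l2, _ = adversarial_losses(fake, real, dstate)
    assert l1.item() != pytest.approx(l2.item(), abs=1e-9)


# --------------------------------------------------------------------------
# closed forms for the contrastive losses

def identical_projection_inputs(dstate, n, rng):
    row = rng.normal(size=(1, 12))
    return dstate.embed(np.tile(row, (n, 1)))


def test_cell_loss_identical_projections_closed_form(dstate, cc, rng):
    for n in (2, 4, 128):
        emb = identical_projection_inputs(dstate, n, rng)
        loss = cell_contrastive_loss(emb, emb, dstate, cc)
        assert loss.item() == pytest.approx(math.log(2 * n - 1), abs=1e-9)


def test_type_loss_identical_projections_closed_form(dstate, cc, rng):
    for n2 in (4, 8):
        emb = identical_projection_inputs(dstate, n2, rng)
        loss = type_contrastive_loss(emb, np.zeros(n2, dtype=int), dstate, cc)
        assert loss.item() == pytest.approx(n2 * math.log(n2 - 1), abs=1e-9)


# --------------------------------------------------------------------------
# brute-force oracles (explicit double loops over pairs, N <= 4)

def project_and_normalize(head, emb):
    p = head(emb).data
    return p / np.linalg.norm(p, axis=1, keepdims=True)


def brute_cell_loss(t_all, tau):
    """Direct evaluation of the per-anchor NT-Xent terms."""
    m = len(t_all)
    n = m // 2
    total = 0.0
    for i in range(m):
        j = i + n if i < n else i - n
        denom = sum(math.exp(float(t_all[i] @ t_all[k]) / tau)
                    for k in range(m) if k != i)
        total += -math.log(math.exp(float(t_all[i] @ t_all[j]) / tau) / denom)
    return total / m


def brute_type_loss(v_all, types, tau):
    m = len(v_all)
    total = 0.0
    for i in range(m):
        pos = [p for p in range(m) if p != i and types[p] == types[i]]
        if not pos:
            continue
        denom = sum(math.exp(float(v_all[i] @ v_all[a]) / tau)
                    for a in range(m) if a != i)
        total += -sum(math.log(math.exp(float(v_all[i] @ v_all[p]) / tau)
                               / denom) for p in pos) / len(pos)
    return total


@pytest.mark.parametrize("n", [2, 3, 4])
def test_cell_loss_matches_brute_force(dstate, cc, rng, n):
    obs = dstate.embed(rng.gamma(2, 1, size=(n, 12)))
    gen = dstate.embed(rng.gamma(2, 1, size=(n, 12)))
    vec = cell_contrastive_loss(obs, gen, dstate, cc).item()
    t_all = project_and_normalize(dstate.h_cell, concat([obs, gen], axis=0))
    assert vec == pytest.approx(brute_cell_loss(t_all, cc.tau_cell), abs=1e-6)


@pytest.mark.parametrize("n", [2, 3, 4])
def test_type_loss_matches_brute_force(dstate, cc, rng, n):
    emb = dstate.embed(rng.gamma(2, 1, size=(2 * n, 12)))
    types = rng.integers(0, 2, size=2 * n)
    types[0] = types[1]  # guarantee at least one anchor has a positive
    vec = type_contrastive_loss(emb, types, dstate, cc).item()
    v_all = project_and_normalize(dstate.h_type, emb)
    assert vec == pytest.approx(brute_type_loss(v_all, types, cc.tau_type),
                                abs=1e-6)


def test_cell_loss_hand_derived_two_pair_case():
    """N=2 with positive similarity 1 and every other similarity -1.

    Each anchor's denominator excludes itself, leaving the positive
    (exp(1/tau)) and two negatives (exp(-1/tau)); with tau=0.5 the
    per-anchor term is log(1 + 2 exp(-4)) ~ 0.03597.  A geometry realizing
    those similarities exactly needs only two antipodal unit projections
    with each anchor paired to its own copy, which the brute-force oracle
    evaluates directly.
    """
    tau = 0.5
    per_anchor = -math.log(math.exp(1 / tau)
                           / (math.exp(1 / tau) + 2 * math.exp(-1 / tau)))
    assert per_anchor == pytest.approx(math.log(1 + 2 * math.exp(-4.0)),
                                       abs=1e-12)
    assert per_anchor == pytest.approx(0.035976, abs=1e-6)
    # brute-force oracle on the realizing geometry: t = [a, -a, a, -a]
    # (obs_1, obs_2, gen_1, gen_2) gives sim(t_i, that_i) = 1 and -1 for
    # every other pair, so every anchor contributes the same term
    a = np.array([1.0, 0.0])
    t_all = np.array([a, -a, a, -a])
    assert brute_cell_loss(t_all, tau) == pytest.approx(per_anchor, abs=1e-12)


def test_type_loss_separated_lower_than_identical(dstate, cc, rng):
    # two well-separated type clusters in projection space vs all-identical
    m = 8
    types = np.array([0] * 4 + [1] * 4)
    base = rng.normal(size=(1, 12))
    ident = dstate.embed(np.tile(base, (m, 1)))
    l_ident = type_contrastive_loss(ident, types, dstate, cc).item()
    sep_inputs = np.vstack([np.tile(rng.normal(size=(1, 12)), (4, 1)),
                            np.tile(rng.normal(size=(1, 12)), (4, 1))])
    l_sep = type_contrastive_loss(dstate.embed(sep_inputs), types,
                                  dstate, cc).item()
    assert l_sep < l_ident


def test_losses_invariant_under_common_permutation(dstate, cc, rng):
    n = 6
    obs = rng.gamma(2, 1, size=(n, 12))
    gen = rng.gamma(2, 1, size=(n, 12))
    types = rng.integers(0, 2, size=2 * n)
    types[:2] = types[0]
    perm = rng.permutation(n)
    l1 = cell_contrastive_loss(dstate.embed(obs), dstate.embed(gen),
                               dstate, cc).item()
    l2 = cell_contrastive_loss(dstate.embed(obs[perm]),
                               dstate.embed(gen[perm]), dstate, cc).item()
    assert l1 == pytest.approx(l2, abs=1e-9)
    perm2 = rng.permutation(2 * n)
    e = dstate.embed(np.vstack([obs, gen]))
    l3 = type_contrastive_loss(e, types, dstate, cc).item()
    e_p = dstate.embed(np.vstack([obs, gen])[perm2])
    l4 = type_contrastive_loss(e_p, types[perm2], dstate, cc).item()
    assert l3 == pytest.approx(l4, abs=1e-9)


def test_anchor_without_positive_skipped_with_warning(dstate, cc, rng):
    emb = dstate.embed(rng.gamma(2, 1, size=(4, 12)))
    types = np.array([0, 0, 1, 2])   # types 1 and 2 have no partner
    with pytest.warns(UserWarning, match="without positives"):
        loss = type_contrastive_loss(emb, types, dstate, cc)
    assert np.isfinite(loss.item())


def test_cell_loss_needs_two_cells(dstate, cc, rng):
    one = dstate.embed(rng.gamma(2, 1, size=(1, 12)))
    with pytest.raises(ValueError):
        cell_contrastive_loss(one, one, dstate, cc)


def test_gradient_step_pulls_positive_pairs_together(dstate, cc, rng):
    obs = rng.gamma(2, 1, size=(6, 12))
    gen = rng.gamma(2, 1, size=(6, 12))

    def mean_pos_sim():
        t_obs = project_and_normalize(dstate.h_cell, dstate.embed(obs))
        t_gen = project_and_normalize(dstate.h_cell, dstate.embed(gen))
        return float(np.mean(np.sum(t_obs * t_gen, axis=1)))

    before = mean_pos_sim()
    opt = Adam(dstate.parameters(), lr=1e-2)
    for _ in range(5):
        loss = cell_contrastive_loss(dstate.embed(obs), dstate.embed(gen),
                                     dstate, cc)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert mean_pos_sim() > before
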