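"""Dropout-event identification with per-subpopulation Gamma-Normal mixtures.

Each gene's preprocessed expression within a cell subpopulation is modeled
as a two-component mixture

    f(x) = lambda * Gamma(x; alpha, beta) + (1 - lambda) * Normal(x; mu, sigma)

where the Gamma component (support concentrated at the zero level) stands
for dropout events and the Normal component for genuine expression.
Parameters are estimated by EM with a moment-matching update for the Gamma
shape/rate; a zero entry is called a dropout when its posterior probability
of belonging to the Gamma component exceeds the threshold rho.

Subpopulations come from provided cell-type labels, or from K-means
pre-clustering (model order chosen by silhouette, ties broken by the elbow
criterion) when labels are absent.

The EM is vectorized across genes: all genes of a subpopulation are fit
simultaneously with per-gene parameter vectors, which keeps whole-matrix
fits fast without changing per-gene results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .io import (CellLabels, ExpressionMatrix, ZERO_TOL, derive_seed,
                 zero_level)

logger = logging.getLogger("scdropgan")

__all__ = ["MixtureFit", "DropoutProbabilities", "DropoutMask", "precluster",
           "fit_gamma_normal_em", "dropout_probability", "identify_dropouts"]

# numerical guards used throughout the EM
_LAMBDA_MIN, _LAMBDA_MAX = 1e-4, 1.0 - 1e-4
_SIGMA_MIN = 1e-3
_GAMMA_VAR_MIN = 1e-6
# The Gamma component models dropout mass near the zero level; capping its
# shape keeps it from imitating a tight high-mean Normal (identifiability).
_GAMMA_SHAPE_MAX = 20.0
_MIN_CELLS = 10       # minimum cells per (gene, subpopulation) fit
_MIN_EXPRESSED = 3    # minimum above-zero-level values to identify the Normal


@dataclass
class MixtureFit:
    lambda_: float
    alpha: float
    beta: float
    mu: float
    sigma: float
    loglik: float
    n_iter: int
    converged: bool
    trace: list | None = None   # per-iteration log-likelihood (nondecreasing)


@dataclass
class DropoutProbabilities:
    d: np.ndarray   # cells x genes, in [0,1]; zero off the zero level


@dataclass
class DropoutMask:
    mask: np.ndarray   # boolean cells x genes


# ---------------------------------------------------------------------------
# pre-clustering

def precluster(x: ExpressionMatrix, k_max: int, seed: int) -> CellLabels:
    """K-means labels on top principal components; k chosen by silhouette.

    Candidate k ranges over 2..k_max; the k with the highest mean
    silhouette wins, ties (within 1e-6) broken by the elbow criterion
    (largest second difference of the within-cluster SSE curve).
    Degenerate inputs (all cells identical) return a single cluster with a
    warning rather than failing.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if x.n_cells <= k_max:
        raise ValueError("need more cells than k_max")
    values = x.values
    if np.allclose(values, values[0]):
        warnings.warn("all cells identical; returning a single cluster")
        return CellLabels(np.zeros(x.n_cells, dtype=int), source="preclustered")

    n_pc = min(50, x.n_cells - 1, x.n_genes)
    pcs = PCA(n_components=n_pc, random_state=int(seed)).fit_transform(values)

    sils, inertias, labelings = [], [], []
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit(pcs)
        labelings.append(km.labels_)
        inertias.append(km.inertia_)
        sils.append(silhouette_score(pcs, km.labels_)
                    if len(np.unique(km.labels_)) > 1 else -1.0)
    sils = np.asarray(sils)
    best = np.flatnonzero(sils >= sils.max() - 1e-6)
    if len(best) > 1 and len(inertias) >= 3:
        # elbow: maximal second difference of SSE, defined for interior k
        sse = np.asarray(inertias)
        d2 = np.full(len(sse), -np.inf)
        d2[1:-1] = sse[:-2] - 2 * sse[1:-1] + sse[2:]
        best = best[np.argmax(d2[best])]
    else:
        best = best[0]
    return CellLabels(labelings[best], source="preclustered")


# ---------------------------------------------------------------------------
# vectorized Gamma-Normal EM

def _log_gamma_pdf(x, alpha, beta):
    return alpha * np.log(beta) - gammaln(alpha) + (alpha - 1) * np.log(x) - beta * x


def _log_normal_pdf(x, mu, sigma):
    return -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def _gamma_from_moments(m, v):
    """Moment-matched Gamma (shape, rate) with a variance floor and a shape
    cap; the rate is rescaled after capping so the component mean is kept."""
    v = np.maximum(v, _GAMMA_VAR_MIN)
    alpha = np.clip(m ** 2 / v, 1e-3, _GAMMA_SHAPE_MAX)
    beta = np.clip(alpha / np.maximum(m, 1e-12), 1e-3, 1e6)
    return alpha, beta


def _weighted_moments(x, w):
    wsum = w.sum(axis=0)
    wsum = np.maximum(wsum, 1e-12)
    m = (w * x).sum(axis=0) / wsum
    v = (w * (x - m) ** 2).sum(axis=0) / wsum
    return m, v


def _em_many(values: np.ndarray, resp0: np.ndarray, max_iter: int, tol: float,
             record_trace: bool = False):
    """Run the EM on a cells x genes block from initial responsibilities.

    Returns per-gene parameter vectors, final log-likelihoods, iteration
    counts and convergence flags.  The moment-matching Gamma update is not
    a true M-step, so each update is accepted only if the observed-data
    log-likelihood does not decrease; otherwise the previous parameters are
    kept and the fit stops (keeping the likelihood trace nondecreasing).
    """
    x = values
    n, G = x.shape
    r = np.clip(resp0, 0.0, 1.0)

    lam = np.clip(r.mean(axis=0), _LAMBDA_MIN, _LAMBDA_MAX)
    mg, vg = _weighted_moments(x, r)
    alpha, beta = _gamma_from_moments(mg, vg)
    mu, vn = _weighted_moments(x, 1.0 - r)
    sigma = np.maximum(np.sqrt(vn), _SIGMA_MIN)

    def loglik(lam, alpha, beta, mu, sigma):
        lg = np.log(lam) + _log_gamma_pdf(x, alpha, beta)
        ln = np.log1p(-lam) + _log_normal_pdf(x, mu, sigma)
        return np.logaddexp(lg, ln).sum(axis=0), lg, ln

    ll, lg, ln = loglik(lam, alpha, beta, mu, sigma)
    n_iter = np.zeros(G, dtype=int)
    converged = np.zeros(G, dtype=bool)
    active = np.ones(G, dtype=bool)
    trace = [ll.copy()] if record_trace else None

    for it in range(max_iter):
        if not active.any():
            break
        # E-step (responsibility of the Gamma component)
        r = 1.0 / (1.0 + np.exp(np.clip(ln - lg, -700, 700)))
        # M-step
        lam_n = np.clip(r.mean(axis=0), _LAMBDA_MIN, _LAMBDA_MAX)
        mg, vg = _weighted_moments(x, r)
        alpha_n, beta_n = _gamma_from_moments(mg, vg)
        mu_n, vn = _weighted_moments(x, 1.0 - r)
        sigma_n = np.maximum(np.sqrt(vn), _SIGMA_MIN)

        ll_n, lg_n, ln_n = loglik(lam_n, alpha_n, beta_n, mu_n, sigma_n)
        improved = active & (ll_n >= ll - 1e-10)
        for arr, arr_n in ((lam, lam_n), (alpha, alpha_n), (beta, beta_n),
                           (mu, mu_n), (sigma, sigma_n)):
            arr[improved] = arr_n[improved]
        lg[:, improved] = lg_n[:, improved]
        ln[:, improved] = ln_n[:, improved]
        small = improved & (np.abs(ll_n - ll) < tol)
        ll[improved] = ll_n[improved]
        n_iter[active] = it + 1
        converged |= small
        active &= improved & ~small
        if record_trace:
            trace.append(ll.copy())

    return lam, alpha, beta, mu, sigma, ll, n_iter, converged, trace


def _init_responsibilities(x: np.ndarray, rng: np.random.Generator,
                           restart: int) -> np.ndarray:
    """Per-gene two-cluster split of the values; lower cluster -> Gamma.

    Restart 0 splits at the midpoint between the per-gene min and max
    (refined by a few 1-D Lloyd iterations); later restarts split at a
    random per-gene quantile.
    """
    n, G = x.shape
    if restart == 0:
        lo = x.min(axis=0)
        hi = x.max(axis=0)
        thr = 0.5 * (lo + hi)
        for _ in range(5):
            below = x <= thr
            any_b = below.any(axis=0)
            any_a = (~below).any(axis=0)
            c0 = np.where(any_b, np.where(below, x, np.nan).mean(axis=0,
                          where=below), lo)
            c1 = np.where(any_a, np.where(~below, x, np.nan).mean(axis=0,
                          where=~below), hi)
            thr = 0.5 * (c0 + c1)
    else:
        q = rng.uniform(0.2, 0.8, size=G)
        thr = np.quantile(x, 0.5, axis=0)  # base; jitter by quantile draw
        thr = np.array([np.quantile(x[:, j], q[j]) for j in range(G)])
    return (x <= thr).astype(np.float64)


def fit_gamma_normal_em(values: np.ndarray, init_seed: int = 0,
                        max_iter: int = 100, tol: float = 1e-6,
                        n_restarts: int = 3) -> MixtureFit:
    """Fit the two-component Gamma-Normal mixture to one value vector.

    Values must be on the preprocessed shifted-log scale (strictly
    positive) with at least 10 observations.  Runs ``n_restarts``
    initializations and keeps the best final log-likelihood.
    """
    x = np.asarray(values, dtype=np.float64).reshape(-1, 1)
    if x.shape[0] < _MIN_CELLS:
        raise ValueError(f"need at least {_MIN_CELLS} observations, got {x.shape[0]}")
    if np.any(x <= 0):
        raise ValueError("values must be strictly positive (shifted-log scale)")
    rng = np.random.default_rng(int(init_seed))
    best = None
    for restart in range(n_restarts):
        r0 = _init_responsibilities(x, rng, restart)
        lam, a, b, mu, sg, ll, ni, cv, trace = _em_many(
            x, r0, max_iter, tol, record_trace=True)
        fit = MixtureFit(float(lam[0]), float(a[0]), float(b[0]), float(mu[0]),
                         float(sg[0]), float(ll[0]), int(ni[0]), bool(cv[0]),
                         trace=[float(t[0]) for t in trace])
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def dropout_probability(x_ij, fit: MixtureFit):
    """Posterior probability that a value belongs to the Gamma component."""
    x = np.asarray(x_ij, dtype=np.float64)
    if fit.lambda_ <= 0:
        return np.zeros_like(x) if x.ndim else 0.0
    if fit.lambda_ >= 1:
        return np.ones_like(x) if x.ndim else 1.0
    lg = np.log(fit.lambda_) + _log_gamma_pdf(x, fit.alpha, fit.beta)
    ln = np.log1p(-fit.lambda_) + _log_normal_pdf(x, fit.mu, fit.sigma)
    d = 1.0 / (1.0 + np.exp(np.clip(ln - lg, -700, 700)))
    return d if x.ndim else float(d)


# ---------------------------------------------------------------------------
# whole-matrix identification

def _merge_small_subpops(codes: np.ndarray, values: np.ndarray,
                         min_cells: int) -> np.ndarray:
    """Merge subpopulations with fewer than ``min_cells`` cells into the
    nearest (centroid distance) adequately sized subpopulation."""
    codes = codes.copy()
    while True:
        ids, counts = np.unique(codes, return_counts=True)
        small = ids[counts < min_cells]
        big = ids[counts >= min_cells]
        if small.size == 0 or big.size == 0:
            break
        centroids = {i: values[codes == i].mean(axis=0) for i in ids}
        s = small[0]
        dists = [np.linalg.norm(centroids[s] - centroids[b]) for b in big]
        target = big[int(np.argmin(dists))]
        warnings.warn(f"subpopulation {s} has <{min_cells} cells; "
                      f"merged into subpopulation {target}")
        codes[codes == s] = target
    return codes


def identify_dropouts(x: ExpressionMatrix, labels: CellLabels,
                      rho: float = 0.5, seed: int = 0,
                      max_iter: int = 100, tol: float = 1e-6,
                      n_restarts: int = 3):
    """Flag zero-level entries whose dropout probability exceeds ``rho``.

    For every (gene, subpopulation) pair with enough cells and enough
    expressed values, the mixture is fit by EM; the dropout probability is
    evaluated at zero-level entries only.  Genes with fewer than 10 cells
    in a subpopulation, with no zero-level entries, or with fewer than 3
    expressed (above-zero-level) values get d = 0 there (no imputation).

    Returns ``(DropoutProbabilities, DropoutMask, fits)`` where ``fits`` is
    a tidy DataFrame with one row per fitted (gene, subpopulation) pair.
    """
    if len(labels) != x.n_cells:
        raise ValueError("labels must cover all cells")
    z0 = zero_level()
    is_zero = np.abs(x.values - z0) < ZERO_TOL
    d = np.zeros_like(x.values)
    codes = _merge_small_subpops(labels.codes(), x.values, _MIN_CELLS)

    rows = []
    rng = np.random.default_rng(derive_seed(seed, "em"))
    for k in np.unique(codes):
        in_k = codes == k
        sub = x.values[in_k]                       # n_k x G
        zero_sub = is_zero[in_k]
        n_expressed = (~zero_sub).sum(axis=0)
        fit_cols = np.flatnonzero((zero_sub.any(axis=0)) &
                                  (n_expressed >= _MIN_EXPRESSED))
        if fit_cols.size == 0:
            continue
        block = sub[:, fit_cols]
        best = None
        for restart in range(n_restarts):
            r0 = _init_responsibilities(block, rng, restart)
            out = _em_many(block, r0, max_iter, tol)
            if best is None:
                best = list(out)
            else:
                better = out[5] > best[5]
                for i in range(5):
                    best[i][better] = out[i][better]
                best[5][better] = out[5][better]
                best[6][better] = out[6][better]
                best[7][better] = out[7][better]
        lam, alpha, beta, mu, sigma, ll, n_iter, conv = best[:8]

        lg = np.log(lam) + _log_gamma_pdf(block, alpha, beta)
        ln = np.log1p(-lam) + _log_normal_pdf(block, mu, sigma)
        d_block = 1.0 / (1.0 + np.exp(np.clip(ln - lg, -700, 700)))
        d_block = np.where(zero_sub[:, fit_cols], d_block, 0.0)
        d_sub = np.zeros_like(sub)
        d_sub[:, fit_cols] = d_block
        d[in_k] = d_sub

        for idx, j in enumerate(fit_cols):
            rows.append({"gene": x.gene_ids[j], "subpop": int(k),
                         "lambda": lam[idx], "alpha": alpha[idx],
                         "beta": beta[idx], "mu": mu[idx],
                         "sigma": sigma[idx], "loglik": ll[idx],
                         "n_iter": int(n_iter[idx]),
                         "converged": bool(conv[idx])})

    mask = (d > rho) & is_zero
    fits = pd.DataFrame(rows, columns=["gene", "subpop", "lambda", "alpha",
                                       "beta", "mu", "sigma", "loglik",
                                       "n_iter", "converged"])
    return DropoutProbabilities(d), DropoutMask(mask), fits
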