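"""Evaluation metrics and the simulated-data benchmark runner.

Covers the three metric families used to assess selective imputation:
classification of predicted vs true dropout positions (accuracy, F1,
precision, FPR, evaluated over the zero-level positions of the observed
matrix), value recovery at chosen positions (RMSE, Pearson correlation,
cosine similarity) and cell clustering (ARI / NMI of K-means on principal
components against reference labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .io import (CellLabels, ExpressionMatrix, RunConfig, derive_seed,
                 preprocess)
from .dropout import DropoutMask

__all__ = ["ConfusionCounts", "MetricsReport", "dropout_id_metrics",
           "recovery_metrics", "clustering_metrics", "run_benchmark"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    metrics: dict
    context: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.metrics[key]


def _safe_ratio(num, den, name):
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def dropout_id_metrics(pred: DropoutMask | np.ndarray, truth: np.ndarray,
                       observed: ExpressionMatrix,
                       zero_level_value: float = 0.0) -> MetricsReport:
    """Confusion metrics over the zero-level positions of ``observed``.

    Positive class is "dropout event".  Nonzero positions are excluded:
    they are trivially non-dropout and would inflate accuracy.
    """
    pred = pred.mask if isinstance(pred, DropoutMask) else np.asarray(pred)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape or pred.shape != observed.values.shape:
        raise ValueError("pred, truth and observed shapes must match")
    at_zero = np.abs(observed.values - zero_level_value) < 1e-9
    p = pred[at_zero]
    t = truth[at_zero]
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    tn = int(np.sum(~p & ~t))
    fn = int(np.sum(~p & t))
    counts = ConfusionCounts(tp, fp, tn, fn)
    return MetricsReport(
        metrics={
            "accuracy": _safe_ratio(tp + tn, counts.total, "accuracy"),
            "precision": _safe_ratio(tp, tp + fp, "precision"),
            "recall": _safe_ratio(tp, tp + fn, "recall"),
            "f1": _safe_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
            "fpr": _safe_ratio(fp, fp + tn, "FPR"),
        },
        context={"counts": counts, "n_positions": counts.total})


def recovery_metrics(imputed: ExpressionMatrix, truth: ExpressionMatrix,
                     positions="all") -> MetricsReport:
    """RMSE / Pearson r / cosine similarity at the selected positions."""
    if imputed.values.shape != truth.values.shape:
        raise ValueError("imputed and truth shapes must match")
    if isinstance(positions, str) and positions == "all":
        sel = np.ones(truth.values.shape, dtype=bool)
    else:
        sel = np.asarray(positions, dtype=bool)
        if sel.shape != truth.values.shape:
            raise ValueError("positions mask shape must match matrices")
    a = imputed.values[sel].ravel()
    b = truth.values[sel].ravel()
    if a.size < 2:
        raise ValueError("need at least 2 evaluated positions")
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant vector; Pearson correlation undefined (NaN)")
        pcc = float("nan")
    else:
        pcc = float(stats.pearsonr(a, b).statistic)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cosine = float(a @ b / (na * nb)) if na > 0 and nb > 0 else float("nan")
    return MetricsReport(
        metrics={"rmse": rmse, "pcc": pcc, "cosine": cosine},
        context={"n_positions": int(a.size)})


def clustering_metrics(x: ExpressionMatrix, true_labels: CellLabels,
                       k: int | None = None, seed: int = 0,
                       n_seeds: int = 5, n_pcs: int = 50) -> MetricsReport:
    """ARI / NMI of K-means (k = number of cell types) on top PCs.

    K-means is repeated with ``n_seeds`` seeds; mean and sd of both
    scores are reported.
    """
    if len(true_labels) != x.n_cells:
        raise ValueError("labels must cover all cells")
    k = k or true_labels.k
    if k > x.n_cells:
        raise ValueError("k cannot exceed the number of cells")
    n_pc = min(n_pcs, x.n_cells - 1, x.n_genes)
    pcs = PCA(n_components=n_pc, random_state=int(seed)).fit_transform(x.values)
    ref = true_labels.codes()
    aris, nmis = [], []
    for s in range(n_seeds):
        lab = KMeans(n_clusters=k, n_init=10,
                     random_state=derive_seed(seed, f"km{s}")).fit_predict(pcs)
        aris.append(adjusted_rand_score(ref, lab))
        nmis.append(normalized_mutual_info_score(ref, lab))
    return MetricsReport(
        metrics={"ari": float(np.mean(aris)), "ari_sd": float(np.std(aris)),
                 "nmi": float(np.mean(nmis)), "nmi_sd": float(np.std(nmis))},
        context={"k": k, "n_seeds": n_seeds, "n_pcs": n_pc})


# ---------------------------------------------------------------------------
# benchmark harness

_VARIANTS = {
    "full": {},
    "no_adv": {"use_adv": False},
    "no_cell": {"use_cell": False},
    "no_type": {"use_type": False},
    "no_discriminator": {"use_adv": False, "use_cell": False,
                         "use_type": False},
}


def run_benchmark(presets: list[str], seeds: list[int],
                  variants: list[str] = ("full",),
                  cfg_overrides: dict | None = None,
                  sim_overrides: dict | None = None,
                  with_clustering: bool = False) -> pd.DataFrame:
    """Simulate, run the pipeline and score, one tidy row per metric.

    ``variants`` are ablation names from {full, no_adv, no_cell, no_type,
    no_discriminator}.  ``cfg_overrides``/``sim_overrides`` shrink problem
    sizes or schedules for quick runs.
    """
    from .simulate import preset as get_preset, simulate
    from .train import run_pipeline
    from . import io as _io

    rows = []
    for preset_name in presets:
        for seed in seeds:
            params = get_preset(preset_name, seed=seed, **(sim_overrides or {}))
            truth = simulate(params)
            complete_pp = preprocess(truth.complete)
            for variant in variants:
                if variant not in _VARIANTS:
                    raise ValueError(f"unknown variant {variant!r}")
                cfg = RunConfig(seed=seed, **_VARIANTS[variant],
                                **(cfg_overrides or {}))
                result, _ = run_pipeline(truth.observed, cfg,
                                         labels=truth.labels)
                base = {"preset": preset_name, "seed": seed,
                        "variant": variant}
                rep_id = dropout_id_metrics(result.mask,
                                            truth.true_dropout_mask,
                                            truth.observed)
                rep_rec = recovery_metrics(result.values, complete_pp,
                                           positions=truth.true_dropout_mask)
                reports = {"dropout_id": rep_id, "recovery": rep_rec}
                if with_clustering:
                    reports["clustering"] = clustering_metrics(
                        result.values, truth.labels, seed=seed)
                for family, rep in reports.items():
                    for metric, value in rep.metrics.items():
                        rows.append({**base, "family": family,
                                     "metric": metric, "value": value})
    return pd.DataFrame(rows)
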