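"""Horizon metrics, interpretation tables, exact attributions, KernelSHAP.

The quilt model's headline advantage is that its interpretation is read off
the coefficients: a per-episode prediction decomposes exactly into a cohort
baseline plus per-feature contributions (machine-precision additivity).
This module produces those tables, the fixed-horizon discrimination metrics
(AUROC / AUPRC on the 1 − S(horizon) risk score), and a regression-based
KernelSHAP harness so the exact attribution can be contrasted with what a
posthoc explainer reports.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["AttributionVector", "horizon_metrics", "risk_factor_table",
           "cohort_baseline_table", "treatment_effect_table",
           "ground_truth_attribution", "kernel_shap", "disagreement_metrics"]


def horizon_metrics(risk_scores, labels):
    """AUROC (rank statistic, half-credit ties) and AUPRC (average precision)."""
    from sklearn.metrics import average_precision_score, roc_auc_score
    labels = np.asarray(labels, dtype=int)
    risk_scores = np.asarray(risk_scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; metrics undefined")
    return float(roc_auc_score(labels, risk_scores)), \
        float(average_precision_score(labels, risk_scores))


def _interval_labels(pem):
    edges = pem.edges
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        out.append(f"days {lo:g}–{hi:g}" if np.isfinite(hi) else f"days {lo:g}+")
    return out


def risk_factor_table(model, posterior, interval=0, kappa=None, k=40,
                      n_draws=500, seed=0) -> pd.DataFrame:
    """Top-k predictors of an interval by |posterior mean log hazard ratio|."""
    tabs = model.sample_tables(posterior, n_draws, seed)
    cell = 0 if kappa is None else model.config.lattice.cell_id(kappa)
    beta = tabs["beta"][:, cell, interval, :]       # (draws, p)
    names = getattr(model, "column_names", None) or \
        [f"x{j}" for j in range(beta.shape[1])]
    label = _interval_labels(model.config.pem)[interval]
    df = pd.DataFrame({
        "predictor": names,
        "interval": label,
        "mean": beta.mean(axis=0),
        "sd": beta.std(axis=0, ddof=1),
        "lo95": np.quantile(beta, 0.025, axis=0),
        "hi95": np.quantile(beta, 0.975, axis=0),
    })
    df = df.reindex(df["mean"].abs().sort_values(ascending=False).index)
    if k > len(df):
        import warnings
        warnings.warn(f"requested top {k} of only {len(df)} coefficients; "
                      "table truncated", stacklevel=2)
    return df.head(int(k)).reset_index(drop=True)


def cohort_baseline_table(model, posterior, n_draws=500, seed=0) -> pd.DataFrame:
    """Posterior-mean baseline log-hazard per cohort cell × interval."""
    tabs = model.sample_tables(posterior, n_draws, seed)
    alpha = tabs["alpha"].mean(axis=0)              # (cells, I)
    lat = model.config.lattice
    rows = [dict(zip(lat.names, kappa)) for kappa
            in itertools.product(*(range(s) for s in lat.sizes))]
    df = pd.DataFrame(rows)
    for i, lab in enumerate(_interval_labels(model.config.pem)):
        df[lab] = alpha[:, i]
    return df


def treatment_effect_table(model, posterior, interval=0, n_draws=500,
                           seed=0) -> pd.DataFrame:
    """Cumulative placement effects (vs discharge home) per cohort.

    The effect of placement k is Σ_{j≤k} γ_ind,j — the change in log hazard
    relative to home; non-positive by construction.
    """
    tabs = model.sample_tables(posterior, n_draws, seed)
    gamma_ind = tabs["gamma"][:, :, interval, 5:]   # (draws, cells, 5)
    effects = np.cumsum(gamma_ind, axis=2)
    lat = model.config.lattice
    rows = [dict(zip(lat.names, kappa)) for kappa
            in itertools.product(*(range(s) for s in lat.sizes))]
    df = pd.DataFrame(rows)
    for k in range(5):
        df[f"placement>={k + 1} mean"] = effects[:, :, k].mean(axis=0)
        df[f"placement>={k + 1} sd"] = effects[:, :, k].std(axis=0, ddof=1)
    return df


@dataclass
class AttributionVector:
    """Per-feature contributions plus a base value."""

    contributions: np.ndarray
    base: float

    def __post_init__(self):
        self.contributions = np.asarray(self.contributions, dtype=np.float64)
        self.base = float(self.base)

    @property
    def total(self) -> float:
        return self.base + float(self.contributions.sum())


def ground_truth_attribution(coefficients, x, base) -> AttributionVector:
    """Exact linear attribution: contribution_j = coefficient_j · x_j."""
    coefficients = np.asarray(coefficients, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if coefficients.shape != x.shape:
        raise ValueError("coefficients and features must align")
    return AttributionVector(coefficients * x, base)


def _shapley_kernel_weight(p, s):
    return (p - 1) / (math.comb(p, s) * s * (p - s))


def kernel_shap(predict_fn, instance, background, n_coalitions=2048, seed=0,
                sampling="marginal") -> AttributionVector:
    """Regression-based KernelSHAP attribution of one prediction.

    Coalition values use the background set: 'marginal' substitutes
    background values for out-of-coalition features (interventional);
    'conditional' averages predictions over background rows that match the
    instance exactly on the coalition (falling back to marginal when no row
    matches), which respects feature correlation in the background.  All
    2^p − 2 proper coalitions are enumerated when the budget allows,
    otherwise coalitions are sampled from the Shapley kernel; the efficiency
    constraint (attributions sum to f(x) − mean background prediction) is
    imposed exactly.
    """
    x = np.asarray(instance, dtype=np.float64)
    bg = np.asarray(background, dtype=np.float64)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background must be a nonempty matrix")
    p = x.size
    if n_coalitions < p + 2:
        raise ValueError("n_coalitions must be at least n_features + 2")
    rng = np.random.default_rng(seed)
    base = float(np.mean(predict_fn(bg)))
    fx = float(predict_fn(x[None, :])[0])
    total = fx - base

    full = 2 ** p - 2
    if full <= n_coalitions:
        masks = np.array([[int(b) for b in np.binary_repr(m, p)]
                          for m in range(1, 2 ** p - 1)], dtype=bool)
        weights = np.array([_shapley_kernel_weight(p, int(m.sum()))
                            for m in masks])
    else:
        sizes = np.arange(1, p)
        size_w = np.array([_shapley_kernel_weight(p, s) * math.comb(p, s)
                           for s in sizes])
        size_w /= size_w.sum()
        draws = rng.choice(sizes, size=n_coalitions, p=size_w)
        masks = np.zeros((n_coalitions, p), dtype=bool)
        for i, s in enumerate(draws):
            masks[i, rng.choice(p, size=s, replace=False)] = True
        weights = np.ones(n_coalitions)

    values = np.empty(len(masks))
    for i, mask in enumerate(masks):
        if sampling == "conditional":
            match = np.all(bg[:, mask] == x[mask], axis=1)
            if match.any():
                values[i] = float(np.mean(predict_fn(bg[match])))
                continue
        synth = bg.copy()
        synth[:, mask] = x[mask]
        values[i] = float(np.mean(predict_fn(synth)))

    # weighted least squares with φ_p eliminated by the efficiency constraint
    Z = masks.astype(np.float64)
    y = values - base - Z[:, -1] * total
    A = Z[:, :-1] - Z[:, [-1]]
    W = weights
    AtWA = A.T * W @ A
    if np.linalg.matrix_rank(AtWA) < p - 1:
        raise np.linalg.LinAlgError(
            "singular KernelSHAP regression system; increase n_coalitions "
            "or enlarge the background")
    phi_head = np.linalg.solve(AtWA, A.T * W @ y)
    phi = np.append(phi_head, total - phi_head.sum())
    return AttributionVector(phi, base)


def disagreement_metrics(shap: AttributionVector, truth: AttributionVector,
                         top_k=1):
    """Spearman rank correlation of |attributions| and top-k overlap."""
    a = np.abs(shap.contributions)
    b = np.abs(truth.contributions)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two aligned attribution vectors, >= 2 features")
    rho = float(spearmanr(a, b).statistic)
    top_a = set(np.argsort(-a, kind="stable")[:top_k])
    top_b = set(np.argsort(-b, kind="stable")[:top_k])
    return rho, len(top_a & top_b) / top_k
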