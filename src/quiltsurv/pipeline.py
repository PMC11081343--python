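"""End-to-end workflow helpers: episode table → design → fit → risk scores.

These functions are the programmatic interface behind the command-line
tool: they validate the episode schema, apply (or compute) the quantile
cutoff table, assemble `ModelData`, run ADVI, and score fixed-horizon
risks from posterior draws.  Model artifacts serialize to a plain-text
directory (JSON) for exact round-tripping.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .advi import Posterior, QuiltProblem, TrainConfig, fit
from .decomposition import Lattice
from .featurization import CutoffTable, binarize, compute_cutoffs
from .model import ModelData, QuiltModel, QuiltModelConfig
from .pem import PEMConfig, interval_exposures

__all__ = ["prepare_data", "fit_quilt", "risk_scores", "save_model",
           "load_model"]


def prepare_data(df: pd.DataFrame, feature_cols, attr_cols, lattice: Lattice,
                 pem: PEMConfig = PEMConfig(), cutoffs: CutoffTable = None,
                 quantile_grid=None):
    """Binarize features and package outcomes into ModelData.

    Returns (data, cutoff_table, column_names).  Same-day events are floored
    to `pem.min_wait_days`.
    """
    missing = [c for c in (*feature_cols, *attr_cols, "placement", "time",
                           "event") if c not in df.columns]
    if missing:
        raise ValueError(f"episode table is missing columns {missing}")
    raw = df[list(feature_cols)].to_numpy(dtype=np.float64)
    if cutoffs is None:
        kwargs = {} if quantile_grid is None else {"quantile_grid": quantile_grid}
        cutoffs = compute_cutoffs(raw, feature_names=list(feature_cols), **kwargs)
    X, names = binarize(raw, cutoffs)
    kappas = df[list(attr_cols)].to_numpy(dtype=int) if attr_cols else \
        np.zeros((len(df), 1), dtype=int)
    time = np.maximum(df["time"].to_numpy(dtype=np.float64), pem.min_wait_days)
    data = ModelData.build(X, kappas, df["placement"].to_numpy(dtype=int),
                           time, df["event"].to_numpy(dtype=int), lattice, pem)
    return data, cutoffs, names


def fit_quilt(data: ModelData, model_config: QuiltModelConfig,
              train_config: TrainConfig = TrainConfig(),
              column_names=None):
    """Fit the joint quilt model by minibatch ADVI."""
    model = QuiltModel(model_config)
    if column_names is not None:
        model.column_names = list(column_names)
    posterior = fit(QuiltProblem(model, data), train_config)
    return model, posterior


def risk_scores(model: QuiltModel, posterior: Posterior, data: ModelData,
                horizon: float = 30.0, n_draws: int = 100,
                seed: int = 0) -> np.ndarray:
    """Posterior-mean Pr(event by horizon) per episode."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    pem = model.config.pem
    expo = interval_exposures(float(horizon), pem)
    draws = posterior.draw(n_draws, seed)
    acc = np.zeros(len(data))
    for d in range(n_draws):
        tables = _numpy_tables(model, draws[d])
        log_haz = model.predicted_log_hazards(tables, data)
        acc += 1.0 - np.exp(-(np.exp(log_haz) * expo[None, :]).sum(axis=1))
    return acc / n_draws


def _numpy_tables(model: QuiltModel, z: np.ndarray):
    from ._autodiff import value_of
    tabs = model.tables(model.split(z))
    return {fam: value_of(t) for fam, t in tabs.items()}


def save_model(path, model: QuiltModel, posterior: Posterior,
               cutoffs: CutoffTable = None):
    """Persist config, variational state, trace and cutoffs as JSON text."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "model_config.json").write_text(model.config_json())
    state = {
        "mu": posterior.mu.tolist(),
        "omega": posterior.omega.tolist(),
        "trace": [[float(a), float(b)] for a, b in posterior.trace],
        "train_config": {k: (v if not isinstance(v, np.generic) else v.item())
                         for k, v in vars(posterior.config).items()},
        "converged_epochs": posterior.converged_epochs,
    }
    (path / "posterior.json").write_text(json.dumps(state))
    if cutoffs is not None:
        (path / "cutoffs.json").write_text(cutoffs.to_json())
    if getattr(model, "column_names", None):
        (path / "columns.json").write_text(json.dumps(model.column_names))
    trace_txt = "\n".join(f"epoch {i}: loss={l:.6f} lr={r:.6g}"
                          for i, (l, r) in enumerate(posterior.trace))
    (path / "training.log").write_text(trace_txt + "\n")


def load_model(path):
    """Inverse of :func:`save_model`; returns (model, posterior, cutoffs)."""
    path = Path(path)
    model = QuiltModel.from_config_json((path / "model_config.json").read_text())
    state = json.loads((path / "posterior.json").read_text())
    posterior = Posterior(
        np.asarray(state["mu"]), np.asarray(state["omega"]),
        [tuple(t) for t in state["trace"]],
        TrainConfig(**state["train_config"]),
        state.get("converged_epochs", 0))
    cutoffs = None
    cpath = path / "cutoffs.json"
    if cpath.exists():
        cutoffs = CutoffTable.from_json(cpath.read_text())
    cols = path / "columns.json"
    if cols.exists():
        model.column_names = json.loads(cols.read_text())
    return model, posterior, cutoffs
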