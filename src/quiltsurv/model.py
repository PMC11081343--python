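"""The joint quilt model: PEM outcome × ordinal placement, lattice-decomposed.

Ties the modules together into one Bayesian joint density,

    T_n ~ PEM(α(κ_n), β(κ_n)·x_n, γ(κ_n)·I_n)
    I_n ~ OrdinalLogistic(ξ(κ_n)·x_n, c(κ_n)),

where every parameter is an additive multi-order decomposition over the
cohort lattice.  Intercept-like decompositions (α, raw cutpoints) carry
zero-mean normal priors with geometrically shrinking per-order scales; slope
decompositions (β, γ, ξ) carry non-centered horseshoe priors.  The five
exceedance probabilities Pr(I≥k|x) enter the survival covariate vector as
per-draw values, so the confounding adjustment is inferred jointly rather
than frozen in a first stage.

All density code is written against the dispatching ops in `_autodiff`, so
the same functions serve fast numpy evaluation and gradient computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from .decomposition import (DecomposedParameter, Lattice, PriorSpec, log_prior,
                            materialize_table)
from .ordinal import N_CATEGORIES, N_CUTPOINTS, ordered_cutpoints
from .pem import N_TREATMENT_COVARIATES, PEMConfig, constrain_gamma, \
    interval_exposures

__all__ = ["QuiltModelConfig", "QuiltModel", "ModelData"]

_PROB_FLOOR = 1e-300  # guards log of a telescoping difference


@dataclass(frozen=True)
class QuiltModelConfig:
    """Structural and prior configuration of the joint model."""

    lattice: Lattice
    n_features: int
    pem: PEMConfig = field(default_factory=PEMConfig)
    max_order: int = 2
    order_scale: float = 0.5      # per-order geometric prior-scale multiplier
    alpha_scale: float = 2.0      # normal prior scale, baseline log-hazards
    cutpoint_scale: float = 2.0   # normal prior scale, raw ordinal cutpoints
    beta_scale: float = 1.0       # horseshoe base scale, survival slopes
    gamma_scale: float = 1.0      # horseshoe base scale, treatment block
    xi_scale: float = 1.0         # horseshoe base scale, placement slopes
    # temperature of the non-positivity hinge on γ's indicator block; small
    # values make the constrained effect ~min(raw, 0), so horseshoe shrinkage
    # of the raw coefficient implies a near-null treatment effect
    treatment_hinge_scale: float = 0.1

    def __post_init__(self):
        if self.max_order > self.lattice.ndim:
            raise ValueError("max_order exceeds lattice dimensionality")


@dataclass
class ModelData:
    """Preprocessed arrays the likelihood consumes (one row per episode)."""

    X: np.ndarray            # (n, p) binary design
    cell: np.ndarray         # (n,) flat lattice cell ids
    placement: np.ndarray    # (n,) int 0..5
    time: np.ndarray         # (n,) days, > 0
    event: np.ndarray        # (n,) 0/1
    exposures: np.ndarray    # (n, I) interval overlaps Δ_i(T)
    event_onehot: np.ndarray  # (n, I) event interval indicator (0 if censored)
    ind_block: np.ndarray    # (n, 5) observed 1{I >= k}
    upper_sel: np.ndarray    # (n, 5) selects Pr(I >= obs) (zero row if obs = 0)
    lower_sel: np.ndarray    # (n, 5) selects Pr(I >= obs+1) (zero row if obs = 5)
    is_zero: np.ndarray      # (n,) 1 where obs = 0 (upper prob is 1)

    @classmethod
    def build(cls, X, kappas, placement, time, event, lattice: Lattice,
              pem: PEMConfig) -> "ModelData":
        X = np.asarray(X, dtype=np.float64)
        placement = np.asarray(placement, dtype=int)
        time = np.asarray(time, dtype=np.float64)
        event = np.asarray(event, dtype=int)
        n = X.shape[0]
        if not (len(placement) == len(time) == len(event) == n):
            raise ValueError("episode arrays must share the same length")
        if np.any((placement < 0) | (placement >= N_CATEGORIES)):
            raise ValueError("placement outside 0..5")
        if np.any(time <= 0):
            raise ValueError("wait times must be positive "
                             f"(floor same-day events at {pem.min_wait_days})")
        kappas = np.asarray(kappas, dtype=int)
        cell = lattice.cell_ids(kappas) if kappas.ndim == 2 else kappas
        I = pem.n_intervals
        expo = interval_exposures(time, pem)
        idx = np.searchsorted(np.asarray(pem.breakpoints), time, side="right")
        onehot = np.zeros((n, I))
        onehot[np.arange(n), idx] = event
        ks = np.arange(1, N_CATEGORIES)
        ind = (placement[:, None] >= ks[None, :]).astype(np.float64)
        upper = np.zeros((n, N_CUTPOINTS))
        rows = placement >= 1
        upper[rows, placement[rows] - 1] = 1.0
        lower = np.zeros((n, N_CUTPOINTS))
        rows = placement <= 4
        lower[rows, placement[rows]] = 1.0
        return cls(X, cell.astype(int), placement, time, event, expo, onehot,
                   ind, upper, lower, (placement == 0).astype(np.float64))

    def __len__(self):
        return self.X.shape[0]

    def subset(self, idx) -> "ModelData":
        return ModelData(self.X[idx], self.cell[idx], self.placement[idx],
                         self.time[idx], self.event[idx], self.exposures[idx],
                         self.event_onehot[idx], self.ind_block[idx],
                         self.upper_sel[idx], self.lower_sel[idx],
                         self.is_zero[idx])


class QuiltModel:
    """Latent layout, priors, likelihood and summaries of the joint model."""

    FAMILIES = ("alpha", "beta", "gamma", "cut", "xi")

    def __init__(self, config: QuiltModelConfig):
        self.config = config
        lat, p, I = config.lattice, config.n_features, config.pem.n_intervals
        mo, osc = config.max_order, config.order_scale
        self.dp = {
            "alpha": DecomposedParameter.zeros(lat, mo, (I,), osc),
            "beta": DecomposedParameter.zeros(lat, mo, (I, p), osc),
            "gamma": DecomposedParameter.zeros(lat, mo, (I, N_TREATMENT_COVARIATES), osc),
            "cut": DecomposedParameter.zeros(lat, mo, (N_CUTPOINTS,), osc),
            "xi": DecomposedParameter.zeros(lat, mo, (p,), osc),
        }
        self.priors = {
            "alpha": PriorSpec("normal", config.alpha_scale),
            "beta": PriorSpec("horseshoe", config.beta_scale),
            "gamma": PriorSpec("horseshoe", config.gamma_scale),
            "cut": PriorSpec("normal", config.cutpoint_scale),
            "xi": PriorSpec("horseshoe", config.xi_scale),
        }
        # latent layout: (key, shape, offset); horseshoe families get a raw
        # and a local-scale latent per term plus one global-scale latent
        self.layout = []
        offset = 0
        for fam in self.FAMILIES:
            dp = self.dp[fam]
            hs = self.priors[fam].kind == "horseshoe"
            for k, term in enumerate(dp.terms):
                shape = np.shape(term.values)
                self.layout.append(((fam, k, "value"), shape, offset))
                offset += int(np.prod(shape))
                if hs:
                    self.layout.append(((fam, k, "ulocal"), shape, offset))
                    offset += int(np.prod(shape))
            if hs:
                self.layout.append(((fam, None, "uglobal"), (), offset))
                offset += 1
        self.dim = offset
        self._slices = {key: (off, off + int(np.prod(shape)), shape)
                        for key, shape, off in self.layout}

    # -- latent bookkeeping ---------------------------------------------
    def split(self, z):
        """Slice the flat latent vector into named, shaped blocks."""
        out = {}
        for key, (lo, hi, shape) in self._slices.items():
            out[key] = ad.reshape(z[lo:hi], shape)
        return out

    def _coefficient_terms(self, parts, fam):
        """Per-term coefficient tensors on the constrained scale."""
        dp, prior = self.dp[fam], self.priors[fam]
        if prior.kind == "normal":
            return [parts[(fam, k, "value")] for k in range(len(dp.terms))]
        glob = ad.softplus(parts[(fam, None, "uglobal")])
        out = []
        for k, term in enumerate(dp.terms):
            lam = ad.softplus(parts[(fam, k, "ulocal")])
            scale = prior.base_scale * dp.order_scale ** term.order
            out.append(parts[(fam, k, "value")] * lam * (glob * scale))
        return out

    def tables(self, parts):
        """Materialized per-cell parameter tables (flattened to n_cells rows).

        γ is returned with its indicator block already constrained to be
        non-positive, and cutpoints already ordered.
        """
        lat = self.config.lattice
        n_cells = lat.n_cells
        out = {}
        for fam in self.FAMILIES:
            terms = self._coefficient_terms(parts, fam)
            table = materialize_table(self.dp[fam], terms)
            flat = ad.reshape(table, (n_cells,) + self.dp[fam].trailing_shape)
            if fam == "gamma":
                flat = constrain_gamma(flat, self.config.treatment_hinge_scale)
            elif fam == "cut":
                flat = ordered_cutpoints(flat)
            out[fam] = flat
        return out

    # -- density ---------------------------------------------------------
    def log_prior(self, parts):
        total = 0.0
        for fam in self.FAMILIES:
            dp, prior = self.dp[fam], self.priors[fam]
            values = [parts[(fam, k, "value")] for k in range(len(dp.terms))]
            if prior.kind == "normal":
                total = total + log_prior(dp, prior, values)
            else:
                ulocals = [parts[(fam, k, "ulocal")] for k in range(len(dp.terms))]
                uglob = parts[(fam, None, "uglobal")]
                locs = [ad.softplus(u) for u in ulocals]
                glob = ad.softplus(uglob)
                total = total + log_prior(dp, prior, values, locs, glob)
                # log-Jacobian of scale = softplus(u):  dλ/du = σ(u)
                for u in ulocals:
                    total = total - ad.tsum(ad.softplus(-u))
                total = total - ad.tsum(ad.softplus(-uglob))
        return total

    def log_likelihood(self, tables, batch: ModelData):
        """Summed PEM + ordinal log-likelihood of a batch, given tables."""
        B = len(batch)
        alpha_b = ad.take(tables["alpha"], batch.cell)        # (B, I)
        beta_b = ad.take(tables["beta"], batch.cell)          # (B, I, p)
        gamma_b = ad.take(tables["gamma"], batch.cell)        # (B, I, 10)
        cut_b = ad.take(tables["cut"], batch.cell)            # (B, 5)
        xi_b = ad.take(tables["xi"], batch.cell)              # (B, p)

        eta = ad.tsum(xi_b * batch.X, axis=1)                 # (B,)
        exc = ad.sigmoid(ad.reshape(eta, (B, 1)) - cut_b)     # (B, 5)
        upper = batch.is_zero + ad.tsum(exc * batch.upper_sel, axis=1)
        lower = ad.tsum(exc * batch.lower_sel, axis=1)
        ll_ord = ad.tsum(ad.log(ad.clip_min(upper - lower, _PROB_FLOOR)))

        treat = ad.concat([exc, batch.ind_block], axis=1)     # (B, 10)
        bx = ad.tsum(beta_b * batch.X[:, None, :], axis=2)    # (B, I)
        gi = ad.tsum(gamma_b * ad.reshape(treat, (B, 1, 10)), axis=2)
        log_haz = alpha_b + bx + gi
        ll_surv = ad.tsum(batch.event_onehot * log_haz) \
            - ad.tsum(ad.exp(log_haz) * batch.exposures)
        return ll_surv + ll_ord

    def joint_log_density(self, z, batch: ModelData, n_total: int):
        """(n/|batch|)·batch log-likelihood + log prior (with Jacobians)."""
        parts = self.split(z)
        if len(batch) == 0:
            return self.log_prior(parts)
        tables = self.tables(parts)
        scale = float(n_total) / len(batch)
        return scale * self.log_likelihood(tables, batch) + self.log_prior(parts)

    # -- posterior access -------------------------------------------------
    def sample_tables(self, posterior, n_draws=500, seed=0):
        """Constrained per-cell tables for each posterior draw.

        Returns {family: array (n_draws, n_cells, *trailing)}.
        """
        if n_draws < 2:
            raise ValueError("need at least 2 draws")
        rng = np.random.default_rng(seed)
        z = posterior.mu + posterior.sigma * rng.standard_normal(
            (n_draws, posterior.mu.size))
        out = {fam: [] for fam in self.FAMILIES}
        for d in range(n_draws):
            tabs = self.tables(self.split(z[d]))
            for fam in self.FAMILIES:
                out[fam].append(ad.value_of(tabs[fam]))
        return {fam: np.stack(v) for fam, v in out.items()}

    def predicted_log_hazards(self, tables, data: ModelData):
        """Per-episode per-interval log-hazards from numpy tables."""
        return ad.value_of(self.log_hazard_matrix(tables, data))

    def log_hazard_matrix(self, tables, data: ModelData):
        B = len(data)
        alpha_b = ad.take(tables["alpha"], data.cell)
        beta_b = ad.take(tables["beta"], data.cell)
        gamma_b = ad.take(tables["gamma"], data.cell)
        cut_b = ad.take(tables["cut"], data.cell)
        xi_b = ad.take(tables["xi"], data.cell)
        eta = ad.tsum(xi_b * data.X, axis=1)
        exc = ad.sigmoid(ad.reshape(eta, (B, 1)) - cut_b)
        treat = ad.concat([exc, data.ind_block], axis=1)
        bx = ad.tsum(beta_b * data.X[:, None, :], axis=2)
        gi = ad.tsum(gamma_b * ad.reshape(treat, (B, 1, 10)), axis=2)
        return alpha_b + bx + gi

    # -- persistence -------------------------------------------------------
    def config_json(self) -> str:
        c = self.config
        return json.dumps({
            "lattice": {"names": list(c.lattice.names),
                        "sizes": list(c.lattice.sizes)},
            "n_features": c.n_features,
            "breakpoints": list(c.pem.breakpoints),
            "max_order": c.max_order, "order_scale": c.order_scale,
            "alpha_scale": c.alpha_scale, "cutpoint_scale": c.cutpoint_scale,
            "beta_scale": c.beta_scale, "gamma_scale": c.gamma_scale,
            "xi_scale": c.xi_scale,
            "treatment_hinge_scale": c.treatment_hinge_scale,
        })

    @classmethod
    def from_config_json(cls, text: str) -> "QuiltModel":
        d = json.loads(text)
        return cls(QuiltModelConfig(
            Lattice(tuple(d["lattice"]["names"]), tuple(d["lattice"]["sizes"])),
            d["n_features"], PEMConfig(tuple(d["breakpoints"])),
            d["max_order"], d["order_scale"], d["alpha_scale"],
            d["cutpoint_scale"], d["beta_scale"], d["gamma_scale"],
            d["xi_scale"], d["treatment_hinge_scale"]))
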