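"""Acuity-ordered discharge-placement model and treatment covariates.

Placement I ∈ {0..5} is ordered from home (0) to other less-acute inpatient
care (5).  A proportional-odds model governs the assignment:

    Pr(I ≥ k | x) = σ(ξ'x − c_k),   c_1 < … < c_5,

with cohort-varying slopes ξ and cutpoints c.  The fitted exceedance
probabilities, concatenated with the observed indicator block 1{I≥k}, form
the 10-entry treatment covariate vector that carries the assignment
(confounding) adjustment into the survival model.

Cutpoints are parameterized as a free first cutpoint plus cumulative
softplus increments so that the ordering constraint holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .decomposition import DecomposedParameter, materialize

__all__ = ["TreatmentModelSpec", "TreatmentCovariates", "ordered_cutpoints",
           "ordinal_probs", "ordinal_log_likelihood",
           "build_treatment_covariates", "constrain_treatment_effects",
           "N_CATEGORIES"]

N_CATEGORIES = 6
N_CUTPOINTS = N_CATEGORIES - 1


@dataclass
class TreatmentModelSpec:
    """Decomposed ordinal model: raw cutpoint parameters and slopes ξ.

    `cutpoints_raw` has trailing shape (5,): entry 0 is the first cutpoint,
    entries 1..4 are unconstrained increments mapped through softplus.
    `xi` has trailing shape (n_features,).
    """

    cutpoints_raw: DecomposedParameter
    xi: DecomposedParameter

    @property
    def n_features(self) -> int:
        return self.xi.trailing_shape[0]


def ordered_cutpoints(raw):
    """Map raw trailing-(5,) values to strictly increasing cutpoints.

    A tiny floor on the softplus increments keeps the ordering strict even
    when a raw increment underflows.
    """
    first = raw[..., :1]
    steps = ad.softplus(raw[..., 1:]) + 1e-12
    return ad.concat([first, first + ad.cumsum(steps, axis=-1)], axis=-1)


def exceedance(eta, cutpoints):
    """Pr(I ≥ k) for k = 1..5 given linear predictor(s) and cutpoints."""
    eta = np.asarray(eta, dtype=np.float64)
    return ad.sigmoid(eta[..., None] - np.asarray(cutpoints, dtype=np.float64))


def _category_probs(exc):
    upper = np.concatenate([np.ones(exc.shape[:-1] + (1,)), exc], axis=-1)
    lower = np.concatenate([exc, np.zeros(exc.shape[:-1] + (1,))], axis=-1)
    return upper - lower


def ordinal_probs(spec: TreatmentModelSpec, x, kappa):
    """Six category probabilities and five exceedance probabilities."""
    x = np.asarray(x, dtype=np.float64)
    cut = ordered_cutpoints(materialize(spec.cutpoints_raw, kappa))
    if np.any(np.diff(cut) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    eta = float(materialize(spec.xi, kappa) @ x)
    exc = exceedance(eta, cut)
    return _category_probs(exc), exc


def ordinal_log_likelihood(spec: TreatmentModelSpec, x, kappa, observed: int):
    """log Pr(I = observed | x, κ) under the proportional-odds model."""
    observed = int(observed)
    if not 0 <= observed < N_CATEGORIES:
        raise ValueError(f"placement must be in 0..{N_CATEGORIES - 1}")
    probs, _ = ordinal_probs(spec, x, kappa)
    return float(np.log(probs[observed]))


@dataclass
class TreatmentCovariates:
    """The 10-entry vector [Pr(I≥1..5), 1{I≥1..5}] fed to the survival model."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (10,):
            raise ValueError("treatment covariates must have 10 entries")
        probs, ind = v[:5], v[5:]
        if np.any(probs < 0) or np.any(probs > 1) or np.any(np.diff(probs) > 1e-12):
            raise ValueError("exceedance block must be nonincreasing in [0, 1]")
        if not set(np.unique(ind)) <= {0.0, 1.0} or np.any(np.diff(ind) > 0):
            raise ValueError("indicator block must be binary and nonincreasing")
        self.values = v


def build_treatment_covariates(exc, observed: int) -> TreatmentCovariates:
    """Concatenate exceedance probabilities with the 1{I≥k} indicator block."""
    exc = np.asarray(exc, dtype=np.float64)
    if exc.shape != (N_CUTPOINTS,):
        raise ValueError("need 5 exceedance probabilities")
    observed = int(observed)
    if not 0 <= observed < N_CATEGORIES:
        raise ValueError(f"placement must be in 0..{N_CATEGORIES - 1}")
    ind = (np.arange(1, N_CATEGORIES) <= observed).astype(np.float64)
    return TreatmentCovariates(np.concatenate([exc, ind]))


def constrain_treatment_effects(raw, scale=1.0):
    """Map raw indicator-block treatment coefficients to (−∞, 0].

    Temperature-scaled negative softplus −scale·softplus(−raw/scale): smooth
    and strictly increasing in the raw value, with raw → +∞ giving an effect
    of 0⁻ (no benefit) and raw → −∞ unbounded benefit; enforces that
    more-acute placement never increases the hazard.  At scale 1 this is the
    plain negative softplus (value −log 2 at raw 0); smaller scales sharpen
    the hinge toward min(raw, 0), so a coefficient shrunk to raw = 0 implies
    a near-null effect (−scale·log 2) rather than a material one.
    """
    return -scale * ad.softplus(-raw / scale)
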