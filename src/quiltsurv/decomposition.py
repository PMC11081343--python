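"""Additive multi-order decomposition of parameters over a cohort lattice.

A regionally-varying parameter θ(κ) on a discrete lattice of cohorts is
written as a sum of interaction tensors,

    θ(κ) = θ(*,…,*) + Σ_d θ(κ_d,*) + Σ_{d<e} θ(κ_d,κ_e,*) + …,

truncated at a maximum interaction order.  The zero-order term is a global
value, first-order terms are per-dimension main effects, and so on.  Higher
orders are regularized toward zero by order-graded prior scales, so sparse
cells partially pool toward related lower-order effects; no sum-to-zero
identifiability constraints are imposed — the graded shrinkage priors are the
sole regularizer.

Priors come in two flavours: plain zero-mean normals (intercept-like
parameters) and the hierarchical horseshoe (regression slopes), the latter in
its non-centered form  coefficient = raw · local · global  with half-Cauchy
local and global scales.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad

__all__ = [
    "Lattice", "InteractionTerm", "DecomposedParameter", "PriorSpec",
    "enumerate_terms", "materialize", "materialize_table", "log_prior",
    "sample_prior", "pack", "unpack",
]

LOG_HALF_CAUCHY_CONST = math.log(2.0 / math.pi)


@dataclass(frozen=True)
class Lattice:
    """Discrete cohort grid: named dimensions with finite cardinalities."""

    names: tuple
    sizes: tuple

    def __post_init__(self):
        if len(self.names) != len(self.sizes) or not self.sizes:
            raise ValueError("lattice needs >= 1 named dimension")
        if any(int(s) < 1 for s in self.sizes):
            raise ValueError("lattice cardinalities must be >= 1")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))

    @property
    def ndim(self) -> int:
        return len(self.sizes)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.sizes))

    def cell_id(self, kappa) -> int:
        """Row-major flat index of a multi-index κ."""
        kappa = tuple(int(k) for k in kappa)
        if len(kappa) != self.ndim:
            raise IndexError(f"multi-index length {len(kappa)} != {self.ndim}")
        for k, s in zip(kappa, self.sizes):
            if not 0 <= k < s:
                raise IndexError(f"multi-index {kappa} outside lattice {self.sizes}")
        return int(np.ravel_multi_index(kappa, self.sizes))

    def cell_ids(self, kappas: np.ndarray) -> np.ndarray:
        """Vectorized row-major flat indices for an (n, D) array of multi-indices."""
        kappas = np.asarray(kappas, dtype=int)
        return np.ravel_multi_index(tuple(kappas.T), self.sizes)


def enumerate_terms(lattice: Lattice, max_order: int) -> list:
    """All dimension subsets of size <= max_order, by size then lexicographic."""
    if not 0 <= max_order <= lattice.ndim:
        raise ValueError(f"max_order {max_order} outside [0, {lattice.ndim}]")
    out = []
    for order in range(max_order + 1):
        out.extend(itertools.combinations(range(lattice.ndim), order))
    return out


@dataclass
class InteractionTerm:
    """One tensor of the decomposition, indexed by a subset of lattice dims."""

    dims: tuple
    values: np.ndarray  # shape = sizes[dims] + trailing_shape

    @property
    def order(self) -> int:
        return len(self.dims)


@dataclass
class DecomposedParameter:
    """The full truncated decomposition of one (scalar or vector) parameter."""

    lattice: Lattice
    max_order: int
    trailing_shape: tuple = ()
    terms: list = field(default_factory=list)
    order_scale: float = 0.5  # per-order geometric prior-scale multiplier

    @classmethod
    def zeros(cls, lattice, max_order, trailing_shape=(), order_scale=0.5):
        dp = cls(lattice, max_order, tuple(trailing_shape), [], order_scale)
        for dims in enumerate_terms(lattice, max_order):
            shape = tuple(lattice.sizes[d] for d in dims) + dp.trailing_shape
            dp.terms.append(InteractionTerm(dims, np.zeros(shape)))
        return dp

    def term(self, dims) -> InteractionTerm:
        dims = tuple(dims)
        for t in self.terms:
            if t.dims == dims:
                return t
        raise KeyError(f"no term for dims {dims}")

    def validate(self):
        expected = enumerate_terms(self.lattice, self.max_order)
        got = [t.dims for t in self.terms]
        if got != expected:
            raise ValueError("terms do not match canonical enumeration")
        for t in self.terms:
            shape = tuple(self.lattice.sizes[d] for d in t.dims) + self.trailing_shape
            if tuple(np.shape(t.values)) != shape:
                raise ValueError(f"term {t.dims} has shape {np.shape(t.values)}, "
                                 f"expected {shape}")

    # -- serialization (exact float round-trip via repr-based JSON) -----
    def to_json(self) -> str:
        return json.dumps({
            "lattice": {"names": list(self.lattice.names),
                        "sizes": list(self.lattice.sizes)},
            "max_order": self.max_order,
            "trailing_shape": list(self.trailing_shape),
            "order_scale": self.order_scale,
            "terms": [{"dims": list(t.dims),
                       "values": np.asarray(t.values).tolist()}
                      for t in self.terms],
        })

    @classmethod
    def from_json(cls, text: str) -> "DecomposedParameter":
        d = json.loads(text)
        lat = Lattice(tuple(d["lattice"]["names"]), tuple(d["lattice"]["sizes"]))
        dp = cls(lat, d["max_order"], tuple(d["trailing_shape"]),
                 [InteractionTerm(tuple(t["dims"]),
                                  np.asarray(t["values"], dtype=np.float64))
                  for t in d["terms"]],
                 d["order_scale"])
        dp.validate()
        return dp


def _term_broadcast_shape(lattice: Lattice, dims, trailing_shape):
    return tuple(lattice.sizes[d] if d in dims else 1
                 for d in range(lattice.ndim)) + tuple(trailing_shape)


def materialize_table(dp: DecomposedParameter, term_values=None):
    """θ materialized on the whole lattice: shape sizes + trailing_shape.

    `term_values` optionally overrides the stored tensors (e.g. autodiff
    tensors during inference); entries must follow the canonical term order.
    """
    values = [t.values for t in dp.terms] if term_values is None else term_values
    total = None
    for t, v in zip(dp.terms, values):
        shape = _term_broadcast_shape(dp.lattice, t.dims, dp.trailing_shape)
        piece = ad.reshape(v, shape)
        total = piece if total is None else total + piece
    full = tuple(dp.lattice.sizes) + tuple(dp.trailing_shape)
    if isinstance(total, ad.Tensor):
        return total + ad.Tensor(np.zeros(full))
    return np.broadcast_to(total, full).copy()


def materialize(dp: DecomposedParameter, kappa):
    """θ(κ): the additive sum of all included terms at one lattice cell."""
    kappa = tuple(int(k) for k in kappa)
    dp.lattice.cell_id(kappa)  # bounds check
    out = np.zeros(dp.trailing_shape)
    for t in dp.terms:
        idx = tuple(kappa[d] for d in t.dims)
        out = out + np.asarray(t.values)[idx]
    return float(out) if dp.trailing_shape == () else out


@dataclass(frozen=True)
class PriorSpec:
    """Prior over decomposition tensors.

    kind 'normal': term entries ~ N(0, (base_scale·order_scale^order)^2).
    kind 'horseshoe': coefficient = raw·local·global·base_scale·order_scale^order
    with raw ~ N(0,1) and local, global ~ half-Cauchy(0,1); evaluated on the
    raw/scale latents supplied alongside.
    """

    kind: str = "normal"
    base_scale: float = 1.0

    def __post_init__(self):
        if self.kind not in ("normal", "horseshoe"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.base_scale <= 0:
            raise ValueError("prior scale must be positive")


def _normal_logpdf(x, scale):
    return ad.tsum(-0.5 * ad.square(x / scale)) \
        - float(np.size(ad.value_of(x))) * (math.log(scale) + 0.5 * math.log(2 * math.pi))


def _half_cauchy_logpdf_sum(x):
    # standard half-Cauchy on (0, inf)
    return ad.tsum(-ad.log1p(ad.square(x))) \
        + float(np.size(ad.value_of(x))) * LOG_HALF_CAUCHY_CONST


def log_prior(dp: DecomposedParameter, prior: PriorSpec, term_values=None,
              local_scales=None, global_scale=None):
    """Joint log prior density of all term tensors of `dp`.

    For 'normal', evaluated at the term tensors themselves.  For 'horseshoe',
    `term_values` are the *raw* (standard-normal) latents, `local_scales`
    matches the terms elementwise and `global_scale` is a positive scalar;
    the implied coefficient is raw·local·global·(per-order scale).
    """
    values = [t.values for t in dp.terms] if term_values is None else term_values
    total = 0.0
    if prior.kind == "normal":
        for t, v in zip(dp.terms, values):
            scale = prior.base_scale * dp.order_scale ** t.order
            total = total + _normal_logpdf(v, scale)
        return total
    # horseshoe: raws are standard normal; scales carry half-Cauchy priors
    if local_scales is None or global_scale is None:
        raise ValueError("horseshoe prior needs local_scales and global_scale")
    for v in values:
        total = total + _normal_logpdf(v, 1.0)
    for lam in local_scales:
        total = total + _half_cauchy_logpdf_sum(lam)
    total = total + _half_cauchy_logpdf_sum(global_scale)
    return total


def horseshoe_coefficients(dp: DecomposedParameter, prior: PriorSpec,
                           raw_values, local_scales, global_scale):
    """Map non-centered horseshoe latents to coefficient tensors per term."""
    out = []
    for t, raw, lam in zip(dp.terms, raw_values, local_scales):
        scale = prior.base_scale * dp.order_scale ** t.order
        out.append(raw * lam * (global_scale * scale))
    return out


def sample_prior(dp: DecomposedParameter, prior: PriorSpec, rng: np.random.Generator):
    """Draw one set of coefficient tensors from the prior (for MC checks)."""
    draws = []
    for t in dp.terms:
        shape = tuple(dp.lattice.sizes[d] for d in t.dims) + dp.trailing_shape
        scale = prior.base_scale * dp.order_scale ** t.order
        if prior.kind == "normal":
            draws.append(rng.normal(0.0, scale, size=shape))
        else:
            raw = rng.normal(size=shape)
            lam = np.abs(rng.standard_cauchy(size=shape))
            glob = abs(rng.standard_cauchy())
            draws.append(raw * lam * glob * scale)
    return draws


def pack(dp: DecomposedParameter) -> np.ndarray:
    """Flatten all term tensors (canonical order) into one vector."""
    dp.validate()
    if not dp.terms:
        return np.zeros(0)
    return np.concatenate([np.asarray(t.values, dtype=np.float64).ravel()
                           for t in dp.terms])


def unpack(dp: DecomposedParameter, flat: np.ndarray) -> DecomposedParameter:
    """Inverse of :func:`pack`; returns a new DecomposedParameter."""
    flat = np.asarray(flat, dtype=np.float64)
    expected = sum(int(np.prod(np.shape(t.values))) for t in dp.terms)
    if flat.shape != (expected,):
        raise ValueError(f"flat vector length {flat.shape} != ({expected},)")
    out = DecomposedParameter(dp.lattice, dp.max_order, dp.trailing_shape, [],
                              dp.order_scale)
    pos = 0
    for t in dp.terms:
        size = int(np.prod(np.shape(t.values)))
        out.terms.append(InteractionTerm(
            t.dims, flat[pos:pos + size].reshape(np.shape(t.values)).copy()))
        pos += size
    return out
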