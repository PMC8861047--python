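"""Embedding of target properties into the conditional feature vector y.

Each condition is embedded by its own small network: scalar targets are
expanded on a Gaussian radial basis over [lambda_min, lambda_max] with
spacing d_omega (values outside the range are allowed — the basis decays
smoothly, which is what permits targeting beyond the training regime);
vector-valued targets (e.g., 1024-bit fingerprints) feed an MLP directly;
atomic compositions weight learnable per-element embeddings by the element
fractions and concatenate them in a fixed global type order.  The per-
condition features are concatenated in declared order and aggregated by a
final MLP into y (length D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, concat
from .chem_data import Composition
from .representation import NetworkParams, mlp

__all__ = ["ConditionSpec", "ConditionSet", "expand_scalar", "scalar_basis",
           "embed_vector", "embed_composition", "aggregate_conditions",
           "condition_vector", "spec_to_dict", "spec_from_dict",
           "default_condition_specs"]


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    kind: str                      # "scalar" | "vector" | "composition"
    lam_min: float = 0.0           # scalar kind: basis range and spacing,
    lam_max: float = 1.0           # in the units of the property
    d_omega: float = 0.1
    length: int = 0                # vector kind: input length
    type_order: tuple[int, ...] = ()   # composition kind: global element order
    g_dim: int = 8                 # composition kind: per-element embedding width
    widths: tuple[int, ...] = (32,)    # embedding MLP widths; last = output

    def __post_init__(self):
        if self.kind not in ("scalar", "vector", "composition"):
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.kind == "scalar":
            if not (self.lam_min < self.lam_max) or self.d_omega <= 0:
                raise ValueError("scalar condition needs lam_min < lam_max, "
                                 "d_omega > 0")
            if self.n_basis < 2:
                raise ValueError("scalar basis needs at least 2 centers")
        if self.kind == "vector" and self.length < 1:
            raise ValueError("vector condition needs a positive length")
        if self.kind == "composition" and not self.type_order:
            raise ValueError("composition condition needs a type order")

    @property
    def n_basis(self) -> int:
        # centers at lam_min + l*d_omega for 0 <= l <= (lam_max-lam_min)/d_omega
        return int(np.floor((self.lam_max - self.lam_min) / self.d_omega + 1e-9)) + 1

    @property
    def in_width(self) -> int:
        if self.kind == "scalar":
            return self.n_basis
        if self.kind == "vector":
            return self.length
        return self.g_dim * len(self.type_order)

    @property
    def out_width(self) -> int:
        return self.widths[-1]


def spec_to_dict(spec: ConditionSpec) -> dict:
    return {"name": spec.name, "kind": spec.kind, "lam_min": spec.lam_min,
            "lam_max": spec.lam_max, "d_omega": spec.d_omega,
            "length": spec.length, "type_order": list(spec.type_order),
            "g_dim": spec.g_dim, "widths": list(spec.widths)}


def spec_from_dict(d: dict) -> ConditionSpec:
    d = dict(d)
    d["type_order"] = tuple(d.get("type_order", ()))
    d["widths"] = tuple(d["widths"])
    return ConditionSpec(**d)


def default_condition_specs(name: str, **overrides) -> ConditionSpec:
    """Documented defaults for the properties used in this package."""
    presets = {
        "gap": dict(kind="scalar", lam_min=0.0, lam_max=12.0, d_omega=0.25),
        "polarizability": dict(kind="scalar", lam_min=0.0, lam_max=120.0,
                               d_omega=1.0),
        "relative_atomic_energy": dict(kind="scalar", lam_min=-0.3,
                                       lam_max=0.3, d_omega=0.01),
        "fingerprint": dict(kind="vector", length=1024, widths=(128, 64)),
        "composition": dict(kind="composition", type_order=(1, 6, 7, 8, 9)),
        "n_atoms": dict(kind="scalar", lam_min=1.0, lam_max=35.0, d_omega=1.0),
    }
    if name not in presets:
        raise KeyError(f"no default condition spec named {name!r}")
    kw = dict(presets[name])
    kw.update(overrides)
    return ConditionSpec(name=name, **kw)


@dataclass
class ConditionSet:
    """Ordered target values; order and kinds must match the model's specs."""

    values: dict[str, object] = field(default_factory=dict)

    def value_for(self, spec: ConditionSpec):
        if spec.name not in self.values:
            raise KeyError(f"missing condition value {spec.name!r}")
        return self.values[spec.name]


def scalar_basis(lam: float, spec: ConditionSpec) -> np.ndarray:
    """Gaussian radial basis: entry l = exp(-(lam - (lam_min + l*d_omega))^2
    / (2 d_omega^2))."""
    if not np.isfinite(lam):
        raise ValueError(f"non-finite scalar condition {spec.name!r}")
    centers = spec.lam_min + spec.d_omega * np.arange(spec.n_basis)
    return np.exp(-((lam - centers) ** 2) / (2.0 * spec.d_omega ** 2))


def expand_scalar(lam: float, spec: ConditionSpec,
                  params: dict[str, Tensor]) -> Tensor:
    """Basis expansion followed by the spec's embedding MLP; (1, out) Tensor."""
    if spec.kind != "scalar":
        raise ValueError(f"{spec.name!r} is not a scalar condition")
    basis = Tensor(scalar_basis(float(lam), spec).reshape(1, -1))
    return mlp(basis, params, f"cond/{spec.name}", len(spec.widths))


def embed_vector(lam_vec, spec: ConditionSpec,
                 params: dict[str, Tensor]) -> Tensor:
    if spec.kind != "vector":
        raise ValueError(f"{spec.name!r} is not a vector condition")
    v = np.asarray(lam_vec, dtype=float).reshape(-1)
    if v.shape[0] != spec.length:
        raise ValueError(f"condition {spec.name!r} expects length {spec.length}, "
                         f"got {v.shape[0]}")
    return mlp(Tensor(v.reshape(1, -1)), params, f"cond/{spec.name}",
               len(spec.widths))


def embed_composition(comp: Composition, spec: ConditionSpec,
                      params: dict[str, Tensor]) -> Tensor:
    """Fraction-weighted type embeddings, concatenated in the global type
    order, then the embedding MLP.  Depends on fractions only, not on size;
    the total atom count is a separate scalar condition."""
    if spec.kind != "composition":
        raise ValueError(f"{spec.name!r} is not a composition condition")
    fracs = comp.fractions
    unknown = set(fracs) - set(spec.type_order)
    if unknown:
        raise KeyError(f"composition contains element(s) {sorted(unknown)} "
                       f"outside the type order {spec.type_order}")
    g = params[f"cond/{spec.name}/g"]          # (n_types, g_dim)
    weights = np.array([[fracs.get(z, 0.0)] for z in spec.type_order])
    weighted = g * Tensor(weights)             # broadcast over g_dim
    flat = weighted.reshape(1, spec.g_dim * len(spec.type_order))
    return mlp(flat, params, f"cond/{spec.name}", len(spec.widths))


def _embed_one(value, spec: ConditionSpec, params) -> Tensor:
    if spec.kind == "scalar":
        return expand_scalar(value, spec, params)
    if spec.kind == "vector":
        return embed_vector(value, spec, params)
    return embed_composition(value, spec, params)


def aggregate_conditions(features: list[Tensor], net: NetworkParams) -> Tensor:
    """y = mlp(f_1 (+) ... (+) f_k): concatenation is ordered, so permuting
    the declared property order changes y."""
    cfg = net.config
    if len(features) != len(cfg.conditions):
        raise ValueError(f"model declares {len(cfg.conditions)} conditions, "
                         f"got {len(features)} feature blocks")
    if not features:
        raise ValueError("a conditional model needs at least one condition")
    stacked = concat(features, axis=1)
    return mlp(stacked, net.params, "agg", len(cfg.agg_hidden) + 1)


def condition_vector(conditions: ConditionSet, net: NetworkParams) -> Tensor:
    """The conditional features y (shape (1, D)) for a set of target values."""
    feats = [_embed_one(conditions.value_for(spec), spec, net.params)
             for spec in net.config.conditions]
    return aggregate_conditions(feats, net)
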