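"""Parameter initialization and a convenience facade over the network parts."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor
from .conditioning import ConditionSet, condition_vector
from .model_heads import distance_distributions, type_distribution
from .representation import ModelConfig, NetworkParams, featurize, mlp_shapes

__all__ = ["init_params", "AtomPlacementModel"]


def _init_mlp(params, prefix, widths, rng):
    for i, (n_in, n_out) in enumerate(mlp_shapes(widths)):
        params[f"{prefix}/W{i}"] = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(n_in), (n_in, n_out)),
            requires_grad=True)
        params[f"{prefix}/b{i}"] = Tensor(np.zeros(n_out), requires_grad=True)


def init_params(cfg: ModelConfig, rng: np.random.Generator) -> NetworkParams:
    """Fresh parameters for a config; weights ~ N(0, 1/fan_in), zero biases,
    unit-normal type embeddings."""
    F = cfg.n_features
    p: dict[str, Tensor] = {}
    # type embeddings: chemical types + origin + focus tokens
    p["embed/E"] = Tensor(rng.normal(0.0, 1.0, (cfg.n_chemical + 2, F)),
                          requires_grad=True)
    for t in range(cfg.n_interactions):
        _init_mlp(p, f"int{t}/filter", (cfg.n_rbf, F, F), rng)
        p[f"int{t}/in/W"] = Tensor(rng.normal(0.0, 1.0 / np.sqrt(F), (F, F)),
                                   requires_grad=True)
        p[f"int{t}/in/b"] = Tensor(np.zeros(F), requires_grad=True)
        _init_mlp(p, f"int{t}/out", (F, F, F), rng)
    for spec in cfg.conditions:
        if spec.kind == "composition":
            p[f"cond/{spec.name}/g"] = Tensor(
                rng.normal(0.0, 1.0, (len(spec.type_order), spec.g_dim)),
                requires_grad=True)
        _init_mlp(p, f"cond/{spec.name}", (spec.in_width, *spec.widths), rng)
    in_agg = sum(s.out_width for s in cfg.conditions)
    if cfg.conditions:
        _init_mlp(p, "agg", (in_agg, *cfg.agg_hidden, cfg.d_condition), rng)
    _init_mlp(p, "type_head", (F + cfg.d_condition, *cfg.type_head_hidden,
                               cfg.n_type_classes), rng)
    _init_mlp(p, "dist_head", (F + cfg.d_condition, *cfg.dist_head_hidden,
                               cfg.n_bins), rng)
    if not cfg.tie_next_embedding:
        p["g_next"] = Tensor(rng.normal(0.0, 1.0, (cfg.n_chemical, F)),
                             requires_grad=True)
    return NetworkParams(config=cfg, params=p)


class AtomPlacementModel:
    """Bundles config + parameters and exposes the per-step predictions."""

    def __init__(self, net: NetworkParams):
        self.net = net

    @property
    def config(self) -> ModelConfig:
        return self.net.config

    @staticmethod
    def create(cfg: ModelConfig, seed: int = 0) -> "AtomPlacementModel":
        return AtomPlacementModel(init_params(cfg, np.random.default_rng(seed)))

    def condition_vector(self, conditions: ConditionSet) -> Tensor:
        return condition_vector(conditions, self.net)

    def featurize(self, positions, types) -> Tensor:
        return featurize(positions, types, self.net)

    def type_distribution(self, X: Tensor, y: Tensor) -> Tensor:
        return type_distribution(X, y, self.net)

    def distance_distributions(self, X: Tensor, y: Tensor,
                               next_type: int) -> Tensor:
        return distance_distributions(X, y, next_type, self.net)
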