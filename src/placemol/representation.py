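"""Invariant atom-wise representation and shared network building blocks.

Structures (atoms plus the two auxiliary tokens, which are treated exactly
like atoms) are featurized with a SchNet-style network: a learned embedding
per type followed by interaction blocks whose continuous-filter convolutions
mix neighboring features through filters generated from Gaussian-expanded
interatomic distances with a smooth cosine cutoff.  Because only pairwise
distances enter, the features are exactly invariant to global rotation and
translation, and permuting input rows permutes the output rows identically.

`ModelConfig` + `NetworkParams` carry everything the downstream heads and the
sampler need; checkpoints are single .npz files with the config embedded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, concat
from .trajectory import token_codes

__all__ = ["shifted_softplus", "mlp", "mlp_shapes", "ModelConfig",
           "NetworkParams", "featurize", "save_checkpoint", "load_checkpoint"]


def shifted_softplus(x):
    """ssp(x) = ln(e^x/2 + 1/2); ssp(0) = 0, asymptotically x - ln 2."""
    if isinstance(x, Tensor):
        return ad.ssp(x)
    return np.logaddexp(0.0, np.asarray(x, dtype=float)) - np.log(2.0)


def mlp(x: Tensor, params: dict[str, Tensor], prefix: str, n_layers: int) -> Tensor:
    """Successive affine layers with shifted softplus between them (none after
    the last).  Layer i uses params f"{prefix}/W{i}" (in x out) and f"{prefix}/b{i}"."""
    h = Tensor.as_tensor(x)
    for i in range(n_layers):
        h = h @ params[f"{prefix}/W{i}"] + params[f"{prefix}/b{i}"]
        if i < n_layers - 1:
            h = ad.ssp(h)
    return h


def mlp_shapes(widths: tuple[int, ...]) -> list[tuple[int, int]]:
    """(in, out) per layer for a width chain like (in, hidden..., out)."""
    return [(widths[i], widths[i + 1]) for i in range(len(widths) - 1)]


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the full generative network.

    Presets: `tiny` (F=16, 2 interaction blocks) runs the whole pipeline in
    seconds and is what the test-suite experiments use; `full_scale` is the
    full-size configuration (F=128, 9 blocks, 300 distance bins of 0.05 A).
    """

    chemical_types: tuple[int, ...] = (1, 6, 7, 8, 9)
    n_features: int = 128          # F
    n_interactions: int = 9
    n_rbf: int = 50
    cutoff: float = 5.0            # A, interaction cutoff
    n_bins: int = 300              # L
    bin_width: float = 0.05        # d-mu, A
    conditions: tuple = ()         # ConditionSpec tuple (see conditioning)
    d_condition: int = 64          # D
    type_head_hidden: tuple[int, ...] = (64,)
    dist_head_hidden: tuple[int, ...] = (128,)
    agg_hidden: tuple[int, ...] = (64,)
    tie_next_embedding: bool = False

    def __post_init__(self):
        object.__setattr__(self, "chemical_types",
                           tuple(sorted(int(z) for z in self.chemical_types)))

    # -- derived vocabulary ---------------------------------------------------
    @property
    def n_chemical(self) -> int:
        return len(self.chemical_types)

    @property
    def n_type_classes(self) -> int:
        """|Z^all| = chemical types + stop marker."""
        return self.n_chemical + 1

    @property
    def stop_index(self) -> int:
        return self.n_chemical  # stop marker is last

    @property
    def token_type_codes(self) -> tuple[int, int]:
        return token_codes(self.chemical_types)

    def type_index(self, code: int) -> int:
        """Embedding row for a chemical type or token code."""
        origin, focus = self.token_type_codes
        if code == origin:
            return self.n_chemical
        if code == focus:
            return self.n_chemical + 1
        try:
            return self.chemical_types.index(int(code))
        except ValueError:
            raise KeyError(f"unknown type code {code}")

    def type_indices(self, codes) -> np.ndarray:
        return np.array([self.type_index(int(c)) for c in codes], dtype=np.intp)

    @staticmethod
    def tiny(conditions=(), chemical_types=(1, 6, 7, 8, 9)) -> "ModelConfig":
        return ModelConfig(chemical_types=chemical_types, n_features=16,
                           n_interactions=2, n_rbf=25, cutoff=6.0,
                           n_bins=120, bin_width=0.1, conditions=tuple(conditions),
                           d_condition=16, type_head_hidden=(32,),
                           dist_head_hidden=(64,), agg_hidden=(32,))

    @staticmethod
    def full_scale(conditions=()) -> "ModelConfig":
        return ModelConfig(conditions=tuple(conditions))


@dataclass
class NetworkParams:
    """All learnable parameters plus the config they were built for."""

    config: ModelConfig
    params: dict[str, Tensor]

    def copy_data(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_data(self, data: dict[str, np.ndarray]) -> None:
        for k, arr in data.items():
            self.params[k].data[...] = arr

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())


# ---------------------------------------------------------------------------
# Featurizer
# ---------------------------------------------------------------------------

def _rbf_expand(d: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    centers = np.linspace(0.0, cfg.cutoff, cfg.n_rbf)
    gamma = 1.0 / (2.0 * (centers[1] - centers[0]) ** 2)
    return np.exp(-gamma * (d[..., None] - centers) ** 2)


def _cosine_cutoff(d: np.ndarray, cutoff: float) -> np.ndarray:
    out = 0.5 * (np.cos(np.pi * np.clip(d / cutoff, 0.0, 1.0)) + 1.0)
    out[d >= cutoff] = 0.0
    return out


def featurize(partial_positions: np.ndarray, partial_types,
              net: NetworkParams) -> Tensor:
    """Atom-wise features X (rows aligned with the input order, tokens first).

    `partial_types` are raw codes (token codes + atomic numbers).  Unknown
    codes raise KeyError.  Output is an (m, F) Tensor differentiable w.r.t.
    the network parameters; geometry enters only through pairwise distances.
    """
    cfg, P = net.config, net.params
    pos = np.asarray(partial_positions, dtype=float).reshape(-1, 3)
    idx = cfg.type_indices(partial_types)
    m = pos.shape[0]
    if m < 1:
        raise ValueError("featurize needs at least one atom or token")

    diff = pos[:, None, :] - pos[None, :, :]
    d = np.sqrt((diff ** 2).sum(-1))
    rbf = _rbf_expand(d, cfg)                       # (m, m, n_rbf), constant
    fcut = _cosine_cutoff(d, cfg.cutoff)
    np.fill_diagonal(fcut, 0.0)                     # no self-interaction

    x = P["embed/E"][idx]                           # (m, F)
    rbf_flat = Tensor(rbf.reshape(m * m, cfg.n_rbf))
    fcut_t = Tensor(fcut[..., None])
    for t in range(cfg.n_interactions):
        filt = mlp(rbf_flat, P, f"int{t}/filter", 2)
        filt = filt.reshape(m, m, cfg.n_features) * fcut_t
        h = x @ P[f"int{t}/in/W"] + P[f"int{t}/in/b"]
        msg = (filt * h.reshape(1, m, cfg.n_features)).sum(axis=1)
        v = msg @ P[f"int{t}/out/W0"] + P[f"int{t}/out/b0"]
        v = ad.ssp(v)
        v = v @ P[f"int{t}/out/W1"] + P[f"int{t}/out/b1"]
        x = x + v
    return x


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | Path, net: NetworkParams,
                    extra: dict | None = None) -> None:
    from .conditioning import spec_to_dict

    cfg = dataclasses.asdict(net.config)
    cfg["conditions"] = [spec_to_dict(s) for s in net.config.conditions]
    meta = {"version": _CHECKPOINT_VERSION, "config": cfg, "extra": extra or {}}
    arrays = {f"param/{k}": p.data for k, p in net.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> NetworkParams:
    from .conditioning import spec_from_dict
    from .model import init_params

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        cfg_d = dict(meta["config"])
        cfg_d["conditions"] = tuple(spec_from_dict(d) for d in cfg_d["conditions"])
        for key in ("chemical_types", "type_head_hidden", "dist_head_hidden",
                    "agg_hidden"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = ModelConfig(**cfg_d)
        net = init_params(cfg, np.random.default_rng(0))
        stored = {k[len("param/"):]: data[k] for k in data.files
                  if k.startswith("param/")}
    if set(stored) != set(net.params):
        raise ValueError("checkpoint parameter names do not match the config")
    for k, arr in stored.items():
        if net.params[k].data.shape != arr.shape:
            raise ValueError(f"shape mismatch for parameter {k!r}")
        net.params[k].data[...] = arr
    return net
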