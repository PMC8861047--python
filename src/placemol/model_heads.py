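"""Output heads: next-type distribution and per-neighbor distance distributions.

The type head scores every type class (chemical types plus the stop marker)
from each atom-wise feature row concatenated with the conditional features,
softmaxes per row and averages the row-wise softmaxes — tokens contribute
rows like ordinary atoms.  The distance head gates each feature row with a
learnable embedding of the sampled next type (Hadamard product), concatenates
the conditional features and softmaxes over L distance bins of width d-mu.
Both heads inherit exact rigid-motion invariance from the featurizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, concat
from .representation import NetworkParams, mlp
from .trajectory import STOP_CODE

__all__ = ["DistanceBinning", "bin_index", "bin_centers",
           "type_distribution", "distance_distributions"]


@dataclass(frozen=True)
class DistanceBinning:
    """L bins of width d_mu; bin l (1-based) is centered at (l-1)*d_mu."""

    n_bins: int
    width: float

    def __post_init__(self):
        if self.n_bins < 2 or self.width <= 0:
            raise ValueError("need n_bins >= 2 and width > 0")

    @staticmethod
    def of(net_or_cfg) -> "DistanceBinning":
        cfg = getattr(net_or_cfg, "config", net_or_cfg)
        return DistanceBinning(cfg.n_bins, cfg.bin_width)


def bin_index(d, binning: DistanceBinning):
    """Map distances (A) to 1-based bin indices: ceil((d + d_mu/2) / d_mu),
    clipped to the overflow bin L beyond (L-1)*d_mu.  Vectorized."""
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be non-negative")
    idx = np.ceil((d_arr + 0.5 * binning.width) / binning.width).astype(int)
    idx = np.maximum(idx, 1)  # d == 0 -> ceil(1/2) == 1
    idx = np.where(d_arr > (binning.n_bins - 1) * binning.width,
                   binning.n_bins, idx)
    if np.isscalar(d) or d_arr.ndim == 0:
        return int(idx)
    return idx


def bin_centers(binning: DistanceBinning) -> np.ndarray:
    return binning.width * np.arange(binning.n_bins)


def _with_conditions(X: Tensor, y: Tensor) -> Tensor:
    m = X.shape[0]
    y_rows = Tensor(np.ones((m, 1))) @ y     # broadcast (1, D) to every row
    return concat([X, y_rows], axis=1)


def type_distribution(X: Tensor, y: Tensor, net: NetworkParams) -> Tensor:
    """p(Z_i = z | X, y): per-row softmax over type classes, averaged
    uniformly over all rows (tokens included)."""
    cfg = net.config
    scores = mlp(_with_conditions(X, y), net.params, "type_head",
                 len(cfg.type_head_hidden) + 1)          # (m, |Z^all|)
    probs = ad.softmax(scores, axis=1)
    return probs.mean(axis=0)


def next_type_embedding(next_type: int, net: NetworkParams) -> Tensor:
    cfg = net.config
    if next_type == STOP_CODE:
        raise ValueError("the distance head is never invoked on stop steps")
    chem_idx = cfg.chemical_types.index(int(next_type))
    if cfg.tie_next_embedding:
        return net.params["embed/E"][np.array([chem_idx])]
    return net.params["g_next"][np.array([chem_idx])]


def distance_distributions(X: Tensor, y: Tensor, next_type: int,
                           net: NetworkParams) -> Tensor:
    """Row-stochastic (m, L) matrix: p(r_ij in bin l | x_j, y, Z_i) for every
    preceding atom/token j, given the already-sampled chemical next type."""
    cfg = net.config
    g = next_type_embedding(next_type, net)             # (1, F)
    gated = X * g                                       # Hadamard, broadcast
    scores = mlp(_with_conditions(gated, y), net.params, "dist_head",
                 len(cfg.dist_head_hidden) + 1)         # (m, L)
    return ad.softmax(scores, axis=1)
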