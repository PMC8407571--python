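"""Structural analytics of sparse connectivity.

Training under evolutionary rewiring reshapes the connection graph — the
in-degree distribution flattens under dendritic normalisation, efferent
contacts concentrate on informative input pixels, and the recurrent mask
develops short average path lengths.  This module measures those
structures: degree/weight histograms, per-pixel efferent maps, the directed
average shortest path length (ASPL), and the fraction of hidden neurons
reached by both input units of the recurrent binary-addition network.

The ASPL convention: directed breadth-first distances over ordered node
pairs (i ≠ j), with pairs that have no path excluded from the mean;
self-loops never contribute.  A symmetrised variant is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.stats import chisquare

from .sparse_net import RecurrentNetwork, SparseLayer

__all__ = [
    "DirectedConnectivity",
    "average_shortest_path",
    "degree_and_weight_stats",
    "in_degree_chisquare",
    "efferent_map",
    "both_input_fraction",
]


@dataclass(frozen=True)
class DirectedConnectivity:
    """Unweighted directed edge structure of a recurrent (or square) mask."""

    adjacency: np.ndarray  # bool (n, n)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        object.__setattr__(self, "adjacency", adj)

    @classmethod
    def from_layer(cls, layer: SparseLayer) -> "DirectedConnectivity":
        return cls(layer.mask.copy())

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


def average_shortest_path(g: DirectedConnectivity, symmetrise: bool = False) -> float:
    """Mean BFS distance over reachable ordered pairs (i ≠ j).

    Self-loops are ignored; unreachable pairs are excluded from the mean.
    Raises if no ordered pair is reachable at all.
    """
    if g.n < 2:
        raise ValueError("need at least 2 nodes")
    adj = g.adjacency.copy()
    np.fill_diagonal(adj, False)
    if symmetrise:
        adj = adj | adj.T
    dist = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=True)
    np.fill_diagonal(dist, np.inf)
    finite = np.isfinite(dist)
    if not finite.any():
        raise ValueError("no reachable ordered pairs: path length undefined")
    return float(dist[finite].mean())


def degree_and_weight_stats(
    layer: SparseLayer,
    dataset=None,
    degree_bins=None,
    weight_bins=None,
    input_bins=None,
) -> dict:
    """Histograms of in-degree, |effective weight| and mean weighted input.

    The weighted-input statistic is the per-neuron mean of ``z_i - b_i``
    over a supplied evaluation set (required for that histogram only).
    Bin edges are configurable; defaults cover the observed ranges.
    Returns a dict of ``(counts, edges)`` pairs plus the raw statistics, and
    a chi-squared comparison is left to the caller (the raw in-degrees are
    included for that purpose).
    """
    n = layer.n
    w = np.abs(layer.effective_weights()[layer.mask])
    if degree_bins is None:
        degree_bins = np.arange(-0.5, layer.fan_in + 1.5)
    if weight_bins is None:
        weight_bins = np.linspace(0.0, max(w.max(), 1e-12), 30)
    out = {
        "in_degree": np.histogram(n, bins=degree_bins),
        "abs_weight": np.histogram(w, bins=weight_bins),
        "in_degrees_raw": n,
        "abs_weights_raw": w,
    }
    if dataset is not None:
        x = np.asarray(dataset, dtype=float)
        if x.shape[0] == 0:
            raise ValueError("empty dataset for the weighted-input statistic")
        z = x @ layer.effective_weights()
        mean_input = z.mean(axis=0)
        if input_bins is None:
            input_bins = np.linspace(mean_input.min(), mean_input.max() + 1e-12, 30)
        out["mean_weighted_input"] = np.histogram(mean_input, bins=input_bins)
        out["mean_weighted_input_raw"] = mean_input
    return out


def in_degree_chisquare(layer: SparseLayer, epsilon: float) -> float:
    """P-value of a chi-squared test of the in-degrees against Binomial(fan_in, ε).

    Adjacent bins are pooled until every expected count is at least 5.
    Used to validate fresh Erdős–Rényi layers (fresh layers guarantee
    in-degree ≥ 1 by construction, which the test tolerates at usual sizes).
    """
    from scipy.stats import binom

    n = layer.n
    ks = np.arange(layer.fan_in + 1)
    expected = binom.pmf(ks, layer.fan_in, epsilon) * layer.m
    observed = np.bincount(n, minlength=layer.fan_in + 1).astype(float)
    # pool low-expectation tails
    obs_pooled, exp_pooled = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5:
            obs_pooled.append(o_acc)
            exp_pooled.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and exp_pooled:
        obs_pooled[-1] += o_acc
        exp_pooled[-1] += e_acc
    obs_pooled = np.asarray(obs_pooled)
    exp_pooled = np.asarray(exp_pooled) * obs_pooled.sum() / np.sum(exp_pooled)
    return float(chisquare(obs_pooled, exp_pooled).pvalue)


def efferent_map(layer: SparseLayer, image_shape: tuple[int, int]) -> np.ndarray:
    """Outgoing-connection count of each input unit, on the image grid."""
    if int(np.prod(image_shape)) != layer.fan_in:
        raise ValueError("image_shape does not match the layer fan-in")
    return layer.mask.sum(axis=1).reshape(image_shape)


def both_input_fraction(rnet: RecurrentNetwork) -> float:
    """Fraction of hidden neurons receiving contacts from both input units.

    Only meaningful for the sparse-feedforward recurrent variant; the dense
    variant trivially connects everything and is rejected.
    """
    if rnet.dense_input:
        raise ValueError("both-input fraction is not applicable to dense feedforward input")
    both = rnet.mask_in[0] & rnet.mask_in[1]
    return float(both.mean())
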