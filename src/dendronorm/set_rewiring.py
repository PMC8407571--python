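"""Sparse Evolutionary Training: excise the weakest connections, regrow at random.

After each training epoch a fraction ζ of the weakest contacts in a
connection pool is removed and the same number of new connections is created
uniformly at random among the currently absent pairs, with fresh weights
(standard normal by default).  A pool is one or more weight streams — a
single sparse layer, or the feedforward and recurrent streams of a
recurrent network considered together, in which case weak connections of
the two streams compete for survival.

"Weakest" defaults to the smallest absolute *effective* weight |w| (after
normalisation), since the effective weight is the functional strength of
the contact; under the dendritic scheme this makes a contact's survival
depend on its neuron's in-degree, the mechanism that flattens the in-degree
distribution during training.  Ranking on the raw |v| instead is available
via ``metric="local"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RewireReport", "rewire"]


@dataclass(frozen=True)
class RewireReport:
    """Summary of one rewiring event; excision and regrowth counts balance."""

    excised: int
    regrown: int
    per_stream_counts: tuple[dict, ...]

    def __post_init__(self) -> None:
        if self.excised != self.regrown:
            raise ValueError("connection count not conserved")


def rewire(
    streams,
    zeta: float,
    rng: np.random.Generator,
    weight_sampler=None,
    metric: str = "effective",
    forbidden=None,
) -> RewireReport:
    """Excise the ⌊ζ·E⌋ weakest contacts of the pooled streams and regrow.

    ``streams`` is a sequence of layer-like objects exposing ``v``, ``mask``
    and ``effective_weights()``; their arrays are modified in place.  Ties
    in |w| are broken by a random permutation.  ``forbidden`` optionally
    gives, per stream, a boolean array of positions that must never be
    created (e.g. self-connections).  Raises if the pool has fewer absent
    pairs than connections to regrow.
    """
    if not 0 <= zeta < 1:
        raise ValueError("zeta must lie in [0, 1)")
    if metric not in ("effective", "local"):
        raise ValueError("metric must be 'effective' or 'local'")
    if weight_sampler is None:
        weight_sampler = lambda r, size: r.standard_normal(size)
    if forbidden is None:
        forbidden = [None] * len(streams)

    masks = [s.mask for s in streams]
    total = int(sum(m.sum() for m in masks))
    k = int(np.floor(zeta * total))
    counts = [{"excised": 0, "regrown": 0} for _ in streams]
    if k == 0:
        return RewireReport(0, 0, tuple(counts))

    # --- rank pooled contacts by |w| with random tie-breaking -------------
    strengths, owners, positions = [], [], []
    for si, s in enumerate(streams):
        w = s.effective_weights() if metric == "effective" else s.v
        idx = np.nonzero(s.mask.ravel())[0]
        strengths.append(np.abs(w.ravel()[idx]))
        owners.append(np.full(idx.size, si))
        positions.append(idx)
    strengths = np.concatenate(strengths)
    owners = np.concatenate(owners)
    positions = np.concatenate(positions)
    perm = rng.permutation(strengths.size)
    order = np.lexsort((perm, strengths))
    doomed = order[:k]
    for si, s in enumerate(streams):
        sel = owners[doomed] == si
        flat = positions[doomed][sel]
        s.mask.ravel()[flat] = False
        s.v.ravel()[flat] = 0.0
        counts[si]["excised"] = int(sel.sum())

    # --- regrow uniformly among absent pairs across the pool --------------
    absent_owner, absent_pos = [], []
    for si, s in enumerate(streams):
        absent = ~s.mask
        if forbidden[si] is not None:
            absent = absent & ~forbidden[si]
        idx = np.nonzero(absent.ravel())[0]
        absent_owner.append(np.full(idx.size, si))
        absent_pos.append(idx)
    absent_owner = np.concatenate(absent_owner)
    absent_pos = np.concatenate(absent_pos)
    if absent_pos.size < k:
        raise RuntimeError("pool saturated: not enough absent pairs to regrow")
    chosen = rng.choice(absent_pos.size, size=k, replace=False)
    new_w = weight_sampler(rng, k)
    for si, s in enumerate(streams):
        sel = absent_owner[chosen] == si
        flat = absent_pos[chosen][sel]
        s.mask.ravel()[flat] = True
        s.v.ravel()[flat] = new_w[sel]
        counts[si]["regrown"] = int(sel.sum())
    return RewireReport(k, k, tuple(counts))
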