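"""Weight-normalisation families and their exact cost gradients.

A sparsely connected artificial neuron holds an *unnormalised* afferent
weight vector ``v`` on its existing connections; the *effective* weights
used in the forward pass are

    w = e * v / prod_{p in orders} ||v||_p

where ``||v||_0 = n`` is the number of existing connections (the in-degree),
``||v||_p = (sum |v_j|^p)^(1/p)`` for p >= 1, and the excitability ``e`` is
either a scalar ``s`` shared by every neuron of a class (constant mode) or a
per-neuron ``g_i`` (variable mode).  The singleton ``{0}`` scheme is the
dendritic normalisation — dividing afferent strength by afferent count, as a
passive dendrite does — and ``{2}`` is the heterosynaptic (weight-norm)
scheme; pairs such as ``{0, 2}`` multiply both norms in the denominator.

All gradients here are the *exact* chain rule of the cost through the
reparametrisation (validated against central finite differences in the
test-suite).  For the dendritic scheme this reduces to the simple scaling
``grad_v = (s/n) grad_w``: well-connected neurons take smaller steps and are
therefore more stable, while sparsely connected neurons learn fast.  For
p >= 1 the Jacobian term uses ``sign(v) |v|^(p-1)`` so signed weights are
handled for every order, including even ``p``.

Functions come in two granularities: per-neuron (:class:`AfferentVector`)
and column-vectorised over a whole layer (the ``*_matrix`` forms used by
:mod:`dendronorm.sparse_net`); the vectorised forms are the single source of
truth and the per-neuron wrappers delegate to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NormScheme",
    "AfferentVector",
    "normalise",
    "grad_v",
    "grad_excitability",
    "normalise_matrix",
    "grad_matrix",
    "gradient_magnitude_surface",
]

_VALID_ORDERS = frozenset(range(6))


@dataclass
class NormScheme:
    """A normalisation family: which norm orders and which excitability mode.

    ``orders`` is a set of 1 or 2 norm orders from {0,...,5}; a pair means
    the joint product normalisation.  In ``constant`` mode a single scalar
    ``s`` multiplies every neuron of the class; in ``per_neuron`` mode each
    neuron has its own ``g``.  Both are trainable and default to 1.
    """

    orders: frozenset = frozenset({0})
    excitability_mode: str = "constant"
    s: float | None = None
    g: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.orders = frozenset(self.orders)
        if not self.orders or len(self.orders) > 2:
            raise ValueError("orders must contain 1 or 2 elements")
        if not self.orders <= _VALID_ORDERS:
            raise ValueError(f"orders must be drawn from {sorted(_VALID_ORDERS)}")
        if self.excitability_mode not in ("constant", "per_neuron"):
            raise ValueError("excitability_mode must be 'constant' or 'per_neuron'")
        if self.excitability_mode == "constant":
            if self.g is not None:
                raise ValueError("constant mode carries s, not g")
            if self.s is None:
                self.s = 1.0
        else:
            if self.s is not None:
                raise ValueError("per_neuron mode carries g, not s")

    @property
    def p_orders(self) -> list[int]:
        """The p >= 1 orders of the scheme (the L0 order needs no Jacobian term)."""
        return sorted(o for o in self.orders if o >= 1)

    def excitability(self, m: int) -> np.ndarray:
        """Excitability as a length-``m`` vector (broadcast of s, or g)."""
        if self.excitability_mode == "constant":
            return np.full(m, self.s)
        if self.g is None:
            self.g = np.ones(m)
        return self.g


@dataclass
class AfferentVector:
    """Unnormalised weights of one neuron on its existing connections.

    ``values`` is a full-length vector that is exactly zero off ``support``;
    ``n`` (the L0 norm) is the support size and is untouched by gradient
    descent — connections are only created or destroyed by rewiring.
    """

    values: np.ndarray
    support: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.support is None:
            self.support = np.nonzero(self.values)[0]
        self.support = np.asarray(self.support, dtype=int)

    @property
    def n(self) -> int:
        return int(self.support.size)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.values.shape, dtype=bool)
        m[self.support] = True
        return m


def _norms(v: np.ndarray, mask: np.ndarray, scheme: NormScheme) -> dict[int, np.ndarray]:
    """Per-column ||v||_p for every order of the scheme (L0 = in-degree)."""
    out: dict[int, np.ndarray] = {}
    for p in scheme.orders:
        if p == 0:
            out[0] = mask.sum(axis=0).astype(float)
        else:
            out[p] = np.sum(np.abs(v) ** p * mask, axis=0) ** (1.0 / p)
    return out


def _denominator(norms: dict[int, np.ndarray], scheme: NormScheme, n: np.ndarray):
    denom = np.ones_like(n, dtype=float)
    for p in scheme.orders:
        denom = denom * norms[p]
    bad = (n > 0) & (denom == 0)
    if np.any(bad):
        raise ValueError(
            "degenerate norm: a p >= 1 norm vanished on a non-empty support"
        )
    return denom


def normalise_matrix(v: np.ndarray, mask: np.ndarray, scheme: NormScheme | None):
    """Effective weights of a layer: column ``i`` is neuron ``i``'s afferents.

    ``v`` is (fan_in, M) with zeros off ``mask``.  ``scheme=None`` is the
    unnormalised control (w = v).  Empty columns (in-degree 0) yield zero
    effective weights — such a neuron simply contributes its bias.
    """
    if scheme is None:
        return v
    n = mask.sum(axis=0).astype(float)
    denom = _denominator(_norms(v, mask, scheme), scheme, n)
    e = scheme.excitability(v.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, e / np.where(denom > 0, denom, 1.0), 0.0) * v
    return w * mask


def grad_matrix(
    v: np.ndarray,
    mask: np.ndarray,
    scheme: NormScheme | None,
    grad_w: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Exact chain-rule gradients through the normalisation, per layer.

    Returns ``(grad_v, grad_e)`` where ``grad_v`` is (fan_in, M) restricted
    to the support and ``grad_e`` is the per-neuron derivative with respect
    to the excitability (the caller sums it when the excitability is a
    shared scalar).  For the control (``scheme=None``) ``grad_v`` is the
    masked ``grad_w`` and ``grad_e`` is None.

    Writing P = prod_p ||v||_p and e for the excitability,

        grad_v = (e/P) [grad_w - (grad_w . v) sum_{p>=1} sign(v)|v|^{p-1} / ||v||_p^p]
        grad_e = (grad_w . v) / P
    """
    grad_w = grad_w * mask
    if scheme is None:
        return grad_w, None
    n = mask.sum(axis=0).astype(float)
    norms = _norms(v, mask, scheme)
    denom = _denominator(norms, scheme, n)
    e = scheme.excitability(v.shape[1])
    safe = np.where(denom > 0, denom, 1.0)
    dot = np.sum(grad_w * v, axis=0)  # grad_w . v per neuron

    correction = np.zeros_like(v)
    for p in scheme.p_orders:
        jac = np.sign(v) * np.abs(v) ** (p - 1) * mask
        correction = correction + jac * (dot / np.where(norms[p] > 0, norms[p] ** p, 1.0))
    gv = (e / safe) * (grad_w - correction) * (denom > 0)
    ge = np.where(denom > 0, dot / safe, 0.0)
    return gv * mask, ge


def normalise(av: AfferentVector, scheme: NormScheme | None) -> np.ndarray:
    """Effective weights ``w`` of a single neuron (zeros stay zero)."""
    _check_single(av, scheme)
    return normalise_matrix(
        av.values[:, None], av.mask()[:, None], _as_single(scheme)
    )[:, 0]


def grad_v(av: AfferentVector, scheme: NormScheme | None, grad_w: np.ndarray):
    """Cost gradient w.r.t. the unnormalised weights of a single neuron."""
    _check_single(av, scheme)
    gv, _ = grad_matrix(
        av.values[:, None],
        av.mask()[:, None],
        _as_single(scheme),
        np.asarray(grad_w, dtype=float)[:, None],
    )
    return gv[:, 0]


def grad_excitability(av: AfferentVector, scheme: NormScheme | None, grad_w):
    """Cost derivative w.r.t. the neuron's excitability (s or g_i).

    For a shared scalar ``s`` the network-level derivative is the sum of
    this quantity over all afferent vectors sharing ``s``.
    """
    _check_single(av, scheme)
    _, ge = grad_matrix(
        av.values[:, None],
        av.mask()[:, None],
        _as_single(scheme),
        np.asarray(grad_w, dtype=float)[:, None],
    )
    return float(ge[0])


def _check_single(av: AfferentVector, scheme: NormScheme | None) -> None:
    if scheme is not None and av.n < 1:
        raise ValueError("afferent vector has empty support")


def _as_single(scheme: NormScheme | None) -> NormScheme | None:
    """Clone a scheme for a single neuron, preserving the excitability value."""
    if scheme is None:
        return None
    if scheme.excitability_mode == "constant":
        return NormScheme(scheme.orders, "constant", s=scheme.s)
    g = None if scheme.g is None else np.atleast_1d(scheme.g)[:1]
    return NormScheme(scheme.orders, "per_neuron", g=g)


def gradient_magnitude_surface(
    scheme: NormScheme,
    n_grid,
    meanabs_grid,
    epsilon: float = 0.2,
    reps: int = 50,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Relative learning-gradient scale over (in-degree, mean |weight|) cells.

    For each in-degree ``n`` and target mean absolute weight, draws ``reps``
    standard-normal afferent vectors of length ``n``, rescales each to the
    target mean absolute weight, and averages the gradient prefactor
    ``e / prod_p ||v||_p`` that multiplies ``grad_w`` in the chain rule.
    The matrix is then scaled linearly to a maximum of 1, mirroring how the
    relative plasticity of differently connected neurons is compared across
    norm orders.  For the dendritic scheme every row is constant in the mean
    weight (the prefactor is ``s/n``); for the heterosynaptic scheme cells
    scale as ``1/(mean|w| sqrt(n))``.

    ``epsilon`` is kept as the nominal connection probability of the
    surrounding sparse layer for documentation of the sampling regime; the
    prefactor itself depends only on the realised in-degree.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_grid = np.asarray(list(n_grid), dtype=int)
    meanabs_grid = np.asarray(list(meanabs_grid), dtype=float)
    if n_grid.size == 0 or meanabs_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    out = np.empty((n_grid.size, meanabs_grid.size))
    for i, n in enumerate(n_grid):
        draws = rng.standard_normal((reps, n))
        draws /= np.mean(np.abs(draws), axis=1, keepdims=True)
        for j, target in enumerate(meanabs_grid):
            v = draws * target
            prefac = np.ones(reps)
            for p in scheme.orders:
                if p == 0:
                    prefac = prefac / n
                else:
                    prefac = prefac / np.sum(np.abs(v) ** p, axis=1) ** (1.0 / p)
            out[i, j] = prefac.mean()
    return out / out.max()
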