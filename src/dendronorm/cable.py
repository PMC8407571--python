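"""Passive cable theory for a dendrite with distributed synapses.

A neuron's dendrite is modelled as an unbranched passive cable of physical
length ``l`` and constant radius ``r``, sealed at the distal end, with the
soma (optionally a lumped isopotential sphere of radius ``rho``) at the
proximal end.  Synaptic currents arrive at uniformly random electrotonic
locations ``X`` on ``[0, L]`` and the quantities of interest are the somatic
voltage responses: the steady-state transfer resistance, the impulse
response, and the mean/variance over synaptic location of transient and
integrated voltages.  The headline result is that the expected somatic
response to a change of local synaptic strength scales as ``1/L`` — and,
because dendritic length tracks afferent connectivity, as ``1/n`` in the
number of afferent contacts.  This is the biophysical basis of the L0
("dendritic") weight normalisation implemented in :mod:`dendronorm.normschemes`.

Units
-----
The public interface takes micrometres for ``r``, ``l`` and ``rho``,
Ω·cm for the axial resistivity, S/cm² for the membrane leak conductivity
and μF/cm² for the specific capacitance; internally everything is converted
to cm / S / F / s.  Currents are in mA (``delta_syn``) or mA·s
(``theta_syn``), so resistances are in Ω and voltages in mV.

A finite-difference compartmental model (:func:`compartmental_oracle`) is
provided as an independent numerical check on the closed forms; it is used
by the test-suite, never by the analytics themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

__all__ = [
    "CableParameters",
    "SynapticKernel",
    "transfer_resistance",
    "steady_moments",
    "impulse_response",
    "mean_synaptic_voltage",
    "voltage_variance",
    "peak_voltage",
    "total_voltage",
    "compartmental_oracle",
]

_UM_TO_CM = 1e-4
_UF_TO_F = 1e-6

#: relative bound at which mode sums are truncated
SERIES_RTOL = 1e-9
#: hard cap on the number of series terms
SERIES_MAX_TERMS = 10_000


@dataclass(frozen=True)
class CableParameters:
    """Physical constants of a passive dendritic cable with optional soma.

    Parameters
    ----------
    r : float
        Dendrite radius (μm).
    l : float
        Physical dendrite length (μm).
    r_a : float
        Axial resistivity (Ω·cm).
    g_l : float
        Membrane leak conductivity (S/cm²).
    c : float
        Specific membrane capacitance (μF/cm²).
    rho : float
        Soma radius (μm); 0 means no soma.

    All electrotonic constants (``lam``, ``L``, ``G_inf``, ``G_s``,
    ``tau_l``) are derived properties, recomputed from the physical fields.
    """

    r: float = 1.0
    l: float = 500.0
    r_a: float = 100.0
    g_l: float = 5e-5
    c: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r", "l", "r_a", "g_l", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")

    @property
    def lam(self) -> float:
        """Electrotonic length constant λ = √(r / (2 r_a g_l)) in μm."""
        r_cm = self.r * _UM_TO_CM
        return np.sqrt(r_cm / (2.0 * self.r_a * self.g_l)) / _UM_TO_CM

    @property
    def L(self) -> float:
        """Electrotonic length L = l / λ (dimensionless)."""
        return self.l / self.lam

    @property
    def G_inf(self) -> float:
        """Input conductance of a semi-infinite cable, π r² / (λ r_a), in S."""
        r_cm = self.r * _UM_TO_CM
        return np.pi * r_cm**2 / (self.lam * _UM_TO_CM * self.r_a)

    @property
    def G_s(self) -> float:
        """Somatic leak conductance 4π ρ² g_l in S (0 without a soma)."""
        return 4.0 * np.pi * (self.rho * _UM_TO_CM) ** 2 * self.g_l

    @property
    def tau_l(self) -> float:
        """Membrane time constant c / g_l in seconds."""
        return self.c * _UF_TO_F / self.g_l

    def tau_n(self, n) -> np.ndarray:
        """Time constant of the n-th voltage mode, τ_l (1 + (πn/L)²)⁻¹."""
        n = np.asarray(n, dtype=float)
        return self.tau_l / (1.0 + (np.pi * n / self.L) ** 2)


@dataclass(frozen=True)
class SynapticKernel:
    """Difference-of-exponentials synaptic current kernel.

    The current time course is ``theta_syn (e^{-t/tau_f} - e^{-t/tau_s})
    / (tau_f - tau_s)``, which integrates to ``theta_syn`` (mA·s).  The
    kernel is singular for coincident time constants, so ``tau_f == tau_s``
    is rejected.  ``delta_syn`` (mA) is the magnitude of a steady
    perturbation used for the steady-state moments.
    """

    tau_f: float = 0.002
    tau_s: float = 0.010
    theta_syn: float = 1.0
    delta_syn: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_f <= 0 or self.tau_s <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.tau_f == self.tau_s:
            raise ValueError(
                "degenerate kernel: tau_f and tau_s must differ "
                "(the difference-of-exponentials form is singular at equality)"
            )

    def current(self, t) -> np.ndarray:
        """Synaptic current ζ(t) in mA."""
        t = np.asarray(t, dtype=float)
        return (
            self.theta_syn
            * (np.exp(-t / self.tau_f) - np.exp(-t / self.tau_s))
            / (self.tau_f - self.tau_s)
        )


def _soma_denominator(p: CableParameters) -> float:
    # sinh L + (G_s / G_inf) cosh L : the dimensionally consistent soma load
    return np.sinh(p.L) + (p.G_s / p.G_inf) * np.cosh(p.L)


def transfer_resistance(params: CableParameters, X) -> np.ndarray:
    """Steady-state somatic voltage per unit current injected at ``X``.

    ``R_L(X) = cosh(L - X) / (G_inf sinh L)`` for a sealed cable, with the
    soma adding a leak term ``(G_s/G_inf) cosh L`` to the denominator.
    Returns Ohms.  ``X`` must lie in ``[0, L]``.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0) or np.any(X > params.L):
        raise ValueError(f"X must lie in [0, L] = [0, {params.L}]")
    return np.cosh(params.L - X) / (params.G_inf * _soma_denominator(params))


def steady_moments(params: CableParameters, delta_syn: float) -> tuple[float, float]:
    """Mean and variance of the steady somatic voltage change.

    A steady perturbation of magnitude ``delta_syn`` (mA) at a uniformly
    random location produces a somatic voltage change ``delta_syn R_L(X)``.
    The mean is ``delta_syn sinh L / (L G_inf D)`` with
    ``D = sinh L + (G_s/G_inf) cosh L`` — reducing to
    ``delta_syn / (L G_inf)`` without a soma, the exact 1/L law — and the
    variance is the population variance of ``delta_syn R_L(X)``, derived in
    closed form (``∫cosh²(L-X)dX = L/2 + sinh(2L)/4``) rather than taken
    from any printed rendering.
    """
    L, G = params.L, params.G_inf
    D = _soma_denominator(params)
    mean = delta_syn * np.sinh(L) / (L * G * D)
    second = delta_syn**2 * (L / 2.0 + np.sinh(2.0 * L) / 4.0) / (L * G**2 * D**2)
    return mean, second - mean**2


def impulse_response(
    params: CableParameters,
    X,
    T,
    rtol: float = SERIES_RTOL,
    max_terms: int = SERIES_MAX_TERMS,
) -> np.ndarray:
    """Somatic impulse response density at normalised delay ``T = t/τ_l``.

    ``ε(X, T) = e^{-T}/L [ 1/2 + Σ_{n≥1} cos(nπX/L) e^{-(πn/L)² T} ]``.
    The mode sum is truncated once the bound ``e^{-(πn/L)²T}`` on the next
    term falls below ``rtol`` of the running sum, with a hard cap of
    ``max_terms`` terms.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("T must be non-negative")
    if np.any(X < 0) or np.any(X > params.L):
        raise ValueError("X must lie in [0, L]")
    L = params.L
    total = np.full(np.broadcast_shapes(X.shape, T.shape), 0.5)
    for n in range(1, max_terms + 1):
        decay = np.exp(-((np.pi * n / L) ** 2) * T)
        total = total + np.cos(n * np.pi * X / L) * decay
        if np.all(decay <= rtol * np.abs(total)):
            break
    return np.exp(-T) / L * total


def _mode_kernel(kernel: SynapticKernel, tau_mode, t) -> np.ndarray:
    """Convolution of the synaptic kernel (without Θ/(τf−τs)) with e^{-t/τ_mode}."""
    tf, ts = kernel.tau_f, kernel.tau_s
    tau_mode = np.asarray(tau_mode, dtype=float)
    return tf * tau_mode / (tf - tau_mode) * (
        np.exp(-t / tf) - np.exp(-t / tau_mode)
    ) - ts * tau_mode / (ts - tau_mode) * (np.exp(-t / ts) - np.exp(-t / tau_mode))


def _check_distinct(params: CableParameters, kernel: SynapticKernel) -> None:
    taus = (kernel.tau_f, kernel.tau_s, params.tau_l)
    if len({*taus}) < 3:
        raise ValueError(
            "degenerate kernel: tau_f, tau_s and tau_l must be pairwise distinct"
        )


def mean_synaptic_voltage(params: CableParameters, kernel: SynapticKernel, t) -> np.ndarray:
    """Expected somatic voltage at time ``t`` after one synaptic activation.

    Closed-form convolution of the difference-of-exponentials current with
    the location-averaged impulse response ``e^{-T}/(2L)``:

    ``v̄(t) = Θ τ_l / (2L(τf−τs)) [ τf/(τf−τl)(e^{-t/τf}−e^{-t/τl})
    − τs/(τs−τl)(e^{-t/τs}−e^{-t/τl}) ]``

    and is proportional to ``1/L`` at every ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    _check_distinct(params, kernel)
    coeff = kernel.theta_syn / (2.0 * params.L * (kernel.tau_f - kernel.tau_s))
    return coeff * _mode_kernel(kernel, params.tau_l, t)


def voltage_variance(
    params: CableParameters,
    kernel: SynapticKernel,
    t,
    rtol: float = SERIES_RTOL,
    max_terms: int = SERIES_MAX_TERMS,
) -> np.ndarray:
    """Variance over synaptic location of the somatic voltage at time ``t``.

    Expanding the impulse response in cosine modes and using
    ``E[cos²(nπX/L)] = 1/2`` for uniform ``X`` gives

    ``var v(t) = Θ² / (2L²(τf−τs)²) Σ_{n≥1} K_n(t)²``

    with ``K_n`` the convolution of the synaptic kernel with ``e^{-t/τ_n}``
    and ``τ_n = τ_l(1+(πn/L)²)⁻¹``.  The coefficient is derived directly
    from mode orthogonality and validated against Monte-Carlo sampling of
    the synapse location in the test-suite.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    _check_distinct(params, kernel)
    total = np.zeros(t.shape)
    for n in range(1, max_terms + 1):
        term = _mode_kernel(kernel, params.tau_n(n), t) ** 2
        total = total + term
        if np.all(term <= rtol * np.abs(total)):
            break
    coeff = kernel.theta_syn**2 / (
        2.0 * params.L**2 * (kernel.tau_f - kernel.tau_s) ** 2
    )
    return coeff * total


def peak_voltage(params: CableParameters, kernel: SynapticKernel) -> tuple[float, float]:
    """Time and magnitude of the peak expected somatic voltage.

    The stationary point ``t*`` of the mean voltage satisfies

    ``(τs−τl)(τf e^{-t*/τl} − τl e^{-t*/τf}) =
    (τf−τl)(τs e^{-t*/τl} − τl e^{-t*/τs})``

    (which also has a trivial root at ``t = 0`` where the response starts
    flat); ``t*`` is located by bracketed root-finding and is independent of
    ``L`` — only the amplitude scales with length.
    """
    _check_distinct(params, kernel)
    tf, ts, tl = kernel.tau_f, kernel.tau_s, params.tau_l

    def residual(t: float) -> float:
        return (ts - tl) * (tf * np.exp(-t / tl) - tl * np.exp(-t / tf)) - (
            tf - tl
        ) * (ts * np.exp(-t / tl) - tl * np.exp(-t / ts))

    t_max = 20.0 * max(tf, ts, tl)
    grid = np.linspace(t_max * 1e-6, t_max, 512)
    vals = residual(grid)
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    if sign_change.size == 0:
        raise RuntimeError(f"peak time not bracketed in (0, {t_max}]")
    lo, hi = grid[sign_change[0]], grid[sign_change[0] + 1]
    t_star = brentq(residual, lo, hi)
    return t_star, float(mean_synaptic_voltage(params, kernel, t_star))


def total_voltage(
    params: CableParameters,
    kernel: SynapticKernel,
    rtol: float = SERIES_RTOL,
    max_terms: int = SERIES_MAX_TERMS,
) -> tuple[float, float]:
    """Mean and variance of the time-integrated somatic voltage.

    The mean is exactly ``V̄ = Θ τ_l / (2L)`` — independent of the synaptic
    time constants.  Integrating each cosine mode gives
    ``V(X) = Θ/L (τ_l/2 + Σ cos(nπX/L) τ_n)``, hence
    ``var V = Θ²/(2L²) Σ τ_n²`` by mode orthogonality (the τ_n⁴ decay makes
    the truncated sum converge quickly).
    """
    mean = kernel.theta_syn * params.tau_l / (2.0 * params.L)
    total = 0.0
    for n in range(1, max_terms + 1):
        term = float(params.tau_n(n)) ** 2
        total += term
        if term <= rtol * total:
            break
    var = kernel.theta_syn**2 / (2.0 * params.L**2) * total
    return mean, var


def charge_to_voltage(params: CableParameters) -> float:
    """Conversion from normalised transient response units to mV per mA·s.

    The transient forms (:func:`impulse_response`, :func:`mean_synaptic_voltage`,
    …) are expressed in the dimensionless response-density convention in
    which the impulse response integrates (over time, averaged over
    location) to ``τ_l/(2L)``.  Multiplying by ``2L / C_tot`` — with
    ``C_tot = 2π r l c`` the total membrane capacitance — converts to
    physical somatic millivolts per unit injected charge, which is the scale
    the compartmental oracle produces.  Equivalently ``2L/C_tot =
    1/(G_inf τ_l / 2L)``.
    """
    c_tot = 2.0 * np.pi * (params.r * _UM_TO_CM) * (params.l * _UM_TO_CM) * (
        params.c * _UF_TO_F
    )
    return 2.0 * params.L / c_tot  # (mA·s)/F = mV


# ---------------------------------------------------------------------------
# numerical compartmental oracle (used by the test-suite)
# ---------------------------------------------------------------------------

def compartmental_oracle(
    params: CableParameters,
    synapse_X: float,
    *,
    steady_current: float | None = None,
    kernel: SynapticKernel | None = None,
    n_compartments: int = 400,
    t_stop: float | None = None,
    dt: float | None = None,
):
    """Finite-difference simulation of the cable equation.

    Discretises the dendrite into ``n_compartments`` cylinders (with an
    explicit lumped soma compartment at the proximal end when ``rho > 0``)
    and injects current at the compartment nearest electrotonic location
    ``synapse_X``.  With ``steady_current`` (mA) the steady somatic voltage
    (mV) is returned; with ``kernel`` an implicit-Euler transient is run and
    ``(t, v_soma)`` arrays are returned.  Purely numerical — independent of
    every closed form above — and used to validate them.
    """
    if n_compartments < 200:
        raise ValueError("need at least 200 compartments")
    if (steady_current is None) == (kernel is None):
        raise ValueError("provide exactly one of steady_current or kernel")
    if not 0 <= synapse_X <= params.L:
        raise ValueError("synapse_X must lie in [0, L]")

    N = n_compartments
    l_cm = params.l * _UM_TO_CM
    r_cm = params.r * _UM_TO_CM
    dx = l_cm / N
    g_axial = np.pi * r_cm**2 / (params.r_a * dx)  # S between adjacent nodes
    g_mem = 2.0 * np.pi * r_cm * dx * params.g_l  # S per compartment
    c_mem = 2.0 * np.pi * r_cm * dx * params.c * _UF_TO_F  # F per compartment

    has_soma = params.rho > 0
    n_nodes = N + (1 if has_soma else 0)
    # node 0 is the soma when present; dendritic nodes sit at cell centres
    g_diag = np.full(n_nodes, g_mem)
    c_diag = np.full(n_nodes, c_mem)
    if has_soma:
        g_diag[0] = params.G_s
        c_diag[0] = 4.0 * np.pi * (params.rho * _UM_TO_CM) ** 2 * params.c * _UF_TO_F

    # conductance matrix in banded form: couplings between consecutive nodes
    # (soma couples to the first dendritic half-cell with doubled conductance)
    g_link = np.full(n_nodes - 1, g_axial)
    if has_soma:
        g_link[0] = 2.0 * g_axial
    main = g_diag.copy()
    main[:-1] += g_link
    main[1:] += g_link

    inj = np.zeros(n_nodes)
    frac = synapse_X / params.L if params.L > 0 else 0.0
    comp = min(int(frac * N), N - 1) + (1 if has_soma else 0)
    inj[comp] = 1.0

    def solve(rhs: np.ndarray, diag: np.ndarray) -> np.ndarray:
        ab = np.zeros((3, n_nodes))
        ab[0, 1:] = -g_link
        ab[1] = diag
        ab[2, :-1] = -g_link
        return solve_banded((1, 1), ab, rhs)

    if steady_current is not None:
        v = solve(inj * steady_current * 1e-3, main)  # mA -> A
        return float(v[0] * 1e3)  # V -> mV

    tau_max = max(kernel.tau_f, kernel.tau_s, params.tau_l)
    if t_stop is None:
        t_stop = 10.0 * tau_max
    if dt is None:
        dt = min(kernel.tau_f, kernel.tau_s, params.tau_l) / 200.0
    steps = int(np.ceil(t_stop / dt))
    # implicit Euler: (C/dt + G) v_{k+1} = C/dt v_k + I(t_{k+1})
    diag = main + c_diag / dt
    v = np.zeros(n_nodes)
    times = np.arange(1, steps + 1) * dt
    trace = np.empty(steps)
    for k, t in enumerate(times):
        rhs = c_diag / dt * v + inj * kernel.current(t) * 1e-3
        v = solve(rhs, diag)
        trace[k] = v[0]
    return times, trace * 1e3
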