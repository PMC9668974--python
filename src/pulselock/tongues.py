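"""Closed-form frequency-locking theory for two pulse-coupled class I neurons.

Two unidirectionally coupled oscillators lock when the circle map for
the driven neuron's phase, sampled at the driver's spikes, has a stable
fixed point.  For QIF neurons the map and its fixed points are exact at
any coupling strength; for an arbitrary class I phase response curve the
same construction holds to first order in ``g`` near the resonances
``T2/T1 ~ n``.  This module provides:

* the exact QIF circle maps and their stationary phases;
* Arnold-tongue boundaries with frozen weights (``g1_fixed``,
  ``g2_fixed``) and under STDP (``g1_stdp``, ``g2_stdp``);
* the per-cycle STDP weight budgets for the two unidirectional modes
  and the thresholds ``Q1``/``Q2`` at which their signs flip;
* near-resonance boundaries for arbitrary class I neurons from a
  parabolic fit of the PRC peak.

Conventions: neuron 1 is the faster (``T1 < T2``); mode i is the
slow->fast unidirectional link ``(W12, W21) = (1, 0)`` locking at
winding number ``n/1``; mode ii is the fast->slow link ``(0, 1)``
locking at ``1/1``.  Phases are calibrated so a neuron fires at
``2*pi``.  The STDP boundaries assume ``p == d`` and
``tau_p <= tau_d``; other regimes are rejected rather than
extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .qif import TWO_PI, arccot
from .stdp import StdpParams

__all__ = [
    "PRCFit",
    "TonguePoint",
    "weight_budget_mode_i",
    "weight_budget_mode_ii",
    "q1",
    "q2",
    "winding_integer",
    "qif_map_step",
    "map_derivative_qif",
    "stationary_phase_qif",
    "g1_fixed",
    "g2_fixed",
    "g1_stdp",
    "g2_stdp",
    "resonance_epsilon",
    "resonance_g_fixed",
    "resonance_g_stdp",
    "general_map_step",
    "tongue_table",
]

Mode = Literal["i", "ii"]


@dataclass(frozen=True)
class PRCFit:
    """Parabolic summary of a PRC peak: ``Z(phi) ~ Z_max - alpha*(phi - phi_max)**2``."""

    Z_max: float
    phi_max: float
    alpha: float

    def __post_init__(self):
        if self.Z_max <= 0 or self.alpha <= 0:
            raise ValueError("Z_max and alpha must be positive")
        if not 0.0 < self.phi_max < TWO_PI:
            raise ValueError(f"phi_max must lie in (0, 2*pi), got {self.phi_max}")

    def __call__(self, phi):
        return self.Z_max - self.alpha * (np.asarray(phi) - self.phi_max) ** 2


@dataclass(frozen=True)
class TonguePoint:
    """Tongue boundaries at one period ratio ``T2/T1``."""

    ratio: float
    n: int
    g_fixed: float
    g_stdp: float
    phase_at_boundary: float


# ---------------------------------------------------------------------------
# Per-cycle weight budgets and the Q thresholds
# ---------------------------------------------------------------------------

def weight_budget_mode_i(
    T1: float, T2: float, n: int, deltaT: float, params: StdpParams
) -> tuple[float, float]:
    """Net per-cycle weight drifts ``(dW12, dW21)`` in the ``n/1`` locked mode.

    One synchronization cycle of length ``T2`` contains ``n`` spikes of
    the fast neuron, at lags ``deltaT + j*T1`` (``j = 0..n-1``) after
    the slow neuron's spike, followed by the slow neuron's next spike a
    time ``T2 - (n-1)*T1 - deltaT`` later.  Each fast spike potentiates
    W12 and depresses W21; the closing slow spike does the opposite.
    The mode is STDP-stable when ``dW12 > 0`` and ``dW21 < 0``.
    """
    if not (0.0 <= deltaT < T1):
        raise ValueError(f"deltaT must lie in [0, T1), got {deltaT}")
    tail = T2 - (n - 1) * T1 - deltaT
    if tail <= 0:
        raise ValueError("cycle partition invalid: (n-1)*T1 + deltaT must be < T2")
    j = np.arange(n)
    fast_lags = j * T1 + deltaT
    dW12 = params.p * np.exp(-fast_lags / params.tau_p).sum() - params.d * math.exp(
        -tail / params.tau_d
    )
    dW21 = params.p * math.exp(-tail / params.tau_p) - params.d * np.exp(
        -fast_lags / params.tau_d
    ).sum()
    return float(dW12), float(dW21)


def weight_budget_mode_ii(
    T1: float, deltaT: float, params: StdpParams
) -> tuple[float, float]:
    """Net per-period drifts ``(dW12, dW21)`` in the ``1/1`` fast-driver mode.

    Both neurons fire once per ``T1``; the slow neuron lags the fast one
    by ``deltaT``.  Stability of mode ii requires ``dW12 < 0`` and
    ``dW21 > 0``.
    """
    if not (0.0 <= deltaT < T1):
        raise ValueError(f"deltaT must lie in [0, T1), got {deltaT}")
    dW12 = params.p * math.exp(-(T1 - deltaT) / params.tau_p) - params.d * math.exp(
        -deltaT / params.tau_d
    )
    dW21 = params.p * math.exp(-deltaT / params.tau_p) - params.d * math.exp(
        -(T1 - deltaT) / params.tau_d
    )
    return float(dW12), float(dW21)


def _require_symmetric(params: StdpParams) -> None:
    params.require_symmetric()


def q1(T1: float, T2: float, n: int, tau_p: float, tau_d: float) -> float:
    """Mode-i stability threshold on the normalized lag ``deltaT / T1``.

    With ``p == d`` and ``tau_p <= tau_d`` the sign conditions on the
    mode-i weight budget reduce to ``deltaT / T1 < Q1``.
    """
    if tau_p > tau_d:
        raise ValueError("Q1 is derived under tau_p <= tau_d")
    if n < 1:
        raise ValueError(f"winding integer n must be >= 1, got {n}")
    log_sum = math.log(np.exp(-np.arange(n) * T1 / tau_p).sum())
    return (T2 / T1 - n + 1 + (tau_d / T1) * log_sum) / (1.0 + tau_d / tau_p)


def q2(T1: float, T2: float, tau_p: float, tau_d: float) -> float:
    """Mode-ii stability threshold on ``deltaT / T2``: ``(T1/T2) / (1 + tau_d/tau_p)``."""
    if tau_p > tau_d:
        raise ValueError("Q2 is derived under tau_p <= tau_d")
    return (T1 / T2) / (1.0 + tau_d / tau_p)


# ---------------------------------------------------------------------------
# Exact QIF circle maps and tongue boundaries
# ---------------------------------------------------------------------------

def winding_integer(ratio: float) -> int:
    """The tongue index ``n`` with ``n - 1 < T2/T1 <= n``."""
    if ratio <= 0:
        raise ValueError(f"period ratio must be positive, got {ratio}")
    return int(math.ceil(ratio - 1e-12))


def qif_map_step(phi: float, omega_response: float, T_drive: float, g: float) -> float:
    """Exact QIF circle map: the driven phase just after one driver spike.

    ``phi' = 2*arccot(cot((phi + omega*T)/2) - 2*g/omega)``; the driven
    neuron's free rotation over one driver period followed by the exact
    pulse-induced jump.  ``phi`` is taken modulo ``2*pi``.
    """
    u = math.fmod(phi + omega_response * T_drive, TWO_PI)
    if u <= 0.0:
        u += TWO_PI
    half = u / 2.0
    return float(2.0 * arccot(1.0 / math.tan(half) - 2.0 * g / omega_response))


def map_derivative_qif(phi: float, omega_response: float, T_drive: float, g: float) -> float:
    """Analytic derivative of :func:`qif_map_step` with respect to ``phi``."""
    u = math.fmod(phi + omega_response * T_drive, TWO_PI)
    if u <= 0.0:
        u += TWO_PI
    half = u / 2.0
    x = 1.0 / math.tan(half) - 2.0 * g / omega_response
    return 1.0 / ((1.0 + x * x) * math.sin(half) ** 2)


def stationary_phase_qif(
    T_drive: float, T_response: float, g: float, *, unstable: bool = False
) -> float | None:
    """Stationary phase of the driven neuron in the locked state, or ``None``.

    Solves the fixed-point equation of the exact QIF circle map:
    ``phi_bar = pi + 2*arctan(G +/- sqrt(G**2 - 1 - 2*G*cot(pi*T_drive/T_response)))``
    with ``G = g / omega_response``.  The "+" root is the stable fixed
    point (returned by default); ``unstable=True`` selects the "-" root.
    Returns ``None`` when the radicand is negative (outside the tongue);
    at radicand zero the two roots merge on the tongue boundary.
    """
    if g <= 0:
        return None
    omega = TWO_PI / T_response
    G = g / omega
    c = 1.0 / math.tan(math.pi * T_drive / T_response)
    radicand = G * G - 1.0 - 2.0 * G * c
    if radicand < 0:
        return None
    root = math.sqrt(radicand)
    return math.pi + 2.0 * math.atan(G - root if unstable else G + root)


def g1_fixed(T1: float, T2: float) -> float:
    """Mode-i tongue boundary with frozen weights ``(1, 0)``.

    ``g1 = omega1 * cot((pi/2) * (T2/T1 - n + 1))`` for the tongue
    ``n - 1 < T2/T1 <= n``; zero at exact resonance ``T2/T1 = n`` and
    diverging toward the lower edge of the tongue.
    """
    if T2 < T1:
        raise ValueError("requires T2 >= T1 (neuron 1 is the faster one)")
    r = T2 / T1
    n = winding_integer(r)
    x = (math.pi / 2.0) * (r - n + 1)
    omega1 = TWO_PI / T1
    return omega1 / math.tan(x)


def g2_fixed(T1: float, T2: float) -> float:
    """Mode-ii (1/1) tongue boundary with frozen weights ``(0, 1)``:
    ``g2 = omega2 * cot((pi/2) * T1/T2)``."""
    if T2 < T1:
        raise ValueError("requires T2 >= T1")
    omega2 = TWO_PI / T2
    return omega2 / math.tan((math.pi / 2.0) * T1 / T2)


def boundary_phase_mode_i(T1: float, T2: float) -> float:
    """Stationary phase of the fast neuron on the frozen-weight mode-i boundary:
    ``2*pi * (1 - (T2/T1 - n + 1)/2)``."""
    r = T2 / T1
    n = winding_integer(r)
    return TWO_PI * (1.0 - 0.5 * (r - n + 1))


def boundary_phase_mode_ii(T1: float, T2: float) -> float:
    """Stationary phase of the slow neuron on the frozen-weight mode-ii
    boundary: ``2*pi * (1 - T1 / (2*T2))``."""
    return TWO_PI * (1.0 - 0.5 * T1 / T2)


def g1_stdp(T1: float, T2: float, params: StdpParams) -> float:
    """Mode-i tongue boundary in the presence of STDP.

    The frozen-weight lock survives STDP iff the stationary phase
    satisfies ``phi_bar_1 > 2*pi*(1 - Q1)``.  When that already holds on
    the frozen-weight boundary the two boundaries coincide; otherwise
    the STDP boundary is the coupling at which the stationary phase
    equals ``2*pi*(1 - Q1)``:
    ``omega1 / (2*sin(pi*Q1)**2 * (cot(pi*Q1) - cot(pi*T2/T1)))``.
    """
    _require_symmetric(params)
    r = T2 / T1
    n = winding_integer(r)
    Q1 = q1(T1, T2, n, params.tau_p, params.tau_d)
    if Q1 >= 0.5 * (r - n + 1):
        return g1_fixed(T1, T2)
    omega1 = TWO_PI / T1
    s = math.sin(math.pi * Q1)
    denom = 2.0 * s * s * (1.0 / math.tan(math.pi * Q1) - 1.0 / math.tan(math.pi * r))
    return omega1 / denom


def g2_stdp(T1: float, T2: float, params: StdpParams) -> float:
    """Mode-ii tongue boundary under STDP (always above the frozen one).

    With ``tau_d > tau_p`` the frozen-weight stationary phase never
    satisfies the mode-ii stability condition on the boundary, so the
    STDP boundary is strictly larger:
    ``omega2 / (2*sin(pi*Q2)**2 * (cot(pi*Q2) - cot(pi*T1/T2)))``.
    """
    _require_symmetric(params)
    if params.tau_d <= params.tau_p:
        raise ValueError("mode-ii STDP boundary is derived for tau_d > tau_p")
    Q2 = q2(T1, T2, params.tau_p, params.tau_d)
    omega2 = TWO_PI / T2
    s = math.sin(math.pi * Q2)
    denom = 2.0 * s * s * (
        1.0 / math.tan(math.pi * Q2) - 1.0 / math.tan(math.pi * T1 / T2)
    )
    return omega2 / denom


# ---------------------------------------------------------------------------
# Near-resonance results for arbitrary class I PRCs
# ---------------------------------------------------------------------------

def resonance_epsilon(ratio: float, *, max_abs: float = 0.25) -> tuple[int, float]:
    """Split ``T2/T1`` into ``n + epsilon`` with ``n = round(ratio)``.

    The near-resonance formulas are first order in ``epsilon``;
    ``|epsilon| > max_abs`` is rejected as outside their regime.
    """
    n = int(round(ratio))
    if n < 1:
        raise ValueError(f"ratio {ratio} is below the first resonance")
    eps = ratio - n
    if abs(eps) > max_abs:
        raise ValueError(f"|epsilon|={abs(eps):.3f} exceeds the resonance regime ({max_abs})")
    return n, eps


def resonance_g_fixed(Z_max: float, epsilon: float, mode: Mode) -> float:
    """Frozen-weight tongue boundary near resonance: ``|2*pi*epsilon| / Z_max``.

    Mode i tongues (``n >= 2``) open toward ``epsilon < 0``; the mode ii
    tongue (``n = 1``) opens toward ``epsilon > 0``.  The sign of
    ``epsilon`` must match the mode.
    """
    if Z_max <= 0:
        raise ValueError("Z_max must be positive")
    if mode == "i":
        if epsilon >= 0:
            raise ValueError("mode i requires epsilon < 0 (T2/T1 below the resonance)")
        return -TWO_PI * epsilon / Z_max
    if mode == "ii":
        if epsilon <= 0:
            raise ValueError("mode ii requires epsilon > 0 (T2/T1 above 1)")
        return TWO_PI * epsilon / Z_max
    raise ValueError(f"mode must be 'i' or 'ii', got {mode!r}")


def _resonance_B(fit: PRCFit, n: int, T1: float, params: StdpParams, mode: Mode) -> float:
    if mode == "i":
        log_sum = math.log(np.exp(-np.arange(n) * T1 / params.tau_p).sum())
        return (
            TWO_PI
            - fit.phi_max
            - (TWO_PI / (1.0 + params.tau_d / params.tau_p))
            * (1.0 + (params.tau_d / T1) * log_sum)
        )
    return TWO_PI / (1.0 + params.tau_p / params.tau_d) - fit.phi_max


def resonance_g_stdp(
    fit: PRCFit, epsilon: float, n: int, T1: float, params: StdpParams, mode: Mode
) -> float:
    """STDP tongue boundary near resonance for an arbitrary class I PRC.

    ``g_bar = (1 + beta) * g_fixed`` with ``beta = B**2 * alpha / Z_max``
    when the STDP stability margin ``B`` is positive and ``beta = 0``
    otherwise.  ``B`` measures how far the resonant stationary phase
    (the PRC peak ``phi_max``) falls short of the phase the STDP budget
    requires.
    """
    _require_symmetric(params)
    g0 = resonance_g_fixed(fit.Z_max, epsilon, mode)
    B = _resonance_B(fit, n, T1, params, mode)
    beta = 0.0 if B <= 0 else B * B * fit.alpha / fit.Z_max
    return (1.0 + beta) * g0


def general_map_step(
    phi: float,
    omega_response: float,
    T_drive: float,
    g: float,
    Z: Callable[[float], float],
) -> float:
    """One iterate of the weak-coupling circle map for an arbitrary PRC.

    ``phi' = phi + omega*T + g*Z(phi + omega*T)`` reduced modulo
    ``2*pi``; ``Z`` is evaluated on the wrapped argument.  For the QIF
    PRC this agrees with the exact map to first order in ``g``.
    """
    u = math.fmod(phi + omega_response * T_drive, TWO_PI)
    if u <= 0.0:
        u += TWO_PI
    out = math.fmod(u + g * float(Z(u)), TWO_PI)
    return out + TWO_PI if out <= 0.0 else out


def tongue_table(
    T1: float,
    ratios: np.ndarray,
    params: StdpParams,
    mode: Mode = "i",
):
    """Tabulate frozen and STDP boundaries over a grid of period ratios.

    Returns a pandas DataFrame with columns ``ratio, n, g_fixed, g_stdp,
    phase_at_boundary`` (exported as CSV by the CLI).
    """
    import pandas as pd

    rows = []
    for r in np.asarray(ratios, dtype=float):
        T2 = r * T1
        if mode == "i":
            gf = g1_fixed(T1, T2)
            gs = g1_stdp(T1, T2, params)
            phase = boundary_phase_mode_i(T1, T2)
        else:
            gf = g2_fixed(T1, T2)
            gs = g2_stdp(T1, T2, params)
            phase = boundary_phase_mode_ii(T1, T2)
        rows.append(
            TonguePoint(
                ratio=float(r),
                n=winding_integer(r) if mode == "i" else 1,
                g_fixed=gf,
                g_stdp=gs,
                phase_at_boundary=phase,
            )
        )
    return pd.DataFrame([t.__dict__ for t in rows])
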