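"""Wang-Buzsaki and Morris-Lecar conductance-based class I neurons.

Both models sit near a SNIC bifurcation at their standard parameters:
the firing period diverges as the drive current approaches the
bifurcation from above, which is what makes them class I (arbitrarily
low firing rates, purely positive phase response curve).  This module
integrates the single-neuron equations, measures steady-state periods,
localizes the SNIC current by bisection, extracts phase response
curves by direct pulse perturbation of the membrane potential, and
fits the PRC peak with the parabola consumed by the locking theory.

Phase convention: phase 0 (equivalently ``2*pi``) at the maximum of the
membrane potential, increasing with time.

Units: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .qif import TWO_PI
from .tongues import PRCFit

__all__ = [
    "WbParams",
    "MlParams",
    "PrcCurve",
    "integrate",
    "measure_period",
    "find_snic_current",
    "compute_prc",
    "fit_parabola",
]


@dataclass(frozen=True)
class WbParams:
    """Wang-Buzsaki fast-spiking interneuron parameters.

    Defaults are the standard set: conductances ``(g_K, g_Na, g_L) =
    (9, 35, 0.1)`` mS/cm^2, reversals ``(-90, 55, -65)`` mV, gating rate
    scale ``phi_gate = 5`` and unit membrane capacitance.  ``I`` is the
    direct drive current; the SNIC bifurcation of this set sits near
    0.16 uA/cm^2.
    """

    C_m: float = 1.0
    g_K: float = 9.0
    g_Na: float = 35.0
    g_L: float = 0.1
    v_K: float = -90.0
    v_Na: float = 55.0
    v_L: float = -65.0
    phi_gate: float = 5.0
    I: float = 0.162677

    spike_threshold: float = 0.0  # mV; v maxima above this count as spikes
    state_dim: int = 3

    def rest_state(self) -> np.ndarray:
        v = -64.0
        return np.array([v, self._h_inf(v), self._n_inf(v)])

    # steady-state gating helpers used only for initial conditions
    def _h_inf(self, v):
        a, b = _wb_alpha_h(v), _wb_beta_h(v)
        return a / (a + b)

    def _n_inf(self, v):
        a, b = _wb_alpha_n(v), _wb_beta_n(v)
        return a / (a + b)

    def rhs(self, t, y):
        v, h, n = y
        am, bm = _wb_alpha_m(v), _wb_beta_m(v)
        m_inf = am / (am + bm)
        I_Na = self.g_Na * m_inf**3 * h * (v - self.v_Na)
        I_K = self.g_K * n**4 * (v - self.v_K)
        I_L = self.g_L * (v - self.v_L)
        dv = (-I_K - I_Na - I_L + self.I) / self.C_m
        dh = self.phi_gate * (_wb_alpha_h(v) * (1 - h) - _wb_beta_h(v) * h)
        dn = self.phi_gate * (_wb_alpha_n(v) * (1 - n) - _wb_beta_n(v) * n)
        return (dv, dh, dn)

    def dv_dt(self, t, y):
        return self.rhs(t, y)[0]


def _wb_alpha_m(v):
    x = v + 35.0
    if abs(x) < 1e-7:  # removable singularity of x/(1-exp(-0.1 x))
        return 1.0 + 0.05 * x
    return 0.1 * x / (1.0 - math.exp(-0.1 * x))


def _wb_beta_m(v):
    return 4.0 * math.exp(-(v + 60.0) / 18.0)


def _wb_alpha_h(v):
    return 0.07 * math.exp(-(v + 58.0) / 20.0)


def _wb_beta_h(v):
    return 1.0 / (1.0 + math.exp(-0.1 * (v + 28.0)))


def _wb_alpha_n(v):
    x = v + 34.0
    if abs(x) < 1e-7:
        return 0.1 + 0.005 * x
    return 0.01 * x / (1.0 - math.exp(-0.1 * x))


def _wb_beta_n(v):
    return 0.125 * math.exp(-(v + 44.0) / 80.0)


@dataclass(frozen=True)
class MlParams:
    """Morris-Lecar neuron with a per-neuron time-scaling factor.

    Defaults are the standard class I set: ``(g_Ca, g_K, g_L) =
    (4, 8, 2)`` mS/cm^2, reversals ``(120, -80, -60)`` mV, shape
    voltages ``(v1..v4) = (-1.2, 18, 12, 17.4)`` mV, ``I0 = 40``
    uA/cm^2, ``C_m = 5`` uF/cm^2 and gating rate ``phi_rate = 1/15``
    /ms.  The drive current cannot tune the period over a wide range
    here, so heterogeneity is introduced by the time-scaling factor
    ``eta_scale`` multiplying all rates: a neuron with ``eta_scale =
    eta`` has period ``T(1) / eta``.
    """

    C_m: float = 5.0
    g_Ca: float = 4.0
    g_K: float = 8.0
    g_L: float = 2.0
    v_Ca: float = 120.0
    v_K: float = -80.0
    v_L: float = -60.0
    v1: float = -1.2
    v2: float = 18.0
    v3: float = 12.0
    v4: float = 17.4
    I0: float = 40.0
    phi_rate: float = 1.0 / 15.0
    eta_scale: float = 1.0

    spike_threshold: float = 10.0  # mV
    state_dim: int = 2

    def rest_state(self) -> np.ndarray:
        v = -30.0
        return np.array([v, self._n_inf(v)])

    def _m_inf(self, v):
        return 0.5 * (1.0 + math.tanh((v - self.v1) / self.v2))

    def _n_inf(self, v):
        return 0.5 * (1.0 + math.tanh((v - self.v3) / self.v4))

    def rhs(self, t, y):
        v, n = y
        ion = (
            -self.g_Ca * self._m_inf(v) * (v - self.v_Ca)
            - self.g_K * n * (v - self.v_K)
            - self.g_L * (v - self.v_L)
            + self.I0
        )
        dv = self.eta_scale * ion / self.C_m
        # tau_n = 1/cosh((v - v3)/(2*v4)) so the rate is phi*cosh(...)
        dn = (
            self.eta_scale
            * self.phi_rate
            * (self._n_inf(v) - n)
            * math.cosh((v - self.v3) / (2.0 * self.v4))
        )
        return (dv, dn)

    def dv_dt(self, t, y):
        return self.rhs(t, y)[0]


@dataclass(frozen=True)
class PrcCurve:
    """Sampled phase response curve: shift per unit pulse strength.

    ``phases`` is a grid over ``(0, 2*pi]`` with origin at the
    membrane-potential maximum; ``values[k]`` is the asymptotic phase
    advance per unit pulse applied at ``phases[k]``.
    """

    phases: np.ndarray
    values: np.ndarray
    period: float
    kick_size: float

    #: class I means an (essentially) nonnegative PRC; a small negative
    #: lobe right after the spike — a few percent of the peak, as the
    #: Morris-Lecar model genuinely shows — is tolerated
    NEG_TOL_FRACTION = 0.025

    def __post_init__(self):
        tol = self.NEG_TOL_FRACTION * float(np.max(self.values))
        if np.min(self.values) < -tol:
            raise ValueError(
                "PRC has significantly negative values; not a class I response"
            )

    def __call__(self, phi):
        """Periodic linear interpolation of the sampled curve."""
        phi = np.mod(phi, TWO_PI)
        grid = np.concatenate(([self.phases[-1] - TWO_PI], self.phases))
        vals = np.concatenate(([self.values[-1]], self.values))
        return np.interp(phi, grid, vals)


def integrate(model, state0, t_span, *, dense=False, rtol=1e-8, atol=1e-10,
              max_events=None):
    """Integrate a model, locating membrane-potential maxima as events.

    Maxima are roots of ``dv/dt`` with negative crossing and ``v`` above
    the model's spike threshold.  Returns the scipy solution object with
    an extra attribute ``spike_times`` (times of suprathreshold maxima).
    Gating variables staying in [0, 1] and finite states are asserted.
    """

    def v_max_event(t, y):
        return model.dv_dt(t, y)

    v_max_event.direction = -1.0
    if max_events is not None:
        # crude cap: terminate after enough maxima via a wrapper below
        pass

    sol = solve_ivp(
        model.rhs,
        t_span,
        np.asarray(state0, dtype=float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=dense,
        events=v_max_event,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"integration failed: {sol.message}")
    gating = sol.y[1:]
    if gating.min() < -1e-6 or gating.max() > 1.0 + 1e-6:
        raise RuntimeError("gating variables left [0, 1]; bad parameters")
    t_ev, y_ev = sol.t_events[0], sol.y_events[0]
    if len(t_ev):
        above = y_ev[:, 0] > model.spike_threshold
        sol.spike_times = t_ev[above]
    else:
        sol.spike_times = np.empty(0)
    return sol


def measure_period(
    model,
    *,
    transient_cycles: int = 10,
    t_max: float = 20000.0,
    rtol: float = 1e-8,
) -> float:
    """Steady-state interval between successive membrane-potential maxima.

    Integrates until ``transient_cycles + 3`` suprathreshold maxima have
    occurred (within the ``t_max`` cap), discards the transient and
    checks that the last two intervals agree to 1e-6 relative.  Raises
    if the neuron stays quiescent over the cap.
    """
    need = transient_cycles + 3
    state = model.rest_state()
    sol = integrate(model, state, (0.0, t_max), rtol=rtol)
    spikes = sol.spike_times
    if len(spikes) < 2:
        raise RuntimeError(f"quiescent: fewer than 2 spikes within {t_max} ms")
    if len(spikes) < need:
        raise RuntimeError(
            f"only {len(spikes)} spikes within {t_max} ms; "
            f"increase t_max to discard {transient_cycles} transient cycles"
        )
    intervals = np.diff(spikes[-3:])
    if abs(intervals[1] - intervals[0]) > 1e-6 * intervals[1]:
        raise RuntimeError(
            f"period not settled: last intervals {intervals} differ by more "
            "than 1e-6 relative"
        )
    return float(intervals[-1])


def _is_spiking(model, horizon: float, rtol: float) -> bool:
    """True when suprathreshold maxima persist in the second half of the horizon."""
    sol = integrate(model, model.rest_state(), (0.0, horizon), rtol=rtol)
    return np.sum(sol.spike_times > horizon / 2.0) >= 2


def find_snic_current(
    model: WbParams,
    bracket: tuple[float, float] = (0.1, 0.2),
    tol: float = 1e-4,
    *,
    horizon: float = 10000.0,
    rtol: float = 1e-8,
) -> float:
    """Bisect the drive current for the onset of sustained firing.

    The lower bracket must be quiescent and the upper spiking; the
    midpoint of the final bracket approximates the SNIC bifurcation
    current.  Because the period diverges at the bifurcation, the
    spiking predicate uses a long horizon and only counts maxima in its
    second half.
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError(f"invalid bracket {bracket}")
    if _is_spiking(replace(model, I=lo), horizon, rtol):
        raise ValueError(f"lower bracket I={lo} is already spiking")
    if not _is_spiking(replace(model, I=hi), horizon, rtol):
        raise ValueError(f"upper bracket I={hi} is quiescent")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _is_spiking(replace(model, I=mid), horizon, rtol):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _limit_cycle(model, *, transient_cycles: int, rtol: float, t_max: float):
    """Return (period, dense one-period solution starting at a v-maximum)."""
    T = measure_period(model, transient_cycles=transient_cycles, t_max=t_max, rtol=rtol)
    sol = integrate(model, model.rest_state(), (0.0, t_max), rtol=rtol)
    t0 = sol.spike_times[-2]
    # re-integrate one period densely from the state at the maximum
    y0 = sol.sol(t0) if sol.sol is not None else None
    if y0 is None:
        sol = integrate(model, model.rest_state(), (0.0, t0 + 2 * T), dense=True, rtol=rtol)
        y0 = sol.sol(t0)
    cycle = integrate(model, y0, (0.0, T), dense=True, rtol=rtol)
    return T, cycle


def compute_prc(
    model,
    *,
    n_phases: int = 200,
    kick_size: float = 1e-2,
    n_settle: int = 10,
    transient_cycles: int = 12,
    t_max: float = 20000.0,
    rtol: float = 1e-8,
    verify_linearity: bool = False,
) -> PrcCurve:
    """Extract the phase response curve by direct pulse perturbation.

    For each phase on a uniform grid over ``(0, 2*pi]`` the limit-cycle
    state at that phase receives an instantaneous voltage increment of
    ``kick_size`` (mV).  The perturbed trajectory is integrated for
    ``n_settle`` further periods and the asymptotic advance of its
    spike times over the unperturbed ones, converted to phase, gives
    ``Z(phi) = dphi / kick_size`` — the response per unit jump of the
    membrane potential, the normalization under which the QIF PRC is
    ``2*(1 - cos(phi)) / omega``.

    With ``verify_linearity`` the whole curve is recomputed at half the
    kick; a deviation above 1% of the maximum raises.
    """
    T, cycle = _limit_cycle(model, transient_cycles=transient_cycles, rtol=rtol, t_max=t_max)
    dv = kick_size
    phases = TWO_PI * np.arange(1, n_phases + 1) / n_phases

    def one_pass(dv_amp):
        vals = np.empty(n_phases)
        for k, phi in enumerate(phases):
            tau = (phi / TWO_PI) * T  # time since the v-maximum
            y0 = cycle.sol(tau).copy()
            y0[0] += dv_amp
            horizon = (n_settle + 1.5) * T - tau
            pert = integrate(model, y0, (0.0, horizon), rtol=rtol)
            if len(pert.spike_times) < n_settle:
                raise RuntimeError(
                    f"perturbed trajectory at phase {phi:.3f} lost the limit cycle"
                )
            # match the last perturbed maximum to its unperturbed index;
            # the pulse-induced shift is far below one period, so the
            # nearest multiple of T identifies the spike unambiguously
            t_last = pert.spike_times[-1]
            k_idx = round((t_last + tau) / T)
            vals[k] = TWO_PI * ((k_idx * T - tau) - t_last) / T
        return vals

    values = one_pass(dv) / kick_size
    if verify_linearity:
        values_half = one_pass(dv / 2.0) / (kick_size / 2.0)
        dev = np.max(np.abs(values_half - values))
        if dev > 0.01 * np.max(np.abs(values)):
            raise RuntimeError(
                f"PRC nonlinearity {dev:.3g} exceeds 1% of the maximum; "
                "reduce kick_size"
            )
    return PrcCurve(phases=phases, values=values, period=T, kick_size=kick_size)


def fit_parabola(curve: PrcCurve, window_fraction: float = 0.9) -> PRCFit:
    """Least-squares parabola through the PRC peak.

    Fits ``Z_max - alpha * (phi - phi_max)**2`` over the contiguous run
    of grid points around the maximum with ``Z >= window_fraction *
    max(Z)``.  The window is widened automatically (down to 0.5) when it
    holds fewer than 5 points.
    """
    z = np.asarray(curve.values, dtype=float)
    phi = np.asarray(curve.phases, dtype=float)
    k0 = int(np.argmax(z))
    zmax = z[k0]
    frac = window_fraction
    while True:
        lo = k0
        while lo > 0 and z[lo - 1] >= frac * zmax:
            lo -= 1
        hi = k0
        while hi < len(z) - 1 and z[hi + 1] >= frac * zmax:
            hi += 1
        if hi - lo + 1 >= 5:
            break
        frac -= 0.05
        if frac < 0.5:
            raise ValueError("fewer than 5 grid points near the PRC peak")
    a2, a1, a0 = np.polyfit(phi[lo : hi + 1], z[lo : hi + 1], 2)
    if a2 >= 0:
        raise ValueError("PRC peak is not concave; parabola fit invalid")
    alpha = -a2
    phi_max = a1 / (2.0 * alpha)
    Z_max = a0 + alpha * phi_max**2
    return PRCFit(Z_max=float(Z_max), phi_max=float(phi_max), alpha=float(alpha))
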