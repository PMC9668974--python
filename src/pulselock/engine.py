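"""Exact event-driven simulation of pulse-coupled phase neurons with STDP.

Between spikes every phase advances linearly at its natural frequency,
so the next firing time is known in closed form and the simulation
jumps from event to event with no integration error.  At each event the
firing neuron's spike instantaneously kicks every other neuron — through
the exact QIF phase-jump formula, or through a tabulated phase response
curve ``phi += g * W * Z(phi)`` for general class I neurons — and the
STDP rule updates the weights feeding and leaving the firing neuron.

A kick applied through a tabulated PRC can push a target past the
firing threshold; such neurons fire at the same instant in a zero-delay
cascade, processed in ascending index order.  The exact QIF jump can
only approach the threshold, so QIF cascades arise only from exact
ties in the next-event time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Literal, Sequence
import warnings

import numpy as np

from .qif import TWO_PI, arccot
from .stdp import StdpParams, apply_spike_update

__all__ = [
    "NeuronSpec",
    "NetworkConfig",
    "EventLog",
    "next_event",
    "run",
    "interspike_intervals",
    "winding_number",
    "classify_mode",
]


@dataclass(frozen=True)
class NeuronSpec:
    """One oscillator: natural period ``T`` and, optionally, a tabulated PRC.

    ``prc=None`` selects the exact QIF phase dynamics.  A tabulated PRC
    is a callable ``Z(phi)`` (phase shift per unit pulse strength) used
    in the weak-coupling Winfree update; phase 0 is calibrated at the
    membrane-potential maximum so firing occurs at ``2*pi``.
    """

    T: float
    prc: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError(f"natural period must be positive, got {self.T}")

    @property
    def omega(self) -> float:
        return TWO_PI / self.T


@dataclass
class ConvergenceRule:
    """Early stopping once all weights have saturated at the bounds.

    The run terminates when every off-diagonal weight stays within
    ``tol`` of 0 or 1 for ``patience`` consecutive periods of the
    slowest neuron.  Saturation happens in stages, so the patience
    window guards against declaring convergence during the first stage.
    """

    tol: float = 1e-3
    patience: int = 50


@dataclass
class NetworkConfig:
    """Complete description of one simulation run."""

    neurons: Sequence[NeuronSpec]
    g: float
    t_max: float
    stdp: StdpParams | None = None
    W0: np.ndarray | None = None
    phases0: np.ndarray | None = None
    seed: int | None = None
    convergence: ConvergenceRule | None = field(default_factory=ConvergenceRule)
    sample_every: float | None = None

    def __post_init__(self):
        if self.g < 0:
            raise ValueError(f"coupling strength must be >= 0, got {self.g}")
        if self.t_max <= 0:
            raise ValueError(f"t_max must be positive, got {self.t_max}")
        if len(self.neurons) == 0:
            raise ValueError("need at least one neuron")


@dataclass
class EventLog:
    """Time-ordered record of a run."""

    spike_times: np.ndarray
    spike_neurons: np.ndarray
    final_W: np.ndarray
    weight_trace_times: np.ndarray
    weight_trace: np.ndarray  # (n_samples, N, N)
    periods: np.ndarray  # natural periods of the neurons
    converged_at: float | None
    saturated_at: float | None
    t_end: float
    seed: int | None

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.spike_times[self.spike_neurons == neuron]


def default_initial_phases(N: int) -> np.ndarray:
    """Near-identical initial phases with a tiny index-proportional stagger.

    A strict tie at t=0 is broken deterministically; the stagger
    ``2*pi*i/N * 1e-3`` is far below any phase scale of the dynamics.
    """
    return TWO_PI * np.arange(N) / max(N, 1) * 1e-3


def next_event(phases: np.ndarray, omegas: np.ndarray) -> tuple[int, float]:
    """Index and delay of the next neuron to reach the firing threshold.

    ``dt_i = (2*pi - phi_i) / omega_i``; ties go to the lowest index
    (``argmin`` convention).
    """
    dts = (TWO_PI - np.asarray(phases)) / np.asarray(omegas)
    j = int(np.argmin(dts))
    return j, float(dts[j])


def _kick_qif(phases: np.ndarray, omegas: np.ndarray, kicks: np.ndarray) -> np.ndarray:
    """Vectorized exact QIF pulse response; phases at 0 are unaffected."""
    out = phases.copy()
    act = (kicks > 0) & (phases > 0) & (phases < TWO_PI)
    if act.any():
        half = phases[act] / 2.0
        out[act] = 2.0 * arccot(1.0 / np.tan(half) - 2.0 * kicks[act] / omegas[act])
    return out


def run(config: NetworkConfig) -> EventLog:
    """Simulate the network to ``t_max`` or weight convergence.

    Returns an :class:`EventLog` with all spikes, sampled weight
    snapshots and the final weight matrix.  With ``stdp=None`` the
    weights stay frozen at ``W0``.
    """
    neurons = list(config.neurons)
    N = len(neurons)
    omegas = np.array([nu.omega for nu in neurons])
    periods = np.array([nu.T for nu in neurons])
    prcs = [nu.prc for nu in neurons]
    all_qif = all(z is None for z in prcs)
    if not all_qif and any(z is None for z in prcs):
        raise ValueError("mix of exact-QIF and tabulated-PRC neurons is not supported")

    if config.W0 is None:
        W = np.zeros((N, N))
    else:
        W = np.array(config.W0, dtype=float)
        if W.shape != (N, N):
            raise ValueError(f"W0 must be {N}x{N}, got {W.shape}")
        if np.any((W < 0) | (W > 1)):
            raise ValueError("initial weights must lie in [0, 1]")
        np.fill_diagonal(W, 0.0)

    phi = (
        default_initial_phases(N)
        if config.phases0 is None
        else np.array(config.phases0, dtype=float)
    )
    if np.any((phi < 0) | (phi >= TWO_PI)):
        raise ValueError("initial phases must lie in [0, 2*pi)")

    T_slow = periods.max()
    sample_every = (
        config.sample_every if config.sample_every is not None else max(config.t_max / 400.0, T_slow)
    )

    t = 0.0
    last_fire = np.full(N, np.nan)
    spike_t: list[float] = []
    spike_id: list[int] = []
    trace_t: list[float] = [0.0]
    trace_W: list[np.ndarray] = [W.copy()]
    next_sample = sample_every

    conv = config.convergence if config.stdp is not None else None
    offdiag = ~np.eye(N, dtype=bool)
    saturated_since: float | None = None
    converged_at: float | None = None
    next_conv_check = T_slow

    g = config.g
    while t < config.t_max:
        j, dt = next_event(phi, omegas)
        t_new = t + dt
        if t_new > config.t_max:
            break
        t = t_new
        phi = phi + omegas * dt
        phi[j] = TWO_PI

        # zero-delay cascade: the firing neuron kicks the others; a kick
        # through a tabulated PRC may fire them at the same instant
        pending = [j]
        fired_now: set[int] = set()
        while pending:
            f = pending.pop(0)
            if f in fired_now:
                raise RuntimeError(f"neuron {f} fired twice in one event cascade (runaway)")
            fired_now.add(f)
            spike_t.append(t)
            spike_id.append(f)
            if g > 0 and N > 1:
                kicks = g * W[:, f]
                kicks[f] = 0.0
                targets = phi < TWO_PI
                if all_qif:
                    phi = np.where(targets, _kick_qif(phi, omegas, kicks), phi)
                else:
                    newphi = phi.copy()
                    for i in np.nonzero(targets & (kicks > 0))[0]:
                        newphi[i] = phi[i] + kicks[i] * float(prcs[i](phi[i]))
                    if np.any(newphi >= 2 * TWO_PI):
                        raise RuntimeError("a single kick advanced a phase past a full turn")
                    phi = newphi
            if config.stdp is not None:
                apply_spike_update(W, config.stdp, f, t, last_fire, inplace=True)
            last_fire[f] = t
            phi[f] = 0.0
            over = [int(i) for i in np.nonzero(phi >= TWO_PI)[0]]
            if any(i in fired_now for i in over):
                raise RuntimeError(
                    "a neuron crossed threshold twice within one event cascade "
                    "(runaway kick; check PRC magnitude and coupling strength)"
                )
            crossed = [i for i in over if i not in pending]
            if len(fired_now) + len(pending) + len(crossed) > N:
                raise RuntimeError("cascade depth exceeded network size")
            pending.extend(sorted(crossed))
            for i in crossed:
                phi[i] = TWO_PI

        if t >= next_sample:
            trace_t.append(t)
            trace_W.append(W.copy())
            next_sample += sample_every

        if conv is not None and t >= next_conv_check:
            next_conv_check += T_slow
            at_bounds = np.all(np.abs(W[offdiag] - np.round(W[offdiag])) <= conv.tol)
            if at_bounds:
                if saturated_since is None:
                    saturated_since = t
                elif t - saturated_since >= conv.patience * T_slow:
                    converged_at = t
                    break
            else:
                saturated_since = None

    trace_t.append(t)
    trace_W.append(W.copy())
    return EventLog(
        spike_times=np.array(spike_t),
        spike_neurons=np.array(spike_id, dtype=int),
        final_W=W,
        weight_trace_times=np.array(trace_t),
        weight_trace=np.array(trace_W),
        periods=periods,
        converged_at=converged_at,
        saturated_at=saturated_since,
        t_end=t,
        seed=config.seed,
    )


def interspike_intervals(log: EventLog, neuron: int) -> np.ndarray:
    """Consecutive differences of one neuron's spike times."""
    times = log.spikes_of(neuron)
    if times.size < 2:
        warnings.warn(f"neuron {neuron} fired fewer than twice; no intervals")
        return np.empty(0)
    return np.diff(times)


def _analysis_start(log: EventLog) -> float:
    """Post-transient cut for winding/mode analysis.

    With a converged run, everything after saturation of the weights is
    asymptotic; otherwise only the last 20% of the horizon is used.
    """
    if log.saturated_at is not None:
        return min(log.saturated_at, 0.8 * log.t_end)
    return 0.8 * log.t_end


def winding_number(
    log: EventLog,
    fast: int,
    slow: int,
    window: int = 20,
    *,
    lag_tol: float = 1e-4,
) -> Fraction | None:
    """Locked spike-count ratio ``n/1`` of ``fast`` per period of ``slow``.

    Over the last ``window`` interspike intervals of the slow neuron
    (post-transient), requires (a) the same integer number of fast
    spikes in every slow period and (b) a converged lag between the
    slow spike and the preceding fast spike (drift below ``lag_tol``
    per period, in units of the slow period).  Returns the reduced
    ratio, or ``None`` when the pair is unlocked.
    """
    t0 = _analysis_start(log)
    slow_times = log.spikes_of(slow)
    fast_times = log.spikes_of(fast)
    slow_times = slow_times[slow_times >= t0]
    if slow_times.size < window + 1:
        raise ValueError(
            f"analysis window needs {window + 1} post-transient slow spikes, "
            f"got {slow_times.size}"
        )
    slow_times = slow_times[-(window + 1):]
    counts = np.histogram(fast_times, bins=slow_times)[0]
    if counts.min() != counts.max():
        return None
    n = int(counts[0])
    if n == 0:
        return None
    # lag of the last fast spike before each slow spike, in slow-period units
    idx = np.searchsorted(fast_times, slow_times[1:], side="left") - 1
    if np.any(idx < 0):
        return None
    lags = (slow_times[1:] - fast_times[idx]) / np.diff(slow_times)
    if np.max(np.abs(np.diff(lags))) > lag_tol:
        return None
    return Fraction(n, 1)


def classify_mode(
    log: EventLog,
    eps_w: float = 0.05,
    window: int = 20,
) -> Literal["i", "ii", "iii", "other"]:
    """Label the asymptotic state of a two-neuron run.

    mode i: slow->fast link saturated, ``(W12, W21) ~ (1, 0)``, locked
    at ``n/1`` with ``n >= 2``; mode ii: the reverse link, locked 1/1;
    mode iii: both links dead and no locking.  Everything else is
    ``"other"``.  Neuron 0 is the faster one by convention.
    """
    if log.final_W.shape != (2, 2):
        raise ValueError("mode classification is defined for two-neuron runs")
    W12 = log.final_W[0, 1]  # slow (1) -> fast (0)
    W21 = log.final_W[1, 0]  # fast (0) -> slow (1)
    try:
        w = winding_number(log, fast=0, slow=1, window=window)
    except ValueError:
        return "other"
    if W12 > 1 - eps_w and W21 < eps_w and w is not None and w >= 2:
        return "i"
    if W12 < eps_w and W21 > 1 - eps_w and w == 1:
        return "ii"
    if W12 < eps_w and W21 < eps_w and w is None:
        return "iii"
    return "other"
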