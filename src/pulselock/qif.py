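"""Quadratic integrate-and-fire neurons in phase representation.

The QIF membrane equation ``dv/dt = v**2 + eta`` with reset at
``v = -inf`` and peak at ``v = +inf`` is the normal form of class I
excitability near a SNIC bifurcation.  For ``eta > 0`` the neuron spikes
periodically with period ``T = pi / sqrt(eta)``.  The substitution
``v = -sqrt(eta) * cot(phi / 2)`` maps the voltage onto a phase
``phi in (0, 2*pi]`` that advances uniformly at the natural angular
frequency ``omega = 2*pi / T`` between synaptic pulses; the neuron fires
when ``phi`` reaches ``2*pi``.  A delta pulse of strength ``k`` adds
``k`` to the voltage, which in phase variables is the exact jump
implemented by :func:`phase_jump`.  The linear response to a weak pulse
is the phase response curve ``Z(phi) = 2 * (1 - cos(phi)) / omega``.

All functions here are pure and exact (no time stepping); the event
engine composes them into a simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QifNeuron",
    "natural_period",
    "eta_from_period",
    "voltage_to_phase",
    "phase_to_voltage",
    "qif_prc",
    "phase_jump",
    "arccot",
]

TWO_PI = 2.0 * math.pi


def natural_period(eta: float) -> float:
    """Period of a free QIF neuron, ``T = pi / sqrt(eta)``.

    Parameters
    ----------
    eta : float
        Excitability parameter; must be positive (spiking regime).  For
        ``eta <= 0`` the neuron is excitable, not oscillatory, and is
        rejected.
    """
    if eta <= 0:
        raise ValueError(f"eta must be > 0 for a spiking QIF neuron, got {eta}")
    return math.pi / math.sqrt(eta)


def eta_from_period(T: float) -> float:
    """Inverse of :func:`natural_period`: ``eta = (pi / T)**2``."""
    if T <= 0:
        raise ValueError(f"period must be positive, got {T}")
    return (math.pi / T) ** 2


def arccot(x):
    """Inverse cotangent with range ``(0, pi)``.

    This is the branch for which ``arccot(cot(theta)) == theta`` on
    ``(0, pi)``, so the half-angle phase map round-trips exactly.
    """
    return math.pi / 2.0 - np.arctan(x)


def voltage_to_phase(v: float, eta: float) -> float:
    """Map a membrane potential to its phase, ``phi = 2*arccot(-v/sqrt(eta))``.

    ``v -> -inf`` (reset) maps to phase 0 and ``v -> +inf`` (peak) to
    ``2*pi``; finite voltages land strictly inside ``(0, 2*pi)``.
    """
    if eta <= 0:
        raise ValueError(f"eta must be > 0, got {eta}")
    s = math.sqrt(eta)
    if math.isinf(v):
        return TWO_PI if v > 0 else 0.0
    return float(2.0 * arccot(-v / s))


def phase_to_voltage(phi: float, eta: float, *, allow_infinite: bool = False) -> float:
    """Membrane potential at phase ``phi``: ``v = -sqrt(eta) * cot(phi/2)``.

    Exact inverse of :func:`voltage_to_phase` on ``(0, 2*pi)``.  The
    endpoints correspond to infinite voltage; they are rejected unless
    ``allow_infinite`` is set, in which case signed infinity is returned
    (``-inf`` at 0, ``+inf`` at ``2*pi``).
    """
    if eta <= 0:
        raise ValueError(f"eta must be > 0, got {eta}")
    if phi <= 0.0 or phi >= TWO_PI:
        if allow_infinite and (phi == 0.0 or phi == TWO_PI):
            return -math.inf if phi == 0.0 else math.inf
        raise ValueError(f"phase must lie in (0, 2*pi), got {phi}")
    return -math.sqrt(eta) / math.tan(phi / 2.0)


def qif_prc(phi, omega: float):
    """QIF phase response curve ``Z(phi) = 2*(1 - cos(phi)) / omega``.

    Nonnegative (class I), zero at ``phi = 0`` and maximal, ``4/omega``,
    at ``phi = pi``.  Accepts scalars or arrays.
    """
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    return 2.0 * (1.0 - np.cos(phi)) / omega


def phase_jump(phi, omega: float, dt: float = 0.0, kick: float = 0.0):
    """Drift a QIF phase for ``dt`` then apply a delta pulse of strength ``kick``.

    Returns ``2*arccot(cot((phi + omega*dt)/2) - 2*kick/omega)``, the
    exact post-pulse phase.  The result always lies in ``(0, 2*pi)`` and
    is never below the unkicked phase (excitatory pulses only advance a
    class I neuron); as ``kick -> inf`` the phase approaches ``2*pi``
    without crossing it, so an exact QIF pulse never fires the target
    within the same event.  Accepts scalar or array ``phi``/``kick``.
    """
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if omega <= 0:
        raise ValueError(f"omega must be > 0, got {omega}")
    half = (np.asarray(phi) + omega * dt) / 2.0
    out = 2.0 * arccot(1.0 / np.tan(half) - 2.0 * np.asarray(kick) / omega)
    if np.ndim(phi) == 0 and np.ndim(kick) == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class QifNeuron:
    """A spiking QIF neuron, constructed from its excitability ``eta``.

    Attributes
    ----------
    eta : float
        Excitability (must be > 0).
    T : float
        Natural period ``pi / sqrt(eta)``.
    omega : float
        Natural angular frequency ``2*pi / T``.
    """

    eta: float
    T: float
    omega: float

    def __init__(self, eta: float | None = None, *, T: float | None = None):
        if (eta is None) == (T is None):
            raise ValueError("specify exactly one of eta or T")
        if eta is None:
            eta = eta_from_period(T)
        period = natural_period(eta)
        object.__setattr__(self, "eta", float(eta))
        object.__setattr__(self, "T", period)
        object.__setattr__(self, "omega", TWO_PI / period)

    def prc(self, phi):
        return qif_prc(phi, self.omega)
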