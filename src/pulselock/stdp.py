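"""Additive nearest-neighbor pair-based STDP with hard weight bounds.

When neuron ``j`` fires at time ``t``, every partner ``i != j`` that has
fired before contributes one pair with spike-time difference
``delta = t - t_i_last >= 0``:

* the incoming weight ``W[j][i]`` (link i -> j, pre before post) is
  potentiated by ``p * exp(-delta / tau_p)``;
* the outgoing weight ``W[i][j]`` (link j -> i, post before pre) is
  depressed by ``d * exp(-delta / tau_d)``.

Updates are additive, and weights are clipped to ``[0, 1]`` after every
update (hard bounds).  Only the most recent spike of each partner is
paired (nearest-neighbor scheme); neurons that have never fired
contribute nothing.  With ``p == d`` and ``tau_p < tau_d`` depression
dominates at every positive ``delta``, which drives the competition
between the two directions of a synapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StdpParams", "apply_spike_update"]


@dataclass(frozen=True)
class StdpParams:
    """Amplitudes and learning windows of the pair-based rule.

    ``p``/``d`` are the maximum potentiation/depression amplitudes (both
    << 1 so weights drift slowly relative to firing); ``tau_p``/``tau_d``
    are the corresponding exponential learning windows, in the same time
    units as the simulation.
    """

    p: float
    d: float
    tau_p: float
    tau_d: float

    def __post_init__(self):
        for name in ("p", "d", "tau_p", "tau_d"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def require_symmetric(self) -> None:
        """Assert the ``p == d``, ``tau_p <= tau_d`` regime of the analytic theory."""
        if self.p != self.d:
            raise ValueError(f"analytic results require p == d, got p={self.p}, d={self.d}")
        if self.tau_p > self.tau_d:
            raise ValueError(
                f"analytic results require tau_p <= tau_d, got tau_p={self.tau_p}, tau_d={self.tau_d}"
            )


def apply_spike_update(
    W: np.ndarray,
    params: StdpParams,
    j: int,
    t: float,
    last_fire: np.ndarray,
    *,
    inplace: bool = False,
) -> np.ndarray:
    """Apply the STDP rule for a spike of neuron ``j`` at time ``t``.

    Parameters
    ----------
    W : ndarray, shape (N, N)
        Weight matrix; ``W[i][j]`` is the synapse from presynaptic ``j``
        to postsynaptic ``i``.  Diagonal must be zero and stays zero.
    last_fire : ndarray, shape (N,)
        Most recent firing time of each neuron; ``nan`` for a neuron
        that has never fired.  ``last_fire[j]`` itself is ignored (no
        self-pairing).
    inplace : bool
        Mutate ``W`` instead of copying (used by the event engine).

    Returns
    -------
    ndarray
        Updated weight matrix, clipped to ``[0, 1]``; only row ``j`` and
        column ``j`` are touched.
    """
    W = W if inplace else W.copy()
    n = W.shape[0]
    fired = np.isfinite(last_fire)
    fired[j] = False
    if not fired.any():
        return W
    delta = t - last_fire[fired]
    if np.any(delta < -1e-12):
        raise ValueError(
            f"negative spike-time difference (min {delta.min()}): event ordering is broken"
        )
    delta = np.maximum(delta, 0.0)
    idx = np.nonzero(fired)[0]
    W[j, idx] = np.clip(W[j, idx] + params.p * np.exp(-delta / params.tau_p), 0.0, 1.0)
    W[idx, j] = np.clip(W[idx, j] - params.d * np.exp(-delta / params.tau_d), 0.0, 1.0)
    W[j, j] = 0.0
    assert W.shape == (n, n)
    return W
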