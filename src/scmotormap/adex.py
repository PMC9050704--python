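"""Adaptive exponential integrate-and-fire (AdEx) dynamics with conductance
synapses.

Every neuron in both layers follows

    C dV/dt = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T) - q
              + g_exc (E_exc - V) + g_inh (E_inh - V) + I_ext
    tau_q dq/dt = a (V - E_L) - q

with a spike emitted when V reaches V_cut, after which V is clamped to
V_reset for a refractory period t_ref and the adaptation current q is
incremented by b.  Synaptic conductances are non-negative and decay
exponentially with their own time constants; presynaptic spikes increment
them instantaneously.

Integration is forward Euler for (V, q) and exponential Euler for the
conductances, at dt <= 0.1 ms.  The exponential spike-initiation term is
clamped at +10 slope factors above V_T to prevent overflow; the V_cut
detection fires long before the clamp matters at the default dt.

The input layer additionally passes its external drive through a saturating
sigmoid (:func:`rate_cap_transfer`), which together with its 2.5 ms
refractory period caps input-layer firing at 400 spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

__all__ = [
    "AdExParams",
    "AdExState",
    "LayerParams",
    "adex_step",
    "deliver_spike",
    "rate_cap_transfer",
    "step_layer",
    "SimulationError",
]

# Clamp on (V - V_T)/Delta_T inside the exponential term.
EXP_CLAMP = 10.0


class SimulationError(RuntimeError):
    """Raised when the integrator produces a non-finite state."""


@dataclass(frozen=True)
class AdExParams:
    """Biophysical constants of one AdEx neuron (pF, nS, mV, ms, pA units)."""

    C_pF: float
    g_L_nS: float
    E_L_mV: float = -70.0
    V_T_mV: float = -50.0
    Delta_T_mV: float = 2.0
    a_nS: float = 0.0
    b_pA: float = 0.0
    tau_q_ms: float = 30.0
    V_reset_mV: float = -58.0
    V_cut_mV: float = -30.0
    t_ref_ms: float = 1.0
    E_exc_mV: float = 0.0
    E_inh_mV: float = -80.0
    tau_syn_exc_ms: float = 1.5
    tau_syn_inh_ms: float = 5.0

    def __post_init__(self) -> None:
        if self.C_pF <= 0 or self.g_L_nS <= 0:
            raise ValueError("C and g_L must be positive")
        if self.Delta_T_mV <= 0 or self.tau_q_ms <= 0:
            raise ValueError("Delta_T and tau_q must be positive")
        if not self.E_inh_mV < self.E_L_mV < self.E_exc_mV:
            raise ValueError("reversal potentials must satisfy E_inh < E_L < E_exc")
        if not self.V_reset_mV <= self.V_T_mV < self.V_cut_mV:
            raise ValueError("potentials must satisfy V_reset <= V_T < V_cut")
        if self.tau_syn_exc_ms <= 0 or self.tau_syn_inh_ms <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.t_ref_ms < 0:
            raise ValueError("t_ref must be non-negative")

    @property
    def tau_m_ms(self) -> float:
        return self.C_pF / self.g_L_nS


@dataclass(frozen=True)
class AdExState:
    """Dynamic variables of one neuron at time ``t_ms``."""

    V_mV: float
    q_pA: float = 0.0
    g_exc_nS: float = 0.0
    g_inh_nS: float = 0.0
    t_last_spike_ms: float = -np.inf
    t_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.g_exc_nS < 0 or self.g_inh_nS < 0:
            raise ValueError("synaptic conductances must be non-negative")


class LayerParams:
    """AdEx constants of a whole layer as broadcast arrays.

    Built from a scalar :class:`AdExParams` plus optional per-neuron
    overrides (used for the rostral-caudal adaptation gradient).
    """

    FIELDS = ("C_pF", "g_L_nS", "E_L_mV", "V_T_mV", "Delta_T_mV", "a_nS",
              "b_pA", "tau_q_ms", "V_reset_mV", "V_cut_mV", "t_ref_ms",
              "E_exc_mV", "E_inh_mV", "tau_syn_exc_ms", "tau_syn_inh_ms")

    def __init__(self, base: AdExParams, n: int,
                 overrides: Mapping[str, np.ndarray] | None = None) -> None:
        self.n = n
        overrides = dict(overrides or {})
        unknown = set(overrides) - set(self.FIELDS)
        if unknown:
            raise ValueError(f"unknown AdEx fields: {sorted(unknown)}")
        for name in self.FIELDS:
            if name in overrides:
                arr = np.broadcast_to(np.asarray(overrides[name], float), (n,)).copy()
            else:
                arr = np.full(n, getattr(base, name), dtype=float)
            setattr(self, name, arr)
        if np.any(self.tau_q_ms <= 0):
            raise ValueError("tau_q must be positive for every neuron")

    def scaled(self, current_scale: float) -> "LayerParams":
        """Copy with (C, g_L) jointly multiplied by ``current_scale``.

        Scaling both leaves all voltage trajectories and time constants
        unchanged for a proportionally scaled input current, i.e. it sets the
        current sensitivity of the layer without touching its dynamics.
        """
        if current_scale <= 0:
            raise ValueError("current_scale must be positive")
        out = object.__new__(LayerParams)
        out.n = self.n
        for name in self.FIELDS:
            arr = getattr(self, name).copy()
            if name in ("C_pF", "g_L_nS"):
                arr *= current_scale
            setattr(out, name, arr)
        return out


def step_layer(V: np.ndarray, q: np.ndarray, g_exc: np.ndarray,
               g_inh: np.ndarray, t_last: np.ndarray, t_ms: float, dt_ms: float,
               I_ext: np.ndarray | float, p: LayerParams) -> np.ndarray:
    """Advance one layer by one step in place; return the boolean spike mask.

    Spikes are stamped at the beginning of the step in which V crossed V_cut.
    Synaptic conductances decay after the membrane update so that increments
    delivered afterwards enter the next step undecayed.
    """
    in_ref = (t_ms - t_last) < p.t_ref_ms
    expo = np.exp(np.minimum((V - p.V_T_mV) / p.Delta_T_mV, EXP_CLAMP))
    I_mem = (-p.g_L_nS * (V - p.E_L_mV)
             + p.g_L_nS * p.Delta_T_mV * expo
             - q
             + g_exc * (p.E_exc_mV - V)
             + g_inh * (p.E_inh_mV - V)
             + I_ext)
    dq = (dt_ms / p.tau_q_ms) * (p.a_nS * (V - p.E_L_mV) - q)
    V_new = np.where(in_ref, p.V_reset_mV, V + (dt_ms / p.C_pF) * I_mem)
    q += dq
    spiked = ~in_ref & (V_new >= p.V_cut_mV)
    V_new[spiked] = p.V_reset_mV[spiked]
    q[spiked] += p.b_pA[spiked]
    t_last[spiked] = t_ms
    V[:] = V_new
    g_exc *= np.exp(-dt_ms / p.tau_syn_exc_ms)
    g_inh *= np.exp(-dt_ms / p.tau_syn_inh_ms)
    return spiked


def adex_step(state: AdExState, params: AdExParams, I_ext_pA: float,
              dt_ms: float) -> tuple[AdExState, bool]:
    """Advance a single neuron by one step; returns (new state, spiked)."""
    if not 0.0 < dt_ms <= 0.1:
        raise ValueError("dt must lie in (0, 0.1] ms")
    p = LayerParams(params, 1)
    V = np.array([state.V_mV])
    q = np.array([state.q_pA])
    ge = np.array([state.g_exc_nS])
    gi = np.array([state.g_inh_nS])
    t_last = np.array([state.t_last_spike_ms])
    spiked = step_layer(V, q, ge, gi, t_last, state.t_ms, dt_ms, I_ext_pA, p)
    if not (np.isfinite(V[0]) and np.isfinite(q[0])):
        raise SimulationError("AdEx state became non-finite")
    new = AdExState(V_mV=float(V[0]), q_pA=float(q[0]), g_exc_nS=float(ge[0]),
                    g_inh_nS=float(gi[0]), t_last_spike_ms=float(t_last[0]),
                    t_ms=state.t_ms + dt_ms)
    return new, bool(spiked[0])


def deliver_spike(state: AdExState, weight_nS: float,
                  polarity: str) -> AdExState:
    """Increment a synaptic conductance by a routed (non-negative) weight."""
    if weight_nS < 0:
        raise ValueError("routed synaptic weights must be non-negative")
    if polarity == "excitatory":
        return replace(state, g_exc_nS=state.g_exc_nS + weight_nS)
    if polarity == "inhibitory":
        return replace(state, g_inh_nS=state.g_inh_nS + weight_nS)
    raise ValueError(f"polarity must be 'excitatory' or 'inhibitory', got {polarity!r}")


def rate_cap_transfer(drive_pA, I_sat_pA: float = 15.0):
    """Saturating sigmoid on the external drive of input-layer neurons.

    ``I_sat * tanh(drive / I_sat)`` is identity-like (within about 2%) for
    drives up to the default 3 pA and bounds the effective drive by
    ``I_sat``; together with the input layer's 2.5 ms refractory period this
    caps input-layer firing at 400 spikes/s.
    """
    if I_sat_pA <= 0:
        raise ValueError("I_sat must be positive")
    out = I_sat_pA * np.tanh(np.asarray(drive_pA, dtype=float) / I_sat_pA)
    return out if out.ndim else float(out)
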