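"""Two-layer SC motor-map network: topology, gradients and simulation.

The input layer (no recurrence) projects one-to-one onto the SC layer with a
rostral-caudal gradient of feedforward weights; SC neurons are all-to-all
connected (minus self) through a Mexican-hat lateral kernel

    w_exc(i <- n) = S_n * W_exc_bar * exp(-d^2 / (2 sigma_exc^2))      n != i
    w_inh(i <- n) = S_n * (1 - W_inh_bar * exp(-d^2 / (2 sigma_inh^2)))  n != i

with d = |u_i - u_n|, scaled by the source neuron's site gain S_n.  At short
range w_inh is negative (net disinhibition); those negative values are routed
into the excitatory conductance so that conductances stay physical while the
net drive w_exc - w_inh is preserved.

Three tuned location gradients shape the rostral-caudal response repertoire:

    tau_q(u) = 60 - 12 u   (ms)   adaptation time constant
    w_FS(u)  = 10 - 1.2 u  (nS)   feedforward projection strength
    S(u)     = 1 - 0.04 u^2       lateral synaptic gain

Rostral cells (small u) get strong feedforward input and strong lateral
coupling, producing short high-frequency bursts for small saccades; caudal
cells the converse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .adex import AdExParams, LayerParams, SimulationError, rate_cap_transfer, step_layer
from .geometry import MapGrid
from .stimulus import StimulusSpec, spatial_profile, temporal_profile

__all__ = [
    "NetworkConfig",
    "SpikeRecord",
    "Network",
    "location_params",
    "lateral_weight",
    "net_lateral_kernel",
    "route_signed_weights",
    "build_network",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Connectivity constants and location gradients of the SC layer."""

    W_exc_bar_nS: float = 0.16
    W_inh_bar_nS: float = 1.15
    sigma_exc_mm: float = 0.2
    sigma_inh_mm: float = 0.7
    tau_q_intercept_ms: float = 60.0
    tau_q_slope_ms_per_mm: float = -12.0
    wFS_intercept_nS: float = 10.0
    wFS_slope_nS_per_mm: float = -1.2
    S_coeff_per_mm2: float = 0.04
    # Which side of a lateral connection supplies the site gain S; the
    # default follows the outgoing-profile reading of the kernel.
    scale_side: str = "source"

    def __post_init__(self) -> None:
        if self.sigma_exc_mm <= 0 or self.sigma_inh_mm <= 0:
            raise ValueError("kernel widths must be positive")
        if self.sigma_exc_mm >= self.sigma_inh_mm:
            raise ValueError("short-range excitation requires sigma_exc < sigma_inh")
        if self.scale_side not in ("source", "target"):
            raise ValueError("scale_side must be 'source' or 'target'")


def location_params(u_mm, cfg: NetworkConfig = NetworkConfig()):
    """Gradients (tau_q, w_FS, S) at map position u; exact affine/quadratic."""
    u = np.asarray(u_mm, dtype=float)
    if np.any(u < 0) or np.any(u > 5.0):
        raise ValueError(f"u={u_mm} outside the 0-5 mm map")
    tau_q = cfg.tau_q_intercept_ms + cfg.tau_q_slope_ms_per_mm * u
    w_FS = cfg.wFS_intercept_nS + cfg.wFS_slope_nS_per_mm * u
    S = 1.0 - cfg.S_coeff_per_mm2 * u**2
    if u.ndim:
        return tau_q, w_FS, S
    return float(tau_q), float(w_FS), float(S)


def _kernel_pair(dist_mm, S, cfg: NetworkConfig):
    g_exc = np.exp(-np.asarray(dist_mm, float) ** 2 / (2.0 * cfg.sigma_exc_mm**2))
    g_inh = np.exp(-np.asarray(dist_mm, float) ** 2 / (2.0 * cfg.sigma_inh_mm**2))
    w_exc = S * cfg.W_exc_bar_nS * g_exc
    w_inh = S * (1.0 - cfg.W_inh_bar_nS * g_inh)
    return w_exc, w_inh


def lateral_weight(u_source_mm: float, u_target_mm: float,
                   cfg: NetworkConfig = NetworkConfig()) -> tuple[float, float]:
    """Signed lateral weight pair (w_exc, w_inh) in nS for one directed edge."""
    if u_source_mm == u_target_mm:
        raise ValueError("self-connections are not part of the lateral kernel")
    u_gain = u_source_mm if cfg.scale_side == "source" else u_target_mm
    _, _, S = location_params(u_gain, cfg)
    w_exc, w_inh = _kernel_pair(abs(u_target_mm - u_source_mm), S, cfg)
    return float(w_exc), float(w_inh)


def net_lateral_kernel(delta_u_mm, u_source_mm: float,
                       cfg: NetworkConfig = NetworkConfig()):
    """Net lateral effect w_exc - w_inh at distance delta_u from a source.

    Symmetric in delta_u, positive at short range (net excitation, +0.23 nS
    at zero distance for the 15-deg site) and negative beyond the
    Mexican-hat zero crossing.  delta_u = 0 is allowed here as the analytic
    limit of the kernel; actual self-connections do not exist.
    """
    _, _, S = location_params(u_source_mm, cfg)
    w_exc, w_inh = _kernel_pair(delta_u_mm, S, cfg)
    out = w_exc - w_inh
    return out if np.ndim(out) else float(out)


def route_signed_weights(w_exc_nS, w_inh_nS):
    """Resolve the signed kernel pair into non-negative conductance increments.

    Negative short-range inhibitory weights (disinhibition) are folded into
    the excitatory increment, preserving the net drive w_exc - w_inh.
    """
    w_exc = np.asarray(w_exc_nS, dtype=float)
    w_inh = np.asarray(w_inh_nS, dtype=float)
    exc_inc = w_exc + np.maximum(0.0, -w_inh)
    inh_inc = np.maximum(0.0, w_inh)
    if exc_inc.ndim:
        return exc_inc, inh_inc
    return float(exc_inc), float(inh_inc)


@dataclass
class SpikeRecord:
    """Spike times of one simulated layer, per neuron, in ms."""

    layer: str
    times_ms: list[np.ndarray]
    positions_mm: np.ndarray
    dt_ms: float
    t_end_ms: float

    @property
    def n_neurons(self) -> int:
        return len(self.times_ms)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.times_ms])

    def total(self) -> int:
        return int(self.counts().sum())

    def min_isi_ms(self) -> float:
        """Smallest inter-spike interval over all neurons (inf if none)."""
        isis = [np.diff(t) for t in self.times_ms if len(t) > 1]
        return float(min((i.min() for i in isis if len(i)), default=np.inf))

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(self.layer, n, self.positions_mm[n], t)
                for n in range(self.n_neurons) for t in self.times_ms[n]]
        return pd.DataFrame(rows, columns=["layer", "neuron", "u_mm", "t_ms"])

    def write(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, layer: str, n_neurons: int,
                       positions_mm: np.ndarray, dt_ms: float = np.nan,
                       t_end_ms: float = np.nan) -> "SpikeRecord":
        sub = df[df["layer"] == layer] if "layer" in df else df
        times = [np.sort(sub.loc[sub["neuron"] == n, "t_ms"].to_numpy(float))
                 for n in range(n_neurons)]
        return cls(layer, times, np.asarray(positions_mm, float), dt_ms, t_end_ms)


class Network:
    """Tuned two-layer network ready for simulation."""

    def __init__(self, grid: MapGrid, input_params: AdExParams,
                 sc_params: AdExParams, cfg: NetworkConfig,
                 input_I_sat_pA: float = 15.0) -> None:
        if grid.length_mm > 5.0 + 1e-12:
            raise ValueError("gradients are defined on a 0-5 mm map")
        self.grid = grid
        self.cfg = cfg
        self.input_I_sat_pA = float(input_I_sat_pA)
        u = grid.positions
        tau_q, w_FS, S = location_params(u, cfg)
        if np.any(tau_q <= 0) or np.any(w_FS <= 0) or np.any(S < 0):
            raise ValueError("gradients must stay positive on the grid")
        self.w_FS_nS = w_FS
        self.S = S
        self.input_layer = LayerParams(input_params, grid.n_neurons)
        self.sc_layer = LayerParams(sc_params, grid.n_neurons,
                                    overrides={"tau_q_ms": tau_q})
        # Routed lateral increment matrices, (target, source), zero diagonal.
        dist = np.abs(u[:, None] - u[None, :])
        S_edge = S[None, :] if cfg.scale_side == "source" else S[:, None]
        w_exc, w_inh = _kernel_pair(dist, S_edge, cfg)
        M_exc, M_inh = route_signed_weights(w_exc, w_inh)
        np.fill_diagonal(M_exc, 0.0)
        np.fill_diagonal(M_inh, 0.0)
        self.M_exc_nS = np.ascontiguousarray(M_exc)
        self.M_inh_nS = np.ascontiguousarray(M_inh)

    def with_scales(self, input_scale: float = 1.0,
                    sc_scale: float = 1.0) -> "Network":
        """Copy with layer current sensitivities rescaled (calibration knob)."""
        out = object.__new__(Network)
        out.grid, out.cfg = self.grid, self.cfg
        out.input_I_sat_pA = self.input_I_sat_pA
        out.w_FS_nS, out.S = self.w_FS_nS, self.S
        out.M_exc_nS, out.M_inh_nS = self.M_exc_nS, self.M_inh_nS
        out.input_layer = self.input_layer.scaled(input_scale)
        out.sc_layer = self.sc_layer.scaled(sc_scale)
        return out

    def simulate(self, spec: StimulusSpec, dt_ms: float = 0.05,
                 t_end_ms: float | None = None,
                 record_input_only: bool = False) -> tuple[SpikeRecord, SpikeRecord]:
        """Deterministic run of both layers; returns (input, SC) spike records.

        Events are delivered within the step in which they occur (zero axonal
        delay).  ``record_input_only`` skips the SC layer, which is useful for
        input-layer calibration.
        """
        if dt_ms <= 0 or dt_ms > 0.1:
            raise ValueError("dt must lie in (0, 0.1] ms")
        t_end = float(t_end_ms if t_end_ms is not None else spec.t_end_ms)
        n_steps = int(round(t_end / dt_ms))
        n = self.grid.n_neurons
        u = self.grid.positions

        f_u = spec.I0_pA * spatial_profile(u, spec)
        g_t = temporal_profile((np.arange(n_steps) * dt_ms), spec)

        inp, sc = self.input_layer, self.sc_layer
        V_in = inp.E_L_mV.copy()
        q_in = np.zeros(n)
        ge_in = np.zeros(n)
        gi_in = np.zeros(n)
        last_in = np.full(n, -1e9)
        V_sc = sc.E_L_mV.copy()
        q_sc = np.zeros(n)
        ge_sc = np.zeros(n)
        gi_sc = np.zeros(n)
        last_sc = np.full(n, -1e9)

        in_idx: list[np.ndarray] = []
        in_t: list[float] = []
        sc_idx: list[np.ndarray] = []
        sc_t: list[float] = []

        for k in range(n_steps):
            t = k * dt_ms
            I_drive = rate_cap_transfer(f_u * g_t[k], self.input_I_sat_pA)
            spk_in = step_layer(V_in, q_in, ge_in, gi_in, last_in, t, dt_ms,
                                I_drive, inp)
            if spk_in.any():
                in_idx.append(np.nonzero(spk_in)[0])
                in_t.append(t)
            if record_input_only:
                continue
            if spk_in.any():
                # one-to-one feedforward, same-step delivery
                ge_sc[spk_in] += self.w_FS_nS[spk_in]
            spk_sc = step_layer(V_sc, q_sc, ge_sc, gi_sc, last_sc, t, dt_ms,
                                0.0, sc)
            if spk_sc.any():
                idx = np.nonzero(spk_sc)[0]
                sc_idx.append(idx)
                sc_t.append(t)
                ge_sc += self.M_exc_nS[:, idx].sum(axis=1)
                gi_sc += self.M_inh_nS[:, idx].sum(axis=1)

        for arr, name in ((V_in, "input V"), (V_sc, "SC V"),
                          (q_in, "input q"), (q_sc, "SC q")):
            if not np.all(np.isfinite(arr)):
                raise SimulationError(f"non-finite {name} after {t_end} ms "
                                      f"(spec={spec})")

        rec_in = _gather(in_idx, in_t, "input", n, u, dt_ms, t_end)
        rec_sc = _gather(sc_idx, sc_t, "sc", n, u, dt_ms, t_end)
        return rec_in, rec_sc


def _gather(idx_chunks: Iterable[np.ndarray], t_chunks: Iterable[float],
            layer: str, n: int, positions: np.ndarray, dt: float,
            t_end: float) -> SpikeRecord:
    per_neuron: list[list[float]] = [[] for _ in range(n)]
    for idx, t in zip(idx_chunks, t_chunks):
        for i in idx:
            per_neuron[int(i)].append(t)
    times = [np.asarray(ts, dtype=float) for ts in per_neuron]
    return SpikeRecord(layer, times, positions, dt, t_end)


def build_network(cfg: NetworkConfig, grid: MapGrid, input_params: AdExParams,
                  sc_params: AdExParams, input_I_sat_pA: float = 15.0) -> Network:
    """Construct the tuned two-layer network (validates config and gradients)."""
    return Network(grid, input_params, sc_params, cfg, input_I_sat_pA)
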