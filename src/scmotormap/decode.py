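"""Linear spike-vector decoding of SC activity and saccade kinematics.

The eye displacement is the running sum of spike vectors over the whole SC
population,

    S(t) = sum_n m_n * N_n(t),    m_n = zeta * R(u_n) / N_ref,

binned at a fixed decoder resolution (1 ms by default).  The instantaneous
eye velocity is the Savitzky-Golay smoothed first derivative of S(t).
Saccade onset and offset are the 5%-of-peak-velocity crossings around the
velocity peak; amplitude is the displacement between them.

Two kinematic laws are fitted over a set of saccades:

    main sequence   V_peak = V0 * (1 - exp(-alpha R))
    amplitude law   V_peak * D = k * R        (zero-intercept, k ~ 2 for
                                               single-peaked, roughly
                                               triangular velocity profiles)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .geometry import MotorMap
from .network import SpikeRecord

__all__ = [
    "SaccadeTrajectory",
    "SaccadeMetrics",
    "MainSequenceFit",
    "KinematicFit",
    "decode_trajectory",
    "eye_velocity",
    "saccade_metrics",
    "spike_density",
    "central_cell",
    "fit_main_sequence",
    "fit_kinematic_slope",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a kinematic fit fails to converge."""


@dataclass
class SaccadeTrajectory:
    t_ms: np.ndarray
    S_deg: np.ndarray
    V_deg_s: np.ndarray | None = None

    @property
    def dt_ms(self) -> float:
        return float(self.t_ms[1] - self.t_ms[0])


@dataclass
class SaccadeMetrics:
    """Summary of one decoded saccade (deg, deg/s, ms)."""

    amplitude_deg: float
    peak_velocity_deg_s: float
    duration_ms: float
    onset_ms: float
    offset_ms: float
    valid: bool = True
    total_sc_spikes: int | None = None
    central_spike_count: int | None = None
    central_peak_rate_spk_s: float | None = None
    burst_duration_ms: float | None = None


@dataclass
class MainSequenceFit:
    V0_deg_s: float
    alpha_per_deg: float
    rms_residual_deg_s: float
    n_points: int


@dataclass
class KinematicFit:
    k: float
    rms_residual: float
    n_points: int


def decode_trajectory(spikes: SpikeRecord, motor_map: MotorMap, zeta: float,
                      N_ref: float, dt_ms: float = 1.0) -> SaccadeTrajectory:
    """Cumulative spike-vector sum S(t) on a uniform time base.

    The final amplitude equals sum_n m_n * N_n exactly (no smoothing of
    position); an empty record decodes to the zero trajectory.
    """
    if spikes.layer not in ("sc", "SC"):
        raise ValueError(f"decoder expects SC-layer spikes, got layer "
                         f"{spikes.layer!r}")
    t_end = spikes.t_end_ms if np.isfinite(spikes.t_end_ms) else max(
        (float(t[-1]) for t in spikes.times_ms if len(t)), default=0.0)
    n_bins = max(int(np.ceil(t_end / dt_ms)), 1)
    edges = np.arange(n_bins + 1) * dt_ms
    m = motor_map.spike_vectors(zeta, N_ref)
    increments = np.zeros(n_bins)
    for n, times in enumerate(spikes.times_ms):
        if len(times) == 0:
            continue
        hist, _ = np.histogram(times, bins=edges)
        increments += m[n] * hist
    S = np.concatenate([[0.0], np.cumsum(increments)])
    return SaccadeTrajectory(t_ms=edges.copy(), S_deg=S)


def eye_velocity(traj: SaccadeTrajectory, window: int = 21,
                 order: int = 3) -> SaccadeTrajectory:
    """Savitzky-Golay smoothed derivative of S(t), in deg/s."""
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if order >= window:
        raise ValueError("polynomial order must be below the window length")
    if len(traj.S_deg) < window:
        raise ValueError(f"trajectory of {len(traj.S_deg)} samples is shorter "
                         f"than the {window}-sample filter window")
    V = savgol_filter(traj.S_deg, window, order, deriv=1,
                      delta=traj.dt_ms) * 1000.0
    return SaccadeTrajectory(t_ms=traj.t_ms, S_deg=traj.S_deg, V_deg_s=V)


def saccade_metrics(traj: SaccadeTrajectory,
                    onset_frac: float = 0.05) -> SaccadeMetrics:
    """Onset/offset at the ``onset_frac``-of-peak velocity crossings.

    Scans outward from the velocity peak, which makes the criterion robust
    for the slow near-threshold saccades where a fixed deg/s threshold fails.
    A zero (or velocity-less) trajectory is returned flagged invalid.
    """
    if traj.V_deg_s is None:
        traj = eye_velocity(traj)
    V = traj.V_deg_s
    i_peak = int(np.argmax(V))
    v_peak = float(V[i_peak])
    if v_peak <= 0.0:
        return SaccadeMetrics(0.0, 0.0, np.nan, np.nan, np.nan, valid=False)
    thresh = onset_frac * v_peak
    below = V < thresh
    before = np.nonzero(below[:i_peak])[0]
    i_on = int(before[-1] + 1) if len(before) else 0
    after = np.nonzero(below[i_peak:])[0]
    i_off = int(i_peak + after[0] - 1) if len(after) else len(V) - 1
    R = float(traj.S_deg[i_off] - traj.S_deg[i_on])
    return SaccadeMetrics(
        amplitude_deg=R,
        peak_velocity_deg_s=v_peak,
        duration_ms=float(traj.t_ms[i_off] - traj.t_ms[i_on]),
        onset_ms=float(traj.t_ms[i_on]),
        offset_ms=float(traj.t_ms[i_off]),
    )


def spike_density(times_ms: np.ndarray, kernel_sigma_ms: float = 4.0,
                  dt_ms: float = 0.5,
                  t_range_ms: tuple[float, float] | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel spike density (spikes/s) on a uniform grid.

    The grid extends 5 sigma beyond the first and last spike unless a range
    is given, so the integral of the trace recovers the spike count.
    """
    if kernel_sigma_ms <= 0:
        raise ValueError("kernel width must be positive")
    times = np.asarray(times_ms, dtype=float)
    if t_range_ms is None:
        if len(times) == 0:
            grid = np.arange(0.0, 1.0 + dt_ms, dt_ms)
            return grid, np.zeros_like(grid)
        lo = times.min() - 5 * kernel_sigma_ms
        hi = times.max() + 5 * kernel_sigma_ms
    else:
        lo, hi = t_range_ms
    grid = np.arange(lo, hi + dt_ms / 2, dt_ms)
    if len(times) == 0:
        return grid, np.zeros_like(grid)
    z = (grid[:, None] - times[None, :]) / kernel_sigma_ms
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (kernel_sigma_ms * np.sqrt(2 * np.pi))
    return grid, dens * 1000.0  # per ms -> per s


def central_cell(spikes: SpikeRecord, u_T_mm: float) -> int:
    """Index of the most active neuron; ties break toward the image point."""
    counts = spikes.counts()
    best = counts.max()
    candidates = np.nonzero(counts == best)[0]
    dist = np.abs(spikes.positions_mm[candidates] - u_T_mm)
    return int(candidates[np.argmin(dist)])


def fit_main_sequence(R_deg, V_peak_deg_s) -> MainSequenceFit:
    """Least-squares fit of the saturating main sequence V0 (1 - exp(-alpha R))."""
    R = np.asarray(R_deg, dtype=float)
    V = np.asarray(V_peak_deg_s, dtype=float)
    if len(R) < 3:
        raise ValueError("main-sequence fit needs at least 3 points")
    if np.any(R <= 0):
        raise ValueError("amplitudes must be positive")
    model = lambda r, V0, alpha: V0 * (1.0 - np.exp(-alpha * r))
    p0 = (1.2 * V.max(), 1.0 / max(R.mean(), 1e-9))
    # V0 is bounded so that saturation-free (near-linear) data converges to
    # the degenerate limit V0 -> bound, alpha -> slope/V0 instead of diverging.
    try:
        popt, _ = curve_fit(model, R, V, p0=p0, maxfev=40000,
                            bounds=((1e-9, 1e-9), (1e7, 10.0)))
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise FitError(f"main-sequence fit did not converge: {err}; "
                       f"R={R!r}, V={V!r}") from err
    resid = V - model(R, *popt)
    return MainSequenceFit(float(popt[0]), float(popt[1]),
                           float(np.sqrt(np.mean(resid**2))), len(R))


def fit_kinematic_slope(R_deg, VD_deg) -> KinematicFit:
    """Zero-intercept least squares of V_peak * D = k * R."""
    R = np.asarray(R_deg, dtype=float)
    VD = np.asarray(VD_deg, dtype=float)
    if len(R) < 2:
        raise ValueError("kinematic fit needs at least 2 points")
    denom = float(np.sum(R**2))
    if denom == 0.0:
        raise ValueError("all amplitudes are zero")
    k = float(np.sum(R * VD) / denom)
    resid = VD - k * R
    return KinematicFit(k, float(np.sqrt(np.mean(resid**2))), len(R))
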