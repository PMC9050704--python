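"""External input currents: a separable Gaussian (space) x gamma (time) profile.

The cortical drive to the input layer is

    I_ext(u, t) = I0 * exp(-(u - u_T)^2 / (2 sigma_pop^2)) * g(t)
    g(t) = (t^gamma * exp(-beta t)) / ((gamma/beta)^gamma * exp(-gamma))

i.e. a spatial Gaussian of width ``sigma_pop`` centred on the image point
``u_T`` of the target, multiplied by a gamma-shaped burst whose peak is
normalized to 1 so that ``I0`` is the maximum current anywhere (pA).  Time is
in ms and ``beta`` in 1/ms: with the default beta = 0.03 and gamma = 1.8 the
burst peaks at t = gamma/beta = 60 ms and lasts roughly 150 ms at half height
(about 300 ms at beta = 0.019).

This module also generates the parameter sets for the two sweep protocols:

* spatial sweep  — sigma_pop in [0.05, 1.0] mm with the current amplitude
  ramped linearly from 2.0 pA (at 0.05 mm) to 3.0 pA (at 0.5 mm) and held at
  3.0 pA above 0.5 mm;
* temporal sweep — beta in [0.019, 0.030] / ms at fixed sigma_pop = 0.5 mm,
  with I0 recalibrated by bisection per beta so that either the SC-layer
  ("fixed_output_spikes") or the input-layer ("fixed_input_spikes") total
  spike count matches the default run within 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np

__all__ = [
    "StimulusSpec",
    "external_current",
    "temporal_profile",
    "spatial_profile",
    "spatial_sweep_specs",
    "temporal_sweep_specs",
    "CalibrationRecord",
    "DEFAULT_SPATIAL_SIGMAS",
    "DEFAULT_BETAS",
]

# 12-point sigma_pop grid covering the stated 0.05-1.0 mm range, including the
# 0.1 mm reduced-input condition and the 0.5 mm default.
DEFAULT_SPATIAL_SIGMAS = (0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

# 12-point beta grid covering 0.019-0.030 / ms in 0.001 steps.
DEFAULT_BETAS = tuple(np.round(np.linspace(0.019, 0.030, 12), 6))


@dataclass(frozen=True)
class StimulusSpec:
    """All parameters of one external-current condition."""

    I0_pA: float = 3.0
    sigma_pop_mm: float = 0.5
    beta_per_ms: float = 0.03
    gamma: float = 1.8
    u_T_mm: float = 2.5
    t_end_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.I0_pA < 0:
            raise ValueError("I0 must be non-negative")
        if self.sigma_pop_mm <= 0:
            raise ValueError("sigma_pop must be positive")
        if self.beta_per_ms <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be positive")
        if not 0.0 <= self.u_T_mm <= 5.0:
            raise ValueError("u_T must lie on the 0-5 mm map")
        if self.t_end_ms <= 0:
            raise ValueError("t_end must be positive")

    @property
    def t_peak_ms(self) -> float:
        """Time of the temporal peak, gamma / beta."""
        return self.gamma / self.beta_per_ms


def temporal_profile(t_ms, spec: StimulusSpec):
    """Gamma burst profile g(t), normalized to unit peak at t = gamma/beta."""
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    g, b = spec.gamma, spec.beta_per_ms
    log_peak = g * np.log(g / b) - g
    with np.errstate(divide="ignore"):
        logt = np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), -np.inf)
    out = np.exp(g * logt - b * t - log_peak)
    out = np.where(t > 0, out, 0.0)
    return out if out.ndim else float(out)


def spatial_profile(u_mm, spec: StimulusSpec):
    """Gaussian recruitment profile f(u), unit peak at u = u_T."""
    u = np.asarray(u_mm, dtype=float)
    out = np.exp(-((u - spec.u_T_mm) ** 2) / (2.0 * spec.sigma_pop_mm**2))
    return out if out.ndim else float(out)


def external_current(u_mm, t_ms, spec: StimulusSpec):
    """Separable external input current I_ext(u, t) in pA."""
    return spec.I0_pA * spatial_profile(u_mm, spec) * temporal_profile(t_ms, spec)


def _spatial_ramp_I0(sigma_mm: float, I0_lo: float = 2.0, I0_hi: float = 3.0,
                     sigma_lo: float = 0.05, sigma_ref: float = 0.5) -> float:
    """Current amplitude for the spatial sweep: linear in sigma below the
    default width, constant at the maximum above it."""
    if sigma_mm >= sigma_ref:
        return I0_hi
    frac = (sigma_mm - sigma_lo) / (sigma_ref - sigma_lo)
    return I0_lo + (I0_hi - I0_lo) * max(frac, 0.0)


def spatial_sweep_specs(u_T_mm: float = 2.5,
                        sigmas: Sequence[float] = DEFAULT_SPATIAL_SIGMAS,
                        t_end_ms: float = 400.0) -> list[StimulusSpec]:
    """Stimulus conditions of the spatial input-variation protocol."""
    return [
        StimulusSpec(I0_pA=_spatial_ramp_I0(s), sigma_pop_mm=s,
                     u_T_mm=u_T_mm, t_end_ms=t_end_ms)
        for s in sigmas
    ]


@dataclass(frozen=True)
class CalibrationRecord:
    """Outcome of the per-beta amplitude calibration of a temporal sweep."""

    beta_per_ms: float
    I0_pA: float
    n_input_spikes: int
    n_sc_spikes: int
    target_spikes: int
    converged: bool
    n_iter: int


Scenario = Literal["fixed_output_spikes", "fixed_input_spikes"]

# I0 search brackets (pA) per scenario.
_I0_BOUNDS = {"fixed_output_spikes": (0.2, 3.0), "fixed_input_spikes": (1.2, 3.0)}


def temporal_sweep_specs(
    scenario: Scenario,
    count_spikes: Callable[[StimulusSpec], tuple[int, int]],
    u_T_mm: float = 2.5,
    betas: Sequence[float] = DEFAULT_BETAS,
    t_end_ms: float = 400.0,
    rel_tol: float = 0.01,
    max_iter: int = 40,
) -> list[tuple[StimulusSpec, CalibrationRecord]]:
    """Stimulus conditions of the temporal input-variation protocol.

    For every ``beta`` the current amplitude ``I0`` is found by bisection such
    that the total spike count of the constrained layer (SC output for
    ``fixed_output_spikes``, input layer for ``fixed_input_spikes``) matches
    the default condition (beta = 0.03, I0 = 3.0 pA) within ``rel_tol``.

    ``count_spikes`` must run the tuned network for a spec and return the pair
    ``(input-layer total, SC-layer total)``.  Calibration failures are
    reported in the record (``converged=False``), never silently clipped.
    """
    if scenario not in _I0_BOUNDS:
        raise ValueError(f"unknown scenario {scenario!r}")
    lo_bound, hi_bound = _I0_BOUNDS[scenario]
    layer = 1 if scenario == "fixed_output_spikes" else 0

    default = StimulusSpec(I0_pA=3.0, sigma_pop_mm=0.5, u_T_mm=u_T_mm,
                           t_end_ms=t_end_ms)
    counts_default = count_spikes(default)
    target = counts_default[layer]
    if target <= 0:
        raise RuntimeError("default condition produced no spikes; cannot calibrate")

    out: list[tuple[StimulusSpec, CalibrationRecord]] = []
    for beta in betas:
        if abs(beta - default.beta_per_ms) < 1e-12:
            # The default condition is its own calibration point.
            rec = CalibrationRecord(beta, default.I0_pA, counts_default[0],
                                    counts_default[1], target, True, 0)
            out.append((default, rec))
            continue
        spec_at = lambda I0: replace(default, beta_per_ms=beta, I0_pA=I0)
        lo, hi = lo_bound, hi_bound
        counts_lo, counts_hi = count_spikes(spec_at(lo)), count_spikes(spec_at(hi))
        f_lo, f_hi = counts_lo[layer] - target, counts_hi[layer] - target
        best_I0, best_counts = (lo, counts_lo) if abs(f_lo) < abs(f_hi) else (hi, counts_hi)
        converged, n_iter = False, 0
        if abs(best_counts[layer] - target) <= rel_tol * target:
            converged = True
        elif f_lo > 0 or f_hi < 0:
            converged = False  # bracket does not contain the target
        else:
            for n_iter in range(1, max_iter + 1):
                mid = 0.5 * (lo + hi)
                counts_mid = count_spikes(spec_at(mid))
                f_mid = counts_mid[layer] - target
                if abs(f_mid) < abs(best_counts[layer] - target):
                    best_I0, best_counts = mid, counts_mid
                if abs(f_mid) <= rel_tol * target:
                    converged = True
                    break
                if f_mid < 0:
                    lo = mid
                else:
                    hi = mid
        rec = CalibrationRecord(beta, best_I0, best_counts[0], best_counts[1],
                                target, converged, n_iter)
        out.append((spec_at(best_I0), rec))
    return out
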