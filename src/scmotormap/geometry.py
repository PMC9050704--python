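"""Anatomical geometry of the collicular motor map.

The model places ``n_neurons`` cells uniformly on a one-dimensional strip of
tissue (the horizontal meridian of the motor map).  Target eccentricity ``T``
(deg) maps onto an anatomical image point ``u_T`` (mm) through the standard
logarithmic afferent magnification

    u_T = B_u * ln((T + A) / A)

with offset ``A`` (deg) and scale ``B_u`` (mm).  The efferent map is its exact
inverse, ``R(u) = A * (exp(u / B_u) - 1)``, and assigns each cell the saccade
amplitude it codes for.  Each spike of the cell at position ``u`` contributes a
fixed miniature eye displacement (its "spike vector")

    m(u) = zeta * R(u) / N_ref

where ``N_ref`` is the reference total spike count of a saccade-related
population and ``zeta`` a single global gain calibrated so that the default
stimulation at T = 15 deg decodes to a 15 deg saccade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MapGrid", "MotorMap", "afferent_map", "efferent_map", "spike_vector"]


@dataclass(frozen=True)
class MapGrid:
    """Uniform anatomical lattice shared by the input and SC layers.

    Neuron ``n`` sits at ``u_n = n * length_mm / n_neurons`` so that, with the
    defaults (200 neurons on 0-5 mm), neuron 100 sits at exactly 2.5 mm.
    """

    n_neurons: int = 200
    length_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError(f"n_neurons must be >= 2, got {self.n_neurons}")
        if self.length_mm <= 0:
            raise ValueError(f"length_mm must be positive, got {self.length_mm}")

    @property
    def spacing_mm(self) -> float:
        return self.length_mm / self.n_neurons

    @property
    def positions(self) -> np.ndarray:
        """Anatomical coordinates u_n in mm, strictly increasing from 0."""
        return np.arange(self.n_neurons) * self.spacing_mm

    def index_at(self, u_mm: float) -> int:
        """Index of the neuron closest to anatomical position ``u_mm``."""
        if not 0.0 <= u_mm <= self.length_mm:
            raise ValueError(f"u={u_mm} mm outside the map [0, {self.length_mm}]")
        return int(round(u_mm / self.spacing_mm))


def afferent_map(T_deg, A_deg: float = 3.0, B_u_mm: float = 1.4):
    """Eccentricity (deg) -> anatomical image point u_T (mm).

    Monotonically increasing log map with afferent(0) = 0; the defaults place
    T = 15 deg at u_T = 2.5085 mm, i.e. the 2.5 mm site of the default grid.
    """
    T = np.asarray(T_deg, dtype=float)
    if np.any(T < 0):
        raise ValueError("eccentricity T must be non-negative")
    out = B_u_mm * np.log((T + A_deg) / A_deg)
    return out if out.ndim else float(out)


def efferent_map(u_mm, A_deg: float = 3.0, B_u_mm: float = 1.4,
                 length_mm: float = 5.0):
    """Anatomical position (mm) -> coded saccade amplitude R (deg).

    Exact inverse of :func:`afferent_map`; rejects positions off the map.
    """
    u = np.asarray(u_mm, dtype=float)
    if np.any(u < 0) or np.any(u > length_mm):
        raise ValueError(f"u={u_mm} mm outside the map [0, {length_mm}]")
    out = A_deg * np.expm1(u / B_u_mm)
    return out if out.ndim else float(out)


def spike_vector(u_mm, zeta: float, N_ref: float, A_deg: float = 3.0,
                 B_u_mm: float = 1.4, length_mm: float = 5.0):
    """Per-spike eye displacement m(u) = zeta * R(u) / N_ref (deg per spike)."""
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if N_ref <= 0:
        raise ValueError("N_ref must be positive")
    R = efferent_map(u_mm, A_deg, B_u_mm, length_mm)
    return zeta * np.asarray(R) / N_ref if np.ndim(R) else zeta * R / N_ref


@dataclass(frozen=True)
class MotorMap:
    """Grid plus afferent/efferent mapping constants, bundled for convenience."""

    grid: MapGrid
    A_deg: float = 3.0
    B_u_mm: float = 1.4

    def afferent(self, T_deg):
        return afferent_map(T_deg, self.A_deg, self.B_u_mm)

    def efferent(self, u_mm):
        return efferent_map(u_mm, self.A_deg, self.B_u_mm, self.grid.length_mm)

    def spike_vectors(self, zeta: float, N_ref: float) -> np.ndarray:
        """Spike vectors m_n for every neuron on the grid (deg per spike)."""
        return spike_vector(self.grid.positions, zeta, N_ref,
                            self.A_deg, self.B_u_mm, self.grid.length_mm)
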