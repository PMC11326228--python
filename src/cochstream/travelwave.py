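"""Parametric cochlear traveling-wave surrogate.

The organ of Corti (OoC) rides on the basilar membrane and is deformed by
sound-evoked traveling waves that propagate from the base toward the apex
with decaying phase velocity, peak near the characteristic-frequency (CF)
place of the stimulus, and stall shortly apical of it.  Active outer hair
cells modulate the OoC cross-sectional area, so the top wall of the Corti
fluid channel executes a time-periodic peristaltic motion.  This module
builds that motion kinematically — an amplitude envelope ``A(x)``, a phase
profile ``phi(x) = -∫ k(s) ds`` and the resulting wall displacement

    u_m(x, t) = A(x) * cos(2*pi*f*t + phi(x))

— which the flow solver consumes as a moving-wall boundary condition.

All quantities are SI internally (m, s, Hz); helper I/O uses mm/kHz where
stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CochlearGeometry",
    "PlaceFrequencyMap",
    "TravelingWaveParams",
    "WallMotionField",
    "place_frequency_map",
    "amplitude_envelope",
    "phase_profile",
    "wall_motion",
    "amplitude_from_spl",
]


@dataclass(frozen=True)
class CochlearGeometry:
    """Two-layer unrolled cochlear duct geometry.

    Parameters
    ----------
    length : float
        Basilar-membrane length in m (gerbil default 12 mm). ``x = 0`` at
        the base (round-window side), increasing apically.
    corti_height : float
        Height of the Corti-fluid channel (top layer), m.
    scala_height : float
        Height of the scala tympani (bottom layer), m.
    dx : float
        Axial grid spacing, m. Must divide ``length`` to within one cell.
    """

    length: float = 12e-3
    corti_height: float = 60e-6
    scala_height: float = 500e-6
    dx: float = 100e-6

    def __post_init__(self) -> None:
        if self.length <= 0 or self.corti_height <= 0 or self.scala_height <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        ncell = self.length / self.dx
        if abs(ncell - round(ncell)) > 1.0:
            raise ValueError("dx must divide length to within one cell")

    @property
    def nx(self) -> int:
        return int(round(self.length / self.dx))

    @property
    def x_centers(self) -> np.ndarray:
        """Axial cell-center coordinates, m."""
        return (np.arange(self.nx) + 0.5) * self.dx


@dataclass(frozen=True)
class PlaceFrequencyMap:
    """Greenwood-form place–frequency map, gerbil defaults.

    CF(x) = a * (10**(alpha * (1 - x/L)) - k)  [kHz], x in m from the base.

    Monotone decreasing base→apex; invertible on (CF(L), CF(0)).
    """

    a_khz: float = 0.398
    alpha: float = 2.2
    k: float = 0.631
    length: float = 12e-3

    def place_to_cf(self, x: float | np.ndarray) -> float | np.ndarray:
        """CF in kHz at place ``x`` (m from base)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < -1e-12) or np.any(x > self.length + 1e-12):
            raise ValueError(f"place outside [0, {self.length}] m")
        cf = self.a_khz * (10.0 ** (self.alpha * (1.0 - x / self.length)) - self.k)
        return float(cf) if cf.ndim == 0 else cf

    def cf_to_place(self, cf_khz: float | np.ndarray) -> float | np.ndarray:
        """Place in m from base for CF in kHz."""
        cf = np.asarray(cf_khz, dtype=float)
        lo, hi = self.cf_range_khz
        if np.any(cf < lo - 1e-9) or np.any(cf > hi + 1e-9):
            raise ValueError(f"CF outside map range [{lo:.3g}, {hi:.3g}] kHz")
        x = self.length * (1.0 - np.log10(cf / self.a_khz + self.k) / self.alpha)
        return float(x) if x.ndim == 0 else x

    @property
    def cf_range_khz(self) -> tuple[float, float]:
        return (self.place_to_cf(self.length), self.place_to_cf(0.0))


def place_frequency_map(
    value: float | np.ndarray,
    direction: str = "place_to_cf",
    pf_map: PlaceFrequencyMap | None = None,
) -> float | np.ndarray:
    """Convert between place (m from base) and CF (kHz).

    ``direction`` is ``"place_to_cf"`` or ``"cf_to_place"``.
    """
    pf_map = pf_map or PlaceFrequencyMap()
    if direction == "place_to_cf":
        return pf_map.place_to_cf(value)
    if direction == "cf_to_place":
        return pf_map.cf_to_place(value)
    raise ValueError(f"unknown direction {direction!r}")


def amplitude_from_spl(level_db_spl: float, ref_level: float = 80.0,
                       ref_amplitude: float = 25e-9) -> float:
    """Map sound level to peak wall displacement, linear in pressure.

    Default calibration: 80 dB SPL → 25 nm at the wave peak (order of
    magnitude only; configurable).
    """
    return ref_amplitude * 10.0 ** ((level_db_spl - ref_level) / 20.0)


@dataclass(frozen=True)
class TravelingWaveParams:
    """Kinematic parameters of the peristaltic OoC wall wave.

    The envelope has a long shallow basal tail rising at ``tail_slope_db_mm``
    dB per mm toward a peak ``a_peak`` at the CF place of ``frequency``, then
    tapers smoothly (cos²) to zero over ``stall_margin`` — waves stall
    shortly apical of the CF place.  Local phase velocity decreases linearly
    from ``c_base`` at the base to ``c_peak`` at the CF place; the wavenumber
    is ``k(x) = 2*pi*f / c(x)``.

    ``a_peak`` is the amplitude of the net cross-section (area-change) wall
    motion of the Corti channel, not the much smaller basilar-membrane-referred
    displacement: outer-hair-cell somatic motility modulates the OoC
    cross-section at the micrometre scale for a moderately loud stimulus, and
    it is this area motion that pumps.  Default 2 um at 80 dB SPL with active
    outer hair cells — a few percent of the 60-um channel height, matching
    outer-hair-cell somatic strains of 2-5% on 20-50 um cells
    (config-exposed; ``amplitude_from_spl`` maps sound levels to BM-referred
    displacement if that is what a user measures).
    """

    frequency: float = 1000.0          # Hz
    level_db_spl: float = 80.0
    a_peak: float = 2e-6               # m; peak wall-motion amplitude at CF place
    tail_slope_db_mm: float = 3.0      # envelope growth toward the peak
    stall_margin: float = 0.5e-3       # m; taper window apical of CF place
    c_base: float = 40.0               # m/s phase velocity at the base
    c_peak: float = 3.0                # m/s phase velocity at the CF place
    active_gain: float = 1.0           # 1 = active OHCs; <1 emulates salicylate
    pf_map: PlaceFrequencyMap = field(default_factory=PlaceFrequencyMap)

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.a_peak < 0:
            raise ValueError("a_peak must be non-negative")
        if self.c_base <= 0 or self.c_peak <= 0:
            raise ValueError("phase velocities must be positive")
        if self.active_gain < 0:
            raise ValueError("active_gain must be non-negative")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def cf_place(self, geometry: CochlearGeometry) -> float:
        """Place (m from base) of this stimulus frequency's CF location."""
        x = self.pf_map.cf_to_place(self.frequency / 1e3)
        if not (0.0 <= x <= geometry.length):
            raise ValueError("stimulus CF place lies outside the cochlea")
        return float(x)

    def with_gain(self, gain: float) -> "TravelingWaveParams":
        return replace(self, active_gain=gain)


def amplitude_envelope(geometry: CochlearGeometry, params: TravelingWaveParams,
                       x: np.ndarray | None = None) -> np.ndarray:
    """Envelope A(x) in m of the wall-displacement wave.

    Shallow exponential (constant dB/mm) basal tail, maximum ``active_gain *
    a_peak`` at the CF place, cos² taper to exactly zero over the stall
    margin, zero apical of the stall point.
    """
    x = geometry.x_centers if x is None else np.asarray(x, dtype=float)
    x_cf = params.cf_place(geometry)
    a = np.zeros_like(x)
    tail = x <= x_cf
    a[tail] = 10.0 ** (-params.tail_slope_db_mm * (x_cf - x[tail]) * 1e3 / 20.0)
    taper = (x > x_cf) & (x < x_cf + params.stall_margin)
    a[taper] = np.cos(0.5 * np.pi * (x[taper] - x_cf) / params.stall_margin) ** 2
    return params.active_gain * params.a_peak * a


def wavenumber_profile(geometry: CochlearGeometry, params: TravelingWaveParams,
                       x: np.ndarray | None = None) -> np.ndarray:
    """k(x) = 2πf / c(x) in rad/m; c decays linearly base→CF place, constant
    (= c_peak) through the taper and beyond."""
    x = geometry.x_centers if x is None else np.asarray(x, dtype=float)
    x_cf = params.cf_place(geometry)
    frac = np.clip(x / max(x_cf, 1e-12), 0.0, 1.0)
    c = params.c_base + (params.c_peak - params.c_base) * frac
    if np.any(c <= 0):
        raise ValueError("non-positive phase velocity on the propagating span")
    return params.omega / c


def phase_profile(geometry: CochlearGeometry, params: TravelingWaveParams,
                  x: np.ndarray | None = None) -> np.ndarray:
    """phi(x) = -∫_0^x k(s) ds (rad): phase lag accumulates apically.

    Evaluated with cumulative trapezoidal quadrature on a fine sub-grid and
    interpolated to ``x``.
    """
    x = geometry.x_centers if x is None else np.asarray(x, dtype=float)
    xs = np.linspace(0.0, geometry.length, 4096)
    ks = wavenumber_profile(geometry, params, xs)
    phi_s = -np.concatenate(([0.0], np.cumsum(0.5 * (ks[1:] + ks[:-1]) * np.diff(xs))))
    return np.interp(x, xs, phi_s)


@dataclass(frozen=True)
class WallMotionField:
    """Time-periodic kinematic motion of the Corti-fluid top wall.

    ``displacement(t) = A(x) * cos(omega*t + phi(x))`` and ``velocity(t)`` is
    its analytic time derivative.  ``x`` are the sample locations (m).  A
    standing-wave fixture uses a constant phase (no propagation).
    """

    x: np.ndarray
    envelope: np.ndarray        # A(x), m
    phase: np.ndarray           # phi(x), rad
    frequency: float            # Hz

    def __post_init__(self) -> None:
        if self.envelope.shape != self.x.shape or self.phase.shape != self.x.shape:
            raise ValueError("envelope/phase must match x in shape")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def displacement(self, t: float) -> np.ndarray:
        """Wall-normal displacement u_m(x, t), m."""
        return self.envelope * np.cos(self.omega * t + self.phase)

    def velocity(self, t: float) -> np.ndarray:
        """Wall-normal velocity du_m/dt (x, t), m/s."""
        return -self.envelope * self.omega * np.sin(self.omega * t + self.phase)

    def resampled(self, x_new: np.ndarray) -> "WallMotionField":
        """Linearly interpolate envelope and phase onto new sample points."""
        x_new = np.asarray(x_new, dtype=float)
        return WallMotionField(
            x=x_new,
            envelope=np.interp(x_new, self.x, self.envelope),
            phase=np.interp(x_new, self.x, self.phase),
            frequency=self.frequency,
        )


def wall_motion(geometry: CochlearGeometry, params: TravelingWaveParams,
                x: np.ndarray | None = None) -> WallMotionField:
    """Build the peristaltic top-wall motion field for the flow solver."""
    x = geometry.x_centers if x is None else np.asarray(x, dtype=float)
    return WallMotionField(
        x=x,
        envelope=amplitude_envelope(geometry, params, x),
        phase=phase_profile(geometry, params, x),
        frequency=params.frequency,
    )
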