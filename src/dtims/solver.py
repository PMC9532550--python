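"""Numeric 1-D ion transport down the drift tube.

The tube is discretised into uniform cells of width dx with centres at
(i + 1/2)·dx, entrance at x = 0, detector at x = L.  Each time step is an
operator split:

1. exact advection by one cell (the time step is locked to dt = dx/v_d so the
   Courant number is exactly 1 and advection is a pure index shift with zero
   numerical diffusion — essential, since physical D ≈ 1e-6 m²/s would
   otherwise be swamped by upwind smearing at dx = 5 µm);
2. an implicit Crank–Nicolson diffusion half-pair (unconditionally stable
   tridiagonal solve) with a time-dependent Dirichlet ghost cell at the
   entrance (the gate schedule) and a zero-curvature ghost at the detector.

The detector current is the drift flux I(t) = C(L)·S·v_d sampled once per
step.  Spectrum time is shifted so t = 0 is the instant the centre of the
injected slab (or blank) crosses x = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded

from .exceptions import CourantError, GridError, ParameterError, TruncatedPeakError
from .theory import (
    DriftTubeConfig,
    InjectionProgram,
    IonSpecies,
    drift_time,
    drift_velocity,
    pulsed_fwhm_analytic,
)

__all__ = ["ConcentrationField", "Spectrum", "build_grid", "advance",
           "simulate_spectrum", "simulate_mixture"]


@dataclass
class ConcentrationField:
    """Ion concentration per cell on the uniform drift-tube grid.

    ``positions`` are cell centres (m), ``values`` one-dimensional
    concentrations (ions/m), ``time`` the solver-clock time (s).
    """

    positions: np.ndarray
    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise GridError("positions and values must be matching 1-D arrays")
        d = np.diff(self.positions)
        if len(d) and (np.any(d <= 0) or np.ptp(d) > 1e-9 * d[0]):
            raise GridError("positions must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("concentration values must be finite")

    @property
    def dx(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def content(self) -> float:
        """Total ion content per unit cross-section, ions."""
        return float(self.values.sum() * self.dx)


@dataclass
class Spectrum:
    """Uniformly sampled detector current versus time.

    ``meta`` records mode ('pulsed' | 'inverse' | 'inverse_corrected' |
    'counteracted'), species label(s) and a snapshot of the configuration.
    """

    times: np.ndarray
    currents: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.shape != self.currents.shape or self.times.ndim != 1:
            raise ParameterError("times and currents must be matching 1-D arrays")
        if self.times.size < 8:
            raise ParameterError("a spectrum needs at least 8 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.currents)):
            raise ParameterError("currents must be finite")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def copy_with(self, *, times=None, currents=None, **meta) -> "Spectrum":
        m = dict(self.meta)
        m.update(meta)
        return Spectrum(
            times=self.times if times is None else times,
            currents=self.currents if currents is None else currents,
            meta=m,
        )


def build_grid(config: DriftTubeConfig) -> ConcentrationField:
    """Zero-initialised concentration field on the config's uniform grid."""
    n = config.n_cells
    positions = (np.arange(n) + 0.5) * config.dx
    return ConcentrationField(positions=positions, values=np.zeros(n), time=0.0)


def _diffusion_system(n: int, r: float):
    """Banded Crank–Nicolson matrix for r = D·dt/dx².

    Interior rows are standard CN; the entrance row couples to a Dirichlet
    ghost handled in the RHS; the detector row is identity (zero-curvature
    ghost makes its Laplacian vanish identically).
    """
    ab = np.zeros((3, n))
    ab[0, 1:] = -r / 2          # upper diagonal A[j-1, j]
    ab[1, :] = 1 + r            # main diagonal
    ab[2, :-1] = -r / 2         # lower diagonal A[j+1, j]
    ab[1, -1] = 1.0             # detector row: identity
    ab[2, -2] = 0.0             # A[n-1, n-2] = 0
    return ab


def _diffuse(values: np.ndarray, ab: np.ndarray, r: float, ghost: float) -> np.ndarray:
    n = values.size
    rhs = np.empty(n)
    rhs[1:-1] = (1 - r) * values[1:-1] + (r / 2) * (values[:-2] + values[2:])
    rhs[0] = (1 - r) * values[0] + (r / 2) * values[1] + r * ghost
    rhs[-1] = values[-1]
    return solve_banded((1, 1), ab, rhs)


def advance(field: ConcentrationField, species: IonSpecies, E_d: float,
            dt: float, inflow: float) -> ConcentrationField:
    """One operator-split transport step; returns a new field at time + dt.

    ``inflow`` is the boundary concentration at x = 0 for this step (the gate
    schedule).  Requires the Courant number v_d·dt/dx to be exactly 1.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be positive, got {dt}")
    v = drift_velocity(species, E_d)
    dx = field.dx
    courant = v * dt / dx
    if abs(courant - 1.0) > 1e-9:
        raise CourantError(f"Courant number must be 1, got {courant:.6g}")
    if inflow < 0:
        raise ParameterError("inflow concentration must be non-negative")
    new = np.empty_like(field.values)
    new[1:] = field.values[:-1]
    new[0] = inflow
    r = species.D * dt / dx**2
    ab = _diffusion_system(new.size, r)
    new = _diffuse(new, ab, r, inflow)
    return ConcentrationField(positions=field.positions, values=new,
                              time=field.time + dt)


def _gate_steps(program: InjectionProgram, dx: float) -> int:
    ratio = program.L_ion / dx
    n_open = int(round(ratio))
    if n_open < 1 or abs(ratio - n_open) > 1e-9 * ratio:
        raise GridError(
            f"L_ion={program.L_ion} must be a positive integer multiple of dx={dx}"
        )
    return n_open


def simulate_spectrum(config: DriftTubeConfig, species: IonSpecies,
                      program: InjectionProgram, t_end: float | None = None) -> Spectrum:
    """Transport one species through the tube and record the detector current.

    Pulsed mode injects blank–ion–blank: inflow C0 for the gate interval of
    duration L_ion/v_d, zero otherwise, into an initially empty tube.
    Inverse mode injects ion–blank–ion: the tube starts at steady state
    (uniform C0) and the inflow is C0 except during the gate interval.
    Spectrum time zero is when the slab (or blank) centre crosses x = 0.
    """
    v = drift_velocity(species, config.E_d)
    dt = config.dx / v                      # Courant-exact per-species step
    t_d = drift_time(config, species)
    fwhm = pulsed_fwhm_analytic(species, config.E_d, config.L_drift)
    tau = program.L_ion / v                 # gate interval
    if t_end is None:
        t_end = t_d + 10 * fwhm
    if t_end <= t_d + 6 * fwhm:
        raise TruncatedPeakError(
            f"t_end={t_end:.4g} s would truncate the peak; need > "
            f"{t_d + 6 * fwhm:.4g} s (t_d + 6 FWHM)"
        )
    n_open = _gate_steps(program, config.dx)
    t_origin = tau / 2 if program.t_origin is None else program.t_origin

    values = np.full(config.n_cells, program.C0 if program.mode == "inverse" else 0.0)
    r = species.D * dt / config.dx**2
    ab = _diffusion_system(values.size, r)

    n_steps = int(np.ceil((t_end + t_origin) / dt))
    times = np.empty(n_steps)
    currents = np.empty(n_steps)
    open_value = program.C0 if program.mode == "pulsed" else 0.0
    rest_value = 0.0 if program.mode == "pulsed" else program.C0
    shifted = np.empty_like(values)
    for k in range(n_steps):
        inflow = open_value if k < n_open else rest_value
        shifted[1:] = values[:-1]
        shifted[0] = inflow
        values = _diffuse(shifted, ab, r, inflow)
        times[k] = (k + 1) * dt - t_origin
        currents[k] = values[-1] * config.S * v

    meta = {
        "mode": program.mode,
        "species": species.label,
        "config": {"L_drift_m": config.L_drift, "E_Vpm": config.E_d,
                   "S_m2": config.S, "dx_m": config.dx,
                   "L_ion_m": program.L_ion, "C0": program.C0,
                   "K": species.K, "D": species.D, "q": species.q},
    }
    return Spectrum(times=times, currents=currents, meta=meta)


def simulate_mixture(config: DriftTubeConfig, species_list: Sequence[IonSpecies],
                     programs: Sequence[InjectionProgram] | InjectionProgram,
                     t_end: float | None = None) -> Spectrum:
    """Superpose independent single-species runs onto a common time axis.

    Space charge is neglected, so species evolve independently; each is
    simulated with its own Courant-exact dt, linearly resampled onto the
    overlap of all time axes at the finest sampling interval, and summed.
    """
    if len(species_list) == 0:
        raise ParameterError("species_list must not be empty")
    if isinstance(programs, InjectionProgram):
        programs = [programs] * len(species_list)
    if len(programs) != len(species_list):
        raise ParameterError("need one injection program per species")
    if t_end is None:
        t_end = max(
            drift_time(config, sp) + 10 * pulsed_fwhm_analytic(sp, config.E_d, config.L_drift)
            for sp in species_list
        )
    spectra = [simulate_spectrum(config, sp, pr, t_end)
               for sp, pr in zip(species_list, programs)]
    t0 = max(s.times[0] for s in spectra)
    t1 = min(s.times[-1] for s in spectra)
    dt = min(s.dt for s in spectra)
    times = np.arange(t0, t1 + dt / 2, dt)
    currents = np.zeros_like(times)
    for s in spectra:
        currents += np.interp(times, s.times, s.currents)
    meta = {
        "mode": programs[0].mode,
        "species": ",".join(sp.label for sp in species_list),
        "config": dict(spectra[0].meta["config"]),
    }
    meta["config"].pop("K", None), meta["config"].pop("D", None)
    return Spectrum(times=times, currents=currents, meta=meta)
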