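"""Closed-form drift–diffusion theory for drift-tube ion mobility spectrometry.

This module collects the analytic machinery behind the inverse diffusion
counterbalance method: the Green's-function arrival-time currents of a pulsed
ion packet and of a blank dip in a continuous beam, the diffusion-limited
resolution of both modes, and the mode-independent resolution enhancement
ratio sqrt(ln 2 / ln(4/3)) ≈ 1.5522.

Everything here is exact algebra on the 1-D advection–diffusion model

    ∂C/∂t = D ∂²C/∂x² − v_d ∂C/∂x,      v_d = K·E_d,

with constant mobility K, diffusion coefficient D and axial field E_d, and
space charge neglected.  The functions double as the independent oracle for
the numeric solver in :mod:`dtims.solver`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const
from scipy.special import erf

from .exceptions import ParameterError

__all__ = [
    "BOLTZMANN",
    "ELEMENTARY_CHARGE",
    "T_DEFAULT",
    "T_REF",
    "IonSpecies",
    "DriftTubeConfig",
    "InjectionProgram",
    "TheoryConstants",
    "PeakSummary",
    "REFERENCE_SPECIES",
    "REFERENCE_CONFIG",
    "drift_velocity",
    "drift_time",
    "beam_current",
    "nernst_einstein",
    "mobility_from_D",
    "einstein_temperature",
    "pulsed_current",
    "peak_current",
    "inverse_current",
    "counteracted_current",
    "tophat_pulsed_current",
    "pulsed_fwhm_analytic",
    "counteracted_fwhm_analytic",
    "diffusion_limit_resolution",
    "counterbalance_resolution",
    "enhancement_ratio_theory",
    "length_equivalence_factor",
]

#: Boltzmann constant, J/K.
BOLTZMANN: float = _const.k

#: Elementary charge, C.
ELEMENTARY_CHARGE: float = _const.e

#: Default temperature for Einstein-relation utilities, K.
T_DEFAULT: float = 298.0

# Reference transport scenario: a 10 mm tube at 50 V/mm with a singly charged
# ion arriving at 1.79 ms.  The mobility is fixed by that drift time,
# K = L/(E_d·t_d); the diffusion coefficient 2.8e-6 m²/s is independent input.
_K_REF = 1.1173e-4
_D_REF = 2.8e-6

#: Temperature at which the reference (K, D) pair satisfies the
#: Nernst–Einstein relation, ≈ 290.8 K.  Used to Einstein-couple mobilities
#: to diffusion coefficients in multi-species sweeps so that the reference
#: species keeps its 1.79 ms drift time.
T_REF: float = _D_REF * ELEMENTARY_CHARGE / (BOLTZMANN * _K_REF)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (np.isfinite(value) and value > 0):
            raise ParameterError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class IonSpecies:
    """Transport parameters of one analyte ion.

    Parameters
    ----------
    label : str
        Free-form species name.
    K : float
        Ion mobility, m²·V⁻¹·s⁻¹.
    D : float
        Diffusion coefficient, m²·s⁻¹.
    q : float
        Charge per ion, C.  Defaults to one elementary charge.
    """

    label: str
    K: float
    D: float
    q: float = ELEMENTARY_CHARGE

    def __post_init__(self) -> None:
        _require_positive(K=self.K, D=self.D, q=self.q)

    @classmethod
    def from_diffusion(
        cls, label: str, D: float, *, T: float = T_REF, q: float = ELEMENTARY_CHARGE
    ) -> "IonSpecies":
        """Build a species from D alone, Einstein-coupling K = D·q/(kB·T)."""
        _require_positive(D=D, T=T, q=q)
        return cls(label=label, K=mobility_from_D(D, TheoryConstants(T=T), q), D=D, q=q)


@dataclass(frozen=True)
class DriftTubeConfig:
    """Geometry and field of the 1-D drift region.

    ``L_drift`` is the entrance-to-detector length (entrance at x = 0), ``E_d``
    the constant axial field, ``S`` the cross-sectional area (a pure scale
    factor on currents) and ``dx`` the uniform grid spacing used by the
    numeric solver.  ``L_drift`` must be an integer multiple of ``dx``.
    """

    L_drift: float
    E_d: float
    S: float = 1.0
    dx: float = 5e-6

    def __post_init__(self) -> None:
        _require_positive(L_drift=self.L_drift, E_d=self.E_d, S=self.S, dx=self.dx)
        ratio = self.L_drift / self.dx
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ParameterError(
                f"L_drift={self.L_drift} is not an integer multiple of dx={self.dx}"
            )

    @property
    def n_cells(self) -> int:
        return int(round(self.L_drift / self.dx))


@dataclass(frozen=True)
class InjectionProgram:
    """Gate schedule for the drift-tube entrance.

    mode='pulsed' injects the temporal sequence blank–ion–blank (a slab of
    spatial width ``L_ion`` in an otherwise empty tube); mode='inverse'
    injects ion–blank–ion (a blank slab of width ``L_ion`` cut out of a
    continuous beam).  ``C0`` is the one-dimensional source concentration,
    ions/m.  ``t_origin`` is the solver-clock time at which the slab (or
    blank) centre crosses x = 0; spectra are reported with that instant as
    t = 0.  When None, the solver sets it to half the gate interval.
    """

    mode: str
    L_ion: float
    C0: float = 1.0
    t_origin: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("pulsed", "inverse"):
            raise ParameterError(f"mode must be 'pulsed' or 'inverse', got {self.mode!r}")
        _require_positive(L_ion=self.L_ion, C0=self.C0)


@dataclass(frozen=True)
class TheoryConstants:
    """Physical constants bundle: Boltzmann constant and temperature."""

    kB: float = BOLTZMANN
    T: float = T_DEFAULT

    def __post_init__(self) -> None:
        _require_positive(kB=self.kB, T=self.T)


@dataclass(frozen=True)
class PeakSummary:
    """Metrology of one arrival-time peak.

    ``R`` is always ``t_d / t_fwhm`` by construction.
    """

    t_d: float
    t_fwhm: float
    height: float
    R: float = field(init=False)

    def __post_init__(self) -> None:
        _require_positive(t_d=self.t_d, t_fwhm=self.t_fwhm)
        if not np.isfinite(self.height):
            raise ParameterError(f"height must be finite, got {self.height!r}")
        object.__setattr__(self, "R", self.t_d / self.t_fwhm)


#: Reference single-ion scenario: K fixed by the 1.79 ms drift time in a
#: 10 mm tube at 50 V/mm, D = 2.8e-6 m²/s.
REFERENCE_SPECIES = IonSpecies(label="reference", K=_K_REF, D=_D_REF)
REFERENCE_CONFIG = DriftTubeConfig(L_drift=0.01, E_d=5.0e4, S=1.0, dx=5e-6)


# --------------------------------------------------------------------------
# Transport basics


def drift_velocity(species: IonSpecies, E_d: float) -> float:
    """Drift velocity v_d = K·E_d, m/s."""
    _require_positive(E_d=E_d)
    return species.K * E_d


def drift_time(config: DriftTubeConfig, species: IonSpecies) -> float:
    """Arrival time of the packet centre, t_d = L/(K·E_d), s."""
    return config.L_drift / drift_velocity(species, config.E_d)


def beam_current(species: IonSpecies, E_d: float, C0: float = 1.0, S: float = 1.0) -> float:
    """Detector current of an unbroken continuous beam, I0 = C0·S·K·E_d."""
    _require_positive(C0=C0, S=S)
    return C0 * S * drift_velocity(species, E_d)


def nernst_einstein(K: float, constants: TheoryConstants | None = None,
                    q: float = ELEMENTARY_CHARGE) -> float:
    """Diffusion coefficient from mobility, D = K·kB·T/q."""
    constants = constants or TheoryConstants()
    _require_positive(K=K, q=q)
    return K * constants.kB * constants.T / q


def mobility_from_D(D: float, constants: TheoryConstants | None = None,
                    q: float = ELEMENTARY_CHARGE) -> float:
    """Mobility from diffusion coefficient, K = D·q/(kB·T) (inverse of D = K·kB·T/q)."""
    constants = constants or TheoryConstants()
    _require_positive(D=D, q=q)
    return D * q / (constants.kB * constants.T)


def einstein_temperature(K: float, D: float, q: float = ELEMENTARY_CHARGE) -> float:
    """Temperature at which a given (K, D) pair satisfies D = K·kB·T/q."""
    _require_positive(K=K, D=D, q=q)
    return D * q / (BOLTZMANN * K)


# --------------------------------------------------------------------------
# Arrival-time currents (delta-pulse Green's function forms)


def pulsed_current(t, x, species: IonSpecies, E_d: float,
                   C0: float = 1.0, S: float = 1.0):
    """Detector current of a delta-pulsed packet of content C0 per unit area.

    I1(t, x) = C0·S·K·E_d/(4πDt)^{1/2} · exp(−(x − K·E_d·t)²/(4Dt)).

    The t → 0 limit is a delta sheet at x = 0 and is not evaluated; t must be
    strictly positive.  Vectorised over ``t`` and ``x``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("pulsed_current requires t > 0")
    _require_positive(E_d=E_d, C0=C0, S=S)
    v = species.K * E_d
    out = C0 * S * v / np.sqrt(4 * np.pi * species.D * t) * np.exp(
        -((np.asarray(x, dtype=float) - v * t) ** 2) / (4 * species.D * t)
    )
    return out if out.ndim else float(out)


def peak_current(species: IonSpecies, E_d: float, L: float,
                 C0: float = 1.0, S: float = 1.0) -> float:
    """Apex current I1pk = C0·S·K·E_d/(4πD·t_d)^{1/2} of the pulsed peak at x = L."""
    _require_positive(L=L)
    v = drift_velocity(species, E_d)
    t_d = L / v
    return C0 * S * v / math.sqrt(4 * math.pi * species.D * t_d)


def inverse_current(t, x, species: IonSpecies, E_d: float,
                    C0: float = 1.0, S: float = 1.0, *, L: float | None = None):
    """Baseline-corrected current of a blank dip in a continuous beam.

    I2(t, x) = I1pk − I1(t, x), where I1pk is the pulsed apex current at the
    detector plane x = L (default: L = x).  By construction the dip minimum at
    (t_d, L) is exactly zero.
    """
    xL = float(np.max(x)) if L is None else L
    return peak_current(species, E_d, xL, C0, S) - pulsed_current(t, x, species, E_d, C0, S)


def counteracted_current(t, x, species: IonSpecies, E_d: float,
                         C0: float = 1.0, S: float = 1.0, *, L: float | None = None):
    """Counterbalanced current I3 = max(0, 2·I1 − I1pk).

    Support is the region where I1 exceeds half its apex; the apex value
    equals I1pk, so the peak height is preserved while the width shrinks by
    sqrt(ln 2 / ln(4/3)).
    """
    xL = float(np.max(x)) if L is None else L
    i1pk = peak_current(species, E_d, xL, C0, S)
    return np.maximum(0.0, 2.0 * pulsed_current(t, x, species, E_d, C0, S) - i1pk)


def tophat_pulsed_current(t, x, species: IonSpecies, E_d: float,
                          C0: float = 1.0, S: float = 1.0, *, L_ion: float):
    """Detector current of a finite slab of width L_ion and concentration C0.

    Superposition of Green's functions over the slab:

    I(t, x) = (C0·S·v/2)·[erf((x − v t + L_ion/2)/√(4Dt))
                          − erf((x − v t − L_ion/2)/√(4Dt))].

    The time-integral at the detector is C0·S·L_ion (mass conservation); for
    L_ion → 0 the current divided by L_ion converges to :func:`pulsed_current`
    (equal total content).  This is the analytic oracle for the numeric
    solver's finite-slab injections.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("tophat_pulsed_current requires t > 0")
    _require_positive(E_d=E_d, C0=C0, S=S, L_ion=L_ion)
    v = species.K * E_d
    sig = np.sqrt(4 * species.D * t)
    u = np.asarray(x, dtype=float) - v * t
    out = 0.5 * C0 * S * v * (erf((u + L_ion / 2) / sig) - erf((u - L_ion / 2) / sig))
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Peak widths and diffusion-limited resolution


def pulsed_fwhm_analytic(species: IonSpecies, E_d: float, L: float) -> float:
    """FWHM of the delta-pulsed arrival peak, (16·D·t_d·ln 2)^{1/2}/(K·E_d).

    Valid for t_d ≫ t_fwhm (the narrow-peak regime in which the arrival-time
    Gaussian has standard deviation (2·D·t_d)^{1/2}/v_d).
    """
    v = drift_velocity(species, E_d)
    t_d = L / v
    return math.sqrt(16 * species.D * t_d * math.log(2)) / v


def counteracted_fwhm_analytic(species: IonSpecies, E_d: float, L: float) -> float:
    """FWHM of the counterbalanced peak, (16·D·t_d·ln(4/3))^{1/2}/(K·E_d)."""
    v = drift_velocity(species, E_d)
    t_d = L / v
    return math.sqrt(16 * species.D * t_d * math.log(4 / 3)) / v


def _resolution(ln_c: float, E_d: float, L: float, *,
                q: float | None = None, constants: TheoryConstants | None = None,
                K: float | None = None, D: float | None = None) -> float:
    _require_positive(E_d=E_d, L=L)
    if K is not None or D is not None:
        if K is None or D is None:
            raise ParameterError("provide both K and D for the (K, D) form")
        _require_positive(K=K, D=D)
        return math.sqrt(K * E_d * L / (16 * D * ln_c))
    q = ELEMENTARY_CHARGE if q is None else q
    constants = constants or TheoryConstants()
    _require_positive(q=q)
    return math.sqrt(E_d * L * q / (16 * constants.kB * constants.T * ln_c))


def diffusion_limit_resolution(E_d: float, L: float, *, q: float | None = None,
                               constants: TheoryConstants | None = None,
                               K: float | None = None, D: float | None = None) -> float:
    """Diffusion-limited resolution of conventional pulsed drift-tube IMS.

    R_d = (E_d·L·q / (16·kB·T·ln 2))^{1/2}, or equivalently
    (K·E_d·L / (16·D·ln 2))^{1/2} when (K, D) are Einstein-linked.  Pass
    either (q, constants) or (K, D).
    """
    return _resolution(math.log(2), E_d, L, q=q, constants=constants, K=K, D=D)


def counterbalance_resolution(E_d: float, L: float, *, q: float | None = None,
                              constants: TheoryConstants | None = None,
                              K: float | None = None, D: float | None = None) -> float:
    """Diffusion-limited resolution of the inverse diffusion counterbalance
    method: R_3 = (E_d·L·q / (16·kB·T·ln(4/3)))^{1/2} (or the (K, D) form)."""
    return _resolution(math.log(4 / 3), E_d, L, q=q, constants=constants, K=K, D=D)


def enhancement_ratio_theory() -> float:
    """Mode-independent resolution enhancement ratio.

    α = R_3/R_d = sqrt(ln 2 / ln(4/3)) ≈ 1.5522, independent of species,
    field, length, charge and temperature — every shared parameter cancels.
    """
    return math.sqrt(math.log(2) / math.log(4 / 3))


def length_equivalence_factor() -> float:
    """Factor by which a conventional tube must be lengthened (fixed field)
    to match the counterbalance resolution: α² = ln 2 / ln(4/3) ≈ 2.409.

    Follows from the square-root length scaling of both resolution forms.
    """
    return math.log(2) / math.log(4 / 3)
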