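"""Configuration, spectrum I/O, synthetic fixtures and experiment runners.

Spectrum files are plain two-column TSV (time_s, current) with '#'-prefixed
``key: value`` metadata header lines.  Scenario files are flat key-value
configs (YAML syntax, strict SI units) naming the tube geometry, field, grid,
gate width and the species list.

The ``run_figure*`` runners reproduce the four simulation studies of the
method end to end: the reference single-ion counterbalance, the
diffusion-coefficient sweep, the five-species overlapping mixture, and the
initial-width degradation sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .counterbalance import correct_inverse, align, subtract_and_clip, run_counterbalance
from .exceptions import ParameterError, ScenarioError, SpectrumParseError
from .peaks import find_peaks, measure_fwhm
from .solver import InjectionProgram, Spectrum, simulate_mixture, simulate_spectrum
from .theory import (
    T_REF,
    DriftTubeConfig,
    ELEMENTARY_CHARGE,
    IonSpecies,
    TheoryConstants,
    drift_time,
    drift_velocity,
    mobility_from_D,
    pulsed_current,
    inverse_current,
    pulsed_fwhm_analytic,
)

__all__ = ["ScenarioConfig", "read_spectrum", "write_spectrum", "load_scenario",
           "reference_scenario", "generate_fixture",
           "run_figure3", "run_figure4", "run_figure5", "run_figure6"]


@dataclass
class ScenarioConfig:
    """A fully resolved simulation scenario."""

    config: DriftTubeConfig
    species: list[IonSpecies]
    L_ion: float
    C0: float = 1.0
    seed: int = 0  # reserved; the pipeline is deterministic

    def __post_init__(self) -> None:
        if not self.species:
            raise ScenarioError("scenario needs at least one species")
        if self.L_ion <= 0 or self.C0 <= 0:
            raise ScenarioError("L_ion and C0 must be positive")


# --------------------------------------------------------------------------
# Spectrum file I/O


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    lines = []
    for key, value in spectrum.meta.items():
        if isinstance(value, dict):
            value = json.dumps(value, sort_keys=True)
        lines.append(f"# {key}: {value}")
    lines.append("# columns: time_s\tcurrent")
    for t, c in zip(spectrum.times, spectrum.currents):
        lines.append(f"{float(t)!r}\t{float(c)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column TSV spectrum; errors carry the offending line number."""
    path = Path(path)
    meta: dict = {}
    times, currents = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key, value = key.strip(), value.strip()
                if key == "columns":
                    continue
                try:
                    meta[key] = json.loads(value)
                except (json.JSONDecodeError, ValueError):
                    meta[key] = value
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise SpectrumParseError(f"expected 2 columns, got {len(parts)}", lineno)
        try:
            times.append(float(parts[0]))
            currents.append(float(parts[1]))
        except ValueError:
            raise SpectrumParseError(f"non-numeric value in {parts!r}", lineno) from None
    if len(times) < 8:
        raise SpectrumParseError(f"{path} holds fewer than 8 samples")
    t = np.asarray(times)
    if np.any(np.diff(t) <= 0):
        raise SpectrumParseError("times are not strictly increasing")
    return Spectrum(times=t, currents=np.asarray(currents), meta=meta)


# --------------------------------------------------------------------------
# Scenario configuration

def _coerce_numbers(obj):
    """Turn numeric-looking strings into floats (YAML 1.1 treats '5.0e4',
    exponent without sign, as a plain string)."""
    if isinstance(obj, dict):
        return {k: _coerce_numbers(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_coerce_numbers(v) for v in obj]
    if isinstance(obj, str):
        try:
            return float(obj)
        except ValueError:
            return obj
    return obj


_REQUIRED_KEYS = {"L_drift_m", "E_Vpm", "dx_m", "L_ion_m", "species"}
_OPTIONAL_KEYS = {"S_m2", "C0", "einstein_T_K", "seed"}
_SPECIES_KEYS = {"label", "K", "D", "q"}


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a flat key-value scenario file (SI units).

    Species entries need ``label`` and ``D``; ``K`` may be omitted when a
    top-level ``einstein_T_K`` is given, in which case it is filled from the
    Einstein relation K = D·q/(kB·T).  ``q`` defaults to one elementary
    charge.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ScenarioError(f"{path} must hold a key-value mapping")
    raw = _coerce_numbers(raw)
    unknown = set(raw) - _REQUIRED_KEYS - _OPTIONAL_KEYS
    if unknown:
        raise ScenarioError(f"unknown keys {sorted(unknown)} in {path}")
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ScenarioError(f"missing required keys {sorted(missing)} in {path}")
    for key in ("L_drift_m", "E_Vpm", "dx_m", "L_ion_m", "S_m2", "C0", "einstein_T_K"):
        if key in raw and (not isinstance(raw[key], (int, float)) or raw[key] <= 0):
            raise ScenarioError(f"{key} must be a positive number, got {raw[key]!r}")
    T = raw.get("einstein_T_K")
    species = []
    if not isinstance(raw["species"], list) or not raw["species"]:
        raise ScenarioError("species must be a non-empty list")
    for entry in raw["species"]:
        if not isinstance(entry, dict):
            raise ScenarioError(f"species entry must be a mapping, got {entry!r}")
        unknown = set(entry) - _SPECIES_KEYS
        if unknown:
            raise ScenarioError(f"unknown species keys {sorted(unknown)}")
        if "label" not in entry or "D" not in entry:
            raise ScenarioError(f"species entry needs label and D: {entry!r}")
        q = entry.get("q", ELEMENTARY_CHARGE)
        K = entry.get("K")
        if K is None:
            if T is None:
                raise ScenarioError(
                    f"species {entry['label']!r} omits K but no einstein_T_K is set")
            K = mobility_from_D(entry["D"], TheoryConstants(T=T), q)
        try:
            species.append(IonSpecies(label=str(entry["label"]), K=K, D=entry["D"], q=q))
        except ParameterError as exc:
            raise ScenarioError(f"species {entry.get('label')!r}: {exc}") from exc
    try:
        config = DriftTubeConfig(L_drift=raw["L_drift_m"], E_d=raw["E_Vpm"],
                                 S=raw.get("S_m2", 1.0), dx=raw["dx_m"])
    except ParameterError as exc:
        raise ScenarioError(str(exc)) from exc
    return ScenarioConfig(config=config, species=species, L_ion=raw["L_ion_m"],
                          C0=raw.get("C0", 1.0), seed=raw.get("seed", 0))


def reference_scenario() -> ScenarioConfig:
    """The packaged reference scenario (10 mm tube, 50 V/mm, 0.1 mm gate)."""
    with resources.as_file(resources.files("dtims").joinpath("data/reference.cfg")) as p:
        return load_scenario(p)


# --------------------------------------------------------------------------
# Synthetic fixtures

_REF = None


def _reference():
    global _REF
    if _REF is None:
        _REF = reference_scenario()
    return _REF


def generate_fixture(kind: str, **params) -> Spectrum:
    """Deterministic synthetic spectra with closed-form metrology.

    Kinds: ``gaussian_peak`` (sigma, apex, dt, span), ``gaussian_dip``
    (baseline + inverted Gaussian), ``two_gaussians`` (separation), ``flat``,
    and ``analytic_reference`` (mode='pulsed'|'inverse': the closed-form
    delta-pulse currents of the reference scenario sampled at the detector).
    """
    if kind in ("gaussian_peak", "gaussian_dip", "two_gaussians"):
        sigma = params.get("sigma", 1e-5)
        apex = params.get("apex", 1e-3)
        dt = params.get("dt", 1e-7)
        span = params.get("span", 12 * sigma)
        amp = params.get("amplitude", 1.0)
        if min(sigma, apex, dt, span, amp) <= 0:
            raise ParameterError("fixture parameters must be positive")
        t = np.arange(apex - span, apex + span + dt / 2, dt)
        if kind == "gaussian_peak":
            y = amp * np.exp(-((t - apex) ** 2) / (2 * sigma**2))
        elif kind == "gaussian_dip":
            base = params.get("baseline", 2.0 * amp)
            y = base - amp * np.exp(-((t - apex) ** 2) / (2 * sigma**2))
        else:
            sep = params.get("separation", 6 * sigma)
            t = np.arange(apex - span, apex + sep + span + dt / 2, dt)
            y = amp * (np.exp(-((t - apex) ** 2) / (2 * sigma**2))
                       + np.exp(-((t - apex - sep) ** 2) / (2 * sigma**2)))
        return Spectrum(times=t, currents=y, meta={"mode": "fixture", "kind": kind})
    if kind == "flat":
        n = params.get("n", 64)
        level = params.get("level", 1.0)
        dt = params.get("dt", 1e-6)
        return Spectrum(times=np.arange(n) * dt, currents=np.full(n, float(level)),
                        meta={"mode": "fixture", "kind": "flat"})
    if kind == "analytic_reference":
        mode = params.get("mode", "pulsed")
        ref = _reference()
        sp, cfg = ref.species[0], ref.config
        t_d = drift_time(cfg, sp)
        fwhm = pulsed_fwhm_analytic(sp, cfg.E_d, cfg.L_drift)
        dt = params.get("dt", fwhm / 50)
        t = np.arange(t_d - 10 * fwhm, t_d + 10 * fwhm + dt / 2, dt)
        if mode == "pulsed":
            y = pulsed_current(t, cfg.L_drift, sp, cfg.E_d, ref.C0, cfg.S)
        elif mode == "inverse":
            y = inverse_current(t, cfg.L_drift, sp, cfg.E_d, ref.C0, cfg.S,
                                L=cfg.L_drift)
        else:
            raise ParameterError(f"unknown analytic_reference mode {mode!r}")
        return Spectrum(times=t, currents=y,
                        meta={"mode": mode, "kind": "analytic_reference"})
    raise ParameterError(f"unknown fixture kind {kind!r}")


# --------------------------------------------------------------------------
# Experiment runners


def _maybe_write(outdir, name, spectrum):
    if outdir is not None:
        write_spectrum(spectrum, Path(outdir) / name)


def _finish(outdir, name, report):
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / name).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def run_figure3(outdir: str | Path | None = None) -> dict:
    """Reference single-ion counterbalance: R_pulsed, R_counteracted, α."""
    ref = _reference()
    sp, cfg = ref.species[0], ref.config
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
    result = run_counterbalance(cfg, sp, ref.L_ion, C0=ref.C0)
    v = drift_velocity(sp, cfg.E_d)
    report = {
        "t_d_s": result.pulsed_summary.t_d,
        "gate_time_s": ref.L_ion / v,
        "R_pulsed": result.pulsed_summary.R,
        "R_counteracted": result.counteracted_summary.R,
        "alpha": result.alpha,
        "pulsed_fwhm_s": result.pulsed_summary.t_fwhm,
        "counteracted_fwhm_s": result.counteracted_summary.t_fwhm,
    }
    _maybe_write(outdir, "fig3_pulsed.tsv", result.pulsed)
    _maybe_write(outdir, "fig3_inverse_corrected.tsv", result.inverse_corrected)
    _maybe_write(outdir, "fig3_counteracted.tsv", result.counteracted)
    return _finish(outdir, "fig3_report.json", report)


def run_figure4(outdir: str | Path | None = None,
                D_values: Sequence[float] | None = None) -> dict:
    """Enhancement ratio across a diffusion-coefficient sweep.

    Nine species with D from 2e-6 to 10e-6 m²/s, mobilities Einstein-coupled
    at the reference calibration temperature so each keeps its own drift
    time.  The ratio is expected to be independent of D.
    """
    ref = _reference()
    cfg = ref.config
    if D_values is None:
        D_values = [d * 1e-6 for d in range(2, 11)]
    per_species = {}
    for D in D_values:
        sp = IonSpecies.from_diffusion(f"D={D:.2e}", D, T=T_REF)
        result = run_counterbalance(cfg, sp, ref.L_ion, C0=ref.C0)
        per_species[sp.label] = {
            "D": D, "K": sp.K, "t_d_s": result.pulsed_summary.t_d,
            "R_pulsed": result.pulsed_summary.R,
            "R_counteracted": result.counteracted_summary.R,
            "alpha": result.alpha,
        }
    alphas = [v["alpha"] for v in per_species.values()]
    report = {"species": per_species,
              "alpha_mean": float(np.mean(alphas)),
              "alpha_spread": float(np.max(alphas) - np.min(alphas))}
    return _finish(outdir, "fig4_report.json", report)


def run_figure5(outdir: str | Path | None = None,
                prominence: float = 0.05) -> dict:
    """Five-species overlapping mixture: peak counts for both modes.

    Diffusion coefficients 2.30e-6…2.50e-6 m²/s in steps of 0.05e-6,
    Einstein-coupled mobilities.  The pulsed mixture overlaps into fewer
    resolvable maxima; the counteracted spectrum separates all five.
    """
    ref = _reference()
    cfg = ref.config
    D_values = np.arange(2.30e-6, 2.501e-6, 0.05e-6)
    species = [IonSpecies.from_diffusion(f"D={D:.2e}", float(D), T=T_REF)
               for D in D_values]
    t_end = max(
        drift_time(cfg, sp) + 10 * pulsed_fwhm_analytic(sp, cfg.E_d, cfg.L_drift)
        for sp in species
    )
    pulsed = simulate_mixture(
        cfg, species, InjectionProgram(mode="pulsed", L_ion=ref.L_ion, C0=ref.C0), t_end)
    inverse = simulate_mixture(
        cfg, species, InjectionProgram(mode="inverse", L_ion=ref.L_ion, C0=ref.C0), t_end)
    corrected, baseline = correct_inverse(inverse)
    p, q = align(pulsed, corrected)
    counteracted = subtract_and_clip(p, q)
    # merge window: half the narrowest analytic pulsed FWHM, rejects ripples
    min_sep = 0.5 * min(pulsed_fwhm_analytic(sp, cfg.E_d, cfg.L_drift) for sp in species)
    pulsed_peaks = find_peaks(p, prominence, min_sep)
    counter_peaks = find_peaks(counteracted, prominence, min_sep)
    report = {
        "n_species": len(species),
        "prominence_threshold": prominence,
        "pulsed_peak_count": len(pulsed_peaks),
        "counteracted_peak_count": len(counter_peaks),
        "counteracted_apexes_s": [pk.t_d for pk in counter_peaks],
        "baseline": baseline,
    }
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
    _maybe_write(outdir, "fig5_pulsed.tsv", p)
    _maybe_write(outdir, "fig5_counteracted.tsv", counteracted)
    return _finish(outdir, "fig5_report.json", report)


def run_figure6(outdir: str | Path | None = None,
                L_ion_values: Sequence[float] | None = None) -> dict:
    """Initial-width sweep: α and pulsed FWHM versus slab width L_ion.

    The method cancels only the diffusive part of the width; the wider the
    injected slab, the smaller the diffusive fraction and the smaller α.
    """
    ref = _reference()
    sp, cfg = ref.species[0], ref.config
    if L_ion_values is None:
        L_ion_values = [5e-5, 1e-4, 2e-4, 4e-4, 7e-4, 1e-3]
    rows = []
    for L_ion in L_ion_values:
        result = run_counterbalance(cfg, sp, L_ion, C0=ref.C0)
        rows.append({"L_ion_m": L_ion, "alpha": result.alpha,
                     "pulsed_fwhm_s": result.pulsed_summary.t_fwhm,
                     "R_pulsed": result.pulsed_summary.R,
                     "R_counteracted": result.counteracted_summary.R})
    report = {"sweep": rows,
              "alpha_monotone_nonincreasing": all(
                  rows[i]["alpha"] >= rows[i + 1]["alpha"] for i in range(len(rows) - 1)),
              "fwhm_monotone_increasing": all(
                  rows[i]["pulsed_fwhm_s"] < rows[i + 1]["pulsed_fwhm_s"]
                  for i in range(len(rows) - 1))}
    return _finish(outdir, "fig6_report.json", report)
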