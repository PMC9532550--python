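# Methods

## Model

All transport is the 1-D advection–diffusion equation for the
one-dimensional ion concentration C(x, t) in a drift tube with entrance at
x = 0 and detector at x = L:

    ∂C/∂t = D ∂²C/∂x² − v_d ∂C/∂x,      v_d = K·E_d.

Assumptions inherited from the diffusion-limit framework: space charge is
negligible (species superpose linearly), diffusion acts only along the drift
axis, the field is uniform, K and D are constants (weak-field regime), and
the pulsed packet and the blank dip diffuse symmetrically. A δ-pulse of unit
content injected at x = 0 arrives at the detector as a Gaussian current

    I1(t) = C0·S·v_d/(4πDt)^{1/2} · exp(−(L − v_d t)²/(4Dt)),

with apex I1pk at t_d = L/v_d and FWHM (16·D·t_d·ln 2)^{1/2}/v_d. The
counterbalance output I3 = max(0, 2·I1 − I1pk) has FWHM
(16·D·t_d·ln(4/3))^{1/2}/v_d, whence the enhancement ratio
α = √(ln 2/ln(4/3)) ≈ 1.55223 and the length-equivalence factor α² ≈ 2.4094.
Both closed-form FWHMs use the narrow-peak approximation t_d ≫ t_fwhm; at
the reference parameters a numeric half-maximum root-find on the exact
expressions agrees with them to 2·10⁻⁵ relative (asserted in the test
suite), so the approximation is immaterial here.

## Reference scenario and calibration

The packaged reference scenario is a 10 mm tube at 50 V/mm with a 5 µm grid
and a 0.1 mm gate slab. Its species has D = 2.8·10⁻⁶ m²/s and mobility
K = L/(E_d·t_d) = 1.1173·10⁻⁴ m²V⁻¹s⁻¹, fixed by the 1.79 ms arrival time;
K and D are independent inputs, so no temperature is assumed in the
transport itself. Where a sweep specifies only diffusion coefficients, the
mobilities are Einstein-coupled, K = D·q/(k_B·T_REF), with
T_REF = D_ref·q/(k_B·K_ref) ≈ 290.8 K chosen so the reference pair is
exactly Einstein-consistent and keeps its printed drift time. Einstein
utilities default to 298 K when no temperature is given explicitly.

## Numeric solver

The tube is divided into N = L/dx cells with centres at (i + ½)dx. Each
step is an operator split:

1. **Advection** at Courant number exactly 1 (dt = dx/v_d per species): a
   pure one-cell index shift with zero numerical diffusion. This is the
   load-bearing choice — any upwind smearing at dx = 5 µm would dwarf the
   physical D ≈ 10⁻⁶ m²/s.
2. **Diffusion** by implicit Crank–Nicolson (tridiagonal banded solve,
   unconditionally stable; the diffusion number D·dt/dx² is ≈ 0.1 at the
   reference parameters).

Boundary conditions: a time-dependent Dirichlet ghost cell at the entrance
carrying the gate schedule, and a zero-curvature ghost at the detector
(which makes the detector row an identity in the diffusion step). The
detector current is the drift flux C(L)·S·v_d sampled at the last cell
centre once per step; the diffusive flux at the detector plane is omitted,
matching the drift-flux definition of the received current (its relative
contribution is of order 1/(2R²) ≈ 3·10⁻⁴ here).

Gate realisation: pulsed mode starts from an empty tube with inflow C0 for
the interval L_ion/v_d; inverse mode starts from the uniform steady state C0
with the inflow blanked for the same interval. Spectrum time zero is the
instant the slab (or blank) centre crosses x = 0. Because the two schedules
are exact complements of the constant-beam run, pulsed + inverse spectra
reproduce the constant current I0 = C0·S·v_d to solver round-off — an
invariant the suite checks at 10⁻⁶ and that in practice holds near machine
precision.

Mixtures are simulated per species with each species' own Courant-exact dt,
linearly resampled onto the overlap of the time axes at the finest dt, and
summed (valid because space charge is neglected).

Default record length is t_d + 10 analytic FWHM; the single-species
reference run is 2000 cells × ≈2500 steps and takes well under a second,
which is why the full suite and the acceptance script finish in seconds.

## Counterbalance on sampled spectra

The baseline of the raw inverse spectrum is its global minimum (an optional
odd moving-average window may locate the minimum on noisy external data;
off by default for simulated spectra). Alignment linearly interpolates both
spectra onto the overlap of their axes at the finer sampling interval —
simulated pairs share one axis already, so this is a no-op there. Clipping
happens inside the subtraction step, before any width measurement.

Peak metrology refines the apex by a parabola through the three samples
around the discrete maximum and finds half-maximum crossings by linear
interpolation on each flank; both are sub-sample accurate and validated
against closed-form Gaussian and triangle fixtures. Multi-peak detection
keeps local maxima above a height fraction (default 0.05) of the global
maximum, greedily merges peaks within a minimum separation keeping the
taller (earlier on a tie), and measures each survivor between its flanking
minima.

## What the simulations show — and a structural limitation

The reference run measures pulsed R ≈ 40.7, counteracted R ≈ 63.2 and
α ≈ 1.552; the nine-species D-sweep (2–10·10⁻⁶ m²/s, Einstein-coupled)
gives the same α for every species, confirming the species-independence of
the enhancement; the slab-width sweep (0.05–1.0 mm) shows α decaying
monotonically from ≈1.553 toward 1, because the method cancels only the
diffusive share of the width, not the injected width itself.

For mixtures the method is applied to the *summed* spectra with a single
global baseline. The counteracted spectrum is then clip(2·ΣI1 − const),
whose interior maxima coincide with those of the pulsed sum: the method
baseline-separates and sharpens maxima that already exist but cannot split
a blob that has fused completely. In the packaged five-species mixture
(D = 2.30–2.50·10⁻⁶ m²/s, step 0.05·10⁻⁶) the pulsed sum retains only 3–4
local maxima (4 in the δ-injection limit, verified analytically), so the
counteracted spectrum shows the same count, baseline-resolved. Fully
separating five such species under a global baseline would need roughly 20%
more diffusion-limit resolution (e.g. L ≳ 15 mm). A per-dip baseline could
do better for well-separated dips; it is deliberately not implemented — the
global minimum rule is the method as defined.

## Limitations

The model is strictly 1-D with a uniform field: no radial profiles, gate
field leakage, Coulomb repulsion, K(E/N) high-field effects, or
temperature/pressure gradients. Simulated spectra are noise-free, so the
tests demonstrate algorithmic correctness, not robustness to detector noise
— on real data the smoothing window and the prominence threshold become the
operative knobs. C0 and S are pure scale factors; every resolution output
is proven invariant to them.
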