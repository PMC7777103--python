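# Methods

This note records the models, conventions, parameter choices and known
limitations behind each component of `cagewater`.

## Geometry and regions

Space is partitioned around the host into **cage** (water oxygen within
`cage_radius` of the cage center), **hydration** (otherwise within
`hydration_cutoff` of any host atom) and **bulk**. The cage interior is a
sphere: the host's cavity is roughly isometric, and a sphere of the default
radius 4.0 Å has a volume of ≈268 Å³, matching the ~270 Å³ cavity of the
Ga₄L₆ tetrahedron. A convex-hull interior test would follow the cavity shape
more closely but is deliberately out of scope; the radius is configurable.
The hydration cutoff defaults to 4.1 Å, measured oxygen-to-nearest-host-atom.
The cage center is either explicit or the centroid of declared vertex atoms.
Minimum-image wrapping applies whenever a frame carries an orthorhombic box;
otherwise boundaries are open.

Region counts come with a block-averaged standard error (default block
length 10 frames) because consecutive MD frames are strongly correlated and
the naive estimator is optimistic.

## Hydrogen bonds

Default geometric criterion: r(O···O) ≤ 3.5 Å **and** O–H···O deviation
≤ 30°, the standard liquid-water definition; both are configurable. The
correlator is the **intermittent** C_HB(t) = ⟨h(t)h(0)⟩/⟨h(0)²⟩ — a bond may
break and re-form without resetting its history — because that is the form
whose decay time feeds the THz band analysis. A continuous-lifetime variant
(`continuous=True`) zeroes h after the first breaking event; it is provided
but not the default. No reactive-flux (Luzar–Chandler) kinetics are
attempted.

Relaxation times default to the **1/e crossing** with linear interpolation
between lag points, optionally after subtracting a plateau (a number, or
`"tail"` = mean of the last 20 % of lags). The 1/e convention makes no
single-exponential assumption; a least-squares `A·exp(−t/τ) + C` fit is the
alternative. Failure (no crossing, non-convergent fit) is flagged in the
returned estimate, never silently replaced.

Orientational dynamics uses the unit dipole along the bisector from O
through the H-midpoint, and C_μ⁽²⁾(t) is computed exactly via FFT of the
nine outer-product component series (⟨(u(0)·u(t))²⟩ = Σ_ab ⟨q_ab(0)q_ab(t)⟩).
With a region filter, membership is evaluated at each time origin and the
water is not dropped if it later migrates — the physically common
convention, and configurable by filtering the input instead.

Residence analysis merges cage exits shorter than `tolerance_gap` (default
0.5 ps, the scale of a recrossing event) and classifies a water as
**arrested** when its longest merged in-cage interval reaches `threshold`
(default 10 ps, an order of magnitude beyond the 1–3 ps bulk exchange time;
demo runs scale it with their shorter durations).

## Order parameters

q follows the Errington–Debenedetti convention: the four nearest water
oxygens regardless of distance or region, so cage-edge molecules may count
exterior neighbors. q = 1 at a perfect tetrahedral site; the isotropic
average is 0 (verified against a Monte-Carlo oracle). Sites with fewer than
four resolvable neighbors yield NaN rather than a guess.

t = (1/s_c)∫₀^{s_c}|g(s) − 1|ds with s = ρ^{1/3}r and s_c = 2.843. It is 0
exactly for g ≡ 1 (the integrand is extended constantly below the first
bin — no assumption about g(0) is injected). An optional normalization
constant rescales a chosen reference (e.g. a thermally broadened fcc
crystal) to t = 1; it is off by default and recorded in metadata when used,
since the reference's broadening width shifts the constant.

Finite-cluster g(r) (cage–cage pairs) is normalized with the local density
N_cage/V_cage; this convention sets absolute peak heights and is recorded in
the output metadata. Periodic g(r) uses (N−1)/V per frame so an ideal gas
gives exactly 1 on average.

## THz spectra

The spectrum is the one-sided cosine transform of the autocorrelation of the
dipole-velocity current J_u(t) = Σ_m P_um v_m(t). Forming J first is
algebraically identical to the full 3N×3N self- plus cross-term double sum
and N-fold cheaper; the equivalence is asserted against an explicit-loop
oracle in the tests. Restricting the atom selection restricts the sum to a
vibrational population (e.g. the cage waters only).

Polar tensors default to **static effective-charge diagonals**: P = qI with
q(O) = −2δ, q(H) = +δ, δ = 0.42 e (a fixed-point-charge model chosen so each
water is neutral and the O/H weighting is water-like). Structure-dependent
tabulated tensors are read from a simple text format for users who have a
parameterization. Raw intensities carry the 2πβ/(3cV) prefactor (β from the
temperature, V from the box); the default output is peak-normalized
(`max1`), the usual convention for comparing band shapes.

A Hann window is applied to the correlation function before transforming
(length = `max_lag`, default half the trajectory); the window, selection and
normalization are recorded in the spectrum metadata. Resolution and Nyquist
limits are Δν = 1/(cT) and ν_max = 1/(2c·dt); requested grids beyond Nyquist
are rejected. No quantum correction factor is applied.

## Cavitation and solvation

Occupancy histograms count water oxygens in a spherical probe — at the cage
center every frame, or at uniformly sampled bulk points rejected within
(radius + hydration cutoff) of any host atom. Δμ_cav = −ln P_v(0) in kT.
When no empty frame is observed, the matched-moment Gaussian's mass on the
n = 0 bin provides an extrapolated estimate, clearly labeled
`gaussian_extrapolated`; the **default workflow instead measures small
probes directly (r = 2.0–3.5 Å), fits Δμ_cav linearly in cavity volume per
environment and extrapolates the bulk − cage difference to the guest radius
(5 Å)**. On Poisson ensembles both the per-radius values (ρV kT) and the
extrapolated difference ((ρ₁−ρ₂)·V) have closed forms that the tests check.

Born: Δμ_q = −(q²/2R)(1 − 1/ε), with 332.06 (kcal/mol)·Å/e² ; ε inside the
cage is a user parameter (there is no meaningful way to compute it for a
dozen molecules), typically explored as a fraction of the bulk value.

Field–bond-dipole: for each HB, the Coulomb field of all partial charges
*excluding the donor and acceptor molecules* is evaluated at the donor-O/
acceptor-O midpoint and projected on the donor→acceptor axis; the per-bond
energy is 0.048·μ[D]·E[MV/cm] kcal/mol. The 0.048 factor is the unit chain
0.2082 (e·Å)/D × 23.061 kcal/mol per e·V × 0.01 (V/Å)/(MV/cm) ≈ 0.048. The
evaluation point and axis are conventions (the midpoint is the natural
center of the bond dipole) and both are configurable; the default HB dipole
is 2.9 D, the value obtained from maximally-localized-Wannier-center
analyses of liquid water. The sign convention takes positive projected
fields as promoting bond breaking; `sign=-1` flips it.

## Three-oscillator spectral model

Absorbance lineshape per mode: A·ν²·w₀ / [(ν₀² − ν²)² + (ν·w₀)²] — a
canonical damped-harmonic-oscillator absorbance whose single-mode maximum
falls exactly at ν₀. Three modes: relaxational (center constrained below
100 cm⁻¹), intermolecular HB stretch, and librational with center fixed at
650 cm⁻¹ (it lies outside a 50–450 cm⁻¹ measurement window, so it cannot be
determined from the data and is conventionally pinned to the bulk-water
value). Defaults for the relaxational mode are (50, 220) cm⁻¹ and for the
librational width 400 cm⁻¹, with unit amplitudes; the stretch defaults take
the measured (center, width) per environment from `STRETCH_BANDS`
(cage 180/249, bulk 293 K 181/537, 273.2 K 193/557, 10 kbar 216/542 cm⁻¹).

The fit is nonlinear least squares (lmfit) with the stretch center bounded
to the data window and, by default, a 3×3 grid of stretch starting points
(centers 140/190/260, widths 150/350/550 cm⁻¹) from which the best residual
is kept — with three broad overlapping bands a single generic start can land
in a poor local minimum. 2σ uncertainties come from the covariance diagonal;
non-convergence is flagged, never hidden. Because generator and fitter share
the lineshape, parameter-recovery tests are self-consistency checks, not
evidence about any particular instrument's lineshape.

Water counting scales a bulk reference spectrum by n·(c_host/c_bulk) with
c_bulk = 55.35 M and picks the integer n (0–30) minimizing squared deviation
over the fit band (default 100–270 cm⁻¹, where the confined-water signal
dominates); per-n residuals are returned so a ±1 ambiguity stays visible.

## Synthetic ensembles: what they emulate, and what they do not

The generators are statistical stand-ins, not physical water models:

- **Poisson ensemble**: per-frame molecule count ~ Poisson(ρV_box) with
  uniform positions, so any sub-volume is exactly Poisson — an ideal gas at
  the chosen density (default 0.0334 Å⁻³, ambient water). No pair structure.
- **Gaussian occupancy ensemble**: the probe-sphere count is drawn first
  from a discretized (rounded, clipped at 0) Gaussian with variance =
  `variance_ratio` × mean, then positions are placed uniformly inside/
  outside. It emulates occupancy statistics only; discretization inflates
  the realized variance ratio by a few percent at small means.
- **Confined droplet**: free-particle Langevin dynamics (velocity
  Ornstein–Uhlenbeck plus drift, i.e. the force-free BAOAB limit) with hard
  reflecting walls — confined waters inside the cage sphere, exchanging
  waters free to cross, exterior waters kept in an outer shell. Hydrogens
  ride rigidly with a fixed per-molecule orientation, so droplet HB dynamics
  are diffusive, not librational. The contract is statistical (thermal
  velocities, wall confinement, continuous paths), not symplectic.
- **Markov HB chains**: the exact discrete skeleton of the two-state
  continuous-time chain, so C_HB(t) = p + (1−p)e^{−(k_b+k_f)t} exactly with
  p = k_f/(k_b+k_f).
- **Rotational diffusion**: tangent-plane Gaussian steps of variance 2D_r·dt
  renormalized to the sphere; C₂ decays as e^{−6D_r t} for the step sizes
  used (dt ≪ 1/D_r).
- **Harmonic velocities / oscillator spectra**: random-phase cosines at
  stated wavenumbers; the three-mode model plus white Gaussian noise.

Passing tests therefore demonstrate that the *analysis machinery* is correct
against known ground truth; they say nothing about force fields, real water
structure, or instrument response.

## Numerical choices

- Correlators use FFT with per-lag unbiased counts; the sample ACF of a
  finite window of length T is still biased low by O(2p(1−p)τ/T), which the
  test bounds account for analytically.
- Quadratures (coordination number, t) are trapezoidal with an interpolated
  endpoint exactly at the cutoff.
- Degenerate inputs fail loudly: empty selections, never-intact bond sets,
  P_v(0) = 0 in direct mode, grids short of the t cutoff, aliased
  frequencies, overfilled cages.
- All stochastic stages derive sub-seeds from one run seed via
  `SeedSequence.spawn`, making pipeline reruns bit-identical.

## Problem sizes in the shipped benchmarks

The benchmark workflow (`scripts/acceptance.py`, mirrored by the `targets`
pipeline stage) uses: a 201-point 50–450 cm⁻¹ grid for the noiseless
oscillator fits; 20 000 configurations of a 14 Å box at ρ = 0.0334 Å⁻³ with
variance ratio 0.6 for the 4 Å-probe occupancy mode; 500 Markov chains of
50 ps at dt = 0.01 ps with k_b = k_f = 0.5 ps⁻¹ for the HB lifetime; and two
500-dipole, 40 ps rotational ensembles with D_r = 0.05 and 0.125 rad²/ps
(τ₂ = 3.33 and 1.33 ps) for the 2.5× relaxation-time ratio. These sizes give
comfortably sub-percent (deterministic) to few-percent (stochastic)
reproducibility and run in well under a minute.

## Known limitations

- The spherical cage-interior criterion is a modeling choice; strongly
  aspherical cavities need a different `CageDefinition`.
- Static effective-charge polar tensors ignore charge-flux contributions to
  IR intensities; absolute intensities are therefore only as meaningful as
  the tensors supplied.
- The Gaussian occupancy generator does not reproduce pair correlations, so
  it must not be used to validate g(r)-based observables.
- The oscillator lineshape is one of several damped-oscillator conventions
  in use; fitted widths are not directly comparable across conventions.
- Bulk-probe sampling assumes the host is far from the box boundary; very
  crowded boxes can make the rejection sampling slow (it aborts after 1000
  attempts per sample).
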