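# cagewater

Analysis toolkit for water confined in supramolecular hosts — specifically
the class of Ga₄L₆ tetrahedral metal–ligand cages whose ~270 Å³ aqueous
cavity encapsulates a small water cluster that is displaced when a cationic
guest binds. The package implements, as reusable and tested components, the
computational characterization of such a confined droplet:

- **Hydrogen-bond and orientational dynamics** — the intermittent HB
  autocorrelation C_HB(t) = ⟨h(t)h(0)⟩/⟨h(0)²⟩ (h = 1 while a bond is
  intact) and the rank-2 dipole correlator C_μ⁽²⁾(t) = ⟨P₂[μ(t)·μ(0)]⟩,
  with 1/e and exponential-fit relaxation times, residence-time
  classification of *arrested* vs *fast* cage waters, and per-region HB
  counts.
- **Structural order** — oxygen–oxygen g(r) with region-resolved
  normalization, coordination numbers 4πρ∫g(r)r²dr, the tetrahedral order
  parameter q = 1 − (3/8)Σ(cos ψ + 1/3)² and the translational order
  t = (1/s_c)∫|g(s) − 1|ds in density-reduced distance.
- **THz-IR spectra from trajectories** — the Fourier transform of the
  polar-tensor-weighted velocity autocorrelation,
  I(ω) ∝ β/(cV) ∫dt e^{iωt} ⟨J(t)·J(0)⟩ with J_u = Σ_m P_um v_m, including
  population-restricted spectra (e.g. cage waters only).
- **Cavitation and solvation thermodynamics** — probe-volume occupancy
  statistics, Δμ_cav = −kT ln P_v(0), linear-in-volume fits and
  extrapolation to guest-sized cavities, the Born charging energy
  −(q²/2R)(1 − 1/ε), and a field–bond-dipole estimate of HB destabilization
  ⟨ΔG⟩ = (1/N)Σ 0.048·μᵢ·Eᵢ (μ in Debye, E in MV/cm, result in kcal/mol).
- **Experimental-side spectrum algebra** — double-difference construction
  ΔΔα = Δα⁽¹⁾ − Δα⁽²⁾ isolating the displaced water cluster, decomposition
  into three damped harmonic oscillators (relaxational, HB stretch,
  librational), water-count estimation by bulk-reference scaling, and
  band-ratio diagnostics.

Because no public trajectories or spectra exist for these systems, the
`synth` module generates every statistical structure the analyses assume —
Poisson/sub-Poissonian occupancy ensembles, wall-confined Langevin droplets,
two-state Markov HB chains, rotational Brownian dipoles, harmonic velocity
signals and noisy oscillator spectra — with analytically known ground truth,
so every stage is testable end to end.

## Worked example

```python
import numpy as np
from cagewater import (make_oscillator_spectrum, fit_oscillators,
                       make_bulk_ensemble, occupancy_distribution,
                       cavitation_free_energy)

# decompose a synthetic THz difference spectrum (cage-water band parameters,
# ~2% noise) into relaxational + stretch + librational modes
spec = make_oscillator_spectrum(noise_sd=1e-4, seed=4)
fit = fit_oscillators(spec)
s, ts = fit.params.stretch, fit.params.two_sigma
print(f"stretch band: center {s.center:.0f} ({ts['stretch_center']:.0f}) cm^-1, "
      f"width {s.width:.0f} ({ts['stretch_width']:.0f}) cm^-1")

# cavitation cost of a 2 Å probe in a bulk-density Poisson ensemble
ens = make_bulk_ensemble(density=0.0334, box=12.0, n_frames=5000, seed=4)
dist = occupancy_distribution(ens, ens.topology, radius=2.0,
                              center=np.full(3, 6.0))
res = cavitation_free_energy(dist)
print(f"P_v(0) = {dist.pv[0]:.3f}, cavitation cost = {res.delta_mu_kT:.2f} kT")
```

prints

```
stretch band: center 176 (6) cm^-1, width 228 (40) cm^-1
P_v(0) = 0.328, cavitation cost = 1.11 kT
```

The recovered stretch parameters bracket the generating values (center 180,
width 249 cm⁻¹) within their 2σ uncertainties — the broad overlapping bands
make the width the softest parameter. The empty-probe probability matches
the Poisson closed form e^(−ρV) = 0.327, i.e. a cavitation cost of
ρV = 1.12 kT.

A command-line interface mirrors the library
(`cagewater run-all --seed 1 --out out/`, plus `generate`, `regions`,
`hbonds`, `fit`, `validate` subcommands).

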