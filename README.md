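# pvatm

Forward optical simulation and spectral-fingerprint analysis for
**polarization-varying anisotropic terahertz microscopy (PV-ATM)** of molecular
crystals — sucrose as the benchmark phonon system, and protein crystals
(e.g. hen egg-white lysozyme, free and inhibitor-bound) as the scientific
target.

## The problem

Low-frequency (10–100 cm⁻¹) vibrations of a protein are collective,
whole-backbone motions whose *directions* — not just energies — govern
function.  Light only excites a vibration whose transition dipole has a
component along the polarization, so polarization-resolved absorbance on an
aligned sample (a crystal) isolates individual vibrational bands that are
invisible in the isotropic spectrum.  PV-ATM rotates a wire-grid polarizer in
front of a fixed crystal in the near field of an electro-optic (EO) detection
crystal, and references every polarizer angle to an empty aperture.

This package implements the full forward model of that measurement and the
analysis chain that turns measured or simulated surfaces into resonance
fingerprints:

- **Lorentz-oscillator dielectrics** per crystal axis:
  ε(ω) = ε_DC + Σₙ (½Aₙ)/(ωₙ² − ω² − iωγₙ), with n(ω) = √ε on the absorbing
  branch and α(ω) = 4πω·Im n, plus least-squares fitting of such models to
  absorption spectra (`pvatm.dielectric`).
- **Jones calculus** through the rotating polarizer
  (R(θ)·diag(t∥, t⊥)·R(−θ), field extinction 20:1) and the birefringent
  sample (R(β)·diag(e^{i√ε_o 2πωd}, e^{i√ε_e 2πωd})·R(−β))
  (`pvatm.jones`).
- **EO detection response** ΔI = |E|[cos(ϕ+ϕ₀)sin 2φ + 2 sin(ϕ+ϕ₀)cos 2φ]
  for a (110)-cut crystal, implemented as a complex superposition so it is
  well defined for elliptical fields, with least-squares recovery of the
  geometry (ϕ₀, φ) from an empty-aperture angle sweep (`pvatm.detection`).
- **Relative-absorbance surfaces**
  Δabs(ω, θ) = −2 ln(|T(ω, θ)| / |T(ω, θ_ref)|) over (ω, θ) grids for both the
  far-field and the full PV-ATM chain (`pvatm.surfaces`).
- **Fingerprints**: per-angle Lorentzian peak extraction with cross-angle
  clustering, 180° periodicity folding, free-vs-bound fingerprint diffs, and
  the √(k/m) lattice-phonon scaling estimate (`pvatm.peaks`).
- **Synthetic inputs** for every stage — sucrose and lysozyme presets,
  peak-parameterized surfaces with exact round-trip properties, seeded noise,
  and a time-domain-spectroscopy emulator (`pvatm.fixtures`) — plus CSV /
  HDF5 / YAML I/O and a CLI (`pvatm.io`, `pvatm.cli`).

## Worked example

Simulate the far-field orientation-dependent absorbance of a c-cut sucrose
crystal (a axis along the 0° reference) and re-extract its phonon lines:

```python
import numpy as np
from pvatm import sucrose_preset, farfield_surface, extract_peaks

sample = sucrose_preset(beta_deg=0.0)          # d = 0.0275 cm, n(0) = 1.8
omega = np.round(np.arange(300, 901) * 0.1, 10)   # 30..90 cm^-1
theta = np.arange(0.0, 361.0, 15.0)
surface = farfield_surface(sample, omega, theta)
print("   nu    FWHM  theta   dabs")
for r in extract_peaks(surface, amplitude_floor=0.3):
    print(f"{r.nu:6.2f}  {r.fwhm:4.2f}  {r.theta_deg:5.1f}  {r.amplitude:+5.2f}")
```

```
   nu    FWHM  theta   dabs
 49.06  2.01   90.0  +3.34
 55.05  1.99   90.0  -2.87
 59.04  1.97   90.0  +2.86
 62.04  2.05   90.0  +2.53
 66.04  1.99   90.0  -3.13
 75.04  1.99   90.0  -2.69
```

The three positive lines (49, 59, 62 cm⁻¹) are the b-axis phonons, strongest
90° from the reference; the negative lines (55, 66, 75 cm⁻¹) are the a/c-axis
family — the sign encodes which axis a phonon is polarized along, and the
59/62 cm⁻¹ doublet is resolved at 0.1 cm⁻¹ grid spacing.

Comparing the free and inhibitor-bound lysozyme fingerprints shows the
binding signature — every line reorients or shifts, none survive a
2 cm⁻¹ / 15° match:

```python
from pvatm import cewl_presets, fingerprint_diff
free, bound = cewl_presets(crystal=1)
diff = fingerprint_diff(free, bound, nu_tol=2.0, theta_tol=15.0)
print("disappeared:", [r.nu for r in diff.disappeared])
print("appeared:   ", [r.nu for r in diff.appeared])
```

```
disappeared: [26.0, 46.0, 53.0, 68.0, 85.0, 92.0]
appeared:    [16.0, 24.0, 31.0, 41.0, 51.0, 97.0]
```

These resonances cannot be crystal lattice phonons: scaling the 49 cm⁻¹
sucrose phonon by √(k/m) for a molecule ~1000× heavier with less than half
the contact stiffness puts lattice phonons near
`lattice_phonon_estimate(49.0, 1000.0, 0.5)` → `1.10` cm⁻¹, an order of
magnitude below the observed bands — so they are intramolecular vibrations.

The same operations are available from the shell:

```sh
pvatm fixture sucrose --beta 0 --out sucrose.json
pvatm simulate-farfield --config sucrose.json --out surface.csv
pvatm extract-peaks surface.csv --amplitude-floor 0.3 --out peaks.csv
pvatm fixture cewl-free --out free.csv
pvatm fixture cewl-bound --out bound.csv
pvatm diff free.csv bound.csv --nu-tol 2 --theta-tol 15
```

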