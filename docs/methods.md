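# Methods

## Forward model

The simulated instrument is a linear chain at each wavenumber ω (cm⁻¹) and
polarizer angle θ (degrees):

    source (linear x) → wire-grid polarizer(θ) → [sample] → EO detection

**Dielectrics.** Each in-plane crystal axis carries a sum of damped Lorentz
oscillators over a DC constant,

    ε(ω) = ε_DC + Σₙ (½Aₙ) / (ωₙ² − ω² − i·ω·γₙ),

with amplitudes Aₙ in cm⁻², centers ωₙ and widths γₙ in cm⁻¹.  The ½Aₙ
prefactor is kept literally, so reported amplitudes include it.  The complex
index is the principal square root with Im n ≥ 0; with the propagation factor
e^{+i·n·2πωd} this branch makes absorbing media decay, and the power
absorption coefficient is α = 4πω·Im n (field magnitude scales as
e^{−αd/2}).  `normalize_dc` solves ε_DC = n₀² − ΣAₙ/(2ωₙ²) so that the
zero-frequency index hits a target (1.8 for sucrose) exactly, and rejects
targets that would need ε_DC < 0.  Wavenumber is the canonical unit
everywhere; THz is accepted only at I/O boundaries (1 THz = 33.356 cm⁻¹).

**Jones optics.**  A single sign convention is used throughout: a positive
angle rotates lab x toward lab y, and an element at angle a is
R(a)·D·R(−a).  The polarizer's diagonal is (t∥, t⊥) = (1, 1/20) by default
(20:1 field, 400:1 power extinction); t⊥ = 0 gives an ideal polarizer.  The
sample's diagonal is pure propagation phase e^{i√ε_{o,e}·2πωd} — no Fresnel
interface losses and no internal-reflection (etalon) terms, which keeps the
model faithful to the transmission matrix it implements; adding interface
terms would be a straightforward extension.  The sample orientation β is the
rotation of the ordinary (a) axis from lab x; −75° is the default
polarization-varying measurement geometry, β = 0 puts the a axis on the 0°
reference as in the far-field geometry.

**EO detection.**  The balanced-detector response of a (110)-cut EO crystal
to a linearly polarized THz field at angle ϕ is
|E|·[cos(ϕ+ϕ₀)sin 2φ + 2 sin(ϕ+ϕ₀)cos 2φ], with ϕ₀ the initial THz offset
and φ the NIR probe angle (defaults ϕ₀ = −5.12°, φ = 48.45°).  Because the
EO effect is linear in the field, the implementation forms the complex
superposition s = e_x′·sin 2φ + 2·e_y′·cos 2φ of the field rotated by ϕ₀ and
reports |s|; this reduces exactly to the scalar expression for linear
polarization and stays well defined for the elliptical fields a birefringent
sample produces.  An alternative "azimuth" mode (scalar expression applied at
the ellipse major-axis azimuth) is selectable for sensitivity analysis.
Signed time-domain signals are out of scope; spectral magnitudes are used
throughout.

**Surfaces.**  The far-field constructor sends a unit linear field at each θ
through the sample and detects the total transmitted magnitude (a
co-polarized analyzer mode is available); the PV-ATM constructor detects the
polarizer-only chain as the empty-aperture reference and the polarizer+sample
chain as the signal, forms |T| = ΔI_sample/ΔI_ref per (ω, θ), and normalizes
at θ = 0°.  Both yield Δabs = −2 ln(ratio), exactly zero at the reference
angle.  Default grids are ω = 0, 0.1, …, 200 cm⁻¹ and θ = 0, 15, …, 360°;
both configurable.  Cells with vanishing reference signal (e.g. an ideal
polarizer crossed with the source) become NaN and stay missing downstream.

A consequence worth stating: passivity bounds the transmitted *field*
(|E_s| ≤ |E_ref| whenever all Aₙ ≥ 0), but not the EO-*detected* ratio.  The
detector weights the two field components asymmetrically (the factor 2 above),
so a birefringent sample that rotates polarization toward the high-response
axis raises ΔI_sample above ΔI_ref at some angles.  This is the mechanism
that gives the polarization-varying measurement its extra structure near the
90° response minimum, and the test suite asserts both facts: field-magnitude
passivity holds everywhere; the detected ratio does exceed unity.

## Fitting

**Lorentzian absorption fits** (`fit_lorentzians`) operate on
absorption-coefficient spectra α(ω); absorbance α·d differs only by the known
thickness.  The default lineshape evaluates α through the permittivity model
itself, so fitted parameters feed the forward simulation with no conversion;
an additive sum-of-Lorentzians fast path (peak height πA/(n₀γ)) is available
behind a flag.  ε_DC is held fixed (default 3.24, n₀ = 1.8) because a DC
offset is unobservable in absorption alone.  The baseline is a polynomial of
configurable order (default 2) for smooth instrument/scattering backgrounds.
Auto-seeding uses local maxima; requesting more peaks than resolvable
features warns and pads seeds rather than failing.

**Detection-geometry fits** (`fit_detection_geometry`) least-squares match
the empty-aperture model to a measured ΔI(θ) curve covering a full
revolution, multi-starting over φ ∈ {0°, 30°, 60°} to escape the trig mirror
symmetries.  The model has exact discrete degeneracies: ϕ₀ → ϕ₀ + 180° and
φ → φ + 90° flip only the sign of s, and the mirror branch
(φ, ϕ₀) → (90° − φ, ϕ₀ − 2δ) with δ = atan2(2cos 2φ, sin 2φ) reproduces the
curve exactly.  Results are canonicalized to ϕ₀ ∈ (−90°, 90°], φ ∈ [0°, 90°)
and the branch with minimal |ϕ₀| is returned (a nominally aligned source is
the physical prior); the alternate branch is reported on the result object.
The overall signal scale is fixed at the model's own scale rather than
fitted — freeing it would collapse the two angles onto a one-parameter
continuum.

## Peak extraction

The extraction that builds fingerprint tables is a two-stage procedure chosen
to match the reporting granularity (ν, Δν, θ, Δabs) of a peak table:

1. Per angle row, local extrema of either sign above the amplitude floor are
   seeded (`scipy.signal.find_peaks`, minimum spacing = `min_separation`,
   default 2 cm⁻¹) and refined by a joint least-squares fit of unit-peak
   Lorentzians plus a constant baseline.  Detections are clustered across
   rows by center frequency with tolerance max(grid step, FWHM/4), using the
   narrower of adjacent linewidths so a blended fit from a weak row cannot
   bridge two resolved lines; clusters overlapping a stronger cluster within
   half their own width are discarded as blend composites.
2. Every row is refit against the resulting consensus line list (centers
   constrained to ±FWHM/2, widths to a factor 3), so lines below the seeding
   threshold in a given row still have their tails modelled and amplitudes
   stay unbiased.  Each line reports the row of maximal |amplitude|, with the
   angle folded into [0°, 180°) (all features of an aligned molecular crystal
   are 180°-periodic).

Valleys are extracted with signed amplitude; file output stores magnitudes
with a sign column.  Fingerprint diffs use greedy nearest-frequency matching
within (ν, θ) tolerances on folded records, ties broken by smaller linewidth
difference; with short tables (< 15 lines) greedy matching is equivalent to
optimal assignment in practice.

## Synthetic data

The fixtures generate the study conditions directly:

- **Sucrose preset**: b-axis oscillators at 49, 59, 62 cm⁻¹ and a/c-axis at
  55, 66, 75 cm⁻¹ (the established phonon positions); d = 0.0275 cm; both
  axes DC-normalized to n(0) = 1.8; β = −75° by default.  Linewidths (2 cm⁻¹,
  typical for molecular crystals at room temperature) and amplitudes
  (100–140 cm⁻², giving far-field Δabs peaks of order 3) are fixture
  choices — the published record fixes only the center frequencies — and are
  never used as ground truth for anything but round-trip consistency.
- **Lysozyme fingerprints**: the free and tri-acetyl-glucosamine-bound peak
  tables (6 lines each), with the bound set's two measured crystals
  selectable (crystal 1 by default; neither is canonical).
- **Peak-to-surface rendering**: each record contributes
  amplitude · L(ω; ν, Δν) · g(θ), with L a unit-peak Lorentzian.  The angular
  weight g must be 180°-periodic, exactly 1 at the record angle and exactly 0
  at the reference angle; the default is the normalized periodic bump
  g = (e^{κcos 2(θ−θₙ)} − e^{κcos 2(θ_ref−θₙ)}) / (e^κ − e^{κcos 2(θ_ref−θₙ)})
  with κ = 4, whose single dominant lobe makes extraction round-trip exactly
  on noiseless output.  The physically motivated cos²-difference profile
  (what a single absorption dipole projects) is available as
  `profile="cos2"`, but its opposite-sign lobe is cot²(θ_ref−θₙ) times the
  peak — larger than the peak whenever the record angle is within 45° of the
  reference — so it cannot serve as a round-trip test generator; with κ = 4
  the bump's opposite lobe stays below the peak for record angles more than
  ~17° from the reference, which covers every fixture record.
- **Noise injection**: seeded i.i.d. Gaussian noise, reference column kept
  exactly zero.
- **TDS emulation**: a derivative-of-Gaussian single-cycle pulse (spectral
  peak 33 cm⁻¹ by default, 0.02 ps sampling), multiplied in the frequency
  domain by the sample's co-polarized transfer function, with the scan span
  set from the requested spectral resolution (default 0.68 cm⁻¹; the sample
  count is rounded up so bin spacing never exceeds the request).  A
  resolution coarser than the narrowest oscillator linewidth warns.

What the synthetic data does **not** emulate: near-field aperture
diffraction, EO-crystal pixel inhomogeneity, atmospheric water lines,
hydration drift, source ellipticity (available as an option but off by
default), and etalon reflections.  Passing round-trip tests therefore
demonstrates self-consistency of the simulation/analysis chain under the
stated optical model, not instrument-level agreement with any particular
measured surface — the in-plane orientation β of a real crystal, for
instance, is unknown a priori and is exposed as a free configuration
parameter rather than fitted pixel-wise.

## Numerical choices

- Square-root branch: principal root, imaginary part forced ≥ 0.
- Missing data: NaN end to end (masked cells never become sentinel numbers
  or infinities); reference signals below a configurable floor mask the cell.
- Surface CSV I/O uses 17-significant-digit formatting and round-trip float
  parsing, so write→read is bit-exact including NaNs.
- Angles are degrees at every interface and in every file; radians only
  inside trigonometry.
- Problem sizes: the shipped tests and the acceptance script use ω spans of
  30–90 cm⁻¹ (sucrose) and 5–120 cm⁻¹ (lysozyme) at the standard 0.1 cm⁻¹
  spacing, θ steps of 15° (simulation convention) or 5° (fingerprint
  rendering, so the 20°/40°/60° record angles lie on the grid), and 100
  noise seeds for the geometry-recovery Monte Carlo; these bracket every
  feature of interest while keeping the whole suite around ten seconds.

## Known limitations

- No Fabry–Pérot or Fresnel terms: simulated |T| lacks the etalon fringes of
  real thin-sample data.
- The additive-Lorentzian fit mode is a weak-damping approximation; its
  amplitude conversion degrades for strongly overlapping lines.
- Greedy diff matching can mispair when more lines fall inside one tolerance
  window than exist in the other fingerprint; tolerances are caller-chosen.
- The detection-geometry mirror degeneracy is resolved by a prior (minimal
  |ϕ₀|), not by data; curves generated far from a nominally aligned source
  would need the alternate branch the result object carries.
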