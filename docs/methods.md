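# Methods

`ionslab` simulates therapeutic-energy light-ion beams in layered slab
phantoms and derives the observables used to judge whether a biomaterial
phantom is dosimetrically equivalent to a real-tissue one: Bragg-peak
position and amplitude, entrance LET, longitudinal and lateral straggle,
and nuclear-recoil (displacement damage) tallies.  This note records the
models, the parameter choices that matter, and the known limitations.

## Phantom model

A phantom is an ordered stack of homogeneous plane-parallel slabs.  Each
slab material is specified by its atomic composition (atomic percent),
total atomic number density (10²² atoms/cm³) and mass density (g/cm³).
Compositions are renormalized to unit fraction sum at construction: the
shipped tissue table contains rows whose printed percentages do not sum to
100 (skin sums to ≈110), and because the atomic density of every compound
is given independently, only relative fractions carry information.  The
printed values are stored verbatim; no corrections are guessed.  Several
tissue rows are physically surprising under this reading (the skin row
implies an electron density ≈2.2× water at mass density 1.02 g/cm³; the
masseter row ≈1.45×); the consequences are discussed under
*Limitations*.

Two ten-layer mandible plate fixtures are shipped — real tissues and
polymeric substitutes (PMMA, parylene N, polyethylene, water, PTFE).  The
sources of the fixture table do not print layer thicknesses.  The defaults
used here keep anatomically plausible proportions
(skin : parotid : SMAS : masseter : fat : mucosa : saliva : gum
= 2 : 8 : 2 : 10 : 5 : 2 : 0.5 : 1.5) scaled ×2.2, with 3 mm cortical and
4 mm cancellous bone, for a 75.2 mm stack.  The scale was fixed once from
CSDA arithmetic so that every beam in the 354–376 MeV scan stops inside
both material variants (helium CSDA ranges are 62–69 mm water-equivalent);
it was not revisited afterwards.  All thicknesses are overridable through
the YAML phantom config.

## Stopping power

Electronic stopping is the relativistic Bethe formula,

  S_e = (4π r_e² m_e c²) n_e (Z₁*)²/β² [ln(2 m_e c² β²γ²/I) − β²],

with a Barkas-type effective charge Z₁* = Z₁(1 − exp(−125β/Z₁^⅔)) and a
compound mean excitation energy from Bragg additivity,
ln I = Σ f_i Z_i ln I_i / Σ f_i Z_i, using ICRU-49 elemental I values.
No shell, Barkas-correction or density-effect terms are included; these
are sub-percent at the energies of interest and the observables compared
across phantoms are relative.  Below 0.25 MeV/u the Bethe logarithm turns
over and stopping is continued ∝ √E (velocity-proportional), matched at
the join; this affects only the last few micrometres of track.  The
validated projectile energy window is 0.1–500 MeV; inputs outside it are
rejected.

Nuclear stopping uses the ZBL universal reduced stopping function summed
over elements.  At scan energies S_n/S_e < 10⁻³; it matters only for the
recoil tallies and the end of range.  Energy-loss straggling uses the Bohr
variance, dΩ²/dx = 4π e⁴ (Z₁*)² n_e, sampled as a Gaussian perturbation
per step — valid in the thick-step regime used here.

The CSDA range ∫dE/(S_e+S_n) from a 0.1 MeV cutoff, evaluated on a
4000-point log grid, reproduces the tabulated helium range in water at
88.5 MeV/u within ~2% and serves as the transport calibration cross-check.

## Transport scheme

Condensed-history, ensemble-vectorized.  Step length is the minimum of
(a) the distance for a 1% fractional energy loss, (b) one depth-bin width
(default 400 bins over the stack, ≈0.19 mm) so tallies stay smooth, and
(c) the distance to the next layer boundary so no step spans two
materials.  Energy loss per step uses a midpoint evaluation of S_e plus
the Bohr straggling draw.  Multiple Coulomb scattering applies the
Highland formula per step as independent Gaussian plane-angle kicks
(θ₀ = 13.6 MeV/(βcp) · Z₁ √(Δs/X₀) [1 + 0.038 ln(Δs Z₁²/(X₀β²))], with
the bracket floored at 0.25 for very short steps); radiation lengths come
from the Tsai approximation with mass-fraction mixing.  Applying the
logarithmic term stepwise underestimates the accumulated deflection
somewhat; the Highland model itself is a ~10% statement, which is why the
straggle comparisons carry generous tolerances.

Nuclear elastic collisions use an unscreened 1/T² Rutherford transfer
spectrum with the kinematic cap T_max = γ E, γ = 4m₁m₂/(m₁+m₂)².
Transfers are split at 1 keV: the expected energy of transfers in
[10 eV, 1 keV) is deposited continuously along the step with per-element
attribution ∝ n_i Z_i² /A_i (the Rutherford weight), while transfers above
1 keV are sampled as discrete Poisson events with explicit struck-element
selection and are recorded as PKA events.  The split is purely a
variance/performance measure — the expected deposition is identical — and
the 10 eV floor is the tally threshold, below which transfers are
neglected.  An ion terminates when its energy falls below 0.1 MeV; the
residual is deposited locally into the recoil tally (so the energy audit
closes identically) or when it exits the stack, carrying its energy out.
With a fixed seed results are bitwise reproducible; the ensemble energy
balance closes to machine precision, far inside the 0.5% audit band.

Not modeled: nuclear fragmentation and secondary-particle transport,
δ-ray transport, large-angle single scattering (the Gaussian Highland
core is what the lateral estimator measures), and dose in Gy.

## Displacement damage

The Kinchin–Pease closed form ν(T) (0 / 1 / T/2E_d / E_c/2E_d) and the
NRT form N_v = 0.8·E_v/(2E_d) above 2.5E_d are implemented directly; the
NRT band edge is continuous at E_v = 2.5E_d.  The damage energy is taken
equal to the PKA energy (no Lindhard partition).  A direct hard-sphere
cascade simulation — recursive uniform energy splitting with threshold
counting — serves as the independent oracle: its mean converges to
T/(2E_d), which is the exact solution of the cascade integral equation,
and tests require 5% agreement at T = 100 E_d with 10⁴ trials.

Defaults: E_d = 25 eV for every element (a standard displacement-threshold
scale; compound-specific measurements do not exist), E_c per element
solved from the crossing of Lindhard–Scharff electronic and ZBL nuclear
stopping of the recoiling atom in its host material, cached.  Both are
overridable.  Whole-track recoil tallies divide the summed recoil energy
by stack depth × ion count, giving eV/(Å·ion); per-element contributions
are percentages of the summed recoil energy.

## Straggle estimators

The longitudinal estimator is σ = [Σx_i²/N − R_p²]^½ and the lateral one
is σ_y = [Σ((|y_i|+|z_i|)/2)²/N]^½, both over stopped (implanted) ions
only, exactly as printed in the TRIM literature.  Note the lateral
estimator averages |y| and |z| *before* squaring: for independent Gaussian
transverse coordinates of width s its expectation is s·√((1+2/π)/2) ≈
0.905 s, not s.  A conventional RMS is reported alongside.  Transmitted
ions are excluded with a logged count.

## Comparison metrics

Cross-phantom "average difference" metrics are means over the common
energy grid of per-energy absolute differences; percent metrics use the
tissue scan as denominator.  The low-to-high straggle increase is
(max − min)/min × 100 over the scan.  The entrance LET is the mean over
the first 5% of depth bins and the peak position/amplitude come from a
parabolic fit through the maximum bin and its neighbours; both knobs are
exposed.  The benchmark report accompanies every scan-mean metric with a
95% bootstrap CI over the twelve per-energy values.

## Problem sizes

The default study is 12 energies × 2 phantoms × 10⁴ ions per energy
(≈1 minute on one core); the reference TRIM study used 10⁵ ions, and the
flag restores that.  The scan-mean metrics are means over 12 energies and
are stable at 10⁴ ions; per-energy recoil totals are the exception (see
below).

## Limitations

* The verbatim tissue composition table dominates the tissue-vs-biomaterial
  comparison.  Because the skin and masseter rows imply much higher
  electron densities than their printed mass densities suggest, the tissue
  fixture stops the beam ~13 mm shallower than the biomaterial fixture,
  and the computed scan-mean Bragg-peak difference (~28%) is far above the
  published 1.9%.  The same range deficit suppresses the tissue-side
  lateral straggle.  These are properties of the printed inputs, not of
  the transport: the water-slab cross-checks (range, straggle magnitude)
  land where tabulated helium data put them.
* Whole-track recoil totals are dominated by the heavy 1/T² tail of rare
  large transfers and fluctuate strongly between energies (as do the
  published per-energy totals); cross-phantom recoil differences at 10⁴
  ions carry ~several-percentage-point uncertainty.
* The Highland per-step treatment and the absence of large-angle single
  scattering bound lateral-straggle accuracy at the ~10–20% level.
* Phantoms are planar stacks; no voxelized or curved geometry.
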