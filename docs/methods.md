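# Methods

`screenlight` simulates the optical emission of granular Gd₂O₂S X-ray
phosphor screens. This note records the model, its assumptions, the
numerical choices, and the known limitations.

## Physical model

A screen is a laterally infinite slab of thickness *T* (100 or 200 μm in
the study configuration) containing phosphor grains at packing fraction
*f* = 0.5 in a binder of refractive index 1.35. A monoenergetic 25 keV
X-ray beam enters at normal incidence through the *z* = 0 face.

**Light birth.** Optical photons are created at the X-ray absorption
sites. The birth-depth density is the truncated exponential
*p(z) ∝ exp(−μ_eff z)* on [0, *T*], with
*μ_eff = (μ/ρ)·ρ·f* — mass attenuation 20.32 cm²/g and density
7.34 g/cm³ give μ_eff = 74.57 /cm at *f* = 0.5. The packing fraction
multiplies the attenuation because only the phosphor-filled fraction of
the volume attenuates; this choice is confirmed by the sublayer budget
(10 equal sublayers: 14%/18% first-sublayer and 7%/5% last-sublayer
fractions at 100/200 μm), which only *f* = 0.5 reproduces. One optical
birth per absorbed X-ray quantum; K-fluorescence escape, Compton
scattering and energy-dependent conversion are not modeled. All births
share one vertical axis, so exit positions directly sample the point
spread function.

**Grain-size distributions.** The six characterized powders are
represented by lognormal distributions truncated to the published
[min, max] diameter window, with (log-mean, log-sd) root-found so that
the analytic truncated mean and SD match the published values (all six
converge to machine precision). The truncated lognormal is the surrogate
of choice because the measured histograms are right-skewed with positive
support; it is *number-weighted* (each counted grain equally likely),
matching manual SEM counting. Only mean/SD/min/max are fit targets —
the published skewness and kurtosis are diagnostics, not constraints,
and the surrogate demonstrably under-represents the heaviest-tailed
sample (kurtosis 8.8 for the small-grain Tb powder). Empirical
distributions (per-grain diameter files or weighted supports) can be
used anywhere a fitted surrogate is used.

**Single-grain optics.** Each grain is a homogeneous sphere of complex
index 2.3 + 1×10⁻⁵ i embedded in the binder. The printed constant
"2.3 × 10⁻⁵ i" is read as real part 2.3 with absorption index 10⁻⁵,
the combination consistent with Gd₂O₂S optical modeling; both parts are
configuration-overridable. The embedded-sphere convention is used: size
parameter *x = π d n_med / λ* and relative index *m = n_p / n_med*
(545/623/513 nm vacuum wavelengths for Tb/Eu/Pr,Ce,F emission). Mie
efficiencies *Q_ext*, *Q_sca*, asymmetry factor *g* and albedo follow
from the standard coefficient series. The per-length extinction
coefficient of the bed is *m_ext = 3 f Q_ext / (2d)* (independent
scatterers; no dependent-scattering correction at *f* = 0.5 — a known
idealization of this model family).

**Transport.** Photons start isotropically (unpolarized luminescence)
and random-walk: at each step a fresh grain diameter is drawn from the
GSD (per-interaction resampling of a polydisperse bed), the free path is
exponential with *m_ext(d)*, and at the interaction the photon is
absorbed with probability 1 − albedo(d) or scattered through a
Henyey–Greenstein deflection with asymmetry *g(d)*. HG replaces the full
Mie phase function — the customary simplification in granular-screen
Monte Carlo; it preserves the first angular moment but underweights the
diffraction forward peak, which tends to slightly overestimate diffusive
spreading and hence absorption. A photon escapes on its first boundary
crossing (no Fresnel reflection/refraction at either face, no backing:
free-standing-screen budgets); the exit point is where the final
straight segment meets the face. A hard iteration cap (10⁶) tallies
runaway walks as absorbed and reports a counter (zero in all study
configurations tested).

**Imaging metrics.** Transmission-side exit offsets are histogrammed
(x-marginal, 1 μm bins, ±500 μm window, tails clipped into edge bins)
into a unit-area line spread function; the MTF is the modulus of its
discrete Fourier transform normalized at zero frequency, up to the
binning Nyquist (500 cycles/mm); limiting resolution is the linearly
interpolated first downward crossing of MTF = 0.10.

## Numerical choices

* **Mie series**: downward recurrence for the logarithmic derivative
  D_n(mx), upward Riccati–Bessel recurrences for the real argument,
  truncation at N = ⌈x + 4x^{1/3} + 2⌉. The downward start order is
  max(N, |mx|) + 48 rather than the customary +15: the short start
  leaves only ~5–6 correct digits near x ≈ 60–80, while +48 holds
  ~1e−13 agreement with an independent arbitrary-precision evaluation.
  Stability bound x ≤ 10⁴.
* **Mie lookup table**: uniform diameter grid at 0.005 μm steps over the
  GSD support; transport snaps sampled diameters to the nearest node
  (≪1% error in Q_ext). GSD sampling inside the compiled kernel uses a
  4096-point inverse-CDF table with linear interpolation.
* **HG sampling**: inverse CDF for the polar cosine, uniform azimuth,
  isotropic fallback for |g| < 10⁻⁶, cosine clipped to [−1, 1]; the
  local-frame rotation guards the polar singularity at |1 − u_z²| <
  10⁻⁹ and renormalizes the direction every step.
* **RNG**: one `SeedSequence` per run derives the birth-depth stream
  (PCG64) and a 31-bit kernel seed (MT19937), so a single integer
  reproduces a run bit-for-bit. The compiled kernel and a plain-Python
  reference loop consume draws in the same order from the same MT19937
  stream; the suite asserts bit-identical outcomes.
* **Degenerate inputs**: zero target SD fits to a single-atom spike;
  vanishing X-ray attenuation degenerates to uniform birth depths;
  single-node Mie tables serve monodisperse beds.

## Problem sizes

The study configuration is 10⁶ photons per screen. The acceptance script
uses 10⁶ photons for three of its four transport cells and 3×10⁵ for the
slowest (small-grain Tb at 200 μm, whose walks are the longest); at
these counts the budget counting noise is ≤0.1 percentage points, far
below the surrogate-GSD tolerance. The test suite's end-to-end grid runs
at 10⁵ photons per cell for the same reason.

## What the surrogate does and does not show

Passing budget checks with fitted surrogates shows that the Mie/HG/slab
chain reproduces the published emission budgets *given a distribution
with the published first two moments and range*. It does not validate
grain-shape effects (real grains are non-spherical aggregates measured
by Feret diameter), higher-moment GSD structure (the small-grain Tb
sample's kurtosis 8.8 is unreachable within a truncated lognormal), or
dependent-scattering corrections. Accordingly the absorbed fraction for
the small-grain Tb screens runs ~2.5–3 percentage points above the
published values, while smooth large-grain samples agree to ~0.1 points;
thickness-contrast *ratios* largely cancel this bias.

## The 200 μm budget-table labeling

The published 200 μm emission table repeats one sample label and omits
another. The unique row-to-sample assignment consistent with all six
published thin/thick transmission-increase percentages and the 200 μm
absorption pair (22.82/21.89) is recovered by exhaustive search over all
6! assignments and shipped alongside the printed version; comparisons use
the corrected mapping. The search is a test-time and import-time
constant, not a tunable.

## MTF derivation ambiguity

The source study states the MTF was "obtained from the FWHM of the PSF".
This package uses the standard chain instead — direct Fourier transform
of the simulated LSF — because it is the defined, assumption-free
transform of the simulated data. The two routes differ materially here:
the simulated point-source LSF has a sharp core (photons born within a
few mean free paths of the exit face) over a broad diffusive halo, and
direct Fourier inversion of that shape keeps more high-frequency
modulation than any single-width parameterization. Consequently the
package's 10%-MTF figures read systematically higher than the published
resolutions (e.g. ~29 vs 12.9 cycles/mm for the small-grain Tb screen at
100 μm, ~13 vs 9.6 for the large-grain Tb screen at 200 μm), and no
single-width reparameterization of the simulated LSF (Gaussian by FWHM,
Gaussian by SD) reproduces the published set either. The qualitative
grain-size ordering (small-grain screens resolve higher at equal
thickness) is reproduced; the absolute published figures are not, and
this is documented rather than calibrated away.

## Limitations

No polarization, no wavelength-resolved transport (one emission line per
activator), no time/decay structure, no optical coupling into a sensor
stack, no dependent scattering, no boundary Fresnel effects, no X-ray
spectrum or fluorescence transport. The slab is laterally infinite, so
side losses are absent.
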