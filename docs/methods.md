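# Methods

This note documents the models, algorithms and numerical choices behind
`sfdi2layer`, in the order the pipeline runs them.

## The measurement model

Spatial frequency domain imaging (SFDI) projects sinusoidal illumination at
spatial frequencies fx = 0 and 0.1 mm⁻¹ in three phase shifts per
wavelength (662, 735, 859 nm) and demodulates the reflected images into a
DC magnitude M(0) and an AC magnitude M(0.1):

    M(0)   = (I₁ + I₂ + I₃) / 3
    M(0.1) = (√2/3) · √[(I₁−I₂)² + (I₂−I₃)² + (I₃−I₁)²]

The symmetric three-term form is used; it is the identity that makes
demodulation exact for an ideal three-phase sinusoid at any phase offset
(verified by a property test over random amplitude/offset/phase).
Calibration against a reference phantom of known optical properties
converts magnitudes to diffuse reflectance, Rd(fx) = M(fx)/Mref(fx) ·
Rd,ref(fx), with Rd,ref computed from the homogeneous Monte Carlo forward
table. The phantom is characterized at 690/830 nm (μa 0.047/0.052 cm⁻¹,
μs′ 7.1/5.3 cm⁻¹); μa is taken as the mean of the two values at all device
wavelengths and μs′ follows the power law μs′(λ) = A(λ/λ₀)⁻ᵇ with
λ₀ = 735 nm.

## Two-layer tissue model

Skin is modeled as a non-perfused epidermis (thickness d_epi = 110 μm,
fixed per-wavelength μs,epi′ = 22.16 / 16.89 / 11.62 cm⁻¹, melanin the only
absorber) over an effectively semi-infinite subcutaneous layer (10 cm,
≈ 40 transport mean free paths) whose absorption derives from oxy- and
deoxyhemoglobin. All layers share g = 0.8 and n = 1.4; internal interfaces
are index matched, only the air/tissue surface refracts.

Melanin follows the extinction spectrum ε_mel(λ) = exp(−0.009 λ + 12.93).
Because reflectance constrains mainly the *product* of epidermal thickness
and absorption, the model optimizes the melanin index

    MI = d_epi · μa,epi(662 nm),

the approximate epidermal optical thickness at 662 nm, on a grid of 161
values over [0, 0.176] (spacing 0.0011; the top maps to
μa,epi(662) = 16 cm⁻¹).

## White Monte Carlo transport

The lookup tables come from a layered white Monte Carlo: a pencil beam
normally incident at the origin, Henyey–Greenstein scattering with
μs = μs′/(1−g), unpolarized Fresnel reflection at the top surface, and
per-layer pathlength recording so that any absorption pair
(μa,epi, μa,sub) can be applied afterwards through Beer–Lambert weights.
Reflectance is scored natively in the spatial frequency domain: the
pencil-beam response is radially symmetric, so each exit event contributes
J₀(2π fx ρ) at exit radius ρ (at fx = 0 this is the total diffuse
reflectance). Units are cm and cm⁻¹ internally; fx is mm⁻¹ at interfaces.

Numerical design of the transport kernel:

- **Surface scoring by weight splitting.** At every top-surface encounter
  the transmitted fraction w·(1−R(θ)) is recorded as an exit event and the
  photon continues inward with w·R(θ). Russian roulette (threshold 10⁻²,
  survival 0.1) retires low-weight survivors; the threshold was chosen by
  measuring estimator efficiency (variance × time), which was flat between
  10⁻² and 10⁻⁴ while transport cost doubled at the lower threshold.
- **Deep-zone similarity acceleration.** Below four transport mean free
  paths into the deepest layer the walk switches to the
  similarity-equivalent isotropic kernel (g = 0, μs = μs′). The radiance
  there is diffusive, so reflectance and pathlength statistics are
  preserved; a validation test compares the accelerated engine against
  exact anisotropic transport and an independently written direct absorbing
  Monte Carlo within combined Monte Carlo error.
- **Optional baseline absorption.** Transport can run at a per-layer
  baseline absorption (weight decays in flight, roulette retires deep
  excursions whose rescaled contribution is negligible), with scoring
  rescaled relative to the baseline: exp(−(μa−μa_base)·L). LUT builds use
  the grid minimum (0.01 cm⁻¹) in the subcutaneous layer, so rescaling
  never upweights. Pure white transport (baseline 0) remains the default
  and is what the validation oracles exercise.
- **RNG.** An inline xorshift64* generator seeded through splitmix64; one
  seed per simulation, recorded in the table metadata. Identical seed and
  inputs give a bit-identical record stream.
- Photons crossing the bottom of the 10 cm layer are terminated; at the
  lowest tabulated absorption their remaining contribution is below the
  per-simulation noise floor.

## Lookup tables

Per wavelength, 17 white-MC simulations (one per μs,sub′ ∈ 4…20 cm⁻¹, 17
values) are Beer-rescaled over the 21 × 75 grid of μa,epi ∈ 0…20 cm⁻¹ and
μa,sub ∈ 0.01…0.75 cm⁻¹ — the rescaling separates by layer, so the grid
fill is a dense matrix product and essentially free. A conventional
homogeneous table (75 × 17 over μa, μs′) is built the same way for
comparison and for the calibration reference.

Because the absorption axes of one μs,sub′ node share a single record set
(their noise is perfectly correlated and smooth), the only independent
noise direction is the μs,sub′ axis. The finished grids are therefore
regularized along that axis by a degree-5 polynomial least-squares fit
(noise reduction ≈ √(6/17) at negligible bias; Rd varies smoothly and
monotonically in μs′). This is on by default and can be disabled.

**Collapse and inversion.** For an assumed μa,epi(λ) the 3-D table is
collapsed by 1-D linear interpolation along the μa,epi axis, yielding a
conventional 2-D table. Inversion of a measured (Rd(0), Rd(0.1)) pair is
scattered-data interpolation over the table's reflectance point cloud:
piecewise linear on a Delaunay triangulation. Measurements outside the
table gamut are clamped to the nearest point of the gamut's convex hull
and flagged; flagged inversions are kept (so dynamic movies remain
processable) but marked invalid.

## Melanin-index optimization

For each candidate MI the implied μa,epi(λ) follows from the melanin
spectrum; the collapsed tables yield μa,sub(λ) and μs,sub′(λ); oxy/deoxy
hemoglobin concentrations come from unconstrained linear least squares
against compiled standard molar extinction coefficients (μa = ln10 · ε · C,
concentrations in mol/L), and the spectral-fit quality is
MSE = (e₆₆₂² + e₇₃₅² + e₈₅₉²)/3 in cm⁻². The selected MI minimizes the
MSE (simulation mode) or the adjusted MSE = MSE/(1−StO₂) (in-vivo mode;
+∞ wherever StO₂ falls outside [0, 1), since saturations above 100% or
below 0% imply negative chromophore concentrations and are treated as
undefined). Exact ties break to the smallest MI.

One selection rule deserves emphasis: **MI values whose inversion fell out
of the table gamut at any wavelength are excluded from the argmin.** When
the assumed melanin is far above truth, the inversion pins μa,sub at the
axis boundary; the clamped, boundary-locked spectrum can cross the
two-chromophore plane and manufacture a spurious near-zero residual at a
grossly wrong MI (the same degeneracy that motivates the adjusted MSE for
in-vivo data). Restricting the argmin to valid inversions removes these
artifacts; the full curves are always retained in the result.

With three wavelengths and two chromophores the residual has a single
degree of freedom, so the minimum-MSE estimate is sensitive to small
absorption errors near MI = 0 (where the grid is one-sided) — the expected
behavior is a slight, noise-level-dependent over-estimate of MI,
propagating to a small positive StO₂ bias and negative tHb bias.

## Software-phantom validation

Forward phantoms are generated by the same white-MC engine: the 8-level
melanin battery (MI = 0, 0.005, 0.01, 0.04, 0.07, 0.1, 0.13, 0.16) with
d_epi = 0.011 cm, μs,sub′ = 10.21/8.94/7.78 cm⁻¹ and μa,sub(λ) from
tHb = 20 μM, StO₂ = 75%; an epidermal-thickness battery (nine thicknesses,
0.003–0.019 cm, with μa,epi co-varied to hold MI); and epidermal-scattering
batteries (amplitude and power each scaled ±10/20/30%, the power anchored
at 735 nm). Phantoms sharing geometry and scattering reuse one record set;
only the Beer weights differ.

Problem sizes: 2×10⁵ photons per LUT simulation, 10⁶ per matched forward
simulation (three simulations cover all eight melanin levels), 5×10⁴ per
mismatch simulation. Each quantity is a single Monte Carlo realization;
the mean hemodynamic errors of the layered model in particular inherit a
common-mode component from the one LUT realization they share, worth
several percentage points on StO₂ at these sizes (seed-replicate studies
showed the 8-phantom mean StO₂ error moving over roughly −2 to +8%).
The mismatch batteries are noisier still: their worst-case errors at
these problem sizes substantially exceed what lower-noise tables show,
because the melanin-index selection destabilizes once the spectral-fit
residual is noise-dominated.

## Dynamic compression processing

The 3-minute protocol (60 s baseline / 60 s at 7.6 kPa / 60 s recovery,
one measurement per 2 s) is processed as: specular-pixel rejection on the
DC magnitude (> 2.5 SD from the per-frame image mean at any time or
wavelength); baseline Rd averaging over the closed window [10, 55] s;
per-pixel inversion and 8-SD screening of μa,sub against a 20 mm central
square (statistics pooled over the measurement); hemoglobin unmixing;
partition of the circular field of view into eight equal-area angular
sectors numbered clockwise from image-up (the sector layout is a package
convention; a 2×4 grid variant is not provided); per-ROI trace averaging;
baseline-stability screening (reject when |slope| > 0.045 pp/s or RMS
deviation from the linear fit > 0.4 pp over [10, 55] s); ROI artifact
rejection when artifacts cover strictly more than 60% of the sector; and a
linear StO₂ slope fit over [65, 113] s. Window endpoints are treated as
closed (boundary frames included). StO₂ is carried as a fraction and
converted to percentage points at the reporting boundary.

## Synthetic data generator

The generator emulates every pipeline input: raw phase-shifted frame
stacks whose demodulation and calibration reproduce a prescribed Rd
exactly in the noise-free limit (plus a matching reference-phantom stack
and a ground-truth sidecar); and compression movies with planted
hemodynamics — a U-shaped tHb blanching dip (half-sine over the
compression minute) and per-ROI linear StO₂ compression slopes with
jitter — mapped to reflectance through forward interpolation of the
collapsed tables (the inverse path goes through the independent
scattered-data inversion, so closed-loop recovery is not circular).
A smooth static field modulates tHb by 10% RMS so the image's spatial
variance dominates its temporal noise, as in real tissue; without it the
any-frame 2.5 SD specular screen would reject almost every pixel of a
spatially flat noisy movie.

Noise presets are declared, not fitted: shot noise SD 0.5% of signal, read
noise SD 0.1% of full scale, optional specular discs and linear drift.
Defaults for planted dynamics (tHb 20 μM, StO₂ 75%, dip 4 μM, slope
−0.011 pp/s) are representative healthy-breast magnitudes. What the
generator does not emulate: skin texture and curvature, contact-pressure
optics, motion, wavelength-dependent illumination profiles, and real
tissue's extra chromophores (water, lipid) — so passing closed-loop tests
demonstrates correctness of the inverse machinery under the model's own
assumptions, not robustness to everything an instrument sees.

## Known limitations

- Three wavelengths give the hemoglobin fit a single residual degree of
  freedom; the MI estimate is correspondingly noise-sensitive at low MI.
- The similarity acceleration and the table smoothing both trade a
  provably tiny bias for variance; both can be disabled (`exact=True`,
  `smooth_musp=False`) where bit-faithful transport matters.
- The adjusted MSE is a pragmatic reweighting, not a likelihood; it shares
  minima with the plain MSE only for two-chromophore data.
- Absolute μa,epi is not identifiable separately from epidermal thickness;
  only their product (MI) is estimated.
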