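# sfdi2layer

Two-layer spatial frequency domain imaging (SFDI) analysis for tissue with
variable skin pigmentation: layered white Monte Carlo lookup tables,
melanin-index optimization by hemoglobin spectral-fit error, and
compression-hemodynamics time-series processing.

## The problem

SFDI quantifies tissue absorption (μa) and reduced scattering (μs′) from
the reflectance of sinusoidally patterned illumination at two spatial
frequencies (0 and 0.1 mm⁻¹). Its shallow sensitivity makes it attractive
for monitoring hemodynamics of superficial breast tissue — e.g. tracking
total hemoglobin (tHb) and oxygen saturation (StO₂) responses to localized
compression — but the same shallowness makes it acutely sensitive to
melanin in the epidermis. A homogeneous inverse model absorbs the melanin
signal into the tissue estimate and, for darker skin, returns
physiologically impossible hemoglobin values.

This package implements a two-layer inverse model that decouples the
epidermis from the subcutaneous tissue. The epidermis (thickness
d_epi = 110 μm, fixed scattering) carries melanin with extinction spectrum
ε_mel(λ) = e^(−0.009λ + 12.93); the semi-infinite bulk carries oxy- and
deoxyhemoglobin. Because reflectance constrains only the product of
epidermal thickness and absorption, the method estimates the **melanin
index**

    MI = d_epi · μa,epi(662 nm)

by grid search (161 values on [0, 0.176]): for each candidate MI the
three-dimensional Monte Carlo lookup table (μa,epi × μa,sub × μs,sub′ →
Rd(0), Rd(0.1), one per wavelength at 662/735/859 nm) is collapsed at the
implied μa,epi(λ), the measured reflectance is inverted, and hemoglobin
concentrations are fit to μa,sub(λ) by least squares; the MI minimizing
the spectral-fit mean squared error (or the adjusted MSE, MSE/(1−StO₂),
for in-vivo data) wins. With melanin accounted for, μa,sub(λ) yields tHb,
StO₂ and power-law scattering (A, b), per pixel or per region.

Everything the pipeline consumes can be generated synthetically — raw
phase-shifted frame stacks, reference-phantom stacks, software-phantom
batteries, and dynamic compression movies with planted hemodynamics — so
the whole method is testable end to end without instrument data.

## Worked example

Build the tables, forward-simulate a pigmented software phantom
(MI = 0.1, tHb = 20 μM, StO₂ = 75%), and recover its hemodynamics with
both inverse models:

```python
from sfdi2layer.lut import build_lut_set
from sfdi2layer.spectral import optimize_mi, invert_homogeneous
from sfdi2layer.synthetic import ForwardEngine, PhantomSpec

lut_set = build_lut_set(n_photons=200_000, seed=11)   # ~10 min, one CPU
engine = ForwardEngine(n_photons=1_000_000, seed=99)
rd = engine.forward_rd(PhantomSpec(mi=0.1))

fit = optimize_mi(rd, lut_set)                        # layered model
h = fit.hemodynamics
print(f"layered:     MI={fit.mi:.4f}  tHb={h.thb:.1f} uM  StO2={h.sto2:.1%}")

homog, _, _ = invert_homogeneous(rd, lut_set.homogeneous)
print(f"homogeneous: tHb={homog.thb:.1f} uM  StO2={homog.sto2:.1%}")
```

Output from this exact script (seeds as shown):

```
layered:     MI=0.1023  tHb=19.9 uM  StO2=77.0%
homogeneous: tHb=46.2 uM  StO2=7.5%
```

The layered model recovers the planted 20 μM / 75% within a few percent,
selecting an MI two grid steps above truth (the expected slight
over-estimate); the homogeneous model misreads the melanin as deep
absorption and returns a tHb over twice the truth with an implausibly low
saturation — the failure mode the two-layer model exists to fix.

A `sfdi` command-line tool wraps the same library for shell use:
`sfdi lut build`, `sfdi demod`, `sfdi calibrate`, `sfdi mi-fit`,
`sfdi dynamics`, `sfdi synth phantom-suite`, `sfdi synth movie`,
`sfdi reproduce` (see `sfdi --help`).

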