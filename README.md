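# skinphasor

Phasor-based analysis of time-resolved (FLIM) autofluorescence images of
human epidermis: calibrated multi-harmonic phasor transforms,
four-component unmixing of **keratin**, **melanin**, **free NADH** and
**protein-bound NADH**, and photon-weighted quantification of component
fractions versus imaging depth.

It is written for researchers working with label-free multiphoton /
fluorescence-lifetime imaging of skin who want a tested, scriptable
implementation of the phasor unmixing workflow — including a synthetic-data
module that emulates the relevant skin scenarios (pigmented skin types III
and V, vitiligo, seborrheic-keratosis horn cysts, ex-vivo metabolic drift)
so every stage can be validated against known ground truth without any
clinical data.

## The method

Each pixel of a time-resolved stack holds photon counts `c_k` over the 32
time bins of one 12.5 ns laser period (80 MHz excitation, 0.39 ns bins).
The **phasor transform** at harmonic *n* maps the decay to a point

```
g_n = Σ_k c_k cos(nω t_k) / Σ_k c_k ,   s_n = Σ_k c_k sin(nω t_k) / Σ_k c_k ,   ω = 2π/T
```

Single-exponential decays of lifetime τ fall on the **universal
semicircle** `g² + s² = g` at

```
g = 1 / (1 + (nωτ)²) ,   s = nωτ / (1 + (nωτ)²)
```

and mixtures fall at the photon-weighted mean of their components'
phasors. Instrument effects (phase shift, modulation loss) are removed by
**calibration** against a reference dye of known lifetime (Coumarin 6,
2.5 ns, or dimethyl-POPOP, 1.45 ns, in ethanol), imaged in the same
session: the complex factor `m_n·e^{iφ_n}` mapping the measured reference
phasor onto its analytic position corrects every pixel per harmonic. The
**phase lifetime** `τ_φ = tan(atan2(s, g))/(nω)` projects any phasor onto
the universal circle along its phase angle.

With the four reference lifetimes (free NADH 0.4 ns, bound NADH 3.4 ns,
keratin 1.1 ns, melanin 0 ns) the coordinates at harmonics 1 and 2 give
four linear constraints per pixel; together with `Σ f_i = 1` they
determine the four **fractional intensities** `f_i` (the fraction of the
pixel's photons from each component). The normalization is enforced
exactly and the phasor equations solved by least squares, so low-SNR
pixels outside the component tetragon legitimately yield negative
fractions — a diagnostic retained in the statistics. Downstream
summaries are **photon-weighted**: percentiles {0.1, 0.5, 0.9} and a
kernel-density mode of the per-pixel fractions, with each pixel weighted
by its photon count, plus OLS fits of these statistics against depth and
the metabolic ratio `f_bound/(f_bound + f_free)`.

## Worked example

```python
import numpy as np
import skinphasor as sp

acq = sp.AcquisitionModel(phase_offset=0.3, mod_loss=0.8)  # distorted instrument
components = sp.ComponentSet.default()

# Session calibration on a simulated Coumarin 6 standard (2.5 ns)
ref = sp.make_monoexponential_stack(2.5, (32, 32), 225.0, acq, noise=False)
cal = sp.compute_calibration(ref, 2.5, reference_name="coumarin6")

# A type-V epidermis phantom: 5 depths, 225 photons/pixel, Poisson noise
phantom = sp.make_phantom(
    sp.PhantomSpec("depth_series_typeV", shape=(256, 256), seed=3),
    components, acq,
)
series = []
for stack in phantom.stacks:
    field = sp.apply_calibration(sp.phasor_transform(stack), cal)
    field = sp.bin_spatial(field, 4)                 # 256² -> 64², photons conserved
    field = sp.median_filter_phasor(field, 3)        # phasor domain only
    fractions = sp.unmix(field, components)
    dist = sp.violin_summary(fractions, "melanin")
    series.append((stack.z, dist))
    print(f"z={stack.z:4.0f} um  melanin p50={dist.percentile(0.5):+.3f}")
trend = sp.depth_trend(series, "p50")
print(f"melanin median slope: {trend.slope:+.5f} per um")
```

Output:

```
z=   0 um  melanin p50=+0.004
z=  15 um  melanin p50=+0.099
z=  30 um  melanin p50=+0.205
z=  45 um  melanin p50=+0.316
z=  60 um  melanin p50=+0.418
melanin median slope: +0.00696 per um
```

The melanin median climbs from ≈0 at the stratum corneum to ≈0.42 at the
melanin-rich basal layer, and the fitted slope is positive — the depth
trend expected for highly pigmented skin.

The same workflow is available from the shell:

```bash
skinphasor simulate --preset depth_series_typeV --shape 256 256 \
    --depths 0 15 30 45 60 --photons 225 --seed 7 --out sim/
skinphasor run --seed 7 --out run_out/     # full pipeline with a manifest
```

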