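# Methods

This note documents the models, parameter choices and limitations behind
`skinphasor`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Acquisition and decay model

The emulated instrument excites at 80 MHz and resolves each 12.5 ns
period into 32 time bins of 0.390625 ns (`AcquisitionModel` defaults).
Fluorescence decays are periodic single exponentials with wrap-around:
the continuous density on one period is
`e^{-t/τ} / (τ (1 - e^{-T/τ}))`, whose Fourier coefficient at harmonic
*n* is `1 / (1 - i n ω τ)` — the universal-circle phasor.

Two on-grid representations of this decay are provided
(`decay_model(..., sampling=...)`):

- **integrated** — exact integrals of the density over each bin,
  evaluated via `expm1` so arbitrarily long lifetimes degrade to the
  uniform distribution rather than overflowing. This is ideal
  photon-counting histogramming, and the test suite verifies it against
  a brute-force summation of the wrapped exponential series to 1e-9.
- **bandlimited** (used by the stack generators) — the alias-free
  projection onto the bin grid: the real bin vector whose discrete
  Fourier coefficients equal the continuous decay's harmonic
  coefficients for all harmonics below Nyquist. This models a detection
  chain in which a finite-bandwidth analog photodetector signal is
  digitized rather than individual photons being histogrammed. On this
  representation the discrete phasor transform is *exactly* consistent
  with the continuous model, so reference-dye calibration closes the
  loop to machine precision: cross-standard lifetime round trips,
  universal-circle membership and mixture linearity all hold at 1e-6 or
  better on noiseless data.

The choice matters because with coarse 32-bin integration the residual
discretization bias after single-reference calibration is of order
1e-3 on the phasor and ~0.2 ns on a delta-like (melanin) lifetime —
measurable with this package by swapping `sampling`. Band-limited
generation is therefore the default for all simulated stacks; the
integrated model remains available as the photon-counting oracle.

Band limiting can produce small negative ringing in expectation values.
The default instrument-response width (below) keeps this under ~0.1% of
a pixel's signal; expectations are clamped at zero before Poisson
sampling, and noisy stacks always contain non-negative integer counts.

## Instrument response and distortion

The instrument is modeled by three parameters that reference-dye
calibration is designed to remove:

- `phase_offset` (rad) — a circular time shift; harmonic *n* of the
  phasor is rotated by `e^{-i n φ}`.
- `mod_loss` ∈ (0, 1] — modulation attenuation at the first harmonic;
  higher harmonics attenuate as `mod_loss^{n²}`, the wrapped-Gaussian
  family, so the whole distortion is a plausible smooth impulse
  response. Calibration is per-harmonic, so any consistent attenuation
  law would be corrected identically.
- `irf_sigma` (ns) — a wrapped-Gaussian instrument response, harmonic
  factor `exp(-(nωσ)²/2)`.

Total expected photons (the DC term) are conserved exactly by
construction. The default `irf_sigma = 0.35 ns` is a package choice, of
the order of the bin width and of real photodetector rise times; it is
what makes the zero-lifetime melanin decay representable on the 32-bin
grid (a true delta has full power at every harmonic and cannot be
band-limited without ringing).

## Calibration conventions

Calibration pools all photons of the reference stack into one decay and
maps its measured phasor onto the analytic single-exponential phasor of
the nominal lifetime, per harmonic; both harmonics used for unmixing are
calibrated from the same reference, mirroring a single per-session
standard. Phase corrections live in (-π, π]; `atan2` fixes the branch.
Bin timestamps are bin centers `t_k = (k + ½)Δ`, which makes the
delta-in-bin-0 phasor example exact. Zero-photon pixels carry NaN
phasor coordinates and an explicit `defined` mask that propagates
through binning, filtering, unmixing and statistics — never a silent
zero. Phase lifetimes are only reported where `g > 0`; beyond the
quarter turn the phase projection has no physical intersection with the
universal circle and pixels are flagged invalid instead of extrapolated.

## Processing defaults

- Spatial binning: non-overlapping integer blocks only (default factor
  4, e.g. 1024² → 256²). Stacks are binned by summing counts (photons
  conserved exactly); phasor fields are binned by photon-weighted means
  of (g, s), which commutes with the transform. Non-divisible trailing
  rows/columns are dropped with a logged warning.
- Median filter: 3×3 on each phasor channel (g₁, s₁, g₂, s₂), one pass
  by default (configurable), edge handling by edge-repeating
  reflection, NaN (undefined) pixels excluded from windows. The
  intensity image is returned untouched.
- Photon threshold: default 30 photons per (possibly binned) pixel,
  keeping unmixing conditioned near the instrument's typical 200–250
  photons/pixel after 4×4 binning while still exercising the low-SNR
  path.
- Keratin-feature exclusion: connected components (8-connectivity) of
  keratin fraction > 0.5 with area ≥ 200 px at full resolution (scaled
  with binning where used). Both numbers are configuration keys; the
  workflow is used before ex-vivo NADH statistics so hairs and folds do
  not dominate.

## Unmixing solver

The design matrix stacks the component coordinates [g₁, s₁, g₂, s₂] and
a row of ones (5 × k, full column rank for distinct lifetimes; duplicate
lifetimes raise an error naming the colliding components). The solver
enforces `Σf = 1` exactly and minimizes the residual of the four phasor
equations within that affine subspace (KKT system, precomputed to a
single per-pixel linear map). On consistent noiseless data this agrees
with ordinary least squares on all five equations; on noisy data the
exact-normalization variant is what reproduces the characteristic
negative fractional intensities of low-SNR pixels outside the component
tetragon — a non-negativity-constrained solver would hide them. No
spectral/quantum-yield weighting is applied: fractions are photon
fractions in the detection channel as measured.

The NADH metabolic ratio is `f_bound / (f_bound + f_free)`. Its
numerical validity threshold is ε = 1e-6 by default; distribution
statistics of the ratio use a physically motivated support threshold of
0.05 (at least 5% of a pixel's photons from NADH), since the ratio of
two near-zero noisy fractions is unbounded and a handful of such pixels
can otherwise stretch the KDE grid arbitrarily.

## Photon-weighted statistics

Percentiles use the inverted-CDF rule — the smallest value whose
cumulative normalized weight reaches q — so weight concentrated on one
value pins the percentile to it; an interpolated variant (Hazen
positions, equal to the standard interpolated percentile under uniform
weights) is provided for users who prefer smooth quantiles. The mode is
the argmax of a photon-weighted Gaussian KDE on a 512-point grid
spanning the sample range, with Silverman's rule bandwidth computed from
the weighted spread and the effective sample size `(Σw)²/Σw²`. Depth
trends are unweighted OLS fits through the per-depth statistics,
matching how regression lines are drawn through violin-plot percentiles
and modes. Violin rendering itself is cosmetic; only the numeric
summaries are contract-bearing, and negative fractions are retained in
distributions by default (an off-by-default clip option exists).

## Synthetic phantoms: what they emulate and what they do not

Phantom composition fields are smooth parametric ramps plus geometric
primitives; the *contracts* below are guaranteed, the exact textures are
free parameters chosen to keep fields resolvable at the instrument's
photon budget (smooth fields with ~20–40 px correlation length, fold
ribbons covering a few percent of the frame):

- `depth_series_typeV` / `typeIII` / `vitiligo`: melanin fraction
  `m = m_max·u·B(x,y)` rises linearly with normalized depth u, with
  `m_max` = 0.45 / 0.22 / 0.01 by skin type (vitiligo ≤ 0.02
  everywhere); keratin takes a declining share of the non-melanin
  signal (surface ramp 0.55 → 0.20) plus constant-share curvilinear
  folds at share 0.92, so its mean strictly decreases with depth and
  the deepest planes are bimodal (fold vs. keratinocyte populations);
  the bound-NADH share of NADH declines 0.65 → 0.35 across depth in
  pigmented skin and is depth-constant (0.60) in vitiligo.
- `sk_horn_cysts`: keratinized disks (share 0.95, melanin 0.04) in a
  melanin-rich surround (m = 0.5·B) — the horn-cyst geometry used to
  validate keratin-feature segmentation/masking.
- `exvivo_pair`: two planes with identical composition except the
  bound-NADH share drops 0.60 → 0.40, emulating the metabolic shift of
  excised tissue after six hours at room temperature.
- `stratum_corneum`: keratin-dominated single plane with fold features.

Depth values are nominal labels (the per-layer depths of real epidermis
vary by subject and are not modeled); photon budget defaults to 225
photons/pixel (midpoint of the instrument's typical 200–250), uniform
across the frame; noise is independent Poisson per (pixel, bin).

Not emulated: depth-dependent optical scattering and PSF blur, FAD and
dermal fluorophores (collagen/elastin), a second spectral channel,
detector afterpulsing/dark counts, absolute radiometry, keratin's
multi-exponential decay (a single 1.1 ns exponential is assumed
throughout, as in the component table). Passing tests therefore
demonstrate the correctness and statistical behaviour of the analysis
chain under the stated model — not performance on clinical images.

## Problem sizes

The validation suite uses 256² phantoms for recovery error and
bimodality, 128² phantoms × 5 depths × 10 seeds for depth-trend signs
and the ex-vivo comparison, and 1024² stacks for the downsampling
checks; these sizes give stable statistics for the contracts tested
while keeping the full suite fast on a single CPU.

## Known limitations

- The band-limited generator is the package's model of analog
  time-resolved detection; data from a true photon-counting (TCSPC)
  instrument with coarse bins would carry the residual discretization
  bias quantified above, and a per-setup reference measurement of that
  bias would be needed for sub-0.05 ns accuracy on such systems.
- Harmonics above 2, modulation lifetimes (τ_m), multi-exponential
  fitting and global analysis are out of scope.
- Reading vendor FLIM formats (.sdt, .ptu) is not implemented; the
  TIFF + JSON-sidecar convention is the package's interchange format
  and documented adapter point.
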