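# Methods

This note documents the models implemented in `speckleflow`, their
assumptions, the defaults that matter, numerical choices, and what the
synthetic data generator does and does not emulate.

## Physical model

Scatterer motion in perfused tissue is modeled as effective Brownian
diffusion: the mean-squared displacement over a lag τ is
`⟨Δr²(τ)⟩ = 6·BFi·τ`, where the blood flow index BFi (cm²/s) absorbs
the shear-induced-diffusion physics of red cells in vessels.  The field
autocorrelation of multiply scattered coherent light then decays with a
rate set by the per-path accumulated momentum transfer, and the
intensity autocorrelation follows from the Siegert relation
`g2(τ) = 1 + β·|g1(τ)|²`, with the coherence parameter β set by the
number of detected modes (DCS) or the speckle-to-pixel sampling
(SCOS).

Two forward routes produce `g1(τ)`:

* **Analytic**: the semi-infinite reflectance solution of the
  correlation diffusion equation,

      g1(τ) = [r_b e^{-K(τ) r_1} − r_1 e^{-K(τ) r_b}] /
              [r_b e^{-K(0) r_1} − r_1 e^{-K(0) r_b}],

  with `K(τ) = sqrt(3 μ_a μ_s′ + 6 k² μ_s′² BFi τ)`,
  `r_1 = sqrt(ρ² + l*²)`, `r_b = sqrt(ρ² + (l* + 2 z_b)²)`,
  `z_b = (2/(3 μ_s′))(1+R_eff)/(1−R_eff)`, and
  `R_eff = −1.440/n² + 0.71/n + 0.668 + 0.0636 n`.
  The wavenumber is taken in-medium, `k = 2πn/λ`, consistently in the
  analytic and history-based estimators (the two conventions floating
  around the literature differ by the factor n²; we use per-tissue n
  everywhere).

* **History-based**: from a table of detected photons with per-tissue
  partial pathlengths `L_i` (cm) and dimensionless momentum transfer
  `Y_i`,

      G1(τ) ∝ Σ_n exp(−(1/3) Σ_i k_i² Y_{n,i} · 6 BFi_i τ) ·
                    exp(−Σ_i μ_{a,i} L_{n,i}),

  normalized to 1 at τ = 0.  Absorption never terminates photons in
  transport; it enters only through these weights, so one transport run
  serves any flow state and any absorption.

SCOS measures the exposure-integrated contrast
`Kf² = (2β/T_exp) ∫₀^{T_exp} g1²(τ)(1 − τ/T_exp) dτ`; the measured
squared contrast adds shot, read and dark terms,
`K² = Kf² + Ks² + Kr² + Kd²` with `Ks² = 1/⟨S⟩`, `Kr² = σ_r²/⟨S⟩²`,
`Kd² = S_dark/⟨S⟩²` in photoelectron units.  Dark contrast defaults to
zero (sub-10-ms exposures); the term exists for the long-exposure
regime.

## Synthetic transport (what it emulates, what it does not)

`run_layered_mc` is a planar layered-slab Monte Carlo standing in for
mesh-based transport on MRI-derived head anatomy.  It uses the
similarity relation — isotropic scattering at the reduced coefficient
μ_s′ — so the per-event expected momentum transfer `E[1 − cos θ]` is
exactly 1 and the per-layer `Y` is recorded as the scattering-event
count (a zero-variance substitution of the per-event expectation).
Detectors are annuli centered on each source-detector separation
(exploiting the slab's cylindrical symmetry; half-width 0.5 mm by
default) with an NA acceptance measured against the surface normal in
the scalp.  Slab presets place the brain 10/15/20 mm under the surface
(scalp 5 mm / skull 3, 8, 13 mm / CSF 2 mm / brain semi-infinite); CSF
keeps its tabulated near-zero scattering and is traversed by optical
depth, so its long steps are exact rather than capped.

What the slab does **not** emulate: head curvature and the
folded cortical surface (absolute sensitivities and CNR values shift;
trends with separation, depth and hardware are preserved), anatomical
partial-volume variation between subjects, and any lateral
heterogeneity.  Results on slabs are therefore read as *trend-level*,
and the test suite asserts orderings and monotonicities, not absolute
CNR values.  Default desk-scale problem size is 10⁶–10⁷ photons (the
test suite uses 10⁶, a few tens of seconds per geometry), versus ~10⁹
for publication-grade head-model runs.

## Instrument models

* **Skin-safe power**: ANSI Z136.1 CW skin MPE,
  `0.2·10^{0.002(λ−700)} W/cm²` (700–1050 nm), `1.0 W/cm²`
  (1050–1400 nm), times the illumination spot area.  The presets pin the
  rounded values used in the hardware tables (38 mW at 850 nm for a
  3.5 mm spot; 100 mW at 1064 nm where the formula gives 96.2 mW) so
  preset scenarios reproduce the published operating points; the
  calculator itself returns the formula value.
* **Fibers**: guided modes counted by LP-cutoff (zeros of J_{l−1}),
  orientation ×2 for l ≥ 1, polarization ×2 — SMF-28 carries 12 modes at
  850 nm and 6 at 1064 nm; bundles use V²/2 per fiber (the convention
  matching the published bundle estimate; V² is available as an option).
* **Detectors**: QE, dark counts, read noise, dead time.  Dead time caps
  the sustained rate at 1/hold-off (4.5×10⁷ cps for a 22 ns Si-SPAD,
  3.0×10⁷ cps for a 33 ns SNSPD); the pipeline caps flux at this limit
  and flags the cap rather than distorting the correlation function.
* **Illumination strategies**: single CW ANSI spot; multiple CW spots
  (floor(P_max/P_ANSI), each at the limit); pulsed with fixed frame rate
  and boosted power (`P_in·f_s·T_exp ≤ P_ANSI`); pulsed at full laser
  power with a slowed frame rate (`P_max·f_s·T_exp ≤ P_ANSI`).  For DCS
  the pulsed mode runs at full power with duty cycle `P_ANSI/P_max`.
  Every resolved plan asserts average power per spot at or below the
  skin limit.
* **Flux calibration**: detected photons per mode for one CW ANSI source
  at a 25 mm separation — 10 kcps at 850 nm, 67.1 kcps at 1064 nm —
  scaled across separations by the simulated relative diffuse
  reflectance (log-interpolated) and linearly in instantaneous power.

## Noise models

**DCS.**  The standard deviation of a photon-counting correlogram at lag
τ uses the single-exponential correlation noise model with bin width T,
averaging time t, mean counts per bin ⟨n⟩ and effective decay rate Γ
(fit from the noiseless curve as `g2 = 1 + β e^{−Γτ}`).  Because the
curves live on a multi-tau grid whose accumulator width doubles each
octave, the pipeline evaluates σ(τ) with the *local* bin width; this is
what a hardware or software multi-tau correlator delivers, and without
it the late-decay lags carry unphysically large noise.  The model is
validated end-to-end against brute-force simulation: doubly stochastic
photon timestamps (speckle-intensity-driven Poisson process with
`round(1/β)` independent channels, dark counts, non-paralyzable dead
time) fed through the multi-tau correlator, 500 streams per regime,
agreeing within 25% over the primary decay in both the shot-limited and
high-count regimes.  Dark counts enter the analytic path as an added
uncorrelated rate that dilutes the intercept:
`β_eff = β (r_s/(r_s+r_d))²`.

**SCOS.**  Contrast noise comes from a dynamic speckle simulator:
circular-Gaussian complex fields with a Gaussian spatial correlation
`μ(d) = exp(−d²/(2σ_x²))`, where the speckle size is the 1/e² diameter
of the intensity correlation, `s = 2√2·σ_x`.  This convention
reproduces the published calibration of the independent-observation
count (NIO ≈ 0.95·n_pixels at s/p = 0.4; a hard-aperture pupil with its
Airy sidelobes gives ≈ 0.75 and is not used).  Temporal evolution mixes
substep fields through the Cholesky factor of the target `g1`
covariance, so the simulated field correlation follows the requested
curve exactly (not an AR(1) approximation); sub-pixel speckles are
synthesized on a finer grid and binned.  Exposures integrate the
substeps, receive Poisson shot noise and Gaussian read noise, and yield
per-frame K², the empirical β(s/p), σ(K²) across frames and
`NIO = 2⟨Kf²⟩²/var(Kf²)`.  Default problem size: 56 independent
exposures, a 24×24 camera-pixel window (16×16 for s/p < 1), ≤ 32
substeps per exposure; σ(K²) is rescaled to the full sensor by
`sqrt(n_sim/n_used)` and to one 10 Hz sample by `1/sqrt(frames per
sample)`.  Sensor coverage: the bundle image spans
`n_modes·(s/p)²` pixels; a larger image than the sensor spills light
(overfilling), a smaller one leaves pixels dark — this is what makes
small speckle-to-pixel ratios advantageous down to `sqrt(n_px/n_modes)`.

## Inversion

Both inverse problems are strictly monotone single-parameter fits, run
as bounded local minimization on log₁₀(BFi) over [10⁻¹², 10⁻⁴] cm²/s
from a deterministic initialization at 10⁻⁸ cm²/s (Powell, xtol 10⁻⁸).
A local method is deliberate: under heavy noise the least-squares
landscape grows a spurious basin where a fully decayed model fits pure
noise, and a global search would jump to it.  Fits landing within one
decade of either bound are counted as failed and excluded; an ensemble
with more than 5% failures is flagged invalid.  The DCS fit range is
controlled by the fraction of the g2 *amplitude* decay completed
(cutoff computed once on the noiseless curve, not per realization); the
alternative τ-range reading is noted as a possible variant.  Fitting is
unweighted least squares, matching the uniform-per-delay Gaussian noise
injection.  β and the optical properties (850 nm: μ_a 0.15, μ_s′
8.5 cm⁻¹; 1064 nm: μ_a 0.15, μ_s′ 6.2 cm⁻¹) are assumed known.

## Performance metrics

Baseline and +20%-cerebral-flow states are compared through:
sensitivity = `(ΔBFi/BFi_base)/(ΔCBF/CBF_base)` (computed from fits of
the noiseless curves — the ensemble mean of a heavy-tailed estimator is
itself noise in photon-starved regimes, while the noiseless fit is the
ensemble's central value); CoV = std/mean of the fitted BFi over 100
noisy realizations at a 10 Hz sample rate (DCS averaging time
`duty·0.1 s`; SCOS averages `floor(f_s/10)` frames per sample); CNR =
sensitivity/CoV.  Acceptability thresholds follow common practice:
sensitivity ≥ 0.10, CoV ≤ 0.1 (physiological variability), CNR ≥ 1.

## Numerical choices

* τ grids are quasi-logarithmic multi-tau grids (1 μs first bin, 8 lags
  per octave) out to 0.1 s; history-based SCOS evaluation uses a
  300-point geometric grid.
* The contrast integral uses composite 8-point Gauss-Legendre panels
  log-spaced over eight decades of normalized lag — exact to ~10⁻¹⁴ for
  smooth decays regardless of how far the exposure exceeds the
  decorrelation time.
* Correlator normalization is symmetric (left/right mean rates per
  lag), which removes the triangular bias of the naive estimator.
* All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` spawning; ensembles are reproducible and
  extensible per realization index.

## Known limitations

* Desk-scale photon counts make long-separation 850 nm DCS ensembles
  photon-starved; there the fitted-BFi distribution is heavy-tailed and
  the std/mean CoV is tail-dominated (the delta-method CoV can be ~6×
  smaller).  Quantities in that regime are reported as computed but are
  not stable comparison anchors.
* Saturation is a hard cap, not a progressive correlation distortion;
  afterpulsing, crosstalk, camera fixed-pattern noise and nonuniform
  bundle projection are not modeled.
* Interferometric/heterodyne variants and multi-exposure SCOS
  reconstruction are out of scope.
* β mis-specification during fitting is not studied (β is assumed
  known, tracked or calibrated).
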