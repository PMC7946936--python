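# Methods

This package simulates and reconstructs speckle metamaterial-assisted
illumination nanoscopy: widefield fluorescence imaging in which a rough
Ag/SiO2 hyperbolic-metamaterial (HMM) substrate converts a low-NA coherent
beam into near-field speckle with in-plane wavevectors far beyond the
free-space limit, and a blind-SIM algorithm recovers sub-diffraction object
detail from a stack of frames taken under different speckle realisations.
This note records the models, their assumptions, the default parameters, and
the numerical choices.

## Multilayer optics (`specklemain.optics`)

Conventions: time dependence e^{-iωt}, so passive permittivities have
Im(ε) ≥ 0 and layer-normal wavevectors use the principal square root with
Im(kz) ≥ 0. Lengths in nm, spatial frequencies in cycles/nm, wavevectors in
rad/nm.

* **Materials.** Silver uses the bundled Johnson & Christy (1972) n,k
  tabulation, interpolated linearly in wavelength (`data/
  ag_johnson_christy_1972.csv`); the table is a configurable choice with
  this fixed default. SiO2 is n = 1.46 (constant), coverslip glass n = 1.52,
  both non-dispersive over the visible range used here.
* **Transfer matrix.** Standard 2×2 forward/backward amplitude formalism
  for isotropic stratified media; TE tracks E, TM tracks H, both give
  interface Fresnel ratios r = (q_i − q_j)/(q_i + q_j) with the
  polarization admittance q = kz (TE) or kz/ε (TM). Power transmittance
  applies the real flux ratio of substrate to superstrate.
  `tmm_coefficients` requires a propagating superstrate channel (power
  normalisation); `tmm_amplitude` is the analytic continuation to evanescent
  input channels used by the speckle surrogate — its |t(k)| peaks beyond k0
  mark the finite stack's guided and surface-plasmon resonances.
* **Dispersion.** `emt_permittivities` gives the effective-medium tensor of
  a metal/dielectric multilayer; `bloch_kz` solves the two-layer Bloch
  relation cos(KΛ) = cos(k₁d₁)cos(k₂d₂) − ½(η+1/η)sin(k₁d₁)sin(k₂d₂),
  branch Im(K) ≥ 0, Re(K)Λ ∈ [0, π]. `max_k_support` scans k_parallel in
  0.05 k0 steps up to the Brillouin edge π/Λ and returns the largest value
  with Im(K)Λ below a threshold (default 1, i.e. at most one e-fold of decay
  per period); for the default 10 nm Ag / 10 nm SiO2 cell at 488 nm this
  gives 9.05 k0. The equal-fill choice for the 20 nm-period cell is a
  documented default; the fill fraction is exposed.
* **Resolution budget.** f = f_det + f_illum with f_det = 2NA/λ_em and
  f_illum = 2 k_max/λ_exc (intensity-pattern cutoff from interfering field
  components of in-plane wavevector up to k_max·k0).

## Rough surface (`specklemain.roughsurf`)

Zero-mean Gaussian random field with Gaussian autocorrelation
exp(−r²/C_l²), synthesised spectrally (white noise × sqrt of the implied
power spectrum, which is ∝ exp(−k²C_l²/4)). Boundary is periodic
(wrap-around correlation). The RMS is enforced exactly by rescaling; C_l is
met in distribution (measured 34.5 ± 0.4 nm over 20 seeds at the 512²,
3 µm AFM geometry for a 35 nm target). `surface_statistics` measures C_l as
the 1/e radius of the radially averaged normalised autocorrelation, with
linear interpolation between one-pixel rings. Defaults follow the measured
topography: RMS 1.1 nm, C_l 35 nm.

## Speckle synthesis (`specklemain.speckle`)

The full-wave scattering problem is replaced by a declared first-Born,
single-scattering angular-spectrum surrogate:

1. The incident field is a finite set of plane waves (NA 0.2 disk, default
   100 modes with uniform random phases — the scrambled multimode fiber; or
   a single plane wave at a chosen incidence angle).
2. All interface/volume disorder is lumped into one effective scattering
   screen with the measured height statistics; each incident component
   a_q e^{iq·r} contributes a specular part plus the scattered spectrum
   i·β·a_q·h̃(k−q).
3. Both parts are filtered by the stack transfer t(k): the TM transmission
   amplitude of the finite three-period stack at every k, including
   evanescent input channels. Beyond the Bloch band this amplitude decays
   with the per-period attenuation of the infinite multilayer, and inside
   it the finite stack's plasmonic/guided resonances (|t| maxima near
   1.9 k0 and 9.2 k0 at 488 nm) shape the speckle. A smoother idealisation
   ("bloch" model: bare exp(iKL) envelope beyond k0) is selectable; it
   lacks the resonance structure and produces nearly angle-invariant
   speckle, so it is not the default.
4. Fields at height z (default 10 nm) follow the scalar angular spectrum,
   evanescent components decaying as exp(−|kz|z).

Scalar approximation throughout (x-polarised input, TM transfer). The
coupling constant β = sqrt(0.2)/1.1 ≈ 0.41 nm⁻¹ puts ~20% of the specular
power into the scattered wave at the measured roughness; it is exposed in
the config. Specular components are summed analytically at their exact
off-grid wavevectors so that incidence-angle scans finer than one FFT bin
are meaningful; only the scattered term uses the FFT.

The default real-space grid for speckle characterisation is 1 µm² at 2 nm
sampling (500²), which resolves the full Bloch band at 488 nm.

**What the surrogate does and does not capture.** High-k conversion by
roughness, Bloch-band filtering, resonance-enhanced scattering and
evanescent decay are all first-order effects and are represented. Multiple
scattering, depolarisation, and the exact per-interface disorder of the
sputtered stack are not. Consequently the absolute speckle decorrelation
rate with incidence angle is model-dependent: the surrogate gives a
half-correlation angle of ~12° at 488 nm (measured experiment-level value:
~15°), with the monotone decay itself robust.

## Forward imaging model (`specklemain.imaging`, `specklemain.scenes`)

Frames are M = bin(PSF ⊛ (ρ·I)) + noise on a fine grid (default 5 nm):
uniform-disk beads (46 nm diameter, unit integral each), paraxial Airy
detection PSF ((2J₁(v)/v)², truncated by default at 1.5 Airy-zero radii
and renormalised), sum-binning to the camera pitch (65 nm), Poisson shot
noise on signal + background, additive Gaussian read noise. Defaults:
5000 expected photons per bead per frame at unit illumination (bright
commercial beads at a ~500 ms exposure), background 5 counts/pixel, read
noise 2 counts. Emission 520 nm for the green channel, 605 nm for the
quantum-dot scenario. The model is 2-D; the bead's axial extent and its
stand-off above the surface are collapsed into the single speckle height z.

Stacks are background-subtracted and intensity-scaled before
reconstruction. Two modes exist: per-frame mean division (appropriate when
the excitation power fluctuates between frames, which is what
intensity-normalised experimental stacks compensate) and a single global
scaling. The pipeline default is the global scaling, because the simulated
source delivers constant power per frame: for a sparse scene the frame
mean is then dominated by how the speckle happens to hit the emitters, and
dividing by it forces the emitters' summed illumination to be constant
across frames. That spurious coupling measurably biases the joint estimate
— on the 60 nm / NA 0.8 pair it pushed the reconstructed lobes ~30%
too far apart, and switching to global scaling removed the bias (59.6 nm
measured at the reference seed). Per-frame mode remains available
(`normalization: frame`) for data with genuine power fluctuation.

## Blind-SIM reconstruction (`specklemain.blindsim`)

Cost: Σ_m ‖M_m − D(H ⊛ (ρ·I_m))‖² + λ Σ_m ‖∇I_m‖², with ρ on a u-fold
oversampled grid (u = 3 → ~22 nm pixels, u = 4 → ~16 nm), H the detection
PSF on that grid (truncated at 1.2 Airy-zero radii in the pipeline — the
tails are featureless and the padded FFT stays small), D the u×u binning
operator, and λ = 10⁻³ a mild pattern-smoothing weight that stabilises the
bilinear problem (an artifact of this implementation, not physics). The
closure constraint Σ_m I_m = M·I₀ is eliminated exactly through the last
pattern; nonnegativity of ρ and of every pattern (including the eliminated
one) is kept by projection — free patterns are clipped at zero and
pixelwise rescaled where their sum would exceed M·I₀.

Optimisation is alternating projected gradient with backtracking line
search per block, wrapped in a monotone Nesterov scheme: each block first
tries an extrapolated step (momentum weight (k−1)/(k+2)) and accepts it
only on strict cost decrease, falling back to the plain backtracking step
otherwise. The recorded cost history is therefore non-increasing by
construction. The alternating structure is retained deliberately: a joint
extrapolated step on (ρ, I) reaches similar cost values but systematically
less-resolved objects on bead scenes — the bilinear landscape has many
near-equal minima and the block dynamics (sharpen ρ against fixed
patterns, then refit patterns) select sharper ones.

Initialisation: ρ⁰ is the upsampled mean frame, patterns start uniform;
an optional seeded multiplicative jitter exists but defaults to zero, so
reconstructions are fully deterministic. Convolution boundary handling is
reflective, with the padding and its exact adjoint implemented as
slice/flip operations so that gradients are exact. Stopping: relative cost
change < 10⁻⁶ or the iteration cap (300 default; the bundled bead
experiments use 400–600, chosen as the point where the pair verdicts
stabilise).

Computation is float32 with float64 cost accumulation; a 500-frame,
60²-camera-pixel problem runs at roughly 0.1–0.3 s per iteration on one
CPU core.

## Metrics (`specklemain.metrics`)

* **FRC** over rings one frequency bin wide, resolution at the first 1/7
  crossing with linear interpolation; optional Tukey apodisation
  (α = 0.25). Single-acquisition resolution uses an even/odd frame split
  reconstructed independently.
* **Two-peak analysis.** Lobes are detected as the two strongest local
  maxima with multi-scale smoothing (σ = 1 → 0.5 → 0 px, relaxed until the
  maxima are ≥ 2 px apart). The reported centre-to-centre separation is the
  distance between 2-D intensity centroids of the lobes (window ~1/3 of
  the lobe distance): deconvolved spots carry pixel-scale substructure that
  biases raw profile-peak positions outward by up to one reconstruction
  pixel, while centroids recover synthetic ground-truth separations of
  60–160 nm to a few percent. The resolved verdict applies the Rayleigh-like
  dip criterion (valley < 0.8 × lower peak, configurable) to the 10×
  cubic-interpolated profile along the lobe axis, extended past both lobes.
  For multi-emitter scenes, `closest_pair_separation` finds up to n maxima
  and measures the closest pair. The experiment pipeline restricts the
  search to the bounding box of the diffraction-limited bright spot
  (> 30% of max, + margin), as one zooms into the identified spot before
  drawing a cross-section.

## In-silico experiments (`specklemain.cli_io`)

`ExperimentConfig` + `run_experiment` wire scene → roughness → per-frame
speckle → camera stack → normalisation → blind-SIM → metrics. One master
seed is split into five stage seeds (scene, roughness, illumination,
camera noise, reconstruction) via SeedSequence spawning; reruns are
bit-identical. Bundled configurations:

| config | scene | frames | NA_det | camera ROI | upsample | iterations |
|---|---|---|---|---|---|---|
| `four_beads_80nm` | 4 beads, closest pair 80 nm | 500 | 1.5 | 20² px | 3 | 400 |
| `two_beads_40nm` | pair at 40 nm | 200 | 1.5 | 16² px | 4 | 800 |
| `two_beads_60nm_na0p8_80frames` | pair at 60 nm | 80 | 0.8 | 16² px | 3 | 600 |

The ROIs are kept just large enough to contain the diffraction-limited
spot with its PSF skirt; the frame and iteration counts are the package's
choices at which the resolution verdicts are stable.

## Known limitations

* Single-scattering surrogate: decorrelation angles and speckle contrast
  are semi-quantitative (factor ~2 class), though trends in θ, λ, and
  roughness are meaningful.
* Scalar fields; no vectorial/polarisation effects at high NA.
* 2-D object model; no axial sectioning, no fluorophore photophysics, no
  metal quenching.
* Blind-SIM verdicts at 40–60 nm separations depend on the speckle and
  noise realisation; a minority of seeds fail to split the pair, matching
  the seeds-majority acceptance framing.
* The generator's defaults emulate bright, sparse bead fields on a clean
  substrate; dense or dim scenes will need different photon budgets and
  possibly stronger regularisation.
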