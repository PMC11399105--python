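# Methods

This note records the model, the sampling scheme, the synthetic-data
conditions, and the numerical and design choices behind `emitrack`, at the
level of detail a user needs to judge what the package's results do and do
not show.

## Generative model

**Measurements.** An acquisition is a stack of N frames of P = R×C pixels.
The recorded count of pixel p in frame n follows the EMCCD read-out model

    w_n^p | u_n^p  ~  Normal( mu + xi * u_n^p ,  upsilon + f * xi^2 * u_n^p )

where `u_n^p` is the expected number of photons incident on the pixel
during the exposure, `mu` (counts) the camera offset, `upsilon` (counts²)
the read variance, `xi` (counts/photon) the overall gain and `f >= 1` the
excess-noise factor of electron multiplication. The Normal form has
unbounded support, so negative or real-valued input counts are legal data.
Per-pixel noise maps (sCMOS-style) are out of scope.

**Expected photons.** `u_n^p` integrates the photon flux over the pixel
area and the exposure window. The flux is a spatially uniform background
`F_n` (photons nm⁻² s⁻¹, per frame) plus one term per active emitter. Each
emitter is an isotropic 2-D Gaussian of unit mass with defocus-dependent
width

    sigma(z) = sigma0 * sqrt(1 + (z / d_z)^2),

a standard astigmatism-free defocus approximation; the PSF enters through
a single function (`psf_lateral_width` plus the axis-separable pixel
integral) and can be swapped for a calibrated form. Because `sigma` is
even in z, the sign of the axial position is unidentifiable and all
reporting uses |z|.

The exposure-time integral is approximated by K midpoint sub-exposure
positions per frame (default K = 4), which is what renders motion blur:
a fast emitter's photons are spread along its within-exposure path. The
pixel integral itself is exact for each sub-position (differences of the
Gaussian cumulative integral along each axis), so pixelation is modeled
rather than approximated by center-point evaluation. Doubling K from 4 to
8 changes the expected image of the default scenario by well under 0.1%
relative, which is the basis for the default.

**Emitter number.** A pool of M candidate emitters (default 50) carries
binary loads `b_m` with P(b_m = 1) = gamma/M — a truncated Beta–Bernoulli
construction whose active count is Binomial(M, gamma/M), approaching
Poisson(gamma) as M grows. `gamma` (default 5) is the a-priori expected
emitter count. Inactive candidates keep fully defined tracks under the
motion prior, so flipping a load never changes the dimension of the state;
the truncation is immaterial as long as the posterior count stays well
below M, which should be checked on the count posterior of any real run.

**Motion.** All candidate tracks follow a Brownian motion prior at
sub-exposure resolution: per-coordinate increments Normal(0, 2·D·dt)
between consecutive sub-exposure times (dead time between exposures is a
single longer step), with one diffusion coefficient D (nm²/s) shared by
all emitters. Initial positions are uniform over the field of view
expanded by 2 pixels per side — emitters may sit or wander outside the
imaged region — and z is uniform on [−z_max, z_max] with z_max = 2·d_z by
default. Gaussian transitions are a deliberately weak motion assumption;
the simulator's directed and confined models exist precisely to generate
data that violate it.

**Parameter priors.** D carries an Inverse-Gamma(shape, scale) prior
(default shape 2, prior mean 1e5 nm²/s); Inverse-Gamma is the conjugate
family for the Gaussian increments, giving an exact full-conditional draw.
Per-frame brightness `h_n` (photons/s per emitter) and background `F_n`
carry independent Gamma priors (defaults: shape 2 / mean 5e4, and shape 1
/ mean 0.02). Independence across frames is an assumption, not a finding;
time courses of both quantities can vary substantially in real data, and
nothing couples them here. Two benchmark-protocol options restrict the
model: `fixed_brightness` pins `h_n` to a known value, and
`constant_background` ties all `F_n` to a single value (its effective
prior is then the product of the per-frame Gamma factors).

## Posterior sampling

The sampler targets the unnormalized log posterior
(likelihood + loads prior + motion prior over all M tracks + parameter
priors) with Metropolis-within-Gibbs sweeps:

* **Track updates.** Single-frame Brownian-bridge moves over a red/black
  frame checkerboard (proposals drawn from the motion-prior conditional
  given the neighboring sub-positions, so acceptance reduces to a
  likelihood ratio), alternating sweep-by-sweep with whole-frame
  random-walk jitters (25 nm lateral / 80 nm axial); longer bridge
  windows of 3 and 7 frames are cycled in, and each active emitter also
  gets a whole-track translation proposal per sweep.
* **Birth/death.** Load flips propose a fresh prior track whose start is
  drawn from a 50/50 mixture of uniform-over-bounds and the normalized
  positive residual image (with the exact Hastings correction), and
  simultaneously shift the background flux to conserve the expected
  photon count — a deterministic unit-Jacobian pairing. The compensation
  matters because a diffuse out-of-focus emitter and uniform background
  are nearly interchangeable explanations; without it, death moves face a
  large likelihood barrier and the chain overcounts.
* **Split/merge.** A reversible pair exchanging two active tracks with
  their midpoint track (the separation path is proposed from the Brownian
  difference density), again flux-compensated. This is the escape route
  from metastable states where k+1 model emitters interleave k true ones.
* **Relocation.** An independence proposal replacing one active emitter's
  entire track via the residual-guided start, for escaping poor modes
  that local moves cannot leave.
* **Diffusion.** A joint Gibbs draw of (D, all inactive tracks): D from
  its Inverse-Gamma conditional given the active increments only, the
  inactive tracks refreshed from the motion prior at the new D. The
  inactive-track prior factors cancel exactly, so this block is an exact
  Gibbs update of the full-dimension target while D mixes at the
  active-track rate rather than being dragged by M−B prior tracks.
* **Scale.** A joint rescale of every track's shape about its start point
  by a factor c together with D → c²D. Brownian scale invariance makes
  the motion-prior ratio cancel the position Jacobian exactly, so
  acceptance is the likelihood ratio times the D-prior ratio times c².
  Sub-exposure roughness is only weakly constrained by the data (motion
  blur averages it), so D and track roughness form a ridge that plain
  Gibbs traverses very slowly; this move walks along the ridge in ~10%
  steps and is what makes the diffusion posterior mix within desk-scale
  run lengths.
* **Brightness/background.** Log-scale random walks (Jacobian included),
  with a symmetric two-component step mixture (sd 0.08 / 1.0) so the
  chains also traverse the prior tails at a useful rate.

Load flips are proposed for a random subset of 4 slots per sweep; slot
selection is direction-symmetric, so each flip kernel individually
satisfies detailed balance. Every move satisfies detailed balance with
respect to the stated posterior; with the likelihood disabled
(`run.prior_only`) the chain must reproduce its priors exactly, and the
test suite checks the count, diffusion and background marginals that way.
The flux-compensated and split/merge moves are additionally validated by
comparing count posteriors with and without them on a small dataset.

**Initialization and burn-in.** Chains start empty (B = 0; emitters are
recruited during burn-in), with background from the frame-wise lower
quartile of the counts inverted through the camera model, and D at a
quarter of its prior mean — a deliberately conservative start that keeps
early track proposals smooth so recruitment sees sharp residual structure
(D is resampled every sweep, so the value only shapes early burn-in).
Two burn-in devices address the dominant failure mode of short runs —
committing early to a local mode in which k+1 entangled model emitters
explain k true ones:

* the likelihood is tempered during the first 60% of burn-in, the inverse
  temperature ramping geometrically from 0.05 to 1, so spurious
  structures melt and emitters crystallize onto the strongest signals as
  the ramp closes (retained samples always target the untempered
  posterior);
* burn-in opens with three short annealed pilot segments (a quarter of
  the burn-in each) and continues from the highest-posterior end state —
  on data where one crystallization goes wrong, an independent pilot
  almost always goes right, and the refined posterior gap between the
  modes (hundreds of log units) makes the selection unambiguous.

No automatic convergence decision is made: acceptance rates and the
log-posterior trace are recorded on the chain, and judging convergence is
the user's responsibility.

**Summaries.** The MAP estimate takes the modal emitter count by sample
frequency (ties toward the smaller count), then the highest-posterior
sample among those carrying it (ties by first occurrence). Credible
intervals are 2.5–97.5 percentiles; per-frame track CIs match each
sample's active emitters to the MAP tracks by gateless per-frame nearest
assignment, because emitter labels are arbitrary across samples.
Percentile intervals need not contain the MAP point.

## Track-comparison metrics

The gated distance between two tracks sums `min(||psi_n - phi_n||, eps)`
over frames; a missing detection contributes `eps`. Sets of tracks are
compared by the minimum total gated distance over one-to-one pairings,
solved as a linear assignment problem with dummy partners costing `eps·N`
(an unmatched track fails localization in every frame). Tracking error
divides by N times the reference track count; the dual-view variant uses
an infinite gate (both views must supply complete tracks), divides by
2·N·M, and takes M as the mean of the two counts when they disagree.
Localization resolution re-pairs positions frame by frame without a gate
and is therefore blind to mislinks; it is undefined when the per-frame
position counts differ, and it never exceeds the tracking error (frame-
wise re-pairing is a relaxation of track-wise pairing). Aggregation is an
arithmetic mean per pair-frame (root-mean-square would be the main
alternative; the mean matches the tracking-error normalization style).
Mixed 2-D/3-D comparisons use the shared lateral coordinates; axial
positions are compared as |z| against |z|. Default gates: 5 pixels
against ground truth, infinite for dual-view comparisons.

## Synthetic data: what it emulates and what it does not

The simulator draws ground-truth tracks (Brownian by default; directed,
confined-by-reflection and immobile variants for robustness data) at the
forward model's sub-exposure resolution, then renders them through the
same expected-image code and EMCCD noise model used in inference, so
rendered stacks are exact with respect to the model. Default conditions,
chosen once to represent a realistic widefield EMCCD acquisition near the
regime of the experimental figures:

| quantity | default | unit |
|---|---|---|
| pixel size | 133 | nm |
| frames / exposure / period | 22 / 100 / 114 | – / ms / ms |
| NA / wavelength | 1.45 / 665 | – / nm (Rayleigh limit 280 nm) |
| PSF width sigma0 / axial scale d_z | 110 / 400 | nm |
| diffusion D | 5e4 | nm²/s |
| brightness h | 5000 | photons/s (≈500 per frame) |
| background F | 0.01 | photons nm⁻² s⁻¹ (≈18 per pixel per frame) |
| camera mu / upsilon / xi / f | 100 / 49 / 2.2 / 2.0 | counts / counts² / counts/photon / – |

Named fixtures package the benchmark layouts: `one-emitter` (16×16 px),
`three-emitter` (20×20 px, well-separated starts), `background-only`, and
two-emitter `displacement-{724,579,434,289,145,0}` scenarios. In the
displacement scenarios the second track reuses the first track's
increment realization, offset laterally so the per-frame mean separation
equals the target exactly (including 0, where the tracks coincide). This
choice is forced by arithmetic: two independent Brownian paths at
realistic D have an irreducible mean separation far above the smaller
targets, so only a common-shape pair can realize the full displacement
ladder; the offset search is still implemented generally (bisection with
a 2% self-check) and reports unreachable targets for independent
increments.

Because rendering uses the inference model, passing recovery tests shows
that the sampler solves the stated inverse problem — it does not probe
PSF misspecification, spatially structured background, photophysics
(blinking, bleaching), non-Gaussian camera noise, or drift. Those are
exactly the effects a real microscope adds, and results on real data
depend on how well the calibrated camera/optics parameters and the
Gaussian-defocus PSF describe it.

## Benchmark analysis protocol and problem sizes

Benchmark inference mirrors the simulation conditions the way a
tool-comparison protocol would: brightness fixed at the generating value,
a constant-in-time background inferred, D inferred. The desk-scale runs in
the test suite use M = 10, gamma = 2, K = 4 and 1200–3000 sweeps
(1200–1600 sweeps with half burn-in for count/tracking benchmarks; 3000
sweeps with 1200 burn-in where the diffusion posterior itself is
summarized, since D has the longest autocorrelation time) on the fixture
ROIs above — sizes chosen so the full replicated suite (tens of
independent chains) completes in tens of minutes on one core. The
acceptance script uses the same sizes. Production defaults
(M = 50, gamma = 5, 3000 sweeps) are the package defaults in
`ModelConfig`/`RunConfig`; longer chains primarily tighten the diffusion
posterior and the count posterior tails.

## Known limitations

* Shared D across emitters; no per-emitter or state-switching diffusion.
* Spatially uniform background per frame; structured background is an
  extension point at `background_photons`.
* The defocus PSF is a stand-in; real astigmatic or aberrated PSFs need a
  calibrated width model (single replacement point, see above).
* Out-of-focus emitters and background are close to unidentifiable; the
  flux-compensated moves make the sampler traverse that ridge, but on
  real data the count posterior for dim, far-from-focus emitters should
  be read with corresponding caution.
* Axial information degrades quickly with |z|; |z| estimates are much
  less precise than lateral ones, and the sign is unrecoverable.
* The sampler is serial; per-pixel likelihood parallelism is possible but
  not implemented.
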