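# emitrack

Joint Bayesian inference of **how many** fluorescent emitters are present
in a widefield timelapse and **where they move**, at superresolution, from
the raw pixel counts alone — no photoswitching, no spot detection, no
separate linking step.

## The problem

Single-particle tracking pipelines traditionally work in modules: detect
spots in each frame, localize them, then link localizations into tracks.
Each module commits to hard decisions that the next one cannot revisit,
which breaks down exactly where tracking is interesting: emitters closer
than the diffraction limit, moving out of focus, or leaving the field of
view. `emitrack` instead treats the entire image stack as one generative
model and samples the joint posterior

    P(emitter number, tracks, D, brightness, background | images)

so that counting, localization and linking inform each other. Emitter
number is handled nonparametrically: a pool of M candidate emitters carries
binary loads `b_m ~ Bernoulli(gamma/M)` (a truncated Beta–Bernoulli
construction; the active count is the inferred emitter number B), so the
model dimension never changes while B varies.

The forward model is physical end to end:

* each emitter is a 2-D Gaussian PSF whose width grows with defocus,
  `sigma(z) = sigma0 * sqrt(1 + (z/d_z)^2)` — axial distance is estimated
  from spot width, up to the sign of z (only |z| is reported);
* motion blur: the photon flux is integrated over each exposure through K
  sub-exposure track positions, and over each pixel's area exactly
  (differences of Gaussian integrals, no center-point approximation);
* EMCCD read-out: counts follow
  `w ~ Normal(mu + xi*u, upsilon + f*xi^2*u)` for `u` expected photons,
  with offset `mu`, read variance `upsilon`, gain `xi` and excess-noise
  factor `f`;
* Brownian motion prior with a shared diffusion coefficient D, uniform
  entry positions extending beyond the field of view, and per-frame
  brightness and background fluxes.

Inference is MCMC (blocked Metropolis–Hastings with Brownian-bridge track
proposals, residual-guided birth/death and split/merge of emitters, and a
conjugate Inverse-Gamma draw for D). Point estimates are MAP-style: the
modal emitter count first, then the best sample carrying it; uncertainties
are 2.5–97.5 percentile credible intervals.

Track quality is scored with gated-distance metrics: the pairing distance
(optimal one-to-one matching of tracks under a gate `eps`, missing
detections costing `eps` per frame), the tracking error (pairing distance
per reference track per frame), its dual-camera variant (halved, since
both views share the discrepancy), and the mislink-insensitive
localization resolution (per-frame identity-free re-pairing).

## Worked example

```python
from emitrack import make_fixture, map_estimate, run_chain
from emitrack import TrackSet, localization_resolution

stack, truth, scenario = make_fixture("one-emitter")   # 22 frames, 16x16 px
config = scenario.config(
    M=10, gamma=2.0,
    fixed_brightness=scenario.brightness,  # benchmark protocol
    constant_background=True,
).with_run(iterations=3000, burn_in=1200, seed=1)

chain = run_chain(stack, config)
est = map_estimate(chain)
print("MAP emitter count:", est.n_emitters)
print("count posterior:", est.count_posterior)
print("D 95% CI (nm^2/s):", est.diffusion_ci)

lat = lambda ts: TrackSet(ts.positions[..., :2])
print("lateral resolution vs truth (nm):",
      round(localization_resolution(lat(est.trackset()), lat(truth)), 1))
```

Output from this exact session:

```
MAP emitter count: 1
count posterior: {1: 0.691..., 2: 0.305, 3: 0.0038...}
D 95% CI (nm^2/s): (38248.45..., 75133.29...)
lateral resolution vs truth (nm): 30.2
```

The movie was generated at D = 5e4 nm²/s with one emitter, so the chain
recovered the count exactly, covered the generating diffusion coefficient,
and localized the moving emitter to ~30 nm per frame — an order of
magnitude below the 280 nm diffraction limit of the simulated optics.

The same workflow is available from a shell:

```bash
emitrack simulate one-emitter -o work/
emitrack track work/one-emitter.tif -c work/one-emitter.config.yaml -o work/
emitrack evaluate work/one-emitter.map_tracks.csv work/one-emitter.truth.csv
```

`simulate` writes the movie as multi-page TIFF plus ground-truth tracks as
CSV and TrackMate-style XML (so external trackers can be benchmarked on
identical data); `track` writes the chain archive, MAP tracks with CIs,
the emitter-count posterior and a run manifest; `evaluate` reports pairing
distance, tracking error and localization resolution between any two track
files.

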