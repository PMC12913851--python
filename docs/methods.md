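# Methods

## The measurement problem

After localized laser-induced DNA damage, two things happen within
seconds to minutes: a damage sensor (e.g. PARP1) accumulates at the
lesion, and the surrounding chromatin decompacts. Both are visible in a
two-channel confocal time-lapse — the marker channel gains localized
foci, and the DNA counterstain inside the irradiated region loses mean
intensity and spatial heterogeneity. `chromodyn` quantifies both
processes per time point and summarizes their kinetics with exponential
time constants.

## Image products

Four products are derived from each raw stack before any statistics:

1. **Nuclei count masks.** Each counterstain frame is binarized with the
   iterative-intermeans (isodata) histogram threshold, connected
   components are labeled (8-connected) and objects below a minimum area
   (default 500 px²) discarded. Labels are linked across frames by
   maximal pixel overlap with the previous frame so a nucleus keeps one
   identity; a flat frame yields an empty mask rather than an error.
2. **Damage-area count masks** — the nuclei masks restricted to the
   irradiation ROI (0-based, half-open pixel rectangles; physical sizes
   convert via the pixel size with round-half-up).
3. **Damage-foci binary masks** — damage-channel pixels at ≥ 80% of the
   per-frame maximum. The per-frame (not stack-wide) maximum is used so
   foci remain detectable as the overall amplitude evolves; an all-zero
   frame yields an empty mask plus a warning.
4. **Intensity images** — counterstain frames mean-filtered (3×3,
   configurable) and rolling-ball background-subtracted (default radius
   100 px, matching the largest heterochromatin features), clipped at 0.
   Large radii use the standard coarse-grid scheme (min-pool, roll a
   scaled ball, bilinear upsample, cap at the image), which agrees with
   direct grayscale opening by a ball to within a few percent of feature
   height. Background subtraction is applied to the DNA channel only.

## ICCS colocalization

For fluctuation images δIᵢ = Iᵢ − ⟨Iᵢ⟩ computed inside a binary analysis
mask (zero outside), the masked spatial correlation is

    G(ξ, η) = ⟨δI₁ δI₂⟩(ξ, η) / (⟨I₁⟩ ⟨I₂⟩),

with the pair average at each lag normalized by the number of in-mask
pixel pairs at that lag, obtained from the autocorrelation of the mask
itself. This handles arbitrarily shaped regions (the irradiated part of
one nucleus) without windowing bias; an FFT implementation is verified
against brute-force pair sums to 1e−8. Masks under 100 px are refused —
fewer pairs produce amplitude estimates dominated by noise.

The cross-correlation fraction is f₁ = G_cc(0)/G_ac,2(0) (and f₂ with
channel 1's autocorrelation), clipped to [−1, 1]:

* G_cc(0) is the **measured** central value of the cross-correlation —
  detector shot noise is uncorrelated between channels, so no spike sits
  at zero cross-lag. A 3×3 central smoothing option exists but is off by
  default.
* G_ac(0) is **extrapolated**: the autocorrelation surface is fit with an
  isotropic Gaussian g(r) = g₀·exp(−r²/w²) + offset over all lag pixels
  up to the maximum lag (default ±32 px), excluding r = 0 where the
  shot-noise spike sits. Exact lag radii are used rather than integer
  radial bins; binning was found to bias g₀ by several percent on
  noiseless Gaussian surfaces. A full 2D elliptical fit was deliberately
  not used: confocal point-spread functions are near-isotropic in-plane
  and the radial fit is better conditioned on small masks.
* If either autocorrelation fit fails or yields g₀ ≤ 0, the frame is
  flagged invalid and carries NaN — never 0, which is a meaningful f₁.

When a damage-area mask holds several labels, the largest object is
analyzed (one irradiated nucleus per ROI by design).

## DNA density, intensity, CV

Per frame: `I_norm = I_DNA / I_max` with I_max the maximum of the
background-subtracted counterstain over the nucleus mask (computing I_max
after smoothing/background subtraction tames hot pixels; a
high-percentile mode exists but is off by default). DNA density is the
mean of I_norm over nucleus ∩ foci; intensity and CV = σ/μ (population σ)
are computed over the damage-area mask. CV uses the n rather than n−1
denominator; at the thousands of pixels in a typical ROI the difference
is far below other error sources. Traces are normalized either to the
first post-bleach time point (counterstain metrics) or to their peak
(damage-marker recruitment traces).

## Kinetics

Association: y(t) = y₀ + (plateau − y₀)(1 − exp(−(t − t_first)/τ)) fit
over [first post frame, 60 s]; the short window isolates recruitment
before redistribution sets in. Decay: y(t) = plateau +
(y₀ − plateau)·exp(−(t − t_start)/τ), started at the first post-bleach
frame for counterstain metrics or at the trace peak (argmax of a 3-point
moving average, suppressing single-frame noise) for damage-marker traces.
Fits use bounded trust-region least squares (lmfit) with
τ ∈ (0.1, 1000] s, initialized from trace endpoints and window/5. A τ at
its bounds, a non-decaying trace, or fewer than 4 points all yield
`success = False` with NaN τ instead of an exception, so flat
(inhibited-like) traces are reported as "no decay" rather than as an
arbitrary constant. Fitted τ scales exactly with a rescaling of the time
axis and is invariant to positive rescaling of y.

## The simulator

`synth_nucleus` draws an elliptical nucleus whose counterstain rate is a
uniform euchromatin level plus Gaussian heterochromatin blobs (default
contrast 3, σ = 4 px); the heterochromatin mask is the top quartile of
in-nucleus density. `synth_timelapse` then builds expected photon rates
per frame and draws Poisson counts (hybrid detectors in photon-counting
mode), with every random choice derived from an explicit integer seed:

* **Channel 2 (counterstain).** Outside the ROI the density map is
  static. Inside roi ∩ nucleus, after the bleach the rate is
  (μ + (D − μ)·c(t))·m(t) with m(t) = 1 − A(1 − e^(−t/τ_I)) and
  c(t) = 1 − A(1 − e^(−t/τ_CV)): m scales the whole region (the ROI mean
  decays with exactly τ_I), while c shrinks fluctuations toward the ROI
  mean (the rate CV decays with exactly τ_CV, since m cancels in σ/μ).
  This contrast-shrinkage construction realizes both observables
  analytically with no calibration loop; a time-increasing blur would
  produce the same phenomenology but only approximately and at higher
  cost. A = `relax_amplitude` is the shared relaxation amplitude: 0.4 in
  the control preset, 0 in the PARP-inhibited preset. The magnitude of
  the counterstain drop is not constrained by published numbers; 0.4 was
  chosen once so the decay spans several times the photon noise over the
  150 s series. Optional counterstain photobleaching is off by default.
* **Channel 1 (damage marker).** A uniform nucleoplasmic rate plus
  Gaussian foci (σ = 2 px) whose centers land, with probability
  `damage_bias` (default 0.9) each, on density-weighted heterochromatin
  pixels in roi ∩ nucleus, else uniformly in roi ∩ nucleus; both
  candidate draws use common random numbers so the heterochromatin
  fraction is non-decreasing in the bias for a fixed seed. The focus
  amplitude rises as recruit_amplitude·(1 − e^(−t/T_on)) and decays with
  `t_off_foci` (default 40 s) after `decay_start_s` (default 53.6 s,
  the observed control peak time; effectively ∞ in the inhibited preset,
  emulating trapping).
* **Schedule.** Pre-bleach frames end at −1.3 s, bleach iterations are
  dead time (no frames emitted), the first post frame falls at 2.6 s and
  the 50th at 149.6 s. Emitted frames always number n_pre + n_post.

Preset kinetic constants (control: T_on 5.8 s, T_off 26.5 s intensity /
35.4 s CV; inhibited: T_on 18.2 s) correspond to reported live-cell
values for untreated and PARP-inhibitor-treated cells.

What the simulator does **not** model: optical PSF blur beyond the blob
textures, nucleoli, cell motion or focus drift, detector afterpulsing,
and any coupling between marker recruitment and counterstain intensity.
Passing tests on synthetic data therefore demonstrate correctness of the
estimators and fits under Poisson statistics and known geometry — not
robustness to motion artifacts or segmentation of crowded fields.

## Default problem sizes

Tests and demos run on 128–192 px frames with proportionally scaled ROI
and rolling-ball radius (50 px), 40–60 blobs and ~20-count mean rates;
ensembles use 6–30 seeds. These sizes keep full pipeline runs in seconds
per cell while leaving photon noise realistic; all algorithms are
size-agnostic and run unchanged on 512×512 acquisitions.

## Known limitations

* Per-frame isodata thresholding couples the analysis region to the
  signal: as the ROI dims during strong relaxation, low-density pixels
  drop below threshold and the damage-area mask erodes toward bright
  heterochromatin. This inflates pipeline-level apparent T_on relative
  to fixed-region fits (which recover generator truth within a few
  percent). It is inherent to count-mask-based workflows; the truth
  comparison emitted by `run_demo` quantifies it per run.
* Touching nuclei are not split (no watershed); one nucleus per ROI is
  assumed.
* f₂ is computed alongside f₁ but plays no role in the summary outputs.
* Measured CV contains a shot-noise floor (≈ 1/√μ per pixel), so CV decay
  amplitudes are compressed relative to the underlying rate CV; decay
  *time constants* are much less affected.
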