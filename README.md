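# chromodyn

Quantitative analysis of DNA-damage localization and chromatin remodeling
in live-cell confocal time-lapse movies.

In laser micro-irradiation experiments, a focused UV laser inflicts DNA
damage inside a rectangular nuclear region of interest (ROI) while a vital
DNA counterstain (e.g. Hoechst 33342) doubles as photosensitizer and
chromatin marker, and an optional second channel follows a damage marker
such as a PARP1 chromobody. `chromodyn` turns those two-channel (or
counterstain-only) photon-count stacks into four quantitative readouts:

* **f₁, the ICCS cross-correlation fraction** — image cross-correlation
  spectroscopy measures the colocalization of the damage marker with
  high-density (heterochromatic) chromatin from spatial correlation
  amplitudes inside the irradiated area:

  ```
  G(ξ, η) = ⟨δI₁ δI₂⟩(ξ, η) / (⟨I₁⟩⟨I₂⟩),      f₁ = G_cc(0) / G_ac,2(0)
  ```

  where G_cc(0) is the measured zero-lag cross-correlation amplitude and
  G_ac,2(0) the channel-2 autocorrelation amplitude extrapolated to zero
  lag by a radial Gaussian fit that excludes r = 0 (the shot-noise spike).
  f₁ runs from 1 (full colocalization) through 0 (none) to −1
  (anti-correlation).

* **DNA density** — the mean of the max-normalized counterstain image
  `I_norm = I_DNA / I_max` over the damage foci (pixels ≥ 80% of the
  damage-channel maximum), a [0, 1] proxy for chromatin compaction at the
  damage sites.

* **Intensity and CV** — mean counterstain intensity and its coefficient
  of variation `CV = σ/μ` in the irradiated nuclear area; both fall as
  chromatin relaxes.

* **Kinetics** — one-phase exponential fits: association time constant
  T_on for marker recruitment (fit over the first 60 s post-bleach) and
  decay constant T_off for intensity/CV relaxation.

Because no public raw data accompany this type of experiment, the package
ships a **ground-truthed simulator** (`chromodyn.synthetic`) that generates
two-channel Poisson photon-count stacks with known nucleus geometry, focus
placement bias, recruitment and relaxation constants, on the standard
acquisition schedule (5 pre-bleach frames at 1.3 s, 2 × 1.3 s bleach dead
time, 50 post-bleach frames at 3 s; first post frame at t = 2.6 s, last at
149.6 s). Every analysis stage is validated against that ground truth.

## Worked example

Colocalization bounds on synthetic chromatin textures
(`examples/02_iccs_colocalization.py`):

```
duplicated channels:   f1 = +1.000   (full colocalization -> 1)
independent channels:  f1 = -0.009   (no colocalization -> 0)
inverted channel:      f1 = -1.000   (anti-correlation -> -1)
```

Recovering known kinetics from simulated movies
(`examples/04_recruitment_kinetics.py`):

```
T_on : fitted  6.11 +- 0.29 s (truth 6.0 s) over 10 seeds
T_off: fitted 30.20 +- 0.25 s (truth 30.0 s)
```

The full pipeline contrast between an untreated cell and a PARP-inhibited
cell (`examples/05_full_pipeline_demo.py`): in the control condition f₁,
DNA density, counterstain mean and CV all decrease across the post-bleach
series and T_on is fast, while in the inhibited condition the DNA metrics
stay flat (the decay fit correctly reports "no decay") and recruitment is
slow — the computational analogue of PARP-inhibitor trapping.

From the shell, the same stages are available as subcommands:

```bash
chromodyn simulate --condition control --seed 0 --out sim/
chromodyn analyze --stack sim/stack.tif --roi 0,0,192,56 --out analysis/
chromodyn demo --condition parp_inhibited --seed 1 --out demo/
```

`analyze` writes the four intermediate image products (nuclei count masks,
damage-area count masks, foci masks, background-subtracted intensity
images), a per-frame `metrics.csv`, a `kinetics.csv` fit summary, a log of
skipped frames and a JSON provenance block.

## Layout

| Path | Contents |
| --- | --- |
| `src/chromodyn/synthetic.py` | acquisition schedule, nucleus/texture generator, two-channel simulator |
| `src/chromodyn/preprocess.py` | nuclei segmentation + tracking, damage-area masks, 80%-of-max foci masks, rolling-ball background subtraction |
| `src/chromodyn/iccs.py` | masked spatial correlation, radial Gaussian amplitude fit, f₁/f₂ |
| `src/chromodyn/metrics.py` | normalized DNA image, DNA density, CV, trace normalization |
| `src/chromodyn/kinetics.py` | one-phase association/decay fits (T_on, T_off) |
| `src/chromodyn/pipeline.py`, `cli.py` | orchestration, config, reports; `chromodyn` CLI |
| `examples/` | one narrative script per capability |
| `docs/methods.md` | models, assumptions, parameter choices, limitations |
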