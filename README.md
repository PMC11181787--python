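# ctdiscrim

Simulated low-dose-CT lesion-discrimination experiments as a tested, reusable
pipeline: stimulus synthesis under controlled resolution and noise, a
two-alternative forced-choice (2AFC) psychophysics engine driven by synthetic
linear observers, and the full observer-analysis suite (Ideal-Observer
efficiency, classification images, spectral features, sampling efficiency and
its per-frequency gradient, and "unapodized" classification images).

The package is aimed at researchers in task-based medical image quality who
want to study how noise texture and apodization (reconstruction smoothing)
affect discrimination performance — without collecting human-subject data —
or who need a reference implementation of the analysis chain for experiments
of their own.

## The model

**Tasks.** Three two-class discrimination tasks on radially symmetric
lesions in air background (B = −1000 HU, lesion intensity L = 200 HU). The
benign profile is

    s0(r) = B + L·Φ((R_L − r)/σ_L),        σ_L = 0.25 mm,

with Φ the standard normal CDF. Task T1 (size, R_L = 1.5 mm) enlarges the
radius by ΔR; task T2 (edge sharpness, R_L = 2.5 mm) inflates the edge scale
to σ_L + Δσ; task T3 (interior uniformity, R_L = 2.5 mm) depresses the
interior and raises the outer annulus by L·ΔC/2, with interior radius
R_I = 0.71·R_L.

**Imaging.** Objects are sampled on a 9×-oversampled 1152² grid (87.5 mm
square), filtered by a cosine-rolloff MTF, M(f) = ½ + ½cos(πf/f₀) (System 1:
f₀ = 0.59 cyc/mm; System 2: f₀ = 0.73 cyc/mm), times a Shepp-Logan
apodization filter A(f) = sinc(f/f_c) at four levels (f_c = ∞, 2f₀, f₀,
0.8f₀), then decimated to the 128² image grid (0.684 mm pixels). Noise is a
stationary Gaussian process with a ramp power spectrum N(f) = C_N·f up to
the pixel Nyquist frequency (leveling quadratically below 5% of Nyquist),
attenuated by A(f)², with C_N calibrated so the unapodized pixel SD is
166.5 HU.

**Observers and endpoints.** The Ideal Observer is the prewhitened matched
filter ŵ_IO = Δμ̂ / (Σ̂ + σ_Q²); its SNR sets the information ceiling per
condition. Synthetic subjects are linear templates (optionally mis-tuned:
spatially undersized, or with attenuated low frequencies) plus Gaussian
internal noise on the decision variable. Training uses a 3-down-1-up
staircase on the task parameter (±15% steps, ≈79% correct asymptote);
testing runs 2000 fresh 2AFC trials at threshold. Endpoints are proportion
correct, detectability d = √2·Φ⁻¹(PC), threshold contrast energy
E_c = A_pix·Σ(μ_T−μ_A)² and its PC-corrected form, and efficiency
η = (d/SNR_IO)². Classification images are score-weighted averages of
prewhitened noise-field differences; their radial spectra, integrated power
and mean frequency (below 0.35 cyc/mm), sampling efficiency
(SNR_w/SNR_IO)² and its gradient complete the analysis.

## Worked example

The analytic resolution (frequency where M·A falls to 10% of max) and pixel
noise table:

```bash
$ ctdiscrim table
system apod  resolution_cyc_per_mm  pixel_sd_hu
    S1   A1                 0.4691       166.50
    S1   A2                 0.4520       113.60
    S1   A3                 0.3956        47.08
    S1   A4                 0.3561        33.69
    S2   A1                 0.5805       166.50
    S2   A2                 0.5593       129.74
    S2   A3                 0.4894        64.79
    S2   A4                 0.4406        46.36
```

Each row is one system × apodization condition: stronger apodization trades
resolution for noise (System 1 without apodization resolves to 0.47 cyc/mm
at 166.5 HU pixel noise; at level A3 it resolves only 0.40 cyc/mm but noise
drops to 47 HU).

Train and test one synthetic subject (an Ideal-Observer template degraded by
internal noise to ~25% efficiency) on the interior-uniformity task:

```bash
$ ctdiscrim train --task T3 --system S1 --apod A1 --observer obs-io25 --seed 3
threshold theta = 0.860688 (log: staircase.csv)

$ ctdiscrim test --task T3 --system S1 --apod A1 --observer obs-io25 \
      --theta 0.8 --trials 200 --seed 4
...
contrast_energy              23970.894863
contrast_energy_corrected    32528.729138
snr_io                           1.925049
efficiency                       0.281707
```

The staircase found the interior-contrast parameter giving ≈80% correct
(ΔC ≈ 0.86); at ΔC = 0.8 the Ideal Observer's SNR is 1.93, and the
observer's measured detectability implies it uses ≈28% of the available
task information — close to its dialed-in 25% target. `ctdiscrim classify`
then estimates the observer's template from the same trials, and
`ctdiscrim run` orchestrates the full 24-condition × 6-observer study
(`--fast` switches to the non-rendering analytic responder).

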