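# Methods

This note records the model assumptions, numerical conventions and design
choices behind `ctdiscrim`, and what the synthetic-observer experiments do
and do not establish.

## Grids and Fourier conventions

All stimuli live on a 128×128 crop of a simulated 512-pixel, 350 mm
reconstruction, so the pixel pitch is exactly 350/512 = 0.68359375 mm
(0.68 mm rounded) and the crop spans 87.5 mm. Objects are synthesized at 9×
oversampling (1152², pitch ≈ 0.0760 mm), which makes the fine and coarse
grids commensurate: decimating every 9th fine sample lands exactly on pixel
centers, and the lesion center sits at index N/2 of both grids. Even-sized
FFT grids need a declared center; placing it at N/2 and transforming with an
`ifftshift` keeps the spectra of symmetric objects purely real (imaginary
residuals are at machine precision and are asserted in tests). The image
frequency step is ΔFreq = 1/(128·Δ_pix) ≈ 0.01143 cyc/mm and the Nyquist
frequency 1/(2·Δ_pix) ≈ 0.7314 cyc/mm.

## Lesion objects

Profiles are evaluated per-sample from the radial distance (no polar
interpolation), with Φ the standard normal CDF. Parameters (R_L = 1.5 mm for
the size task, 2.5 mm otherwise; σ_L = 0.25 mm; L = 200 HU on B = −1000 HU;
R_I = 0.71·R_L) are fixed; only the task parameter θ (ΔR, Δσ or ΔC) varies.
The spectral mean frequency (Σf·w/Σw over the full fine-frequency grid) uses
amplitude weighting |ŝ| for object spectra, because the jinc-like spectra
change sign and a signed mean frequency is not meaningful; this convention
reproduces lesion-spectrum mean frequencies of 0.40 cyc/mm (3 mm lesion) and
0.37 cyc/mm (5 mm lesion), and 0.50 cyc/mm for the interior-uniformity
feature (which is exactly θ-free by linearity). The size and edge-sharpness
feature spectra depend on θ, so their mean frequencies are reported for a
given θ rather than asserted as constants.

## Imaging chain

The MTF is a cosine rolloff with cutoff f₀ and the apodization a Shepp-Logan
(sinc) profile with cutoff f_c, both radial; the combined transfer is applied
on the fine grid before decimation, so frequencies beyond the image Nyquist
are present in the object but removed by the chain (the tasks are
deliberately resolution-limited). DC gain is 1, so the background level is
preserved exactly.

The noise power spectrum is a ramp C_N·f with a quadratic leveling branch
(C_N/2)(f²/f_L + f_L) below f_L = 5% of Nyquist — the unique quadratic form
continuous at f_L — and a **radial** cutoff at the Nyquist frequency (the 2D
grid corners carry no power). The radial cutoff is a modeling choice that
makes the discrete variance quadrature df²·ΣN·A² reproduce the analytic
pixel SDs used for calibration; with corner power included the
higher-apodization SDs cannot be matched. C_N is calibrated so the
unapodized pixel SD is 166.5 HU. With the cutoffs f_c = 0.8·f₀ the A4 cells
of the resolution/SD table computed here (0.36/0.44 cyc/mm, 33.7/46.4 HU)
are the analytic consequences of that definition; they are reported but not
used as calibration anchors.

Noise fields are synthesized directly on the image grid by frequency-domain
filtering of white noise: n = IFFT(FFT(z)·Σ̂^{1/2})/Δ_pix for z i.i.d.
standard normal, which gives pixel variance df²·ΣΣ̂ exactly and real fields
by symmetry of the radial filter. Every draw is filtered twice — with the
condition's apodization and with none — so each trial retains a matched
pre-apodization noise field for the unapodized classification-image
analysis. Display rendering (1500 HU window at −650 HU level, 8-bit
truncating quantization) is applied only to viewing exports; analysis
operates on unquantized HU images.

## Observers

The Ideal Observer template is the prewhitened matched filter
ŵ_IO = Δμ̂/(Σ̂ + σ_Q²), where σ_Q² = (window/2^bits)²/12 ≈ 2.86 HU² is the
uniform-quantization variance of the display. The term is kept in both the
template denominator and the response-variance quadrature, where it
regularizes frequencies nulled by apodization; it is added to Σ̂ directly
(mixing HU² with HU²·mm²), which follows the source analysis convention —
since the synthetic trials are scored on unquantized images the term acts
purely as a small regularizer and its unit convention is immaterial.
Template SNR is Δρ/σ with Δρ = Σw·Δμ and σ² = df²·Σ(Σ̂+σ_Q²)|ŵ|²; with the
synthesis normalization above this is the exact covariance quadratic form,
so Monte-Carlo 2AFC proportion correct matches Φ(SNR/√2) (asserted at 10⁴
trials).

Synthetic subjects add Gaussian internal noise to the decision variable,
parameterized in units of the template-response SD: κ yields
SNR_eff = SNR/√(1+κ²), so an Ideal-Observer template with κ = √(1/η − 1)
has efficiency η by construction. Mis-tuned templates are produced by radial
rescaling of the spatial weights (an undersized perceived lesion) or by
Butterworth-style attenuation of low frequencies. The default roster of six
subjects spans target efficiencies 0.10–0.40, the range reported for human
readers in this paradigm; matching that range is a design input, not a
finding.

## Psychophysics

The staircase is 3-down-1-up with multiplicative ±15% steps, whose
asymptotic convergence point is PC = 0.5^{1/3} ≈ 0.794. Six runs are
performed per condition, each restarting at a suprathreshold θ₀; the
threshold is the geometric mean (multiplicative steps ⇒ geometric mean) of
reversal values pooled over the last five runs, discarding the first two
reversals of each run as the descent transient. Without that discard the
estimate is biased toward easy values by an amount that grows with θ₀;
with it, the converged PC measured over replicate staircases is 0.79–0.81
across psychometric slopes and start ratios up to ~8×. Run length defaults
to 80 trials (not specified by the source; chosen for stable reversal
counts). Runs with fewer than two reversals are flagged, and a block whose
testing PC exceeds 0.90 is flagged for retraining.

Testing blocks draw fresh stimuli per trial. For the size and edge tasks the
mean images are nonlinear in θ and are re-rendered (and cached) per distinct
θ; for the interior task they are exactly linear in θ, so only a unit
difference response is ever rendered. A closed-form "analytic responder"
(Bernoulli at Φ(SNR_eff(θ)/√2)) is available for fast training runs; it is
exact for the linear-observer model and is used where trial images are not
needed.

## Classification images

Per trial, the score-weighted field is (O − PC)·J/(J−1)·(n̂⁺−n̂⁻)/(Σ̂+σ_Q²),
with PC the plug-in sample estimate (hence the J/(J−1) factor) and the
denominator the condition's own spectrum (standard variant) or the
unapodized spectrum with the matched unapodized fields (unapodized variant);
σ_Q² is always included — it is what keeps the strongly apodized
denominators nonzero. Long blocks are accumulated streamingly (sums of the
fields and of outcome-weighted fields), which is algebraically identical to
the per-trial average and keeps memory constant.

Smoothing applies, in order: a 4th-order Butterworth spatial window
(half-max radius 7.5 mm), a 4th-order Butterworth frequency window (half-max
0.4 cyc/mm) with the imaginary spectrum zeroed (enforcing symmetry), and
averaging over one-pixel-wide radial annuli (the source gives no band width;
one pixel is the finest choice consistent with the grid). The frequency
window is applied before radial binning. Spectral features integrate power
strictly below 0.35 cyc/mm (the printed bound is ambiguous between < and ≤;
with ΔFreq ≈ 0.0114 the difference is at most one annulus).

Differential sampling efficiency is the per-frequency-bin gradient of
(SNR_w/SNR_IO)², with each perturbation symmetrized in the spatial domain
and multiplied by the spatial window before evaluation. Two routes are
implemented: a closed-form gradient of the quadratic form (one FFT for all
bins), and a central finite difference. The finite-difference step satisfies
the rule that it change the template SD by under 1%; because the step bound
itself leaves visible curvature error, the default step is 1% of the
closed-form bound, at which the two routes agree to ~10⁻⁴ relative. At the
Ideal-Observer template the gradient vanishes identically (stationarity of
the maximum), which is used as a test anchor.

## What the synthetic experiments show — and what they do not

The synthetic data generator reproduces the statistical structure the
analysis assumes: stationary Gaussian noise with known spectrum, linear
decision variables, binomial trial outcomes near 80% correct, and the study
trial counts (6 staircase runs; 2000 testing trials; 10 analysis sessions of
200 trials). Passing tests therefore establish the *internal consistency*
of the pipeline — that thresholds, efficiencies, classification images and
their spectra are recovered correctly when the generating model is the
assumed one. They do not establish anything about human readers: human
efficiencies, apodization effects and spectral-feature contrasts are
empirical results outside the reach of simulation, and the human-range
roster targets are inputs. Nonlinear or uncertain observers, channelized
models, and non-Gaussian or nonstationary CT noise are out of scope.

## Problem sizes used in the checked experiments

Acceptance-level checks run at the study's native sizes where the quantity
demands it (10⁴ Monte-Carlo trials for the 2AFC consistency check, 2000
trials for classification-image recovery, 50 replicate staircases, 8×200
trial sessions per apodization level for the unapodized-invariance check);
unit tests use reduced grids (288² object patches) and short blocks where
the property under test is size-free.
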