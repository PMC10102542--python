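# Methods

This note documents the models, conventions and numerical choices behind
`phtrace`, and what the synthetic-data validation does and does not show
about real recordings.

## Timing and window conventions

Frames are 1-based in files and 0-based internally; frame k (0-based) is
stamped at its start, t = k / frame_rate. All windows given in seconds are
half-open `[start, end)` and are mapped to frames via `searchsorted` on the
timestamp vector. Window lengths in seconds convert to frames by rounding
half up with a minimum of one frame ("1 s" is 5 frames at 5 fps, 20 at
20 fps).

Moving averages are **centered**, with truncated edges (edge outputs
average the frames actually available), so smoothing introduces no
systematic lag into plateau estimates. The plateau estimators (Max, Min)
smooth the windowed segment only, so baseline frames cannot leak into a
plateau estimate across the window boundary.

## Preprocessing

The corrected trace is F = ROI − background, elementwise; no bleach model
is fitted. Rationale: the background ROI, placed inside the animal next to
the signal ROI, bleaches at a similar rate as the signal ROI, so
subtraction corrects bleaching to first order, and explicit bleach
regression under an alternating light protocol is unstable. ΔF/F₀ uses
F₀ = mean F over `[0, stim_start)`; the pre-stimulation mean of ΔF/F₀ is
therefore zero by construction, and the normalization is invariant to
rescaling F by any positive constant. F₀ ≤ 0 (background brighter than
signal) is a hard error, not a NaN.

## Responder classification and exclusions

A trace is a **strong responder** iff the maximum of the 1 s moving average
of F over the stimulation window exceeds `m + max(k·s, floor)`, with m and
s the raw (unsmoothed) pre-stimulation mean and sample SD (ddof = 1),
k = 3, and floor = 2 a.u. The absolute floor guards quiet baselines where
3 SD is within camera noise; it is camera-dependent and configurable, and
synthetic cohorts must choose baseline/noise scales at which 2 a.u. is
meaningful (the defaults do: baseline 100 a.u., corrected-trace noise SD
≈ 2 a.u.).

Two shape exclusions are applied independently of the fits:

- `post_stim_increase`: the smoothed post-stimulus maximum exceeds both the
  smoothed in-stimulus maximum and the responder threshold **and** peaks at
  least 1 s after light-off. The grace second matters: the evoked peak
  commonly straddles the light-off boundary, and without it noise makes
  the flag a coin flip on perfectly clean decaying traces.
- `spontaneous_event`: a smoothed pre-stimulus excursion crosses the
  threshold computed from **robust** baseline statistics (median and
  1.4826 · MAD). Robust statistics are essential here, not cosmetic: a
  spontaneous event sits inside the very window used to estimate the
  baseline, and with mean/SD statistics a bump of any height inflates its
  own threshold enough to mask itself (smoothed max ≈ h·min(w,5)/5 versus
  threshold ≈ h·(w/50 + 3·sqrt(w/50·(1−w/50))) for a bump of height h over
  w of 50 baseline frames — the ratio never exceeds 1 at k = 3).

Fit-stage failures are folded back into the verdict: `unfittable_rise`
(rise plateau ≤ 0, i.e. no increase during stimulation) and `no_decay`
(the smoothed post-stimulus segment ends higher than it starts). Excluded
animals keep their row in the results table, with reasons, and contribute
nothing to group statistics.

## Constrained exponential fits

Both fits have a single free parameter, τ:

- rise over `[stim_start, stim_end)`: f(t) = f₀ + (Max − f₀)(1 − e^(−(t−t₀)/τ)),
  f₀ = 0; Max = maximum of the five-frame moving average of ΔF/F₀ over the
  stimulation window extended by 1 s ("immediately after"; the margin is
  configurable).
- decay over `[stim_end, trace_end)`: f(t) = (f₀ − Min)·e^(−(t−t₀)/τ) + Min,
  f₀ = Max as above; Min = minimum of the 5 s moving average of ΔF/F₀ after
  stimulation.

t₀ is the first frame time at or after the transition. With frame-aligned
stimuli the at-or-after convention makes the model origin coincide with
the true signal origin; a strictly-after convention would shift the origin
one frame late and bias every recovered τ.

τ is minimized by unweighted least squares over τ ∈ [frame interval,
10 × window length]: the interval is split into eight log-spaced
sub-brackets, each minimized with bounded Brent (xatol 1e-10), and the best
minimum kept. The problem is one-dimensional, so the optimizer is checked
against an exhaustive 10⁴-point log-grid search — agreement within one grid
step on every tested trace, no local-optimum caveats. Degenerate
configurations (Max ≤ f₀, or f₀ ≤ Min, with a 1e-12 tolerance for float
dust) raise instead of returning garbage, and feed the exclusion flags.
The residual sum of squares is reported per fit for downstream QC; no
automatic SSE threshold is applied (log-only, mirroring manual fit
inspection).

**Known bias.** Fixing the rise plateau to the *maximum* of a smoothed
noisy trace makes it an order statistic: at the default noise level
(pre-stim ΔF/F₀ SD ≈ 0.02, amplitude 0.2) Max is inflated by roughly
+2σ of the smoothed noise (≈ +4–9% of the amplitude), and the fitted τ_rise
responds with ≈ 2.9× that relative error — a systematic ≈ +11% median
τ_rise bias, reported (not hidden) by the acceptance script. τ_decay is
much less affected (≈ +4%) because its plateau enters as f₀, to which the
fit is less sensitive. A free-but-bounded plateau would remove the bias at
the cost of a second parameter; the single-free-parameter design was kept
because it makes the fits exhaustively verifiable.

## Amplitude and releasable fraction

Amplitude is the mean ΔF/F₀ over the reporter-mode window: the last 5 s of
stimulation for the green reporter (seconds 15–20 of the standard
protocol), the first 1 s after stimulus end for the red reporter (whose
in-stimulus frames are contaminated by the actuation light).

In the cultured-neuron assay the releasable fraction is
RF = F_MaxStim / F_NH4Cl, with F_MaxStim the maximum of the 1 s moving
average of ΔF/F₀ during stimulation and F_NH4Cl the mean ΔF/F₀ over the
85–90 s window of the NH₄Cl (pH 7.4) phase, during which the entire
vesicular pool is dequenched. RF is undefined (an error) when the protocol
has no NH₄Cl phase covering the reference window or when the reference
level is not positive.

## Synthetic-data generator

Defaults are the wild-type-like study conditions: amplitude 0.21, τ_rise
2.3 s, τ_decay 15.2 s, baseline 100 a.u., background 50 a.u., additive
Gaussian camera noise 1.4 a.u. per channel and frame (giving pre-stim
ΔF/F₀ SD ≈ 0.02 after subtraction), bleach 1e-4 /s on both channels,
log-normal between-animal variability with CV 0.2, 5 fps / 90 s protocol
with a 10 s stimulus after 10 s. The bleach default deliberately sits in
the regime where background subtraction corrects bleaching to ≈ 1% τ bias
over 90 s — the regime the assay operates in; at 20× that rate the
subtraction-only pipeline would carry a +50% τ_decay bias and the method's
premise would not hold. Noise is Gaussian and frame-independent (camera
read noise dominates at these intensities); a Poisson mode is deliberately
omitted.

**Phenomenological mode** emits exactly the fit model: ΔF/F₀ is 0 before
the stimulus, amp·(1 − e^(−(t−t_on)/τ_eff)) during it, and decays
exponentially from the reached level afterwards. Pulsed stimulation scales
the effective drive by the duty cycle (0.2 for 100 ms pulses at 2 Hz), so
τ_eff = τ_rise / duty. In red-reporter mode an optional photoswitching
artifact (a transient decaying from light-off) emulates the spurious
post-stimulus increase of no-ATR controls. Conversion to a.u.:
ROI = (background + baseline·(1 + ΔF/F₀))·e^(−λt) + noise, background
channel = background·e^(−λt) + independent noise — both channels bleach at
the same rate, which is what makes subtraction a bleach correction.

**Mechanistic mode** tracks reporter fractions: surface S (bright) and
vesicular V = 1 − S (brightness q, the quench factor, default 0.05 — a
free modelling choice, no measured quench ratio exists for these fusion
constructs). A releasable pool ρ·(1 − S₀) of the vesicular reporter is
driven to the surface at k_exo = 1/τ_rise while the light is on (within
pulses only, in pulsed mode); endocytosis returns evoked surface reporter
to the releasable pool at k_endo = 1/τ_decay. Because retrieved reporter
re-enters the releasable pool, sustained saturating light holds the whole
releasable fraction on the surface — a plateau, as observed — and RF
recovers ρ exactly in the saturating limit; a hard once-only release
budget was rejected because it makes the signal sag during the stimulus
and biases RF low by the ratio (1 − e^(−k_endo))/k_endo. The resting
surface fraction S₀ (default 0.05) is held by the balanced spontaneous
exo/endocytosis cycle. Fluorescence is S + qV in saline, S + V under
NH₄Cl, q(S + V) under the pH 5.6 acid buffer (below baseline whenever
S₀ > 0). Integration is fixed-step explicit Euler at ≥ 10× the frame rate;
a step that drives any pool out of [0, 1] raises an instability error
rather than clamping. Frames during buffer phases can be thinned to one
per 5 s, emulating the reduced acquisition rate used to limit bleaching.

Cohorts draw per-animal parameters log-normally (positivity; CV 0.2) from
independent substreams spawned from a master seed, so growing a cohort
never perturbs the animals already drawn, and the responder flag is
Bernoulli. Every drawn parameter lands in the ground-truth table.

**What passing tests do not show.** The generator has no motion artifacts,
no focal drift, no gut autofluorescence, no photoswitching in green mode,
Gaussian rather than Poisson noise, and exponential rather than
multi-phase recycling. Validation against it demonstrates that the
pipeline recovers the parameters of its own model class under realistic
noise — not that real traces follow that model class.

## Group statistics

Thin wrappers over scipy/statsmodels, chosen per metric: amplitudes are
compared with unpaired t (two groups) or one-way ANOVA with Dunnett
comparisons against the first group; time constants, being right-skewed,
with Mann–Whitney (two groups) or Kruskal–Wallis followed by pairwise
Mann–Whitney with Holm–Šídák adjustment. The τ_decay-vs-amplitude check
uses Spearman rank correlation (robust to the skew; ≥ 3 animals required).
SEM is computed over animals, not biological replicates.

## Determinism

All randomness flows from explicit integer seeds (numpy Generator /
SeedSequence). The full simulate → analyze → summarize chain is
bit-reproducible: identical master seeds give byte-identical CSVs. Output
files carry 12 significant digits, which round-trips every double the
pipeline produces at the 1e-11 level.

## Problem sizes used in validation

Grid-oracle agreement uses a 50-trace cohort (≈ 100 fits) against 10⁴-point
grids; exact recovery a 5-point τ sweep (2–40 s); noisy recovery a
100-trace cohort; the classifier null rate 10⁵ vectorized noise traces;
RF recovery 3 noiseless saturating-drive simulations plus a 50-cell noisy
cohort; the demo cohorts 8–60 animals. These sizes give the Monte-Carlo
margins used in the assertions (binomial 3σ, 3 SEM) while keeping the whole
validation run in the tens of seconds.
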