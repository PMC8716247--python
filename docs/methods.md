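# Methods

`erdkit` analyzes trial-structured EEG from a two-condition lower-limb
motor-imagery (MI) paradigm — high-frequency imagery (HFMI, four imagined
leg raises per 4 s) versus low-frequency imagery (LFMI, two raises) — and
ships a parametric simulator of such recordings so the whole chain is
testable against known ground truth. This note documents the models, the
defaults and why, the numerical choices, and what the synthetic validation
does and does not show about real data.

## Trial model and time convention

A trial is baseline (2 s) → visual cue (1 s) → motor imagery (4 s) → relax
(4 s), sampled at 1000 Hz by default. Time is measured relative to MI onset:
`t = 0` starts the imagery window, so an epoch spans `[-3, 8)` s. All
windows are half-open `[start, end)` in seconds; cropping uses integer
sample arithmetic so repeated crops are exact.

## Synthetic ERD-EEG generator (`erdkit.synth`)

Each channel of each trial is the sum of:

* **1/f background noise** — white Gaussian noise spectrally shaped to a
  `1/f^exponent` power spectrum (exponent 1.0 by default, flattened below
  0.5 Hz), normalized to unit standard deviation per trial and channel and
  scaled by `noise_amplitude` (default 1.0).
* **Two band-limited oscillators** (alpha and beta) at per-subject peak
  frequencies drawn once per subject from the integers 8–11 Hz (alpha) and
  17–21 Hz (beta). Each oscillator is a *constant-envelope* sinusoid with a
  random phase and a per-trial Gaussian frequency offset (FWHM 1.0 Hz for
  alpha, 2.0 Hz for beta): trial-to-trial frequency scatter broadens the
  spectral line (inhomogeneous broadening) while the constant envelope makes
  per-trial band power deterministic. This is the one deliberately
  unrealistic simplification in the generator — real sensorimotor rhythms
  wax and wane within trials — and it is what makes an injected dB drop
  *exactly* recoverable. A stochastic-envelope (filtered-noise) oscillator
  was evaluated first; its burst-envelope sampling noise puts ±0.6 dB of
  scatter on 40-trial ERD estimates, which would drown the quantity the
  recovery tests need to measure. Default amplitudes: alpha 1.2, beta 0.9
  (alpha is the sharper, more prominent rhythm), giving an oscillator-to-
  noise ratio of roughly 25 inside the oscillator band.

**ERD injection.** During the MI window the oscillator amplitude is scaled
by `g = 10^(depth_db / 20)` with 200 ms raised-cosine ramps at the window
edges (ramps avoid spectral splatter). Band power therefore drops by exactly
`depth_db` dB before noise dilution. Depth is per condition × band ×
channel: the per-channel weight (`erd_spatial_profile`, default
`0.2 + 0.8·exp(-i/2)` over a vertex-out montage ordering) makes the ERD
focal at Cz, as expected for the leg sensorimotor representation, and is
what gives the two classes different *spatial patterns* of band power — the
contrast CSP exploits. Default condition depths are the emulated study's
group means recomputed from its per-subject table: HFMI −1.867 dB alpha /
−3.449 dB beta, LFMI −1.349 / −2.289.

**Cohorts.** Subject `k` uses sub-seed `seed + k`. Per-subject depth
variability is a Gaussian jitter per band shared by both conditions
(σ = 0.35 dB, subject "responsiveness", which also induces the strong
between-condition correlation seen in real cohorts) plus an independent
per band × condition term (σ = 0.15 dB); jittered depths are clipped at 0.
Configured 0 dB depths stay exactly 0 (no-ERD conditions remain null).
Identical config + seed gives byte-identical output.

Out of scope by design: volume conduction (channels are independent),
EMG/EOG/line-noise artifacts, and ERS (post-movement power increase).

## Preprocessing (`erdkit.preprocess`)

Zero-phase forward–backward Butterworth band-pass (order 4 per pass),
0.1–30 Hz by default, applied per channel per trial with reflection padding
of `min(n-1, 3·fs/low_cut)` samples. Zero-phase filtering preserves ERD
latency. Known limitation: a 0.1 Hz high-pass has a ~1.6 s time constant, so
epoch edges carry a slow transient that no finite padding removes; it is
confined below ~2 Hz and decays within a few seconds of each edge. The 1–3
Hz rows of an ERSP computed from an epoch whose baseline abuts the epoch
start are therefore unreliable; the 8–30 Hz analyses are unaffected.

## ERSP, ERD and the energy curve (`erdkit.spectral`)

The event-related spectral perturbation is the trial-averaged
magnitude-squared STFT, `ERSP(f,t) = (1/n) Σ_k |F_k(f,t)|²`, converted to dB
relative to the per-frequency mean power over a pre-MI baseline interval
(default −2.5 to −0.6 s, i.e. all pre-MI data whose analysis windows stay
inside the epoch). The raw power average is retained on the map (`power`),
so unions of trial sets stay linear pre-dB. The frequency axis is restricted
to 1–30 Hz.

STFT defaults: 1 s Hann window, 90 % overlap, zero-padding to a 1 Hz grid.
A 0.5 s window was evaluated and rejected: its main lobe is ~4 Hz wide at
the nulls, which smears the alpha and beta ERD troughs into each other and
biases the characteristic frequency by up to 2 Hz; the 1 s window makes the
effective resolution match the 1 Hz grid.

* **Mean ERD** over a band × window rectangle is the arithmetic mean of the
  dB surface over bins whose centers fall inside (edges inclusive). More
  negative = stronger desynchronization.
* **Energy curve**: per-frequency mean dB over the MI window; baseline sits
  at 0 dB.
* **Characteristic frequency**: argmin of the energy curve inside a band's
  search range (alpha 8–13 Hz, beta 14–30 Hz); ties break to the lowest
  frequency. The **characteristic band** is the maximal contiguous run of
  bins around the argmin, inside the search range, with energy strictly
  below 0 dB; clipping to the search range keeps the alpha and beta bands
  from merging through incidental sub-baseline bins between them. A curve
  that never dips below baseline in the range returns a flagged no-ERD
  result rather than an error or a fabricated frequency.
* **Spectral entropy**: the window-averaged STFT power is normalized to a
  discrete probability over frequency bins (any multiplicative constant in
  the density definition cancels), and `H = −Σ pᵢ ln pᵢ` is reported in
  nats with `0·ln 0 := 0`, so `0 ≤ H ≤ ln(n_bins)`.

ERD-recovery validation measures the band mean over the injected peak ±1 Hz
and the window 0.5–3.5 s: the trimmed window keeps analysis bins whose 1 s
windows lie inside the (ramped) MI interval, so the measured value is
attributable to the injected depth rather than to edge dilution. Expected
residual bias at −3 dB injection with the default SNR is ≈ +0.2 dB toward
zero (noise-floor dilution).

## CSP (`erdkit.csp`)

Per-trial spatial covariances are trace-normalized (removing trial-level
global amplitude) and averaged per class. Filters solve the generalized
eigenproblem `Σ₁ w = λ (Σ₁+Σ₂) w` via the whitening route: eigendecompose
the (optionally ridge-regularized, ε = 1e−10) composite covariance, whiten,
eigendecompose the whitened class-1 covariance. Columns are sorted by
descending class-1 eigenvalue λ ∈ [0,1] (the class-2 share is 1−λ), and each
filter is scaled so its largest-magnitude coefficient is positive, making
output reproducible across eigensolvers. The retained set is the first and
last `n_pairs` columns (default 3 pairs — the standard eigenvalue-extremes
selection). Features are `log(var_j / Σ var)` of the retained projections:
the variance-share form is invariant to global trial scaling. Tests verify
the whitening contract `Wᵀ(Σ₁+Σ₂)W = I` and equivalence with a dense
generalized eigendecomposition to 1e−8.

## Recognition rate (`erdkit.classify`)

Epochs are band-passed to 8–30 Hz (where the ERD contrast lives) and cropped
to 1–4 s after MI onset, then scored by stratified 10-fold cross-validation.
Inside each outer training fold, CSP filters are fitted and the RBF-SVM cost
C is chosen from {0.001, 0.01, 0.1, 1} by an inner stratified 5-fold grid
search on the training portion only — fitting CSP on all data before
splitting would leak test information into the filters, so nesting is used
even though a flat protocol would score higher. γ follows the "auto"
convention (1 / number of features); ties in inner-CV score go to the
smallest C (strongest regularization).

Per-condition recognition tables are produced by decoding each condition's
MI-window epochs (1–4 s) against same-length rest epochs cut from the relax
period (5–8 s) of the same trials, re-anchored to a common time axis. This
realizes "one recognition rate per condition" with a single binary decoder
per condition, and makes the rate increase with that condition's ERD depth.

## Statistics (`erdkit.stats`, `erdkit.reference`)

Sample standard deviations use the n−1 denominator — the convention that
reproduces the consistent printed STD cells of the reference tables.
Paired comparisons use the two-tailed paired t-test (df = n−1); association
uses Pearson r. Zero-variance inputs yield explicitly flagged degenerate
results, never a silent number. No multiple-testing correction is applied
(none is applied in the emulated study). `erdkit.reference` ships the
published per-subject values and documents, cell by cell, which printed
summary rows are inconsistent with their own columns; recomputation from
per-subject values is authoritative throughout the package, and the
inconsistent printed cells are excluded from exact tests.

## Pipeline (`erdkit.pipeline`, CLI `erdkit`)

simulate → analyze → classify → report, each stage reading the previous
stage's files (delimited text + JSON), writing per-subject artifacts and a
manifest of SHA-256 content hashes. The ERD summaries quantify each
subject's ERD over their own recovered characteristic band (falling back to
the search band on a no-ERD result). Stage failures leave partial outputs
plus a `FAILED` marker naming the stage. EDF+ epoch files (one per subject,
one data record per trial, `MI/<condition>` annotations at MI onsets) are
written natively and read back through MNE.

## Problem sizes used in tests

The test and acceptance runs use reduced problem sizes — 160–250 Hz
sampling, 4–8 channels, 12–60 trials per condition, cohorts of 6–10
subjects — chosen so the full validation (including a 50-cohort replication
of the group-level ordering) completes in minutes while keeping every
estimator in the regime where its tolerances are meaningful. All sizes are
configuration, not code: the defaults reproduce the emulated study's
geometry (1000 Hz, up to 64 channels, 10 subjects).

## What passing tests show — and what they do not

The synthetic validation establishes that the implementation is correct:
injected depths, peaks and orderings are recovered at known tolerances, CSP
matches an independent eigensolver, and the decoder behaves at chance under
the null. It does not establish that real lower-limb MI data behave like
the generator: real EEG has within-trial rhythm bursting, coherent volume
conduction across channels, artifacts, and non-Gaussian noise, all absent
here. Conclusions about the emulated study itself are limited to its
printed per-subject tables, which the statistics layer reproduces exactly
where they are internally consistent.
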