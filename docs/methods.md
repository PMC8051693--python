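# Methods

This note records the models implemented, the estimator and parameter
choices that were genuinely open, what the synthetic generator does and
does not emulate, and the numerical conventions. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Hypnogram dynamics

**Markov model.** The scored hypnogram (one label per 5-s epoch) is
modelled as a first-order Markov chain on (W, NREM, REM). The transition
probability P(X/Y) is the count of Y→X epoch successions divided by the
count of Y epochs that have a successor; marginal state probabilities are
label frequencies over non-artifact epochs. The fragmentation index is
FI(X) = 1 − P(X/X), in [0, 1].

**Artifact handling.** Artifact epochs are spliced out before transition
counting: an epoch pair that would span a removed artifact is *not*
counted (no bridging). FI of a state never observed with a successor is
missing (NaN), never 0 — REM is routinely absent after strong REM
suppression, and a silent 0 would read as "perfectly stable".

**Per-recording vs pooled estimation.** For paired statistics each
recording gets its own row-normalised matrix (the subject is the unit of
analysis). For parameter recovery across a cohort,
`pooled_transition_matrix` sums succession counts before normalising:
averaging per-recording probabilities is biased for rarely visited rows
(≈300 REM epochs per 6-h session gives a per-subject REM-row bias of
~0.003–0.01), while the pooled estimator is the MLE of the shared chain.

**Latency censoring.** Latency to a state that never occurs is the full
recording duration (21,600 s for 6 h) with `censored=True`, so survival
analysis can treat it correctly rather than as an observed event.

**Binning conventions.** Epoch k covers samples [k·epoch_s·fs,
(k+1)·epoch_s·fs) (0-based, half-open). Per-bin transition counts assign
a transition to the bin of its destination epoch. Bout histograms use
[k·w, (k+1)·w) bins with w = 10 s (wake) and 50 s (NREM) by default,
normalised to probabilities.

## Epoch selection for EEG measures

All EEG measures (power, coherence, NSTE, LZc) run on artifact-free,
*non-transition* epochs: an epoch is retained iff it is not an artifact
and its label equals both neighbours' labels (edge epochs are compared to
their single neighbour). This is the strictest common reading of
"non-transition"; it discards the first and last epoch of every bout.
States with zero retained windows are reported missing rather than padded.

## Multitaper spectra and coherence

5-s windows at 512 Hz (2560 samples), K = 3 DPSS tapers with
time-bandwidth product NW = 2 (half-bandwidth 0.4 Hz), eigenspectra
averaged with equal weights; the frequency grid is 0.2 Hz. Tapers are
unit-energy, so the one-sided PSD integrates to the window variance
(Parseval, verified within 5% on noise).

Band powers are PSD *integrals* over [f_lo, f_hi), with the 45–75 Hz gap
removed from every quantity (band powers, coherence band means, the
complexity filter); shares are normalised by the sum over the seven
scheme bands, hence scale-invariant and summing to 1.

Coherence is |S_xy| / √(S_xx S_yy) with auto/cross spectra averaged over
tapers *and* windows (≥2 windows required; a single-window coherence is
identically 1). Fisher z = atanh(C) is applied after window averaging,
with C clipped at 1 − 1e-6 so identical channels stay finite. Whether to
transform before or after averaging is not pinned by conventional usage;
transforming the averaged coherence was chosen and is the only supported
path.

Line noise: synthetic data has none; for real recordings a fixed 60/120 Hz
notch can be applied upstream. No multitaper regression line-noise removal
is implemented.

## Normalized symbolic transfer entropy

Ordinal-pattern symbolisation with embedding dimension dE = 3 and
per-band delays τ = 64, 28, 17, 9, 6, 2 samples at 512 Hz for
δ(0.5–4), θ(4–9), σ(9–15), β(15–30), low-γ(30–45), high-γ(75–115).
Ties rank by temporal order (earlier sample lower), making symbolisation
deterministic and invariant under strictly monotone amplitude transforms.

Per 5-s window and direction, TE(X→Y; δ) = H(Y_{t+δ}|Y_t) −
H(Y_{t+δ}|Y_t, X_t) with plug-in entropies from the window's joint symbol
counts (no pooling across windows). The normalised statistic is

    NSTE = (TE − ⟨TE_shuffled⟩) / H(Y_{t+δ}|Y_t), clipped to [0, 1],

with 20 full time-permutations of the source symbol series as the shuffle
ensemble (seeded; the permutations are shared across candidate δ, since
the shuffle bias depends on the marginal symbol distribution, not the
lag). δ is searched over 1–50 samples independently per direction and the
maximum *normalised* value kept. The exact normalisation used in the
lineage this statistic comes from is not printed in standard references at
this level of detail; the construction above is the package's documented
choice.

**Null behaviour worth knowing.** On independent *broadband* signals the
mean NSTE is ≪ 0.05. On independent signals band-passed into a *narrow*
band (e.g. θ with τ = 28), the mean null NSTE rises to ~0.1: within a
single 5-s window two independent narrowband signals hold a nearly fixed
phase relation, which is genuine within-window dependence, inflated
further by the max-over-δ selection. Between-condition contrasts are
paired per band, so this common-mode offset cancels; absolute NSTE values
in narrow bands should not be read as evidence of coupling on their own.

Filters: zero-phase (forward-backward) order-4 Butterworth band-pass,
unit passband gain, shared with the spectral module.

## Lempel-Ziv complexity

Pipeline order (a documented choice; the processing chain is not fully
pinned by convention): local linear detrend → low-pass 115 Hz + band-stop
45–75 Hz (zero-phase order-4 Butterworth) → [surrogate generation here]
→ Hilbert amplitude → 5-s windows → binarise at the window mean (ties →
0) → LZ76.

The detrend fits straight lines in 1-s windows sliding by 0.5 s and
blends overlapping fits with triangular weights (window ≪ epoch, ≫ the
high-γ period; the method's window length is not standardised).

LZ76 counts words in the exhaustive sequential parse: a new word is the
shortest extension not copyable from anywhere in the preceding history
(copies may self-overlap); a trailing incomplete word counts. The
implementation is verified against an independent naive
reproduce-or-extend parser on all 8,190 binary strings of length ≤ 12.

Correction: raw count / mean count over N = 50 phase-randomised
surrogates (random uniform phases on the rFFT of the *filtered* signal,
conjugate-symmetric, one independent draw per surrogate, seeded per
window), each surrogate re-run through amplitude → binarise → parse.
White noise scores ≈1 (its surrogates are statistically identical);
values below 1 indicate dynamics more regular than their spectrum
predicts. A constant-amplitude deterministic sinusoid plus noise can
score *above* 1 (its Hilbert envelope is flat, so binarisation digitises
the noise, while the narrowband surrogates have slow Rayleigh envelopes)
— an estimator property, not a bug; realistic waxing/waning rhythms score
below 1.

## Synthetic generator: the stated world

**Chains.** Default control/treatment transition matrices are the
printed group means of the study this package models, each row
renormalised to sum exactly 1 (printed means don't): control rows
W = (0.9205, 0.079, 0), N = (0.031, 0.9621, 0.0072), R = (0.0625, 0.003,
0.9621); treatment rows W = (0.8983, 0.1017, 0), N = (0.060, 0.9384,
0.0017), R = (0.0833, 0.011, 0.9052). The source prints 0.9621 ± 0.003
for both control p(N→N) and control p(R→R) — possibly a transcription
duplicate; the value is used verbatim. W→REM is 0 by default (never
observed empirically) but can be overridden. Sessions are 4320 epochs
(6 h), initial state W (animals are injected awake). Per-subject
variability is Gaussian jitter (sd 0.01, about the printed SEM scale) on
the diagonal probabilities, off-diagonal mass rescaled.

**EEG.** Per state, a sum of sinusoidal oscillators on 1/f background
noise (unit-sd, exponent 1): wake has low-amplitude θ (7 Hz, 0.3) and
fast (35 Hz, 0.2) activity; NREM has high-amplitude waxing/waning slow
oscillations (0.75 Hz, amp 3.5, AM 0.3 Hz depth 0.8), δ (2.5 Hz, 2.0)
and σ spindles (12 Hz, 0.5, fully modulated); REM has θ (7 Hz, 1.5)
stronger occipitally. Oscillator (and modulation) phases are drawn once
per *bout*, not per epoch, to avoid an artificial 5-s periodicity.
Amplitude modulation exists because real slow-wave and spindle trains wax
and wane; it is also what gives NREM a corrected LZc below wake's — a
constant-amplitude oscillator would not (see above). Directed coupling is
delayed linear mixing (default frontal→occipital, 20 ms, gain 0.5),
giving an analytically known direction for NSTE recovery. EMG is white
noise with per-state RMS (wake 1.0, NREM 0.2, REM 0.05).

Where a test scenario needed an unstated noise level (the direction-
recovery null adds "+ noise" to a delayed copy at gain 0.8), independent
white noise at σ = 0.5 of the unit-σ source was fixed once.

**What the generator does not emulate** — hence what a green test does
not establish: biophysical waveforms (K-complexes, sawtooth θ, spindle
morphology), circadian/homeostatic drift across the 6 h, mains noise,
artifacts with realistic spectra, volume conduction, or non-Markov bout
statistics (real bout durations are heavier-tailed than geometric).
Recovery tests certify the estimators, not the biology.

## Statistics

Wrappers over scipy/statsmodels/lifelines with the package's contracts:
pairs with a missing side are dropped and counted; one-tailed directions
are configuration (pre-registered), never inferred from the data; Wilcoxon
drops zero differences and uses the exact null for n ≤ 25; BH is the
step-up procedure at FDR 0.05; the survival endpoint is Kaplan-Meier
probability-of-no-state with log-rank between arms (the specific survival
test is the package's choice). Identical-arm simulated cohorts calibrate
each paired test's rejection rate to α within binomial error (500
replicates, seeded, in the acceptance suite).

## Limitations

- EDF input is not supported (no EDF reader in the dependency set); use
  CSV or .npz exports.
- NSTE is bivariate; no conditional/multivariate variant.
- The repeated-measures ANOVA family is intentionally out of scope; the
  pipeline emits tidy per-subject tables ready for external tools.
- Runtime: NSTE with the full δ search is O(n_δ × n_shuffle) entropy
  evaluations per window (~0.1 s); whole-session, all-band runs are
  minutes per subject, not seconds.
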