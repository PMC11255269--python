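# Methods

## Task and data model

The package analyses an auditory go/no-go discrimination task: a 1-s pure
tone (3 kHz or 12 kHz), a 2-s response window, and a 4–6-s inter-trial
interval.  Four session types are modelled:

| session   | composition                     | phases (T1/T2/T3) | early/late split |
|-----------|---------------------------------|-------------------|------------------|
| Stable    | 50% go / 50% no-go              | thirds            | 67 / 33 %        |
| Uncertain | 40 go / 40 no-go / 10 RO / 10 UR| thirds            | 67 / 33 %        |
| Reversal  | 50/50, tone–outcome swapped     | 15 / 35 / 50 %    | 15 / 85 %        |
| Re-stable | as Reversal, after re-learning  | thirds            | 67 / 33 %        |

RO trials play the go cue but withhold reward after a correct lick; UR
trials deliver reward with no tone (and no modelled choice).  Phase
boundaries round half-up on cumulative fractions, the last phase absorbing
the remainder; boundaries depend only on the trial count and the fractions,
never on trial content.  Whether a non-divisible n rounds up or down at a
boundary is a convention; the choice here (round-half-up) reproduces the
printed splits for the usual session lengths (e.g. 15/35/50 at n = 100) and
is recorded in the outputs.

Performance is d′ = Φ⁻¹(Hit rate) − Φ⁻¹(FA rate).  Correct licks on RO
trials count toward the Hit rate (the choice was correct; only the outcome
was withheld).  Degenerate rates 0 and 1 are clipped to 1/(2n) — a standard
correction keeping d′ finite; proficiency is d′ ≥ 1.5.

## Calcium processing

Raw traces are min-max mapped to [0, 1] per neuron over the session and
low-pass filtered at 5 Hz with a 4th-order Butterworth applied
forward–backward (zero phase; ≥ 20 dB attenuation at 10 Hz).  The mapping
is applied before ΔF/F (raw → map → filter → ΔF/F); the statistics consumed
downstream (two-fold ratios, z-scores, SI) are invariant to the positive
affine rescaling, so this ordering choice does not propagate.  ΔF/F uses a
robust per-trial baseline: F₀ is the mean of the 2-s pre-stimulus samples
lying between the 25th and 75th percentiles (inclusive; linear-interpolation
percentiles).  Event-aligned z-scores subtract the mean of the 0.5 s before
the event and divide by the sample s.d. (n − 1); zero-s.d. or non-positive-F₀
entries are flagged invalid and excluded rather than patched.

Responsiveness is a paired Wilcoxon signed-rank test of per-trial stimulus
vs baseline window means (P < 0.05), signed into activated/suppressed by the
median difference.  Onset detection smooths each trial with a 3-frame moving
average and rank-sum tests each post-stimulus frame against the pooled
per-trial baseline means (P < 0.01); onset is the first significant frame
and is left undefined — not clamped — when no frame qualifies.  Because the
frames are tested sequentially without multiplicity correction, pure noise
can occasionally produce a spurious onset; the screen is intended for
neurons that already passed the responsiveness test.

## Functional classification

The two-fold rule `R_high − R_low > |R_low|` (strict inequality, applied to
the stored window means) defines:

- **Outcome monitoring** — Uncertain: mean response in a 1-s window after
  the first response-window lick, RO vs Hit trials.  Reversal: air-puff
  response, early (first 15%) vs late (last 85%) period.
- **Value updating** — Uncertain: go-cue response (1-s post-onset), early
  (first 67%) vs late (last 33%).  Reversal: no-go-cue (3 kHz) response,
  early vs late.
- **Dual-function** — both.

The same inequality form is used in all four contexts.  All neurons are
classified by default (a `responsive` mask can restrict it): restricting to
responsive neurons changes denominators, not the rule.  Neurons with fewer
than 3 trials in a required condition are skipped with a warning.

Selectivity: SI = (R̄_go − R̄_no-go)/σ_p, where σ_p pools the two condition
variances weighted by (nᵢ − 1).  The pooled term is a variance as written;
its square root is taken so SI is in s.d. units.  Significance uses 1000
label shuffles, two-sided on |SI| (a neuron may prefer either cue):
significant when |SI| exceeds the 95th percentile of the shuffled |SI|.

## Geometry, decoding, GLMs

One PCA (SVD on the column-centered time × condition matrix of
trial-averaged z-scores, −0.5 to 1 s) is fitted on the concatenation of all
conditions/sessions so trajectories share one space.  Trajectory length is
the summed Euclidean step in PC1–3 over the 1-s stimulus window; trajectory
distance the summed pointwise Euclidean distance.  The bootstrap draws
40-neuron subsets without replacement (5,000 iterations by default) and
re-fits the PCA per draw — re-fitting, rather than reusing loadings, keeps
each draw a self-contained experiment.

Decoding uses a linear maximum-margin SVM (C = 1; features standardized on
the training split only; fixed solver seed).  Neurons pooled across animals
are not simultaneous, so population vectors are pseudo-trials: each neuron
contributes the window mean of one same-label trial sampled with
replacement.  Real trials are partitioned into class-balanced folds
*before* pseudo-trial construction; training and test pseudo-trials draw
from disjoint real trials.  This matters: resampling first and splitting
pseudo-trials afterwards leaks trial noise and inflates shuffled-label
accuracy far above chance.  Balanced pseudo-trial counts per class also
handle class imbalance without majority-class subsampling.  Features are
window means (0–1 s post-event), not full time courses — per-frame features
are switchable but add dimensionality without changing the planted-structure
conclusions.

The history GLM is OLS of per-trial Hit-trial stimulus responses on the five
preceding outcome indicators (non-reward = 1, reward = 0); the first five
trials are dropped rather than zero-padded to avoid biased lag estimates.
Per-neuron fits are aggregated afterwards (signed-rank of each lag's
coefficients against zero; rank-sum between sessions).  The task-variable
GLM uses stimulus (constant), cumulative unexpected-outcome fraction
(in [0, 1]), previous-outcome indicator, and licking rate (licks/s in the
1-s stimulus window — the window is a package choice); contributions are the
drop in 5-fold held-out explained variance (1 − SSE/SST with SST from the
held-out fold; negative values reported as-is) when a variable is removed,
on identical folds.

## SARSA model with adaptive learning rate

Only 3 kHz-tone trials are modelled.  Per trial: Δr = R − Q(A) for the
chosen action A, Q(A) ← Q(A) + αΔr, and the next trial's learning rate is
α ← clip(θ′α + θ|Δr|, 0, 1).  Defaults: θ′ = 0.6, θ = 0.08, α₀ = 0.1,
Q₀ = (0.98, 0.02); rewards Hit 1, Miss 0.1, RO −0.1, FA −2, CR 0.1; softmax
β = 2.3 (Stable/Uncertain) or 1.68 (Reversal).  Conventions:

- The first modelled trial updates with α₀ directly; the recurrence applies
  from the second trial on.  This makes the θ = 0 closed form
  α_t = θ′ᵗα₀ (t zero-based) exact.
- Only the chosen action's Q is updated, and Δr is computed against it; the
  unchosen Q persists.  No-lick trials update Q(no-lick) with R(Miss)/R(CR)
  by default (`update_nolick=False` disables it).
- α is clipped to [0, 1]: the recurrence can exceed 1 under extreme errors
  (an FA from a high Q gives |Δr| ≈ 3).
- β is fixed per session type; it is not re-derived from behavior.

`recover_parameters` maximizes the Bernoulli log-likelihood of observed lick
choices, replaying the deterministic (given parameters) Q/α trace through
the observed action–outcome sequence; a 7³ grid seeds a Nelder–Mead
refinement, vectorised across equal-length sessions.  The recovery study
uses Uncertain-composition sessions: Stable sessions drive α → 0 early and
leave θ and θ′ weakly identified, whereas recurring reward omissions keep
the learning-rate dynamics excited.

## Synthetic-data generator

Trial types are drawn in exact design proportions (largest-remainder
rounding, uniform shuffle); ITIs are uniform on [4, 6] s.  Choices on the
modelled tone come from the SARSA agent; the other tone licks with a fixed
per-session probability (0.10 where it is the no-go cue, 0.80/0.90 in
Reversal/Re-stable where it is the rewarded cue).  Within-response-window
lick times are uniform on [1.05, 1.8] s — a modelling convenience carrying
no task structure, flagged as such.

Fluorescence per neuron/trial is baseline × (1 + transients + noise) on a
[−2, 4] s window at 30 frames/s.  Transients are single-exponential kernels
(τ = 0.4 s, GCaMP6f-like — the simplest kernel preserving window-mean
structure) at stimulus onset and at outcome delivery (first lick; +1 s for
un-cued rewards), scaled by planted condition/period amplitudes with 20%
multiplicative jitter, plus Gaussian frame noise (s.d. 0.1 ΔF/F units, the
reference SNR).  Planted structure:

- class mix 33% monitoring / 21% updating / 7% dual (largest-remainder
  counts), 5% unresponsive;
- monitoring neurons: RO (and UR) amplitude = Hit × U(2.6, 3.6), and
  air-puff early = late × U(2.6, 3.6) — satisfying the two-fold rule with
  margin; non-class ratios U(0.85, 1.15) stay well below it;
- updating neurons: 3 kHz-cue amplitude early = late × U(2.6, 3.6);
- 30% of neurons carry negative outcome-history weights
  (−0.3, −0.15, −0.05, 0, 0 × U(0.5, 1.5)) on the go-cue amplitude.

What the generator does **not** emulate: correlated noise across neurons,
bursting/nonlinear indicator dynamics, slow drift unrelated to task value,
lick-artefact contamination, or neuropil.  Passing tests therefore show the
analysis code is correct under the stated statistical structure, not that
real recordings satisfy that structure.

A corner case: with noise and jitter exactly zero, the session-wide min-max
mapping sends the pre-stimulus baseline to 0, making ΔF/F undefined; the
noiseless recovery check therefore computes ΔF/F from the raw traces
(`process_session(..., minmax=False)`), which is equivalent for the
scale-invariant two-fold statistics.

## Problem sizes and determinism

Default analysis sizes follow the study conventions (5,000-iteration
bootstraps, 500/1000 decoding repeats, 1000-shuffle permutation tests,
3000-repeat SARSA ensembles).  The test suite and the acceptance script
exercise the same code paths at the sizes stated in each test (e.g. 3000
SARSA repeats, 10,000-neuron calibration screens, 300-neuron classification
studies, 25-repeat decoding checks), chosen so the whole suite runs in
about a minute on one core.  All randomness descends from one master seed
through named substreams (`accvi._rng.substream`); no global RNG state is
touched, and repeated runs are byte-identical (the SVM solver seed is
pinned for the same reason).

## Known limitations

- The onset detector inherits the per-frame multiple-comparison behaviour
  of the underlying procedure (see above).
- The two-fold rule on near-zero responses is a coin flip under pure noise;
  percentages over populations with many unresponsive neurons should be
  read against the responsive denominator.
- β recovery assumes one β across the fitted sessions; mixing session types
  with different true β would bias it.
- Eq-level statistics on real recordings (RM-ANOVA-style omnibus tests,
  lick-latency analyses, optogenetics) are out of scope.
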