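# Methods

## Stimulation protocol and event model

The default protocol delivers 5-s trains of 14-ms air puffs at 13
frequencies between 1 and 40 Hz (1, 2, 3, 5, 8, 10, 12, 15, 20, 25, 30, 35,
40), ten trains per frequency with 3-s gaps, preceded by a 180-s
spontaneous-activity segment and terminated by 50 pulses of 100 ms at 1 Hz.
The reduced lemniscal protocol uses 2-s trains over 9 of those frequencies.
The first stimulus of a train is at t = 0, so a train at frequency `f`
contains `floor(duration × f) + 1` stimuli (6 at 1 Hz, 11 at 2 Hz for 5-s
trains).

Spike times are stored in seconds; all binning is at 1 ms with half-open
bins `[t, t + 1)`. A spike belongs to the most recent stimulus onset. The
train segment of a recording spans `[0, n(f)/f]` seconds — the last stimulus
owns a full period even when it falls at the nominal train end, because its
response is emitted during the inter-train gap. Without this the last
stimulus would always contribute zero early spikes and RRTF would be biased
low by `(n−2)/(n−1)` (−20% at 1 Hz). TSR, by contrast, counts spikes in the
nominal train window `[0, 5 s)`.

Comparisons against bin edges carry a 1-ns guard so that a spike placed
exactly on an edge by construction is never split across bins by float
rounding; the guard is far below any physiological time scale.

## Metrics

* **RRTF** — `sp(j)` is averaged over trials per stimulus index (making the
  ratio invariant to the trial count) and the early window is the half-open
  `[0, 15)` ms at every frequency (the 40-Hz period is 25 ms, so the window
  never exceeds a period).
* **MRL** — the 50% half-rise of the steady-state cycle histogram (first
  stimuli excluded, no smoothing, 1-ms resolution). The crossing is linearly
  interpolated between the bracketing bins; when the response rises directly
  out of an empty bin the crossing is placed at that bin's left edge (a
  single-bin response at 7 ms has latency 7 ms). `MRL0` applies the same
  rule to the terminal long-pulse histogram (all 50 pulses folded on the
  1-s period). When the terminal sequence is absent, `MRL0` falls back to
  the smallest defined per-frequency MRL.
* **VS** — phases are pooled over all trials and all spikes of the train,
  each referenced to its own most recent onset.
* **Effectiveness** — stimulus presentations are pooled over trials
  (denominator `n(f) × trials`); the effective RRTF averages, per stimulus
  index, only the trials in which that stimulus was effective, and the first
  ever-effective index serves as the reference.
* Undefined metrics are NaN and are excluded pairwise downstream, never
  imputed as zero.

## Filtering-profile classification

Decision order: band-pass first (an interior measured frequency at least
20% above the mean of its two adjacent measured frequencies; the largest
relative excess picks the peak, so edge frequencies cannot be peaks), then
no-filtering (all values within 10% of the profile mean), then the trend
between the mean of the lowest and highest thirds of the measured grid.
All rules are relative, so the label is invariant to positive rescaling.

For the latency metric (MRL) the LP/HP trend sense is inverted: a latency
that grows with stimulation frequency degrades the transmission of fast
stimuli and is the latency signature of a low-pass neuron, so rising-latency
profiles are labelled LP. This matches how latency profiles are described in
the experimental literature on this pathway; the BP and NF rules are
unchanged.

Whisking-band edges default to 4 and 12 Hz (the 4–14 Hz variant is
available via the `edges` parameter). The tonic/phasic decision thresholds
the sustained ratio — spikes in (25, 100] ms over spikes in [0, 25] ms after
long-pulse onset, pooled over pulses — at 0.2; an onset-only response has
ratio 0, uniform firing through a 100-ms pulse has ratio 3.

## Projecting-neuron separation

Seven profile groups (RRTF-LP, RRTF-BP, TSR-HP, TSR-BP, MRL-LP, MRL-BP,
VS-LP) are clustered independently with k-means (squared-Euclidean
distance, 10 restarts, fixed seed; k over 2–5 chosen by the mean silhouette
width with the same metric). Features are the raw metric values restricted
to the 9 frequencies shared with the lemniscal protocol, not standardised.
A neuron enters only the groups matching its own labels; neurons with an
undefined value on the shared grid, or labelled NF for a metric, are
excluded from that metric's groups only. Per group, the cluster whose
centroid is nearest (squared-Euclidean) the mean profile of the
like-labelled LEM recordings is selected, ties going to the lowest cluster
id. The putative projecting set is the neurons present in the selected
cluster of every group applicable to them (at least one). Groups too small
to cluster, or without a LEM reference, are skipped with a warning.

## Rate model and simulation

Each neuron is an inhomogeneous Poisson process sampled by 1-ms bin-wise
thinning (per bin, a spike fires when a uniform draw falls below
`min(r, 1)`; at most one spike per bin; spike times at bin centres).

`r0(t)` is the first-stimulus rate, estimated as a pooled PSTH of
first-stimulus responses across all frequencies and trials, each bin
normalised by the number of presentations whose window covers it.

For subsequent stimuli the response begins `t1(f) = MRL(f) − MRL0` ms later
(floored at 0): the template is *delayed* by `t1` with fractional-bin linear
interpolation, so the simulated latency reproduces `MRL(f)`. Three gains
complete the rate:

* the early window (`t1` to 15 ms) is scaled so that the expected early
  count of a subsequent stimulus equals `RRTF(f)` times the first
  stimulus's expected early count — the defining property of RRTF (a plain
  multiplier would lose the response mass the delay pushes past the fixed
  15-ms boundary);
* the late window (after 15 ms) carries a gain solved by bisection so the
  expected train total (clipping included, truncated last stimulus window
  included) equals `TSR(f)`; negative gains clip to 0 and the late rate is
  capped at the early-rate peak — an adapted response cannot out-fire its
  stimulus-locked onset — so measurement noise in TSR cannot be amplified
  through a near-empty late template;
* per stimulus, with probability `1 − VS(f)`, all of that stimulus's spikes
  are displaced by independent normal deviates (σ = 1 ms by default,
  configurable) and clamped to the train.

The baseline latency subtracted in `t1` defaults to the half-rise latency
of the model's own `r0` template. The terminal-sequence `MRL0` estimates
the same quantity and may be supplied explicitly, but its 50-pulse histogram
is sparse and the half-rise estimator is then biased upward by half a bin
(an empty pre-onset bin suppresses the interpolation), which would misalign
every simulated response systematically.

Decortication is modelled as an excitability shift: the population-mean
`r0(t)` difference between intact and decorticated recordings is added
(Ph+) or subtracted (T−) from each model's `r0(t)`, clipped at zero.

Simulated and reference responses are compared per neuron and frequency by
the squared Pearson correlation of their period-folded peristimulus
histograms (all stimuli and trials pooled, identical 1-ms bins), with the
two-sided p-value; significance is p < 0.05. Whole-train PSTHs at ten
trials are Poisson-noise-limited — two independent realisations of the same
rate correlate at r² ≈ 0.5 — whereas folding pools `n(f) × trials`
presentations per bin. In the fidelity experiment the reconstruction is
simulated with 100 trains per frequency so that the comparison probes the
model's expected response; the reference keeps the protocol's 10 trains.

## Synthetic populations

Four archetypes parameterise response curves over the frequency grid and an
`r0` template (onset transient: latency, peak rate, exponential decay; a
sustained component for the pulse duration; a spontaneous floor):

| archetype | RRTF | TSR | MRL | VS | r0 |
|---|---|---|---|---|---|
| tonic_intact | BP, peak 10 Hz (0.7 + 0.8 bump) | BP (derived) | rising 5.3→8.7 ms (LP) | 0.93→0.68 (LP) | 4 ms, 0.45/ms, τ 6 ms, sustained 0.05/ms, 1.5 Hz |
| phasic_intact | LP, 1.0→0.03 | LP (derived) | rising 4.1→5.9 ms (LP) | 0.96→0.78 (LP) | 3 ms, 0.80/ms, τ 2.5 ms, no sustained, 0.5 Hz |
| tonic_decorticated | BP, peak 8 Hz, lower | BP (derived) | rising 7→11.8 ms (LP) | 0.95→0.77 (LP) | 5 ms, 0.30/ms, τ 6 ms, sustained 0.03/ms, 0.8 Hz |
| lem_projecting | BP, peak 10 Hz, higher base | BP (derived) | rising 8.3→12.1 ms (LP) | 0.97→0.78 (LP) | 7 ms, 0.40/ms, τ 8 ms, sustained 0.06/ms, 2 Hz |

TSR curves are never free parameters: each neuron's per-frequency train
total is derived from its own `r0`, RRTF curve and a late-gain curve through
the same expected-count identity the simulator enforces, so generated data
are self-consistent with the rate model by construction. VS curves sit near
1 (phase locking in this pathway is close to perfect, especially below
15 Hz) and decay with frequency; phasic locking exceeds tonic. The
projecting archetype sits a roughly 1.6× level contrast from `tonic_intact`
in every metric — less adaptation, longer latency, steadier locking, more
spikes — with the train-total potentiation peak carried by a late-gain
(sustained-response) resonance in the whisking band, because the
latency-compressed early window clips at 1 spike/bin and cannot express it.
This contrast is what clear cluster separation between projecting and local
profiles requires at the default noise level; archetype ground-truth
filtering labels are defined as the classifier's output on the noiseless
curves.

Noise: one lognormal gain per neuron per metric (σ = 0.10) times small
independent per-frequency lognormal jitter (σ = 0.04). Whole-profile gains
leave filtering labels unchanged (all rules are relative); the jitter
perturbs them realistically. For the bounded VS the noise multiplies the
instability `1 − VS`, keeping near-perfect locking near-perfect. Spontaneous
segments are homogeneous Poisson at each archetype's low spontaneous rate
(≤ 3 Hz, anesthetized regime). All randomness flows through one seeded
generator (one spawned substream per neuron); identical seeds give
byte-identical event files.

What the generator does *not* emulate: bursting, refractory structure,
trial-to-trial excitability drift, inter-neuron correlations, or receptive
field structure. Passing tests therefore show that the pipeline's
estimators, classifiers and the simulator are mutually consistent under the
assumed rate model — not that real recordings satisfy that model.

## Statistics

Per-frequency comparisons use two-sided Mann–Whitney tests — exact null
distribution for tie-free samples up to n = 25, tie-corrected normal
approximation otherwise — adjusted by the Benjamini–Hochberg–Yekutieli
step-up procedure with the Σ 1/i dependence factor. The family size stays
at the full grid (m = 13) even when some frequencies are untestable.
Proportions use the chi-square independence test, replaced by Fisher's
exact test for 2×2 tables with any expected count below 5. α = 0.05
throughout.

## Problem sizes and known limitations

* The fidelity experiment runs 20 tonic + 10 phasic reference neurons over
  the full 13 × 10 protocol, with 100 simulated trains per frequency for
  the reconstruction (a few minutes on one core). The sub-0.6 tail of
  significant r² values sits at the measurement-noise ceiling: for strongly
  adapted phasic responses at 25–40 Hz, two independent realisations of the
  *same* rate model correlate at r² ≈ 0.55, so occasional comparisons below
  0.6 reflect sparse folded histograms, not model error.
* RRTF recovery at 10 trials carries an irreducible ≈ 12% median relative
  error from sampling noise in the 10-trial first-stimulus reference count.
* Measured VS of simulated trains is bounded below by the phase
  concentration of the response envelope itself; with σ = 1 ms jitter the
  mechanism cannot produce low VS from a narrow transient, so VS round-trip
  agreement is only guaranteed in the near-1 regime the generator uses.
* Type-I error of the per-frequency + FDR chain is verified at reduced
  sample size (n = 8 per group, 1000 replicates); BY is conservative there.
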