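# Methods

This note documents the models, defaults and numerical choices behind
`vreeg`, and what the synthetic experiments do and do not demonstrate.

## 1. Supply-chain game engine

The game is a deterministic daily simulation of a four-actor chain
(farmer → manufacturer → distributor → retailer → customer). The
customer places a scripted order each day — 5, 8, 12, 8, 8, 5, 3 units
over the one-week scenario — and the retailer (the player) starts with
10 units. The farmer is an infinite-capacity source and the customer a
pure demand sink; both are placeholders that bracket the decision-making
actors.

**NPC policy.** Distributor and manufacturer follow a reorder-point
policy targeting a 95% service level: safety stock `SS = z·D̄·L`,
reorder point `ROP = SS + D̄·L`, batch `EOQ = sqrt(2·D̄·K/h)` with
`K = h = 1`. The safety-stock expression is used in this product form
deliberately; the classical formula is `z·σ_D·√L` with the demand
standard deviation, and the product form used here coincides with it
only when σ_D is read as D̄ and L = 1. We implement the product form
verbatim as the game's specification of record and flag the discrepancy
here rather than silently "correcting" it. `z` defaults to 1.645, the
one-sided 95% standard-normal quantile; it is configurable.

**Defaults the scenario leaves open.** Lead time is 1 day on every link;
distributor and manufacturer start with 20 units (about five EOQ
batches, enough to serve the first days without an immediate stockout);
the player's unit sale price and holding-cost rate are both 1,
mirroring the NPCs' unit costs. All are configurable in
`ScenarioConfig`.

**Mechanics.** Within a day, actors act downstream-to-upstream
(retailer, distributor, manufacturer, farmer); each receives pipeline
arrivals due that day, fulfils demand (unmet demand is *lost*, not
backordered — the game scores lost sales and has no backlog), places
its order, and shipped units enter the orderer's pipeline with arrival
`day + L`. Inventory position = on-hand + shipped-in-transit; an order
that the upstream actor could not fill is simply re-triggered the next
day. Orders are integers, so EOQ is rounded up, and the ROP comparison
is inclusive (`position ≤ ROP` triggers an order). The communication
phase adds a disclosure block (upstream inventories and the order each
NPC would place) to the day record; it never alters state evolution.

**Bullwhip.** `var(orders)/var(demand)` with population variances. A
caveat worth recording: with the scripted parameters the EOQ batch
(⌈√14⌉ = 4) is *below* mean daily demand (7), so the NPCs order
near-constantly and the engine's distributor ratio is ≈ 0 — batching
only amplifies variance when the batch is large relative to demand.
The engine reports the ratio as computed.

## 2. Synthetic EEG cohorts

The generator emulates the study's acquisition: 14 channels in the
consumer-headset montage, four contiguous time events (eyes-open and
eyes-closed baselines, defaulting to 60 s each since their lengths are
not part of the scenario script; 180 s lecture; 300 s gameplay), and a
sampling rate of 128 Hz — a common output rate for this headset class,
chosen as a default rather than a documented property of the original
recordings.

Per (group, event, electrode, band) the signal contains a band-limited
oscillation synthesized as white noise restricted to the band in the
frequency domain and scaled to a target RMS (µV). Filtered noise rather
than sinusoids keeps the within-band spectrum realistic. Defaults:
θ 4, α 5, βL 2.5, βH 2, γ 1.2 µV RMS, plus 1/f background noise
(exponent 1, 3 µV RMS). Two structural effects are built in:

- **eyes-closed alpha**: occipital (O1, O2) alpha is multiplied by 2
  during event 2, the classic baseline contrast;
- **group effect**: the experimental group's high-beta RMS is multiplied
  by 1.5 at AF4, F4, F8 and FC6 during events 3-4. This mirrors the
  qualitative finding the pipeline is meant to recover — elevated right
  frontal/prefrontal beta during lecture and play — but the magnitude is
  a free parameter and constitutes ground truth, not a claim about
  effect sizes in real recordings.

Artifacts are transient 300 µV, 0.5 s movement bursts (Poisson, one per
minute by default) on random single channels; contact dropouts replace a
channel's trace by a 500-800 µV step drift and force its CQ/EQ to 10%.
CQ/EQ are emulated at 1 Hz as 100 minus an exponential noise floor —
the analysis only consumes them through the 70% threshold, so only
their threshold behaviour matters. Everything is a pure function of the
spec and seed (per-participant seeds are spawned from the master seed).

What the generator does *not* emulate: volume conduction and channel
correlation, non-stationarity within events, eye blinks/EMG spectra,
headset-specific filtering. Passing tests therefore demonstrate that the
*analysis chain* is correct and sensitive, not that it would reach the
same numbers on real recordings (which are unavailable).

Likert surveys are drawn per question from group-specific categorical
profiles over 1-7; the default profiles lean positive in both groups,
slightly more so in the experimental group.

## 3. Feature extraction

**Quality gate.** A participant is kept only if, in every analysed
event, the fraction of (channel, time) quality samples with CQ ≥ 70%
*and* EQ ≥ 70% reaches the coverage level (default 1.0, i.e.
consistently good contact; comparisons inclusive). Recordings without
quality series raise — quality is never silently assumed.

**Epoching.** Events are cut into non-overlapping epochs (2 s for band
power tables, 1 s for PM series by default) and an epoch is rejected
when any channel's peak-to-peak amplitude exceeds 100 µV — a standard
surface-EEG heuristic standing in for the vendor's undisclosed trial
rejection. Rejected epochs become missing PM values, which is how the
missing-value counts in the summary tables arise.

**Band power.** Hann-windowed periodogram per channel with the mean
removed (DC- and sign-invariant); band power integrates the PSD over
bins with frequency in `[low, high)`. θ (4-8), βH (16-25) and γ (25-45)
edges are fixed by the analysis convention; α (8-12) and βL (12-16) are
chosen to tile the gap exactly, so the five bands partition 4-45 Hz and
band powers sum to the in-range total to machine precision. A 1-s epoch
at 128 Hz gives 1 Hz resolution, enough for the narrowest (4 Hz) band;
shorter epochs raise a resolution error.

**Performance-metric proxies.** Documented replacements (not
reconstructions) for the vendor's opaque metrics: attention = frontal
(βL+βH)/(θ+α); engagement = all-channel β/(α+θ); excitement = frontal
(βH+γ)/total; stress = right-left frontal alpha asymmetry
(R−L)/(R+L) over {AF4,F4} vs {AF3,F3}; relaxation = occipital α/total;
interest = (F4−F3)/(F4+F3) on alpha. Each raw index is standardized
against the participant's own baseline (events 1-2) mean/SD and mapped
through the logistic, so 0.5 means "at baseline" and a zero baseline SD
falls back to 1 (keeping the mapping defined for deterministic
signals). PM cadence defaults to one value per second to match
per-second attention curves; the study-scale summary uses 10-s epochs so
that a 300-s event yields 30 values per participant and the pooled group
sizes (9 × 30 = 270 vs 6 × 30 = 180) match the published table layout.

Interior gaps in PM series are linearly interpolated, edge gaps held at
the nearest observation; all-missing series raise. Group time courses
report per-bin mean, population SD and n.

## 4. Topographic maps

Electrode-mean band powers are min-max normalized to [0, 1] within each
(group, event, band) panel — matching per-panel colour scales — with a
degenerate panel (max = min) mapping to 0.5. Maps are rendered with
inverse-distance weighting (power 2) over a grid masked to a disk of
1.1× the outermost electrode radius: IDW is exact at electrode sites,
bounded by the input range, and fully reproducible; a thin-plate spline
is available behind a switch but is not bounded. 2-D positions come
from the standard 10-20 montage shipped with MNE, azimuthally projected
and symmetrized across homologous pairs so mirrored inputs render
mirrored maps exactly.

The 10-20→MNI152 lookup pins seven electrodes to published per-study
coordinates (FC6, FC5, AF4, P7, T8, F4, F7; provenance `"paper"`). The
rest are filled by sign-flipping the x of a contralateral pinned
homologue, except O1/O2 which come from a standard rounded
10-20-to-MNI atlas; all derived entries carry provenance `"standard"`.

## 5. Statistics

Normality screening is Shapiro–Wilk (α = 0.05), motivating
non-parametric tests throughout; all alternatives are two-sided.
Mann–Whitney uses midranks, exact null enumeration when
`n_x·n_y ≤ 64` with no ties and otherwise the normal approximation with
tie and continuity corrections; the reported `W` is the U statistic of
the first sample — the convention R's `wilcox.test` prints — so output
is comparable with R-style tables. The permutation test uses the
standardized difference of group means, 10,000 label shufflings by
default, and the add-one estimator `(1 + #{|Z| ≥ |Z_obs|})/(n_perm+1)`,
whose p can never fall below `1/(n_perm+1)`; these choices (statistic,
replicate count, estimator) are this package's, as the original analysis
does not specify them. Likert sentiment maps 1-3/4/5-7 to
negative/neutral/positive. Raw p-values are reported; Holm adjustment is
available but off by default.

Calibration is tested, not assumed: the exact Mann–Whitney path is
checked against brute-force enumeration over rank assignments, and the
permutation test's type-I error at α = 0.05 is verified to lie in
[0.03, 0.07] over 1000 null replicates.

## 6. Pipeline, I/O, determinism

A `RunConfig` fully determines a run; it is archived as YAML next to the
outputs together with a run report (exclusions with reasons, stage
counts, artifact list, config hash), and two runs with one seed produce
byte-identical CSVs. The desk-scale `demo` configuration (4+3
participants, 20/20/40/60 s events, 500 permutations) exercises every
stage in a few seconds; the full study-scale experiment (9+6, 600 s per
participant) runs in well under a minute. These sizes are the package's
demonstration defaults; all are configurable.

Recordings interchange as EDF+C — the field's native export format —
with quality series stored as auxiliary `CQ_<label>`/`EQ_<label>`
signals (EDF has no quality field; this dialect is documented in
`vreeg.io`) and events as EDF+ annotations. The EDF codec is
implemented in-package and cross-checked in tests against MNE's
independent reader; round trips agree to one 16-bit quantization step.
A full-precision CSV fallback round-trips bit-exactly.

## 7. Known limitations

- The safety-stock product form (see §1) differs from the textbook
  formula; both give identical numbers only for L = 1 with σ_D read as
  D̄.
- With the scripted K = h = 1, NPC order batches are small and the
  bullwhip ratio stays below 1; demonstrating variance amplification
  requires a larger batch-to-demand ratio than the scripted parameters
  allow.
- PM proxies are interpretable but not the vendor's metrics; absolute
  values are not comparable to vendor output, only within-pipeline
  contrasts are meaningful.
- The synthetic cohort omits inter-channel correlation and realistic
  artifact spectra; statistical power estimates on it will be
  optimistic relative to real data.
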