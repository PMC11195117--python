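# Methods

This note documents the models, parameter choices, numerical conventions
and limitations of `boutonpipe`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic sessions

Real corticostriatal bouton imaging couples three data streams: a lever
trace with task annotations, a boutons × frames fluorescence matrix with a
bouton→axon map, and day-by-day structural bouton inventories. The
generator (`boutonpipe.synthetic`) produces all three with a complete
generative record, from a single seed expanded into independent substreams
(behavior / fluorescence / structure), so identical `(config, seed)` gives
bit-identical output and each stream can be regenerated alone.

**Behavior.** Cues every `task_period + iti` seconds (10 s + 4 s defaults).
With probability `p_success` a cued trial contains a rewarded push — a
half-sine displacement bump (0.6 s wide) with amplitude 1.8–2.6 mm, above
the 1.5 mm threshold — at a 0.3–1.5 s latency; otherwise, with
`p_fail_push`, a sub-threshold push (0.5–1.2 mm); with `p_iti_push` an
additional un-cued push lands in the ITI. Pushes are placed so that
successive bouts are separated by more than 0.5 s, making the 500-ms
merging rule unambiguous. The lever is sampled at the imaging frame rate
(15 Hz): the task gives no lever DAQ rate, and a shared clock makes the
behavior–imaging alignment exact in simulation. Ground truth records the
frame-quantized onset/offset and RM/UM label of every push.

**Fluorescence.** Each axon carries a shared spontaneous event train
(exponential gaps plus a refractory minimum spacing, 1 s default, so the
670-ms matching rule is unambiguous). Each bouton realizes a shared event
with probability `p_shared`, adds bouton-unique events at
`unique_event_rate`, and — if tuned RM-only / UM-only / both (drawn per
bouton from `frac_*`) — emits a transient of amplitude `response_gain`
50–200 ms after each preferred-outcome onset. Impulses are convolved with
a difference-of-exponentials kernel, `exp(−t/τ_d) − exp(−t/τ_r)`
normalized to unit peak (τ_r = 0.2 s, τ_d = 1.0 s — GCaMP6s-like fast
rise, slow decay; no biophysical spike-to-calcium model beyond this).
The refractory spacing is also enforced across a bouton's *combined*
impulse train; colliding impulses are dropped and not recorded, so every
ground-truth event is a separable transient and "every emitted transient
has exactly one ground-truth record" holds exactly. Raw fluorescence is
`F0 · (1 + signal + ε)` with a constant per-bouton baseline
F0 ~ U(100, 200) a.u. (keeps ΔF/F division well defined) and Gaussian
noise ε of sd `noise_sd` (0.05 ΔF/F default). Ground-truth event times are
the observable kernel-peak times. No pixel-level synthesis: simulation is
at ROI-trace level.

The imaging statistics the experiments do not pin down — SNR, transient
amplitudes (0.5–1.0 ΔF/F spontaneous), event rates (0.05 Hz shared,
0.02 Hz unique) — are free parameters chosen once to resemble sparse
striatal axon imaging; they are study conditions, not fitted values.

**Structure.** Axons of length 100 µm start at 1 bouton / 10 µm. Per
inter-session interval (days 0, 2, 4, 6, 8, 10), each present bouton is
eliminated with `elimination_rate` (0.06) and Binomial(n_present,
`formation_rate` = 0.08) new boutons appear — uniformly along the axon,
or, with `cluster_scale_um` set, as Gaussian displacements from a randomly
chosen existing or co-formed bouton. Per-axon rate overrides let tests and
the pipeline couple structural dynamics to functional class (RM axons
forming more boutons). Every change is logged, so the bookkeeping identity
present(d) = present(d−2) − eliminated + formed is exact by construction
and verified against the presence matrix.

**What the generator does not emulate** — and hence what passing tests do
and do not show about real data: no motion artifacts or neuropil
contamination (motion correction and ROI extraction are assumed done
upstream), no slow drift or bleaching in F0, no amplitude correlations
between boutons beyond shared events, no sensory (cue/reward-lick)
responses distinct from movement responses, Poisson-like rather than
burst-structured spontaneous activity, and 1-D rather than 3-D axon
geometry. Recovery results certify the *estimators* under the stated
generative model, not robustness to these real-data complications.

## Analysis conventions

- **ΔF/F**: centered 30-s sliding window, truncated (shrinking) at segment
  edges — centering avoids baseline lag at segment start. Percentile uses
  linear interpolation between order statistics (the numpy default
  dialect); the interior is computed from two order statistics via
  partition, identical to a full sort to ≤1e-14.
- **z-scoring** is per continuous imaged segment, matching the per-segment
  PCA convention; the 1-sd event criterion applies to the peak's z value
  (not its prominence).
- **Event peaks**: local maxima with a minimum separation of 3 frames
  (configurable); plateaus take the first sample.
- **Bout threshold**: mean + k·sd of the lever position during rest
  (k = 2 default in the library). The pipeline annotates rest robustly
  (median ± 3 MAD-sigma) and uses k = 5, keeping the threshold above
  extreme noise excursions and far below the smallest simulated push.
- **RM definition**: a bout is RM iff its peak reaches the push threshold
  *and its onset* falls inside a cue-initiated task period; a push starting
  before the cue that crosses the threshold inside the period is UM (the
  alternative — requiring only the crossing inside the period — is not
  used).
- **Movement-trajectory correlation** uses a −0.5…+1.5 s window around
  onset resampled to 64 points; reaction time is the median cue-to-
  threshold-crossing latency of rewarded trials.
- **Responsiveness**: the reference sd is the bouton's ΔF/F sd over the
  full imaged segment (the same quantity z-scoring uses); the 5th
  percentile is taken over the full averaged −1…+3 s trace (not the
  baseline only — the alternative would make the statistic insensitive to
  sustained pre-onset activity); the exceedance is strict. Classification
  requires ≥ 5 trials of each type (our addition; below that a bouton is
  flagged and classed `none` rather than guessed).
- **Axon threshold histogram** spans [0, max peak] with 0.1-sd bins; mode
  ties break toward the lower bin (deterministic, conservative).
- **Peak matching** is greedy over events in global time order, each event
  taking its nearest unmatched partner within 670 ms. On trains whose
  within-train spacing exceeds 2×670 ms this equals maximum-cardinality
  bipartite matching (property-tested against an exhaustive oracle);
  differences are confined to pathological spacings. The same-peak
  fraction counts a matched pair once per bouton, 2·matched/(nᵢ+nⱼ); the
  alternative matched/max(nᵢ,nⱼ) convention is available via an argument.
  Aggregation is hierarchical: bouton → axon → mouse. Overlapping RM and
  UM outcome windows resolve to the nearest onset.
- **Axon heterogeneity** counts only RM-only and UM-only boutons; "both"
  boutons carry no outcome preference and are excluded (including them in
  the majority class would deflate heterogeneity for mixed axons).
- **PCA**: bouton columns are mean-centered, no variance scaling (unscaled
  PCA on ΔF/F). Each PC's sign is fixed so its largest-magnitude loading
  is positive, for reproducibility. Mean trajectories are computed over
  *all* trials of a type, including the trial under evaluation — no
  leave-one-out — which biases single-trial selectivity slightly toward
  +1 when trial counts are small; a caveat, not a correction we apply.
  Frames where a trial is equidistant-at-zero from both means are excluded
  from the trial-mean index rather than scored 0 (0 would fabricate
  neutrality). The selectivity index is exported at every level (per
  frame, per trial, per session mean) so any downstream averaging order
  can be applied.
- **Structure**: re-appearance (present→absent→present) counts as an
  elimination followed by a formation; turnover percentages are normalized
  to the earlier session's bouton count; density normalization is to the
  first imaged day; along-axon distances use the stored 1-D coordinate
  (no 3-D path reconstruction).
- **Statistics**: two-sided Wilcoxon rank-sum for early/late group
  comparisons, Pearson r for correlations, two-sided Kolmogorov–Smirnov
  for distance distributions; mean ± SEM; raw p-values with no
  multiple-testing correction, flagged * p<0.05, ** p<0.01, *** p<0.001;
  tests with < 3 replicates per group are skipped with a notice.

## Pipeline stage conditions

The orchestrated run (`boutonpipe.pipeline`) emulates learning with two
parameter sets: early sessions use p_success = 0.4, frac_rm_only = 0.15,
frac_um_only = 0.30, p_shared = 0.65; late sessions use 0.75 / 0.35 /
0.15 / 0.85. These move in the direction of the experimental effects
(success and RM representation rise, same-axon heterogeneity falls).
Structural runs compare a training group (formation 0.08, elimination
0.06, new-bouton clustering scale 5 µm) against controls (0.05 / 0.05,
uniform placement). Stages are deterministic in `(config, seed)`; a
subset run regenerates upstream results in memory and refreshes exactly
the requested outputs.

## Problem sizes

Tests run at deliberately small scale: most unit tests use a handful of
axons and 2–4·10³ frames. The deeper recovery checks use the sizes their
statistics need: 500 boutons (100 axons × 5) over a 1000-s session
(15 000 frames at 15 Hz, ≈ 35 clean RM and ≈ 45 clean UM trials) for
classification recovery — the responsiveness criterion's false-positive
rate on untuned boutons is set by how many trials the average pools, so
adequate trial counts per class are part of the study condition — and 500
boutons over 6 sessions for structural rate recovery. Same-peak
convergence uses a ≈ 27-min two-bouton segment with ≥ 200 detected events.

## Known limitations

- The greedy matcher is order-dependent for trains with inter-event
  spacing below 2×tolerance; only its maximum-cardinality behavior above
  that spacing is guaranteed.
- `segment_pca` on very long segments computes a full PCA; no incremental
  variant is provided.
- The activated-ensemble definition (≥ 1 detected event in the
  −0.33…+0.67 s window around onset) is an operational stand-in; no
  standard definition exists for "activated in a trial" at bouton level.
- The report's early/late comparison treats each simulated mouse as one
  replicate; with the default 4 mice per group the rank-sum test's
  granularity is coarse (smallest attainable p ≈ 0.03).
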