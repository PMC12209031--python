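# Methods

This note documents the models implemented in `rgtkit`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions applied throughout.

## Task model and behavioral metrics

A gambling probe session consists of `n_trials` (default 90) trials in
a two-lever arena. The low-risk lever pays 1 pellet with probability
0.9; the high-risk lever pays 3 pellets with probability 0.3 — equal
expected value, so preference reflects risk attitude rather than
payoff maximization. A trial not completed within the 15-s limit is an
omission; completed trials are classed LR/LNo/HR/HNo by arm and
outcome. Consecutive lever presses are separated by at least the 10-s
inter-trial interval.

The choice preference index per block of `block_size` (default 10)
consecutive trials is `(n_low − n_high) / n_completed`. The printed
form of this formula is ambiguous about parenthesization; the stated
range [−1, 1] forces the difference-over-completed reading, and the
same bound forces the denominator to count only completed trials.
Blocks tile the raw trial sequence (omissions count toward block
membership but never toward the numerator or denominator); a block with
zero completed trials has an undefined CPI, represented as NaN and
rendered as a gap. A final partial block is kept and flagged rather
than dropped, since synthetic sessions need not be multiples of the
block size. Curve smoothing is a centered 3-point moving mean whose
window shrinks at the edges (no padding), preserving curve length; NaN
entries stay NaN and are excluded from their neighbours' means.

Latency summaries use the sample SD (ddof = 1) over completed trials
and are undefined (NaN) with no completed trials. The preference-switch
locator interpolates the zero crossing of the smoothed CPI curve
between the last positive and first nonpositive block; it is reported
in block units.

## PETH, smoothing and Z-scoring

PETHs span −5 s to +10 s around the lever press (press = 0) in 50-ms
bins: `rate[b] = total count in bin b across events / (n_events ×
bin_width)`. Bins are half-open `[t, t + Δ)` in press-relative time, so
a spike exactly at the press lands in the first post-press bin; this
convention is stated once and applied everywhere, which is what makes
the bin-count conservation identity exact. Overlapping event windows
are allowed — each event contributes independently, standard PETH
practice. A class with zero events yields an explicit empty-PETH
marker, never silent zeros. Raw per-bin counts are retained on the
unsmoothed PETH for conservation checks.

The "width of 3 points" Gaussian filter is implemented as a 3-bin
truncated kernel with σ = 1 bin (the width is the only stated
parameter; σ is configurable). Kernel weights sum to 1 and are
renormalized over the available bins at the edges, so constants are
invariant and interior-supported mass is conserved to 1e−9.

Z-scoring uses the same PETH's pre-press bins as the baseline:
`Z = (x − m)/SD` with `m`, `SD` the baseline-bin mean and population
SD (ddof = 0). Baselines are per unit *and per response class*; whether
baselines should pool across classes is genuinely open, so pooling is
exposed as an option (pass an explicit `baseline` interval) with
per-class the default, matching the use of the same 5-s pre-press
window for the activity-ratio standardization. A zero-SD baseline
flags the unit `degenerate_baseline` and excludes it from Z-based
summaries rather than fabricating Z = 0 for silent units.

## Feature matrix, clustering and the cut rule

The clustering feature is the activity ratio: mean PETH rate over
[0, 5 s) divided by mean rate over [−5 s, 0), per response class. A
silent pre-press baseline makes the ratio infinite; such units are
excluded with reason `zero_baseline`. Units missing a class (no trials
of that type) are excluded with reason `missing_class` rather than
imputed — imputation would fabricate response profiles. Units with a
session-wide rate below `min_rate_hz` are excluded first; the default
is 0.5 Hz with kept-if-equal boundary ("below threshold" excludes
strictly below). A 1-Hz variant of this exclusion also appears in the
source analyses; both are reachable through `min_rate_hz`.

Included units are agglomerated with average linkage on Euclidean
distances (`scipy.cluster.hierarchy.linkage`). Row standardization
before the distance computation is exposed (`row_standardize`) but off
by default, since the activity ratio is already the standardization.

The dendrogram cut: only merges with linkage distance strictly below
`cut_threshold` (default 3, absolute linkage distance) may be applied.
Candidate cuts apply the first *m* sub-threshold merges; the gap
credited to a cut is the distance increase opened by the next merge,
`d[m] − d[m−1]` — including the jump from the last sub-threshold merge
to the first merge above threshold, so two well-separated groups whose
final merge exceeds the threshold are still split at that jump. The
largest gap wins; ties resolve to the earliest cut; rounding-level
differences (≤ 1e−9 relative to the distance scale) are no gap, so an
equal-distance regime applies every sub-threshold merge (one cluster);
with no sub-threshold merge at all, every unit is a singleton.
Cluster labels are ordered by smallest member index, making partitions
invariant to input permutation up to renaming.

Per-cluster response magnitude is the mean over member units of each
unit's mean Z over the 5-s post-press window, per class, computed on
the smoothed Z-scored PETHs; degenerate units are skipped and a
cluster with no valid unit is NaN. The flexibility score counts the
classes with |mean Z| ≥ 1.96 (two-sided 5% normal bound, configurable)
— a quantitative rendering of a cluster's capacity to encode multiple
task outcomes.

## Expression

Delta-Ct with GAPDH as the housekeeping gene: replicate Ct values
(triplicates by default) are averaged arithmetically per sample and
gene, `ΔCt = Ct_target − Ct_housekeeping`, `rel_expr = 2^−ΔCt`. ΔΔCt
normalization is deliberately not applied; group-level fold changes
are reported descriptively, and group comparisons delegate to the
two-sided Mann–Whitney test (`scipy.stats.mannwhitneyu`). No outlier
handling of replicates is performed by default.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested. Sessions follow the task contingencies above; the behavioral
agent chooses omission first (probability `p_omit`), then the low-risk
lever with probability `p_low_choice`, optionally drifting per trial
or stepping to `p_low_after` at `switch_trial` (emulating the shift
toward the large uncertain reward between control and pain periods).
Latencies are truncated-normal on (0, 15 s] (mean 2 s, SD 1 s by
default — a plausible press latency well inside the trial limit).

Spike trains are inhomogeneous Poisson processes: rate
`baseline_rate` everywhere and `baseline_rate × gain(class)` during
the 5 s after each press of that class, mirroring the analysis window
(configurable). When post-press windows overlap, the later event's
gain takes over from its onset and a warning is emitted. Cluster
structure is planted by giving unit groups shared gain profiles; a
gain of 3 on rewarded classes and suppressive gains (< 1) on
non-rewarded classes reproduce the dominant empirical response types
(excitation after rewarded presses, suppression after non-rewarded
ones). All randomness flows through `numpy` generators derived from a
single mandatory seed (per-unit streams spawned from a
`SeedSequence`), so identical configurations are bit-identical.

Recovery and flexibility simulations use 150-trial sessions with
`p_low_choice = 0.45` rather than the 90-trial default: the low-risk
non-rewarded class has per-trial probability ≈ 0.045, and a 90-trial
session leaves it empty often enough that whole populations would be
dropped for `missing_class`; 150 trials give every class a reliable
handful of events while keeping simulations fast (a 20-seed recovery
run takes seconds).

What the generator does **not** emulate: within-session learning or
outcome-dependent choice (the agent is not reinforcement-sensitive),
bursting/refractory spike statistics, waveform or cell-type diversity,
electrode drift, correlated noise across units, and video/position
data. Passing tests therefore demonstrate correctness of the
*computations* under a faithful rendering of the task structure and
Poisson firing — not robustness to every property of cortical data.

## Numerical conventions and degenerate inputs

- Undefined values (CPI of an all-omission block, latency of an
  empty set, mean Z of an empty cluster) are NaN markers, not errors;
  genuinely invalid configurations (probabilities outside [0, 1], even
  smoothing windows, empty sessions, a missing housekeeping gene)
  raise `ValueError`.
- The PETH bin-count identity `Σ rate·Δ·n_events = total in-window
  spikes` holds exactly on raw PETHs; Z-scored baselines standardize
  to mean 0, SD 1 within 1e−9 whenever the baseline SD is nonzero.
- Merge trees from random continuous features match an exhaustive
  brute-force average-linkage recomputation to 1e−12 (the oracle lives
  in the test suite and is never the implementation path).
- Pipeline runs serialize their configuration next to the outputs; the
  configuration hash excludes the output directory, and rerunning an
  identical configuration reproduces byte-identical CSV/JSON outputs.
- Cross-period cluster comparison matches clusters by nearest mean-Z
  profile (clusters are re-derived independently per period); this
  matching is an artifact convention, flagged with a warning when it
  is not one-to-one.

## Known limitations

- The cut rule's "threshold 3" is interpreted as an absolute linkage
  distance on the natural (activity-ratio) feature scale; under row
  standardization or rescaled features the threshold should be revised
  by the caller.
- Average linkage is not guaranteed monotone in general; on these
  feature matrices merge distances are nondecreasing (asserted by the
  oracle-equivalence tests), and the cut rule reads the merge sequence
  in order, so a non-monotone tree would shift gap positions.
- The Mann–Whitney comparison assumes independent samples per group;
  paired designs (control vs. pain within animal) should use a paired
  rank test instead, which the expression module does not provide.
- Proprietary acquisition formats (e.g., Plexon NEX/PLX) are not read;
  the CSV interchange schemas in `rgtkit.io` are the contract.
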