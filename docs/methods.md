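# Methods

## The problem and the model

An ERP component is modelled as a stereotyped deflection that a given
stimulus presentation either does or does not evoke. The observed epoch of
trial *i* is

x_i(t) = Σ_k z_ik · a_ik · w_k(t − τ_k − δ_ik) + ε_i(t)

where for component *k*: z_ik ∈ {0, 1} is presence, a_ik > 0 the amplitude,
τ_k the nominal peak latency, δ_ik the latency jitter, w_k a unimodal
waveform, and ε broadband noise. Averaging over all trials estimates
p_k·E[a]·w_k smeared by jitter; the package's purpose is to recover the sets
{i : z_ik = 1} ("efficient trials") per component and re-average on them.

## Pipeline stages and their conventions

**Epoching.** Windows are half-open [t − pre, t + post) in seconds, converted
to sample counts by rounding pre·rate and post·rate once, so every epoch has
identical length; the event sample is round((t − start)·rate). Events whose
window leaves the recording are dropped and reported with a reason. No
baseline correction or filtering is applied by default (an optional
per-trial pre-stimulus-mean subtraction is available); SEM uses the n−1
sample standard deviation over trials divided by √n, and is defined as 0 for
a single trial.

**Component windows.** Auto-detection takes maximal constant-sign runs of
the averaged waveform, bounded by zero crossings located by linear
interpolation and snapped outward to the sample grid, keeping runs of at
least `min_duration_s` (default 40 ms). Windows may instead be supplied as a
table, which is the ordinary supervised use. The component amplitude is the
*signed* value of the average at the sample of maximal absolute deflection
inside the window — the same measure used for the pseudo-responses, so real
and null amplitudes are commensurable. Whether that deflection should be
signed or absolute is a genuine free choice; we use the signed value
throughout and sort/count per polarity.

**Permutation test.** Each of n_perm permutations draws the same number of
pseudo-triggers as real stimuli, uniformly at sample resolution over the
part of the recording where a full epoch fits (duplicates re-drawn), averages
the windows, and records the signed peak deflection. Only the component
window is materialised per pseudo-epoch; this is arithmetically identical to
averaging full epochs and slicing (verified by a dual-route test).
Pseudo-triggers are *not* excluded from the real stimulation epochs by
default; an `exclude_events` option (CLI `--exclude-real-windows`) is
provided. The p-value is count/n_perm (rank arithmetic: rank 25 of 500 ⇔
p = 0.05) with a floor of 1/n_perm; the (count+1)/(n+1) correction is
deliberately not applied, so p is very slightly anti-conservative in
exchange for the transparent rank mapping. The critical value at level α is
the element at 1-based rank ⌈α·n_perm⌉ of the polarity-sorted distribution.
Significance is decided as p ≤ α with α = 0.05 by default; no correction
across components is applied, so with many windows tested an occasional
false positive is expected (the worked example in the README shows one).

**Similarity.** Pearson r between the trial's window slice and the template
(the averaged shape in the window), mapped to S = 1 − r² for r > 0 and S = 1
otherwise. Zero-variance (flat) trial segments get r = 0, hence S = 1: a
flat trial carries no component. The maxshift search evaluates every integer
shift in [−maxshift, +maxshift] of the comparison window over the trial
(template fixed; positive shift = trial response later than template) and
keeps the minimum S. Whether the search grid should be ±maxshift or maxshift
points in total is ambiguous in the field's usage; we use ±maxshift. Ties in
S are broken by smallest |shift|, then negative before positive — a
least-jitter assumption that makes output deterministic.

**Threshold selection.** For each threshold in the grid (default 0.5–0.9 in
steps of 0.1) trials split into efficient (S ≤ threshold) and residual sets,
and both group averages over the component window are recorded. Flatness of
the residual average is Σ|w_i|; the primary rule selects the threshold with
minimal flatness, ties to the lowest threshold. The curvature read-out fits
a·t² + b·t + c by least squares (t in seconds) and reports sign(−a), with
|a| < 10⁻³ μV/s² counted as flat; the first threshold whose residual
curvature sign differs from the component polarity is reported as the
reversal candidate, and disagreement between the two rules is flagged rather
than resolved — the two rules are stated side by side in the field and do
not specify a precedence, so a single deterministic primary rule (minimal
flatness) plus an advisory is the design choice here. An empty residual set
yields *missing* flatness, not zero, so threshold 1 can never win by
vacuity. `--force-threshold` overrides selection entirely, since the right
operating point ultimately depends on whether false inclusions or false
exclusions are costlier for the study.

**Pure shapes.** For component k the exclusive set is its efficient set
minus the union of all other components' efficient sets; the outputs are
pairwise disjoint by construction and may well be empty when components
co-occur in most trials.

## The simulator

`synthetic.generate` emulates a stimulation session: n_trials markers at a
jittered inter-stimulus interval (default 2.5 ± 0.25 s, so 1 s + 1 s epochs
never overlap), each component added as a half-sine bump (zero at the window
edges, extremum at the peak — matching the zero-crossing-bounded windows the
analysis uses) with Bernoulli presence, Gaussian amplitude (clipped at 0)
and Gaussian latency jitter. Noise is a variance-normalised mixture of white
and 1/f noise (default SD 20 μV, half the variance pink), the 1/f part
generated by spectral shaping; the total noise SD equals `noise_sd` exactly,
which is what "amplitude = 3× in-window noise RMS" refers to in the tests.
Marker times are snapped to the sample grid, as an acquisition system would
record them. One RNG substream per (trial, component) pair is derived from
the master seed, so editing one component's parameters leaves the others'
ground truth unchanged.

`reference_config` is the reference condition: 131 trials at 250 Hz with
components P200 (+, 120 ms wide), N340 (−, 120 ms), P500 (+, 160 ms), each
20 μV mean amplitude (SD 5 μV), presence probability 0.6, jitter SD 10 ms.
250 Hz is a standard EEG rate; the slow visceral ERPs modelled here are well
below its Nyquist limit.

What the simulator does *not* emulate: rhythmic background (alpha spindles,
K-complexes), artifacts, multi-channel structure, component waveform
variability beyond amplitude and latency, or overlap between responses to
consecutive stimuli. Passing tests therefore demonstrate correctness and
calibration of the algorithms under the stated generative model, not
robustness to every property of real EEG.

## Numerical choices and degenerate inputs

* Pearson r is computed from centred dot products and clipped to [−1, 1];
  the test suite checks it against direct summation formulas to 1e−12
  relative tolerance.
* Text signal files store floats via shortest round-trip repr, so
  write→read→write is byte-identical. EDF is written with 16-bit
  quantisation against the per-channel physical range re-parsed from its own
  8-character header fields, so a reader reconstructs amplitudes to within
  one quantisation step; the rate is stored exactly (one-second records when
  the integer rate divides the sample count, otherwise a single record).
* Empty trial sets, empty residual groups, zero-variance segments, windows
  outside the epoch, and non-increasing marker times all raise explicit
  validation errors or documented sentinel values (see module docstrings)
  rather than propagating NaNs.
* All pipeline randomness flows from one master seed through named
  substreams (simulation, per-component permutations), making the CLI
  `report` byte-reproducible from (config, seed).

## Calibration and problem sizes

The statistical guarantees are exercised on simulated sessions: type-I
calibration on 200 noise-only sessions (3 component windows each, 200
permutations per test), and recovery/threshold-selection quality on 20
sessions at presence 0.5 and amplitude 3× noise RMS, with and without 10 ms
jitter. At these sizes the full test suite runs in well under a minute.
Under the default 1/f-mixed noise the measured type-I rate sits near
0.02–0.05 — at or slightly below the nominal 0.05: uniformly placed
pseudo-triggers can cluster, which under long-range-correlated noise widens
the null distribution relative to the evenly spaced real triggers. The
effect is small and conservative (it does not inflate false positives).

## Known limitations

* The residual-flatness criterion compares noise-dominated averages at high
  thresholds; among thresholds that classify equally well its argmin is
  noise-driven, which is why the guarantee tested is "within 0.05 balanced
  accuracy of the best grid threshold", not exact recovery.
* The template comes from the all-trials average, so at low presence
  probability or SNR the template itself is attenuated and noisy; no
  iterative template refinement is attempted (deliberately — the approach
  here is single-pass, not an adaptive filter).
* p-values are granular at 1/n_perm and floored there; report "< 1/n_perm"
  rather than 0.
* Only single-channel analysis is implemented (a channel selector picks one
  channel of multi-channel files), matching the bipolar-derivation use case.
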