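# Methods

This note documents the models, numerical choices and limitations behind
`perictal`, in the order data flows through the pipeline.

## Conventions

Time is in seconds (float); samples are 0-based; **every interval is
half-open `[start, end)`**, which makes segmentation windows partition
cleanly (pre + ictal concatenate exactly to the enclosing slice, and no
sample is ever counted twice).  Amplitude is microvolts everywhere.
Recordings are stored as EDF: the acquisition default is 10 kHz sampling,
and a 16-bit EDF round trip is exact to one quantization step of the
per-channel physical range.  EDF was chosen as the on-disk container
because it is the most widely readable open electrophysiology format; the
writer is a minimal 16-bit serializer in `perictal.io`, the reader wraps
MNE.

## Synthetic LFP generator

The generator produces the study conditions every downstream stage is
tested against.  Per channel the signal is a sum of independent
components; all randomness descends from one integer seed through fixed
per-component substreams, so adding a component never perturbs another
and identical specs give bit-identical recordings.

- **Background**: Gaussian noise shaped to `1/f^α` in the frequency
  domain (flat below 0.5 Hz so total power stays finite), rescaled to an
  exact target RMS.  Defaults α = 1, 50 µV RMS — a typical spectral slope
  and amplitude scale for rodent LFP.
- **Oscillations**: brick-wall band-limited Gaussian noise at a target
  RMS, for delta/theta/gamma structure.
- **Phase–amplitude coupling**: `s(t) = A(t)·sin(2πf_a t) + sin(2πf_p t) + ε`
  with envelope `A(t) = r·(1 + χ·sin(2πf_p t))/(1+χ)`.  The envelope
  modulation depth is exactly χ, giving a ground truth for MI recovery.
  The slow rhythm is placed on the hippocampal channel and the modulated
  fast carrier on both channels, so within-region and inter-regional
  coupling (HC phase → mPFC amplitude) are both present with known depth.
  Defaults couple theta phase (8 Hz) to low-gamma amplitude (80 Hz).
- **Shared source**: `y_i = λ·s + √(1−λ²)·n_i` with s, n₁, n₂ independent
  equal-power band-limited noises.  The expected magnitude-squared
  coherence inside the band is λ⁴ — an analytic target for the coherence
  estimator.
- **Seizures**: inside each scheduled interval a flat-spectrum (white)
  discharge component with power (g−1)× the background power is added,
  raising total broadband power by the factor g, plus a periodic
  spike–wave train (narrow positive spike, σ = 8 ms, followed by a
  broader negative wave, σ = 50 ms, at 3 Hz).  The discharge component is
  deliberately flat-spectrum: sustained population spiking keeps *every*
  10 ms epoch's power elevated, which is what a short-epoch power
  detector keys on; amplifying only the slow-wave background would leave
  power dips at each slow-wave zero crossing and no 100-epoch run would
  ever complete.  Ground-truth events are exactly the scheduled
  intervals; Racine scores are fixed at 4 since behavior is not modeled.

What the generator does **not** emulate: non-stationary background
drift, seizure evolution (tonic→clonic spectral dynamics), inter-subject
variability, electrode artifacts other than stimulation pulses, and
mains hum.  Passing tests therefore demonstrate correctness of the
*computations* under controlled conditions, not robustness to every
property of in-vivo recordings.

## Online detector

Mean squared amplitude per non-overlapping 10 ms epoch; baseline = mean
of the trailing 10 s of *accepted* epoch powers; detection when 100
consecutive epochs each exceed `k`× baseline; onset back-dated to the
run's first epoch; 60 s refractory.  Choices worth noting:

- `k = 4` is a free parameter (not fixed by the protocol constants); at
  50+ samples per epoch the epoch-power distribution under Gaussian
  background is tight enough that 100 consecutive 4× exceedances are
  effectively impossible by chance (none observed in 20 × 600 s of
  stationary noise), while a 4× amplitude step (16× power) is detected
  with latency ≤ (100+1) epochs.
- The baseline is frozen during a candidate run, so ictal power cannot
  inflate it, and epochs inside caller-supplied exclusion intervals
  (stimulation periods) are skipped entirely.
- During refractory the baseline *keeps adapting*: a sustained shift in
  ambient power then produces exactly one detection instead of one per
  refractory cycle.
- Epochs are non-overlapping (hop = epoch length), the simplest reading
  of an epoch-counting rule; overlap is configurable.

## Stimulation

An episode is 4 packages × 200 pulses at 1 Hz, 0.1 ms width.  "5-minute
intervals" between packages is ambiguous; the default places the gap
after each package's last pulse, and start-to-start spacing is also
implemented (it errors if a package outlasts the spacing).  The episode
end time is the last pulse time: trigger + 4·199 s + 3·300 s = 1696 s.

The recorded artifact of passive charge balancing is modeled as a square
pulse of the stimulus width followed by an opposite-sign exponential
(τ = 3 ms default) whose integral cancels the pulse's.  Samples are
**bin-averaged integrals** of that continuous waveform, so net charge on
the sample grid is zero at any sampling rate — including rates where the
0.1 ms pulse is narrower than one sample.  Artifact amplitude is a free
parameter (stimulus intensity in physical units is not modeled).

Removal is blank-and-interpolate: a 10 ms window from each pulse onset is
replaced by linear interpolation between boundary samples (exact for
affine signals, idempotent, merges overlapping windows).  At 1 Hz
stimulation this discards 1 % of the data, which leaves 1–150 Hz band
powers within a few percent of the artifact-free signal.

## Spectral analysis

Segments: pre `[onset−30, onset)`, ictal `[onset, onset+5)`, post
`[termination, termination+30)` s.  Welch PSDs use a Hamming taper with
90 % overlap and a default window of one fifth of the segment (6 s for
30 s segments, 1 s for the ictal segment).  A 6 s window gives a 0.17 Hz
grid, enough to resolve delta; a millisecond-scale window cannot, so the
window length is exposed in `WelchConfig` and the /5 rule is the default.

Band powers integrate the one-sided density with a piecewise-linear rule
that interpolates band edges, so band powers over a partition sum
*exactly* to the integral over the union (Parseval bookkeeping is
airtight; the estimate itself carries the usual taper bias, ~0.1 %).
Delta is floored at 0.5 Hz (detrending floor); gamma sub-bands default to
30–55 / 55–95 / 95–150 Hz, avoiding both 50 and 60 Hz line frequencies.
No notch filter is applied by default (synthetic data has no mains hum);
a notch can be added upstream for real recordings.  Reported powers are
absolute µV², not normalized.

## Coherence and PAC

Magnitude-squared coherence uses the same Welch configuration and
requires ≥ 2 windows (a single window's coherence is identically 1).
Note the estimator's bias floor: with 90 % overlap the effective number
of independent windows is roughly segment/window, so 30 s segments have
a bias around 0.1 for truly independent signals.  Band coherence is the
mean over band bins.

Phase and envelope come from zero-phase 4th-order Butterworth band-pass
(forward–backward, `sosfiltfilt`) followed by the analytic signal; the
first and last second are trimmed to suppress filter transients (shorter
trims are used on the 5 s ictal segment).  The MI bins phase into
eighteen 20° intervals, averages the envelope per bin, normalizes to a
distribution and measures its KL divergence from uniform, scaled by
log 18 to lie in [0, 1].  An empty phase bin makes the MI undefined and
raises an error rather than returning a silent 0.

Comodulograms scan phase centers 1–12 Hz (0.5 Hz steps, ±1 Hz bands; 23
centers) against amplitude centers 35–250 Hz (5 Hz steps — the step is
our choice; 44 centers).  The amplitude filter half-bandwidth is
`max(10, 1.5 × highest phase frequency)` so modulation sidebands pass —
standard PAC practice.  Band-level MI statistics (bar-graph style) use
single band-wide filters with a 50–250 Hz gamma band, matching the
figure-level convention; the 35–250 Hz methods-level grid is retained
for comodulograms.  Each filter is applied once per axis and MI is
computed by binning, so a full 23 × 44 grid on a 30 s segment costs well
under a second at 1 kHz.

## Group statistics

KS normality uses the Lilliefors correction (mean and SD estimated from
the sample; table-based p-values) — the plain KS null would be
anticonservative.  One-way ANOVA is the classical between/within
mean-square ratio with df (k−1, N−k); Tukey HSD reports mean
differences, the studentized-range statistic
`q = |Δ| / √(MS_w/2 · (1/nᵢ + 1/nⱼ))` and family-wise adjusted p.
Per-seizure values are treated as independent samples, mirroring the
experimental design being simulated (e.g. 4 groups with ~14–24 seizures
each giving df ≈ (3, 60)); with several seizures per animal this is
pseudo-replication, which is documented here rather than corrected,
because the package's job is to reproduce the analysis chain, not to
re-design it.  Null calibration (4 groups, n = 16, 2000 replicates) puts
the type-I error at 0.05 ± 0.01.

## Pipeline and problem sizes

The end-to-end runner is deterministic given (config, seed): rerunning
from the JSON manifest reproduces every output byte-for-byte.  The
"intervention model" — seizures overlapping a stimulation episode get
their duration multiplied by a configurable factor — is explicit
bookkeeping so before/during/after seizure accounting can be exercised;
it is not a biological claim.  Post-ictal windows overlapping stimulation
are analyzed after artifact removal.

Tests and the acceptance script run at 1 kHz sampling for most scenarios
and 5 kHz for detector scenarios (50 samples per 10 ms epoch keeps epoch
power estimates stable), with 30–620 s recordings; these sizes were
chosen so the whole suite completes in well under a minute while leaving
every algorithm identical to its 10 kHz configuration, which remains the
default for generated data.

## Known limitations

- The detector threshold `k`, epoch overlap, and the online definition of
  seizure termination are not fixed by the protocol constants; offline
  analysis anchors on annotated termination times.
- MI significance is not assessed (no surrogate/permutation testing), and
  no phase-locking value, PLI or directed measures are provided.
- The EDF writer targets the plain (continuous, identical-rate) EDF
  layout only; EDF+ annotations and variable-rate layouts are out of
  scope.
- Statistical analysis offers no mixed-effects or repeated-measures
  models.
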