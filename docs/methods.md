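# Methods

## The measurement

A decrement evoked potential (DeEP) quantifies conduction slowing
provoked by a premature beat. After a drive train S1 (cycle length
600 ms, 8 beats by default) and one extra-stimulus S2 delivered near the
effective refractory period, the near-field evoked potential (EP) on a
bipolar electrode arrives with latency `L1` after each S1 and `L2` after
S2; the DeEP value is `L2 − L1` in milliseconds, computed per electrode
and independent of every other electrode. Values above a display
threshold (strictly greater than 10 ms by default) are shown as spheres
on the chamber voltage map, with sphere radius growing linearly in the
decrement.

## Pipeline stages and their assumptions

**Pace detection.** Pacing artifacts are large (default threshold 2 mV)
impulse-like peaks present within a 2-ms coincidence window on at least
80% of all channels; a 50-ms refractory period merges the two phases of
one biphasic artifact. The S1 interval is estimated as the median of
inter-event intervals after discarding intervals shorter than 50% of the
running median — robust against the single short S2 coupling interval.
Walking the event sequence, an interval within a ±5% jitter band of the
S1 interval continues the drive train; the first interval at least 10%
shorter than the drive interval identifies the extra-stimulus and ends
the train. The 10% shortening rule is read as *identifying* S2 (the only
reading consistent with the workflow: a premature S2 is the whole point
of the protocol); a train without a qualifying interval carries no S2 and
the pipeline performs no DeEP computation for it — a typed, logged
outcome, not an error.

**Capture confirmation.** Captured beats share one paced QRS morphology.
Each beat's surface-lead segment (20–140 ms post-stimulus) is correlated
at zero lag (segments are stimulus-aligned by construction) against the
per-lead sample-wise **median** of all S1 segments; the median template is
robust to one non-captured beat. Scores are averaged over leads; capture
requires a score ≥ 0.90. The correlation of a constant (flat) segment is
defined as 0. A train is usable only when the last 3 S1 beats and S2 are
all captured; otherwise the typed capture-indeterminate outcome skips
DeEP computation. Which leads and window enter the correlation is
configurable; all leads and 20–140 ms are the defaults.

**EP detection.** The bipolar signal is blanked ±5 ms around every
stimulus (linear interpolation — zeroing would itself introduce a step
that rings through the filter) and band-limited to 30–300 Hz with a
4th-order zero-phase Butterworth filter. Blanking is needed because the
~10 mV broadband pacing artifact otherwise leaks ringing into the band
well past the 10-ms search-window start. The EP fiducial is the peak of
the band-limited magnitude in the search window (10 ms post-stimulus to
90% of the S1 interval, additionally gated at the next stimulus minus the
blanking width so one beat's window never swallows the next beat's
response). Peaks must exceed max(3 × robust noise floor, 0.01 mV), the
noise floor being 1.4826 × MAD of the band-limited quiescent lead-in.
The peak convention (rather than onset) is a deliberate design choice:
it needs no noise-floor-dependent onset criterion, and since the DeEP is
a *difference* of two latencies measured with the same fiducial, any
constant fiducial offset cancels.

**Stability.** The last 3 *captured* S1 beats (generalizing the 8-beat
protocol to any train length ≥ 3) must have latency population standard
deviation ≤ 5 ms and mean pairwise morphology correlation ≥ 0.85.
Stability failure skips the channel only, not the train. The 5 ms / 0.85
cutoffs are package defaults, not published values.

**S2 EP.** The last S1 morphology window (±10 ms around the fiducial) is
slid over the band-limited post-S2 signal (10 ms post-S2 to the end of
the recording); the lag maximizing the normalized cross-correlation gives
the S2 fiducial if the maximum is ≥ 0.7, otherwise the response is
declared absent (conduction block at the premature coupling) — again a
typed outcome. Template matching transfers the S1 fiducial convention to
S2 exactly, which is what makes the latency difference meaningful.

**DeEP and mapping.** Negative DeEP values (S2 EP earlier than S1 EP) are
physically implausible; they are retained and flagged (`negative-deep`)
rather than clipped, so upstream detection faults surface in QC. The
display threshold is strict (`value > threshold`). Voltages are
peak-to-peak bipolar amplitudes of the last captured S1 beat
(10–150 ms post-stimulus, excluding the artifact), interpolated to mesh
vertices by inverse-distance weighting (power 2) within a 10-mm influence
radius; uncovered vertices are NaN. DeEP points project to their nearest
mesh vertex (points > 15 mm off-mesh are excluded with a warning) and
sphere radius is `1 mm + 0.05 mm/ms × DeEP`; linear scaling is a choice —
the clinical software's scaling law is unknown. The 0.5/1.5 mV
scar/border color thresholds are export metadata only.

## Synthetic data: what it emulates and what it does not

The generator plants, per beat and channel: a 2-ms biphasic pacing
artifact (10 mV) on all channels; a smooth 100-ms QRS template (1 mV)
starting 20 ms post-stimulus on surface leads of captured beats; a 15-ms
cosine-carrier Gabor wavelet at 150 Hz (0.5 mV) as the near-field EP at
the planted latency; a low-frequency far-field bump (0.2 mV) on bipoles;
and white Gaussian noise (default 0.02 mV sd). Capture failure omits QRS,
far field and EP while keeping the artifact; conduction block omits only
the S2 EP. The EP wavelet is even-symmetric on purpose: zero-phase
filtering preserves its peak location, so the planted latency *is* the
peak fiducial and clean-limit recovery to within one sample period is a
well-posed requirement. One seed drives everything; per-channel noise
streams are spawned deterministically from it, so identical seeds give
bit-identical recordings.

Defaults (chosen once as a realistic paced-protocol setting): 2 kHz
sampling, 12 surface leads, 8 S1 beats at 600 ms, 300-ms S2 coupling,
200-ms quiet lead-in, 300-ms tail. Configurations whose EP windows would
overlap the next stimulus are rejected with the offending channel named.

What the synthetic data does **not** model: fractionated multi-component
EPs, fusion and pseudo-fusion beats, catheter motion and contact noise,
baseline wander, mains interference, beat-to-beat EP amplitude
variability, and rate-dependent (restitution) latency drift. Passing
tests therefore demonstrate the *logic* of the workflow — correct
fiducial bookkeeping, correct early-termination behaviour, correct
arithmetic and statistics — under idealized morphologies; they do not
certify detection performance on clinical electrograms.

## Validation statistics

The scored unit is one channel-train pair (one potential DeEP site). Two
annotation sets over the same units give TP/TN/FP/FN by mark presence;
sensitivity = 100·TP/(TP+FN) and specificity = 100·TN/(TN+FP), reported
to one decimal, with an explicit typed "undefined" result when a
denominator is empty. Cohen's kappa comes from the 2×2 marginals,
undefined when chance agreement is 1. The correction taxonomy compares an
algorithm set with its expert-corrected version: unchanged
(|Δ decrement| ≤ 5 ms, a package default — no numeric criterion is
published), changed, deleted, added; percentages are over the union
total. Four percentages rounded to one decimal may sum to 100 ± 0.2.
Decrement histograms use half-open bins throughout, including the last.

## Interchange formats

A recording directory holds `header.json` (sampling rate, channel names
and roles, electrode coordinates) plus either `signals.csv`
(full-precision text floats; bit-exact float64 round-trip) or a minimal
WFDB-compatible record (`record.hea`/`record.dat`, format 16: int16 at
1000 ADC units/mV, i.e. 1 µV resolution). WFDB storage quantizes, so its
round-trip is exact from the first read-back onward, not for arbitrary
floats. Map geometry exports to legacy-ASCII VTK or ASCII PLY with a
per-vertex voltage property (values survive round-trip to ≥ 6 significant
digits), spheres to CSV. Annotations are CSV rows
(channel, train, time_ms, label, deep_value_ms); `label=none` registers a
scored unit without a mark, which is what makes true negatives countable.

## Problem sizes and numerical choices

Acceptance-level checks run on synthetic recordings of 8 S1 + 1 S2 beats
(≈ 5.7 s at 2 kHz): a 24-channel noise-free case for clean-limit recovery
and a 200-channel case at per-sample SNR 10 (EP 0.5 mV, noise 0.05 mV sd)
with decrements uniform on [0, 80] ms for noisy recovery — sizes chosen
to exercise the full pipeline across the clinically relevant decrement
range. Observed recovery error is dominated by sample-period quantization
(≈ 0.13 ms MAE at 2 kHz, against a 2-ms acceptance bound). Ties in peak
search resolve to the earliest sample (`argmax` convention). All windows
are half-open `[start, end)`; times are float ms from recording start.

## Known limitations

* One extra-stimulus per train; S3/S4 multi-level protocols are out of
  scope, as are fusion-beat classification and fractionated-EP
  decomposition.
* The detector assumes the pacing artifact is visible on most channels
  (stimulator routed into the recording system).
* Latency resolution is one sample period; at 1 kHz (the minimum
  accepted rate) this is 1 ms, which is material against a 10-ms display
  threshold.
* The voltage map is a display product: inverse-distance weighting over a
  convex chamber mesh, not a geodesic or statistical interpolation.
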