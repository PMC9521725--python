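# deepmap

Automated detection and mapping of **decrement evoked potentials (DeEPs)**
for ventricular tachycardia (VT) substrate analysis.

During VT substrate mapping, the operator paces the ventricle with a
regular drive train (S1, typically 8 beats at a 600 ms cycle length) and
then delivers one premature extra-stimulus (S2) near the effective
refractory period. Healthy tissue answers the extra-stimulus with the same
near-field evoked potential (EP) delay as during the drive; diseased,
slowly conducting tissue answers **later**. That extra delay, in
milliseconds, is the DeEP value of the recording bipole:

```
DeEP = t(EP | S2) − t(EP | last S1)
```

Sites with DeEP above ~10 ms mark decremental — potentially
arrhythmogenic — substrate and co-localize with VT circuit components,
without any need to induce the arrhythmia. `deepmap` automates the whole
workflow on multichannel electrogram recordings:

1. **pace detection** — supra-threshold pacing artifacts coincident across
   channels, then classification of the modal S1 interval and the
   premature S2 (an inter-stimulus interval ≥10% shorter than the drive
   interval identifies the extra-stimulus; without one the run terminates
   and no DeEP is computed);
2. **capture confirmation** — every beat's post-stimulus surface-ECG
   segment is correlated against the median S1 QRS template; the train is
   usable only if the last 3 S1 beats and S2 are all captured;
3. **S1 EP detection and stability** — band-limited (30–300 Hz) peak
   fiducials of the last 3 captured S1 beats; latency standard deviation
   and pairwise morphology correlation must clear thresholds;
4. **S2 EP detection** — normalized cross-correlation of the last S1
   morphology template over the post-S2 window;
5. **DeEP extraction and mapping** — per-bipole decrement values,
   a strict display threshold (>10 ms by default), and size-scaled
   spheres projected onto a 3D voltage map of the chamber.

A synthetic-data module generates paced recordings with planted ground
truth (stimulus times, EP latencies, per-channel decrements, capture
failures, conduction block), so every stage is testable without clinical
data, and a validation module scores annotation sets against a gold
standard (confusion counts, sensitivity, specificity, Cohen's kappa, and
the unchanged/changed/deleted/added correction taxonomy).

## Worked example

```python
from deepmap import ChannelSpec, SimulationConfig, generate_recording, run_pipeline

config = SimulationConfig(
    noise_sd=0.02,
    channels=[
        ChannelSpec("healthy",   base_ep_latency=40.0, planted_decrement=0.0),
        ChannelSpec("border",    base_ep_latency=45.0, planted_decrement=20.0),
        ChannelSpec("substrate", base_ep_latency=55.0, planted_decrement=40.0),
    ],
    rng_seed=2,
)
recording, truth = generate_recording(config)
result = run_pipeline(recording)
for p in result.points:
    print(p.channel, round(p.deep_value, 2), "displayed" if p.displayed else "hidden")
```

prints

```
healthy 0.0 hidden
border 20.0 displayed
substrate 40.0 displayed
```

Each line is one bipolar electrode: the recovered decrement in ms and
whether it clears the strict 10-ms display threshold. The planted 0/20/40
ms decrements are recovered exactly (to within one sample period), and
only the two decremental channels are displayed — exactly what an
operator would see as spheres on the voltage map. More narrative examples
live in `examples/` (stimulus detection, full pipeline, voltage-map
export, validation statistics), and the same stages are available from a
shell via the `deepmap` CLI (`simulate`, `detect-stimuli`, `run`, `map`,
`validate`).

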