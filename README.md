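# oscillotrack

Cortico-acoustic entrainment analysis for parametric auditory stimulation:
synthesis of rate- and jitter-controlled token trains, simulation of
source-level EEG with known brain-to-stimulus phase locking, and
quantification of neural entrainment via the band-scanned phase-locking
value (PLV) with a cross-correlation control and within-subject group
statistics.

## The problem

When the auditory cortex entrains to an ongoing stream of sounds, its
oscillatory activity phase-aligns to the stimulus amplitude envelope.  How
strongly it does so depends on the presentation *rate* (syllabic-rate
streams near 4.5 Hz are of special interest for speech) and on the stream's
*periodicity*: perturbing the inter-stimulus interval (ISI) with random
jitter degrades the temporal predictability of the input while leaving its
mean rate untouched.  Measuring entrainment across rates, jitters, and
stimulus classes (clicks vs. speech-like syllable tokens) requires a
carefully controlled stimulus generator, a source-space reduction of the
EEG, and a frequency-resolved synchrony metric — plus synthetic data with
analytic ground truth to validate every stage.

## The statistic

Entrainment between a cortical source waveform and the stimulus envelope is
quantified by the phase-locking value

```
PLV = (1/T) | Σ_t exp(i [θ1(t) − θ2(t)]) |
```

where θ1, θ2 are the instantaneous Hilbert phases of the two signals after
identical zero-phase band-pass filtering (±0.5 Hz) around each center
frequency of a scan grid (1.1–30 Hz, 0.3 Hz steps).  PLV is 0 for a random
phase relation and 1 for perfect synchrony.  The peak of the PLV spectrum
within ±0.5 Hz of the nominal presentation rate summarizes one condition.

Synthetic subjects are generated with a von Mises phase-error model: the
source oscillation tracks the stimulus-envelope phase with a circular error
of concentration κ, so the expected PLV is the Bessel ratio I₁(κ)/I₀(κ) —
an analytic recovery oracle for the entire pipeline.

## Worked example

```python
import oscillotrack as ot
from oscillotrack.pipeline import RunConfig, Condition, simulate_cell
from oscillotrack.model import EntrainmentModel

cfg = RunConfig(n_subjects=1, conditions=[Condition("click", 4.5, 0.0)],
                fs_audio=8000.0, master_seed=3, kappa={"click_r4.5_j00": 4.0})
train, eeg, spec = simulate_cell(cfg, 0, 0)   # 30 s record, 64 channels
montage = ot.make_fixture_montage(64, seed=3)
res = EntrainmentModel(eeg, 500.0, train, montage, subject_id="s00").fit()
print(res.summary())
```

```
Entrainment fit
================================================================
subject: s00   condition: click_r4.5_j00
stimulus: click  rate: 4.5 Hz  jitter: 0%
segment: 30 s @ 500 Hz   scan: 1.1-30.0 Hz (step 0.3)
----------------------------------------------------------------
source                    peak PLV peak f (Hz) xcorr maxlag (ms)
AC-left-tangential          0.8747        4.10    0.2091     0.0
AC-right-tangential         0.8760        4.10    0.2000   442.0
----------------------------------------------------------------
hemisphere-collapsed        0.8754        4.10    0.2045
```

The programmed locking strength was κ = 4, whose analytic expectation is
I₁(4)/I₀(4) ≈ 0.864; the measured hemisphere-collapsed peak PLV of 0.875
recovers it within the pipeline's tolerance.  The cross-correlation maximum
(~0.20) is the amplitude-domain control for the same record — lower than
PLV because it mixes the phase-locked oscillation with the full broadband
background rather than isolating the entrained band.

For a full synthetic experiment (cohort × 18-cell design) use
`oscillotrack.run_experiment(RunConfig(...), outdir=...)` or the CLI:

```
oscillotrack run-all --cohort 4 --seed 42 --out run_out/
oscillotrack stimgen --stimulus syllable --rate 4.5 --jitter 40 --n-tokens 1000 --out stim/
```

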