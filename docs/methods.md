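# Methods

This note documents the models, numerical choices, and design decisions
behind `oscillotrack`, and states what the synthetic validation surface
does and does not establish about real recordings.

## Stimulus model

Two token classes are synthesized: a 100 µs rectangular click (at least one
sample regardless of rate) and a 60 ms consonant–vowel syllable token
approximating /ba/ by source–filter synthesis — a brief noise burst
followed by a glottal impulse train (default f0 = 120 Hz) through cascaded
second-order resonators, with a rising first-formant transition
(300 → 700 Hz over 30 ms), 5 ms raised-cosine edge ramps, and unit peak
normalization.  The syllable is a re-synthesis: only its 60 ms duration and
broadband spectral character are treated as constraints, not its exact
spectral detail.

Trains place token copies at onsets whose intervals follow the
half-interval jitter rule: each onset-to-onset interval is

ISI = ISI_nom/2 + U,  U ~ Uniform[ISI_nom/2·(1−j), ISI_nom/2·(1+j)],

with jitter fraction j ∈ [0, 1).  This splits the nominal period into a
fixed half and a uniformly jittered half, so E[ISI] = ISI_nom at every
jitter level: periodicity degrades while the mean rate is conserved.
Intervals are defined onset-to-onset (not gap-to-gap), which is the only
convention under which the mean rate is exactly preserved with fixed-length
tokens.  j ≥ 1 is rejected because it would permit non-positive intervals.
The standard design is 2 stimulus classes × (5 rates at 0% jitter +
5 jitters at 4.5 Hz), with the duplicated (4.5 Hz, 0%) cells counted once:
18 distinct conditions.  The full-scale profile uses 1,000 tokens per
condition at 48 818 Hz audio; the pipeline and test profiles synthesize
only the audio needed for the analysed 30 s window, at 8 kHz, which leaves
every analysis quantity unchanged (the envelope is consumed at 500 Hz).
The presentation level of the original paradigm (74.3 dB SPL) is hardware
calibration territory and is never applied to samples.

Acoustic diagnostics operate on the Hilbert envelope of the audio,
downsampled to 500 Hz, so click and syllable trains are directly
comparable.  The autocorrelation is normalized to 1 at lag 0; the first
local maximum at lags beyond half the nominal period is reported as the
periodicity peak, with a relative-prominence guard (10% of the ACF range in
the search window) so resampling-filter ripple is not mistaken for
periodicity.  The envelope spectrum is Welch-averaged (segments of 4096
samples) because a single-bin periodogram read at the nominal rate is too
variable at high jitter to show the expected monotone energy decline.

## Synthetic cohort and ground truth

Each synthetic subject × condition produces left and right auditory-cortex
source currents

s(t) = A·cos(φ_stim(t) + ε(t)) + g·(kernel ⊛ onsets) + n(t),

where φ_stim is the narrowband Hilbert phase of the stimulus envelope at
the oscillation frequency (default: the presentation rate), n(t) is
unit-variance 1/f background noise (power slope −1, flattened below
0.1 Hz), and A is set from the oscillation-to-background SNR in dB
(default 20 dB).  An optional biphasic evoked kernel convolved with token
onsets adds harmonic structure (phase locking at 2F0, 3F0, …), mimicking
the nonlinear harmonics seen in sustained auditory potentials.

The phase error ε(t) implements von Mises(0, κ) locking, and its temporal
structure is the key numerical decision in the package.  The PLV analysis
isolates a ±0.5 Hz band; phase fluctuations faster than that band are
attenuated by the filter rather than measured, so a fast i.i.d. phase-noise
process (e.g. one independent draw per token at ≥2 Hz token rates) would be
smoothed away and the measured PLV would land far above the nominal
I₁(κ)/I₀(κ).  ε(t) is therefore a slow occupation-time construction: a
triangle wave sweeps through (0, 1) and is mapped through the von Mises
quantile function, so the fraction of time the trajectory spends at each
phase offset equals the nominal probability density while its bandwidth
stays inside the analysis band.  The sweep period defaults to 22 s — one
full cycle per trimmed analysis window of a standard 30 s record, and slow
enough that the sweep's spectral sidebands pass unchanged through every
scan band within the peak-extraction window (faster sweeps let off-center
bands clip part of the phase modulation, inflating the extracted peak).
With this construction the realized PLV equals the Bessel ratio almost
deterministically per record; empirical recovery error across
κ ∈ {0.5, 1, 2, 4, 8} is ≤ 0.02, against a validation tolerance of ±0.05.
The trajectory's random initial phase and each hemisphere's independent
noise are drawn from per-(subject, condition) seed substreams.

The fixture montage is a 64-channel leadfield with two columns: spatially
smooth tangential-dipole patterns over the left and right temporal regions
on a bilaterally mirrored synthetic channel grid, zero-meaned (so forward
projection commutes with common-average referencing) and unit-normalized.
It stands in for a dipole-model auditory-evoked-potential montage; real
leadfields can be supplied through the same `SourceMontage` JSON interface.
The four-shell spherical head-model constants are retained as metadata
only — the fixture does not evaluate a volume-conductor forward model.
Scalp records add white sensor noise (default 10 dB below signal power) and
are common-average referenced.

Default generative locking strengths emulate the qualitative pattern of
interest rather than any fitted quantity: clicks at κ = 2 everywhere
(jitter-invariant), syllables at κ = 4 − 2.5·j across jitter (declining
from 4 to 2 at 80%) and reduced away from the 4.5 Hz syllabic rate.  The
default cohort size is 24 subjects; tests and the reduced profile use 3–6.

## Source reduction and PLV analysis

Scalp EEG is common-average referenced and projected to source space with
the Moore–Penrose pseudoinverse of the leadfield (SWF = L⁻¹ × EEG; exact
left inverse for full-column-rank L).  Only the tangential component per
hemisphere is modelled.  A fixed-length segment (default the first 30 s) is
extracted per condition so every cell contributes equal-length data.

The stimulus envelope is the modulus of the analytic signal of the audio,
polyphase-resampled to the EEG rate (500 Hz) after anti-alias filtering and
clipped at zero.  Per scan frequency (1.1–30 Hz, 0.3 Hz steps → 97 bands),
both signals are band-pass filtered with a zero-phase forward–backward
4th-order Butterworth (±0.5 Hz) — zero group delay is essential because any
filter delay would read as a phase offset — and Hilbert phases are
extracted.  Narrowband filters ring, so 2/halfwidth seconds (4 s at the
default halfwidth) are trimmed from each end before the PLV sum; a 30 s
segment therefore contributes 22 s of phase samples.  The condition summary
is the maximum PLV over scan frequencies within ±0.5 Hz of the nominal
rate (ties to the lowest frequency), computed per hemisphere and then
averaged (hemisphere collapsing after peak extraction).

The cross-correlation control normalizes both signals to unit energy and
reports the maximum absolute correlation within ±500 ms and its lag; the
absolute value is taken because source polarity is sign-ambiguous.

## Group statistics

PLV-like bounded values are square-root transformed before testing.  The
jitter effect is tested with a within-subject orthogonal linear contrast:
per subject, values across the ordered jitter levels are projected onto the
centered degree-1 contrast and the contrast scores are tested against zero
with a two-sided one-sample t-test (df = N − 1); the reported slope is the
mean per-subject least-squares slope.  Stimulus-domain differences at each
jitter level use paired t-tests, Holm-adjusted across the five levels.
Brain–behavior relations use Pearson correlation with a t-distributed
two-sided p.  α = 0.05 throughout.  This within-subject machinery replaces
a pooled-cell mixed-model ANOVA with Tukey–Kramer post hocs: it is simpler,
exactly testable against simulation, and sufficient for the synthetic
validation surface — but its degrees of freedom (N − 1) differ from a
pooled mixed model's, so printed t/F statistics from mixed-model analyses
of comparable designs are not comparable numbers.  Degenerate inputs are
handled explicitly: constant values give t = 0, p = 1; identical nonzero
paired differences are flagged as exact separation rather than producing a
spurious finite t.

## What the synthetic validation does and does not show

Passing tests establish that the measurement chain is faithful: the
generator's programmed locking strength is recovered through stimulus
synthesis, forward projection, inverse reduction, filtering, and peak
extraction; the null is calibrated; programmed declines are detected with
high power.  The synthetic records omit much of real EEG: no artifacts
(blinks, muscle), no realistic cortical geometry or inter-subject leadfield
variability, phase-locking confined to a single frequency plus optional
harmonics, and stationary noise.  Results on real recordings depend
additionally on those factors; the real-EEG path (EDF reading, channel
matching by name, user-supplied leadfields) is provided but its scientific
output is only as good as the supplied montage.

## Numerical details and edge cases

- Filters: `scipy.signal.butter` second-order sections with `sosfiltfilt`;
  band edges validated against 0 Hz and Nyquist.
- Envelope resampling: `resample_poly` with the rational rate ratio;
  output length is within one sample of round(duration × 500).
- von Mises quantiles: trapezoidal quadrature of the density on a 4001-point
  grid with linear interpolation; κ ≥ 1e5 short-circuits to zero phase
  error (degenerate concentration).
- Peak extraction ties break to the lowest frequency (first argmax).
- Seeds: a master seed spawns per-(subject, condition) `SeedSequence`
  substreams, so adding subjects or conditions never perturbs existing
  records; reruns are byte-identical.
- The EDF writer emits classic EDF (16-bit, 1 s records, per-channel
  physical scaling from the data extremum); it requires an integer sampling
  rate and zero-pads the final record.  Round-trip error is bounded by one
  quantization step.
- Problem sizes in the test suite (8 kHz audio, 30 s records, cohorts of
  3–6, reduced scan grids in unit tests) are the package's reduced
  validation profile; every quantity tested is independent of these
  reductions by construction.
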