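# Methods

## The model

The localizer is a rate-free, timing-based circuit. Eight *sensory* ("leg")
neurons, one per microphone, are leaky integrators driven by the normalized
channel signal s_k(t):

    dv/dt = (1 + s_k(t) - v) / tau_leg + sigma * sqrt(2/tau_leg) * xi(t)

with threshold 1 and reset 0. The resting drive of 1 parks the membrane
just below threshold, so the positive half-waves of the stimulus trigger
phase-locked spikes; the white-noise term (sigma, dimensionless) adds
physiological jitter.

Each leg spike (a) injects +w_exc into the synaptic cascade of its own
*command* neuron with zero delay, and (b) injects w_inh (negative) into the
cascades of the three command neurons of the angularly opposite legs — the
*triad*, offsets 135/180/225 degrees — after the inter-neuron delay. The
anatomical circuit routes (b) through explicit inhibitory relay neurons; a
relay with a fixed response time is functionally a fixed delay, so the
relays are collapsed into delayed inhibitory synapses. Command neurons
filter their input through a second-order (alpha-function) cascade

    dy/dt = -y/tau_cmd,   dx/dt = (y - x)/tau_cmd,   dv/dt = (x - v)/tau_cmd

spike at v >= 1, reset to 0, and then hold v clamped at reset for an
absolute refractory period. Only relative spike *timing* distinguishes
directions: every leg receives the same waveform at equal amplitude, and the
near legs' inhibition arrives at the far commands before the far legs'
excitation does.

The topology is circulant, so the network is exactly equivariant under
rotation by one leg; the test suite leans on this symmetry (scene, spike
trains and decoded bearings all rotate together, bit-exactly in the
noise-free case).

## Timescales: everything follows the array aperture

The reference implementation of the scorpion circuit uses 1 ms for the
sensory and command time constants, the leg refractory, the command
refractory, and 0.7 ms for the inhibitory delay. These are not five
independent constants: for the scorpion (ring radius 2.5 cm, surface-wave
speed 50 m/s) the travel time across the leg span — the *maximum inter-leg
delay*, 2r/c — is exactly 1 ms. The model's timescale family *is* the
aperture.

This package therefore resolves every unset time parameter against the
geometry it runs on: for the 90 mm microphone ring in air (c = 343 m/s) the
aperture is 262.4 µs, giving tau_leg = tau_cmd = leg refractory = command
refractory = 262.4 µs and inhibitory delay 183.7 µs (0.7×). Instantiated on
the scorpion's geometry the reference values are recovered unchanged. The
alternative — keeping 1 ms constants under a 262 µs aperture — was
implemented and measured first: the membrane dynamics are then 4× slower
than the entire delay structure and the network shows no spatial tuning at
all (all eight command rates equal). Any parameter can still be pinned to
an absolute value in `ModelConfig`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| w_exc / w_inh | +7 / −2 | synaptic weights (dimensionless, threshold = 1) |
| inh_delay | 0.7 × 2r/c | inhibitory (relay) synaptic delay |
| refractory | 2r/c, or fraction of window | command-neuron dead time |
| tau_leg, tau_cmd | 2r/c | membrane / cascade time constants |
| leg_refractory | 2r/c | sensory-neuron dead time |
| sensory_noise_sigma | 0.05 | leg membrane noise (0 → deterministic) |
| dt | 1/fs (20.8 µs at 48 kHz) | Euler integration step |
| window_length | 0.5 s | bearing-estimation window |

The refractory period supports two modes because its historical tuning was
expressed as a percentage: absolute seconds (default = aperture) and
fraction-of-window (15 % → 75 ms at the 500 ms window). At window scale a
refractory acts as a recency weight on the windowed counts — after each
spike the neuron is silenced, so surviving spikes reflect the most recent
source position. The same mechanism caps every neuron's count at
window/refractory, however, and once the *suppressed* neurons' inter-spike
intervals are shorter than the refractory period all eight counts saturate
at the same ceiling and the directional contrast vanishes. Which regime
applies depends on how completely the far side is silenced, i.e. on the
scene's noise level; `scripts/acceptance.py` archives a two-mode sweep
(fractions 5–20 % of the window, multiples 1–4× of the aperture) so the
regime is visible in the results rather than assumed.

## Synthetic scenes

The generator emulates the characterization set-up: an omnidirectional
point source at a constant 1 m from the centre of a 90 mm ring of eight
ideal omnidirectional sensors, in one horizontal plane, rotating 0→360° in
20 s (the physical experiment rotated the *array* under a fixed speaker;
rotating the source bearing is kinematically identical in 2-D with no
room). Channel j is

    gain_j * s(t - tau_j(t)) + offset_j + noise_j(t)

with tau_j(t) the exact spherical-propagation delay re-evaluated at every
output sample (spherical rather than far-field because 1 m is only ~22
radii; a far-field mode exists). Closed-form waveforms (tone, linear sweep,
gated bursts) are evaluated analytically at the retarded times, so
fractional delays carry no interpolation error; user-supplied sample arrays
are interpolated with a Hann-windowed sinc (a nearest-sample delay would
inject up to ~10 µs of bearing-correlated error, a large fraction of the
262 µs aperture).

Defaults for the front-end imperfections: per-channel gains uniform ±10 %,
DC offsets ±1 % of full scale, independent Gaussian noise at 20 dB SNR
relative to the source RMS (the characterization recordings' SNR was never
measured; 20 dB is an ordinary quiet-room figure and the level is a single
`snr_db` knob). All randomness flows from one seed; identical seeds give
bit-identical recordings.

What the generator does *not* model: room reflections and reverberation,
sensor directivity, elevation, loudspeaker coloration, Doppler beyond the
time-varying delay itself, and multiple simultaneous sources. Passing tests
on these scenes therefore demonstrates the mechanism under controlled
mismatch and noise, not performance in reverberant rooms.

## Normalization

Each channel is independently (1) mean-subtracted, (2) divided by its
standard deviation (population convention — observably irrelevant because
of step 3), and (3) divided by its maximum absolute value, yielding zero
mean and max-abs exactly 1. The procedure is invariant to positive affine
transforms, which is what removes the gain/offset mismatch, and it is
idempotent. It is computed over the whole recording (offline
post-processing), not per window. One consequence worth knowing: step (3)
divides by the *peak* of signal+noise, so at low SNR the normalized signal
amplitude shrinks (≈0.7 at 20 dB) and per-channel noise peaks re-introduce
a small amplitude dispersion that step (2) had removed.

## Decoder and error statistics

Windows are half-open, non-overlapping, 500 ms by default (one new bearing
every 500 ms); a trailing partial window is dropped. The population vector
sums over all eight legs. A window is *undefined* when the total count is
zero or |x| < 1e-9 × Σa_j — ties carry no direction, and assigning them an
arbitrary angle would fabricate accuracy; undefined windows are counted and
reported alongside, never averaged in. Ground truth is evaluated at window
centres (the estimate is a window aggregate; centre sampling attributes no
systematic lag to a uniformly moving source). Summaries report mean ± std
of the *absolute* wrapped error; a signed mean would near-cancel on a
symmetric error trace.

## Numerical choices

* Fixed-step Euler at dt = one sample period (20.8 µs at 48 kHz), so the
  inhibitory delay quantizes to whole steps (183.7 µs → 9 steps, rounded to
  nearest) far below the 262 µs aperture. Exact (matrix-exponential)
  integration of the linear cascade was prototyped and changed accuracy by
  well under the seed-to-seed spread, so the simpler scheme stayed.
* Refractory periods round *up* to whole steps, making the
  inter-spike-interval ≥ refractory guarantee exact.
* Delays are delivered through a ring buffer; delay < dt is rejected as
  unresolvable configuration.
* The sensory noise term is pre-scaled per step as sigma·sqrt(2·dt/tau),
  drawn from a seeded generator; sigma = 0 gives the fully deterministic
  mode used by the exact symmetry tests.
* Same seed + same input → bit-identical spike times (the kernel is
  single-threaded and order-deterministic).

## Design choices that were genuinely open

* **Leg-1 orientation**: the hardware does not say which microphone is
  0°; only relative angles matter, so sensor 1 sits at 0° and angles grow
  counterclockwise.
* **Refractory percentage base**: read as a fraction of the 500 ms
  estimation window (75 ms at 15 %), since a recency effect needs the
  window timescale; a percentage of the 262 µs aperture (39 µs) could not
  "reset" anything. Both modes are implemented, and the
  aperture-multiple axis of the archived sweep covers the short-refractory
  regime.
* **Refractory carrier**: the dead time is applied to the command neurons.
  Applying it to the sensory neurons instead was implemented and measured:
  once leg spikes become sparse and asynchronous, every isolated +7 kick
  crosses threshold regardless of inhibition timing and the spatial tuning
  collapses to exactly equal rates; that reading was rejected.
* **Sum over all eight legs** in the population vector (the circuit has
  eight command neurons; a five-term sum would break the ring symmetry).
* **Absolute-error summaries**, as above.

## Known limitations

* Single continuous source only. During silent gaps the estimate is
  noise-driven and unstable; the intermittent-source experiment flags such
  windows (`in_gap`) instead of masking them, reproducing the known
  failure mode rather than hiding it.
* Accuracy is not a monotone function of noise: moderate sensory noise
  (sigma ≈ 0.05) measurably *helps* by dithering the phase-locked spike
  timing, and the interaction of scene noise with the ±10 % gain mismatch —
  per-channel SNR dispersion — dominates the error budget at 20 dB. The
  tests assert only the comparison they compute (40 dB scenes localize at
  least as well as 20 dB ones).
* The long-refractory recency mechanism requires the far-side commands to
  be nearly silent; at 20 dB SNR they are not, so window-fraction
  refractories saturate the counts (visible in the archived sweep as large
  errors and undefined windows at 10–20 %).
* Streaming/real-time operation is out of scope; normalization is offline
  over the full recording.
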