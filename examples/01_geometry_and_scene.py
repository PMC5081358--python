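"""Array geometry, propagation delays, and a synthetic 8-channel scene.

Builds the 90 mm circular 8-microphone array, prints its characteristic
delay constants, then renders a short labeled scene of a 1 kHz tone at 1 m
and verifies that the rendered channels realize the geometric delays.
"""

import numpy as np

from scorploc import (
    ChannelMismatch,
    SineWaveform,
    SourceTrajectory,
    make_geometry,
    max_interleg_delay,
    propagation_delay,
    render_scene,
)

g = make_geometry(n_sensors=8, diameter=0.09, sound_speed=343.0)
aperture = max_interleg_delay(g)
print(f"sensor angles (deg): {g.sensor_angles_deg}")
print(f"max inter-leg delay: {aperture * 1e6:.1f} us  "
      "(wavefront travel time across the array; the network's timescale)")
print(f"inhibitory delay   : {0.7 * aperture * 1e6:.1f} us  (70% of it)")

tau = propagation_delay(g, source_bearing_deg=30.0, source_distance=1.0)
print("\ndelays from a source at 30 deg, 1 m (us):",
      np.round(tau * 1e6, 1))

traj = SourceTrajectory(kind="static", start_bearing_deg=30.0, duration_s=0.5)
rec = render_scene(g, traj, SineWaveform(frequency=1000.0),
                   ChannelMismatch.ideal(8), seed=0)
print(f"\nrendered scene: {rec.n_channels} channels x {rec.n_samples} samples "
      f"at {rec.fs:.0f} Hz")

# measure inter-channel phase at the carrier and convert to delay
probe = np.exp(-2j * np.pi * 1000.0 * rec.times())
phases = np.angle(rec.channels @ probe)
measured = (phases[0] - phases) / (2 * np.pi * 1000.0)
print("measured channel delays relative to channel 1 (us):",
      np.round((measured - measured[0]) * 1e6, 2))
print("geometric expectation (us)                        :",
      np.round((tau - tau[0]) * 1e6, 2))
print("\nThe rendered time-of-arrival structure matches the geometry; this "
      "is the cue the spiking network decodes.")
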