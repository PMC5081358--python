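"""The benchmark experiment end to end.

Synthesizes the default scene -- a 1 kHz tone at 1 m sweeping 0 to 360
degrees in 20 s around the array, 20 dB SNR with per-channel gain/offset
mismatch -- normalizes the channels, runs the scorpion spiking network and
decodes one bearing per 500 ms window with the population vector.
"""

from scorploc import ExperimentConfig, run_rotation_experiment

result = run_rotation_experiment(ExperimentConfig(seed=1))

frame = result.series.frame
cols = ["window_center_s", "bearing_deg", "truth_deg", "error_deg"]
print(frame[cols].head(8).to_string(index=False))
print("...")
print(result.summary)
print(
    "\nEach row is one 500 ms window: the decoded bearing follows the "
    "rotating source; the summary is the mean +/- std absolute wrapped "
    "error over the 40 windows.  The sand scorpion manages ~13 deg."
)
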