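"""Numba inner loop for the spiking-network simulation.

Fixed-step Euler integration at dt = one audio sample period, so the
inhibitory synaptic delay quantizes to whole steps well below the array's
262 us aperture.  Kept free of Python objects so numba can compile it; all
unit handling and validation happens in :mod:`scorploc.snn`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_network(
    drive,          # (n_legs, n_steps) normalized input signal s_k
    noise,          # (n_legs, n_steps) pre-scaled noise increments, or (0, 0)
    dt,
    tau_leg,
    tau_cmd,
    v_threshold,
    v_reset,
    w_exc,
    w_inh,
    inh_targets,    # (n_legs, 3) int64: command neurons inhibited by leg k
    delay_steps,    # int: inhibitory synaptic delay in steps (>= 1)
    refr_steps,     # int: command-neuron absolute refractory in steps
    leg_refr_steps, # int: sensory-neuron refractory in steps
    spike_cap,      # int: per-neuron spike buffer size
):
    """Simulate sensory and command neurons; return command spike times.

    Per step:  pending delayed inhibition is delivered to the synaptic
    cascade variable y; sensory neurons integrate
    dv/dt = (1 + s - v)/tau_leg (+ noise) and on spiking inject +w_exc into
    their own command's cascade immediately and schedule w_inh (< 0) onto the
    three opposite commands delay_steps later; command neurons run the
    second-order cascade y -> x -> v and spike at threshold, after which v is
    clamped at reset for the refractory period.
    """
    n_legs, n_steps = drive.shape
    n_cmd = n_legs
    has_noise = noise.shape[1] == n_steps

    v_leg = np.zeros(n_legs)
    y = np.zeros(n_cmd)
    x = np.zeros(n_cmd)
    v = np.zeros(n_cmd)

    pending = np.zeros((delay_steps, n_cmd))
    leg_ok_at = np.zeros(n_legs, dtype=np.int64)   # first step a leg may spike
    cmd_ok_at = np.zeros(n_cmd, dtype=np.int64)

    spike_times = np.empty((n_cmd, spike_cap))
    spike_counts = np.zeros(n_cmd, dtype=np.int64)

    a_leg = dt / tau_leg
    a_cmd = dt / tau_cmd

    for t in range(n_steps):
        # 1. deliver inhibition scheduled delay_steps ago
        slot = t % delay_steps
        for j in range(n_cmd):
            y[j] += pending[slot, j]
            pending[slot, j] = 0.0

        # 2. sensory neurons (Euler + optional noise term)
        for k in range(n_legs):
            dv = a_leg * (1.0 + drive[k, t] - v_leg[k])
            if has_noise:
                dv += noise[k, t]
            v_leg[k] += dv
            if v_leg[k] >= v_threshold and t >= leg_ok_at[k]:
                v_leg[k] = v_reset
                leg_ok_at[k] = t + leg_refr_steps
                y[k] += w_exc                      # own command, no delay
                for m in range(inh_targets.shape[1]):
                    pending[slot, inh_targets[k, m]] += w_inh

        # 3. command neurons: cascade y -> x -> v, threshold, refractory clamp
        for j in range(n_cmd):
            y_old = y[j]
            x_old = x[j]
            y[j] += -a_cmd * y_old
            x[j] += a_cmd * (y_old - x_old)
            if t < cmd_ok_at[j]:
                v[j] = v_reset                     # clamped while refractory
            else:
                v[j] += a_cmd * (x_old - v[j])
                if v[j] >= v_threshold:
                    v[j] = v_reset
                    cmd_ok_at[j] = t + refr_steps
                    if spike_counts[j] < spike_cap:
                        spike_times[j, spike_counts[j]] = t * dt
                        spike_counts[j] += 1

    return spike_times, spike_counts
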