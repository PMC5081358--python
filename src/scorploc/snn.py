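"""The scorpion-inspired spiking network.

The sand scorpion localizes prey from the arrival order of surface waves at
its eight legs.  Each leg drives one excitatory *command* neuron and, via
inhibitory partner neurons, suppresses the command neurons of the three
angularly opposite legs (the *triad*, offsets 135/180/225 degrees).  A wave
arriving from some direction excites the near legs first; their inhibition
reaches the far commands before the wavefront does, so command activity ends
up concentrated on the source side.  Here the "legs" are microphones and the
waves travel in air, but the circuit is unchanged.

Dynamics (all dimensionless, threshold 1, reset 0):

* sensory (leg) neurons, one per channel, driven by the normalized signal
  s_k(t):  dv/dt = (1 + s_k(t) - v)/tau_leg + sigma sqrt(2/tau_leg) xi(t)
  -- a leaky integrator resting just below threshold, pushed over it by the
  positive half-waves of the stimulus;
* each leg spike injects +w_exc into its command neuron's synaptic cascade
  immediately, and w_inh (negative) into each opposite-triad command after
  the inter-neuron delay (the explicit inhibitory relay neurons of the
  anatomical circuit are collapsed into delayed synapses -- a relay with a
  fixed response time is exactly a fixed delay);
* command neurons filter their input through a second-order (alpha-function)
  cascade y -> x and integrate dv/dt = (x - v)/tau_cmd, with an absolute
  refractory period after each spike during which v is clamped at reset.

The network is circulant, so it is exactly equivariant under rotation by one
leg; the tests lean on this symmetry heavily.

Characteristic constants (defaults follow the reference implementation of
the scorpion model): excitatory weight +7, inhibitory weight -2, inter-neuron
delay 0.7 x the maximum inter-leg delay, refractory period equal to the
maximum inter-leg delay.  The refractory period may alternatively be given
as a fraction of the bearing-estimation window (e.g. 0.15 x 500 ms = 75 ms),
where it acts as a recency weight on the windowed spike counts -- the knob
the accuracy experiments sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._kernel import run_network
from .geometry import ArrayGeometry, max_interleg_delay
from .scenes import MultichannelRecording

__all__ = [
    "ModelConfig",
    "NetworkSpec",
    "SpikeTrainSet",
    "TopologyError",
    "SimulationConfigError",
    "triad",
    "build_network",
    "simulate",
]


class TopologyError(ValueError):
    """Raised for leg layouts the triad wiring is not defined for."""


class SimulationConfigError(ValueError):
    """Raised for unresolvable simulation configurations."""


def triad(k: int, n_legs: int = 8) -> set[int]:
    """The three legs angularly opposite leg ``k`` (1-based indices).

    For the 8-leg layout these sit at offsets 135, 180 and 225 degrees, i.e.
    legs k+3, k+4, k+5 wrapped into 1..8.  With legs ordered
    R1,R2,R3,R4,L4,L3,L2,L1 around the circle, the triad of R3 (k=3) is
    {L3, L2, L1} = {6, 7, 8}.  The relation is symmetric:
    j in triad(k)  iff  k in triad(j).
    """
    if n_legs != 8:
        raise TopologyError(f"the opposite-triad wiring is defined for 8 legs, got {n_legs}")
    if not 1 <= k <= n_legs:
        raise TopologyError(f"leg index {k} outside 1..{n_legs}")
    return {((k - 1 + off) % n_legs) + 1 for off in (3, 4, 5)}


@dataclass(frozen=True)
class ModelConfig:
    """All network constants.

    Time-valued fields default to None and are resolved against a concrete
    geometry/recording by :func:`resolve_config`.  Every timescale of the
    reference scorpion model equals (or is a fixed fraction of) that
    animal's maximum inter-leg delay of 1 ms, so here they all follow the
    array's own aperture: inh_delay -> 0.7 x max inter-leg delay;
    refractory, tau_leg, tau_cmd and leg_refractory -> max inter-leg delay;
    dt -> one sample period.  Setting ``refractory_fraction`` instead
    expresses the command refractory as a fraction of the estimation window.
    Any field may be pinned to an absolute value in seconds.
    """

    w_exc: float = 7.0
    w_inh: float = -2.0
    inh_delay: float | None = None
    refractory: float | None = None
    refractory_fraction: float | None = None
    tau_leg: float | None = None
    tau_cmd: float | None = None
    v_threshold: float = 1.0
    v_reset: float = 0.0
    sensory_noise_sigma: float = 0.05
    leg_refractory: float | None = None
    dt: float | None = None

    def __post_init__(self):
        if not self.w_exc > 0:
            raise SimulationConfigError("excitatory weight must be positive")
        if self.w_inh > 0:
            raise SimulationConfigError("inhibitory weight must be <= 0")
        for name in ("tau_leg", "tau_cmd"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise SimulationConfigError(f"{name} must be positive")
        for name in ("inh_delay", "refractory", "leg_refractory", "dt"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise SimulationConfigError(f"{name} must be non-negative")
        if self.refractory_fraction is not None and not (
            0 < self.refractory_fraction < 1
        ):
            raise SimulationConfigError("refractory_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def resolve_config(
    cfg: ModelConfig,
    g: ArrayGeometry,
    fs: float,
    window_length: float = 0.5,
) -> ModelConfig:
    """Fill in geometry- and rate-dependent defaults, returning a concrete config."""
    base = max_interleg_delay(g)
    inh_delay = cfg.inh_delay if cfg.inh_delay is not None else 0.7 * base
    if cfg.refractory_fraction is not None:
        refractory = cfg.refractory_fraction * window_length
    elif cfg.refractory is not None:
        refractory = cfg.refractory
    else:
        refractory = base
    dt = cfg.dt if cfg.dt is not None else 1.0 / fs
    return replace(
        cfg,
        inh_delay=inh_delay,
        refractory=refractory,
        refractory_fraction=None,
        tau_leg=cfg.tau_leg if cfg.tau_leg is not None else base,
        tau_cmd=cfg.tau_cmd if cfg.tau_cmd is not None else base,
        leg_refractory=cfg.leg_refractory if cfg.leg_refractory is not None else base,
        dt=dt,
    )


@dataclass(frozen=True)
class NetworkSpec:
    """Explicit edge lists of the leg -> command wiring.

    ``exc_edges``: (leg, command) pairs with weight w_exc and zero delay,
    one per leg.  ``inh_edges``: (leg, command) pairs with weight w_inh and
    delay ``config.inh_delay``, three per leg (24 total for 8 legs).
    Indices are 0-based.
    """

    n_legs: int
    exc_edges: tuple[tuple[int, int], ...]
    inh_edges: tuple[tuple[int, int], ...]
    config: ModelConfig

    def inh_targets_array(self) -> np.ndarray:
        """(n_legs, 3) int64 array of inhibited command indices per leg."""
        out = np.empty((self.n_legs, 3), dtype=np.int64)
        for k in range(self.n_legs):
            targets = sorted(c for (leg, c) in self.inh_edges if leg == k)
            out[k] = targets
        return out

    def to_dict(self) -> dict:
        return {
            "n_legs": self.n_legs,
            "exc_edges": [list(e) for e in self.exc_edges],
            "inh_edges": [list(e) for e in self.inh_edges],
            "config": self.config.to_dict(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def build_network(g: ArrayGeometry, cfg: ModelConfig | None = None) -> NetworkSpec:
    """Wire the triad topology for the given array.

    Each leg excites its own command neuron and inhibits the commands of its
    opposite triad; geometry-dependent constants (inter-neuron delay,
    refractory default) are left symbolic in the returned config and resolved
    at simulation time against the recording's sample rate.
    """
    if cfg is None:
        cfg = ModelConfig()
    exc = tuple((k, k) for k in range(g.n_sensors))
    inh = tuple(
        (k, j - 1)
        for k in range(g.n_sensors)
        for j in sorted(triad(k + 1, g.n_sensors))
    )
    return NetworkSpec(n_legs=g.n_sensors, exc_edges=exc, inh_edges=inh, config=cfg)


@dataclass
class SpikeTrainSet:
    """Command-neuron spike times from one simulation run.

    ``trains[j]`` is a strictly increasing array of spike times in seconds
    for command neuron j; consecutive spikes are separated by at least the
    refractory period of the configuration used.
    """

    trains: list[np.ndarray]
    duration: float
    config: ModelConfig

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.trains])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (j, t) for j, train in enumerate(self.trains) for t in train
        ]
        return pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate(
    net: NetworkSpec,
    rec: MultichannelRecording,
    cfg: ModelConfig | None = None,
    seed: int = 0,
    window_length: float = 0.5,
) -> SpikeTrainSet:
    """Run the network on a (normalized) multichannel recording.

    The integration step is one sample period; the inhibitory delay is
    rounded to the nearest step and the refractory periods up to the next
    whole step (so the inter-spike-interval guarantee holds exactly).  The
    sensory noise stream is drawn from a generator seeded with ``seed``;
    identical seed and input give bit-identical spike times.
    """
    cfg = cfg if cfg is not None else net.config
    if rec.n_channels != net.n_legs:
        raise SimulationConfigError(
            f"recording has {rec.n_channels} channels, network expects {net.n_legs}"
        )
    if rec.geometry is None:
        raise SimulationConfigError(
            "recording carries no geometry; attach one before simulating"
        )
    rcfg = resolve_config(cfg, rec.geometry, rec.fs, window_length)
    dt = rcfg.dt
    if dt > rcfg.inh_delay:
        raise SimulationConfigError(
            f"time step {dt} s exceeds the inhibitory delay {rcfg.inh_delay} s; "
            "the delay cannot be resolved"
        )
    delay_steps = max(1, int(round(rcfg.inh_delay / dt)))
    refr_steps = int(math.ceil(rcfg.refractory / dt - 1e-9))
    leg_refr_steps = int(math.ceil(rcfg.leg_refractory / dt - 1e-9))

    drive = np.ascontiguousarray(rec.channels, dtype=np.float64)
    n_steps = drive.shape[1]
    if rcfg.sensory_noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = rcfg.sensory_noise_sigma * np.sqrt(2.0 * dt / rcfg.tau_leg)
        noise = rng.normal(0.0, scale, size=drive.shape)
    else:
        noise = np.zeros((drive.shape[0], 0))
    spike_cap = n_steps // max(refr_steps, 1) + 2

    times, counts = run_network(
        drive,
        noise,
        dt,
        rcfg.tau_leg,
        rcfg.tau_cmd,
        rcfg.v_threshold,
        rcfg.v_reset,
        rcfg.w_exc,
        rcfg.w_inh,
        net.inh_targets_array(),
        delay_steps,
        refr_steps,
        leg_refr_steps,
        spike_cap,
    )
    trains = [times[j, : counts[j]].copy() for j in range(net.n_legs)]
    return SpikeTrainSet(trains=trains, duration=rec.duration, config=rcfg)
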