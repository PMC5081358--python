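"""Source waveforms for scene synthesis.

A waveform is a continuous-time function ``s(t)`` that the renderer samples
at the retarded times ``t - tau_j(t)`` of each sensor.  The closed-form
kinds (pure tone, linear sweep, gated bursts) are evaluated exactly at any
real-valued time, so fractional propagation delays introduce no
interpolation error at all.  Arbitrary sampled material (e.g. a WAV file a
user supplies) is wrapped in :class:`SampledWaveform`, which reconstructs
inter-sample values with band-limited windowed-sinc interpolation.

Tones are defined for all t (the source was already playing when the
recording started); gated bursts are zero outside their on-intervals, with a
short raised-cosine ramp at each edge to avoid clicks that no loudspeaker
would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SineWaveform",
    "SweepWaveform",
    "BurstWaveform",
    "SampledWaveform",
]


@dataclass(frozen=True)
class SineWaveform:
    """Pure tone: ``amplitude * sin(2 pi f t + phase)``."""

    frequency: float = 1000.0
    amplitude: float = 1.0
    phase: float = 0.0
    fs: float = 48000.0

    def __post_init__(self):
        if not self.fs > 2.0 * self.frequency:
            raise ValueError(
                f"sample rate {self.fs} Hz violates Nyquist for {self.frequency} Hz"
            )

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.sin(2.0 * np.pi * self.frequency * t + self.phase)

    def rms(self) -> float:
        return self.amplitude / np.sqrt(2.0)


@dataclass(frozen=True)
class SweepWaveform:
    """Linear frequency sweep from ``f_start`` to ``f_end`` over ``duration``.

    Instantaneous phase: ``2 pi (f_start t + (f_end - f_start) t^2 / (2 T))``.
    Outside [0, duration] the chirp formula is extrapolated, which keeps the
    waveform defined at slightly negative retarded times near t = 0.
    """

    f_start: float = 200.0
    f_end: float = 4000.0
    duration: float = 20.0
    amplitude: float = 1.0
    fs: float = 48000.0

    def __post_init__(self):
        if not self.fs > 2.0 * max(self.f_start, self.f_end):
            raise ValueError("sample rate violates Nyquist for the sweep band")

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        k = (self.f_end - self.f_start) / self.duration
        phase = 2.0 * np.pi * (self.f_start * t + 0.5 * k * t * t)
        return self.amplitude * np.sin(phase)

    def rms(self) -> float:
        return self.amplitude / np.sqrt(2.0)


@dataclass(frozen=True)
class BurstWaveform:
    """A carrier tone gated by an on/off schedule.

    ``on_intervals`` lists the (start, stop) times in seconds during which
    the source is audible; everything outside is silence.  This emulates
    intermittent, speech-like stimuli -- in particular a recording with a
    one-second pause -- without needing actual speech material.  Each edge
    is smoothed with a raised-cosine ramp of ``ramp`` seconds.
    """

    carrier_hz: float = 1000.0
    on_intervals: tuple[tuple[float, float], ...] = ((0.0, 20.0),)
    amplitude: float = 1.0
    ramp: float = 0.002
    fs: float = 48000.0

    def __post_init__(self):
        if not self.fs > 2.0 * self.carrier_hz:
            raise ValueError("sample rate violates Nyquist for the carrier")
        for start, stop in self.on_intervals:
            if stop <= start:
                raise ValueError(f"empty on-interval ({start}, {stop})")

    def envelope(self, t):
        t = np.asarray(t, dtype=float)
        env = np.zeros_like(t)
        for start, stop in self.on_intervals:
            seg = np.clip(
                np.minimum(t - start, stop - t) / max(self.ramp, 1e-12), 0.0, 1.0
            )
            env = np.maximum(env, 0.5 - 0.5 * np.cos(np.pi * seg))
        return env

    def silent_intervals(self, duration: float) -> list[tuple[float, float]]:
        """Complement of the on-intervals within [0, duration]."""
        gaps, cursor = [], 0.0
        for start, stop in sorted(self.on_intervals):
            if start > cursor:
                gaps.append((cursor, min(start, duration)))
            cursor = max(cursor, stop)
        if cursor < duration:
            gaps.append((cursor, duration))
        return [(a, b) for a, b in gaps if b > a]

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        carrier = np.sin(2.0 * np.pi * self.carrier_hz * t)
        return self.amplitude * self.envelope(t) * carrier

    def rms(self) -> float:
        # RMS over the on-time; the renderer scales noise to the audible part.
        return self.amplitude / np.sqrt(2.0)


@dataclass(frozen=True)
class SampledWaveform:
    """Band-limited interpolation of an arbitrary sample array.

    Values between samples are reconstructed with a Hann-windowed sinc
    kernel of ``half_width`` taps each side, so fractional delays are
    rendered faithfully rather than rounded to the nearest sample (a
    half-sample rounding error would be ~10 us at 48 kHz, a substantial
    fraction of the 262 us array aperture).  Outside the sampled support the
    waveform is zero.
    """

    samples: np.ndarray
    fs: float = 48000.0
    half_width: int = 32

    def __post_init__(self):
        object.__setattr__(
            self, "samples", np.ascontiguousarray(self.samples, dtype=float)
        )
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")

    def evaluate(self, t):
        scalar = np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        pos = t * self.fs
        n0 = np.floor(pos).astype(np.int64)
        frac = pos - n0
        w = self.half_width
        out = np.zeros_like(t)
        # Gather taps k = n0 - w + 1 .. n0 + w; windowed-sinc weights.
        for k in range(-w + 1, w + 1):
            idx = n0 + k
            valid = (idx >= 0) & (idx < self.samples.size)
            x = frac - k  # distance in samples from the tap
            window = 0.5 + 0.5 * np.cos(np.pi * x / w)
            taps = np.sinc(x) * window
            out += np.where(valid, self.samples[np.clip(idx, 0, self.samples.size - 1)], 0.0) * taps
        return float(out[0]) if scalar else out

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))
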