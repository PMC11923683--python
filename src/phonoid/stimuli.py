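"""Mathematically structured stimuli: Fibonacci and golden-ratio signals.

Four stimulus families are generated here:

* ``inverse_fibonacci_voltage`` — a step sequence V(n) = V0 / F(n+1), where
  F is the Fibonacci sequence (F(1) = F(2) = 1).
* ``golden_ratio_decay`` — an exponential decay V(n) = V0 * phi**(-n/scale)
  whose consecutive terms a fixed number of steps apart are in golden ratio.
* ``fibonacci_tone_bank`` — pure sinusoids at Fibonacci frequencies
  (144, 233, 377, 610, 987, 1597 Hz by default) plus their normalized sum.
* ``fractal_soundscape`` — an additive-synthesis texture whose harmonics
  follow the geometric progression f_n = f0 * phi**n, with random phases and
  slow amplitude modulation at f_mod = f0 / phi**5.

All audio outputs are normalized to peak amplitude 1 and can be serialized to
CSV or 16-bit PCM WAV via :func:`write_stimulus`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .signal_metrics import Signal

log = logging.getLogger(__name__)

#: The golden ratio, phi = (1 + sqrt(5)) / 2.  Satisfies phi**2 == phi + 1.
PHI: float = (1.0 + math.sqrt(5.0)) / 2.0

#: Default Fibonacci tone frequencies in Hz (consecutive Fibonacci numbers).
FIBONACCI_TONE_FREQUENCIES: tuple[float, ...] = (144.0, 233.0, 377.0, 610.0, 987.0, 1597.0)

DEFAULT_SOUNDSCAPE_SEED = 0

__all__ = [
    "PHI",
    "FIBONACCI_TONE_FREQUENCIES",
    "StimulusKind",
    "StimulusSeries",
    "AudioStimulus",
    "fibonacci_sequence",
    "inverse_fibonacci_voltage",
    "golden_ratio_decay",
    "fibonacci_tone_bank",
    "fractal_soundscape",
    "write_stimulus",
    "read_stimulus_csv",
]


class StimulusKind(str, Enum):
    INVERSE_FIBONACCI = "inverse_fibonacci"
    GOLDEN_DECAY = "golden_decay"


@dataclass
class StimulusSeries:
    """Discrete-index voltage sequence with its generation parameters."""

    values: np.ndarray          # volts per step
    kind: StimulusKind
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stimulus values must be finite")

    @property
    def step_index(self) -> np.ndarray:
        return np.arange(self.values.size)

    def __len__(self) -> int:
        return self.values.size

    def to_signal(self, dt: float = 1e-3) -> Signal:
        """View the sequence as a time series with ``dt`` seconds per step."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        return Signal(self.values, sample_rate=1.0 / dt)


@dataclass
class AudioStimulus:
    """Peak-normalized audio waveform with its sinusoidal components."""

    samples: np.ndarray         # dimensionless amplitude in [-1, 1]
    sample_rate: float          # Hz
    components: list[tuple[float, float, float]] = field(default_factory=list)
    # (frequency Hz, amplitude, phase rad) per sinusoidal component

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        nyq = self.sample_rate / 2.0
        for freq, _, _ in self.components:
            if freq >= nyq:
                raise ValueError(f"component at {freq} Hz is at or above Nyquist {nyq} Hz")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def to_signal(self) -> Signal:
        return Signal(self.samples, sample_rate=self.sample_rate)


def fibonacci_sequence(n_terms: int) -> list[int]:
    """First ``n_terms`` Fibonacci numbers, F(1) = F(2) = 1, as exact ints.

    Python integers are arbitrary precision, so large indices (e.g. F(1000))
    are exact.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    seq = [1, 1]
    while len(seq) < n_terms:
        seq.append(seq[-1] + seq[-2])
    return seq[:n_terms]


def inverse_fibonacci_voltage(v0: float, n_steps: int) -> StimulusSeries:
    """Voltage sequence V(n) = v0 / F(n+1) for steps n = 0..n_steps-1.

    The first two values equal ``v0`` (F(1) = F(2) = 1); thereafter the
    sequence decreases following the reciprocal Fibonacci pattern.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    fib = fibonacci_sequence(n_steps)
    values = np.array([v0 / f for f in fib], dtype=float)
    return StimulusSeries(
        values,
        kind=StimulusKind.INVERSE_FIBONACCI,
        params={"v0": v0, "n_steps": n_steps},
    )


def golden_ratio_decay(v0: float, n_steps: int, scale: float = 100.0) -> StimulusSeries:
    """Golden-ratio decay V(n) = v0 * phi**(-n/scale), n = 0..n_steps-1.

    With the default scale of 100, terms 100 steps apart are in exact golden
    ratio and 1000 steps starting at 10 V end near 0.0817 V.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    n = np.arange(n_steps, dtype=float)
    values = v0 * PHI ** (-n / scale)
    return StimulusSeries(
        values,
        kind=StimulusKind.GOLDEN_DECAY,
        params={"v0": v0, "n_steps": n_steps, "scale": scale},
    )


def fibonacci_tone_bank(
    frequencies=FIBONACCI_TONE_FREQUENCIES,
    duration: float = 5.0,
    sample_rate: float = 44100.0,
    amplitudes=None,
    mode: str = "sum",
) -> tuple[list[AudioStimulus], AudioStimulus]:
    """Pure tones at Fibonacci frequencies and their combined waveform.

    Each tone is a unit sinusoid of ``duration`` seconds.  The combined
    output is either the amplitude-weighted superposition (``mode='sum'``,
    default) or the concatenation of the tones (``mode='concat'``), in both
    cases renormalized so max|y| = 1.  Amplitudes default to equal weights.
    """
    frequencies = [float(f) for f in frequencies]
    if duration <= 0:
        raise ValueError("duration must be positive")
    nyq = sample_rate / 2.0
    for f in frequencies:
        if f >= nyq:
            raise ValueError(f"tone at {f} Hz is at or above Nyquist {nyq} Hz")
    if amplitudes is None:
        amplitudes = [1.0] * len(frequencies)
    if len(amplitudes) != len(frequencies):
        raise ValueError("amplitudes must match frequencies in length")
    if mode not in ("sum", "concat"):
        raise ValueError("mode must be 'sum' or 'concat'")

    t = np.arange(round(duration * sample_rate)) / sample_rate
    tones = [
        AudioStimulus(np.sin(2.0 * np.pi * f * t), sample_rate, components=[(f, 1.0, 0.0)])
        for f in frequencies
    ]
    if mode == "sum":
        combined = np.zeros_like(t)
        for f, a in zip(frequencies, amplitudes):
            combined = combined + a * np.sin(2.0 * np.pi * f * t)
    else:
        combined = np.concatenate(
            [a * tone.samples for a, tone in zip(amplitudes, tones)]
        )
    peak = np.max(np.abs(combined))
    if peak > 0:
        combined = combined / peak
    comps = [(f, a / peak if peak > 0 else a, 0.0) for f, a in zip(frequencies, amplitudes)]
    return tones, AudioStimulus(combined, sample_rate, components=comps)


def fractal_soundscape(
    f0: float = 220.0,
    n_harmonics: int = 10,
    sample_rate: float = 44100.0,
    duration: float = 10.0,
    seed: int | None = None,
    modulation_depth: float = 1.0,
) -> AudioStimulus:
    """Golden-ratio harmonic texture with random phases and slow AM.

    Harmonics sit at f_n = f0 * phi**n for n = 0..n_harmonics, each with a
    random phase from the seeded generator.  Components at or above Nyquist
    are dropped with a logged warning (with the 44.1 kHz default the 10th
    harmonic, ~27.1 kHz, aliases and is removed).  The sum is amplitude
    modulated at f_mod = f0 / phi**5 with envelope
    (1 - depth/2) + (depth/2) * sin(2*pi*f_mod*t), then peak-normalized.
    """
    if f0 <= 0 or duration <= 0 or sample_rate <= 0:
        raise ValueError("f0, duration and sample_rate must be positive")
    if n_harmonics < 0:
        raise ValueError("n_harmonics must be >= 0")
    if not 0.0 <= modulation_depth <= 1.0:
        raise ValueError("modulation_depth must be in [0, 1]")
    if seed is None:
        seed = DEFAULT_SOUNDSCAPE_SEED
    rng = np.random.default_rng(seed)

    nyq = sample_rate / 2.0
    freqs = [f0 * PHI**n for n in range(n_harmonics + 1)]
    kept, dropped = [], []
    for f in freqs:
        (kept if f < nyq else dropped).append(f)
    if dropped:
        log.warning(
            "dropping %d soundscape harmonic(s) at or above Nyquist (%.1f Hz): %s",
            len(dropped), nyq, [round(f, 1) for f in dropped],
        )
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(kept))

    t = np.arange(round(duration * sample_rate)) / sample_rate
    z = np.zeros_like(t)
    comps = []
    for f, theta in zip(kept, phases):
        z = z + np.sin(2.0 * np.pi * f * t + theta)
        comps.append((f, 1.0, float(theta)))

    f_mod = f0 / PHI**5
    envelope = (1.0 - modulation_depth / 2.0) + (modulation_depth / 2.0) * np.sin(
        2.0 * np.pi * f_mod * t
    )
    z_mod = z * envelope
    peak = np.max(np.abs(z_mod))
    if peak > 0:
        z_mod = z_mod / peak
    return AudioStimulus(z_mod, sample_rate, components=comps)


def write_stimulus(obj, path, format: str | None = None) -> Path:
    """Serialize a stimulus to CSV or 16-bit PCM WAV.

    CSV columns are ``index,value`` for a :class:`StimulusSeries` and
    ``time_s,value`` for an :class:`AudioStimulus` or :class:`Signal`.
    The format defaults to the file extension.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("csv", "wav"):
        raise ValueError(f"unsupported format {format!r} (csv or wav)")

    if format == "csv":
        if isinstance(obj, StimulusSeries):
            df = pd.DataFrame({"index": obj.step_index, "value": obj.values})
        elif isinstance(obj, (AudioStimulus, Signal)):
            sig = obj.to_signal() if isinstance(obj, AudioStimulus) else obj
            df = pd.DataFrame({"time_s": sig.times, "value": sig.samples})
        else:
            raise TypeError(f"cannot serialize {type(obj).__name__}")
        df.to_csv(path, index=False)
        return path

    if isinstance(obj, StimulusSeries):
        raise TypeError("step sequences have no sample rate; write them as CSV")
    sig = obj.to_signal() if isinstance(obj, AudioStimulus) else obj
    peak = np.max(np.abs(sig.samples))
    scaled = sig.samples / peak if peak > 1.0 else sig.samples
    pcm = np.clip(np.round(scaled * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(round(sig.sample_rate)), pcm)
    return path


def read_stimulus_csv(path, sample_rate: float | None = None) -> Signal:
    """Read a stimulus CSV (``time_s,value`` or ``index,value``) as a Signal.

    Index-based files need an explicit ``sample_rate`` (steps per second).
    """
    df = pd.read_csv(path)
    name = str(df.columns[0]).lower()
    if name.startswith("time"):
        return Signal.from_csv(path)
    if sample_rate is None:
        raise ValueError("sample_rate required for index-based stimulus CSV")
    return Signal(df.iloc[:, 1].to_numpy(dtype=float), sample_rate=sample_rate)
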