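"""Capacitive (RC) model of the proteinoid electrical response.

Proteinoid microsphere ensembles behave electrically like a leaky capacitor:
a resistance R in parallel with a capacitance C, with time constant
tau = R*C.  The reference parameters measured for an L-Glu:L-Phe sample are
R = 128 ohm and C = 2.888 uF, giving tau = 369.664 us.

Under a golden-ratio decaying drive V(n) = V0 * phi**(-n/scale) the capacitor
voltage follows the product of the drive envelope and the textbook charging
term::

    V_c(t_n) = V0 * phi**(-n/scale) * (1 - exp(-t_n / tau)),   t_n = n * dt

so the response starts at zero, charges on the tau time scale and then tracks
the decaying input from below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_metrics import Signal
from .stimuli import PHI

__all__ = ["RCParams", "ImpedanceResult", "time_constant", "golden_capacitive_response", "impedance"]


@dataclass(frozen=True)
class RCParams:
    """Resistance (ohm), capacitance (F) and the step duration dt (s).

    ``dt`` maps the discrete stimulus step index n to physical time
    t_n = n * dt; it defaults to 1 ms.
    """

    R: float
    C: float
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0:
            raise ValueError("R and C must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def tau(self) -> float:
        """Time constant tau = R*C in seconds."""
        return self.R * self.C


@dataclass(frozen=True)
class ImpedanceResult:
    """Impedance magnitude (ohm) and phase (degrees, <= 0) at one frequency."""

    frequency: float
    magnitude: float
    phase: float


def time_constant(R: float, C: float) -> float:
    """tau = R*C in seconds; R in ohms, C in farads."""
    if R <= 0 or C <= 0:
        raise ValueError("R and C must be positive")
    return R * C


def golden_capacitive_response(
    v0: float, params: RCParams, n_steps: int, scale: float = 100.0
) -> Signal:
    """Capacitor voltage under a golden-ratio decaying drive.

    V_c(t_n) = v0 * phi**(-n/scale) * (1 - exp(-t_n/tau)) with t_n = n*dt.
    The response is zero at n = 0 and strictly below the instantaneous drive
    for every later step.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if scale <= 0:
        raise ValueError("scale must be positive")
    n = np.arange(n_steps, dtype=float)
    t = n * params.dt
    vc = v0 * PHI ** (-n / scale) * (1.0 - np.exp(-t / params.tau))
    return Signal(vc, sample_rate=1.0 / params.dt)


def impedance(params: RCParams, frequency: float) -> ImpedanceResult:
    """Parallel-RC impedance at one frequency.

    |Z| = R / sqrt(1 + (2*pi*f*R*C)**2), phase = -atan(2*pi*f*R*C) degrees.
    DC gives (R, 0 deg); the magnitude falls and the phase approaches -90 deg
    as f grows, as for a capacitive element.
    """
    if frequency < 0:
        raise ValueError("frequency must be nonnegative")
    w_rc = 2.0 * math.pi * frequency * params.R * params.C
    magnitude = params.R / math.sqrt(1.0 + w_rc**2)
    phase = -math.degrees(math.atan(w_rc))
    return ImpedanceResult(frequency=frequency, magnitude=magnitude, phase=phase)
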