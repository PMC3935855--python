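"""Calibration model and first-order transient dynamics.

The steady-state signal of a sensor is an affine function of its sorbed
fractions, y_ss = b0 + sum_j b_j x_j; the response to air (x = 0) is the
baseline b0.  Transient signals relax toward the instantaneous steady
state with a first-order step per time unit,

    y(t+1) = y(t) + (y_target - y(t)) / tau,

using tau = tau_rise during the exposition phase and tau = tau_decay
during cleaning, so the residual gap after m steps is exactly
(1 - 1/tau)^m times the initial gap.  With tau = 1 the relaxation is
instantaneous; this is the steady-state-only mode used when the pulse
length tunit is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransientState", "steady_state_signal", "advance_transient"]


@dataclass
class TransientState:
    """Current signal level of one sensor and the phase it is in."""

    y_current: float
    phase: str = "cleaning"  # "exposition" | "cleaning"


def steady_state_signal(baseline: float, sensitivity, sorbed) -> float:
    """Steady-state signal y_ss = b0 + b . x."""
    b = np.asarray(sensitivity, float)
    x = np.asarray(sorbed, float)
    return float(baseline + b @ x)


def advance_transient(y_current: float, y_target: float, tau: float) -> float:
    """One time-unit step of first-order relaxation toward ``y_target``.

    ``tau`` must be >= 1; smaller values would overshoot the target.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    return y_current + (y_target - y_current) / tau
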