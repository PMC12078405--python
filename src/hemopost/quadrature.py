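"""Periodic temporal quadrature over cardiac-cycle phase samples.

Phase samples live at strictly increasing times in [0, T).  Integrals over
one cycle use the periodic trapezoid rule: the sample at t_i carries weight
(t_{i+1} - t_{i-1}) / 2 with wrap-around across the cycle boundary, so the
weights always sum to T exactly.  For uniform spacing every weight is T/N
and a cycle average reduces to the arithmetic mean of the samples.
"""

from __future__ import annotations

import numpy as np

__all__ = ["periodic_weights", "cycle_integral", "cycle_mean"]


def periodic_weights(phase_times: np.ndarray, period: float) -> np.ndarray:
    """Trapezoid weights for one periodic cycle; sum equals ``period``."""
    t = np.asarray(phase_times, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("need at least 2 phases for a temporal statistic")
    dt_next = np.diff(t, append=t[0] + period)
    if np.any(dt_next <= 0):
        raise ValueError("phase_times must be strictly increasing within one period")
    return 0.5 * (dt_next + np.roll(dt_next, 1))


def cycle_integral(samples: np.ndarray, phase_times: np.ndarray,
                   period: float) -> np.ndarray:
    """∫ f dt over one cycle; samples indexed by phase along axis 0."""
    w = periodic_weights(phase_times, period)
    return np.tensordot(w, np.asarray(samples, dtype=float), axes=(0, 0))


def cycle_mean(samples: np.ndarray, phase_times: np.ndarray,
               period: float) -> np.ndarray:
    """(1/T) ∫ f dt over one cycle."""
    return cycle_integral(samples, phase_times, period) / period
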