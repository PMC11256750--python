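"""Shared seasonal-correction convention.

A single trigonometric form is used by both the synthetic observation
generator and the fusion fitter: ``1 + A * cos(2 pi (doy - t_max) / 365.25)``
with day-of-year ``doy`` and period 365.25 days.
"""

from __future__ import annotations

import numpy as np

PERIOD_DAYS = 365.25
_OMEGA = 2.0 * np.pi / PERIOD_DAYS


def seasonal_factor(day_of_year: np.ndarray, amplitude: float, t_max: float) -> np.ndarray:
    """Multiplicative seasonal correction; amplitude < 1 keeps it positive."""
    return 1.0 + amplitude * np.cos(_OMEGA * (np.asarray(day_of_year, float) - t_max))


def phase_to_tmax(a: float, b: float) -> tuple[float, float]:
    """Convert cosine/sine coefficients to (amplitude, peak day-of-year).

    ``a cos(w t) + b sin(w t) = A cos(w (t - t_max))`` with ``A = hypot(a, b)``
    and ``t_max = atan2(b, a)/w`` mapped into (0, 365.25].
    """
    amp = float(np.hypot(a, b))
    t_max = float(np.arctan2(b, a) / _OMEGA % PERIOD_DAYS)
    if t_max < 1.0:
        t_max += PERIOD_DAYS if t_max <= 0 else 0.0
        t_max = max(t_max, 1.0)
    return amp, t_max
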