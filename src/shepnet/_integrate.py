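"""Adaptive explicit Runge-Kutta (4th order) time stepping.

The integrator uses classical RK4 with step-doubling error control: each
trial step of size h is compared against two chained steps of size h/2, and
the Richardson estimate of the local error, (y_half - y_full)/15, is held
below a mixed absolute/relative tolerance per component.  The half-step
solution is kept (no local extrapolation), so the accepted solution is the
plain 4th-order one.

Steps never cross user-supplied breakpoints (tone onsets/offsets, readout
window edges), which keeps the right-hand side smooth inside every step and
lets observers accumulate window integrals exactly on step boundaries.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["StepSizeUnderflow", "integrate_adaptive", "rk4_step"]


class StepSizeUnderflow(RuntimeError):
    """Raised when the controller cannot meet the tolerance above min_step."""

    def __init__(self, t: float, h: float):
        super().__init__(
            f"adaptive RK4 step size underflow at t = {t:.6f} ms (h = {h:.3e} ms)"
        )
        self.t = t
        self.h = h


def rk4_step(f: Callable, t: float, y: np.ndarray, h: float) -> np.ndarray:
    """One classical RK4 step from t to t + h."""
    k1 = f(t, y)
    k2 = f(t + 0.5 * h, y + 0.5 * h * k1)
    k3 = f(t + 0.5 * h, y + 0.5 * h * k2)
    k4 = f(t + h, y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_adaptive(
    f: Callable[[float, np.ndarray], np.ndarray],
    t_span: tuple[float, float],
    y0: np.ndarray,
    *,
    rtol: float = 1e-5,
    atol: float = 1e-5,
    max_step: float = 1.0,
    min_step: float = 1e-4,
    breakpoints: Iterable[float] = (),
    observer: Callable[[float, np.ndarray, float, np.ndarray], None] | None = None,
) -> np.ndarray:
    """Integrate y' = f(t, y) over t_span (ms); return the final state.

    Parameters
    ----------
    f : right-hand side, called as f(t, y) -> dy/dt (same shape as y).
    t_span : (t0, t1) in ms, t1 > t0.
    rtol, atol : per-component mixed error tolerances on the local error.
    max_step, min_step : step-size bounds in ms.
    breakpoints : times the integrator must land on exactly.
    observer : called after every accepted step with
        (t_prev, y_prev, t_new, y_new); y arrays must not be mutated.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError(f"empty time span {t_span}")
    if max_step <= 0 or min_step <= 0 or min_step > max_step:
        raise ValueError("require 0 < min_step <= max_step")

    targets = sorted({float(b) for b in breakpoints if t0 < b < t1} | {t1})
    y = np.asarray(y0, dtype=float).copy()
    t = t0
    h = min(max_step, (t1 - t0) / 10.0)

    for target in targets:
        while t < target - 1e-12:
            h_try = min(h, max_step, target - t)
            while True:
                y_full = rk4_step(f, t, y, h_try)
                y_mid = rk4_step(f, t, y, 0.5 * h_try)
                y_half = rk4_step(f, t + 0.5 * h_try, y_mid, 0.5 * h_try)
                # Richardson: local error of the half-step solution.
                err = np.abs(y_half - y_full) / 15.0
                scale = atol + rtol * np.maximum(np.abs(y), np.abs(y_half))
                ratio = float(np.max(err / scale)) if err.size else 0.0
                if ratio <= 1.0:
                    break
                h_new = 0.9 * h_try * ratio ** (-0.2)
                h_try = max(h_new, 0.2 * h_try)
                if h_try < min_step:
                    raise StepSizeUnderflow(t, h_try)
            t_new = t + h_try
            if observer is not None:
                observer(t, y, t_new, y_half)
            y = y_half
            t = t_new
            # Controller update for the next step (bounded growth).
            if ratio > 0.0:
                h = h_try * min(5.0, max(0.2, 0.9 * ratio ** (-0.2)))
            else:
                h = h_try * 5.0
            h = min(h, max_step)
        t = target
    return y
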