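"""Decision readout: from simulation traces to percepts and psychometrics.

The model's percept for a tone is summarized by the normalized response
difference

    D = (r_up - r_down) / (r_up + r_down),

where r_alpha is the mean activity of population alpha integrated over the
whole tonotopic axis and over the tone's presentation window.  D lies in
[-1, 1]; D > 0 maps to an ascending percept, D < 0 to descending.  A choice
is scored "ascending" when D exceeds a threshold (default 0.1); by the
model's up/down symmetry "descending" is D < -threshold, everything else is
ambiguous.  Trial ensembles are aggregated into psychometric points
P(up) vs N_bias with binomial standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SimulationTrace

__all__ = [
    "DEFAULT_THRESHOLD",
    "Decision",
    "decision",
    "decisions",
    "classify",
    "psychometric",
]

DEFAULT_THRESHOLD = 0.1
_EPS_RATE = 1e-9


@dataclass(frozen=True)
class Decision:
    """Decision variable and percept for one trial and readout window."""

    D: float
    window: tuple[float, float]
    mean_up: float
    mean_down: float
    percept: str  # "ascending" | "descending" | "ambiguous"


def _d_value(mean_up: np.ndarray, mean_down: np.ndarray) -> np.ndarray:
    tot = mean_up + mean_down
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > _EPS_RATE, (mean_up - mean_down) / np.where(tot > 0, tot, 1.0), 0.0)
    return d


def classify(D: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Ascending if D > threshold, descending if D < -threshold, else ambiguous."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if D > threshold:
        return "ascending"
    if D < -threshold:
        return "descending"
    return "ambiguous"


def decision(
    trace: SimulationTrace,
    tone_window: tuple[float, float],
    threshold: float = DEFAULT_THRESHOLD,
    trial: int = 0,
) -> Decision:
    """Decision for one trial of a trace over a tone window.

    If the summed mean activity is below 1e-9 (no response at all), D is
    defined as 0 and the percept flagged ambiguous with a warning.
    """
    t0, t1 = float(tone_window[0]), float(tone_window[1])
    if t1 <= t0:
        raise ValueError("empty readout window")
    ws = trace.window_stats((t0, t1))
    up, dn = float(ws.mean_up[trial]), float(ws.mean_down[trial])
    if up + dn <= _EPS_RATE:
        warnings.warn("no population response in readout window; D set to 0")
        return Decision(0.0, (t0, t1), up, dn, "ambiguous")
    d = float(_d_value(np.asarray(up), np.asarray(dn)))
    return Decision(d, (t0, t1), up, dn, classify(d, threshold))


def decisions(
    trace: SimulationTrace,
    tone_window: tuple[float, float],
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Vectorized decisions for every trial in a batched trace."""
    ws = trace.window_stats((float(tone_window[0]), float(tone_window[1])))
    d = _d_value(ws.mean_up, ws.mean_down)
    choice = np.where(d > threshold, "ascending", np.where(d < -threshold, "descending", "ambiguous"))
    return pd.DataFrame(
        {
            "trial": np.arange(len(d)),
            "D": d,
            "mean_up": ws.mean_up,
            "mean_down": ws.mean_down,
            "choice": choice,
        }
    )


def psychometric(trial_table: pd.DataFrame, by: str = "N_bias") -> pd.DataFrame:
    """Aggregate per-trial choices into psychometric points.

    ``trial_table`` needs columns ``choice`` and the grouping column.  P_up
    is the fraction of trials scored ascending (ambiguous and descending
    trials stay in the denominator); sem is the binomial standard error.
    """
    if len(trial_table) == 0:
        raise ValueError("need at least one trial")
    rows = []
    for key, grp in trial_table.groupby(by, sort=True):
        n = len(grp)
        p = float((grp["choice"] == "ascending").mean())
        rows.append({by: key, "P_up": p, "n_trials": n, "sem": np.sqrt(p * (1.0 - p) / n)})
    return pd.DataFrame(rows)
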