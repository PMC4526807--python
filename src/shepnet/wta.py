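"""Three-variable winner-take-all reduction and phase-plane analysis.

The tonotopic competition between the two direction-selective populations
reduces, near a decision, to two excitatory units E_u and E_d inhibited by
one global inhibitory unit I with (possibly unequal) weights w_iu, w_id:

    tau_E dE_u/dt = -E_u + S_e(w_ee E_u - w_iu I + In_e)
    tau_E dE_d/dt = -E_d + S_e(w_ee E_d - w_id I + In_e)
    tau_I dI/dt   = -I   + S_i(w_ei (E_u + E_d) + In_i)

Prior tones from above/below effectively facilitate w_iu/w_id.  For the
phase plane, I is taken instantaneous, I = S_i(w_ei(E_u+E_d) + In_i),
projecting the dynamics onto the (E_u, E_d) plane.  With symmetric weights
the plane has three steady states — two stable dominance states U
(E_u > E_d) and D (E_u < E_d) and a saddle S on the diagonal; enough
asymmetry leaves a single winner.

The weights carry no canonical values; the defaults below were selected
with ``scan_symmetric`` (shipped) as a set producing the three-state
competition layout with the stability pattern above.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._integrate import integrate_adaptive
from .dynamics import sigmoid

__all__ = [
    "WTAParams",
    "FixedPoint",
    "PhasePortrait",
    "wta_derivatives",
    "i_instantaneous",
    "nullclines",
    "fixed_points",
    "phase_portrait",
    "simulate_wta",
    "scan_asymmetry",
    "scan_symmetric",
]


@dataclass(frozen=True)
class WTAParams:
    """Weights, inputs and time constants of the reduced model.

    Sigmoid parameters and time constants are shared with the full network;
    the default weights give three fixed points (U, D stable; S saddle)
    under symmetric inhibition (see ``scan_symmetric``).
    """

    omega_ee: float = 0.75
    omega_ei: float = 1.0
    omega_iu: float = 1.0
    omega_id: float = 1.0
    in_e: float = 0.65
    in_i: float = 0.0
    tau_e: float = 20.0
    tau_i: float = 30.0
    theta_e: float = 0.5
    k_e: float = 0.1
    theta_i: float = 0.3
    k_i: float = 0.2

    def __post_init__(self):
        if min(self.omega_ee, self.omega_ei, self.omega_iu, self.omega_id) < 0:
            raise ValueError("weights must be non-negative")
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("time constants must be positive")

    def se(self, x):
        return sigmoid(x, self.theta_e, self.k_e)

    def si(self, x):
        return sigmoid(x, self.theta_i, self.k_i)


@dataclass(frozen=True)
class FixedPoint:
    e_u: float
    e_d: float
    i: float
    label: str  # "U" | "D" | "S"
    stability: str  # "stable" | "saddle" | "unstable"
    eigenvalues: tuple[complex, complex]


@dataclass
class PhasePortrait:
    """Sampled nullclines and classified fixed points in the (E_u, E_d) plane."""

    nullcline_u: np.ndarray  # (m, 2) points (E_u, E_d) where dE_u/dt = 0
    nullcline_d: np.ndarray
    fixed_points: list[FixedPoint] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"kind": "nullcline_u", "E_u": p[0], "E_d": p[1]} for p in self.nullcline_u
        ] + [
            {"kind": "nullcline_d", "E_u": p[0], "E_d": p[1]} for p in self.nullcline_d
        ] + [
            {"kind": f"fixed_{fp.label}_{fp.stability}", "E_u": fp.e_u, "E_d": fp.e_d}
            for fp in self.fixed_points
        ]
        return pd.DataFrame(rows)


def wta_derivatives(state: np.ndarray, params: WTAParams) -> np.ndarray:
    """Right-hand side of the full 3-variable system; state = (E_u, E_d, I)."""
    e_u, e_d, i = state
    return np.array(
        [
            (-e_u + params.se(params.omega_ee * e_u - params.omega_iu * i + params.in_e)) / params.tau_e,
            (-e_d + params.se(params.omega_ee * e_d - params.omega_id * i + params.in_e)) / params.tau_e,
            (-i + params.si(params.omega_ei * (e_u + e_d) + params.in_i)) / params.tau_i,
        ]
    )


def i_instantaneous(params: WTAParams, e_u, e_d):
    """Inhibitory rate when I is slaved to the excitatory populations."""
    return params.si(params.omega_ei * (np.asarray(e_u) + np.asarray(e_d)) + params.in_i)


def _reduced_rhs(params: WTAParams, e_u, e_d):
    """(dE_u/dt, dE_d/dt) * tau_e of the reduced planar system."""
    i = i_instantaneous(params, e_u, e_d)
    fu = -np.asarray(e_u) + params.se(params.omega_ee * np.asarray(e_u) - params.omega_iu * i + params.in_e)
    fd = -np.asarray(e_d) + params.se(params.omega_ee * np.asarray(e_d) - params.omega_id * i + params.in_e)
    return fu, fd


def _branch_points(g, n: int) -> list[tuple[float, float]]:
    """All roots of g(e; other) = 0 for e in [0, 1], via sign-change bisection."""
    grid = np.linspace(0.0, 1.0, n)
    vals = np.array([g(e) for e in grid])
    roots = []
    for a, b, va, vb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if va == 0.0:
            roots.append(a)
        elif va * vb < 0:
            roots.append(brentq(g, a, b, xtol=1e-12))
    if vals[-1] == 0.0:
        roots.append(grid[-1])
    return roots


def nullclines(params: WTAParams, n: int = 201) -> PhasePortrait:
    """Sample both nullclines on a dense grid over [0, 1]^2.

    Each nullcline may fold (multiple E_u solutions for one E_d), so it is
    returned as an unordered point set; points satisfy the nullcline
    equation to brentq tolerance.
    """
    pts_u, pts_d = [], []
    for other in np.linspace(0.0, 1.0, n):
        for e in _branch_points(lambda e_u: _reduced_rhs(params, e_u, other)[0], n):
            pts_u.append((e, other))
        for e in _branch_points(lambda e_d: _reduced_rhs(params, other, e_d)[1], n):
            pts_d.append((other, e))
    return PhasePortrait(np.array(pts_u).reshape(-1, 2), np.array(pts_d).reshape(-1, 2))


def _reduced_jacobian(params: WTAParams, e_u: float, e_d: float, h: float = 1e-6) -> np.ndarray:
    """Numerical Jacobian of the reduced planar vector field (rates /tau_e)."""
    def f(v):
        fu, fd = _reduced_rhs(params, v[0], v[1])
        return np.array([fu, fd]) / params.tau_e

    v0 = np.array([e_u, e_d])
    J = np.empty((2, 2))
    for j in range(2):
        dv = np.zeros(2)
        dv[j] = h
        J[:, j] = (f(v0 + dv) - f(v0 - dv)) / (2 * h)
    return J


def fixed_points(
    params: WTAParams,
    n_starts: int = 21,
    tol: float = 1e-10,
    dedup: float = 1e-6,
    diag_tol: float = 1e-4,
) -> list[FixedPoint]:
    """Find and classify all steady states of the reduced system.

    Roots are located by intersecting the E_u-nullcline branches with the
    E_d-nullcline equation along a scan of the plane, polished by 2-D
    Newton iteration, deduplicated, and classified by the eigenvalues of
    the reduced Jacobian (stable / saddle / unstable) and by the sign of
    E_u - E_d (U / D / S with tolerance ``diag_tol``).
    """
    candidates = []
    for e_d in np.linspace(0.0, 1.0, n_starts):
        for e_u in _branch_points(lambda e: _reduced_rhs(params, e, e_d)[0], 201):
            candidates.append((e_u, e_d))
    found = []
    for e_u, e_d in candidates:
        v = np.array([e_u, e_d])
        ok = False
        for _ in range(60):
            fu, fd = _reduced_rhs(params, v[0], v[1])
            r = np.array([fu, fd])
            if np.max(np.abs(r)) < tol:
                ok = True
                break
            J = _reduced_jacobian(params, v[0], v[1]) * params.tau_e
            try:
                step = np.linalg.solve(J, r)
            except np.linalg.LinAlgError:
                break
            v = v - step
            if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > 2.0:
                break
        if not ok:
            continue
        if any(abs(v[0] - f.e_u) < dedup and abs(v[1] - f.e_d) < dedup for f in found):
            continue
        J = _reduced_jacobian(params, v[0], v[1])
        eig = np.linalg.eigvals(J)
        re = np.real(eig)
        if np.max(re) < 0:
            stability = "stable"
        elif re.min() < 0 < re.max():
            stability = "saddle"
        else:
            stability = "unstable"
        if abs(v[0] - v[1]) < diag_tol:
            label = "S"
        elif v[0] > v[1]:
            label = "U"
        else:
            label = "D"
        found.append(
            FixedPoint(float(v[0]), float(v[1]), float(i_instantaneous(params, v[0], v[1])),
                       label, stability, (complex(eig[0]), complex(eig[1])))
        )
    found.sort(key=lambda f: (f.e_u - f.e_d), reverse=True)
    return found


def phase_portrait(params: WTAParams, n: int = 201) -> PhasePortrait:
    """Nullclines plus classified fixed points."""
    portrait = nullclines(params, n)
    portrait.fixed_points = fixed_points(params)
    return portrait


def simulate_wta(
    initial: Sequence[float],
    params: WTAParams,
    t_span: tuple[float, float] = (0.0, 3000.0),
    rtol: float = 1e-5,
    atol: float = 1e-5,
):
    """Integrate the full 3-variable system; returns (t, trajectory (n_t, 3)).

    Uses the same adaptive 4th-order integrator as the network model.
    """
    ts, ys = [t_span[0]], [np.asarray(initial, dtype=float)]

    def observer(t0, y0, t1, y1):
        ts.append(t1)
        ys.append(y1.copy())

    integrate_adaptive(
        lambda t, y: wta_derivatives(y, params),
        t_span,
        np.asarray(initial, dtype=float),
        rtol=rtol,
        atol=atol,
        max_step=1.0,
        observer=observer,
    )
    return np.asarray(ts), np.asarray(ys)


def scan_asymmetry(
    params: WTAParams,
    omega_id_values: Sequence[float],
) -> pd.DataFrame:
    """Fixed-point count as w_id grows from symmetric (continuation scan).

    As w_id increases past a critical value the D and S states collide and
    vanish, leaving only the U state (3 -> 1 transition).
    """
    rows = []
    for w in omega_id_values:
        fps = fixed_points(replace(params, omega_id=float(w)))
        rows.append(
            {
                "omega_id": float(w),
                "n_fixed_points": len(fps),
                "labels": "".join(sorted(f.label for f in fps)),
            }
        )
    return pd.DataFrame(rows)


def scan_symmetric(
    omega_ee_values: Sequence[float] = (0.5, 0.75, 1.0, 1.25, 1.5),
    omega_ei_values: Sequence[float] = (1.0, 2.0),
    omega_i_values: Sequence[float] = (1.0, 1.5, 2.0, 2.5, 3.0),
    in_e_values: Sequence[float] = (0.35, 0.45, 0.55, 0.65),
    in_i: float = 0.0,
) -> pd.DataFrame:
    """Search symmetric weight sets for the three-state competition layout.

    Returns one row per candidate with the fixed-point count, labels and
    stability pattern; rows with ``competition == True`` have exactly three
    states, U and D stable and S a saddle.  This is the utility used to
    select the package defaults.
    """
    rows = []
    for wee in omega_ee_values:
        for wei in omega_ei_values:
            for wi in omega_i_values:
                for ine in in_e_values:
                    p = WTAParams(omega_ee=wee, omega_ei=wei, omega_iu=wi,
                                  omega_id=wi, in_e=ine, in_i=in_i)
                    fps = fixed_points(p)
                    pattern = ",".join(f"{f.label}:{f.stability}" for f in fps)
                    comp = (
                        len(fps) == 3
                        and sorted(f.label for f in fps) == ["D", "S", "U"]
                        and all(f.stability == "stable" for f in fps if f.label in "UD")
                        and all(f.stability == "saddle" for f in fps if f.label == "S")
                    )
                    rows.append(
                        {
                            "omega_ee": wee, "omega_ei": wei, "omega_i": wi,
                            "in_e": ine, "in_i": in_i,
                            "n_fixed_points": len(fps), "pattern": pattern,
                            "competition": comp,
                        }
                    )
    return pd.DataFrame(rows)
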