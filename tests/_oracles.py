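"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's FFT convolution and adaptive stepper:
convolutions are explicit dense-matrix Riemann sums, time stepping is plain
fixed-step RK4, and the gain function is re-derived locally.
"""

from __future__ import annotations

import numpy as np


def direct_conv(kernel: np.ndarray, field: np.ndarray, grid) -> np.ndarray:
    """O(n^2) Riemann-sum convolution: h(x_i) = sum_j w(x_i - x_j) f(x_j) dx."""
    n = grid.n
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    if grid.topology == "ring":
        idx = (i - j) % n
    else:
        idx = (i - j) + (n - 1)
    return (kernel[idx] * field[..., None, :]).sum(axis=-1) * grid.dx


def _gain(x, theta, k):
    x0 = 1.0 / (1.0 + np.exp(theta / k))
    return np.maximum((1.0 / (1.0 + np.exp((theta - x) / k)) - x0) / (1.0 - x0), 0.0)


def fixed_step_rk4(drive, params, kernels, t_end: float, dt: float, checkpoints=()):
    """Fixed-step RK4 reference solution of the network ODEs.

    Uses dense-matrix convolutions built from the sampled kernels.  Returns
    {checkpoint_time: state (4, n)}.  Checkpoints must be multiples of dt.
    """
    grid = drive.grid
    n = grid.n
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    idx = (i - j) % n if grid.topology == "ring" else (i - j) + (n - 1)
    M_ee = kernels.omega_ee[idx] * grid.dx
    M_ei = kernels.omega_ei[idx] * grid.dx
    M_up = kernels.omega_up[idx] * grid.dx
    M_dn = kernels.omega_down[idx] * grid.dx
    a_ie = float(params.a_ie)

    def rhs(t, y):
        r_up, r_dn, r_i, f = y
        inp = drive.evaluate(t)[0]
        g = (1.0 + params.gamma_f * f) * r_i
        h_up = a_ie * (M_up @ g)
        h_dn = a_ie * (M_dn @ g)
        h_ee_u = params.a_ee * (M_ee @ r_up)
        h_ee_d = params.a_ee * (M_ee @ r_dn)
        h_ei = params.a_ei * (M_ei @ (r_up + r_dn))
        return np.stack(
            [
                (-r_up + _gain(h_ee_u - h_up + params.gamma_e * inp, params.theta_e, params.k_e)) / params.tau_e,
                (-r_dn + _gain(h_ee_d - h_dn + params.gamma_e * inp, params.theta_e, params.k_e)) / params.tau_e,
                (-r_i + _gain(h_ei + params.gamma_i * inp, params.theta_i, params.k_i)) / params.tau_i,
                -f / params.tau_fd + r_i * (1.0 - f) / params.tau_fr,
            ]
        )

    y = np.zeros((4, n))
    out = {}
    n_steps = int(round(t_end / dt))
    checkpoints = {round(c / dt): c for c in checkpoints}
    for step in range(n_steps):
        t = step * dt
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if step + 1 in checkpoints:
            out[checkpoints[step + 1]] = y.copy()
    return out
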