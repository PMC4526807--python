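"""Minimal figure helpers for the CLI's --plot flag."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_trace",
    "plot_step_response",
    "plot_sweep",
    "plot_psychometric",
    "plot_portrait",
]


def plot_trace(trace, path, trial: int = 0):
    """Space-time maps of r_up - r_down and of the facilitation level."""
    fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    diff = trace.r_up[:, trial] - trace.r_down[:, trial]
    extent = [trace.t[0], trace.t[-1], trace.grid.st[0], trace.grid.st[-1]]
    im0 = axes[0].imshow(diff.T, aspect="auto", origin="lower", extent=extent, cmap="RdBu_r")
    axes[0].set_ylabel("pitch class (st)")
    fig.colorbar(im0, ax=axes[0], label="r_up - r_down")
    im1 = axes[1].imshow(trace.F[:, trial].T, aspect="auto", origin="lower", extent=extent)
    axes[1].set_xlabel("time (ms)")
    axes[1].set_ylabel("pitch class (st)")
    fig.colorbar(im1, ax=axes[1], label="facilitation F")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_step_response(df, path):
    fig, ax = plt.subplots(figsize=(6, 4))
    for (pause, mode), grp in df.groupby(["pause", "facilitation"]):
        ls = "--" if mode == "on" else "-"
        ax.plot(grp["step"], grp["D"], ls, label=f"pause {pause:g} ms ({mode})")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("step T2 - T1 (st)")
    ax.set_ylabel("D")
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_sweep(df, x, y, path, hue=None):
    fig, ax = plt.subplots(figsize=(6, 4))
    if hue is None:
        ax.plot(df[x], df[y], "o-")
    else:
        for key, grp in df.groupby(hue):
            ax.plot(grp[x], grp[y], "o-", label=f"{hue}={key}")
        ax.legend(fontsize=8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_psychometric(df, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(df["N_bias"], df["P_up"], yerr=2 * df["sem"], fmt="o-", capsize=3)
    ax.set_xlabel("number of bias tones")
    ax.set_ylabel("P(up)")
    ax.set_ylim(-0.02, 1.02)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_portrait(portrait, path, trajectories=()):
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(portrait.nullcline_u[:, 0], portrait.nullcline_u[:, 1], ".", ms=2, label="E_u nullcline")
    ax.plot(portrait.nullcline_d[:, 0], portrait.nullcline_d[:, 1], ".", ms=2, label="E_d nullcline")
    for fp in portrait.fixed_points:
        marker = "o" if fp.stability == "stable" else "x"
        ax.plot(fp.e_u, fp.e_d, marker, color="k", ms=8)
        ax.annotate(fp.label, (fp.e_u, fp.e_d), textcoords="offset points", xytext=(6, 6))
    for traj in trajectories:
        ax.plot(traj[:, 0], traj[:, 1], lw=1)
    ax.set_xlabel("E_u")
    ax.set_ylabel("E_d")
    ax.set_xlim(-0.02, 1)
    ax.set_ylim(-0.02, 1)
    ax.legend(fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
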