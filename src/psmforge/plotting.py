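"""Optional PNG plots (behind the CLI --plots flag)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .km_reconstruct import km_curve


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_state_membership(trace, out_path) -> Path:
    """Stacked area chart of state occupancy per arm."""
    plt = _mpl()
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, arm in zip(axes, ("control", "intervention")):
        a = trace.arms[arm]
        ax.stackplot(a.cycle, a.pfs, a.pps, a.dead,
                     labels=["PFS", "PPS", "dead"], alpha=0.8)
        ax.set_title(arm)
        ax.set_xlabel("month")
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("state occupancy")
    axes[1].legend(loc="center right")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_fit_overlay(ipd, model, out_path, horizon: int = 60, title: str = "") -> Path:
    """Fitted parametric curve over the observed KM step function."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(6, 4))
    km = km_curve(ipd)
    tt = np.linspace(0, max(float(np.max(ipd.time)), 1.0), 200)
    ax.step(tt, km.evaluate(tt), where="post", label="observed KM", lw=1.2)
    tx = np.linspace(0, horizon, 400)
    ax.plot(tx, model.survival(tx), label=f"{model.family} (AIC {model.aic:.1f})")
    ax.set_xlabel("month")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_tornado(tornado_frame, base_icer, out_path) -> Path:
    """Horizontal tornado bars of ICER excursions, widest on top."""
    plt = _mpl()
    rows = tornado_frame[::-1]  # widest at the top of the chart
    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(rows), 2) + 1.5))
    for i, (_, r) in enumerate(rows.iterrows()):
        lo = r["icer_low"] if r["icer_low"] != "" else base_icer
        hi = r["icer_high"] if r["icer_high"] != "" else base_icer
        left, width = min(lo, hi), abs(hi - lo)
        ax.barh(i, width, left=left, height=0.6,
                color="tab:orange" if "engine-failure" in
                (r["status_low"], r["status_high"]) else "tab:blue")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base ICER")
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels(rows["parameter"])
    ax.set_xlabel("ICER")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
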