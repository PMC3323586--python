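"""Figures: spaghetti profiles with per-age density, Kaplan-Meier +
empirical hazard, and the Weibull probability plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import diagnostics
from .mixture import MixtureFit
from .types import IsotopeSeries


def plot_profiles(series_list: list[IsotopeSeries], mix: MixtureFit | None, path) -> None:
    """δ¹³C trajectories for every individual, coloured by the growth
    mixture's most probable foraging component, with the fitted component
    mean curves overlaid."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    assign = mix.hard_assignment() if mix is not None else None
    for i, s in enumerate(series_list):
        color = "C0" if assign is None or assign[i] == 1 else "C3"
        ax.plot(s.ages, s.values, color=color, alpha=0.35, lw=0.8)
    if mix is not None:
        t = mix.age_classes
        ax.step(t, mix.curve(1), where="mid", color="C0", lw=2.5,
                label="component 1 (Subantarctic)")
        ax.step(t, mix.curve(2), where="mid", color="C3", lw=2.5,
                label="component 2 (Antarctic)")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("age (yr)")
    ax.set_ylabel(r"$\delta^{13}$C (‰ VPDB)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_survival(longevities, joint_fit, path) -> None:
    """Kaplan-Meier curve with Greenwood band plus binned empirical hazard
    with its lowess smooth; the hazard CI widens as the risk set shrinks."""
    km = diagnostics.kaplan_meier(longevities)
    hz = diagnostics.empirical_hazard(longevities)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.step(km.times, km.survival, where="post", color="k")
    ax1.fill_between(km.times, km.ci_lower, km.ci_upper, step="post",
                     alpha=0.2, color="k")
    ax1.set_xlabel("age (yr)")
    ax1.set_ylabel("S(t)")
    ax1.set_title("Kaplan-Meier")
    ok = np.isfinite(hz.hazard)
    ax2.plot(hz.bin_centers[ok], hz.hazard[ok], "o", ms=4, color="grey")
    ax2.plot(hz.bin_centers[ok], hz.smoothed[ok], color="C1", lw=2, label="lowess")
    if joint_fit is not None:
        t = np.linspace(max(0.3, km.times.min()), km.times.max(), 100)
        from .joint import weibull_hazard

        eta = float(np.mean(joint_fit.extra["eta_hat"]))
        ax2.plot(t, weibull_hazard(t, eta, joint_fit.mean("v")), "--", color="C0",
                 label="fitted Weibull")
    ax2.set_xlabel("age (yr)")
    ax2.set_ylabel("hazard (1/yr)")
    ax2.legend(frameon=False, fontsize=8)
    ax2.set_title("empirical hazard")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_weibull(wp, path) -> None:
    """log(−log S) vs log t; straight under a Weibull law, slope ≈ shape."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(wp.log_t, wp.log_neg_log_s, "o", ms=4)
    xs = np.array([wp.log_t.min(), wp.log_t.max()])
    ax.plot(xs, wp.intercept + wp.slope * xs, "-", color="C1",
            label=f"slope {wp.slope:.2f}, $R^2$ {wp.r2:.3f}")
    ax.set_xlabel("log t")
    ax.set_ylabel("log(−log S)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
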