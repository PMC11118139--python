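"""Diagnostic plots: the Bell line and per-rate rupture-voltage histograms."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bell_fit import BellFitResult, TensionPoint
from .rupture_detect import RuptureEvent

__all__ = ["plot_bell_line", "plot_voltage_histograms"]


def plot_bell_line(
    points: Sequence[TensionPoint], fit: BellFitResult, path: str | Path
) -> Path:
    """Characteristic tension vs ln(tension rate) with the fitted Bell line."""
    x = np.log([p.r_sigma_n_per_m_s for p in points])
    y = [p.sigma_e_n_per_m for p in points]
    yerr = [p.sigma_se_n_per_m for p in points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(x, y, yerr=yerr, fmt="o", capsize=3, label="tension points")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(
        xs,
        fit.slope_n_per_m * xs + fit.intercept_n_per_m,
        "-",
        label=(
            f"r = {fit.pore_radius_nm:.2f} nm, "
            f"$W_0$ = {fit.w0_kbt:.1f} $k_BT$, $R^2$ = {fit.r_squared:.3f}"
        ),
    )
    ax.set_xlabel(r"ln $R_{\sigma_e}$  (N m$^{-1}$ s$^{-1}$)")
    ax.set_ylabel(r"$\sigma_e$  (N/m)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_voltage_histograms(
    events: Sequence[RuptureEvent], path: str | Path, bins: int = 30
) -> Path:
    """Rupture-voltage histograms, one overlay per loading rate."""
    by_rate: dict[float, list[float]] = {}
    for ev in events:
        if not ev.censored:
            by_rate.setdefault(ev.loading_rate_vpp_per_s, []).append(
                ev.rupture_voltage_vpp
            )
    fig, ax = plt.subplots(figsize=(5, 4))
    for rate in sorted(by_rate):
        ax.hist(by_rate[rate], bins=bins, alpha=0.5, label=f"{rate:g} $V_{{pp}}$/s")
    ax.set_xlabel("rupture voltage ($V_{pp}$)")
    ax.set_ylabel("cells")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
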