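"""Optional figure helpers mirroring the three result surfaces.

Purely cosmetic: every quantitative claim is asserted on the sweep tables,
never on these figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .sweeps import SweepResult

__all__ = ["plot_binary_sweep", "plot_spiking_sweep", "plot_moment_panels"]


def plot_binary_sweep(result: SweepResult, path: str | Path | None = None,
                      fisher_scale: float = 1.0):
    """Three stacked panels: balance residual, Fano reduction, Fisher info.

    ``fisher_scale`` only rescales the displayed Fisher curve (display
    convention; the table always carries the raw value).
    """
    t = result.table
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(5, 8))
    axes[0].plot(t.w_inh, t.balance_residual)
    axes[0].axhline(0.0, ls=":", c="k")
    axes[0].set_ylabel("input balance")
    axes[1].plot(t.w_inh, t.fano_reduction)
    axes[1].set_ylabel("Fano reduction")
    axes[2].plot(t.w_inh, t.fisher_analytic * fisher_scale)
    axes[2].set_ylabel("Fisher information")
    axes[2].set_xlabel("inhibition level $w_I$")
    root = result.meta.get("balance_root")
    if root is not None:
        for ax in axes:
            ax.axvline(root, ls="--", c="gray")
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig


def plot_spiking_sweep(result: SweepResult, path: str | Path | None = None):
    """Mean current (vs threshold) and empirical Fisher information."""
    t = result.table
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(5, 6))
    axes[0].plot(t.w_inh, t.current_balance_nA, "o-")
    axes[0].axhline(0.0, ls=":", c="k")
    axes[0].set_ylabel("mean current $-$ threshold (nA)")
    fi_cols = [c for c in t.columns
               if c.startswith("fisher_empirical")]
    for c in fi_cols:
        se = t[c.replace("fisher_empirical", "fisher_se")]
        axes[1].errorbar(t.w_inh, t[c], yerr=se, fmt="o-", label=c)
    axes[1].set_ylabel("Fisher information (Hz$^{-2}$)")
    axes[1].set_xlabel("inhibition level $w_I$")
    if len(fi_cols) > 1:
        axes[1].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig


def plot_moment_panels(result: SweepResult, path: str | Path | None = None):
    """Four panels: mean count, its bias-derivative, count variance, and the
    empirical Fisher information with its slope**2/variance fit."""
    t = result.table
    fig, axes = plt.subplots(2, 2, sharex=True, figsize=(8, 6))
    axes[0, 0].plot(t.w_inh, t.mean_count, "o-")
    axes[0, 0].set_ylabel(r"$\langle n \rangle$")
    axes[0, 1].plot(t.w_inh, t.mean_slope, "o-")
    axes[0, 1].set_ylabel(r"$d\langle n \rangle/db$ (Hz$^{-1}$)")
    axes[1, 0].plot(t.w_inh, t.count_variance, "o-")
    axes[1, 0].set_ylabel(r"Var$(n)$")
    axes[1, 1].errorbar(t.w_inh, t.fisher_empirical, yerr=t.fisher_se,
                        fmt="o-", c="r", label="empirical")
    axes[1, 1].plot(t.w_inh, t.fisher_gaussian_form, "k--",
                    label=r"slope$^2$/Var fit")
    axes[1, 1].legend(fontsize=8)
    axes[1, 1].set_ylabel("Fisher information (Hz$^{-2}$)")
    for ax in axes[1]:
        ax.set_xlabel("inhibition level $w_I$")
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig
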