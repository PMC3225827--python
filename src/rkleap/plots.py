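"""Diagnostic plots: stability/variance curves and histogram overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stability import _eval_R, _psi_safe

__all__ = ["plot_stability_and_variance", "plot_histogram_overlay"]


def plot_stability_and_variance(R_evals: dict, eps: float | None = None, z_min: float = -12.0):
    """|R(z)| and psi(z) on the negative real axis for several methods.

    ``R_evals`` maps labels to stability-function callables.  When ``eps``
    is given, the admissible variance band ``1 +- eps`` is shaded.
    """
    z = np.linspace(z_min, -1e-9, 2000)
    fig, (ax_r, ax_p) = plt.subplots(1, 2, figsize=(9, 3.5))
    for label, R in R_evals.items():
        ax_r.plot(z, np.abs(_eval_R(R, z)), label=label)
        psi = _psi_safe(R, z)
        ax_p.plot(z, np.where(np.isfinite(psi), psi, np.nan), label=label)
    ax_r.axhline(1.0, color="k", lw=0.5)
    ax_r.set(xlabel="z", ylabel="|R(z)|", ylim=(0, 2))
    if eps is not None:
        ax_p.axhspan(1 - eps, 1 + eps, color="0.85")
    ax_p.axhline(1.0, color="k", lw=0.5)
    ax_p.set(xlabel="z", ylabel="psi(z)", ylim=(0, 3))
    ax_p.legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_histogram_overlay(comparison):
    """Reference pmf (filled) vs method pmf (line) from a HistogramComparison."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(
        comparison.support, comparison.p_ref, step="mid", alpha=0.4, label="reference"
    )
    ax.plot(comparison.support, comparison.p_method, drawstyle="steps-mid", label="method")
    ax.set(xlabel="count", ylabel="probability")
    ax.legend(fontsize=8, title=f"KL = {comparison.kl_bits:.4g} bits")
    fig.tight_layout()
    return fig
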