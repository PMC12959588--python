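"""Basic plots of the analysis results.

Two figures, deliberately plain: stacked per-group densities of the
predicted probability of a favorable outcome (risk strata vs traditional
subgroups), and treatment benefit (absolute risk difference with 95% CIs)
against the group's mean baseline probability, with the overall-effect band.
The underlying numbers are exported by :meth:`HTEResults.figure_data`;
rendering here is convenience, not the product.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_probability_distributions", "plot_treatment_benefit"]


def plot_probability_distributions(results, path=None):
    """Stacked densities of predicted probability per risk stratum and per
    traditional subgroup (a plain ridgeline)."""
    groups = []
    for g, d in results.strata_distributions.items():
        groups.append((f"risk {g}", d))
    for name, block in results.subgroup_distributions.items():
        for g, d in block["distributions"].items():
            groups.append((g, d))

    fig, ax = plt.subplots(figsize=(7, 0.8 * len(groups) + 1.5))
    offset = 0.0
    yticks, ylabels = [], []
    for label, d in reversed(groups):
        if d.density is not None:
            dens = d.density / d.density.max()
            ax.fill_between(d.grid, offset, offset + dens, alpha=0.6, lw=0.8)
        yticks.append(offset)
        ylabels.append(label)
        offset += 1.2
    ax.set_yticks(yticks)
    ax.set_yticklabels(ylabels)
    ax.set_xlabel("predicted probability of favorable outcome")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_treatment_benefit(results, path=None):
    """Group risk differences (with 95% CIs) vs mean baseline probability,
    overall effect as a horizontal band, zero as a dotted line."""
    fig, ax = plt.subplots(figsize=(7, 5))
    ov = results.overall_effect
    ax.axhspan(ov.ci_low, ov.ci_high, color="0.85")
    ax.axhline(ov.risk_difference, color="0.3", ls="--", label="overall effect")
    ax.axhline(0.0, color="0.5", ls=":")

    def _points(effects, marker, label):
        xs = [e.mean_predicted for e in effects if e.defined]
        ys = [e.risk_difference for e in effects if e.defined]
        lo = [e.risk_difference - e.ci_low for e in effects if e.defined]
        hi = [e.ci_high - e.risk_difference for e in effects if e.defined]
        ax.errorbar(
            xs, ys, yerr=np.array([lo, hi]), fmt=marker, capsize=3, label=label
        )

    _points(results.stratum_effects, "o", "risk strata")
    for name, effects in results.subgroup_effects.items():
        _points(effects, "s", name)
    ax.set_xlabel("mean predicted probability of favorable outcome")
    ax.set_ylabel("absolute risk difference (treated - control)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
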