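"""Rendering: ECE plots, reliability plots, histograms, cost-vs-threshold.

Plots are pure views — every figure writes a sidecar table (CSV) with the
exact arrays drawn, so tests and downstream tooling assert on numbers, not
pixels.  Axis conventions: prior/threshold axes in base-10 logs, entropy
axes in bits.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .bayes import LRSet, log10_from_natural
from .discrimination import ReliabilityTable
from .entropy import ECECurve

__all__ = [
    "render_ece_plot",
    "render_reliability_plot",
    "render_histogram",
    "render_cost_curve",
]


def _sidecar(path: Path, frame: pd.DataFrame) -> Path:
    side = path.with_suffix(path.suffix + ".csv")
    frame.to_csv(side, index=False)
    return side


def render_ece_plot(curve: ECECurve, path) -> Path:
    """Draw the ECE plot: solid system ECE, dashed PAV-calibrated reference,
    dotted neutral (LR = 1 always); x prior log10-odds, y bits.

    Returns the sidecar CSV path holding the plotted arrays.
    """
    if curve.ece_min is None:
        raise ValueError(
            "ECECurve.ece_min is not populated; compute the PAV reference "
            "first (ecelab.pav.ece_decomposition or ece_curve(with_pav=True))"
        )
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    x = curve.prior_log10_odds
    ax.plot(x, curve.ece, "r-", label="ECE")
    ax.plot(x, curve.ece_min, "b--", label="ECE min (PAV-calibrated)")
    ax.plot(x, curve.neutral, "k:", label="LR = 1 always")
    ax.set_xlabel(r"prior $\log_{10}$ odds")
    ax.set_ylabel("ECE (bits)")
    ax.set_ylim(bottom=0)
    if curve.name:
        ax.set_title(curve.name)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return _sidecar(
        path,
        pd.DataFrame(
            {
                "prior_log10_odds": x,
                "ece": curve.ece,
                "ece_min": curve.ece_min,
                "neutral": curve.neutral,
            }
        ),
    )


def render_reliability_plot(table: ReliabilityTable, path) -> Path:
    """Reliability (empirical calibration) plot: mean stated posterior vs
    observed θ1 frequency per bin; empty bins are omitted from the figure
    but kept in the sidecar table with count 0."""
    path = Path(path)
    occupied = table.count > 0
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot([0, 1], [0, 1], "k:", label="perfect calibration")
    ax.plot(
        table.mean_predicted[occupied],
        table.frequency[occupied],
        "o-",
        label="observed",
    )
    ax.set_xlabel(r"stated posterior $P(\theta_1\mid x)$")
    ax.set_ylabel(r"empirical frequency of $\theta_1$")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return _sidecar(path, table.to_frame())


def render_histogram(lr_set: LRSet, path, bins="fd") -> Path:
    """Per-class histograms of base-10 log-LRs (Freedman–Diaconis default
    binning); infinite values are dropped from the figure, counted in the
    sidecar."""
    path = Path(path)
    x = log10_from_natural(lr_set.log_lr)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    rows = []
    for lab, name, color in ((1, r"$\theta_1$", "tab:blue"),
                             (0, r"$\theta_2$", "tab:red")):
        vals = x[lr_set.label == lab]
        finite = vals[np.isfinite(vals)]
        if finite.size:
            counts, edges = np.histogram(finite, bins=bins)
            ax.stairs(counts, edges, fill=True, alpha=0.45, color=color,
                      label=name)
            rows.append(
                pd.DataFrame(
                    {
                        "class": lab,
                        "bin_left": edges[:-1],
                        "bin_right": edges[1:],
                        "count": counts,
                        "n_infinite_dropped": vals.size - finite.size,
                    }
                )
            )
    ax.set_xlabel(r"$\log_{10}$ LR")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    side = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return _sidecar(path, side)


def render_cost_curve(curve, path) -> Path:
    """Expected cost vs log10 decision threshold, one line per prior, with
    the Bayes threshold of each prior marked as a vertical line."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5.5, 4))
    x = log10_from_natural(curve.log_thresholds)
    frames = []
    for i, prior in enumerate(curve.priors):
        (line,) = ax.plot(x, curve.cost[i], label=f"P(θ1)={prior.p1:g}")
        ax.axvline(
            log10_from_natural(curve.bayes_log_threshold[i]),
            color=line.get_color(),
            linestyle=":",
        )
        frames.append(
            pd.DataFrame(
                {
                    "prior_p1": prior.p1,
                    "log10_threshold": x,
                    "expected_cost": curve.cost[i],
                    "bayes_log10_threshold": log10_from_natural(
                        curve.bayes_log_threshold[i]
                    ),
                }
            )
        )
    ax.set_xlabel(r"$\log_{10}$ threshold")
    ax.set_ylabel("expected cost")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return _sidecar(path, pd.concat(frames, ignore_index=True))
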