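"""Figures: metric-vs-age scatter with phase fits, and onset step curves."""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from .breakpoint import CriticalAgeResults
from .survival import OnsetSurvivalResults
from .vision import better_eye_series

__all__ = ["plot_biphasic", "plot_onset_curves"]


def plot_biphasic(records: Iterable, results: CriticalAgeResults, path: Optional[str] = None):
    """Scatter of the better-eye metric against age with the fitted phase
    lines and the critical age marked; saves to ``path`` if given."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ages, values = better_eye_series(records, results.metric)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ages, values, s=18, alpha=0.6, edgecolor="none")
    spans = []
    if results.critical_age is not None:
        ax.axvline(results.critical_age, ls="--", color="grey", lw=1)
        spans = [(results.phase1, ages.min(), results.critical_age),
                 (results.phase2, results.critical_age, ages.max())]
    else:
        spans = [(results.phase1, ages.min(), ages.max())]
    for fitted, lo, hi in spans:
        if fitted is None:
            continue
        xs = np.linspace(lo, hi, 50)
        ax.plot(xs, fitted.intercept + fitted.slope * xs, color="green", lw=2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("logMAR (better eye)" if results.metric == "va"
                  else "VF width, degrees (better eye)")
    if results.metric == "va":
        ax.invert_yaxis()  # worse acuity downward, clinical convention
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_onset_curves(results: OnsetSurvivalResults, path: Optional[str] = None):
    """Kaplan-Meier step plot of symptom-free fraction per genotype group."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in results.curves.items():
        xs = [0.0] + list(curve.times)
        ys = [1.0] + list(curve.survival)
        ax.step(xs, ys, where="post", label=f"{label} (n={curve.at_risk[0] if curve.at_risk else 0})")
    ax.set_xlabel("age (years)")
    ax.set_ylabel(f"fraction without {results.symptom}")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
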