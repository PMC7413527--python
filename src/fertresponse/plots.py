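"""Optional matplotlib figures: response curves and optimal-dose histograms.

matplotlib is an optional dependency; importing this module without it
installed raises a clear error at call time, not at package import.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .optimize import MODAL_BINS, NUTRIENTS, DoseRecommendation, response_curve

__all__ = ["plot_response_curves", "plot_dose_distribution"]


def _pyplot():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        return plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib (pip install fertresponse[plots])"
        ) from exc


def plot_response_curves(predictors: dict[str, object], fixed_doses,
                         path, dose_bounds=(250.0, 110.0, 208.0),
                         n_points: int = 100, ylabel: str = "prediction"):
    """One panel per nutrient; one curve per named predictor.

    ``predictors`` maps a label to a dose-response callable (see
    :func:`fertresponse.optimize.model_response`).  Writes the figure to
    ``path`` and returns it.
    """
    plt = _pyplot()
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, nut, bound in zip(axes, NUTRIENTS, dose_bounds):
        for label, fn in predictors.items():
            doses, preds = response_curve(fn, fixed_doses, nut, (0.0, bound),
                                          n_points)
            ax.plot(doses, preds, label=label)
        ax.set_xlabel(f"{nut} dose (kg/ha)")
    axes[0].set_ylabel(ylabel)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_dose_distribution(rec: DoseRecommendation, path,
                           dose_bounds=(250.0, 110.0, 208.0)):
    """Histograms of per-posterior-sample optimal doses per nutrient, with
    the mean-curve optimum marked."""
    if rec.per_sample_optima is None:
        raise ValueError("recommendation carries no posterior samples")
    plt = _pyplot()
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for j, (ax, nut) in enumerate(zip(axes, NUTRIENTS)):
        ax.hist(rec.per_sample_optima[:, j], bins=MODAL_BINS,
                range=(0.0, dose_bounds[j]), color="tab:gray")
        if rec.mean_curve_optimum is not None:
            ax.axvline(rec.mean_curve_optimum[j], color="k", lw=1.5,
                       label="mean-curve optimum")
        ax.set_xlabel(f"optimal {nut} dose (kg/ha)")
    axes[0].set_ylabel("samples")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
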