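"""Matplotlib figures for the standard analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .fitting import FitResult
from .model import SACCADE_TYPES, expected_ratio_curves

_COLORS = {
    "intra_object": "tab:red",
    "trans_object": "tab:blue",
    "object_to_background": "tab:orange",
    "background_to_object": "tab:green",
    "background_to_background": "0.5",
}


def _save(fig, path: str | Path) -> None:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ratio_curves(curves, path, model_fit: FitResult | None = None) -> None:
    """Empirical per-order type ratios, optionally with the fitted model's
    expected curves and the expected switch order 1/p_sw."""
    ratios = np.asarray(getattr(curves, "ratios", curves))
    orders = np.arange(1, len(ratios) + 1)
    nrows = 2 if model_fit is not None else 1
    fig, axes = plt.subplots(nrows, 1, figsize=(6, 3 * nrows), squeeze=False)
    for name, col in zip(SACCADE_TYPES, range(5)):
        axes[0, 0].plot(orders, ratios[:, col], color=_COLORS[name], label=name)
    axes[0, 0].set_ylabel("ratio (empirical)")
    axes[0, 0].legend(fontsize=7)
    if model_fit is not None:
        q = expected_ratio_curves(model_fit.best_params).probs
        qo = np.arange(1, len(q) + 1)
        for name, col in zip(SACCADE_TYPES, range(5)):
            axes[1, 0].plot(qo, q[:, col], color=_COLORS[name], label=name)
        if model_fit.best_params.p_sw > 0:
            axes[1, 0].axvline(1 / model_fit.best_params.p_sw, color="m", ls="--")
        axes[1, 0].set_ylabel("ratio (model)")
    axes[-1, 0].set_xlabel("saccade order")
    _save(fig, path)


def plot_gof_profile(fit: FitResult, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    finite = np.where(np.isfinite(fit.gof_profile), fit.gof_profile, np.nan)
    ax.plot(fit.grid[: len(finite)], finite, "o-")
    ax.axvline(fit.best_params.p_sw, color="k", ls="--")
    ax.set_xlabel("$p_{SW}$")
    ax.set_ylabel("max GoF")
    _save(fig, path)


def plot_gof_planes(fit: FitResult, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, plane, title, best in (
        (axes[0], fit.plane_early, "early mode",
         (fit.best_params.p_intra_e, fit.best_params.p_trans_e)),
        (axes[1], fit.plane_late, "late mode",
         (fit.best_params.p_intra_l, fit.best_params.p_trans_l)),
    ):
        finite = np.where(np.isfinite(plane), plane, np.nan)
        im = ax.imshow(
            finite.T, origin="lower", aspect="auto",
            extent=(fit.grid[0], fit.grid[-1], fit.grid[0], fit.grid[-1]),
        )
        ax.plot(*best, "kx", ms=10)
        ax.set_xlabel("$p_{intra}$")
        ax.set_ylabel("$p_{trans}$")
        ax.set_title(title)
        fig.colorbar(im, ax=ax, label="GoF")
    _save(fig, path)


def plot_binned_parameters(binned: dict, path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3))
    for ax, key, label in (
        (axes[0], "fixation_duration", "fixation duration (s)"),
        (axes[1], "saccade_amplitude", "saccade amplitude (deg)"),
    ):
        curve = binned[key]
        centers = curve.bin_edges[:-1] + np.diff(curve.bin_edges) / 2
        ax.errorbar(centers, curve.mean, yerr=curve.sem, fmt="o-")
        ax.set_xlabel("time from stimulus onset (s)")
        ax.set_ylabel(label)
    _save(fig, path)


def plot_event_histograms(hist: dict, path) -> None:
    fig, axes = plt.subplots(2, 2, figsize=(10, 5), sharex=True)
    centers = hist["bin_edges"][:-1] + np.diff(hist["bin_edges"]) / 2
    for kind, color, row in (("object", "tab:red", 0), ("background", "0.5", 1)):
        axes[0, 0].plot(centers, hist["fixation_counts"][row], color=color, label=kind)
        axes[1, 0].plot(centers, hist["fixation_ratios"][row], color=color, label=kind)
    for name, row in zip(SACCADE_TYPES, range(5)):
        axes[0, 1].plot(centers, hist["saccade_counts"][row], color=_COLORS[name], label=name)
        axes[1, 1].plot(centers, hist["saccade_ratios"][row], color=_COLORS[name])
    axes[0, 0].set_ylabel("fixation count")
    axes[1, 0].set_ylabel("fixation ratio")
    axes[0, 1].set_ylabel("saccade count")
    axes[1, 1].set_ylabel("saccade ratio")
    for ax in axes[1]:
        ax.set_xlabel("time from stimulus onset (s)")
    axes[0, 0].legend(fontsize=7)
    axes[0, 1].legend(fontsize=6)
    _save(fig, path)


def plot_object_counts(counts: dict, path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    edges = counts["interval_edges"]
    centers = edges[:-1] + np.diff(edges) / 2
    width = np.diff(edges).mean() * 0.4
    ax.bar(centers - width / 2, counts["objects_mean"], width,
           yerr=counts["objects_sem"], color="0.6", label="objects fixated")
    ax.bar(centers + width / 2, counts["fixations_mean"], width,
           yerr=counts["fixations_sem"], color="w", edgecolor="k", label="fixations")
    ax.set_xlabel("trial interval (s)")
    ax.legend(fontsize=8)
    _save(fig, path)
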