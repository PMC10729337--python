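"""The three instability plots.

Every figure is a derived view of numbers that are also exported as CSV by
:meth:`InstabilityResults.save`; plots never hold data that cannot be
re-derived from the report tables (plus the raw multiverse for the scatter).
Figures are written as both SVG and PNG.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .engine import CalibrationInstability
from .exceptions import ValidationError

#: scatter points above this count are subsampled for drawing (bands are
#: always computed from all points)
SCATTER_CAP = 2_000_000
_SCATTER_SUBSEED = 711


def _save(fig, out: str | Path | None):
    if out is None:
        return None
    out = Path(out)
    stem = out.with_suffix("") if out.suffix in (".svg", ".png") else out
    paths = []
    for ext in (".svg", ".png"):
        p = stem.with_suffix(ext)
        fig.savefig(p, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def _axes(ax):
    if ax is not None:
        return ax.figure, ax
    return plt.subplots(figsize=(5.5, 5.5))


def plot_prediction_instability(results, out=None, ax=None):
    """Scatter of bootstrap predictions against the original prediction.

    Solid diagonal = perfect agreement between a bootstrap model and the
    original model; dashed lines are the per-individual 2.5th/97.5th
    percentile bounds (drawn against the sorted original predictions). The
    vertical spread of points is the instability.
    """
    preds = results.predictions
    fig, ax = _axes(ax)
    x = np.repeat(preds.original, preds.B)
    y = preds.multiverse.ravel()
    subsampled = False
    if x.size > SCATTER_CAP:
        keep = np.random.default_rng(_SCATTER_SUBSEED).choice(
            x.size, SCATTER_CAP, replace=False
        )
        x, y = x[keep], y[keep]
        subsampled = True
    ax.scatter(x, y, s=2, alpha=0.15, color="#1f77b4", rasterized=True, lw=0)
    order = np.argsort(preds.original)
    ax.plot([0, 1], [0, 1], color="black", lw=1.2)
    ax.plot(
        preds.original[order],
        results.interval_lower[order],
        "--",
        color="crimson",
        lw=1.0,
    )
    ax.plot(
        preds.original[order],
        results.interval_upper[order],
        "--",
        color="crimson",
        lw=1.0,
    )
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Predicted risk, original model")
    ax.set_ylabel("Predicted risk, bootstrap models")
    title = f"Prediction instability (B = {preds.B})"
    if subsampled:
        title += f"\n(scatter subsampled to {SCATTER_CAP:,} points; bands use all)"
    ax.set_title(title)
    saved = _save(fig, out)
    return saved if out is not None else ax


def plot_classification_instability(results, threshold, out=None, ax=None):
    """Per-individual classification instability index vs original prediction.

    The vertical reference marks the decision threshold; the index peaks for
    individuals whose original prediction sits near it.
    """
    if threshold not in results.cii:
        raise ValidationError(
            f"CII was not computed at threshold {threshold}; "
            f"available: {sorted(results.cii)}"
        )
    fig, ax = _axes(ax)
    ax.scatter(
        results.predictions.original,
        results.cii[threshold],
        s=4,
        alpha=0.4,
        color="#1f77b4",
        lw=0,
    )
    ax.axvline(threshold, color="black", ls=":", lw=1.0)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Predicted risk, original model")
    ax.set_ylabel("Classification instability index")
    ax.set_title(f"Classification instability at t = {threshold:g}")
    saved = _save(fig, out)
    return saved if out is not None else ax


def plot_calibration_instability(
    calibration: CalibrationInstability, out=None, ax=None
):
    """Overlay of bootstrap calibration curves with the original curve.

    Light solid lines: bootstrap-model curves on the original sample; dashed
    line: the original model's curve; solid diagonal: ideal calibration.
    Curves are clipped to their own fitted support (no extrapolation).
    """
    if calibration is None or (
        not calibration.bootstrap_curves and calibration.original_curve is None
    ):
        raise ValidationError("no calibration curves to plot")
    fig, ax = _axes(ax)
    for curve in calibration.bootstrap_curves:
        ax.plot(
            curve.grid, curve.smoothed_observed, color="#9ecae1", lw=0.6, alpha=0.6
        )
    oc = calibration.original_curve
    lim = max(0.05, float(oc.grid.max()) * 1.1)
    ax.plot([0, 1], [0, 1], color="black", lw=1.2)
    ax.plot(oc.grid, oc.smoothed_observed, "--", color="crimson", lw=1.4)
    ax.set_xlim(0, min(1.0, lim))
    ax.set_ylim(0, min(1.0, lim))
    ax.set_xlabel("Predicted risk")
    ax.set_ylabel("Smoothed observed risk")
    ax.set_title(
        f"Calibration instability ({len(calibration.bootstrap_curves)} bootstrap "
        f"curves)\nmax per-grid-point spread = {calibration.max_spread:.3f}"
    )
    saved = _save(fig, out)
    return saved if out is not None else ax
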