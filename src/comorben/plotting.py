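"""Minimal step-curve plotting (benefit-curve overlays)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .enumeration import StepCurve

__all__ = ["plot_step_curves"]


def plot_step_curves(
    curves: dict[str, StepCurve],
    path=None,
    ax=None,
    xlabel: str = "benefit threshold",
    ylabel: str = "probability of at least this benefit",
    title: str | None = None,
):
    """Overlay step curves; each curve is drawn with its 0+ intercept (the
    any-benefit probability), matching how these curves are read clinically.

    Returns the axes; saves to ``path`` if given.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        xs = [0.0]
        ys = [curve.intercept]
        for t, v in zip(curve.thresholds, curve.values):
            xs.append(float(t))
            ys.append(float(v))
        # value v_i holds on the interval up to and including threshold t_i
        ax.step(xs, ys, where="pre", label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_xlim(0, 1)
    ax.set_ylim(bottom=0)
    if title:
        ax.set_title(title)
    if len(curves) > 1:
        ax.legend(fontsize="small")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
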