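"""Basic OR-curve plotting."""

from __future__ import annotations

from .curves import ORCurve


def plot_or_curve(curve: ORCurve, ax=None, color="C0", label=None):
    """Plot a standardized OR curve with its 95% credible band.

    Returns the matplotlib axes; a log-scaled y axis, the reference line
    at OR = 1, and the reference age are marked.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(curve.ages, curve.lo, curve.hi, alpha=0.25, color=color, lw=0)
    ax.plot(curve.ages, curve.median, color=color, label=label or curve.source)
    ax.axhline(1.0, color="0.5", lw=0.8, ls="--")
    ax.axvline(curve.reference_age, color="0.8", lw=0.8)
    ax.set_yscale("log")
    ax.set_xlabel(f"{curve.axis} age (years)")
    ax.set_ylabel(f"odds ratio vs age {curve.reference_age}")
    if curve.outcome:
        ax.set_title(curve.outcome)
    if label or curve.source:
        ax.legend(frameon=False)
    return ax
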