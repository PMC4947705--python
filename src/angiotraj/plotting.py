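"""Minimal per-stage figures (threshold-sweep performance curves)."""

from __future__ import annotations

from .rules import RuleEvaluation

__all__ = ["plot_threshold_sweep"]


def plot_threshold_sweep(evaluations: list[RuleEvaluation], ax=None,
                         highlight_threshold: float | None = 0.5, **plot_kw):
    """Failure rate (1 - prediction rate) against mean %PFS prediction time.

    Points toward the lower left predict more patients earlier; the
    conventionally highlighted point marks the 50%-over-nadir rule.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xs = [e.mean_prediction_time for e in evaluations]
    ys = [100.0 - e.prediction_rate for e in evaluations]
    ax.plot(xs, ys, marker="o", **plot_kw)
    if highlight_threshold is not None:
        for e in evaluations:
            if e.threshold_fraction == highlight_threshold:
                ax.plot(e.mean_prediction_time, 100.0 - e.prediction_rate,
                        marker="D", markersize=10, color="black", zorder=5)
    ax.set_xlabel("mean prediction time (% of PFS)")
    ax.set_ylabel("patients without prediction (%)")
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    return ax
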