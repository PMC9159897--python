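"""Rendering of individual control charts."""

from __future__ import annotations

__all__ = ["plot_chart"]


def plot_chart(results, ax=None):
    """Draw one fitted I-chart: series, centreline, 2-sigma and 3-sigma
    lines, baseline pair greyed out, signalling points flagged."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    series = results.series
    chart = results.chart
    x = list(series.session_index)
    y = list(series.scores)

    ax.plot(x, y, "o-", color="0.25", lw=1, ms=4, label="score")
    ax.plot(x[:2], y[:2], "o", color="0.7", ms=5, label="baseline pair")
    ax.axhline(chart.centreline, color="tab:blue", lw=1.2, label="centreline")
    for level, style, lab in (
        (chart.ucl, "-", "3$\\sigma$ control"),
        (chart.lcl, "-", None),
        (chart.uwl, "--", "2$\\sigma$ warning"),
        (chart.lwl, "--", None),
    ):
        ax.axhline(level, color="tab:red", lw=0.9, ls=style, label=lab)
    flagged = sorted({s.index for s in results.signals})
    if flagged:
        ax.plot(
            [x[i - 1] for i in flagged],
            [y[i - 1] for i in flagged],
            "o",
            mfc="none",
            mec="tab:red",
            ms=11,
            mew=1.6,
            label="signal",
        )
    ax.set_xlabel("session")
    ax.set_ylabel("score")
    ax.set_title(f"{series.patient_id}: {results.outcome.label}")
    ax.legend(loc="best", fontsize=8)
    return ax
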