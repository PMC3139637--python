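"""Optional plots (reaction-vs-disparity, proportion-changing curves).

Requires matplotlib (``pip install gbsearch[plot]``); imported lazily so the
core package has no plotting dependency.
"""

from __future__ import annotations

from pathlib import Path

from .engine import FeedbackMode, GameLog
from .stats import _group_reactions, proportion_changing


def plot_reaction_response(logs: list[GameLog], path: str | Path) -> Path:
    """Scatter of total group reaction vs prior disparity, with the optimal line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, mode in zip(axes, (FeedbackMode.NUMERIC, FeedbackMode.DIRECTIONAL)):
        x, y = _group_reactions(logs, mode)
        ax.scatter(x, y, s=8, alpha=0.4)
        if len(x):
            lim = max(x.max(), 1.0)
            ax.plot([0, lim], [0, lim], "k--", label="optimal (reaction = disparity)")
        ax.set_title(f"{mode} feedback")
        ax.set_xlabel("disparity magnitude before round")
        ax.legend(loc="upper left", fontsize=8)
    axes[0].set_ylabel("total group reaction")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_proportion_changing(logs: list[GameLog], path: str | Path) -> Path:
    """Proportion of members changing guesses vs rounds before solution."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = proportion_changing(logs)
    fig, ax = plt.subplots(figsize=(5, 4))
    if report.table is not None:
        for cls, sub in report.table.groupby("size_class"):
            ax.plot(
                sub["rounds_before_solution"], sub["proportion"], marker="o", label=cls
            )
    ax.set_xlabel("rounds before solution")
    ax.set_ylabel("proportion of members changing guess")
    ax.invert_xaxis()
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
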