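"""Figures: violin plots of active-state probability distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .compare import ActiveStateDistribution

__all__ = ["plot_active_state_distributions"]


def plot_active_state_distributions(
    distributions: dict[str, ActiveStateDistribution],
    reference: str | None = None,
    path=None,
):
    """Violin plot of per-system bootstrap distributions.

    The middle bar of each violin marks the median, the outer bars the
    extremes; a dashed line marks the reference median when given.
    Returns the matplotlib figure; saves it if ``path`` is given.
    """
    labels = list(distributions)
    data = [distributions[l].values for l in labels]
    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    parts = ax.violinplot(data, showmedians=True, showextrema=True)
    for body in parts["bodies"]:
        body.set_alpha(0.6)
    if reference is not None and reference in distributions:
        ax.axhline(distributions[reference].median, ls="--", color="k", lw=1)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("active state probability")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
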