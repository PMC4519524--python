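"""Report figures: stay-probability bar charts by previous outcome and transition."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .factorial import OUTCOME_CATS, TRANSITIONS


def plot_stay_probabilities(long: pd.DataFrame, ax=None, title: str | None = None):
    """Group-mean stay probabilities as the standard 2x2 bar chart.

    ``long`` is the long-format table from :func:`twostep.stay_long_table`
    (optionally pre-filtered to one group/valence).  Bars show the mean
    stay probability by previous outcome (better/worse) and previous
    transition (common/rare) with s.e.m. whiskers; the crossover between
    common and rare bars is the model-based signature, a pure
    better-vs-worse step the model-free one.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    width = 0.35
    xs = np.arange(len(OUTCOME_CATS))
    for k, trans in enumerate(TRANSITIONS):
        sub = long[long["transition"] == trans]
        stats = sub.groupby("outcome_cat")["stay_p"].agg(["mean", "sem"])
        stats = stats.reindex(list(OUTCOME_CATS))
        ax.bar(xs + (k - 0.5) * width, stats["mean"], width, yerr=stats["sem"],
               label=trans, capsize=3)
    ax.set_xticks(xs, OUTCOME_CATS)
    ax.set_xlabel("previous outcome")
    ax.set_ylabel("P(stay)")
    ax.set_ylim(0, 1)
    ax.legend(title="previous transition", fontsize=8)
    if title:
        ax.set_title(title)
    return ax
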