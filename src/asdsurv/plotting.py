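"""Score-distribution plots (classification-score histograms by class)."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def plot_score_histogram(scores, truth: Mapping[str, str], ax=None,
                         bins: int = 20):
    """Overlaid histograms of prediction scores for cases vs non-cases.

    The vertical line marks the vote-share cutoff; mass of the wrong class
    on either side of it is the misclassified fraction.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    s = scores.as_mapping()
    for cls, color in (("case", "tab:blue"), ("noncase", "tab:red")):
        vals = [s[cid] for cid, t in truth.items() if t == cls]
        ax.hist(vals, bins=bins, range=(0, 1), alpha=0.55, color=color,
                label=cls)
    ax.axvline(scores.cutoff, color="black", lw=1.2, ls="--",
               label=f"cutoff {scores.cutoff:.3f}")
    ax.set_xlabel("classification score (fraction of trees voting case)")
    ax.set_ylabel("children")
    ax.legend()
    return ax
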