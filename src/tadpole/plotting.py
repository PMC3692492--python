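"""Dot-plot rendering.

Dot-plots show every raw data point and therefore expose the "kissing
tadpoles" signature of asymmetric outlier handling that bar charts conceal:
after manipulation, each group's tail facing the other group is attenuated.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .manipulations import TwoGroupStudy

__all__ = ["render_dotplot"]


def render_dotplot(
    study: TwoGroupStudy,
    path: str | Path,
    *,
    jitter: float = 0.08,
    seed: int = 0,
    title: str | None = None,
) -> Path:
    """Write a two-column jittered dot-plot with group means as bars.

    Every raw point is drawn (one matplotlib path per group, so the plotted
    point count equals the data count); horizontal jitter is deterministic
    for a given ``seed``.  Output format follows the file suffix (.png/.svg).
    """
    if study.group_high.size == 0 or study.group_low.size == 0:
        raise ValueError("cannot plot an empty group")
    path = Path(path)
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(4, 5))
    for pos, (label, values) in enumerate(
        zip(study.labels, (study.group_high, study.group_low))
    ):
        x = pos + rng.uniform(-jitter, jitter, size=values.size)
        ax.plot(x, values, "o", markersize=4, alpha=0.6, label=label)
        ax.hlines(values.mean(), pos - 0.22, pos + 0.22, colors="black", linewidth=2)
    ax.set_xticks([0, 1], study.labels)
    ax.set_xlim(-0.6, 1.6)
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
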