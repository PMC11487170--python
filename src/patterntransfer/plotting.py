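"""Optional figure helpers: pattern-weight heatmaps and projection dot plots."""

from __future__ import annotations

from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .factorization import Factorization
from .io_formats import SampleAnnotation, annotations_by_sample
from .projection import ProjectionResult

__all__ = ["pattern_heatmap", "projection_dotplot"]


def pattern_heatmap(fact: Factorization, ax=None):
    """Samples x patterns heatmap of sample weights (blue low, red high)."""
    if ax is None:
        _, ax = plt.subplots(
            figsize=(1.0 + 0.45 * fact.k, 1.0 + 0.22 * len(fact.sample_ids))
        )
    im = ax.imshow(fact.P.T, aspect="auto", cmap="coolwarm")
    ax.set_xticks(range(fact.k), fact.pattern_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(fact.sample_ids)), fact.sample_ids, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label="sample weight")
    ax.set_xlabel("pattern")
    return ax


def projection_dotplot(
    result: ProjectionResult,
    annotations: Iterable[SampleAnnotation],
    pattern: str,
    ax=None,
):
    """Projected scores for one pattern, one dot per target sample,
    grouped by tissue x state."""
    ann = annotations_by_sample(annotations)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    groups: dict[tuple[str, str], list[float]] = {}
    for s in result.target_sample_ids:
        a = ann[s]
        groups.setdefault((a.tissue, a.state), []).append(
            float(result.scores.loc[pattern, s])
        )
    labels = sorted(groups)
    for x, key in enumerate(labels):
        ys = groups[key]
        ax.scatter(np.full(len(ys), x), ys, s=18, alpha=0.8)
    ax.set_xticks(range(len(labels)), [f"{t}\n{s}" for t, s in labels], fontsize=7)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_ylabel("projected score")
    ax.set_title(pattern)
    return ax
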