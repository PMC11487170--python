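"""Classify factorization patterns, pick the pattern count, find marker genes.

A fitted pattern is useful when its sample weights track a biological
factor (tissue, physiological state, or a tissue x state combination)
rather than a single sample or a technical covariate such as sequencing
depth.  This module operationalizes that visual judgement with three
statistics per pattern:

* dominance — largest sample weight over the weight sum; near 1 for a
  pattern that loads on one sample only (over-factorization noise);
* eta² — fraction of sample-weight variance explained by grouping the
  samples by tissue, by state, or by tissue x state cell;
* depth correlation — Pearson r between sample weights and library size;
  |r| near 1 marks a technical, depth-driven pattern.

The pattern count is chosen as the largest scanned k at which no pattern
is sample-specific; technical patterns are permitted at selection time
and removed afterwards.  Pattern markers use the scaled-amplitude
distance statistic: each gene's amplitude row is compared against the
unit indicator of each pattern and assigned to the nearest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .factorization import Factorization
from .io_formats import ExpressionMatrix, SampleAnnotation, annotations_by_sample

__all__ = [
    "Thresholds",
    "PatternInfo",
    "PatternClassification",
    "PatternMarkerTable",
    "classify_patterns",
    "select_pattern_count",
    "drop_technical_patterns",
    "pattern_markers",
]

CATEGORIES = (
    "tissue",
    "state",
    "tissue_state",
    "sample_specific",
    "technical",
    "unclassified",
)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for pattern classification.

    dominance: a pattern is sample-specific when the best sample weight
    among the dominating sample's replicate group-mates falls below this
    fraction of the top weight (real programs keep replicates within
    jitter/depth variation of each other, well above 1/3; single-sample
    patterns leave them near the noise floor); eta2: minimum
    explained-variance fraction to call a metadata category; depth:
    minimum |Pearson r| with library size to call a pattern technical;
    eta2_guard: a pattern whose tissue x state cell means explain at
    least this fraction of weight variance is treated as group-driven
    even when replicate support is low (protects noisy but genuinely
    cell-specific patterns from the sample-specific call).
    """

    dominance: float = 0.5
    eta2: float = 0.5
    eta2_guard: float = 0.75
    depth: float = 0.8


@dataclass
class PatternInfo:
    pattern_id: str
    category: str
    dominance: float
    eta2_tissue: float
    eta2_state: float
    eta2_interaction: float
    depth_correlation: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class PatternClassification:
    patterns: list[PatternInfo]

    def categories(self) -> list[str]:
        return [p.category for p in self.patterns]

    def has_category(self, category: str) -> bool:
        return category in self.categories()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pattern": p.pattern_id,
                    "category": p.category,
                    "dominance": p.dominance,
                    "eta2_tissue": p.eta2_tissue,
                    "eta2_state": p.eta2_state,
                    "eta2_interaction": p.eta2_interaction,
                    "depth_correlation": (
                        "" if p.depth_correlation is None else p.depth_correlation
                    ),
                }
                for p in self.patterns
            ]
        )


def _eta_squared(values: np.ndarray, groups: Sequence) -> float:
    """Between-group sum of squares over total sum of squares."""
    values = np.asarray(values, dtype=float)
    grand = values.mean()
    tss = float(np.sum((values - grand) ** 2))
    if tss == 0.0:
        return 0.0
    bss = 0.0
    for g in set(groups):
        sel = values[[i for i, x in enumerate(groups) if x == g]]
        bss += len(sel) * (sel.mean() - grand) ** 2
    return float(min(max(bss / tss, 0.0), 1.0))


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def classify_patterns(
    fact: Factorization,
    annotations: Iterable[SampleAnnotation],
    thresholds: Thresholds = Thresholds(),
) -> PatternClassification:
    """Assign one category per pattern from its sample-weight profile.

    Decision cascade: technical (|depth correlation| >= tau_depth, when
    library sizes are available) → sample-specific → tissue / state /
    tissue_state by eta² against tau_eta → unclassified.  All statistics
    are invariant to sample order and to rescaling a pattern's weights by
    a positive constant.

    A pattern is sample-specific when it separates its dominating sample
    from that sample's own replicate group: the group (tissue x state)
    must have at least 2 samples and the best weight among the group
    mates must fall below ``tau_dom`` times the top weight.  A pattern
    driven by tissue or state keeps all replicates of the dominating
    sample's group high, so this fires only for single-sample
    (over-factorization) patterns.
    """
    ann = annotations_by_sample(annotations)
    missing = [s for s in fact.sample_ids if s not in ann]
    if missing:
        raise ValueError(f"samples without annotation: {missing[:5]}")
    if len(fact.sample_ids) < 2:
        raise ValueError("need at least 2 samples to classify patterns")

    tissues = [ann[s].tissue for s in fact.sample_ids]
    states = [ann[s].state for s in fact.sample_ids]
    cells = list(zip(tissues, states))
    lib = [ann[s].library_size for s in fact.sample_ids]
    have_depth = all(v is not None for v in lib)
    cell_counts: dict[tuple[str, str], int] = {}
    for c in cells:
        cell_counts[c] = cell_counts.get(c, 0) + 1

    infos: list[PatternInfo] = []
    for j in range(fact.k):
        w = fact.P[j]
        total = w.sum()
        dominance = float(w.max() / total) if total > 0 else 0.0
        e_t = _eta_squared(w, tissues)
        e_s = _eta_squared(w, states)
        e_i = _eta_squared(w, cells)
        depth_r = _pearson(w, np.asarray(lib, dtype=float)) if have_depth else None

        top = int(np.argmax(w))
        siblings = [
            i for i in range(len(w)) if i != top and cells[i] == cells[top]
        ]
        sibling_support = (
            max(w[i] for i in siblings) / w[top] if siblings and w[top] > 0 else 1.0
        )

        if depth_r is not None and abs(depth_r) >= thresholds.depth:
            category = "technical"
        elif (
            siblings
            and w[top] > 0
            and sibling_support < thresholds.dominance
            and e_i < thresholds.eta2_guard
        ):
            category = "sample_specific"
        elif e_t >= thresholds.eta2 and e_s < thresholds.eta2:
            category = "tissue"
        elif e_s >= thresholds.eta2 and e_t < thresholds.eta2:
            category = "state"
        elif e_i >= thresholds.eta2:
            category = "tissue_state"
        else:
            category = "unclassified"
        infos.append(
            PatternInfo(
                pattern_id=fact.pattern_ids[j],
                category=category,
                dominance=dominance,
                eta2_tissue=e_t,
                eta2_state=e_s,
                eta2_interaction=e_i,
                depth_correlation=depth_r,
            )
        )
    return PatternClassification(patterns=infos)


def select_pattern_count(
    classifications: Mapping[int, PatternClassification],
) -> int:
    """Largest scanned k at which every pattern shows tissue and/or state
    specificity and none is sample-specific.

    A k is disqualified by a sample-specific pattern or by a pattern with
    no metadata specificity at all (unclassified); technical patterns do
    not disqualify (they are dropped afterwards, not kept).
    """
    ks = sorted(classifications)
    if not ks:
        raise ValueError("empty scan")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"scan is not a contiguous k range: {ks}")
    disqualifying = {"sample_specific", "unclassified"}
    clean = [
        k
        for k in ks
        if not (disqualifying & set(classifications[k].categories()))
    ]
    if not clean:
        raise ValueError(
            "every scanned pattern count produced a sample-specific pattern; "
            "more replicates per tissue/state group are needed"
        )
    return max(clean)


def drop_technical_patterns(
    fact: Factorization,
    classification: PatternClassification,
    X: ExpressionMatrix | np.ndarray | None = None,
) -> Factorization:
    """Remove technical patterns (A columns and P rows); others untouched.

    If the training matrix ``X`` is supplied the Frobenius error is
    recomputed for the reduced model; otherwise the stored full-model
    error is kept.
    """
    if len(classification.patterns) != fact.k:
        raise ValueError("classification does not match factorization k")
    keep = [
        j
        for j, p in enumerate(classification.patterns)
        if p.category != "technical"
    ]
    if not keep:
        raise ValueError("all patterns are technical; nothing would remain")
    if len(keep) == fact.k:
        return fact
    A = fact.A[:, keep]
    P = fact.P[keep]
    err = fact.frobenius_error
    if X is not None:
        Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
        err = float(np.linalg.norm(Xv - A @ P))
    return Factorization(
        gene_ids=list(fact.gene_ids),
        sample_ids=list(fact.sample_ids),
        A=A,
        P=P,
        k=len(keep),
        frobenius_error=err,
        seed=fact.seed,
        iterations=fact.iterations,
        converged=fact.converged,
        pattern_ids=[fact.pattern_ids[j] for j in keep],
    )


@dataclass
class PatternMarkerTable:
    """Per-gene pattern assignment with a specificity distance and rank."""

    table: pd.DataFrame  # columns: gene_id, pattern, marker_score, rank
    unassigned: list[str] = field(default_factory=list)  # all-zero amplitude rows

    def top_markers(self, pattern: str, n: int) -> list[str]:
        sub = self.table[self.table["pattern"] == pattern]
        return list(sub.sort_values("rank")["gene_id"].head(n))


def pattern_markers(fact: Factorization) -> PatternMarkerTable:
    """Assign each gene to the pattern it marks most specifically.

    Each amplitude column is scaled to unit maximum; gene g's scaled row
    is compared with the unit indicator e_j of every pattern j by
    Euclidean distance, and g is assigned to the nearest indicator (ties
    go to the lowest pattern index).  Within a pattern, rank 1 is the
    smallest distance, i.e. the most exclusive marker.
    """
    if fact.k < 2:
        raise ValueError("pattern markers need k >= 2")
    A = fact.A
    if not A.any():
        raise ValueError("amplitude matrix is all zero")
    colmax = A.max(axis=0)
    scale = np.where(colmax > 0, colmax, 1.0)
    S = A / scale[None, :]

    nonzero = A.any(axis=1)
    unassigned = [g for g, nz in zip(fact.gene_ids, nonzero) if not nz]

    rows = []
    eye = np.eye(fact.k)
    for gi in np.nonzero(nonzero)[0]:
        d = np.linalg.norm(S[gi][None, :] - eye, axis=1)
        j = int(np.argmin(d))  # argmin takes the lowest index on ties
        rows.append((fact.gene_ids[gi], fact.pattern_ids[j], float(d[j])))
    frame = pd.DataFrame(rows, columns=["gene_id", "pattern", "marker_score"])
    frame["rank"] = (
        frame.groupby("pattern")["marker_score"]
        .rank(method="first", ascending=True)
        .astype(int)
    )
    return PatternMarkerTable(table=frame, unassigned=unassigned)
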