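"""Transfer learned gene weights into a new dataset and test sample groups.

Given an amplitude matrix A learned in a source dataset, projection asks
how strongly each source pattern is expressed in every sample of a
target dataset.  Across species the two gene namespaces are first
reconciled through a one-to-one ortholog map — only genes with orthologs
in both the reference and the target are used.  Each target sample's
(optionally gene-centered) expression vector y is then regressed on the
aligned gene weights by unconstrained ordinary least squares,
``scores = argmin_b ‖y − A·b‖²``; scores may be negative, and a higher
score means the sample's profile resembles the pattern.  Group
differences (e.g. torpor vs euthermia) are tested per pattern with a
two-sided two-sample Student's t-test (pooled variance by default,
Welch behind a flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, OrthologMap, SampleAnnotation, annotations_by_sample

__all__ = [
    "AlignedPair",
    "GroupTest",
    "ProjectionResult",
    "restrict_to_orthologs",
    "project_patterns",
    "compare_groups",
]

logger = logging.getLogger(__name__)

_TINY_P = float(np.finfo(float).tiny)


@dataclass
class AlignedPair:
    """Source gene weights and target expression on a shared ortholog row space."""

    A: pd.DataFrame  # shared genes (source namespace) x patterns
    Y: pd.DataFrame  # shared genes (source namespace) x target samples
    target_gene_ids: list[str]
    n_dropped: int


@dataclass
class GroupTest:
    pattern: str
    state_a: str
    state_b: str
    t_statistic: float
    df: float
    p_value: float
    n_a: int
    n_b: int
    tissue: str | None = None


@dataclass
class ProjectionResult:
    """Per-sample scores of source patterns in a target dataset."""

    source_pattern_ids: list[str]
    target_sample_ids: list[str]
    scores: pd.DataFrame  # patterns x target samples
    n_genes_used: int
    group_tests: list[GroupTest] = field(default_factory=list)

    def tests_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pattern": t.pattern,
                    "tissue": "" if t.tissue is None else t.tissue,
                    "state_a": t.state_a,
                    "state_b": t.state_b,
                    "t_statistic": t.t_statistic,
                    "df": t.df,
                    "p_value": t.p_value,
                    "n_a": t.n_a,
                    "n_b": t.n_b,
                }
                for t in self.group_tests
            ]
        )


def restrict_to_orthologs(
    A_source: pd.DataFrame,
    Y_target: ExpressionMatrix,
    omap: OrthologMap,
    source_species: str | None = None,
) -> AlignedPair:
    """Align source gene weights and target expression on ortholog pairs.

    ``A_source`` is indexed by source gene ids (columns = patterns).  The
    orientation — whether the source namespace is ``omap.species_a`` or
    ``omap.species_b`` — is taken from ``source_species`` or inferred
    from which side the source gene ids overlap; overlapping both sides
    is ambiguous and raises.  Pairs absent from either input are dropped
    (count logged).  Output rows follow the map's pair order.
    """
    if source_species is not None:
        if source_species == omap.species_a:
            oriented = omap
        elif source_species == omap.species_b:
            oriented = omap.reversed()
        else:
            raise ValueError(
                f"source_species {source_species!r} is neither "
                f"{omap.species_a!r} nor {omap.species_b!r}"
            )
    else:
        src = set(map(str, A_source.index))
        hits_a = any(a in src for a, _ in omap.pairs)
        hits_b = any(b in src for _, b in omap.pairs)
        if hits_a and hits_b:
            raise ValueError(
                "ambiguous orientation: source gene ids match both sides of "
                "the ortholog map; pass source_species explicitly"
            )
        if hits_a:
            oriented = omap
        elif hits_b:
            oriented = omap.reversed()
        else:
            raise ValueError("no source gene id matches either side of the ortholog map")

    src_index = set(map(str, A_source.index))
    tgt_index = {g: i for i, g in enumerate(Y_target.gene_ids)}
    keep_src: list[str] = []
    keep_tgt: list[str] = []
    for s, t in oriented.pairs:
        if s in src_index and t in tgt_index:
            keep_src.append(s)
            keep_tgt.append(t)
    n_dropped = len(oriented.pairs) - len(keep_src)
    if not keep_src:
        raise ValueError("no ortholog pair is present in both inputs")
    if n_dropped:
        logger.info("restrict_to_orthologs: dropped %d/%d pairs absent from an input",
                    n_dropped, len(oriented.pairs))
    A = A_source.loc[keep_src].astype(float)
    Yv = Y_target.values[[tgt_index[t] for t in keep_tgt]]
    Y = pd.DataFrame(Yv, index=keep_src, columns=Y_target.sample_ids)
    return AlignedPair(A=A, Y=Y, target_gene_ids=keep_tgt, n_dropped=n_dropped)


def project_patterns(
    aligned: AlignedPair | tuple[pd.DataFrame, pd.DataFrame],
    center: bool = True,
) -> ProjectionResult:
    """Solve per-sample least squares Y ≈ A·scores over the aligned genes.

    With ``center`` on (the default) each gene's mean across target
    samples is subtracted from Y; A is left untouched.  No intercept and
    no non-negativity constraint: projected scores take both signs.
    """
    if isinstance(aligned, AlignedPair):
        A, Y = aligned.A, aligned.Y
    else:
        A, Y = aligned
    Av = A.to_numpy(dtype=float)
    Yv = Y.to_numpy(dtype=float)
    n_genes, k = Av.shape
    if n_genes < k:
        raise ValueError(
            f"only {n_genes} shared genes for {k} patterns; need at least k"
        )
    if n_genes < 2:
        raise ValueError("need at least 2 shared genes")
    rank = int(np.linalg.matrix_rank(Av))
    if rank < k:
        corr = np.corrcoef(Av.T)
        collinear = [
            (str(A.columns[i]), str(A.columns[j]))
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(
            f"gene-weight matrix is rank-deficient on shared genes "
            f"(rank {rank} < {k}); collinear pattern pairs: {collinear}"
        )
    if center:
        Yv = Yv - Yv.mean(axis=1, keepdims=True)
    scores, *_ = np.linalg.lstsq(Av, Yv, rcond=None)
    return ProjectionResult(
        source_pattern_ids=[str(c) for c in A.columns],
        target_sample_ids=[str(c) for c in Y.columns],
        scores=pd.DataFrame(scores, index=A.columns, columns=Y.columns),
        n_genes_used=n_genes,
    )


def compare_groups(
    result: ProjectionResult,
    annotations: Iterable[SampleAnnotation],
    pattern: str,
    state_a: str,
    state_b: str,
    tissue: str | None = None,
    equal_var: bool = True,
) -> GroupTest:
    """Two-sided two-sample Student's t-test on one pattern's scores.

    Pooled (equal-variance) by default with df = n_a + n_b − 2; Welch via
    ``equal_var=False``.  Both groups need at least 2 samples.  The test
    record is appended to ``result.group_tests`` and returned.
    """
    ann = annotations_by_sample(annotations)
    if pattern not in result.scores.index:
        raise ValueError(f"unknown pattern {pattern!r}")

    def _group(state: str) -> np.ndarray:
        vals = [
            result.scores.loc[pattern, s]
            for s in result.target_sample_ids
            if s in ann
            and ann[s].state == state
            and (tissue is None or ann[s].tissue == tissue)
        ]
        return np.asarray(vals, dtype=float)

    ga, gb = _group(state_a), _group(state_b)
    where = f" in tissue {tissue!r}" if tissue else ""
    if len(ga) < 2:
        raise ValueError(f"state {state_a!r}{where} has {len(ga)} samples; need >= 2")
    if len(gb) < 2:
        raise ValueError(f"state {state_b!r}{where} has {len(gb)} samples; need >= 2")

    if equal_var:
        df = len(ga) + len(gb) - 2
    if ga.std() == 0 and gb.std() == 0 and ga.mean() == gb.mean():
        t, p = 0.0, 1.0
        if not equal_var:
            df = len(ga) + len(gb) - 2
    else:
        res = stats.ttest_ind(ga, gb, equal_var=equal_var)
        t = float(res.statistic)
        p = float(res.pvalue)
        df = float(res.df)
        if not np.isfinite(t):  # zero pooled variance, different means
            t = float(np.sign(ga.mean() - gb.mean()) * np.inf)
        p = min(max(p, _TINY_P), 1.0)
    record = GroupTest(
        pattern=pattern, state_a=state_a, state_b=state_b,
        t_statistic=t, df=float(df), p_value=p,
        n_a=len(ga), n_b=len(gb), tissue=tissue,
    )
    result.group_tests.append(record)
    return record
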