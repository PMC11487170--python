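"""Preranked weighted gene-set enrichment of non-negative pattern weights.

Genes are ordered by their (non-negative) amplitude in one pattern and a
gene set's enrichment score is the maximum of the classic weighted
running sum: walking down the ranking, a member gene at rank i adds
``w_i^exponent / Σ_members w^exponent`` and a non-member subtracts
``1/(N − N_members)``.  Because the weights are non-negative, only the
positive deviation is scored (the "pos" regime), so ES ∈ [0, 1].
Significance comes from a gene-label permutation null: random same-size
gene subsets drawn without replacement, with the permutation p-value
``(1 + #{null ES ≥ observed}) / (1 + n_perm)`` and NES = ES / mean(null
ES).  BH adjustment is applied across the sets tested for one pattern.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, OrthologMap

__all__ = [
    "rank_genes_by_pattern",
    "enrichment_score",
    "gsea_pos",
]

logger = logging.getLogger(__name__)


def rank_genes_by_pattern(
    A: pd.DataFrame,
    pattern: str,
    symbol_map: OrthologMap | Mapping[str, str] | None = None,
) -> list[tuple[str, float]]:
    """Order genes by descending weight in one pattern.

    ``symbol_map`` optionally translates gene ids into a reference
    namespace (e.g. human symbols); unmapped genes are dropped with a
    logged count.  Ties are broken lexicographically by symbol.
    """
    if pattern not in A.columns:
        raise ValueError(f"unknown pattern {pattern!r}")
    weights = A[pattern].astype(float)
    if (weights < 0).any():
        raise ValueError("pattern weights must be non-negative")
    if isinstance(symbol_map, OrthologMap):
        mapping: Mapping[str, str] | None = symbol_map.a_to_b()
    else:
        mapping = symbol_map
    items: list[tuple[str, float]] = []
    dropped = 0
    for gene, w in weights.items():
        if mapping is None:
            items.append((str(gene), float(w)))
        elif str(gene) in mapping:
            items.append((mapping[str(gene)], float(w)))
        else:
            dropped += 1
    if dropped:
        logger.info("rank_genes_by_pattern: dropped %d unmapped genes", dropped)
    if not items:
        raise ValueError("no genes left after symbol mapping")
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return items


def _es_from_positions(
    w_pow: np.ndarray, positions: np.ndarray, n_total: int
) -> np.ndarray:
    """Vectorized ES for rows of member positions (0-based, any order).

    The running sum attains its maximum immediately after a hit, so the
    ES is the max over hits of (cumulative hit weight fraction) −
    (misses so far)/(N − m), floored at 0.
    """
    positions = np.sort(np.atleast_2d(positions), axis=1)
    m = positions.shape[1]
    if not (1 <= m < n_total):
        raise ValueError("gene set must be a non-empty strict subset of the ranking")
    w_hit = w_pow[positions]
    cw = np.cumsum(w_hit, axis=1)
    denom = cw[:, -1].copy()
    uniform = denom <= 0
    if np.any(uniform):  # all member weights zero: fall back to equal increments
        cw[uniform] = np.arange(1, m + 1)[None, :]
        denom[uniform] = m
    misses_before = positions - np.arange(m)[None, :]
    running = cw / denom[:, None] - misses_before / (n_total - m)
    return np.maximum(running.max(axis=1), 0.0)


def enrichment_score(
    ranked: Sequence[tuple[str, float]],
    gene_set: Iterable[str],
    exponent: float = 1.0,
) -> float:
    """Weighted running-sum enrichment score of ``gene_set`` in ``ranked``.

    Positive-only regime: the score is the maximum positive deviation of
    the running sum, in [0, 1].  The set must intersect the ranking and
    must not cover it entirely (the miss decrement would be undefined).
    """
    symbols = [s for s, _ in ranked]
    weights = np.asarray([w for _, w in ranked], dtype=float)
    if np.any(weights < 0):
        raise ValueError("ranking weights must be non-negative")
    members = set(gene_set)
    positions = np.asarray([i for i, s in enumerate(symbols) if s in members])
    n = len(symbols)
    if positions.size == 0:
        raise ValueError("gene set does not intersect the ranking")
    if positions.size == n:
        raise ValueError("gene set covers the whole ranking; ES undefined")
    w_pow = weights ** exponent
    return float(_es_from_positions(w_pow, positions[None, :], n)[0])


def gsea_pos(
    ranked: Sequence[tuple[str, float]],
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA of every eligible set against one ranking.

    Returns a DataFrame with columns ``set_name, es, nes, p_value,
    p_adjusted, set_size_used`` (BH adjustment across the surviving
    sets).  Sets are filtered to ``min_size <= |set ∩ ranking| <=
    max_size``; the null for each distinct set size is n_perm random
    same-size subsets of the ranking, seeded and shared across sets of
    that size.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable permutation null")
    symbols = [s for s, _ in ranked]
    weights = np.asarray([w for _, w in ranked], dtype=float)
    n = len(symbols)
    index_of = {s: i for i, s in enumerate(symbols)}

    surviving: list[tuple[str, np.ndarray]] = []
    for name, members in sets.sets.items():
        pos = np.asarray(sorted({index_of[m] for m in members if m in index_of}))
        if min_size <= pos.size <= max_size and pos.size < n:
            surviving.append((name, pos))
    columns = ["set_name", "es", "nes", "p_value", "p_adjusted", "set_size_used"]
    if not surviving:
        warnings.warn("no gene set survived size filtering", stacklevel=2)
        return pd.DataFrame(columns=columns)

    w_pow = weights ** exponent
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, pos in surviving:
        m = pos.size
        if m not in null_cache:
            # n_perm same-size subsets without replacement, vectorized
            rand = rng.random((n_perm, n))
            null_pos = np.argpartition(rand, m - 1, axis=1)[:, :m]
            null_cache[m] = _es_from_positions(w_pow, null_pos, n)
        null_es = null_cache[m]
        es = float(_es_from_positions(w_pow, pos[None, :], n)[0])
        p = (1.0 + float(np.sum(null_es >= es))) / (1.0 + n_perm)
        mean_null = float(null_es.mean())
        nes = es / mean_null if mean_null > 0 else (0.0 if es == 0 else np.inf)
        rows.append((name, es, nes, p, m))

    frame = pd.DataFrame(rows, columns=["set_name", "es", "nes", "p_value", "set_size_used"])
    frame["p_adjusted"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    frame["p_adjusted"] = np.maximum(frame["p_adjusted"], frame["p_value"])
    return frame[columns]
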