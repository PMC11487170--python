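"""Non-negative matrix factorization of expression matrices.

The model is X ≈ A·P with X a genes x samples TPM matrix, A a genes x k
amplitude (gene-weight) matrix and P a k x samples pattern (sample-weight)
matrix, both constrained non-negative.  Fitting minimizes the Frobenius
reconstruction loss ``‖X − A·P‖_F`` by multiplicative updates with
multiple seeded restarts, which makes runs exactly reproducible for a
fixed (X, k, seed, max_iter, tol, n_restarts).

Two entry points exist: :func:`nmf_factorize` fits the full matrix, and
:func:`nmf_consensus` splits the genes into seeded random subsets, fits
each subset independently, matches the per-subset sample-weight vectors
by hierarchical clustering on correlation distance, and refits gene
amplitudes against the consensus patterns by non-negative least squares —
the genome-wide strategy used to scale pattern discovery across gene
subsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .io_formats import FLOAT_FORMAT, ExpressionMatrix, FormatError

__all__ = [
    "Factorization",
    "tpm_normalize",
    "nmf_factorize",
    "nmf_consensus",
    "scan_k",
    "write_factorization",
    "read_factorization",
]

_EPS = 1e-12


@dataclass
class Factorization:
    """Result of one non-negative factorization X ≈ A·P."""

    gene_ids: list[str]
    sample_ids: list[str]
    A: np.ndarray  # genes x k, non-negative gene weights
    P: np.ndarray  # k x samples, non-negative sample pattern weights
    k: int
    frobenius_error: float
    seed: int
    iterations: int
    converged: bool
    error_trace: list[float] = field(default_factory=list, repr=False)
    pattern_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not self.pattern_ids:
            self.pattern_ids = [f"pattern{j + 1}" for j in range(self.k)]
        if self.A.shape != (len(self.gene_ids), self.k):
            raise ValueError("A shape inconsistent with gene_ids/k")
        if self.P.shape != (self.k, len(self.sample_ids)):
            raise ValueError("P shape inconsistent with k/sample_ids")
        if np.any(self.A < 0) or np.any(self.P < 0):
            raise ValueError("A and P must be non-negative")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.P))):
            raise ValueError("A and P must be finite")

    def reconstruction(self) -> np.ndarray:
        return self.A @ self.P

    def a_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.gene_ids, columns=self.pattern_ids)

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.pattern_ids, columns=self.sample_ids)


def tpm_normalize(
    counts,
    lengths,
    *,
    length_unit: str = "bases",
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Convert a count matrix to TPM given per-gene (effective) lengths.

    Per sample, counts are divided by gene length in kilobases to give a
    rate, and rates are rescaled so each column sums to 1e6.
    """
    if isinstance(counts, ExpressionMatrix):
        gene_ids = counts.gene_ids
        sample_ids = counts.sample_ids
        counts = counts.values
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if length_unit == "bases":
        lengths_kb = lengths / 1000.0
    elif length_unit in ("kb", "kilobases"):
        lengths_kb = lengths.copy()
    else:
        raise ValueError(f"unknown length_unit {length_unit!r}")
    if np.any(lengths_kb <= 0) or not np.all(np.isfinite(lengths_kb)):
        raise FormatError("gene lengths must be positive and finite")
    if lengths_kb.shape != (counts.shape[0],):
        raise FormatError("one length per gene row required")
    rate = counts / lengths_kb[:, None]
    colsum = rate.sum(axis=0)
    if np.any(colsum <= 0):
        j = int(np.nonzero(colsum <= 0)[0][0])
        raise FormatError(f"sample column {j} has zero total rate; cannot TPM-normalize")
    tpm = rate / colsum[None, :] * 1e6
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(counts.shape[0])]
    if sample_ids is None:
        sample_ids = [f"s{j + 1}" for j in range(counts.shape[1])]
    return ExpressionMatrix(gene_ids=list(gene_ids), sample_ids=list(sample_ids), values=tpm)


def _as_matrix(X) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(X, ExpressionMatrix):
        return X.values, list(X.gene_ids), list(X.sample_ids)
    if isinstance(X, pd.DataFrame):
        return (
            X.to_numpy(dtype=float),
            [str(i) for i in X.index],
            [str(c) for c in X.columns],
        )
    X = np.asarray(X, dtype=float)
    return (
        X,
        [f"g{i + 1}" for i in range(X.shape[0])],
        [f"s{j + 1}" for j in range(X.shape[1])],
    )


def _child_seed(seed: int, *tags: int) -> int:
    """Deterministic sub-seed derived from (seed, tags)."""
    return int(np.random.SeedSequence([int(seed), *map(int, tags)]).generate_state(1)[0])


def _mu_fit(
    Xv: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float], bool, int]:
    """One multiplicative-update run from a random non-negative start.

    Returns (W, H, error trace, converged, iterations).  The Frobenius
    error is non-increasing across iterations, a property of the
    multiplicative update for this loss.
    """
    n, m = Xv.shape
    scale = np.sqrt(max(Xv.mean(), _EPS) / k)
    W = scale * rng.random((n, k)) + _EPS
    H = scale * rng.random((k, m)) + _EPS
    trace: list[float] = [float(np.linalg.norm(Xv - W @ H))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ Xv) / (W.T @ W @ H + _EPS)
        W *= (Xv @ H.T) / (W @ (H @ H.T) + _EPS)
        err = float(np.linalg.norm(Xv - W @ H))
        prev = trace[-1]
        trace.append(err)
        if prev - err < tol * max(prev, _EPS):
            converged = True
            break
    return W, H, trace, converged, it


def _anls_polish(
    Xv: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    trace: list[float],
    rounds: int,
    tol: float,
) -> int:
    """Alternating non-negative least-squares refinement after MU.

    Each half-step solves the exact NNLS subproblem for one factor given
    the other, so the Frobenius error is non-increasing; unlike the
    multiplicative update, NNLS reaches exact zeros, which sharpens
    sample-specific and marker structure.
    """
    done = 0
    for _ in range(rounds):
        for j in range(Xv.shape[1]):
            H[:, j], _ = nnls(W, Xv[:, j])
        for i in range(Xv.shape[0]):
            W[i, :], _ = nnls(H.T, Xv[i, :])
        err = float(np.linalg.norm(Xv - W @ H))
        prev = trace[-1]
        trace.append(err)
        done += 1
        if prev - err < tol * max(prev, _EPS):
            break
    return done


def _rescale_unit_max(A: np.ndarray, P: np.ndarray) -> None:
    """Fix the scale degeneracy: rows of P to unit maximum, inverse into A."""
    for j in range(P.shape[0]):
        m = P[j].max()
        if m > 0:
            P[j] /= m
            A[:, j] *= m


def nmf_factorize(
    X,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 3,
    polish_rounds: int = 3,
) -> Factorization:
    """Fit X ≈ A·P at a fixed pattern count k, keeping the best restart.

    Restarts are independently seeded from ``seed``; the one with the
    lowest Frobenius error wins, ties going to the lowest restart index.
    The winning restart is refined by up to ``polish_rounds`` alternating
    NNLS passes (error still non-increasing).
    """
    Xv, gene_ids, sample_ids = _as_matrix(X)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > min(Xv.shape):
        raise ValueError(
            f"k={k} exceeds min(genes, samples)={min(Xv.shape)}"
        )
    if np.any(Xv < 0):
        raise ValueError("input matrix must be non-negative")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    if not Xv.any():
        A = np.zeros((Xv.shape[0], k))
        P = np.zeros((k, Xv.shape[1]))
        return Factorization(
            gene_ids, sample_ids, A, P, k,
            frobenius_error=0.0, seed=seed, iterations=0, converged=True,
            error_trace=[0.0],
        )

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(_child_seed(seed, r))
        W, H, trace, converged, it = _mu_fit(Xv, k, rng, max_iter, tol)
        err = trace[-1]
        if best is None or err < best[2]:
            best = (W, H, err, trace, converged, it)
    W, H, err, trace, converged, it = best
    if polish_rounds > 0:
        it += _anls_polish(Xv, W, H, trace, polish_rounds, tol)
    _rescale_unit_max(W, H)
    err = float(np.linalg.norm(Xv - W @ H))
    return Factorization(
        gene_ids, sample_ids, W, H, k,
        frobenius_error=err, seed=seed, iterations=it, converged=converged,
        error_trace=trace,
    )


def _correlation_distance(rows: np.ndarray) -> np.ndarray:
    """Condensed 1 − Pearson distance; constant rows are maximally distant."""
    d = pdist(rows, metric="correlation")
    return np.nan_to_num(d, nan=1.0)


def nmf_consensus(
    X,
    k: int,
    n_sets: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 3,
) -> Factorization:
    """Consensus factorization across random gene subsets.

    Genes are randomly partitioned (seeded) into ``n_sets`` groups, each
    factorized independently at k; the ``n_sets * k`` sample-weight
    vectors are clustered into k consensus patterns by average-linkage
    agglomeration on correlation distance; the consensus P is the
    per-cluster mean (rows rescaled to unit maximum) and the final A is
    solved per gene by non-negative least squares against the consensus P.

    ``n_sets == 1`` reduces exactly to :func:`nmf_factorize` with the
    same seed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if n_sets == 1:
        return nmf_factorize(X, k, seed=seed, max_iter=max_iter, tol=tol,
                             n_restarts=n_restarts)

    Xv, gene_ids, sample_ids = _as_matrix(X)
    if k > min(Xv.shape):
        raise ValueError(f"k={k} exceeds min(genes, samples)={min(Xv.shape)}")
    rng = np.random.default_rng(_child_seed(seed, 0xA11))
    order = rng.permutation(Xv.shape[0])
    groups = np.array_split(order, n_sets)
    for g in groups:
        if len(g) < k:
            raise ValueError(
                f"a gene subset of size {len(g)} is smaller than k={k}; "
                "use fewer sets"
            )

    rows = []
    iterations = 0
    all_converged = True
    for i, g in enumerate(groups):
        sub = nmf_factorize(
            Xv[np.sort(g)], k,
            seed=_child_seed(seed, 1, i), max_iter=max_iter, tol=tol,
            n_restarts=n_restarts,
        )
        rows.append(sub.P)
        iterations = max(iterations, sub.iterations)
        all_converged = all_converged and sub.converged
    stacked = np.vstack(rows)  # (n_sets * k) x samples

    Z = linkage(_correlation_distance(stacked), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) != k:
        raise RuntimeError(
            f"consensus clustering produced {len(np.unique(labels))} "
            f"clusters instead of {k}"
        )
    # deterministic cluster order: by first appearance in the stacked rows
    first_seen: dict[int, int] = {}
    for idx, lab in enumerate(labels):
        first_seen.setdefault(int(lab), idx)
    cluster_order = sorted(first_seen, key=first_seen.get)
    P = np.vstack([stacked[labels == lab].mean(axis=0) for lab in cluster_order])
    for j in range(k):
        m = P[j].max()
        if m > 0:
            P[j] /= m

    A = np.empty((Xv.shape[0], k))
    Pt = P.T  # samples x k design for per-gene NNLS
    for gidx in range(Xv.shape[0]):
        A[gidx], _ = nnls(Pt, Xv[gidx])
    err = float(np.linalg.norm(Xv - A @ P))
    return Factorization(
        gene_ids, sample_ids, A, P, k,
        frobenius_error=err, seed=seed, iterations=iterations,
        converged=all_converged,
    )


def scan_k(
    X,
    k_min: int,
    k_max: int,
    seed: int = 0,
    n_sets: int = 1,
    max_iter: int = 2000,
    tol: float = 1e-6,
    n_restarts: int = 3,
) -> list[Factorization]:
    """Factorize at every k in [k_min, k_max], independently seeded by (seed, k)."""
    if not (1 <= k_min <= k_max):
        raise ValueError("need 1 <= k_min <= k_max")
    results = []
    for k in range(k_min, k_max + 1):
        results.append(
            nmf_consensus(
                X, k, n_sets=n_sets, seed=_child_seed(seed, k),
                max_iter=max_iter, tol=tol, n_restarts=n_restarts,
            )
        )
    return results


def write_factorization(fact: Factorization, directory: str | Path) -> None:
    """Serialize as A.tsv (genes x patterns), P.tsv (patterns x samples), meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fact.a_frame().to_csv(directory / "A.tsv", sep="\t",
                          float_format=FLOAT_FORMAT, lineterminator="\n")
    fact.p_frame().to_csv(directory / "P.tsv", sep="\t",
                          float_format=FLOAT_FORMAT, lineterminator="\n")
    meta = {
        "k": fact.k,
        "seed": fact.seed,
        "frobenius_error": fact.frobenius_error,
        "iterations": fact.iterations,
        "converged": fact.converged,
    }
    (directory / "meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_factorization(directory: str | Path) -> Factorization:
    directory = Path(directory)
    A = pd.read_csv(directory / "A.tsv", sep="\t", index_col=0)
    P = pd.read_csv(directory / "P.tsv", sep="\t", index_col=0)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    return Factorization(
        gene_ids=[str(g) for g in A.index],
        sample_ids=[str(s) for s in P.columns],
        A=A.to_numpy(dtype=float),
        P=P.to_numpy(dtype=float),
        k=int(meta["k"]),
        frobenius_error=float(meta["frobenius_error"]),
        seed=int(meta["seed"]),
        iterations=int(meta["iterations"]),
        converged=bool(meta["converged"]),
        pattern_ids=[str(p) for p in A.columns],
    )
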