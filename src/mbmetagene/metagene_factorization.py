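"""Metagene extraction by non-negative matrix factorization (NMF).

A preprocessed probes x samples matrix V is factorized as V ~ W @ H with W
(probes x k) the nonnegative basis — the contribution of each CpG probe to
each metagene — and H (k x samples) the nonnegative coefficients — how each
sample is associated with the metagenes.  Multiplicative updates are used
with either the generalized Kullback-Leibler divergence (the historical
metagene-NMF convention, the default) or the squared Frobenius norm.

Stability of a candidate rank is assessed by consensus clustering over
random restarts: each restart assigns every sample to its dominant metagene,
the consensus matrix records co-assignment frequencies, and the cophenetic
correlation coefficient between consensus-derived distances and the
average-linkage dendrogram's cophenetic distances quantifies how close the
consensus is to a clean ultrametric block structure (1.0 = perfectly
stable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

_EPS = 1e-12  # guards update denominators against division by zero


@dataclass
class FactorizationResult:
    """One NMF run: factors, objective trace and run metadata."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray
    rank: int
    seed: int
    n_iter: int
    converged: bool

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def dominant_metagene(self) -> np.ndarray:
        """Per-sample argmax over H columns (ties -> lowest index)."""
        return np.argmax(self.H, axis=0)


@dataclass
class ConsensusResult:
    """Multi-restart stability summary at one rank."""

    consensus: np.ndarray
    cophenetic: float
    rank: int
    n_runs: int
    best: FactorizationResult


def nmf(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    objective: str = "kl",
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FactorizationResult:
    """Factorize a complete nonnegative matrix by multiplicative updates.

    Parameters
    ----------
    V
        Complete nonnegative probes x samples matrix.
    k
        Factorization rank, 1 <= k < min(V.shape).
    seed
        Seeds the uniform(0, 1] initialization of W and H.
    objective
        ``"kl"`` (generalized Kullback-Leibler divergence, default) or
        ``"frobenius"`` (squared error).
    max_iter, tol
        Stop after ``max_iter`` updates or when the relative objective
        change between iterations drops below ``tol``.

    Both update rules are monotone: the objective trace is non-increasing
    up to floating-point rounding.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-D matrix")
    if not np.isfinite(V).all():
        raise ValueError("V contains non-finite entries")
    if (V < 0).any():
        raise ValueError("V contains negative entries")
    if not (1 <= k < min(V.shape)):
        raise ValueError(f"rank k={k} out of range for shape {V.shape}")
    if objective not in ("kl", "frobenius"):
        raise ValueError(f"unknown objective {objective!r}")

    m, n = V.shape
    rng = np.random.default_rng(seed)
    # uniform on (0, 1]: strictly positive init avoids zero-locking at start
    W = 1.0 - rng.random((m, k))
    H = 1.0 - rng.random((k, n))

    pos_idx = np.flatnonzero(V.ravel() > 0)
    v_pos = V.ravel()[pos_idx]
    v_logv = float(np.dot(v_pos, np.log(v_pos)))
    v_sum = float(V.sum())
    trace = []
    converged = False
    n_iter = 0
    R = np.empty_like(V)
    if objective == "kl":
        WH = W @ H
        WH += _EPS
    for it in range(max_iter):
        if objective == "kl":
            np.divide(V, WH, out=R)
            H *= (W.T @ R) / (W.sum(axis=0)[:, None] + _EPS)
            WH = W @ H
            WH += _EPS
            np.divide(V, WH, out=R)
            W *= (R @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
            WH = W @ H
            WH += _EPS
            # generalized KL: sum(V log(V/WH)) - sum(V) + sum(WH), 0 log 0 = 0
            obj = v_logv - float(np.dot(v_pos, np.log(WH.ravel()[pos_idx]))) - v_sum + float(WH.sum())
        else:
            H *= (W.T @ V) / (W.T @ W @ H + _EPS)
            W *= (V @ H.T) / (W @ H @ H.T + _EPS)
            diff = V - W @ H
            obj = 0.5 * float(np.sum(diff * diff))
        trace.append(obj)
        n_iter = it + 1
        if it > 0:
            prev = trace[-2]
            denom = abs(prev) if prev != 0 else 1.0
            if abs(prev - obj) / denom < tol:
                converged = True
                break
    return FactorizationResult(
        W=W,
        H=H,
        objective_trace=np.asarray(trace),
        rank=k,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
    )


def consensus_nmf(
    V: np.ndarray,
    k: int,
    n_runs: int = 30,
    base_seed: int = 0,
    objective: str = "kl",
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Run NMF from ``n_runs`` seeded restarts and build the consensus matrix.

    Restart ``r`` uses seed ``base_seed + r``.  Each restart assigns every
    sample to its dominant metagene; the consensus matrix entry (i, j) is the
    fraction of restarts in which samples i and j share an assignment.  The
    returned ``best`` run has the lowest final objective.
    """
    if n_runs < 2:
        raise ValueError("consensus requires n_runs >= 2 (stability is undefined for one run)")
    n = V.shape[1]
    consensus = np.zeros((n, n))
    best: FactorizationResult | None = None
    for r in range(n_runs):
        res = nmf(V, k, seed=base_seed + r, objective=objective, max_iter=max_iter, tol=tol)
        assign = res.dominant_metagene()
        consensus += (assign[:, None] == assign[None, :]).astype(float)
        if best is None or res.final_objective < best.final_objective:
            best = res
    consensus /= n_runs
    coph = cophenetic_coefficient(consensus)
    return ConsensusResult(
        consensus=consensus, cophenetic=coph, rank=k, n_runs=n_runs, best=best
    )


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of a consensus matrix.

    Distances 1 - consensus are clustered by average linkage; the returned
    value is the Pearson correlation between the original off-diagonal
    distances and the dendrogram's cophenetic distances.  An
    ultrametric-consistent consensus yields exactly 1.
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus must be square")
    if C.shape[0] < 3:
        raise ValueError("cophenetic coefficient needs at least 3 samples")
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("consensus must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-12):
        raise ValueError("consensus must have unit diagonal")
    D = squareform(1.0 - C, checks=False)
    if np.ptp(D) == 0:
        raise ValueError("degenerate consensus: all off-diagonal distances equal")
    Z = linkage(D, method="average")
    c, _ = cophenet(Z, D)
    return float(c)


def rank_scan(
    V: np.ndarray,
    ranks,
    n_runs: int = 30,
    base_seed: int = 0,
    objective: str = "kl",
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Consensus stability across candidate ranks.

    Returns one row per rank with columns ``rank``, ``cophenetic``,
    ``final_objective`` (best restart) and ``n_runs``.  Deterministic for a
    given ``base_seed``; all ranks share the same restart seeds.
    """
    rows = []
    for k in ranks:
        res = consensus_nmf(
            V, int(k), n_runs=n_runs, base_seed=base_seed,
            objective=objective, max_iter=max_iter, tol=tol,
        )
        rows.append(
            {
                "rank": int(k),
                "cophenetic": res.cophenetic,
                "final_objective": res.best.final_objective,
                "n_runs": n_runs,
            }
        )
    return pd.DataFrame(rows)
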