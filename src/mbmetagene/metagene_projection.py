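"""Projection of an independent cohort onto a fixed metagene basis.

Once a basis W has been extracted from the primary cohort, a validation
cohort is represented in the same metagene space by solving, per sample v,

    minimize ||W h - v||_2  subject to  h >= 0

(non-negative least squares).  A pseudoinverse would minimize the same
residual without the constraint but can produce negative coefficients,
which have no interpretation as metagene activity; NNLS keeps the projected
coefficients on the same nonnegative scale as the training coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .matrix_io import BetaMatrix, ValidationError

_KKT_TOL = 1e-8


@dataclass
class ProjectionResult:
    """Per-sample NNLS coefficients against a fixed basis."""

    H_V: np.ndarray
    residual_norms: np.ndarray
    probe_coverage: float
    sample_ids: list[str] | None = None


def nnls_solve(W: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve min ||W h - v||_2 s.t. h >= 0 (Lawson–Hanson active set).

    Returns the nonnegative coefficient vector and the Euclidean residual.
    The Karush–Kuhn–Tucker conditions are verified on the result: gradient
    components at zero-valued coordinates must be >= -1e-8.
    """
    W = np.asarray(W, dtype=float)
    v = np.asarray(v, dtype=float)
    if W.ndim != 2 or v.ndim != 1 or W.shape[0] != v.shape[0]:
        raise ValueError(f"shape mismatch: W {W.shape}, v {v.shape}")
    if not (np.isfinite(W).all() and np.isfinite(v).all()):
        raise ValueError("non-finite input to nnls_solve")
    col_norms = np.linalg.norm(W, axis=0)
    if (col_norms == 0).any():
        raise ValueError("basis has an all-zero column")
    h, residual = _scipy_nnls(W, v)
    grad = W.T @ (W @ h - v)
    at_zero = h <= 0
    if at_zero.any() and grad[at_zero].min() < -_KKT_TOL * max(1.0, abs(grad).max()):
        raise RuntimeError("NNLS KKT conditions violated; solver did not converge")
    return h, float(residual)


def project(
    W_P: np.ndarray,
    V_val: np.ndarray,
    sample_ids=None,
    probe_coverage: float = 1.0,
) -> ProjectionResult:
    """Project every column of ``V_val`` onto the fixed basis ``W_P``.

    Column s of the returned H_V is ``nnls_solve(W_P, V_val[:, s])``;
    columns are solved independently, so the result is invariant to sample
    order up to the same permutation.
    """
    W_P = np.asarray(W_P, dtype=float)
    V_val = np.asarray(V_val, dtype=float)
    if V_val.ndim != 2 or V_val.shape[0] != W_P.shape[0]:
        raise ValueError(
            f"probe dimension mismatch: basis {W_P.shape[0]}, cohort {V_val.shape[0]}"
        )
    k, n = W_P.shape[1], V_val.shape[1]
    H_V = np.empty((k, n))
    residuals = np.empty(n)
    for s in range(n):
        H_V[:, s], residuals[s] = nnls_solve(W_P, V_val[:, s])
    return ProjectionResult(
        H_V=H_V,
        residual_norms=residuals,
        probe_coverage=probe_coverage,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )


def align_probes(
    V_val: BetaMatrix,
    basis_probe_ids,
    fill_policy: str = "error",
    train_means: dict | None = None,
    coverage_floor: float = 0.95,
) -> tuple[np.ndarray, dict]:
    """Reorder a cohort's rows to the basis probe order.

    Probes absent from the cohort are handled per ``fill_policy``:
    ``"error"`` refuses, ``"train-mean"`` fills the row with the stored
    training-cohort mean for that probe.  Either way, coverage (fraction of
    basis probes present) below ``coverage_floor`` is an error.

    Returns the aligned probes x samples array and a coverage report with
    the filled probe ids.
    """
    basis_probe_ids = list(basis_probe_ids)
    if not basis_probe_ids:
        raise ValueError("basis_probe_ids is empty")
    if fill_policy not in ("error", "train-mean"):
        raise ValueError(f"unknown fill_policy {fill_policy!r}")
    pos = {p: i for i, p in enumerate(V_val.probe_ids)}
    present = [p for p in basis_probe_ids if p in pos]
    coverage = len(present) / len(basis_probe_ids)
    if coverage < coverage_floor:
        raise ValidationError(
            f"probe coverage {coverage:.3f} below floor {coverage_floor}"
        )
    missing = [p for p in basis_probe_ids if p not in pos]
    if missing and fill_policy == "error":
        raise ValidationError(
            f"{len(missing)} basis probe(s) absent from cohort, e.g. {missing[:5]}"
        )
    if missing and (train_means is None or any(p not in train_means for p in missing)):
        raise ValidationError("train-mean policy requires stored means for absent probes")
    out = np.empty((len(basis_probe_ids), V_val.n_samples))
    for i, p in enumerate(basis_probe_ids):
        if p in pos:
            out[i, :] = V_val.beta[pos[p], :]
        else:
            out[i, :] = train_means[p]
    report = {
        "coverage": coverage,
        "n_basis_probes": len(basis_probe_ids),
        "n_filled": len(missing),
        "filled_probe_ids": missing,
        "fill_policy": fill_policy,
    }
    return out, report
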