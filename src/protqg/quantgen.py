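"""Multivariate breeder's-equation machinery.

The response to selection of a mean shape is dz = G b, where G is the
genetic covariance matrix (here the between-structure proxy B) and b the
vector of selection gradients.  Working backwards from an observed
(realized) response dz = mu_target - mu_source, the long-term gradient
is b = G^+ dz; with the phenotypic covariance in place of G the same
algebra recovers the directional gradient b = V_P^+ S from a selection
differential.  Substituting the dynamic (pooled within-snapshot) matrix
M for G yields the dynamic gradient with no separate code path.

Because G is rank-deficient by construction (rank <= S - 1 groups, far
below l = 3k traits), inversion uses the Moore-Penrose pseudo-inverse
with a documented singular-value cutoff; an optional ridge (G + eps I)
is offered as an alternative.  Constraint is quantified by angles, in
degrees: 0 means the gradient and the response point the same way (no
genetic constraint), 90 means an absolute constraint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelectionAnalysis",
    "response_to_selection",
    "realized_response",
    "selection_gradient",
    "differential_gradient",
    "constraint_angle",
    "subspace_angle",
    "per_residue_gradient",
    "rank_residues",
]


def response_to_selection(G: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Predicted response dz = G b of the multivariate breeder's equation."""
    G = np.asarray(G, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if G.ndim != 2 or G.shape[1] != beta.shape[0]:
        raise ValueError(f"non-conformable: G {G.shape}, beta {beta.shape}")
    return G @ beta


def realized_response(target_mean: np.ndarray, source_mean: np.ndarray) -> np.ndarray:
    """Realized response: target minus source mean, in a common frame."""
    t = np.asarray(target_mean, dtype=float)
    s = np.asarray(source_mean, dtype=float)
    if t.shape != s.shape:
        raise ValueError(f"frame mismatch: target {t.shape} vs source {s.shape}")
    return t - s


def _pinv_solve(
    M: np.ndarray,
    v: np.ndarray,
    rank_tolerance: float | None,
    ridge: float,
) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    v = np.asarray(v, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or M.shape[1] != v.shape[0]:
        raise ValueError(f"non-conformable: matrix {M.shape}, vector {v.shape}")
    if not np.any(M):
        raise ValueError("matrix is identically zero: no variation to invert")
    if ridge > 0.0:
        return np.linalg.solve(M + ridge * np.eye(M.shape[0]), v)
    if rank_tolerance is None:
        rank_tolerance = 1e-10 * M.shape[0]
    return np.linalg.pinv(M, rcond=rank_tolerance, hermitian=True) @ v


def selection_gradient(
    G: np.ndarray,
    delta_z: np.ndarray,
    rank_tolerance: float | None = None,
    ridge: float = 0.0,
) -> np.ndarray:
    """Long-term selection gradient b = G^+ dz.

    Singular values below ``rank_tolerance`` times the largest singular
    value are treated as zero (default ``1e-10 * l``); directions of dz
    outside the retained range of G are annihilated.  Passing
    ``ridge > 0`` solves (G + ridge I) b = dz instead.
    """
    return _pinv_solve(G, delta_z, rank_tolerance, ridge)


def differential_gradient(
    v_p: np.ndarray,
    s_diff: np.ndarray,
    rank_tolerance: float | None = None,
    ridge: float = 0.0,
) -> np.ndarray:
    """Directional selection gradient b = V_P^+ S from a differential."""
    return _pinv_solve(v_p, s_diff, rank_tolerance, ridge)


def constraint_angle(delta_z: np.ndarray, beta: np.ndarray) -> float:
    """Angle in degrees between the response and the gradient.

    0 degrees: the response follows the gradient (no constraint);
    90 degrees: the response is orthogonal to it (absolute constraint).
    """
    a = np.asarray(delta_z, dtype=float)
    b = np.asarray(beta, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angle undefined for a zero vector")
    ua, ub = a / na, b / nb
    # atan2 form: numerically exact near 0 and 180 degrees, where the
    # arccos of a cosine similarity loses half the significant digits.
    angle = 2.0 * np.arctan2(np.linalg.norm(ua - ub), np.linalg.norm(ua + ub))
    return float(np.degrees(angle))


def subspace_angle(v: np.ndarray, G: np.ndarray, variance_fraction: float = 0.99) -> float:
    """Angle between ``v`` and the leading eigenspace of ``G``.

    The subspace is spanned by the top eigenvectors whose cumulative
    eigenvalue share (of the positive spectrum) first reaches
    ``variance_fraction``; the angle is between ``v`` and its orthogonal
    projection onto that subspace, in degrees.
    """
    v = np.asarray(v, dtype=float)
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError("variance fraction must be in (0, 1]")
    nv = np.linalg.norm(v)
    if nv == 0.0:
        raise ValueError("angle undefined for a zero vector")
    vals, vecs = np.linalg.eigh(np.asarray(G, dtype=float))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    positive = vals > 0.0
    if not positive.any():
        raise ValueError("matrix has no positive eigenvalues: no subspace")
    vals, vecs = vals[positive], vecs[:, positive]
    share = np.cumsum(vals) / vals.sum()
    keep = int(np.searchsorted(share, variance_fraction) + 1)
    basis = vecs[:, :keep]
    projection = basis @ (basis.T @ v)
    cosine = np.clip(np.linalg.norm(projection) / nv, -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def per_residue_gradient(beta: np.ndarray) -> np.ndarray:
    """Per-residue gradient magnitude, min-max standardized to [0, 1].

    For each residue the absolute values of its three coordinate
    components are summed; the sums are then scaled so the smallest is 0
    and the largest 1.  If every residue has the same sum there is
    nothing to rank and a zero vector is returned.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 1 or beta.shape[0] % 3 != 0:
        raise ValueError("gradient length must be divisible by 3")
    sums = np.abs(beta.reshape(-1, 3)).sum(axis=1)
    span = sums.max() - sums.min()
    if span == 0.0:
        return np.zeros_like(sums)
    return (sums - sums.min()) / span


_TABLE_COLUMNS = [
    "residue_index",
    "residue_name",
    "beta_x",
    "beta_y",
    "beta_z",
    "dz_x",
    "dz_y",
    "dz_z",
]


def rank_residues(
    beta: np.ndarray,
    delta_z: np.ndarray,
    top: int = 5,
    labels: list[tuple[int, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank residues under directional and purifying selection.

    Directional table: residues with at least one positive gradient
    component, ranked by descending sum of absolute gradient components.
    Purifying table: residues with at least one negative component,
    ranked by ascending sum of raw components.  Each row carries the
    three gradient and three response components of the residue.

    ``labels`` supplies (author residue number, residue name) per
    alignment column; without it residues are numbered 1..k.
    """
    beta = np.asarray(beta, dtype=float)
    delta_z = np.asarray(delta_z, dtype=float)
    if beta.shape != delta_z.shape or beta.ndim != 1 or beta.shape[0] % 3 != 0:
        raise ValueError("beta and delta_z must be equal-length, divisible by 3")
    k = beta.shape[0] // 3
    if labels is None:
        labels = [(j + 1, "UNK") for j in range(k)]
    if len(labels) != k:
        raise ValueError(f"expected {k} residue labels, got {len(labels)}")
    if top > k:
        warnings.warn(f"top={top} exceeds residue count {k}; returning all")
        top = k

    b3 = beta.reshape(k, 3)
    d3 = delta_z.reshape(k, 3)
    rows = pd.DataFrame(
        {
            "residue_index": [lab[0] for lab in labels],
            "residue_name": [lab[1] for lab in labels],
            "beta_x": b3[:, 0],
            "beta_y": b3[:, 1],
            "beta_z": b3[:, 2],
            "dz_x": d3[:, 0],
            "dz_y": d3[:, 1],
            "dz_z": d3[:, 2],
        },
        columns=_TABLE_COLUMNS,
    )
    rows["_abs_sum"] = np.abs(b3).sum(axis=1)
    rows["_raw_sum"] = b3.sum(axis=1)

    directional = (
        rows[(b3 > 0).any(axis=1)]
        .sort_values(["_abs_sum", "residue_index"], ascending=[False, True])
        .head(top)
        .drop(columns=["_abs_sum", "_raw_sum"])
        .reset_index(drop=True)
    )
    purifying = (
        rows[(b3 < 0).any(axis=1)]
        .sort_values(["_raw_sum", "residue_index"], ascending=[True, True])
        .head(top)
        .drop(columns=["_abs_sum", "_raw_sum"])
        .reset_index(drop=True)
    )
    return directional, purifying


@dataclass
class SelectionAnalysis:
    """Bundle of selection quantities computed against one matrix."""

    matrix_used: str  # "G", "M" or "V_P"
    delta_z: np.ndarray
    beta: np.ndarray
    theta_dz_beta: float  # constraint angle between dz and beta, degrees
    theta_dz_subspace: float  # dz vs leading eigenspace of the matrix
    theta_beta_subspace: float  # beta vs leading eigenspace of the matrix
    per_residue: np.ndarray  # standardized per-residue gradient in [0, 1]
    directional: pd.DataFrame = field(repr=False, default=None)
    purifying: pd.DataFrame = field(repr=False, default=None)


def analyze_selection(
    matrix: np.ndarray,
    delta_z: np.ndarray,
    matrix_used: str = "G",
    variance_fraction: float = 0.99,
    rank_tolerance: float | None = None,
    ridge: float = 0.0,
    top: int = 5,
    labels: list[tuple[int, str]] | None = None,
) -> SelectionAnalysis:
    """Gradient, angles, per-residue map and rankings for one matrix."""
    beta = selection_gradient(matrix, delta_z, rank_tolerance, ridge)
    directional, purifying = rank_residues(beta, delta_z, top=top, labels=labels)
    return SelectionAnalysis(
        matrix_used=matrix_used,
        delta_z=np.asarray(delta_z, dtype=float),
        beta=beta,
        theta_dz_beta=constraint_angle(delta_z, beta),
        theta_dz_subspace=subspace_angle(delta_z, matrix, variance_fraction),
        theta_beta_subspace=subspace_angle(beta, matrix, variance_fraction),
        per_residue=per_residue_gradient(beta),
        directional=directional,
        purifying=purifying,
    )


__all__.append("analyze_selection")
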