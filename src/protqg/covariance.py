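"""Covariance decomposition of grouped shape coordinates.

The phenotypic covariance V_P of all aligned snapshots is split into a
pooled within-group component W (the "dynamic" matrix M: snapshot-level
flexibility around each homolog's mean) and a between-group component
B = V_P - W (the proxy for the genetic covariance matrix G).  The
decomposition is additive by construction; W and V_P are positive
semidefinite while B, being a difference of estimates, need not be.

Estimation is direct: per-group mean deviations, summed cross-products
over all observations, normalized by n - S (n observations, S groups).
Within-group error cannot be separated from within-group signal here, so
W absorbs it; the between-group residue of that error is what B absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import PhenotypeMatrix

__all__ = [
    "SingletonGroupError",
    "CovarianceDecomposition",
    "phenotypic_covariance",
    "pooled_within",
    "between_covariance",
    "decompose",
    "nearest_psd",
]


class SingletonGroupError(ValueError):
    """A group with a single observation cannot contribute to W."""


def _as_values_groups(P, groups=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(P, PhenotypeMatrix):
        return P.values, P.groups.astype(str)
    X = np.asarray(P, dtype=float)
    if groups is None:
        raise ValueError("group labels are required for a plain array")
    return X, np.asarray(groups).astype(str)


def _symmetrize(M: np.ndarray) -> np.ndarray:
    return (M + M.T) / 2.0


def phenotypic_covariance(P) -> np.ndarray:
    """Sample covariance of all rows (divisor n - 1)."""
    X = P.values if isinstance(P, PhenotypeMatrix) else np.asarray(P, dtype=float)
    if X.ndim != 2:
        raise ValueError("phenotype values must be 2-D")
    n = X.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    Xc = X - X.mean(axis=0)
    return _symmetrize(Xc.T @ Xc / (n - 1))


def pooled_within(P, groups=None) -> np.ndarray:
    """Pooled within-group covariance (divisor n - S).

    Deviations are taken from each group's own mean, cross-products are
    summed over every observation of every group, and the sum is
    normalized by n - S.  Every group must contribute at least two
    observations.
    """
    X, g = _as_values_groups(P, groups)
    labels, inverse, counts = np.unique(g, return_inverse=True, return_counts=True)
    singles = labels[counts < 2]
    if singles.size:
        raise SingletonGroupError(
            f"groups with a single observation: {singles.tolist()}"
        )
    n, S = X.shape[0], labels.size
    if n - S < 1:
        raise ValueError("need n - S >= 1 within-group degrees of freedom")
    # Two-pass: group means first, then centered cross-products.
    sums = np.zeros((S, X.shape[1]))
    np.add.at(sums, inverse, X)
    group_means = sums / counts[:, None]
    D = X - group_means[inverse]
    return _symmetrize(D.T @ D / (n - S))


def between_covariance(v_p: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Between-group component B = V_P - W, symmetrized."""
    v_p = np.asarray(v_p, dtype=float)
    w = np.asarray(w, dtype=float)
    if v_p.shape != w.shape:
        raise ValueError(f"shape mismatch: {v_p.shape} vs {w.shape}")
    return _symmetrize(v_p - w)


def nearest_psd(M: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped PSD repair (negative eigenvalues set to zero).

    B = V_P - W is not guaranteed PSD; this optional repair returns the
    nearest (in Frobenius norm) positive-semidefinite matrix.
    """
    M = _symmetrize(np.asarray(M, dtype=float))
    vals, vecs = np.linalg.eigh(M)
    return _symmetrize((vecs * np.clip(vals, 0.0, None)) @ vecs.T)


@dataclass
class CovarianceDecomposition:
    """V_P = W + B with bookkeeping about the grouping."""

    v_p: np.ndarray
    within: np.ndarray  # W, the dynamic matrix M
    between: np.ndarray  # B, the genetic proxy G
    n: int
    n_groups: int
    group_sizes: dict[str, int]

    @property
    def l(self) -> int:  # noqa: E743
        return self.v_p.shape[0]


def decompose(P, groups=None) -> CovarianceDecomposition:
    """Full V_P / W / B decomposition of a grouped phenotype matrix."""
    X, g = _as_values_groups(P, groups)
    v_p = phenotypic_covariance(X)
    w = pooled_within(X, g)
    b = between_covariance(v_p, w)
    labels, counts = np.unique(g, return_counts=True)
    return CovarianceDecomposition(
        v_p=v_p,
        within=w,
        between=b,
        n=X.shape[0],
        n_groups=labels.size,
        group_sizes=dict(zip(labels.tolist(), counts.tolist())),
    )
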