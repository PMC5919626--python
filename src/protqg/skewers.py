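"""Random-skewer comparison of covariance matrices.

Two covariance matrices are similar, in the sense that matters for
evolution, when they translate the same selection vectors into the same
response directions.  The random-skewer test draws selection vectors
uniformly on the unit sphere, applies both matrices, and averages the
vector correlation (cosine similarity) of the paired responses.  The
p-value is the fraction of a null distribution — correlations between
pairs of independent random unit vectors of the same dimension — that
exceeds the observed mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SkewerResult", "random_skewers"]


@dataclass
class SkewerResult:
    """Mean response-vector correlation and its permutation-style null."""

    rho: float
    p_value: float
    n_skewers: int
    n_used: int
    seed: int | None
    method: str

    def __str__(self) -> str:
        return (
            f"random skewers: rho={self.rho:.4f} p={self.p_value:.4g} "
            f"({self.n_used}/{self.n_skewers} skewers, {self.method})"
        )


def _unit_vectors(l: int, n: int, rng: np.random.Generator) -> np.ndarray:
    V = rng.standard_normal((l, n))
    return V / np.linalg.norm(V, axis=0)


def _paired_correlation(RA: np.ndarray, RB: np.ndarray, method: str) -> np.ndarray:
    if method == "pearson":
        RA = RA - RA.mean(axis=0)
        RB = RB - RB.mean(axis=0)
    elif method != "cosine":
        raise ValueError(f"unknown correlation method {method!r}")
    na = np.linalg.norm(RA, axis=0)
    nb = np.linalg.norm(RB, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sum(RA * RB, axis=0) / (na * nb)


def random_skewers(
    A: np.ndarray,
    B_mat: np.ndarray,
    n_skewers: int = 1000,
    seed: int | None = None,
    method: str = "cosine",
) -> SkewerResult:
    """Cheverud's random-skewer similarity of two covariance matrices.

    Parameters
    ----------
    A, B_mat:
        Conformable symmetric (covariance) matrices.
    n_skewers:
        Number of random selection vectors (>= 1).
    seed:
        Seed for the skewer and null draws; a fixed seed makes the
        result bit-reproducible.
    method:
        "cosine" (vector correlation of responses, the default) or
        "pearson" (responses centered before correlating).

    Skewers for which either response is exactly zero are skipped with a
    warning; if all are skipped an error is raised.
    """
    A = np.asarray(A, dtype=float)
    B_mat = np.asarray(B_mat, dtype=float)
    if A.shape != B_mat.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"non-conformable matrices: {A.shape} vs {B_mat.shape}")
    if n_skewers < 1:
        raise ValueError("need at least one skewer")
    l = A.shape[0]
    rng = np.random.default_rng(seed)
    V = _unit_vectors(l, n_skewers, rng)
    RA = A @ V
    RB = B_mat @ V
    ok = (np.linalg.norm(RA, axis=0) > 0.0) & (np.linalg.norm(RB, axis=0) > 0.0)
    n_used = int(ok.sum())
    if n_used == 0:
        raise ValueError("every skewer produced a zero response")
    if n_used < n_skewers:
        warnings.warn(f"skipped {n_skewers - n_used} skewers with zero response")
    rho = float(np.mean(_paired_correlation(RA[:, ok], RB[:, ok], method)))

    null = np.sum(_unit_vectors(l, n_skewers, rng) * _unit_vectors(l, n_skewers, rng), axis=0)
    p_value = float(np.mean(null >= rho))
    return SkewerResult(
        rho=rho,
        p_value=p_value,
        n_skewers=n_skewers,
        n_used=n_used,
        seed=seed,
        method=method,
    )
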