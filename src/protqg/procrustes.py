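"""Ordinary and Generalized Procrustes Superimposition (GPS/GPA).

Rigid-body differences (translation, rotation, optionally uniform scale)
are removed by least squares.  Reflections are always forbidden: protein
chirality is physical, so only proper rotations (det = +1) are allowed.
Scaling defaults to off because landmark coordinates are in Angstrom and
absolute size is meaningful for the energetic fitness proxy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .landmarks import LandmarkConfiguration

__all__ = [
    "DegenerateConfigurationError",
    "GPAResult",
    "superimpose_pair",
    "gpa",
    "gpa_configurations",
]


class DegenerateConfigurationError(ValueError):
    """Fewer than 3 landmarks, or all landmarks (nearly) collinear."""


def _as_coords(obj) -> np.ndarray:
    if isinstance(obj, LandmarkConfiguration):
        return obj.coords
    return np.asarray(obj, dtype=float)


def _check_configuration(coords: np.ndarray) -> None:
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("a configuration must be a (k, 3) array")
    if coords.shape[0] < 3:
        raise DegenerateConfigurationError(
            f"need at least 3 landmarks, got {coords.shape[0]}"
        )
    centered = coords - coords.mean(axis=0)
    # Rank of the centered cloud must be >= 2 for a unique rotation.
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise DegenerateConfigurationError("landmarks are (nearly) collinear")


def _optimal_rotation(mobile_c: np.ndarray, target_c: np.ndarray) -> np.ndarray:
    """Proper least-squares rotation (Kabsch) for centered clouds."""
    H = mobile_c.T @ target_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def superimpose_pair(
    mobile,
    target,
    allow_scaling: bool = False,
):
    """Superimpose ``mobile`` onto ``target`` by least squares.

    Parameters
    ----------
    mobile, target:
        ``(k, 3)`` arrays or :class:`LandmarkConfiguration` with equal
        ``k >= 3`` and non-degenerate geometry.
    allow_scaling:
        Additionally fit a uniform scale factor (full similarity
        transform) instead of a rigid motion.

    Returns
    -------
    (aligned, rmsd):
        The transformed mobile (same type as the input) and the residual
        root-mean-square distance in Angstrom.
    """
    mob = _as_coords(mobile)
    tgt = _as_coords(target)
    if mob.shape != tgt.shape:
        raise ValueError(f"landmark counts differ: {mob.shape} vs {tgt.shape}")
    _check_configuration(mob)
    _check_configuration(tgt)

    mob_centroid = mob.mean(axis=0)
    tgt_centroid = tgt.mean(axis=0)
    mob_c = mob - mob_centroid
    tgt_c = tgt - tgt_centroid
    R = _optimal_rotation(mob_c, tgt_c)
    scale = 1.0
    if allow_scaling:
        scale = np.trace(mob_c @ R @ tgt_c.T) / (mob_c**2).sum()
    aligned = scale * (mob_c @ R) + tgt_centroid
    rmsd = float(np.sqrt(((aligned - tgt) ** 2).sum() / mob.shape[0]))
    if isinstance(mobile, LandmarkConfiguration):
        return mobile.with_coords(aligned), rmsd
    return aligned, rmsd


@dataclass
class GPAResult:
    """Outcome of a Generalized Procrustes Superimposition."""

    aligned: np.ndarray  # (m, k, 3) in the consensus frame
    mean_shape: np.ndarray  # (k, 3), centered at the origin
    iterations: int
    objective: float  # sum of squared distances to the mean, A^2
    converged: bool
    objective_history: list[float]


def gpa(
    configs: Sequence,
    allow_scaling: bool = False,
    tolerance: float = 1e-10,
    max_iterations: int = 100,
) -> GPAResult:
    """Iteratively superimpose a set of configurations onto their mean.

    All configurations are centered, then repeatedly aligned to the
    current consensus (coordinate-wise mean) until the summed squared
    distance to the consensus decreases by less than ``tolerance`` or
    ``max_iterations`` is reached (then a warning is emitted and the
    result is flagged unconverged).  With ``allow_scaling`` the total
    sum of squares of the set is held at its initial value so the
    consensus cannot collapse to a point.
    """
    if len(configs) == 0:
        raise ValueError("GPA needs at least one configuration")
    coords = [_as_coords(c).copy() for c in configs]
    for c in coords:
        _check_configuration(c)
    shapes = {c.shape for c in coords}
    if len(shapes) > 1:
        raise ValueError(f"landmark counts differ across configurations: {shapes}")

    X = np.array(coords)
    X -= X.mean(axis=1, keepdims=True)
    total_ss = (X**2).sum()

    mean = X.mean(axis=0)
    objective = float(((X - mean) ** 2).sum())
    history = [objective]
    converged = len(X) == 1  # a single shape is trivially aligned
    iterations = 1
    for iterations in range(1, max_iterations + 1):
        if len(X) == 1:
            break
        for i in range(len(X)):
            R = _optimal_rotation(X[i], mean)
            if allow_scaling:
                s = np.trace(X[i] @ R @ mean.T) / (X[i] ** 2).sum()
                X[i] = s * (X[i] @ R)
            else:
                X[i] = X[i] @ R
        if allow_scaling:
            X *= np.sqrt(total_ss / (X**2).sum())
        mean = X.mean(axis=0)
        new_objective = float(((X - mean) ** 2).sum())
        history.append(new_objective)
        if objective - new_objective < tolerance:
            objective = new_objective
            converged = True
            break
        objective = new_objective
    if not converged:
        warnings.warn(
            f"GPA did not converge within {max_iterations} iterations "
            f"(last objective change {history[-2] - history[-1]:.3e})"
        )
    mean = mean - mean.mean(axis=0)
    return GPAResult(
        aligned=X,
        mean_shape=mean,
        iterations=iterations,
        objective=objective,
        converged=converged,
        objective_history=history,
    )


def gpa_configurations(
    configs: Sequence[LandmarkConfiguration],
    allow_scaling: bool = False,
    tolerance: float = 1e-10,
    max_iterations: int = 100,
) -> tuple[list[LandmarkConfiguration], GPAResult]:
    """GPA over LandmarkConfigurations, returning aligned copies."""
    result = gpa(
        configs,
        allow_scaling=allow_scaling,
        tolerance=tolerance,
        max_iterations=max_iterations,
    )
    aligned = [c.with_coords(x) for c, x in zip(configs, result.aligned)]
    return aligned, result
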