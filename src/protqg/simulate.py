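"""Synthetic grouped-landmark data with known covariance structure.

The generator emulates the data layout of an ensemble study: S taxa
(homologs), each observed through R replicate snapshots of a p-trait
shape.  Taxon mean shapes are drawn from a multivariate normal with
between-taxon covariance B; replicates scatter around their taxon mean
with within-taxon covariance W; an independent isotropic error term
N(0, sigma2_e I) — measurement/registration noise that the estimator
cannot separate — is added on top.

Both the *population* parameters (the MVN covariances) and the
*realized* generating matrices (the sample covariance of the drawn taxon
means; the pooled covariance of the drawn within-taxon deviations,
before error) are recorded.  The feasibility benchmark scores the
pooled-within estimator against the realized matrices: in a simulation
these are exactly known, and they isolate the estimator's decomposition
accuracy from the Wishart sampling noise of a finite taxon draw, which
no estimator can remove.  Convergence toward the population parameters
as taxa accumulate is a separate property, tested against the
parameters themselves.

Default random covariance matrices use a log-uniform eigenvalue
spectrum spanning two decades with a random orthogonal eigenbasis —
anisotropic enough that random-skewer correlations are informative
(flat-spectrum matrices make every skewer trivially agree).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariance import decompose
from .landmarks import PhenotypeMatrix
from .skewers import random_skewers

__all__ = [
    "random_psd",
    "tree_covariance",
    "SimulatedDataset",
    "simulate_dataset",
    "feasibility_benchmark",
]

#: Default relative magnitude of the iid error term: sigma2_e equals
#: this fraction of the mean eigenvalue of the within-taxon matrix.
DEFAULT_ERROR_SCALE = 0.05


def random_psd(
    p: int,
    rng: np.random.Generator,
    decades: float = 2.0,
    eigenvalues: np.ndarray | None = None,
) -> np.ndarray:
    """Random PSD matrix Q diag(lambda) Q^T with a random orthogonal Q.

    Eigenvalues default to a sorted log-uniform sample spanning
    ``decades`` decades below 1.
    """
    if eigenvalues is None:
        lams = 10.0 ** rng.uniform(-decades, 0.0, size=p)
    else:
        lams = np.asarray(eigenvalues, dtype=float)
        if lams.shape != (p,) or (lams < 0).any():
            raise ValueError("eigenvalues must be p non-negative numbers")
    lams = np.sort(lams)[::-1]
    Q = np.linalg.qr(rng.standard_normal((p, p)))[0]
    return (Q * lams) @ Q.T


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    vals = np.linalg.eigvalsh(M)
    if vals.min() < -1e-8 * max(vals.max(), 1.0):
        raise ValueError(f"{name} is not positive semidefinite")
    return (M + M.T) / 2.0


def _chol(M: np.ndarray) -> np.ndarray:
    # Tiny jitter keeps the factorization alive for singular PSD inputs.
    p = M.shape[0]
    jitter = 1e-12 * max(float(np.trace(M)) / max(p, 1), 1.0)
    return np.linalg.cholesky(M + jitter * np.eye(p))


def tree_covariance(newick: str) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance among the tips of a Newick tree.

    Cov(i, j) is the shared path length from the root to the most recent
    common ancestor of tips i and j.  Returns tip labels and the matrix.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    depth = {t: tree.find_node_for_taxon(t).root_distance for t in taxa}
    S = len(taxa)
    C = np.zeros((S, S))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i == j:
                C[i, j] = depth[ti]
            else:
                C[i, j] = (depth[ti] + depth[tj] - pdm.patristic_distance(ti, tj)) / 2.0
    return labels, C


@dataclass
class SimulatedDataset:
    """Synthetic phenotype matrix plus the matrices that generated it."""

    phenotypes: PhenotypeMatrix
    between_true: np.ndarray  # realized covariance of the drawn taxon means
    within_true: np.ndarray  # realized pooled covariance of the drawn deviations
    between_population: np.ndarray  # MVN parameter for taxon means
    within_population: np.ndarray  # MVN parameter for replicates
    sigma2_error: float
    seed: int | None
    n_taxa: int
    n_replicates: int
    n_traits: int


def simulate_dataset(
    n_traits: int,
    n_taxa: int = 100,
    n_replicates: int = 500,
    between: np.ndarray | None = None,
    within: np.ndarray | None = None,
    error_scale: float = DEFAULT_ERROR_SCALE,
    sigma2_error: float | None = None,
    seed: int | None = None,
    tree: str | None = None,
) -> SimulatedDataset:
    """Draw a grouped dataset with known covariance structure.

    Parameters
    ----------
    n_traits, n_taxa, n_replicates:
        Problem size: p traits, S taxa, R snapshots per taxon.  The
        defaults (100 taxa, 500 replicates) are the ensemble-study scale
        the feasibility benchmark operates at.
    between, within:
        Optional user-supplied PSD covariance parameters; by default
        each is an independent :func:`random_psd` draw.
    error_scale, sigma2_error:
        The iid error variance; ``sigma2_error`` wins if given,
        otherwise it is ``error_scale`` times the mean eigenvalue
        (``trace/p``) of the within matrix.
    tree:
        Optional Newick string; taxon means then follow Brownian motion
        along the tree (tip count must equal ``n_taxa``) instead of
        being independent draws.
    """
    if n_taxa < 2 or n_replicates < 2 or n_traits < 1:
        raise ValueError("need n_taxa >= 2, n_replicates >= 2, n_traits >= 1")
    rng = np.random.default_rng(seed)
    B = random_psd(n_traits, rng) if between is None else _check_psd(between, "between")
    W = random_psd(n_traits, rng) if within is None else _check_psd(within, "within")
    if sigma2_error is None:
        sigma2_error = error_scale * float(np.trace(W)) / n_traits
    if sigma2_error < 0:
        raise ValueError("error variance must be non-negative")

    LB, LW = _chol(B), _chol(W)
    if tree is not None:
        labels, C = tree_covariance(tree)
        if len(labels) != n_taxa:
            raise ValueError(
                f"tree has {len(labels)} tips but n_taxa={n_taxa}"
            )
        LC = _chol(_check_psd(C, "tree covariance"))
        means = LC @ rng.standard_normal((n_taxa, n_traits)) @ LB.T
        taxa = [str(lab) for lab in labels]
    else:
        means = rng.standard_normal((n_taxa, n_traits)) @ LB.T
        width = len(str(n_taxa - 1))
        taxa = [f"taxon{i:0{width}d}" for i in range(n_taxa)]

    n = n_taxa * n_replicates
    g = np.repeat(np.arange(n_taxa), n_replicates)

    # Realized between matrix: sample covariance of the drawn means.
    mc = means - means.mean(axis=0)
    between_true = mc.T @ mc / (n_taxa - 1)

    # Replicate deviations; their realized pooled covariance is the
    # within matrix the estimator should recover (before error).
    X = rng.standard_normal((n, n_traits)) @ LW.T
    dev_group_means = X.reshape(n_taxa, n_replicates, n_traits).mean(axis=1)
    centered = X - dev_group_means[g]
    within_true = centered.T @ centered / (n - n_taxa)
    del centered

    X += means[g]
    if sigma2_error > 0.0:
        X += rng.standard_normal((n, n_traits)) * np.sqrt(sigma2_error)

    groups = np.array([taxa[i] for i in g], dtype=object)
    row_ids = [f"{taxa[i]}:{r + 1}" for i in range(n_taxa) for r in range(n_replicates)]
    phen = PhenotypeMatrix(values=X, groups=groups, row_ids=row_ids)
    return SimulatedDataset(
        phenotypes=phen,
        between_true=(between_true + between_true.T) / 2.0,
        within_true=(within_true + within_true.T) / 2.0,
        between_population=B,
        within_population=W,
        sigma2_error=float(sigma2_error),
        seed=seed,
        n_taxa=n_taxa,
        n_replicates=n_replicates,
        n_traits=n_traits,
    )


def feasibility_benchmark(
    trait_series: list[int],
    n_taxa: int = 100,
    n_replicates: int = 500,
    n_skewers: int = 1000,
    seed: int | None = None,
    error_scale: float = DEFAULT_ERROR_SCALE,
) -> pd.DataFrame:
    """Accuracy of the pooled-within decomposition across trait counts.

    For each p in ``trait_series``: simulate, estimate V_P / W / B, and
    random-skewer the estimated between matrix against the realized
    generating between matrix (``rs_b``) and the estimated within matrix
    against the realized within matrix (``rs_w``).  Wall time per row is
    reported informationally.
    """
    if not trait_series:
        raise ValueError("trait series must be non-empty")
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(len(trait_series))
    rows = []
    for p, child in zip(trait_series, children):
        t0 = time.perf_counter()
        sim_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        data = simulate_dataset(
            n_traits=p,
            n_taxa=n_taxa,
            n_replicates=n_replicates,
            error_scale=error_scale,
            seed=sim_seed,
        )
        dec = decompose(data.phenotypes.values, data.phenotypes.groups)
        rs_b = random_skewers(
            dec.between, data.between_true, n_skewers=n_skewers, seed=sim_seed + 1
        )
        rs_w = random_skewers(
            dec.within, data.within_true, n_skewers=n_skewers, seed=sim_seed + 2
        )
        rows.append(
            {
                "traits": p,
                "rs_b_rho": rs_b.rho,
                "rs_b_p": rs_b.p_value,
                "rs_w_rho": rs_w.rho,
                "rs_w_p": rs_w.p_value,
                "seconds": time.perf_counter() - t0,
                "seed": sim_seed,
            }
        )
        del data, dec
    return pd.DataFrame(rows)
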