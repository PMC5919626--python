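"""Fitness proxies for structure ensembles.

The default fitness of a snapshot is its unfolding free energy averaged
over residues, dG_hat = dG_unfold / r (kcal/mol/residue), which makes
stabilities comparable across proteins of different size.  Where enzyme
kinetics toward a common substrate are available the stability can be
combined with catalytic efficiency as F = dG * kcat / KM.  The framework
itself is fitness-agnostic: any per-model scalar works, and extreme
(most-fit / least-fit) snapshots define the target and source phenotypes
of a realized response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .landmarks import PhenotypeMatrix

__all__ = [
    "FitnessTable",
    "per_residue_energy",
    "combined_fitness",
    "parse_energy_table",
    "select_extremes",
    "fitness_surface",
]

ModelKey = tuple[str, int]  # (structure id, model id)


def per_residue_energy(delta_g: float, r: int) -> float:
    """Unfolding energy per residue, dG / r (kcal/mol/residue)."""
    if r < 1:
        raise ValueError(f"residue count must be >= 1, got {r}")
    return delta_g / r


def combined_fitness(delta_g: float, kcat: float, km: float) -> float:
    """Stability-times-efficiency fitness F = dG * kcat / KM."""
    if km <= 0.0:
        raise ValueError(f"Michaelis constant must be positive, got {km}")
    return delta_g * kcat / km


@dataclass
class FitnessTable:
    """Per-model fitness rows keyed by (structure id, model id).

    Columns: ``structure_id``, ``model_id``, ``total_energy`` (kcal/mol),
    ``residue_count``, ``dg_hat`` (= total_energy / residue_count,
    kcal/mol/residue) and, when kinetics are supplied, ``kcat`` (1/s),
    ``km`` (M), ``substrate`` and ``combined`` (= total_energy * kcat/KM).
    A single substrate id is enforced per analysis.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"structure_id", "model_id", "total_energy", "residue_count", "dg_hat"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"fitness table misses columns: {sorted(missing)}")
        keys = list(zip(self.data["structure_id"], self.data["model_id"]))
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (structure_id, model_id) rows")
        if len(self.data) and (self.data["residue_count"] < 1).any():
            raise ValueError("residue counts must be >= 1")
        if "substrate" in self.data.columns and len(self.data):
            substrates = set(self.data["substrate"].dropna())
            if len(substrates) > 1:
                raise ValueError(
                    f"kinetic fitness needs a single common substrate, got {substrates}"
                )

    def __len__(self) -> int:
        return len(self.data)

    def fitness(self, column: str = "dg_hat") -> dict[ModelKey, float]:
        return {
            (str(r.structure_id), int(r.model_id)): float(getattr(r, column))
            for r in self.data.itertuples()
        }


def parse_energy_table(
    path: str | Path,
    residue_counts: dict[str, int] | None = None,
    negate_energy: bool = False,
) -> FitnessTable:
    """Parse a tab-separated per-model energy table.

    The file needs columns ``structure_id``, ``model_id`` and
    ``total_energy`` (e.g. tabulated FoldX totals); a ``residue_count``
    column may be present, or counts are supplied per structure via
    ``residue_counts`` (e.g. from the landmark sets).  Optional ``kcat``,
    ``km`` and ``substrate`` columns trigger the combined fitness.
    ``negate_energy`` flips the sign of ``total_energy`` for energy
    conventions in which smaller totals mean higher stability.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"structure_id": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"empty fitness table {path}")
        df = pd.DataFrame(columns=["structure_id", "model_id", "total_energy"])
    required = {"structure_id", "model_id", "total_energy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fitness table {path} misses columns: {sorted(missing)}")
    df = df.copy()
    df["model_id"] = df["model_id"].astype(int)
    df["total_energy"] = df["total_energy"].astype(float)
    if negate_energy:
        df["total_energy"] = -df["total_energy"]
    if "residue_count" not in df.columns:
        if residue_counts is None:
            raise ValueError(
                "no residue_count column and no residue counts supplied"
            )
        try:
            df["residue_count"] = [
                residue_counts[sid] for sid in df["structure_id"]
            ]
        except KeyError as exc:
            raise ValueError(f"no residue count for structure {exc.args[0]!r}") from exc
    df["residue_count"] = df["residue_count"].astype(int)
    df["dg_hat"] = df["total_energy"] / df["residue_count"]
    if {"kcat", "km"} <= set(df.columns):
        if (df["km"] <= 0).any():
            raise ValueError("Michaelis constants must be positive")
        df["combined"] = df["total_energy"] * df["kcat"] / df["km"]
    return FitnessTable(data=df)


def select_extremes(
    table: FitnessTable,
    column: str = "dg_hat",
    explicit: tuple[ModelKey, ModelKey] | None = None,
) -> tuple[ModelKey, ModelKey]:
    """(target, source) = (most fit, least fit) model keys.

    Higher stored fitness is better; ties break toward the
    lexicographically lowest (structure id, model id).  An ``explicit``
    (target, source) pair bypasses the extremes — any source-to-target
    gradient is a valid selection hypothesis.
    """
    if explicit is not None:
        return explicit
    if len(table) < 2:
        raise ValueError("need at least 2 fitness rows to pick extremes")
    fit = table.fitness(column)
    target = min(fit, key=lambda key: (-fit[key], key))
    source = min(fit, key=lambda key: (fit[key], key))
    return target, source


def fitness_surface(
    P: PhenotypeMatrix,
    table: FitnessTable,
    column: str = "dg_hat",
) -> pd.DataFrame:
    """Shape PCA scores paired with fitness, for surface exploration.

    Returns one row per snapshot with scores on the two leading
    principal axes of the centered phenotype matrix and the snapshot's
    fitness as the vertical axis.  Eigenvector signs are fixed so the
    largest-magnitude loading of each axis is positive.
    """
    if P.n < 3:
        raise ValueError(f"need at least 3 snapshots for a PCA, got {P.n}")
    fit = table.fitness(column)
    keys = [
        (rid.rsplit(":", 1)[0], int(rid.rsplit(":", 1)[1])) for rid in P.row_ids
    ]
    absent = [key for key in keys if key not in fit]
    if absent:
        raise ValueError(f"fitness table does not cover rows: {absent[:5]}")
    X = P.values - P.values.mean(axis=0)
    cov = X.T @ X / (P.n - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:2]
    axes = vecs[:, order]
    for a in range(axes.shape[1]):
        lead = np.argmax(np.abs(axes[:, a]))
        if axes[lead, a] < 0:
            axes[:, a] = -axes[:, a]
    scores = X @ axes
    return pd.DataFrame(
        {
            "structure_id": [key[0] for key in keys],
            "model_id": [key[1] for key in keys],
            "pc1": scores[:, 0],
            "pc2": scores[:, 1] if scores.shape[1] > 1 else 0.0,
            "fitness": [fit[key] for key in keys],
        }
    )
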