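"""Residue-centroid landmarks from structure ensembles.

A protein snapshot is abstracted as an ordered set of 3-D landmarks, one
per residue, placed at the unweighted centroid of the residue's heavy
side-chain atoms plus the alpha carbon.  Backbone N, C, O (and OXT) are
excluded so the landmark tracks side-chain position while the CA anchors
it to the backbone; for glycine the landmark is the CA itself.

Ensembles of snapshots (multi-model PDB files, one file per homolog) are
reduced to :class:`LandmarkConfiguration` lists, and a user-supplied
homology map restricts and orders the landmarks of each homolog into the
shared trait space of fully homologous alignment columns, yielding a
:class:`PhenotypeMatrix` of ``n`` snapshots by ``l = 3k`` coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BACKBONE_ATOMS",
    "EnsembleFormatError",
    "MissingHomologyError",
    "ResidueRecord",
    "LandmarkConfiguration",
    "HomologyMap",
    "PhenotypeMatrix",
    "read_ensemble",
    "residue_centroid",
    "apply_homology_map",
    "select_ambassador",
]

#: Backbone heavy atoms excluded from the centroid (CA is kept).
BACKBONE_ATOMS = frozenset({"N", "C", "O", "OXT"})


class EnsembleFormatError(ValueError):
    """The structure file could not be interpreted as a model ensemble."""


class MissingHomologyError(KeyError):
    """A homology-map entry points at a residue absent from a model."""


#: Residue identity within one structure: (chain id, author residue
#: number, insertion code).  Insertion codes are part of the key.
ResidueKey = tuple[str, int, str]


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of one model: identity plus its heavy atoms."""

    chain: str
    number: int
    icode: str
    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Angstrom

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.number, self.icode)

    def has_ca(self) -> bool:
        return "CA" in self.atom_names


@dataclass
class LandmarkConfiguration:
    """One snapshot of one structure as an ordered landmark set."""

    structure_id: str
    model_id: int
    coords: np.ndarray  # (k, 3), Angstrom
    residue_keys: list[ResidueKey]
    residue_names: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("landmark coordinates must be a (k, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"non-finite landmark coordinates in "
                f"{self.structure_id} model {self.model_id}"
            )

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            self.structure_id,
            self.model_id,
            np.asarray(coords, dtype=float),
            list(self.residue_keys),
            list(self.residue_names),
        )


def residue_centroid(residue: ResidueRecord, strict_con: bool = False) -> np.ndarray:
    """Unweighted centroid of CA plus heavy side-chain atoms.

    Parameters
    ----------
    residue:
        Residue with at least a CA atom; hydrogens are assumed to have
        been stripped already (any remaining are ignored).
    strict_con:
        If true, restrict side-chain atoms to elements C, N and O,
        excluding sulfur and selenium (Cys SG, Met SD, Sec SE).  The
        default keeps every heavy side-chain atom, so Cys and Met
        centroids are not silently displaced.

    Returns
    -------
    (3,) array — the landmark position in Angstrom.  For glycine this is
    exactly the CA coordinate.
    """
    if not residue.has_ca():
        raise ValueError(f"residue {residue.key} {residue.name} has no CA atom")
    picked = []
    for atom_name, element, xyz in zip(
        residue.atom_names, residue.elements, residue.coords
    ):
        if element == "H":
            continue
        if atom_name == "CA":
            picked.append(xyz)
        elif atom_name not in BACKBONE_ATOMS:
            if strict_con and element not in ("C", "N", "O"):
                continue
            picked.append(xyz)
    return np.mean(np.asarray(picked, dtype=float), axis=0)


# ---------------------------------------------------------------------------
# PDB reading


def _parse_models(path: Path):
    """Yield (model_id, AtomArray of amino-acid heavy atoms)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as exc:  # biotite raises various types on bad input
        raise EnsembleFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if n_models < 1:
        raise EnsembleFormatError(f"no coordinate models found in {path}")
    for model in range(1, n_models + 1):
        try:
            atoms = pdb.get_structure(model=model, altloc="occupancy")
        except Exception as exc:
            raise EnsembleFormatError(
                f"cannot build model {model} of {path}: {exc}"
            ) from exc
        mask = (
            struc.filter_amino_acids(atoms)
            & ~atoms.hetero
            & (atoms.element != "H")
        )
        yield model, atoms[mask]


def _group_residues(atoms) -> dict[ResidueKey, ResidueRecord]:
    """Group an AtomArray into ResidueRecords keyed by (chain, num, icode)."""
    import biotite.structure as struc

    records: dict[ResidueKey, ResidueRecord] = {}
    if atoms.array_length() == 0:
        return records
    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    icodes = atoms.ins_code if "ins_code" in atoms.get_annotation_categories() else None
    for begin, end in zip(starts[:-1], starts[1:]):
        chain = str(atoms.chain_id[begin])
        number = int(atoms.res_id[begin])
        icode = str(icodes[begin]).strip() if icodes is not None else ""
        name = str(atoms.res_name[begin])
        rec = ResidueRecord(
            chain=chain,
            number=number,
            icode=icode,
            name=name,
            atom_names=tuple(str(a) for a in atoms.atom_name[begin:end]),
            elements=tuple(str(e) for e in atoms.element[begin:end]),
            coords=np.array(atoms.coord[begin:end], dtype=float),
        )
        records[rec.key] = rec
    return records


def read_ensemble(
    path: str | Path,
    structure_id: str,
    strict_con: bool = False,
) -> list[LandmarkConfiguration]:
    """Read a multi-model PDB file into landmark configurations.

    Each MODEL becomes one :class:`LandmarkConfiguration` (a file without
    MODEL records yields a single configuration).  Waters, hetero groups
    and hydrogens are excluded.  A residue lacking a CA in any model is
    dropped from every model of the ensemble (with a warning) so that all
    configurations share an identical, ``(chain, residue number, icode)``-
    ordered landmark set.
    """
    path = Path(path)
    per_model: list[tuple[int, dict[ResidueKey, ResidueRecord]]] = []
    for model_id, atoms in _parse_models(path):
        per_model.append((model_id, _group_residues(atoms)))
    if not per_model:
        raise EnsembleFormatError(f"no models in {path}")

    # Residues must be present, with a CA, in every model.
    common: set[ResidueKey] | None = None
    for model_id, residues in per_model:
        keys = set()
        for key, rec in residues.items():
            if rec.has_ca():
                keys.add(key)
            else:
                warnings.warn(
                    f"{structure_id} model {model_id}: residue "
                    f"{key[0]}{key[1]}{key[2]} {rec.name} has no CA; dropped"
                )
        common = keys if common is None else (common & keys)
    assert common is not None
    if not common:
        raise EnsembleFormatError(
            f"{structure_id}: no residue with a CA is shared by all models"
        )
    ordered = sorted(common)

    configs = []
    for model_id, residues in per_model:
        coords = np.array(
            [residue_centroid(residues[key], strict_con=strict_con) for key in ordered]
        )
        configs.append(
            LandmarkConfiguration(
                structure_id=structure_id,
                model_id=model_id,
                coords=coords,
                residue_keys=list(ordered),
                residue_names=[residues[key].name for key in ordered],
            )
        )
    return configs


# ---------------------------------------------------------------------------
# Homology map


@dataclass
class HomologyMap:
    """Ordered fully-homologous alignment columns.

    ``columns[j]`` maps each structure id to the ``(chain, residue
    number, insertion code)`` of the residue occupying column ``j``;
    ``resnames[j]`` carries the residue names for reporting.  Only
    columns in which every structure is present (fully homologous sites)
    are representable.
    """

    columns: list[dict[str, ResidueKey]]
    resnames: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.resnames:
            self.resnames = [{} for _ in self.columns]
        sids = self.structure_ids
        for j, col in enumerate(self.columns):
            if set(col) != set(sids):
                raise ValueError(
                    f"homology column {j + 1} does not cover every structure"
                )

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def structure_ids(self) -> list[str]:
        return sorted(self.columns[0]) if self.columns else []

    def residue_labels(self, structure_id: str) -> list[tuple[int, str]]:
        """Per-column (author residue number, residue name) of one structure."""
        return [
            (col[structure_id][1], names.get(structure_id, "UNK"))
            for col, names in zip(self.columns, self.resnames)
        ]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologyMap":
        """Read the tab-separated map.

        Expected header: ``column  structure_id  chain  resnum  icode
        resname``; one row per (column, structure); columns are 1-based
        in the file.
        """
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"structure_id": str, "chain": str, "icode": str, "resname": str},
            keep_default_na=False,
        )
        required = {"column", "structure_id", "chain", "resnum", "icode", "resname"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"homology map misses columns: {sorted(missing)}")
        columns: list[dict[str, ResidueKey]] = []
        resnames: list[dict[str, str]] = []
        for col_id in sorted(df["column"].unique()):
            sub = df[df["column"] == col_id]
            columns.append(
                {
                    str(r.structure_id): (str(r.chain), int(r.resnum), str(r.icode))
                    for r in sub.itertuples()
                }
            )
            resnames.append({str(r.structure_id): str(r.resname) for r in sub.itertuples()})
        return cls(columns=columns, resnames=resnames)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for j, (col, names) in enumerate(zip(self.columns, self.resnames), start=1):
            for sid in sorted(col):
                chain, resnum, icode = col[sid]
                rows.append(
                    {
                        "column": j,
                        "structure_id": sid,
                        "chain": chain,
                        "resnum": resnum,
                        "icode": icode,
                        "resname": names.get(sid, "UNK"),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype matrix


def trait_names(k: int) -> list[str]:
    """Trait names ``res<j>_<axis>`` with 1-based residue columns."""
    return [f"res{j + 1}_{axis}" for j in range(k) for axis in "xyz"]


@dataclass
class PhenotypeMatrix:
    """GPS-aligned shape coordinates with homolog (group) labels.

    Rows are snapshots; for landmark-derived matrices the columns follow
    the convention that alignment column ``j`` (0-based) occupies matrix
    columns ``3j, 3j+1, 3j+2`` = (x, y, z).  Simulated matrices may
    carry an arbitrary trait count; landmark-specific views (``k``,
    ``configurations``) then refuse to apply.
    """

    values: np.ndarray  # (n, l); l = 3k for landmark data
    groups: np.ndarray  # (n,) structure/taxon id per row
    row_ids: list[str]  # "structure_id:model_id"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be 2-D")
        if len(self.groups) != self.values.shape[0]:
            raise ValueError("one group label per row is required")
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError("one row id per row is required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def l(self) -> int:  # noqa: E743 - the field's symbol for trait count
        return self.values.shape[1]

    @property
    def k(self) -> int:
        if self.l % 3 != 0:
            raise ValueError(f"trait count {self.l} is not landmark-shaped (3k)")
        return self.l // 3

    @property
    def trait_names(self) -> list[str]:
        if self.l % 3 != 0:
            return [f"t{j + 1}" for j in range(self.l)]
        return trait_names(self.k)

    def group_sizes(self) -> dict[str, int]:
        labels, counts = np.unique(self.groups.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def group_means(self) -> tuple[list[str], np.ndarray]:
        labels = sorted(set(self.groups.astype(str)))
        means = np.array(
            [self.values[self.groups.astype(str) == g].mean(axis=0) for g in labels]
        )
        return labels, means

    def row(self, structure_id: str, model_id: int) -> np.ndarray:
        rid = f"{structure_id}:{model_id}"
        try:
            i = self.row_ids.index(rid)
        except ValueError:
            raise KeyError(f"no phenotype row {rid}") from None
        return self.values[i]

    def configurations(self) -> np.ndarray:
        """Rows reshaped to (n, k, 3) landmark configurations."""
        return self.values.reshape(self.n, self.k, 3)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, "structure_id:model_id", self.row_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        row_ids = df.iloc[:, 0].astype(str).tolist()
        groups = np.array([rid.rsplit(":", 1)[0] for rid in row_ids], dtype=object)
        return cls(values=df.iloc[:, 1:].to_numpy(float), groups=groups, row_ids=row_ids)


def apply_homology_map(
    ensembles: Mapping[str, Sequence[LandmarkConfiguration]],
    hmap: HomologyMap,
) -> PhenotypeMatrix:
    """Assemble the phenotype matrix restricted to fully homologous sites.

    Every model of every ensemble becomes one row; matrix columns follow
    the homology-map column order with the (x, y, z) convention.  A map
    entry naming a residue absent from a model raises
    :class:`MissingHomologyError`.
    """
    for sid in hmap.structure_ids:
        if sid not in ensembles:
            raise MissingHomologyError(f"no ensemble supplied for structure {sid!r}")

    rows, groups, row_ids = [], [], []
    for sid in hmap.structure_ids:
        for config in ensembles[sid]:
            index = {key: i for i, key in enumerate(config.residue_keys)}
            picked = np.empty((hmap.n_columns, 3))
            for j, col in enumerate(hmap.columns):
                key = col[sid]
                if key not in index:
                    raise MissingHomologyError(
                        f"structure {sid!r} column {j + 1}: residue "
                        f"{key[0]}{key[1]}{key[2]} absent from model "
                        f"{config.model_id}"
                    )
                picked[j] = config.coords[index[key]]
            rows.append(picked.reshape(-1))
            groups.append(sid)
            row_ids.append(f"{sid}:{config.model_id}")
    return PhenotypeMatrix(
        values=np.array(rows), groups=np.array(groups, dtype=object), row_ids=row_ids
    )


def select_ambassador(ensemble: Sequence[LandmarkConfiguration]) -> int:
    """Model id of the configuration closest to the ensemble mean shape.

    Distance is the root-sum-of-squares over landmarks to the
    coordinate-wise mean configuration; ties break toward the lowest
    model id.  The ensemble is expected to be GPS-aligned already.
    """
    if len(ensemble) == 0:
        raise ValueError("cannot select an ambassador from an empty ensemble")
    stack = np.array([c.coords for c in ensemble])
    mean = stack.mean(axis=0)
    dists = np.sqrt(((stack - mean) ** 2).sum(axis=(1, 2)))
    order = sorted(range(len(ensemble)), key=lambda i: (dists[i], ensemble[i].model_id))
    return ensemble[order[0]].model_id
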