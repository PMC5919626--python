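"""Shared fixtures: programmatic PDB text builders and toy ensembles."""

from __future__ import annotations

import numpy as np
import pytest

# (atom name, element) sets per residue type used in fixtures
RESIDUE_ATOMS = {
    "GLY": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")],
    "ALA": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")],
    "CYS": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("SG", "S")],
    "SER": [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C"), ("OG", "O")],
}


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    xyz,
    element: str,
    record: str = "ATOM",
    icode: str = " ",
    altloc: str = " ",
    occupancy: float = 1.0,
    b_factor: float = 0.0,
) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record:<6s}{serial:5d} {name_field}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}{icode}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{b_factor:6.2f}          {element:>2s}"
    )


def residue_lines(
    resname: str,
    resnum: int,
    ca_xyz,
    chain: str = "A",
    serial_start: int = 1,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """ATOM lines for one residue with atoms offset around the CA."""
    ca = np.asarray(ca_xyz, dtype=float)
    offsets = {
        "N": (-1.2, 0.5, 0.0),
        "CA": (0.0, 0.0, 0.0),
        "C": (1.2, 0.5, 0.0),
        "O": (1.4, 1.7, 0.0),
        "CB": (0.0, -1.0, 1.1),
        "SG": (0.3, -2.2, 2.0),
        "OG": (0.3, -2.0, 1.8),
    }
    lines = []
    for i, (name, element) in enumerate(RESIDUE_ATOMS[resname]):
        xyz = ca + np.asarray(offsets[name])
        if jitter and rng is not None:
            xyz = xyz + rng.normal(0.0, jitter, size=3)
        lines.append(
            atom_line(serial_start + i, name, resname, chain, resnum, xyz, element)
        )
    return lines


def build_pdb(models: list[list[str]]) -> str:
    """Assemble PDB text from per-model ATOM-line lists."""
    if len(models) == 1:
        return "\n".join(models[0] + ["END"]) + "\n"
    chunks = []
    for i, lines in enumerate(models, start=1):
        chunks.append(f"MODEL     {i:4d}")
        chunks.extend(lines)
        chunks.append("ENDMDL")
    chunks.append("END")
    return "\n".join(chunks) + "\n"


def three_residue_model(
    ca_positions,
    resnames=("ALA", "GLY", "SER"),
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[str]:
    lines: list[str] = []
    serial = 1
    for resnum, (resname, ca) in enumerate(zip(resnames, ca_positions), start=1):
        new = residue_lines(resname, resnum, ca, serial_start=serial, jitter=jitter, rng=rng)
        lines.extend(new)
        serial += len(new)
    return lines


BASE_CA = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [5.5, 3.4, 0.0]])


@pytest.fixture
def toy_ensemble_file(tmp_path):
    """Factory writing a jittered 3-residue multi-model PDB file."""

    def _make(structure_id: str, n_models: int = 4, seed: int = 0, shift=(0, 0, 0)):
        rng = np.random.default_rng(seed)
        models = [
            three_residue_model(BASE_CA + np.asarray(shift), jitter=0.05, rng=rng)
            for _ in range(n_models)
        ]
        path = tmp_path / f"{structure_id}.pdb"
        path.write_text(build_pdb(models))
        return path

    return _make


@pytest.fixture
def toy_homology_map_file(tmp_path):
    """Homology map covering the 3 shared residues of two toy structures."""

    def _make(structure_ids=("strA", "strB"), n_columns: int = 3):
        resnames = ["ALA", "GLY", "SER"]
        rows = ["column\tstructure_id\tchain\tresnum\ticode\tresname"]
        for col in range(1, n_columns + 1):
            for sid in structure_ids:
                rows.append(f"{col}\t{sid}\tA\t{col}\t\t{resnames[col - 1]}")
        path = tmp_path / "hmap.tsv"
        path.write_text("\n".join(rows) + "\n")
        return path

    return _make


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
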