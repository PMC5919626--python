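"""Abstract two tiny structure ensembles as residue-centroid shapes.

Builds two 3-residue homologs with 3 snapshot models each (in a temp
directory), reads them, superimposes each ensemble, and assembles the
homology-restricted phenotype matrix.
"""

import tempfile
from pathlib import Path

import numpy as np

from protqg import HomologyMap, apply_homology_map, gpa_configurations, read_ensemble

ATOMS = {  # minimal alanine-like residue: backbone + CB
    "N": ("N", (-1.2, 0.5, 0.0)),
    "CA": ("C", (0.0, 0.0, 0.0)),
    "C": ("C", (1.2, 0.5, 0.0)),
    "O": ("O", (1.4, 1.7, 0.0)),
    "CB": ("C", (0.0, -1.0, 1.1)),
}


def write_ensemble(path: Path, n_models: int, seed: int) -> None:
    rng = np.random.default_rng(seed)
    ca = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0], [5.5, 3.4, 0.0]])
    chunks = []
    for m in range(1, n_models + 1):
        chunks.append(f"MODEL     {m:4d}")
        serial = 1
        for resnum, base in enumerate(ca, start=1):
            for name, (element, offset) in ATOMS.items():
                x, y, z = base + np.asarray(offset) + rng.normal(0, 0.05, 3)
                field = f" {name:<3s}"
                chunks.append(
                    f"ATOM  {serial:5d} {field} ALA A{resnum:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
                )
                serial += 1
        chunks.append("ENDMDL")
    path.write_text("\n".join(chunks + ["END"]) + "\n")


with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    write_ensemble(tmp / "homologA.pdb", 3, seed=1)
    write_ensemble(tmp / "homologB.pdb", 3, seed=2)
    hmap_rows = ["column\tstructure_id\tchain\tresnum\ticode\tresname"]
    for col in (1, 2, 3):
        for sid in ("homologA", "homologB"):
            hmap_rows.append(f"{col}\t{sid}\tA\t{col}\t\tALA")
    (tmp / "hmap.tsv").write_text("\n".join(hmap_rows) + "\n")

    ensembles = {}
    for sid in ("homologA", "homologB"):
        configs = read_ensemble(tmp / f"{sid}.pdb", sid)
        aligned, result = gpa_configurations(configs)
        ensembles[sid] = aligned
        print(
            f"{sid}: {len(configs)} models, k = {configs[0].k} landmarks, "
            f"ensemble GPA objective {result.objective:.4f} A^2"
        )

    phen = apply_homology_map(ensembles, HomologyMap.from_tsv(tmp / "hmap.tsv"))
    print(f"\nphenotype matrix: {phen.n} snapshots x {phen.l} coordinate traits")
    print("first row (x1 y1 z1 x2 y2 z2 x3 y3 z3):")
    print(np.array2string(phen.values[0], precision=3))

print(
    "\nEach row is one snapshot as the concatenated (x, y, z) of its"
    "\nresidue centroids after rigid superposition; rows are grouped by"
    "\nhomolog for the covariance decomposition."
)
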