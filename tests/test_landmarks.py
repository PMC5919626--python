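"""Landmark extraction, homology mapping and phenotype assembly."""

import numpy as np
import pytest

from protqg.landmarks import (
    HomologyMap,
    LandmarkConfiguration,
    MissingHomologyError,
    PhenotypeMatrix,
    ResidueRecord,
    apply_homology_map,
    read_ensemble,
    residue_centroid,
    select_ambassador,
)

from conftest import (
    BASE_CA,
    atom_line,
    build_pdb,
    random_rotation,
    residue_lines,
    three_residue_model,
)


def _record(name, atoms):
    """ResidueRecord from a list of (atom name, element, xyz)."""
    return ResidueRecord(
        chain="A",
        number=1,
        icode="",
        name=name,
        atom_names=tuple(a[0] for a in atoms),
        elements=tuple(a[1] for a in atoms),
        coords=np.array([a[2] for a in atoms], dtype=float),
    )


class TestResidueCentroid:
    def test_glycine_centroid_is_ca(self):
        ca = (1.5, -2.0, 3.25)
        rec = _record(
            "GLY",
            [("N", "N", (0, 0, 0)), ("CA", "C", ca), ("C", "C", (2, 0, 0)), ("O", "O", (3, 0, 0))],
        )
        assert np.allclose(residue_centroid(rec), ca)

    def test_alanine_centroid_is_ca_cb_midpoint(self):
        rec = _record(
            "ALA",
            [
                ("N", "N", (9, 9, 9)),
                ("CA", "C", (0, 0, 0)),
                ("C", "C", (9, 9, 9)),
                ("O", "O", (9, 9, 9)),
                ("CB", "C", (2, 0, 0)),
            ],
        )
        assert np.allclose(residue_centroid(rec), (1, 0, 0))

    def test_cube_symmetry_cancels(self):
        corners = [(sx, sy, sz) for sx in (-0.5, 0.5) for sy in (-0.5, 0.5) for sz in (-0.5, 0.5)]
        atoms = [("CA", "C", (0.0, 0.0, 0.0))] + [
            (f"C{i}", "C", c) for i, c in enumerate(corners)
        ]
        assert np.allclose(residue_centroid(_record("XXX", atoms)), (0, 0, 0), atol=1e-12)

    def test_strict_con_excludes_sulfur(self):
        atoms = [
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("CB", "C", (1.0, 0.0, 0.0)),
            ("SG", "S", (10.0, 0.0, 0.0)),
        ]
        rec = _record("CYS", atoms)
        assert np.allclose(residue_centroid(rec), (11 / 3, 0, 0))
        assert np.allclose(residue_centroid(rec, strict_con=True), (0.5, 0, 0))

    def test_missing_ca_rejected(self):
        rec = _record("ALA", [("CB", "C", (0, 0, 0))])
        with pytest.raises(ValueError, match="no CA"):
            residue_centroid(rec)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        atoms = [("CA", "C", rng.normal(size=3))] + [
            (f"C{i}", "C", rng.normal(size=3)) for i in range(5)
        ]
        rec = _record("XXX", atoms)
        R = random_rotation(rng)
        t = rng.normal(size=3)
        moved = _record(
            "XXX", [(n, e, R @ np.asarray(x) + t) for n, e, x in atoms]
        )
        assert np.allclose(
            residue_centroid(moved), R @ residue_centroid(rec) + t, atol=1e-9
        )


class TestReadEnsemble:
    def test_single_model(self, tmp_path):
        path = tmp_path / "one.pdb"
        path.write_text(build_pdb([three_residue_model(BASE_CA)]))
        configs = read_ensemble(path, "one")
        assert len(configs) == 1
        assert configs[0].k == 3
        assert configs[0].model_id == 1
        assert [k[1] for k in configs[0].residue_keys] == [1, 2, 3]

    def test_identical_models_yield_identical_configs(self, tmp_path):
        model = three_residue_model(BASE_CA)
        path = tmp_path / "five.pdb"
        path.write_text(build_pdb([model] * 5))
        configs = read_ensemble(path, "five")
        assert len(configs) == 5
        for c in configs[1:]:
            assert np.array_equal(c.coords, configs[0].coords)

    def test_water_excluded(self, tmp_path):
        model = three_residue_model(BASE_CA)
        model.append(
            atom_line(99, "O", "HOH", "A", 101, (8.0, 8.0, 8.0), "O", record="HETATM")
        )
        path = tmp_path / "wet.pdb"
        path.write_text(build_pdb([model]))
        configs = read_ensemble(path, "wet")
        assert configs[0].k == 3

    def test_hydrogens_excluded(self, tmp_path):
        model = three_residue_model(BASE_CA)
        model.append(atom_line(99, "HB1", "SER", "A", 3, (50.0, 50.0, 50.0), "H"))
        path = tmp_path / "h.pdb"
        path.write_text(build_pdb([model]))
        clean = read_ensemble(tmp_path / "h.pdb", "h")
        path2 = tmp_path / "noh.pdb"
        path2.write_text(build_pdb([three_residue_model(BASE_CA)]))
        ref = read_ensemble(path2, "noh")
        assert np.allclose(clean[0].coords, ref[0].coords)

    def test_missing_ca_drops_residue_everywhere(self, tmp_path):
        good = three_residue_model(BASE_CA)
        # Second model lacks the CA of residue 2.
        bad = [
            ln
            for ln in three_residue_model(BASE_CA)
            if not (ln[12:16].strip() == "CA" and int(ln[22:26]) == 2)
        ]
        path = tmp_path / "gap.pdb"
        path.write_text(build_pdb([good, bad]))
        with pytest.warns(UserWarning, match="no CA"):
            configs = read_ensemble(path, "gap")
        assert all(c.k == 2 for c in configs)
        assert all(k[1] in (1, 3) for c in configs for k in c.residue_keys)

    def test_unparsable_file_raises_format_error(self, tmp_path):
        from protqg.landmarks import EnsembleFormatError

        path = tmp_path / "junk.pdb"
        path.write_text("this is not a pdb file\n")
        with pytest.raises(EnsembleFormatError):
            read_ensemble(path, "junk")


def _config(sid, mid, coords, resnums=None):
    coords = np.asarray(coords, dtype=float)
    k = coords.shape[0]
    resnums = resnums or list(range(1, k + 1))
    return LandmarkConfiguration(
        structure_id=sid,
        model_id=mid,
        coords=coords,
        residue_keys=[("A", r, "") for r in resnums],
        residue_names=["ALA"] * k,
    )


def _hmap(structure_ids, columns):
    return HomologyMap(
        columns=[{sid: ("A", r, "") for sid in structure_ids} for r in columns],
        resnames=[{sid: "ALA" for sid in structure_ids} for _ in columns],
    )


class TestApplyHomologyMap:
    def _ensembles(self, k=4, models=2):
        rng = np.random.default_rng(0)
        return {
            sid: [_config(sid, m + 1, rng.normal(size=(k, 3))) for m in range(models)]
            for sid in ("s1", "s2")
        }

    def test_dimension_bookkeeping(self):
        phen = apply_homology_map(self._ensembles(), _hmap(["s1", "s2"], [1, 2, 3, 4]))
        assert phen.values.shape == (4, 12)
        assert sorted(set(phen.groups)) == ["s1", "s2"]

    def test_restricted_columns_dropped(self):
        phen = apply_homology_map(self._ensembles(), _hmap(["s1", "s2"], [1, 2, 4]))
        assert phen.values.shape == (4, 9)

    def test_missing_residue_is_an_error(self):
        with pytest.raises(MissingHomologyError, match="s1.*999|999.*s1"):
            apply_homology_map(self._ensembles(), _hmap(["s1", "s2"], [1, 999]))

    def test_columns_reproduce_mapped_centroids_exactly(self):
        ensembles = self._ensembles()
        hmap = _hmap(["s1", "s2"], [2, 4, 1])
        phen = apply_homology_map(ensembles, hmap)
        for sid in ("s1", "s2"):
            for config in ensembles[sid]:
                row = phen.row(sid, config.model_id)
                for j, col in enumerate(hmap.columns):
                    resnum = col[sid][1]
                    expected = config.coords[resnum - 1]
                    assert np.array_equal(row[3 * j : 3 * j + 3], expected)

    def test_dropping_a_model_leaves_other_rows_bit_identical(self):
        ensembles = self._ensembles()
        hmap = _hmap(["s1", "s2"], [1, 2, 3, 4])
        full = apply_homology_map(ensembles, hmap)
        reduced_ensembles = {"s1": ensembles["s1"][:1], "s2": ensembles["s2"]}
        reduced = apply_homology_map(reduced_ensembles, hmap)
        for rid in reduced.row_ids:
            sid, mid = rid.rsplit(":", 1)
            assert np.array_equal(reduced.row(sid, int(mid)), full.row(sid, int(mid)))


class TestSelectAmbassador:
    def test_single_model(self):
        assert select_ambassador([_config("s", 7, np.eye(3))]) == 7

    def test_tie_breaks_to_lowest_model_id(self):
        coords = np.arange(9.0).reshape(3, 3)
        ensemble = [_config("s", mid, coords) for mid in (3, 1, 2)]
        assert select_ambassador(ensemble) == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        ensemble = [_config("s", m + 1, rng.normal(scale=0.5, size=(5, 3))) for m in range(10)]
        ensemble.append(_config("s", 11, rng.normal(size=(5, 3)) + 10.0))
        # Independent oracle: exhaustive distance to the stack mean.
        stack = np.array([c.coords for c in ensemble])
        dists = [np.sqrt(((c.coords - stack.mean(0)) ** 2).sum()) for c in ensemble]
        expected = ensemble[int(np.argmin(dists))].model_id
        assert select_ambassador(ensemble) == expected
        assert select_ambassador(ensemble) != 11

    def test_empty_ensemble_is_an_error(self):
        with pytest.raises(ValueError):
            select_ambassador([])


class TestRoundTrips:
    def test_phenotype_matrix_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        phen = PhenotypeMatrix(
            values=rng.normal(size=(4, 6)),
            groups=np.array(["a", "a", "b", "b"], dtype=object),
            row_ids=["a:1", "a:2", "b:1", "b:2"],
        )
        path = tmp_path / "phen.tsv"
        phen.to_tsv(path)
        back = PhenotypeMatrix.from_tsv(path)
        assert np.allclose(back.values, phen.values)
        assert list(back.groups) == list(phen.groups)
        assert back.row_ids == phen.row_ids

    def test_homology_map_tsv_round_trip(self, tmp_path):
        hmap = _hmap(["s1", "s2"], [3, 1, 7])
        path = tmp_path / "hmap.tsv"
        hmap.to_tsv(path)
        back = HomologyMap.from_tsv(path)
        assert back.columns == hmap.columns

    def test_incomplete_column_rejected(self):
        with pytest.raises(ValueError, match="every structure"):
            HomologyMap(columns=[{"s1": ("A", 1, "")}, {"s1": ("A", 2, ""), "s2": ("A", 2, "")}])

    def test_nonfinite_landmarks_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            _config("s", 1, [[0, 0, np.nan], [1, 1, 1], [2, 2, 2]])
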