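"""End-to-end analysis pipeline and artifact writing.

The pipeline runs the full chain on a set of homolog ensembles: per-
ensemble GPA, ambassador selection, homology-mapped phenotype assembly,
global GPA, V_P / W / B decomposition, target/source selection from a
fitness table, realized response, selection and dynamic gradients with
their constraint angles, per-residue maps, ranked residue tables, and a
B-factor-encoded structure file for viewer rendering.  Every stage is
timed and logged; all artifacts plus a manifest (versions, seeds,
parameters, warnings) land in the output directory, and the manifest
alone suffices to re-run the pipeline.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariance import decompose
from .fitness import FitnessTable, parse_energy_table, select_extremes
from .landmarks import (
    HomologyMap,
    PhenotypeMatrix,
    apply_homology_map,
    read_ensemble,
    select_ambassador,
)
from .procrustes import gpa, gpa_configurations
from .quantgen import SelectionAnalysis, analyze_selection, realized_response

logger = logging.getLogger("protqg")

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline", "write_gradient_pdb"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    ensembles: dict[str, str]  # structure id -> multi-model PDB path
    homology_map: str
    output_dir: str
    fitness_table: str | None = None
    fitness_column: str = "dg_hat"
    negate_energy: bool = False
    target: str | None = None  # "structure_id:model_id" override
    source: str | None = None
    allow_scaling: bool = False
    strict_con: bool = False
    gpa_tolerance: float = 1e-10
    gpa_max_iterations: int = 100
    rank_tolerance: float | None = None
    variance_fraction: float = 0.99
    top_residues: int = 5
    reference_structure: str | None = None  # residue numbering; default: source
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    phenotypes: PhenotypeMatrix
    decomposition: object
    fitness: FitnessTable | None
    target: tuple[str, int]
    source: tuple[str, int]
    delta_z: np.ndarray
    genetic: SelectionAnalysis
    dynamic: SelectionAnalysis
    ambassadors: dict[str, int]
    manifest: dict = field(repr=False, default_factory=dict)


def _write_matrix(path: Path, M: np.ndarray, names: list[str]) -> None:
    pd.DataFrame(M, index=names, columns=names).to_csv(path, sep="\t")


def _write_vector(path: Path, v: np.ndarray, names: list[str], column: str) -> None:
    pd.DataFrame({"trait": names, column: v}).to_csv(path, sep="\t", index=False)


def _parse_key(text: str) -> tuple[str, int]:
    sid, mid = text.rsplit(":", 1)
    return sid, int(mid)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Any stage error aborts the run as :class:`PipelineError` naming the
    stage.  Returns the in-memory bundle; artifacts and the manifest are
    written to ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "protqg_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "stages": {},
        "warnings": [],
    }
    collected: list[str] = []

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.ctx = warnings.catch_warnings(record=True)
                self_inner.records = self_inner.ctx.__enter__()
                warnings.simplefilter("always")
                logger.info("stage %s ...", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                self_inner.ctx.__exit__(None, None, None)
                for w in self_inner.records:
                    collected.append(f"{name}: {w.message}")
                    warnings.warn_explicit(
                        w.message, w.category, w.filename, w.lineno
                    )
                manifest["stages"][name] = round(time.perf_counter() - self_inner.t0, 4)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(name, exc) from exc
                return False

        return _Stage()

    with stage("read_ensembles"):
        ensembles = {
            sid: read_ensemble(path, sid, strict_con=config.strict_con)
            for sid, path in config.ensembles.items()
        }

    with stage("ensemble_gpa"):
        aligned = {}
        for sid, configs in ensembles.items():
            aligned[sid], _ = gpa_configurations(
                configs,
                allow_scaling=config.allow_scaling,
                tolerance=config.gpa_tolerance,
                max_iterations=config.gpa_max_iterations,
            )

    with stage("ambassadors"):
        ambassadors = {sid: select_ambassador(configs) for sid, configs in aligned.items()}
        manifest["ambassadors"] = ambassadors

    with stage("homology_map"):
        hmap = HomologyMap.from_tsv(config.homology_map)
        phen = apply_homology_map(aligned, hmap)

    with stage("global_gpa"):
        result = gpa(
            list(phen.configurations()),
            allow_scaling=config.allow_scaling,
            tolerance=config.gpa_tolerance,
            max_iterations=config.gpa_max_iterations,
        )
        phen = PhenotypeMatrix(
            values=result.aligned.reshape(phen.n, phen.l),
            groups=phen.groups,
            row_ids=phen.row_ids,
        )
        phen.to_tsv(out / "phenotypes.tsv")
        pd.DataFrame(result.mean_shape, columns=["x", "y", "z"]).to_csv(
            out / "mean_shape.tsv", sep="\t", index=False
        )

    with stage("covariance"):
        dec = decompose(phen)
        names = phen.trait_names
        _write_matrix(out / "V_P.tsv", dec.v_p, names)
        _write_matrix(out / "W.tsv", dec.within, names)
        _write_matrix(out / "B.tsv", dec.between, names)

    with stage("fitness"):
        fitness = None
        if config.fitness_table is not None:
            counts = {sid: configs[0].k for sid, configs in ensembles.items()}
            fitness = parse_energy_table(
                config.fitness_table,
                residue_counts=counts,
                negate_energy=config.negate_energy,
            )
        explicit = None
        if config.target is not None and config.source is not None:
            explicit = (_parse_key(config.target), _parse_key(config.source))
        elif fitness is None:
            raise ValueError(
                "either a fitness table or explicit target and source are required"
            )
        if explicit is not None:
            target, source = explicit
        else:
            target, source = select_extremes(fitness, column=config.fitness_column)
        manifest["target"] = f"{target[0]}:{target[1]}"
        manifest["source"] = f"{source[0]}:{source[1]}"

    with stage("realized_response"):
        delta_z = realized_response(phen.row(*target), phen.row(*source))
        _write_vector(out / "delta_z.tsv", delta_z, names, "delta_z")

    with stage("selection_analysis"):
        ref = config.reference_structure or source[0]
        labels = hmap.residue_labels(ref)
        if np.allclose(delta_z, 0.0):
            # Identical target and source: zero response, zero gradients.
            zeros = np.zeros_like(delta_z)
            empty = pd.DataFrame()
            genetic = SelectionAnalysis(
                "G", delta_z, zeros, float("nan"), float("nan"), float("nan"),
                np.zeros(len(labels)), empty, empty,
            )
            dynamic = SelectionAnalysis(
                "M", delta_z, zeros, float("nan"), float("nan"), float("nan"),
                np.zeros(len(labels)), empty, empty,
            )
        else:
            genetic = analyze_selection(
                dec.between, delta_z, "G",
                variance_fraction=config.variance_fraction,
                rank_tolerance=config.rank_tolerance,
                top=config.top_residues, labels=labels,
            )
            dynamic = analyze_selection(
                dec.within, delta_z, "M",
                variance_fraction=config.variance_fraction,
                rank_tolerance=config.rank_tolerance,
                top=config.top_residues, labels=labels,
            )
        for analysis, tag in ((genetic, "G"), (dynamic, "M")):
            _write_vector(out / f"beta_{tag}.tsv", analysis.beta, names, "beta")
            pd.DataFrame(
                {
                    "residue_index": [lab[0] for lab in labels],
                    "residue_name": [lab[1] for lab in labels],
                    "magnitude": analysis.per_residue,
                }
            ).to_csv(out / f"per_residue_{tag}.tsv", sep="\t", index=False)
            if len(analysis.directional):
                analysis.directional.to_csv(
                    out / f"directional_{tag}.tsv", sep="\t", index=False
                )
                analysis.purifying.to_csv(
                    out / f"purifying_{tag}.tsv", sep="\t", index=False
                )
        pd.DataFrame(
            [
                {
                    "matrix": a.matrix_used,
                    "theta_dz_beta_deg": a.theta_dz_beta,
                    "theta_dz_subspace_deg": a.theta_dz_subspace,
                    "theta_beta_subspace_deg": a.theta_beta_subspace,
                }
                for a in (genetic, dynamic)
            ]
        ).to_csv(out / "angles.tsv", sep="\t", index=False)

    with stage("render"):
        source_path = config.ensembles[source[0]]
        values = {
            key: val
            for key, val in zip(
                (col[source[0]] for col in hmap.columns), genetic.per_residue
            )
        }
        write_gradient_pdb(source_path, values, out / "gradient_source.pdb")

    with stage("manifest"):
        manifest["warnings"] = collected
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    return PipelineResult(
        phenotypes=phen,
        decomposition=dec,
        fitness=fitness,
        target=target,
        source=source,
        delta_z=delta_z,
        genetic=genetic,
        dynamic=dynamic,
        ambassadors=ambassadors,
        manifest=manifest,
    )


def write_gradient_pdb(
    source_path: str | Path,
    values: dict[tuple[str, int, str], float],
    out_path: str | Path,
    model: int = 1,
) -> None:
    """Write a copy of a structure with gradient magnitudes as B-factors.

    Homologous residues (keys of ``values``: (chain, residue number,
    insertion code)) receive ``100 * value`` in the B-factor column;
    every other residue gets the sentinel ``-1.00`` so viewers can color
    the non-homologous class separately.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(source_path))
    atoms = pdb.get_structure(model=model, altloc="occupancy")
    icodes = (
        atoms.ins_code
        if "ins_code" in atoms.get_annotation_categories()
        else np.array([""] * atoms.array_length())
    )
    keys_seen = set()
    b_factor = np.full(atoms.array_length(), -1.0)
    for i in range(atoms.array_length()):
        key = (str(atoms.chain_id[i]), int(atoms.res_id[i]), str(icodes[i]).strip())
        if key in values:
            b_factor[i] = 100.0 * float(values[key])
            keys_seen.add(key)
    missing = set(values) - keys_seen
    if missing:
        raise ValueError(
            f"residues absent from {source_path}: {sorted(missing)[:5]}"
        )
    atoms.set_annotation("b_factor", b_factor)
    out = PDBFile()
    out.set_structure(atoms)
    out.write(str(out_path))
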