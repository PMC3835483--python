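"""End-to-end orchestration of the full analysis.

One call runs, per ensemble: internal-coordinate measurement for each
requested kind, the eigenvalue-weighted PCA ranking, the cross-ensemble
top-set overlap, mass-weighted mean/representative structures, and a
surface-potential map on each representative — writing plain-text
outputs (TSV/JSON/PDB/XYZ) plus a machine-readable manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .errors import InputError
from .esp_map import compute_surface_esp, default_polar_atoms
from .internal_coords import MolecularGraph, enumerate_features, measure
from .io import Ensemble, read_charges, read_pdb_ensemble, read_xyz_ensemble, \
    write_pdb, write_xyz
from .pca_rank import compare, rank_matrix
from .structures import mean_structure
from .synthetic_data import cholesterol_fixture, generate_charges

__all__ = ["RunConfig", "run", "load_config"]

log = logging.getLogger("icpca")

KINDS = ("bond", "angle", "dihedral")


@dataclasses.dataclass
class RunConfig:
    """Flat run configuration; every field maps 1:1 onto a CLI flag."""

    ensembles: dict[str, str]                  # name -> path (.xyz or .pdb)
    output_dir: str = "icpca_out"
    graph: str = "cholesterol"                 # "cholesterol" or bond-list path
    graph_elements: str | None = None          # needed with a bond-list file
    kinds: tuple[str, ...] = KINDS
    variance_threshold: float = 0.90
    top_fraction: float = 0.10
    reference_frame: int = 0
    charges: str | None = None                 # PQR path; None -> fixture-like
    polar_atoms: tuple[int, ...] | None = None # 1-based user indices
    eps_polar: float = 32.6
    eps_core: float = 2.02
    radius_scale: float = 1.1
    surface_density: float = 5.0
    clamp: float = 5.0
    temperature: float = 300.0
    esp: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ensembles:
            raise InputError("at least one ensemble is required")
        if not 0.0 < self.variance_threshold <= 1.0:
            raise InputError("variance threshold must be in (0, 1]")
        if not 0.0 < self.top_fraction <= 1.0:
            raise InputError("top fraction must be in (0, 1]")
        bad = [k for k in self.kinds if k not in KINDS]
        if bad:
            raise InputError(f"unknown feature kind(s): {bad}")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key-value YAML config file."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise InputError(f"{path}: config must be a flat mapping")
    if "kinds" in data and isinstance(data["kinds"], list):
        data["kinds"] = tuple(data["kinds"])
    if "polar_atoms" in data and isinstance(data["polar_atoms"], list):
        data["polar_atoms"] = tuple(data["polar_atoms"])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise InputError(f"{path}: {exc}") from exc


def _load_graph(config: RunConfig) -> MolecularGraph:
    if config.graph == "cholesterol":
        return cholesterol_fixture()
    if config.graph_elements is None:
        raise InputError("a bond-list graph needs graph_elements (one symbol per atom)")
    elements = config.graph_elements.split()
    return MolecularGraph.from_bond_list_file(config.graph, elements)


def _load_ensemble(path: str) -> Ensemble:
    p = Path(path)
    if not p.exists():
        raise InputError(f"ensemble file not found: {p}")
    if p.suffix.lower() == ".pdb":
        return read_pdb_ensemble(p)
    return read_xyz_ensemble(p)


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dict.

    Any stage failure propagates with the stage recorded in the log; the
    manifest is written only on success, so partial output directories
    are recognizable by its absence.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "outputs": [],
    }

    def record(path: Path) -> None:
        manifest["outputs"].append(str(path.relative_to(outdir)))

    try:
        log.info("stage graph: loading connectivity (%s)", config.graph)
        graph = _load_graph(config)
        featuresets = {k: enumerate_features(graph, k) for k in config.kinds}
        for k, fs in featuresets.items():
            log.info("stage enumerate: %d %s features", len(fs), k)
            p = outdir / f"features_{k}.tsv"
            fs.to_tsv(p)
            record(p)

        rankings: dict[str, dict] = {k: {} for k in config.kinds}
        ensembles: dict[str, Ensemble] = {}
        for name, path in config.ensembles.items():
            log.info("stage read: ensemble %s from %s", name, path)
            ens = _load_ensemble(path)
            if ens.n_atoms != graph.n_atoms:
                raise InputError(
                    f"ensemble {name} has {ens.n_atoms} atoms, graph has {graph.n_atoms}"
                )
            ensembles[name] = ens
            for k in config.kinds:
                log.info("stage measure+rank: %s / %s", name, k)
                fm = measure(ens, featuresets[k])
                ranking = rank_matrix(fm, config.variance_threshold,
                                      config.top_fraction, name=name)
                rankings[k][name] = ranking
                p = outdir / f"ranking_{name}_{k}.tsv"
                ranking.to_tsv(p)
                record(p)

        for k in config.kinds:
            if len(rankings[k]) < 2:
                continue
            log.info("stage compare: %s across %d ensembles", k, len(rankings[k]))
            report = compare(list(rankings[k].values()))
            p = outdir / f"overlap_{k}.tsv"
            report.to_tsv(p)
            record(p)
            p = outdir / f"overlap_{k}.json"
            report.to_json(p)
            record(p)

        for name, ens in ensembles.items():
            log.info("stage meanstruct: %s (reference frame %d)",
                     name, config.reference_frame)
            summary = mean_structure(ens, reference=config.reference_frame)
            for stem, structure in (("mean", summary.mean),
                                    ("representative",
                                     ens.frame(summary.representative_frame))):
                for ext, writer in ((".pdb", write_pdb), (".xyz", write_xyz)):
                    p = outdir / f"{stem}_{name}{ext}"
                    writer(structure, p)
                    record(p)
            p = outdir / f"rmsd_{name}.tsv"
            lines = ["frame\trmsd_angstrom"] + [
                f"{i}\t{r:.6f}" for i, r in enumerate(summary.rmsd_to_mean)]
            p.write_text("\n".join(lines) + "\n")
            record(p)
            manifest.setdefault("representative_frames", {})[name] = \
                summary.representative_frame

            if config.esp:
                log.info("stage esp: %s", name)
                if config.charges is not None:
                    charges = read_charges(config.charges, n_atoms=ens.n_atoms)
                else:
                    charges = generate_charges(graph, "fixture-like",
                                               seed=config.seed)
                if config.polar_atoms is not None:
                    polar = [i - 1 for i in config.polar_atoms]
                else:
                    polar = default_polar_atoms(graph)
                esp = compute_surface_esp(
                    ens.frame(summary.representative_frame), graph, charges,
                    polar, eps_polar=config.eps_polar,
                    eps_core=config.eps_core, scale=config.radius_scale,
                    density=config.surface_density,
                    temperature=config.temperature, clamp=config.clamp)
                p = outdir / f"esp_{name}.tsv"
                esp.to_tsv(p)
                record(p)
                p = outdir / f"esp_{name}.pdb"
                esp.to_pdb(p)
                record(p)
    except Exception:
        log.exception("pipeline aborted")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
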