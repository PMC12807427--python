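"""Full-analysis pipeline: RMSD -> PCA + cross-projection -> contacts ->
contact PCA -> optional reweighted free-energy surface.

One validated config drives the whole run.  One system (typically the apo
receptor) defines the PCA essential subspace; every system is cross-projected
onto it.  Native contacts come from the reference structure; contact PCA runs
per system on the native-contact distance series.  When per-frame boost
energies are supplied for a system, a reweighted free-energy surface over its
(PC1, PC2) projections is written as well.  Outputs are plain CSV/PDB files
registered in a manifest whose hash is reproducible for a fixed config and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import amd, conpca, contacts, pca, structure

logger = logging.getLogger("ythdyn.pipeline")

__all__ = ["RunConfig", "SystemConfig", "ReportBundle", "PipelineError",
           "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


class SystemConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    trajectories: list[str] = Field(min_length=1)
    energy_log: str | None = None   # CSV with frame,V_tot,V_dih,deltaV_tot,deltaV_dih


class ReferenceConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    path: str
    model_index: int = 1


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    reference: ReferenceConfig
    systems: dict[str, SystemConfig]
    pca_system: str
    selection: str = "name CA and protein"
    cutoff: float = 6.0
    ligand_nucleotide: int = 3
    reweight_method: str = "exponential"
    maclaurin_order: int = 10
    temperature: float = 300.0
    frame_spacing: float = 1.0
    output_dir: str = "ythdyn_out"
    seed: int = 0
    log_level: str = "INFO"

    @field_validator("cutoff", "temperature", "frame_spacing")
    @classmethod
    def _positive(cls, v: float, info) -> float:
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @field_validator("reweight_method")
    @classmethod
    def _known_method(cls, v: str) -> str:
        if v not in ("exponential", "maclaurin"):
            raise ValueError("reweight_method must be 'exponential' or 'maclaurin'")
        return v

    @field_validator("systems")
    @classmethod
    def _nonempty(cls, v):
        if not v:
            raise ValueError("at least one system is required")
        return v

    def check_paths(self) -> None:
        if self.pca_system not in self.systems:
            raise ValueError(
                f"pca_system {self.pca_system!r} is not a configured system"
            )
        if not os.path.exists(self.reference.path):
            raise ValueError(f"reference.path does not exist: {self.reference.path}")
        for label, sys_cfg in self.systems.items():
            for p in sys_cfg.trajectories:
                if not os.path.exists(p):
                    raise ValueError(
                        f"systems.{label}.trajectories: missing file {p}"
                    )
            if sys_cfg.energy_log and not os.path.exists(sys_cfg.energy_log):
                raise ValueError(
                    f"systems.{label}.energy_log: missing file {sys_cfg.energy_log}"
                )


def validate_config(path: str | os.PathLike) -> RunConfig:
    """Load and validate a YAML or JSON pipeline config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    cfg = RunConfig(**raw)
    cfg.check_paths()
    return cfg


@dataclass
class ReportBundle:
    """Manifest, registered output files, and the run log path."""

    manifest: dict
    files: dict[str, str] = field(default_factory=dict)
    log_path: str = ""

    @property
    def manifest_hash(self) -> str:
        return self.manifest["config_hash"]


def _config_hash(cfg: RunConfig) -> str:
    canon = json.dumps(cfg.model_dump(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _load_trajectory(path: str, template: structure.Structure,
                     frame_spacing: float, replica_id: int) -> structure.Trajectory:
    if path.endswith(".pdb"):
        import biotite.structure.io.pdb as pdb

        pdb_file = pdb.PDBFile.read(path)
        frames = pdb_file.get_coord()
        return structure.Trajectory(frames, template, frame_spacing=frame_spacing,
                                    replica_id=replica_id)
    return structure.read_trajectory_table(path, template,
                                           frame_spacing=frame_spacing,
                                           replica_id=replica_id)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every analysis stage and return the report bundle."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())

    files: dict[str, str] = {}

    def register(key: str, path: Path) -> None:
        files[key] = str(path)

    def save_csv(df: pd.DataFrame, key: str, name: str) -> None:
        path = out_dir / name
        df.to_csv(path, index=False, float_format="%.6f")
        register(key, path)

    thermo = amd.ThermoState(config.temperature)
    stage = "setup"
    try:
        logger.info("=== stage: setup (seed=%d) ===", config.seed)
        config.check_paths()
        reference = structure.read_pdb(config.reference.path,
                                       config.reference.model_index)
        sel = structure.select(reference, config.selection)
        systems: dict[str, list[structure.Trajectory]] = {}
        for label, sys_cfg in config.systems.items():
            systems[label] = [
                _load_trajectory(p, reference, config.frame_spacing, i)
                for i, p in enumerate(sys_cfg.trajectories)
            ]
            logger.info("system %s: %d replicas, %d frames each", label,
                        len(systems[label]), systems[label][0].n_frames)

        stage = "rmsd"
        logger.info("=== stage: rmsd (selection=%r) ===", config.selection)
        for label, trajs in systems.items():
            series = [structure.rmsd_series(t, reference, sel) for t in trajs]
            for t, s in zip(trajs, series):
                save_csv(
                    pd.DataFrame({"frame_index": np.arange(len(s)),
                                  "time": t.times, "rmsd_A": s}),
                    f"rmsd/{label}/replica{t.replica_id}",
                    f"rmsd_{label}_rep{t.replica_id}.csv",
                )
            summary = structure.replica_summary(series,
                                                allow_single=len(series) == 1)
            save_csv(
                pd.DataFrame({"frame_index": np.arange(len(summary.mean)),
                              "rmsd_mean_A": summary.mean,
                              "rmsd_std_A": summary.std}),
                f"rmsd/{label}/summary", f"rmsd_{label}_summary.csv",
            )

        stage = "pca"
        logger.info("=== stage: pca (defining system=%s) ===", config.pca_system)
        cov = pca.build_covariance(systems[config.pca_system], sel, reference)
        modes = pca.eigendecompose(cov)
        fractions = [pca.contribution_fraction(modes, m)
                     for m in range(modes.n_modes)]
        save_csv(
            pd.DataFrame({"mode": np.arange(1, modes.n_modes + 1),
                          "eigenvalue_A2": modes.eigenvalues,
                          "contribution_fraction": fractions}),
            "pca/eigenvalues", "pca_eigenvalues.csv",
        )
        projections: dict[str, pca.ProjectionSet] = {}
        rows = []
        for label, trajs in systems.items():
            per_replica = [
                pca.project(t, modes, (0, 1), reference, source=label)
                for t in trajs
            ]
            values = np.concatenate([p.values for p in per_replica])
            projections[label] = pca.ProjectionSet(values, (0, 1), source=label)
            for t, p in zip(trajs, per_replica):
                for f in range(p.values.shape[0]):
                    rows.append((label, t.replica_id, f, p.values[f, 0],
                                 p.values[f, 1]))
        save_csv(
            pd.DataFrame(rows, columns=["system", "replica", "frame",
                                        "PC1_A", "PC2_A"]),
            "pca/projections", "pca_projections.csv",
        )
        defining = projections[config.pca_system]
        lo_f, hi_f = pca.extreme_conformations(defining, mode=0)
        all_frames = np.concatenate(
            [t.frames for t in systems[config.pca_system]]
        )
        extremes_path = out_dir / "pca_pc1_extremes.pdb"
        structure.write_pdb(reference, extremes_path,
                            np.stack([all_frames[lo_f], all_frames[hi_f]]))
        register("pca/extremes", extremes_path)
        arrows = pca.mode_arrows(modes, 0)
        save_csv(
            pd.DataFrame({
                "atom_index": sel.indices,
                "dx": arrows[:, 0], "dy": arrows[:, 1], "dz": arrows[:, 2],
            }),
            "pca/mode1_arrows", "pca_mode1_arrows.csv",
        )

        stage = "contacts"
        logger.info("=== stage: contacts (cutoff=%.1f A) ===", config.cutoff)
        native = contacts.native_contacts(reference, cutoff=config.cutoff)
        save_csv(
            pd.DataFrame(
                [(p.residue_key[0], p.residue_key[1], p.nucleotide_key[0],
                  p.nucleotide_key[1], p.native_min_distance)
                 for p in native.pairs],
                columns=["chain", "residue", "rna_chain", "nucleotide",
                         "native_distance_A"],
            ),
            "contacts/native", "native_contacts.csv",
        )
        nucleotide_keys = sorted(
            {r.key for r in reference.residues if r.molecule_class == "nucleotide"}
        )
        distance_series: dict[str, contacts.ContactDistanceSeries] = {}
        for label, trajs in systems.items():
            combined = structure.Trajectory(
                np.concatenate([t.frames for t in trajs]), reference,
                frame_spacing=config.frame_spacing,
            )
            distance_series[label] = contacts.min_distance_series(combined, native)
            count_rows = []
            for key in nucleotide_keys:
                cc = contacts.contact_count_series(
                    combined, key, cutoff=config.cutoff
                )
                count_rows.append((key[0], key[1], cc.mean, cc.std))
            save_csv(
                pd.DataFrame(count_rows, columns=["chain", "nucleotide",
                                                  "mean_contacts", "std_contacts"]),
                f"contacts/counts/{label}", f"contact_counts_{label}.csv",
            )

        stage = "conpca"
        logger.info("=== stage: conpca ===")
        ligand_pairs = [
            p for p in native.pairs
            if p.nucleotide_key[1] == config.ligand_nucleotide
        ]
        if ligand_pairs:
            ligand_set = contacts.ContactSet(ligand_pairs, cutoff=native.cutoff)
            for label, trajs in systems.items():
                combined = structure.Trajectory(
                    np.concatenate([t.frames for t in trajs]), reference,
                    frame_spacing=config.frame_spacing,
                )
                series = contacts.min_distance_series(combined, ligand_set)
                cmodes = conpca.conpca_modes(conpca.contact_covariance(series))
                ranked = conpca.rank_components(cmodes, 0)
                save_csv(
                    pd.DataFrame(
                        [(rank + 1, p.residue_key[1], p.nucleotide_key[1], c,
                          abs(c))
                         for rank, (p, c) in enumerate(ranked)],
                        columns=["rank", "residue", "nucleotide", "component",
                                 "abs_component"],
                    ),
                    f"conpca/{label}", f"conpca_components_{label}.csv",
                )
        else:
            logger.warning("no native contacts for nucleotide %d; conPCA skipped",
                           config.ligand_nucleotide)

        stage = "fes"
        for label, sys_cfg in config.systems.items():
            if not sys_cfg.energy_log:
                logger.warning("system %s: no energy log, FES skipped", label)
                continue
            logger.info("=== stage: fes (%s, %s) ===", label,
                        config.reweight_method)
            energies = pd.read_csv(sys_cfg.energy_log)
            delta_v = (energies["deltaV_tot"].to_numpy()
                       + energies.get("deltaV_dih", 0.0))
            weights = amd.reweight(np.asarray(delta_v), thermo,
                                   method=config.reweight_method,
                                   order=config.maclaurin_order)
            surf = amd.fes(projections[label].values, thermo, weights=weights,
                           bins=30)
            xc, yc = np.meshgrid(*surf.bin_centers, indexing="ij")
            save_csv(
                pd.DataFrame({"PC1_A": xc.ravel(), "PC2_A": yc.ravel(),
                              "G_kcal_mol": surf.free_energy.ravel()}),
                f"fes/{label}", f"fes_{label}.csv",
            )
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    manifest = {
        "config": config.model_dump(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "files": sorted(files),
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    register("manifest", manifest_path)
    return ReportBundle(manifest=manifest, files=files, log_path=str(log_path))
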