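"""End-to-end orchestration: maps -> restraints -> BD -> cluster -> score.

One structured configuration drives the whole association stage
sequence on synthetic bodies (or user-supplied PQR files), producing
trajectories, contact frames, pose clusters, hot-spot densities and
perturbation-rescoring tables, together with a manifest (config
snapshot, seeds, artifact checksums) sufficient to rerun any stage
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from rigidbd import bd_engine, pose_analysis
from rigidbd.bd_engine import BDParams, DiffusionModel, build_density_set, build_map_set
from rigidbd.gridmaps import make_frame
from rigidbd.io_formats import write_pqr, write_trajectory
from rigidbd.restraints import RestraintSet, boltzmann_invert
from rigidbd.synthetic_data import (
    ToyBodySpec,
    make_anchor_probe,
    make_toy_barrel,
    sample_anchored_z,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "default_config"]

_KNOWN_KEYS = {
    "seed", "outdir", "replicas", "duration_ns", "timestep_fs", "output_stride_ns",
    "temperature_K", "cutoff_A", "grid_spacing_A", "eps_scale", "energy_cap",
    "solvent_dielectric", "ionic_strength_M", "wall_radius_A", "wall_stiffness",
    "anchor_k", "anchor_z0", "contact_cutoff_A", "rmsd_cutoff_A",
    "score_dielectric", "score_cutoff_A", "d_trans", "d_rot",
    "barrel", "probe", "start_radius_A", "site_residue_id", "site_charge_shift",
}

_TOY_KEYS = {f.name for f in ToyBodySpec.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def default_config() -> dict:
    """A toy end-to-end configuration; every key is overridable.

    The physical defaults mirror the production protocol (1 A grids,
    34 A cutoff, 200 fs step, 0.2 ns stride, 310 K, LJ eps scale 0.3,
    3 A contacts, 10 A cluster cutoff); the geometry and durations are
    the desk-scale toy conditions.
    """
    return {
        "seed": 0,
        "outdir": "pipeline_out",
        "replicas": 20,
        "duration_ns": 50.0,
        "timestep_fs": 500.0,
        "output_stride_ns": 0.2,
        "temperature_K": 310.0,
        "cutoff_A": 34.0,
        "grid_spacing_A": 1.0,
        "eps_scale": 0.3,
        "energy_cap": 30.0,
        "solvent_dielectric": 78.0,
        "ionic_strength_M": 0.0,
        "wall_radius_A": 60.0,
        "wall_stiffness": 10.0,
        "anchor_k": 1.0,
        "anchor_z0": 17.5,
        "contact_cutoff_A": 3.0,
        "rmsd_cutoff_A": 10.0,
        "score_dielectric": 78.0,
        "score_cutoff_A": 12.0,
        "d_trans": 50.0,
        "d_rot": 5.0,
        "barrel": {"kind": "barrel", "patch_charge": 10.0, "patch_center_deg": 0.0},
        "probe": {"kind": "anchor-probe", "probe_charge": -8.0},
        "start_radius_A": 40.0,
        "site_residue_id": 215,
        "site_charge_shift": -2.0,
    }


@dataclass
class PipelineConfig:
    """Validated configuration; unknown keys are rejected."""

    values: dict

    def __post_init__(self) -> None:
        unknown = set(self.values) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for toy_key in ("barrel", "probe"):
            extra = set(self.values.get(toy_key, {})) - _TOY_KEYS
            if extra:
                raise ValueError(f"unknown {toy_key} keys: {sorted(extra)}")
        merged = default_config()
        for k, v in self.values.items():
            if isinstance(v, dict):
                merged[k] = {**merged[k], **v}
            else:
                merged[k] = v
        self.values = merged

    def __getitem__(self, key):
        return self.values[key]


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run."""

    config: dict
    seed: int
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_seconds: dict[str, float] = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    version: str = "0.1.0"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict | PipelineConfig, quiet: bool = True) -> RunManifest:
    """Run the full toy association pipeline and return its manifest.

    Stages: build toy bodies, deposit mobile densities, build stationary
    maps, derive anchor restraints by Boltzmann inversion of synthetic
    z-samples, propagate replicas, detect contact frames, cluster poses,
    score representatives, estimate the anchor hot-spot density, and
    rescore clusters after the configured site charge perturbation.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(dict(config))
    cfg = config.values
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=cfg["seed"])
    log = (lambda *_: None) if quiet else print

    def stage(name):
        t0 = time.perf_counter()

        def done():
            manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
            log(f"[{name}] {manifest.stage_seconds[name]:.1f}s")
        return done

    # --- bodies -----------------------------------------------------------
    done = stage("bodies")
    barrel_spec = ToyBodySpec(**{**cfg["barrel"], "seed": cfg["seed"],
                                 "site_residue_id": cfg["site_residue_id"]})
    probe_spec = ToyBodySpec(**{**cfg["probe"], "seed": cfg["seed"]})
    barrel = make_toy_barrel(barrel_spec)
    probe, anchors = make_anchor_probe(probe_spec)
    write_pqr(barrel, outdir / "barrel.pqr")
    write_pqr(probe, outdir / "probe.pqr")
    done()

    # --- force field ------------------------------------------------------
    done = stage("maps")
    spacing = cfg["grid_spacing_A"]
    extent = cfg["wall_radius_A"] + cfg["cutoff_A"] / 2.0
    n = int(2 * extent / spacing) + 1
    frame = make_frame(origin=(-extent, -extent, -extent), spacing=spacing,
                       shape=(n, n, n))
    maps = build_map_set(barrel, frame,
                         solvent_dielectric=cfg["solvent_dielectric"],
                         ionic_strength=cfg["ionic_strength_M"],
                         cutoff=cfg["cutoff_A"], cap=cfg["energy_cap"],
                         eps_scale=cfg["eps_scale"])
    density = build_density_set(probe, spacing=spacing)
    done()

    # --- restraints -------------------------------------------------------
    done = stage("restraints")
    body = pose_analysis.body_frame_coords(probe)
    anchor_map = {}
    for i, (label, idx) in enumerate(anchors.items()):
        samples = sample_anchored_z(cfg["anchor_k"],
                                    cfg["anchor_z0"] + body[idx][2], 20000,
                                    cfg["temperature_K"], seed=cfg["seed"] * 101 + i,
                                    residue_label=label)
        anchor_map[label] = (body[idx], boltzmann_invert(samples))
    restraints = RestraintSet(anchors=anchor_map,
                              wall_radius=cfg["wall_radius_A"],
                              wall_stiffness=cfg["wall_stiffness"])
    done()

    # --- propagation ------------------------------------------------------
    done = stage("bd")
    model = DiffusionModel(d_trans=cfg["d_trans"], d_rot=cfg["d_rot"],
                           temperature=cfg["temperature_K"])
    params = BDParams(duration=cfg["duration_ns"], timestep=cfg["timestep_fs"],
                      cutoff=cfg["cutoff_A"], output_stride=cfg["output_stride_ns"],
                      seed=cfg["seed"], temperature=cfg["temperature_K"])
    rng = np.random.default_rng(cfg["seed"])
    poses0 = []
    for _ in range(cfg["replicas"]):
        theta = rng.uniform(0, 2 * np.pi)
        poses0.append((np.array([cfg["start_radius_A"] * np.cos(theta),
                                 cfg["start_radius_A"] * np.sin(theta),
                                 cfg["anchor_z0"]]),
                       np.array([1.0, 0.0, 0.0, 0.0])))
    trajs = bd_engine.run_bd(density, maps, restraints, model, params, poses0,
                             mobile_label="probe", stationary_label="barrel")
    traj_paths = []
    for r, traj in enumerate(trajs):
        p = outdir / f"replica_{r:03d}.traj"
        write_trajectory(traj, p)
        traj_paths.append(p)
    done()

    # --- analysis ---------------------------------------------------------
    done = stage("analysis")
    all_coords = []
    all_frames = []
    offset = 0
    cat = np.concatenate
    merged_positions = []
    merged_quats = []
    merged_times = []
    t_shift = 0.0
    for traj in trajs:
        merged_times.append(traj.times + t_shift)
        t_shift = merged_times[-1][-1] + cfg["output_stride_ns"]
        merged_positions.append(traj.positions)
        merged_quats.append(traj.quaternions)
    from rigidbd.io_formats import Trajectory
    merged = Trajectory(times=cat(merged_times), positions=cat(merged_positions),
                        quaternions=cat(merged_quats),
                        mobile_label="probe", stationary_label="barrel")
    contact = pose_analysis.contact_frames(merged, probe, barrel,
                                           cutoff=cfg["contact_cutoff_A"])
    results: dict = {"n_frames": len(merged), "n_contact_frames": int(contact.size)}
    clusters = []
    if contact.size:
        coords = np.stack([pose_analysis.frame_coordinates(merged, probe, f)
                           for f in contact])
        clusters = pose_analysis.cluster_poses(coords, cfg["rmsd_cutoff_A"],
                                               frame_indices=contact)
        clusters = pose_analysis.score_clusters(clusters, merged, probe, barrel,
                                                dielectric=cfg["score_dielectric"],
                                                cutoff=cfg["score_cutoff_A"])
        results["clusters"] = [
            {"size": int(c.member_frames.size), "population": c.population,
             "representative": c.representative,
             "rep_energy_elec": c.rep_energy[0], "rep_energy_vdw": c.rep_energy[1]}
            for c in clusters
        ]
        if contact.size >= 10:
            hotspot = pose_analysis.hotspot_density(
                merged, probe, list(anchors.values()), frames=contact)
            results["hotspot_mode_xy"] = list(hotspot.mode())
        site_atoms = [a for a in barrel.atoms
                      if a.residue_id == cfg["site_residue_id"]]
        mod = {a.name: a.charge + cfg["site_charge_shift"] for a in site_atoms}
        ratios = pose_analysis.phospho_rescore(
            clusters, merged, probe, barrel, cfg["site_residue_id"], mod,
            dielectric=cfg["score_dielectric"], cutoff=cfg["score_cutoff_A"])
        results["rescore_ratios"] = {str(k): v for k, v in ratios.items()}
    manifest.results = results
    done()

    for p in [outdir / "barrel.pqr", outdir / "probe.pqr", *traj_paths]:
        manifest.artifacts[p.name] = _sha256(p)
    with open(outdir / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
    manifest.save(outdir / "manifest.json")
    return manifest
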