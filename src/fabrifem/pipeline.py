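"""End-to-end pipeline: volume -> fabric -> materials -> solve -> profiles.

The pipeline mirrors the study design it reproduces: a binarized
trabecular volume supplies per-element BV/TV and fabric; one of three
constitutive mappings builds element stiffness; the proximal-femur
surrogate is loaded with the tabulated muscle forces and rod-distributed
joint reaction for one gait configuration; mechanostat summaries and
path profiles are derived from the solved fields.  Runs are
deterministic given the seed and emit a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fem, io, postprocess as post, synthetic, tables
from .constitutive import Model, assign_materials
from .fabric import element_structure

log = logging.getLogger("fabrifem")


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run (units in key names)."""

    model: str = "anisotropic"            # anisotropic | iso_hetero | iso_homo
    load_config: str = "config1"          # config1 | config2
    seed: int = 0
    output_dir: str = "fabrifem_out"
    # synthetic volume (used when volume_path is None)
    volume_path: str | None = None
    voxel_size_um: float = 250.0
    volume_bvtv: float = 0.27
    correlation_lengths_um: tuple = (1400.0, 700.0, 700.0)
    # mesh (surrogate used when mesh_path is None)
    mesh_path: str | None = None
    femur_scale: float = 1.0
    target_edge_mm: float = 4.0
    # MIL parameters
    window_size_mm: float = 2.5
    n_directions: int = 32
    line_spacing_vox: float = 2.0
    # solver
    rod_stiffness_n_per_mm: float | None = None
    path_step_mm: float = 2.0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        if cfg.correlation_lengths_um is not None:
            cfg.correlation_lengths_um = tuple(cfg.correlation_lengths_um)
        return cfg

    def validate(self) -> None:
        Model(self.model)
        if self.load_config not in ("config1", "config2"):
            raise ValueError("load_config must be config1 or config2")
        for p in (self.volume_path, self.mesh_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _mesh_hash(mesh) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(mesh.nodes).tobytes())
    h.update(np.ascontiguousarray(mesh.tets).tobytes())
    return h.hexdigest()[:16]


def default_paths(mesh) -> dict:
    """Parametric stand-ins for the compressive/tensile band polylines.

    The compressive path runs from the superior head surface through the
    head centre toward the medial neck; the tensile path from the
    lateral shaft across the neck into the inferior head.
    """
    bb = mesh.bbox()
    return {
        "path1_compressive": np.array([[ -2.0, 14.0, 0.0], [10.0, -12.0, 0.0],
                                       [14.0, -24.0, 0.0]]),
        "path2_tensile": np.array([[30.0, -20.0, 0.0], [10.0, -6.0, 0.0],
                                   [-4.0, -10.0, 0.0]]),
    }


def build_inputs(config: PipelineConfig):
    """Volume + mesh per config (synthetic when no files are given)."""
    if config.mesh_path:
        mesh = io.read_inp(config.mesh_path)
    else:
        mesh = synthetic.femur_like_mesh(scale=config.femur_scale,
                                         target_edge_mm=config.target_edge_mm)
    if config.volume_path:
        vol = io.read_volume_raw(Path(config.volume_path))
    else:
        bb = mesh.bbox()
        margin = config.window_size_mm
        lo = bb[0] - margin
        extent = bb[1] - bb[0] + 2 * margin
        shape = np.ceil(extent / (config.voxel_size_um / 1000.0)).astype(int) + 1
        vol = synthetic.gaussian_field_volume(
            shape, config.correlation_lengths_um, config.volume_bvtv,
            seed=config.seed, voxel_size_um=config.voxel_size_um)
        vol.origin_mm = lo
    return vol, mesh


def run_pipeline(config: PipelineConfig, structures=None):
    """Execute all stages; returns (output_dir, manifest dict).

    ``structures`` may carry a precomputed fabric map (the expensive
    stage) so several models/configurations can share it.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "stages": {}, "versions": _versions()}
    stage = "inputs"
    try:
        t0 = time.time()
        vol, mesh = build_inputs(config)
        card, lc1, lc2, frost = tables.builtin_tables()
        load_case = lc1 if config.load_config == "config1" else lc2
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "volume_bvtv": vol.bvtv, "n_nodes": mesh.n_nodes,
            "n_elements": mesh.n_elements, "mesh_hash": _mesh_hash(mesh),
        }
        log.info("inputs: %d elements, volume BV/TV %.3f", mesh.n_elements, vol.bvtv)

        stage = "fabric"
        t0 = time.time()
        if structures is None:
            structures = element_structure(
                vol, mesh, window_size_mm=config.window_size_mm,
                n_directions=config.n_directions,
                line_spacing=config.line_spacing_vox)
        sdf = io.structures_to_frame(structures)
        sdf.to_csv(out / "element_structure.csv", index=False)
        n_deg = int(sdf.degenerate.sum())
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "mean_rho": float(sdf.rho_bvtv.mean()), "n_degenerate": n_deg,
        }
        log.info("fabric: mean rho %.3f, %d degenerate windows",
                 sdf.rho_bvtv.mean(), n_deg)

        stage = "materials"
        t0 = time.time()
        materials = assign_materials(mesh, structures, config.model, card)
        io.materials_to_frame(materials).to_csv(out / "materials.csv", index=False)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                     "model": config.model}

        stage = "solve"
        t0 = time.time()
        system = fem.build_system(mesh, materials, load_case,
                                  rod_stiffness=config.rod_stiffness_n_per_mm)
        result = fem.solve_static(system, mesh, materials)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3),
                                     "residual": result.residual}
        log.info("solve: residual %.2e", result.residual)

        stage = "post"
        t0 = time.time()
        cell = derive_cell_fields(result, materials, frost)
        io.write_vtk(mesh, out / "solution.vtk",
                     point_data={"displacement_mm": result.u[:mesh.n_nodes]},
                     cell_data={k: v for k, v in cell.items() if k != "frost_zone"})
        frame = cell_frame(cell)
        frame.insert(0, "element_id", np.arange(mesh.n_elements))
        frame.to_csv(out / "fields.csv", index=False)
        for name, poly in default_paths(mesh).items():
            profile = post.sample_path(mesh, {k: v for k, v in cell.items()
                                              if k != "frost_zone"},
                                       poly, step=config.path_step_mm)
            profile.data.to_csv(out / f"profile_{name}.csv", index=False)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
    except Exception as err:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out, manifest


def derive_cell_fields(result, materials, frost) -> dict:
    """Element-wise scalar summaries of the solved fields."""
    m = len(result.strain)
    major_stress = np.empty(m)
    major_strain = np.empty(m)
    vm = np.empty(m)
    W = np.empty(m)
    w = np.empty(m)
    for e in range(m):
        st = post.voigt_to_tensor(result.stress[e], engineering_shear=False)
        sn = post.voigt_to_tensor(result.strain[e], engineering_shear=True)
        major_stress[e], _ = post.principal_abs(st)
        major_strain[e], _ = post.principal_abs(sn)
        vm[e] = post.von_mises(st)
        rho = max(materials[e].rho, 1e-6)
        ed = post.strain_energy_density(result.stress[e], result.strain[e], rho)
        W[e], w[e] = ed.W, ed.w
    zones = post.frost_classify(np.maximum(w, 0.0), frost)
    return {
        "major_principal_stress_MPa": major_stress,
        "von_mises_MPa": vm,
        "major_principal_strain": major_strain,
        "W_MPa": W, "w_MPa": w,
        "frost_zone": zones,
    }


def cell_frame(cell: dict):
    import pandas as pd

    return pd.DataFrame(cell)


def _versions() -> dict:
    import numpy
    import scipy

    from . import __version__

    return {"fabrifem": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__}
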