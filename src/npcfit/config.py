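"""Pipeline configuration schema and seeded end-to-end orchestration.

A single JSON document configures every stage (phantom generation,
averaging, fitting, architectural analysis, co-expression).  One master
seed fans out to independent per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so stages are individually
reproducible without seed collisions.  Every run directory carries a
manifest with the configuration hash, package and library versions, the
derived stage seeds and stage timings; completed stages are skipped on
re-runs against the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .architecture import head_to_tail_graph, ring_geometry, ring_region_masks, rotational_register
from .averaging import align_particle, extract_asymmetric_units, iterative_average
from .density import transform_map
from .coexpression import module_pcc_density, normalize, order_by_clustering, pcc_matrix
from .density import WedgeDescriptor, symmetrize, write_map
from .experiments import PROTOMER_ACCEPT, Y_ACCEPT
from .fitting import count_copies, significant_placements
from .phantoms import (
    build_assembly,
    crnpc_spec,
    default_subunits,
    generate_particle_set,
    hsnpc_like_spec,
    inner_ring_spec,
    render_density,
    simulate_expression,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "ConfigError"]

STAGES = ("generate", "average", "fit", "analyze", "coexpr")
SPEC_FACTORIES = {"crnpc": crnpc_spec, "hsnpc_like": hsnpc_like_spec,
                  "inner_ring": inner_ring_spec}


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    architecture: str = "crnpc"
    voxel_size_nm: float = 3.0
    box_nm: float = 132.0
    resolution_nm: float = 6.0
    n_particles: int = 6
    snr: float | None = 1.0
    tilt_min: float = -60.0
    tilt_max: float = 60.0


class AveragingConfig(_Strict):
    enabled: bool = True
    n_iter: int = 2
    symmetry_order: int = 8
    angular_step_deg: float = 10.0
    max_shift_nm: float = 8.0
    unit_box: int = 0  # 0 = skip asymmetric-unit extraction


class FittingConfig(_Strict):
    enabled: bool = True
    hierarchy: list[str] = Field(default_factory=lambda: ["Y-complex", "IR-protomer"])
    angular_step_deg: float = 24.0
    alpha: float = 0.05
    trans_tol_nm: float = 6.0
    z_split_nm: float = 17.0
    # "particle": fit the symmetrized first particle (the census regime);
    # "average": fit the wedge-compensated average from the averaging stage
    target: str = "particle"


class AnalysisConfig(_Strict):
    enabled: bool = True
    contact_nm: float = 14.0


class CoexprConfig(_Strict):
    enabled: bool = False
    n_genes: int = 200
    n_samples: int = 300
    module_sizes: list[int] = Field(default_factory=lambda: [20, 20])
    within_module_corr: float = 0.8
    p_threshold: float = 0.01


class PipelineConfig(_Strict):
    seed: int = 0
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    averaging: AveragingConfig = Field(default_factory=AveragingConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    coexpr: CoexprConfig = Field(default_factory=CoexprConfig)


def load_config(source) -> PipelineConfig:
    """Validate a config dict / JSON file; errors name the offending key."""
    if isinstance(source, PipelineConfig):
        return source
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    try:
        return PipelineConfig.model_validate(source)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {s: int(c.generate_state(1)[0] % (2**31)) for s, c in zip(STAGES, children)}


def run_pipeline(config, outdir) -> Path:
    """Execute generate -> average -> fit -> analyze (-> coexpr).

    Re-running with the same config and output directory skips stages
    whose done-markers match the configuration hash, making partial runs
    resumable per stage.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    seeds = _stage_seeds(cfg.seed)
    manifest_path = outdir / "manifest.json"
    manifest = {
        "config": cfg.model_dump(),
        "config_hash": chash,
        "npcfit_version": __version__,
        "numpy_version": np.__version__,
        "stage_seeds": seeds,
        "timings_s": {},
    }
    log = (outdir / "run.log").open("a")

    def done(stage):
        marker = outdir / f".{stage}.done"
        return marker.exists() and marker.read_text().strip() == chash

    def mark(stage, dt):
        (outdir / f".{stage}.done").write_text(chash)
        manifest["timings_s"][stage] = round(dt, 2)
        manifest_path.write_text(json.dumps(manifest, indent=1))
        log.write(f"{stage}: {dt:.2f} s\n")
        log.flush()

    ph = cfg.phantom
    spec = SPEC_FACTORIES[ph.architecture]()
    subunits = default_subunits()
    truth, merged = build_assembly(spec, subunits)
    assembly = render_density(merged, ph.voxel_size_nm, ph.box_nm, ph.resolution_nm)
    wedge = WedgeDescriptor(ph.tilt_min, ph.tilt_max)

    # -- generate ---------------------------------------------------------
    t0 = time.perf_counter()
    particles, particle_truth = generate_particle_set(
        assembly, ph.n_particles, wedge, ph.snr, seed=seeds["generate"]
    )
    if not done("generate"):
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        particle_truth.to_csv(outdir / "particle_poses_true.tsv", sep="\t", index=False)
        write_map(assembly, outdir / "assembly.mrc")
        mark("generate", time.perf_counter() - t0)

    # -- average ----------------------------------------------------------
    average, state = None, None
    if cfg.averaging.enabled:
        t0 = time.perf_counter()
        av = cfg.averaging
        average, state = iterative_average(
            particles, n_iter=av.n_iter, symmetry_order=av.symmetry_order,
            angular_step=av.angular_step_deg, max_shift_nm=av.max_shift_nm,
        )
        if not done("average"):
            write_map(average, outdir / "average.mrc")
            pd.DataFrame(
                [[*p.euler_deg, *p.translation] for p in state.poses],
                columns=["alpha", "beta", "gamma", "tx", "ty", "tz"],
            ).to_csv(outdir / "particle_poses_aligned.tsv", sep="\t", index=False)
            if av.unit_box:
                units = extract_asymmetric_units(
                    particles, state.poses, av.symmetry_order, av.unit_box
                )
                (outdir / "n_asymmetric_units.txt").write_text(str(len(units)))
            mark("average", time.perf_counter() - t0)

    # -- fit --------------------------------------------------------------
    assignment = None
    if cfg.fitting.enabled:
        t0 = time.perf_counter()
        fc = cfg.fitting
        if fc.target == "average" and average is not None:
            target = average
        else:
            # symmetrize the first particle after aligning it upright
            p0 = particles[0]
            if state is not None:
                pose0 = state.poses[0]
            else:
                ref = symmetrize(assembly, spec.symmetry_order)
                pose0 = align_particle(p0, ref, angular_step=10.0)[0]
            upright = transform_map(p0.map, pose0.inverse())
            target = symmetrize(p0.map.with_values(upright.values), spec.symmetry_order)
        target.meta["resolution_nm"] = ph.resolution_nm
        masks = ring_region_masks(target, fc.z_split_nm)
        region_models = {"CR": "Y-complex", "NR": "Y-complex", "IR": "IR-protomer"}
        tables = []
        for region, label in region_models.items():
            if label not in fc.hierarchy:
                continue
            settings = Y_ACCEPT if label == "Y-complex" else PROTOMER_ACCEPT
            ring = target.with_values(target.values * (masks[region].values > 0))
            acc = significant_placements(
                subunits[label], ring, angular_step=fc.angular_step_deg,
                alpha=fc.alpha, resolution_nm=ph.resolution_nm, **settings,
            )
            acc.insert(0, "region", region)
            acc.insert(0, "model", label)
            tables.append(acc)
        assignment = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
        counts = count_copies(assignment, masks) if len(assignment) else None
        if not done("fit"):
            assignment.to_csv(outdir / "assignment.tsv", sep="\t", index=False)
            if counts is not None:
                counts.to_csv(outdir / "copy_counts.tsv", sep="\t")
            mark("fit", time.perf_counter() - t0)

    # -- analyze ----------------------------------------------------------
    if cfg.analysis.enabled and assignment is not None and not done("analyze"):
        t0 = time.perf_counter()
        out: dict = {"ring_geometry": ring_geometry(assembly)}
        ys = assignment[assignment["model"] == "Y-complex"]
        masks = ring_region_masks(assembly, cfg.fitting.z_split_nm)
        cr = ys[[masks["CR"].values[tuple(np.rint(assembly.physical_to_index(
            r[["tx", "ty", "tz"]].to_numpy(float))).astype(int))] > 0
            for _, r in ys.iterrows()]] if len(ys) else ys
        nr = ys[[masks["NR"].values[tuple(np.rint(assembly.physical_to_index(
            r[["tx", "ty", "tz"]].to_numpy(float))).astype(int))] > 0
            for _, r in ys.iterrows()]] if len(ys) else ys
        if len(cr) and len(nr):
            out["cr_nr_register"] = {
                k: v for k, v in rotational_register(cr, nr, spec.symmetry_order).items()
            }
        if len(ys):
            out["head_to_tail_edges"] = head_to_tail_graph(
                ys, subunits["Y-complex"], cfg.analysis.contact_nm
            )
        (outdir / "analysis.json").write_text(json.dumps(out, indent=1, default=float))
        mark("analyze", time.perf_counter() - t0)

    # -- coexpr -----------------------------------------------------------
    if cfg.coexpr.enabled and not done("coexpr"):
        t0 = time.perf_counter()
        ce = cfg.coexpr
        mat, labels = simulate_expression(
            ce.n_genes, ce.module_sizes, ce.n_samples,
            within_module_corr=ce.within_module_corr, seed=seeds["coexpr"],
        )
        norm = normalize(mat)
        corr = pcc_matrix(norm, ce.p_threshold)
        order = order_by_clustering(corr)
        sets = {m: list(labels.index[labels == m]) for m in labels.unique() if m}
        dens = module_pcc_density(corr, sets) if sets else {"within_medians": {}}
        mat.to_csv(outdir / "expression.tsv", sep="\t")
        corr.masked_pcc.to_csv(outdir / "pcc_masked.tsv", sep="\t")
        pd.Series(order, name="gene").to_csv(outdir / "gene_order.tsv", sep="\t", index=False)
        (outdir / "coexpr_summary.json").write_text(json.dumps(
            {"within_medians": dens["within_medians"]}, indent=1))
        mark("coexpr", time.perf_counter() - t0)

    log.close()
    return outdir
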