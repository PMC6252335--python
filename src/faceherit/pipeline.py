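"""End-to-end orchestration: simulate/ingest -> symmetrize -> adjust ->
landmark co-heritability -> segmentation -> modular heritability -> report.

Every stage reads its predecessor's artifacts from the output directory
and writes self-describing files (CSV/JSON/NPZ/PLY) plus an entry in the
run manifest, which carries the config hash and master seed.  All
randomness flows from the master seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    adjust_covariates,
    build_hierarchy,
    effective_tests,
    estimate_h2,
    flag_outliers,
    landmark_coheritability,
    latent_morphs,
    make_template,
    module_correlations,
    module_shape_space,
    modular_h2_with_significance,
    nmi,
    plsr_fit,
    read_cohort,
    read_template,
    simulate_cohort,
    subsample_stability,
    symmetrize,
    symmetrize_matrix,
    write_cohort,
    write_scalar_field,
    write_template,
)
from .io_shapes import ScalarField, load_matrix, save_matrix
from .segmentation import SegmentationHierarchy
from .synthetic import SimulationDesign

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "landmark", "segment", "modular", "report")


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Structured configuration for the whole pipeline."""

    output_dir: str = "results/run"
    cohort_dir: str | None = None  # None => synthetic mode
    template_dir: str | None = None
    design: dict = field(default_factory=dict)  # SimulationDesign overrides
    z_max: float = 2.0
    remove_scale: bool = True
    levels: int = 5
    pa_iters: int = 100
    n_perm: int = 9999
    fwer: float = 0.05
    seed: int = 0
    stability_sizes: list[int] = field(default_factory=list)
    stability_reps: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.fwer < 1:
            raise ValueError("fwer must be in (0, 1)")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate(self) -> None:
        for attr in ("cohort_dir", "template_dir"):
            val = getattr(self, attr)
            if val is not None and not Path(val).exists():
                raise PipelineError("validate", "missing_path", f"{attr}: {val}")
        if self.cohort_dir is not None and self.template_dir is None:
            raise PipelineError(
                "validate", "missing_path", "real-data mode needs template_dir"
            )

    def out(self, *parts: str) -> Path:
        p = Path(self.output_dir).joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p


def _substream(seed: int, *tags: int) -> int:
    return int(np.random.SeedSequence([seed, *tags]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig) -> dict:
    design = SimulationDesign(**{"seed": cfg.seed, **cfg.design})
    template = make_template(design.grid_shape)
    cohort = simulate_cohort(design, template)
    tdir = write_template(template, cfg.out("template"))
    cdir = write_cohort(cohort, cfg.out("cohort"), archive=True)
    logger.info("simulated %d pairs, K=%d", cohort.n_pairs, template.vertex_count)
    return {"template": str(tdir["mesh"].parent), "cohort": str(cdir)}


def stage_preprocess(cfg: PipelineConfig) -> dict:
    tdir = cfg.template_dir or cfg.out("template")
    cdir = cfg.cohort_dir or cfg.out("cohort")
    template = read_template(tdir)
    cohort = read_cohort(cdir, template)
    n = cohort.n_pairs
    fathers = cohort.father_array()
    offspring = cohort.offspring_array()

    # QC: symmetrize everything, z-score Procrustes distance to consensus
    decomp, aligned = symmetrize(
        np.concatenate([fathers, offspring]), template, remove_scale=cfg.remove_scale
    )
    flagged = flag_outliers(
        type(aligned)(
            coords=aligned.coords[: 2 * n],
            centroid_sizes=aligned.centroid_sizes[: 2 * n],
            consensus=aligned.consensus,
            scaling_removed=aligned.scaling_removed,
        ),
        z_max=cfg.z_max,
    )
    bad_pairs = np.flatnonzero(flagged[:n] | flagged[n : 2 * n])
    keep = np.setdiff1d(np.arange(n), bad_pairs)
    logger.info("QC flagged %d / %d pairs (z >= %.2g)", bad_pairs.size, n, cfg.z_max)
    if keep.size < 10:
        raise PipelineError("preprocess", "too_few_pairs", f"only {keep.size} pairs pass QC")
    if bad_pairs.size:
        decomp, aligned = symmetrize(
            np.concatenate([fathers[keep], offspring[keep]]),
            template,
            remove_scale=cfg.remove_scale,
        )
    m = keep.size
    sym_f, sym_o = decomp.symmetric[:m], decomp.symmetric[m:]

    off_ids = [cohort.offspring_ids[i] for i in keep]
    fat_ids = [cohort.pairing[o] for o in off_ids]
    adj_f = adjust_covariates(sym_f, cohort.covariate_matrix(fat_ids), cohort_tag="fathers")
    adj_o = adjust_covariates(sym_o, cohort.covariate_matrix(off_ids), cohort_tag="offspring")
    sex = cohort.covariates.loc[off_ids, "sex"].to_numpy().astype(str)

    path = cfg.out("preprocessed.npz")
    np.savez_compressed(
        path,
        fathers=adj_f.coords,
        offspring=adj_o.coords,
        offspring_sex=sex,
        offspring_ids=np.array(off_ids),
        father_ids=np.array(fat_ids),
        n_excluded=bad_pairs.size,
    )
    return {"preprocessed": str(path), "n_pairs": int(m), "n_excluded": int(bad_pairs.size)}


def stage_landmark(cfg: PipelineConfig) -> dict:
    tdir = cfg.template_dir or cfg.out("template")
    template = read_template(tdir)
    with np.load(cfg.out("preprocessed.npz")) as data:
        fathers, offspring = data["fathers"], data["offspring"]
        sex = data["offspring_sex"].astype(str)
    matrix = landmark_coheritability(fathers, offspring, progress=True)
    sym_matrix = symmetrize_matrix(matrix)
    mpath = save_matrix(sym_matrix.values, cfg.out("coheritability"), csv_export=True)
    outputs = {"matrix": str(mpath)}
    # per-cohort landmark heritability maps (matrix diagonal analogue)
    for tag, mask in (("sons", sex == "M"), ("daughters", sex == "F"), ("combined", slice(None))):
        sub_f, sub_o = fathers[mask], offspring[mask]
        if sub_f.shape[0] < 10:
            continue
        diag = np.diag(landmark_coheritability(sub_f, sub_o).values)
        paths = write_scalar_field(
            ScalarField(values=diag, name="h2"), template, cfg.out("maps", f"h2_{tag}")
        )
        outputs[f"h2_map_{tag}"] = str(paths["ply"])
    return outputs


def stage_segment(cfg: PipelineConfig) -> dict:
    values = load_matrix(cfg.out("coheritability.npz"))
    matrix = symmetrize_matrix(values)
    hierarchy = build_hierarchy(matrix, levels=cfg.levels, seed=_substream(cfg.seed, 2))
    jpath = cfg.out("hierarchy.json")
    hierarchy.to_json(jpath)
    labels = pd.DataFrame(
        {f"level_{lvl}": hierarchy.labels_at_level(lvl) for lvl in range(cfg.levels + 1)}
    )
    lpath = cfg.out("segment_labels.csv")
    labels.to_csv(lpath, index_label="landmark")
    # self-consistency NMI per level (1 by construction at level 0)
    nmis = {f"level_{lvl}": nmi(labels[f"level_{lvl}"], labels[f"level_{lvl}"]) for lvl in range(cfg.levels + 1)}
    cfg.out("segmentation_nmi.json").write_text(json.dumps(nmis))
    return {"hierarchy": str(jpath), "labels": str(lpath), "n_segments": hierarchy.segment_count}


def stage_modular(cfg: PipelineConfig) -> dict:
    hierarchy = SegmentationHierarchy.from_json(cfg.out("hierarchy.json"))
    with np.load(cfg.out("preprocessed.npz")) as data:
        fathers, offspring = data["fathers"], data["offspring"]
        sex = data["offspring_sex"].astype(str)
    n = fathers.shape[0]
    pooled = np.concatenate([fathers, offspring])
    strata = {"sons": np.flatnonzero(sex == "M"), "daughters": np.flatnonzero(sex == "F")}
    rows, spaces = [], []
    for sid in sorted(hierarchy.segments):
        idx = hierarchy.segments[sid]
        level = int(np.log2(sid))
        if idx.size < 2:
            logger.warning("segment %d undersized; skipped in modular analysis", sid)
            continue
        space = module_shape_space(
            pooled, idx, module_id=sid, pa_iters=cfg.pa_iters, seed=_substream(cfg.seed, 3, sid)
        )
        spaces.append(space)
        for c_idx, (cohort, rows_idx) in enumerate(strata.items()):
            if rows_idx.size < 10:
                continue
            res = modular_h2_with_significance(
                space,
                rows_idx,
                rows_idx + n,
                cohort=cohort,
                n_perm=cfg.n_perm,
                seed=_substream(cfg.seed, 4, sid, c_idx),
            )
            rows.append(
                {
                    "module_id": sid,
                    "level": level,
                    "cohort": cohort,
                    "n_pairs": res.n_pairs,
                    "retained_pcs": res.retained_pcs,
                    "ncomp": res.ncomp,
                    "h2": res.h2,
                    "r_squared": res.r_squared,
                    "mse": res.mse,
                    "p_value": res.p_value,
                }
            )
    results = pd.DataFrame(rows)
    corr = module_correlations(spaces)
    mt = effective_tests(corr, fwer=cfg.fwer)
    results["significant"] = results["p_value"] <= mt.alpha_adj
    rpath = cfg.out("modular_results.csv")
    results.to_csv(rpath, index=False)
    save_matrix(corr, cfg.out("module_correlations"))
    mt_payload = {
        "m_eff": mt.m_eff,
        "alpha_adj": mt.alpha_adj,
        "fwer": mt.fwer,
        "n_modules": corr.shape[0],
        "eigenvalues": mt.eigenvalues.tolist(),
    }
    cfg.out("multiple_testing.json").write_text(json.dumps(mt_payload))
    return {
        "results": str(rpath),
        "multiple_testing": str(cfg.out("multiple_testing.json")),
        "n_modules": corr.shape[0],
    }


def stage_report(cfg: PipelineConfig) -> dict:
    tdir = cfg.template_dir or cfg.out("template")
    template = read_template(tdir)
    hierarchy = SegmentationHierarchy.from_json(cfg.out("hierarchy.json"))
    results = pd.read_csv(cfg.out("modular_results.csv"))
    mt = json.loads(cfg.out("multiple_testing.json").read_text())
    with np.load(cfg.out("preprocessed.npz")) as data:
        fathers, offspring = data["fathers"], data["offspring"]
        sex = data["offspring_sex"].astype(str)
    n = fathers.shape[0]
    pooled = np.concatenate([fathers, offspring])

    # global-module latent morphs (first three latent pairs, sons)
    global_idx = hierarchy.segments[1]
    space = module_shape_space(
        pooled, global_idx, module_id=1, pa_iters=cfg.pa_iters, seed=_substream(cfg.seed, 3, 1)
    )
    sons = np.flatnonzero(sex == "M")
    outputs: dict = {}
    if sons.size >= 10:
        x = space.retained_scores[sons]
        y = space.retained_scores[sons + n]
        ncomp = min(3, space.retained, x.shape[0] - 1)
        model = plsr_fit(x, y, ncomp)
        for comp in range(model.n_components):
            morph = latent_morphs(space, model, comp, sd_multiplier=4.0, template=template)
            disp = np.zeros(template.vertex_count)
            disp[space.landmark_ids] = morph["normal_displacement"]
            paths = write_scalar_field(
                ScalarField(values=disp, name="normal_displacement"),
                template,
                cfg.out("morphs", f"global_latent_{comp}"),
            )
            outputs[f"morph_{comp}"] = str(paths["ply"])

    # subsample stability of the global module (pooled-sex cohort)
    sizes = cfg.stability_sizes or [max(10, n // 4), max(10, n // 2), n]
    curve = subsample_stability(
        space.retained_scores[:n],
        space.retained_scores[n:],
        sizes=sorted(set(min(s, n) for s in sizes)),
        reps=cfg.stability_reps,
        seed=_substream(cfg.seed, 5),
    )
    spath = cfg.out("stability_curve.csv")
    curve.to_csv(spath, index=False)
    outputs["stability"] = str(spath)

    summary = {
        "n_pairs": int(n),
        "n_modules": int(mt["n_modules"]),
        "m_eff": mt["m_eff"],
        "alpha_adj": mt["alpha_adj"],
        "n_significant": int(results["significant"].sum()),
        "max_h2": {
            cohort: float(sub["h2"].max())
            for cohort, sub in results.groupby("cohort")
        },
    }
    cfg.out("summary.json").write_text(json.dumps(summary, indent=2))
    outputs["summary"] = str(cfg.out("summary.json"))
    return outputs


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "landmark": stage_landmark,
    "segment": stage_segment,
    "modular": stage_modular,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the requested stages in order; returns and writes the manifest."""
    cfg.validate()
    if stages is None:
        stages = STAGES if cfg.cohort_dir is None else STAGES[1:]
    manifest = {"config_hash": cfg.config_hash, "seed": cfg.seed, "stages": {}}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise PipelineError(stage, "unknown_stage", f"no stage named {stage!r}")
        t0 = time.time()
        try:
            manifest["stages"][stage] = _STAGE_FUNCS[stage](cfg)
        except PipelineError:
            raise
        except Exception as exc:  # annotate with the failing stage
            raise PipelineError(stage, "stage_failed", str(exc)) from exc
        logger.info("stage %-10s done in %.1fs", stage, time.time() - t0)
    cfg.out("manifest.json").write_text(json.dumps(manifest, indent=2))
    cfg.to_yaml(cfg.out("config_used.yaml"))
    return manifest
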