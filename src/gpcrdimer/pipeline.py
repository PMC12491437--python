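"""Reproducible end-to-end runs tying the three analysis stages together.

A run is described by a JSON config naming the stages to execute and their
parameter blocks.  Each stage simulates its inputs (with ground truth),
runs the corresponding analysis, and writes its outputs under the run
directory; a ``report.json`` records paths, the parameter echo, the seed
and wall-clock time.

Seed management: the global seed is expanded through
``numpy.random.SeedSequence(seed).generate_state(3) % 2**31`` into one
child seed per stage (palm, poses, bret, in that order), so any stage can
be re-run in isolation with its logged child seed and reproduce its
outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bret import fit_dose_response, fit_kinetics, fit_saturation
from .palm import CensusConfig, run_census, stratify_by_density
from .poses import TopologyFilterConfig, cluster_poses, filter_poses
from .simulate import (
    BretSimConfig,
    PalmSimConfig,
    PoseSimConfig,
    simulate_bret,
    simulate_localizations,
    simulate_poses,
    synthetic_protomer,
)

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("palm", "poses", "bret")

__all__ = ["PipelineError", "validate_config", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _check_block(config: dict, block: str, builder, errors: list[str]) -> None:
    try:
        builder(config.get(block, {}))
    except (TypeError, ValueError, KeyError) as exc:
        errors.append(f"{block}: {exc}")


def validate_config(config: dict | str | Path) -> list[str]:
    """Schema-check a run config; returns every violation found (empty = ok)."""
    if not isinstance(config, dict):
        config = load_config(config)
    errors: list[str] = []
    stages = config.get("stages", list(KNOWN_STAGES))
    for stage in stages:
        if stage not in KNOWN_STAGES:
            errors.append(f"unknown stage {stage!r}; known stages: {KNOWN_STAGES}")
    seed = config.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")

    if "palm" in stages:
        palm = config.get("palm", {})
        _check_block(
            palm,
            "sim",
            lambda b: PalmSimConfig(
                counts_per_size={int(k): int(v) for k, v in b.get(
                    "counts_per_size", {"1": 50, "2": 30, "3": 15, "5": 5}
                ).items()},
                seed=0,
                **{k: v for k, v in b.items() if k != "counts_per_size"},
            ),
            errors,
        )
        _check_block(palm, "census", lambda b: CensusConfig(**b), errors)
    if "poses" in stages:
        poses = config.get("poses", {})
        _check_block(
            poses, "sim", lambda b: PoseSimConfig(
                n_poses=int(b.get("n_poses", 1000)),
                seed=0,
                **{k: tuple(v) if isinstance(v, list) else v
                   for k, v in b.items() if k != "n_poses"},
            ),
            errors,
        )
        _check_block(poses, "filter", lambda b: TopologyFilterConfig(**b), errors)
    if "bret" in stages:
        bret = config.get("bret", {})
        for mode in ("saturation", "kinetics", "dose_response"):
            if mode in bret:
                _check_block(
                    bret,
                    mode,
                    lambda b, m=mode: BretSimConfig(
                        mode=m,
                        grid=tuple(b.get("grid", _default_grid(m))),
                        seed=0,
                        **{k: v for k, v in b.items() if k != "grid"},
                    ),
                    errors,
                )
    return errors


def _default_grid(mode: str) -> tuple[float, ...]:
    if mode == "saturation":
        return tuple(np.geomspace(0.005, 0.5, 12))
    if mode == "kinetics":
        return tuple(np.arange(3.0, 303.0, 3.0))
    return tuple(np.geomspace(1e-9, 1e-3, 10))


def _child_seeds(seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(KNOWN_STAGES))
    return {stage: int(s % 2**31) for stage, s in zip(KNOWN_STAGES, state)}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _run_palm(block: dict, out: Path, seed: int) -> dict:
    sim_block = dict(block.get("sim", {}))
    counts = {
        int(k): int(v)
        for k, v in sim_block.pop("counts_per_size", {1: 50, 2: 30, 3: 15, 5: 5}).items()
    }
    sim_cfg = PalmSimConfig(counts_per_size=counts, seed=seed, **sim_block)
    census_cfg = CensusConfig(**block.get("census", {}))
    dedup = bool(block.get("dedup", sim_cfg.blink_rate > 0))
    logger.info(
        "palm: dedup_radius=%g nm search_radius=%g nm mode=%s density_threshold=%g/um2",
        census_cfg.dedup_radius_nm,
        census_cfg.search_radius_nm,
        census_cfg.assignment_mode,
        census_cfg.density_threshold_per_um2,
    )
    loc_map, truth = simulate_localizations(sim_cfg)
    result, assignment, retained = run_census(loc_map, census_cfg, dedup=dedup)

    loc_path = out / "localizations.csv"
    loc_map.to_csv(loc_path)
    census_path = out / "census.tsv"
    result.to_frame().to_csv(census_path, sep="\t", index=False)
    summary_path = out / "census_summary.json"
    summary = result.summary()
    summary["true_composition"] = {str(k): v for k, v in truth.composition.items()}
    summary["n_true_receptors"] = truth.n_true_receptors
    summary["dedup_applied"] = dedup
    summary_path.write_text(json.dumps(summary, indent=2))
    strat = stratify_by_density([result])
    strat_path = out / "density_strata.tsv"
    strat.to_csv(strat_path, sep="\t", index=False)
    return {
        "outputs": [str(loc_path), str(census_path), str(summary_path), str(strat_path)],
        "summary": summary,
    }


def _run_poses(block: dict, out: Path, seed: int) -> dict:
    sim_block = {
        k: tuple(v) if isinstance(v, list) else v for k, v in dict(block.get("sim", {})).items()
    }
    sim_cfg = PoseSimConfig(n_poses=int(sim_block.pop("n_poses", 1000)), seed=seed, **sim_block)
    filt_cfg = TopologyFilterConfig(**block.get("filter", {}))
    rmsd_cutoff = float(block.get("rmsd_cutoff_A", 3.0))
    logger.info(
        "poses: tilt_max=%g rad z_offset_max=%g A keep_best=%d rmsd_cutoff=%g A",
        filt_cfg.tilt_max_rad,
        filt_cfg.z_offset_max_A,
        filt_cfg.keep_best,
        rmsd_cutoff,
    )
    probe = synthetic_protomer()
    poses, truth = simulate_poses(sim_cfg, probe)
    accepted, metrics = filter_poses(poses, probe, filt_cfg)
    clusters = cluster_poses(accepted, probe, rmsd_cutoff)
    cluster_of = {
        pid: cid for cid, (_, members) in enumerate(clusters.clusters) for pid in members
    }
    metrics["cluster_id"] = metrics["pose_id"].map(lambda p: cluster_of.get(p, -1))
    metrics["is_center"] = metrics["pose_id"].isin(clusters.center_ids)
    table_path = out / "pose_topology.tsv"
    metrics.to_csv(table_path, sep="\t", index=False)
    summary = {
        "n_poses": len(poses),
        "n_accepted": len(accepted),
        "true_n_accept": int(truth.accept.sum()),
        "n_clusters": clusters.n_clusters,
        "tilt_max_rad": filt_cfg.tilt_max_rad,
        "z_offset_max_A": filt_cfg.z_offset_max_A,
        "rmsd_cutoff_A": rmsd_cutoff,
    }
    summary_path = out / "pose_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    return {"outputs": [str(table_path), str(summary_path)], "summary": summary}


def _run_bret(block: dict, out: Path, seed: int) -> dict:
    modes = [m for m in ("saturation", "kinetics", "dose_response") if m in block] or [
        "saturation",
        "kinetics",
        "dose_response",
    ]
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(modes)) % 2**31
    outputs, summary = [], {}
    for mode, sub_seed in zip(modes, sub_seeds):
        b = dict(block.get(mode, {}))
        grid = tuple(b.pop("grid", _default_grid(mode)))
        cfg = BretSimConfig(mode=mode, grid=grid, seed=int(sub_seed), **b)
        data = simulate_bret(cfg)
        data_path = out / f"bret_{mode}.tsv"
        data.to_csv(data_path, sep="\t", index=False)
        outputs.append(str(data_path))
        per_rep = []
        for rep, grp in data.groupby("replicate"):
            if mode == "saturation":
                fit = fit_saturation(grp["x"], grp["y"])
            elif mode == "kinetics":
                fit = fit_kinetics(grp["x"].to_numpy(), grp["y"].to_numpy())
            else:
                fit = fit_dose_response(grp["x"], grp["y"])
            per_rep.append({"replicate": int(rep), **fit.__dict__})
        fits = pd.DataFrame(per_rep)
        fit_path = out / f"bret_{mode}_fits.tsv"
        fits.to_csv(fit_path, sep="\t", index=False)
        outputs.append(str(fit_path))
        summary[mode] = {
            k: float(fits[k].mean())
            for k in fits.columns
            if k not in ("replicate", "converged") and np.issubdtype(fits[k].dtype, np.number)
        }
        summary[mode]["n_replicates"] = len(fits)
        summary[mode]["all_converged"] = bool(fits["converged"].all())
    summary_path = out / "bret_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    outputs.append(str(summary_path))
    return {"outputs": outputs, "summary": summary}


_STAGE_RUNNERS = {"palm": _run_palm, "poses": _run_poses, "bret": _run_bret}


def run_pipeline(config: dict | str | Path, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute the configured stages and write a run report.

    ``seed`` overrides the config's global seed.  Any stage failure aborts
    the run with the stage name and cause; outputs written so far are kept
    alongside a ``FAILED`` marker file.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid run config:\n" + "\n".join(f"  - {e}" for e in errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    stages = config.get("stages", list(KNOWN_STAGES))
    child = _child_seeds(seed)

    report: dict = {
        "seed": seed,
        "stage_seeds": {s: child[s] for s in stages},
        "config": config,
        "version": __version__,
        "stages": {},
    }
    t0 = time.monotonic()
    for stage in stages:
        logger.info("running stage %s (seed %d)", stage, child[stage])
        try:
            report["stages"][stage] = _STAGE_RUNNERS[stage](
                config.get(stage, {}), out, child[stage]
            )
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise PipelineError(stage, exc) from exc
    report["wall_clock_s"] = time.monotonic() - t0
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, default=str))
    report["report_path"] = str(report_path)
    return report
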