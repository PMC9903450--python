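"""End-to-end orchestration: curate -> fit -> evaluate -> importance -> forecast.

Every intermediate artifact is written to the output directory along with a
manifest recording the config digest and all seeds, so a run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from edstack.config import RunConfig
from edstack.curation import curate_dir, curate_frames
from edstack.evaluation import cross_validate, permutation_importance
from edstack.scenarios import SCENARIO_NAMES, ScenarioSpec, forecast_scenario
from edstack.stack import fit_stack, make_train_split
from edstack.synthetic import generate, write_frames

log = logging.getLogger("edstack.pipeline")


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage; returns the manifest path.

    Any stage failure is re-raised annotated with the stage name.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if cfg.input_dir is None:
            stage = "simulate"
            frames, truth = generate(cfg.generator)
            write_frames(frames, out / "inputs", truth)
            raw = frames
            projections = frames["projections"]
        else:
            stage = "ingest"
            from edstack.curation import read_input_dir

            raw = read_input_dir(cfg.input_dir)
            proj_path = Path(cfg.input_dir) / "projections.csv"
            if not proj_path.exists():
                raise FileNotFoundError(f"missing projections file: {proj_path}")
            projections = pd.read_csv(proj_path, dtype={"region_id": str})

        stage = "curate"
        panel, clog = curate_frames(
            raw["providers"], raw["contracts"], raw["contract_map"],
            raw["gp"], raw["regions"],
        )
        panel.to_csv(out / "panel.csv", index=False)
        clog.to_json(out / "curation_log.json")
        log.info("curated %d/%d records", clog.n_final_records,
                 clog.n_potential_records)

        stage = "fit"
        split = make_train_split(len(panel), seed=cfg.seed)
        model = fit_stack(panel, split, cfg.hp_capacity, cfg.hp_health, cfg.seed)
        model.save(str(out / "model.archive"))

        stage = "evaluate"
        report = cross_validate(
            panel, cfg.hp_capacity, cfg.hp_health,
            n_repeats=cfg.cv.repeats, n_folds=cfg.cv.folds, seed=cfg.seed,
        )
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))

        stage = "importance"
        imp = permutation_importance(
            panel, hp_capacity=cfg.hp_capacity, hp_health=cfg.hp_health,
            n_repeats=cfg.cv.repeats, n_folds=cfg.cv.folds, seed=cfg.seed,
        )
        (out / "importance.json").write_text(json.dumps(imp.to_dict(), indent=2))

        stage = "forecast"
        for name in SCENARIO_NAMES:
            spec = ScenarioSpec(
                name=name,
                uplift_fraction=cfg.scenario.uplift_fraction,
                ramp_step=cfg.scenario.ramp_step,
                horizon_years=cfg.scenario.horizon_years,
            )
            series = forecast_scenario(model, panel, projections, spec)
            series.to_frame().to_csv(out / f"forecast_{name}.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "config_digest": cfg.digest(),
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "curation": {
            "n_final_records": clog.n_final_records,
            "n_potential_records": clog.n_potential_records,
        },
        "evaluation": {"r2_mean": report.r2_mean, "r2_sd": report.r2_sd},
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
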