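"""End-to-end workflow: derive → fixture → plausible → select → simulate/sweep.

Each stage reads the artifacts of earlier stages from the output directory
and writes its own, so any prefix of the chain can be run and resumed.  A
provenance JSON (config hash, seeds, package/library versions, stage counts)
accompanies the artifacts; identical config + seeds reproduce identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import InterventionSpec
from .registry import (
    DEFAULT_CALIBRATION_INPUTS,
    default_parameters,
    load_registry,
    parameters_from_inputs,
    save_registry,
)
from .priors import (
    ParameterPrior,
    PlausibilityBox,
    mh_generate_plausible,
    population_to_frame,
)
from .selection import TargetDistribution, ar_select, fit_target, subselect_nafld
from .interventions import (
    cohort_response,
    diet_spec,
    load_intervention,
    pioglitazone_spec,
)
from .sensitivity import (
    default_activation_grid,
    default_inhibition_grid,
    sweep_activation,
    sweep_inhibition,
    sweeps_to_frame,
)
from .fixtures import FixtureConfig, write_fixture_cohort

__all__ = ["RunConfig", "STAGES", "run_pipeline"]

log = logging.getLogger("steatosim")

STAGES = ("derive", "fixture", "plausible", "select", "simulate", "sweep")


@dataclass
class RunConfig:
    """Structured configuration for the pipeline (YAML or JSON on disk)."""

    out_dir: str = "results"
    seed: int = 0
    # derive
    calibration_inputs: dict = field(default_factory=dict)  # overrides of defaults
    registry_path: str | None = None       # use an existing registry instead
    # fixture / target
    fixture_n: int = 2000
    cohort_csv: str | None = None          # user cohort table overriding the fixture
    # plausible
    n_plausible: int = 2000
    prior_fold: float = 4.0
    prior_mass: float = 0.90
    box_liver_fat: tuple = (0.5, 50.0)
    box_plasma_tg: tuple = (30.0, 600.0)
    # select
    threshold_pct: float = 5.0
    # simulate
    intervention: str = "pioglitazone"     # pioglitazone | diet | path to JSON
    # sweep
    sweep_points: int = 8
    sweep_weeks: float = 26.0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("registry_path", "cohort_csv"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {key} points to a missing file: {p}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _seeds(seed: int) -> dict:
    """Expand the run seed into named per-stage substreams (all < 2**31)."""
    names = ("fixture", "plausible", "select")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1, np.uint32)[0]) for n, c in zip(names, children)}


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}; run the "
            f"'{producing_stage}' stage first"
        )
    return path


def run_pipeline(config: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stages in order; returns artifact paths + counts.

    ``stages`` must be an ordered subset of the canonical chain; later stages
    consume earlier artifacts (from this run or a previous one in the same
    output directory).
    """
    order = {s: i for i, s in enumerate(STAGES)}
    stages = list(stages)
    if any(s not in order for s in stages):
        raise ValueError(f"unknown stage in {stages}; valid stages: {STAGES}")
    if [order[s] for s in stages] != sorted(order[s] for s in stages):
        raise ValueError(f"stages must respect the order {STAGES}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed)
    counts: dict = {}
    artifacts: dict = {}

    registry_path = out / "parameters.json"
    fixture_path = out / "fixture_cohort.csv"
    target_path = out / "target.json"
    plausible_path = out / "plausible.csv"
    vpop_path = out / "vpop.csv"
    nafld_path = out / "nafld.csv"

    for stage in stages:
        log.info("stage %s starting", stage)
        if stage == "derive":
            if config.registry_path:
                params = load_registry(config.registry_path)
            else:
                inputs = dict(DEFAULT_CALIBRATION_INPUTS, **config.calibration_inputs)
                params = parameters_from_inputs(inputs)
            save_registry(params, registry_path)
            artifacts["registry"] = str(registry_path)
            counts["parameters"] = len(params.as_dict())

        elif stage == "fixture":
            if config.cohort_csv:
                cohort = pd.read_csv(config.cohort_csv)
                cohort.to_csv(fixture_path, index=False)
            else:
                fc = FixtureConfig(n=config.fixture_n, seed=seeds["fixture"])
                cohort = write_fixture_cohort(fc, fixture_path)
            target = fit_target(cohort)
            target_path.write_text(json.dumps(target.to_dict(), indent=2) + "\n")
            artifacts["fixture"] = str(fixture_path)
            artifacts["target"] = str(target_path)
            counts["fixture_rows"] = len(cohort)

        elif stage == "plausible":
            _require(registry_path, "derive")
            params = load_registry(registry_path)
            from .registry import inputs_from_parameters

            prior = ParameterPrior.from_baseline(
                inputs_from_parameters(params),
                fold_hi=config.prior_fold, mass=config.prior_mass,
            )
            box = PlausibilityBox(
                liver_fat_pct=tuple(config.box_liver_fat),
                plasma_tg=tuple(config.box_plasma_tg),
            )
            patients = mh_generate_plausible(
                prior, box, n_target=config.n_plausible, seed=seeds["plausible"]
            )
            population_to_frame(patients).to_csv(plausible_path, index=False)
            artifacts["plausible"] = str(plausible_path)
            counts["plausible"] = len(patients)
            log.info("plausible patients: %d", len(patients))

        elif stage == "select":
            _require(plausible_path, "plausible")
            _require(target_path, "fixture")
            plausible = pd.read_csv(plausible_path)
            target = TargetDistribution.from_dict(json.loads(target_path.read_text()))
            vpop = ar_select(plausible, target, seed=seeds["select"])
            vpop.frame.to_csv(vpop_path, index=False)
            nafld = subselect_nafld(vpop, config.threshold_pct)
            nafld.to_csv(nafld_path, index=False)
            artifacts["vpop"] = str(vpop_path)
            artifacts["nafld"] = str(nafld_path)
            counts["selected"] = vpop.n_selected
            counts["nafld"] = len(nafld)
            log.info(
                "selected %d of %d plausible; NAFLD cohort %d",
                vpop.n_selected, len(plausible), len(nafld),
            )

        elif stage == "simulate":
            _require(nafld_path, "select")
            cohort = pd.read_csv(nafld_path)
            name = config.intervention
            if name == "pioglitazone":
                spec = pioglitazone_spec()
            elif name == "diet":
                spec = diet_spec()
            else:
                spec = load_intervention(_require(Path(name), "simulate"))
            resp = cohort_response(cohort, spec)
            resp_path = out / f"response_{Path(name).stem}.csv"
            resp.to_frame().to_csv(resp_path, index=False)
            summary_path = out / f"response_{Path(name).stem}_summary.json"
            summary_path.write_text(json.dumps(resp.summary(), indent=2) + "\n")
            artifacts["response"] = str(resp_path)
            counts["response_n"] = resp.n
            log.info("intervention %s: mean %.1f%% sd %.1f%%", name, resp.mean, resp.sd)

        elif stage == "sweep":
            _require(nafld_path, "select")
            cohort = pd.read_csv(nafld_path)
            duration = 7.0 * config.sweep_weeks
            results = [
                sweep_inhibition(
                    cohort, mech,
                    grid=default_inhibition_grid(config.sweep_points),
                    duration_days=duration,
                )
                for mech in ("nefa_uptake", "dnl", "esterification")
            ]
            results.append(sweep_activation(
                cohort, grid=default_activation_grid(config.sweep_points),
                duration_days=duration,
            ))
            sweep_path = out / "sweep.csv"
            sweeps_to_frame(results).to_csv(sweep_path, index=False)
            artifacts["sweep"] = str(sweep_path)
            counts["sweep_points"] = int(sum(len(r.grid) for r in results))

    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages_run": stages,
        "counts": counts,
        "versions": {
            "steatosim": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str) + "\n")
    artifacts["provenance"] = str(out / "provenance.json")
    return {"artifacts": artifacts, "counts": counts}
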