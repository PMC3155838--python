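"""Configuration schema and the end-to-end pipeline runner.

A pipeline run executes: build the competing-model set and design template
from a preset -> optimise the sampling times -> compute sampling windows ->
(optionally) run the simulation-estimation evaluation.  Every run writes the
fully resolved configuration next to its results so a report is
self-contained.  All randomness flows from the configured seeds.
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

from . import __version__
from .estimate import sim_est
from .fim import DesignConstraints, population_fim
from .io import write_json
from .presets import get_design_preset
from .search import SearchConfig, optimize
from .simulate import CohortSpec
from .windows import find_windows

log = logging.getLogger("popkdesign")

_KNOWN_KEYS = {
    "preset", "seed", "output_dir", "constraints", "search", "windows",
    "simest", "central_weight",
}
_CONSTRAINT_KEYS = {"min_spacing", "horizon", "t_min", "time_unit"}
_SEARCH_KEYS = {"grid_resolution", "coarse_factor", "n_multistart", "polish",
                "block_diagonal", "n_refine"}
_WINDOW_KEYS = {"floor", "n_mc", "percentile"}
_SIMEST_KEYS = {"enabled", "n_replicates", "estimate_tlag", "init_perturbation"}


@dataclass
class PipelineConfig:
    preset: str = "adult"
    seed: int = 0
    output_dir: str = None
    central_weight: float = 0.95
    constraints: dict = field(default_factory=dict)
    search: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    simest: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config key(s) {sorted(unknown)}")
        for sub, keys in (("constraints", _CONSTRAINT_KEYS), ("search", _SEARCH_KEYS),
                          ("windows", _WINDOW_KEYS), ("simest", _SIMEST_KEYS)):
            bad = set(d.get(sub, {})) - keys
            if bad:
                raise ValueError(f"unknown {sub} key(s) {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)

    def resolved(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def _constraints_from(cfg: dict) -> DesignConstraints:
    cfg = dict(cfg)
    unit = cfg.pop("time_unit", "hours")
    factor = 1.0 / 60.0 if unit == "minutes" else 1.0
    kw = {k: v * factor for k, v in cfg.items() if k in ("min_spacing", "horizon", "t_min")}
    return DesignConstraints(**kw) if kw else DesignConstraints()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the pipeline; returns (and optionally writes) the run report."""
    t_start = time.time()
    report = {"config": cfg.resolved(), "stages": []}

    def stage(name):
        log.info("stage %s", name)
        report["stages"].append({"name": name, "t": time.time() - t_start})

    stage("build_models")
    cset, template = get_design_preset(cfg.preset, central_weight=cfg.central_weight)
    if cfg.constraints:
        cons = _constraints_from(cfg.constraints)
        template.constraints = cons
        template = template.with_times([
            np.linspace(cons.t_min + cons.min_spacing,
                        min(8.0, cons.horizon), len(g.times))
            for g in template.groups
        ])

    stage("optimize")
    scfg = SearchConfig(seed=cfg.seed, **cfg.search)
    opt = optimize(cset, template, scfg)
    report["optimal_design"] = {
        "objective": opt.objective,
        "groups": [
            {"name": g.name, "n": g.n_subjects, "times_h": list(map(float, g.times))}
            for g in opt.design.groups
        ],
        "per_model_rse": opt.per_model_rse,
    }

    stage("windows")
    wcfg = dict(cfg.windows)
    ws = find_windows(opt, cset, floor=wcfg.get("floor", 0.80),
                      n_mc=wcfg.get("n_mc", 5000), seed=cfg.seed + 1,
                      percentile=wcfg.get("percentile", 5.0),
                      block_diagonal=scfg.block_diagonal)
    report["windows"] = {
        "floor": ws.efficiency_floor,
        "validated_percentile_efficiency": ws.validation,
        "records": ws.as_records(),
        "notice": ws.notice,
    }

    stage("expected_precision")
    pm0 = cset.models[0]
    fr = population_fim(pm0, opt.design, block_diagonal=scfg.block_diagonal)
    report["expected_rse_central_model"] = fr.rse_dict()

    simcfg = dict(cfg.simest)
    if simcfg.get("enabled", False):
        stage("sim_est")
        pm_fit = _simest_fit_model(pm0, estimate_tlag=simcfg.get("estimate_tlag", True))
        design = _attach_cohorts(opt.design, cfg.preset)
        rep = sim_est(pm0, design,
                      n_replicates=simcfg.get("n_replicates", 100),
                      seed=cfg.seed + 2, pm_fit=pm_fit,
                      init_perturbation=simcfg.get("init_perturbation", 0.2))
        report["sim_est"] = {
            "n_converged": rep.n_converged,
            "n_replicates": rep.n_replicates,
            "table": rep.table.to_dict(orient="records"),
        }

    report["elapsed_s"] = time.time() - t_start
    report["config_hash"] = hashlib.sha256(
        json.dumps(cfg.resolved(), sort_keys=True).encode()).hexdigest()[:16]

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(cfg.resolved(), out / "config.resolved.json")
        write_json(report, out / "report.json")
    return report


def _simest_fit_model(pm, estimate_tlag: bool = True):
    """Estimation model for the evaluation: the lag is estimated even when
    the design fixed it, while its BSV stays fixed at the simulated value."""
    from dataclasses import replace

    fixed = pm.fixed_theta.copy()
    if estimate_tlag and "tlag" in pm.param_names:
        j = pm.param_names.index("tlag")
        if pm.theta[j] > 0:
            fixed[j] = False
    return replace(pm, fixed_theta=fixed)


def _attach_cohorts(design, preset: str):
    """Give each design group its stochastic covariate sampler."""
    groups = []
    for g in design.groups:
        cov = g.covariates[0]
        if cov.population_label == "child":
            lo, hi = {"<2y": (0.25, 2.0), "2-10y": (2.0, 10.0),
                      "11-20y": (11.0, 20.0)}.get(g.name, (0.25, 20.0))
            g.cohort = CohortSpec(population_label="child", n_subjects=g.n_subjects,
                                  age_range=(lo, hi), dose_mg_per_kg=g.dose_mg_per_kg)
        elif cov.population_label == "pregnant":
            g.cohort = CohortSpec(population_label="pregnant",
                                  n_subjects=g.n_subjects,
                                  dose_mg_per_kg=g.dose_mg_per_kg)
        else:
            g.cohort = CohortSpec(population_label="non_pregnant_adult",
                                  n_subjects=g.n_subjects,
                                  dose_mg_per_kg=g.dose_mg_per_kg)
        groups.append(g)
    design.groups = groups
    return design
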