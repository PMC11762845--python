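"""End-to-end orchestration of the quadrat-survey analysis.

Stages run in the order of the underlying scientific logic: sampling
completeness and the environmental-filtering test gate the modelling — if
quadrats were statistically equivalent, relating richness to land cover
would be meaningless — followed by model fitting, partial-response export,
and what-if scenarios.  Every stage writes plain CSV/JSON into the output
directory, and a manifest records the configuration hash, seed and package
version so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gam import (
    SmoothTermSpec,
    fit_additive,
    model_to_json,
    partial_response,
    select_df,
    validate,
)
from .filtering import NullModelConfig, filtering_test
from .richness import estimate_all
from .scenarios import builtin_scenario, predict_scenario, scenario_from_config
from .survey import (
    LANDCOVER_CATEGORIES,
    incidence,
    landcover_matrix,
    max_response,
    read_landcover_table,
    read_survey,
)
from .synthetic import GeneratorConfig, generate_community, write_community

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained in the output directory."""


@dataclass
class RunConfig:
    """Settings for one pipeline run (see docs for the YAML layout)."""

    mode: str = "synthetic"  # or "files"
    generator: dict = field(default_factory=dict)
    landcover_path: str | None = None
    survey_paths: list[str] = field(default_factory=list)
    accumulation_iterations: int = 10_000
    null_model: dict = field(default_factory=dict)
    q_interacting_levels: tuple[float, ...] = (0.0, 0.5, 1.0)
    df_cap: int = 4
    model_specs: dict | None = None  # predictor -> df; None = automatic
    scenarios: list = field(default_factory=lambda: list("ABCDEFGH"))
    output_dir: str = "quadbird_run"
    seed: int = 0
    skip_filtering: bool = False
    acknowledge_unfiltered_modelling: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if cfg.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if cfg.mode == "files" and (
            cfg.landcover_path is None or not cfg.survey_paths
        ):
            raise ValueError("files mode needs landcover_path and survey_paths")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def canonical_json(self) -> str:
        # output_dir is excluded: it does not affect any computed number
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k != "output_dir"
        }
        d["q_interacting_levels"] = list(self.q_interacting_levels)
        return json.dumps(d, sort_keys=True, default=str)


def _load_data(cfg: RunConfig, outdir: Path):
    if cfg.mode == "synthetic":
        gen = GeneratorConfig(**{**cfg.generator, "seed": cfg.generator.get("seed", cfg.seed)})
        community = generate_community(gen)
        write_community(community, outdir / "data")
        return community.quadrats, community.sessions
    quadrats = read_landcover_table(cfg.landcover_path)
    sessions = [
        read_survey(p, session_label=i + 1)
        for i, p in enumerate(cfg.survey_paths)
    ]
    return quadrats, sessions


def _stage_completeness(sessions, cfg: RunConfig, outdir: Path) -> dict:
    rows = []
    summary = {}
    for s in sessions:
        ests = estimate_all(
            incidence(s),
            iterations=cfg.accumulation_iterations,
            seed=cfg.seed + s.session_label,
        )
        for name, est in ests.items():
            rows.append(
                {
                    "session": s.session_label,
                    "estimator": name.value,
                    "s_hat": round(est.s_hat, 2),
                    "completeness_pct": est.completeness_pct,
                }
            )
            summary[f"s{s.session_label}_{name.value}"] = est.completeness_pct
    pd.DataFrame(rows).to_csv(outdir / "completeness.csv", index=False)
    return summary


def _stage_filtering(sessions, cfg: RunConfig, outdir: Path) -> dict:
    base = dict(cfg.null_model)
    rows = []
    out = {}
    for s in sessions:
        for q in cfg.q_interacting_levels:
            nm = NullModelConfig(
                **{**base, "q_interacting": q, "seed": base.get("seed", cfg.seed)}
            )
            res = filtering_test(incidence(s), nm)
            rows.append(
                {
                    "session": s.session_label,
                    "q_interacting": q,
                    "c_obs": res.c_obs,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "p_value": res.p_value,
                    "p_ci_lo": res.p_ci[0],
                    "p_ci_hi": res.p_ci[1],
                    "reject_h0": res.reject_h0,
                    **{f"meta_{k}": v for k, v in res.metadata.items()},
                }
            )
            out[f"s{s.session_label}_q{q}"] = res
    pd.DataFrame(rows).to_csv(outdir / "filtering.csv", index=False)
    baseline_reject = all(
        out[k].reject_h0 for k in out if k.endswith("_q0.0")
    )
    if not baseline_reject:
        logger.warning(
            "environmental filtering not established at alpha=%.2f; "
            "downstream model estimates should be interpreted with caution",
            NullModelConfig(**base).alpha if base else 0.10,
        )
    return out


def _stage_fit(quadrats, sessions, cfg: RunConfig, outdir: Path) -> dict:
    x = landcover_matrix(quadrats)
    resp = max_response(sessions)
    models = {}
    for name, y in (
        ("richness", resp.y1_richness),
        ("abundance", resp.y2_abundance),
    ):
        if cfg.model_specs is not None:
            specs = [
                SmoothTermSpec(p, int(cfg.model_specs.get(p, 1)))
                for p in LANDCOVER_CATEGORIES
            ]
        else:
            specs, trace = select_df(x, y, df_cap=cfg.df_cap, response=name)
            (outdir / f"df_selection_{name}.json").write_text(
                json.dumps(trace, indent=1)
            )
        model = fit_additive(x, y, specs, response=name)
        (outdir / f"model_{name}.json").write_text(model_to_json(model))
        models[name] = model
    report = {
        name: {
            "r_squared_pct": m.r_squared,
            "dispersion": m.dispersion,
            "edf_total": m.edf_total,
            "df_per_term": {t.predictor: t.df for t in m.terms},
        }
        for name, m in models.items()
    }
    (outdir / "validation.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return models


def _stage_partials(models, quadrats, outdir: Path, n_grid: int = 50) -> None:
    x = landcover_matrix(quadrats)
    for name, model in models.items():
        frames = []
        for k, pred in enumerate(LANDCOVER_CATEGORIES):
            grid = np.linspace(0.0, float(x[:, k].max()), n_grid)
            pr = partial_response(model, pred, grid)
            frames.append(
                pd.DataFrame(
                    {
                        "predictor": pred,
                        "hectares": pr.grid,
                        "contribution": pr.contribution,
                    }
                )
            )
        pd.concat(frames).to_csv(
            outdir / f"partials_{name}.csv", index=False
        )


def _stage_scenarios(models, quadrats, cfg: RunConfig, outdir: Path) -> dict:
    model = models["richness"]
    summaries = {}
    rows = []
    for item in cfg.scenarios:
        scen = (
            builtin_scenario(item)
            if isinstance(item, str)
            else scenario_from_config(item)
        )
        res = predict_scenario(model, quadrats, scen)
        summaries[scen.name] = {
            "mean_delta": res.mean_delta,
            "sd_delta": res.sd_delta,
            "extreme_quadrat": res.extreme[0],
            "extreme_delta": res.extreme[1],
        }
        for qid, b, p, d in res.per_quadrat:
            rows.append(
                {
                    "scenario": scen.name,
                    "quadrat_id": qid,
                    "baseline_pred": b,
                    "scenario_pred": p,
                    "delta": d,
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "scenario_deltas.csv", index=False)
    (outdir / "scenario_summary.json").write_text(
        json.dumps(summaries, indent=1, sort_keys=True)
    )
    return summaries


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns a dict of per-stage results.

    Outputs land in ``cfg.output_dir``.  If the filtering stage is disabled,
    the run is refused unless ``acknowledge_unfiltered_modelling`` is set,
    because without established environmental filtering the land-cover models
    have no causal footing.
    """
    if cfg.skip_filtering and not cfg.acknowledge_unfiltered_modelling:
        raise PipelineError(
            "refusing to skip the environmental-filtering stage; set "
            "acknowledge_unfiltered_modelling=true to model anyway"
        )
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}

    t0 = time.perf_counter()
    try:
        quadrats, sessions = _load_data(cfg, outdir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'load' failed: {exc}") from exc
    logger.info("stage load: %.2fs (seed %d)", time.perf_counter() - t0, cfg.seed)

    def run_stage(name, fn):
        t = time.perf_counter()
        try:
            results[name] = fn()
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s: %.2fs", name, time.perf_counter() - t)

    run_stage("completeness", lambda: _stage_completeness(sessions, cfg, outdir))
    if not cfg.skip_filtering:
        run_stage("filtering", lambda: _stage_filtering(sessions, cfg, outdir))
    run_stage("fit", lambda: _stage_fit(quadrats, sessions, cfg, outdir))
    run_stage(
        "partials", lambda: _stage_partials(results["fit"], quadrats, outdir)
    )
    if cfg.scenarios:
        run_stage(
            "scenarios",
            lambda: _stage_scenarios(results["fit"], quadrats, cfg, outdir),
        )

    manifest = {
        "config": json.loads(cfg.canonical_json()),
        "config_sha256": hashlib.sha256(
            cfg.canonical_json().encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "quadbird_version": __version__,
        "stages_run": sorted(results),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results
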