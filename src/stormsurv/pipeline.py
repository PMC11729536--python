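"""End-to-end orchestration: data -> GOF/chat -> model selection -> ANODEV.

The run follows the standard two-step workflow: the resighting structure is
selected by QAICc under fully time-dependent survival and then frozen; the
variance inflation factor estimated from the goodness-of-fit tests (excluding
the trap-dependence component, which the resighting structure absorbs) is
applied to every model in the run; covariate-constrained survival models are
then ranked by QAICc and each is assessed with ANODEV against the constant
and time-dependent references.  All stage outputs are written as CSV/JSON and
are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cjs, covariates as cov_mod, gof, storms as storms_mod
from .encounters import build_marray, read_capture_histories, summarize

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("stormsurv")


@dataclass
class RunConfig:
    species: str = "synthetic"
    histories_path: str | None = None
    histories_dialect: str = "matrix-csv"
    covariates_path: str | None = None
    tracks_path: str | None = None
    daily_path: str | None = None
    box: tuple[float, float, float, float] = (-9.0, 1.0, 43.0, 57.0)
    winter_start_years: tuple[int, ...] | None = None
    chat_policy: str | float = "estimate"   # "estimate", "none" (1.0) or a number
    environmental: tuple[str, ...] = ("sSST", "wSST", "lag_sSST", "lag_wSST", "naoi")
    include_population: bool = True
    include_oil: bool = True
    storm_variables: tuple[str, ...] = ()
    outdir: str = "results/run"
    seed: int = 0


def _resolve_chat(policy, gof_result) -> float:
    if policy == "estimate":
        return max(gof_result.chat, 1.0)
    if policy in ("none", None):
        return 1.0
    return float(policy)


def run_pipeline(
    config: RunConfig,
    histories=None,
    covariate_table: pd.DataFrame | None = None,
) -> dict:
    """Execute the full analysis; returns the report bundle (also written to disk).

    ``histories`` and ``covariate_table`` may be passed directly (e.g. from the
    simulator); otherwise they are read from the configured paths.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    # -- load ---------------------------------------------------------------
    stage("load")
    if histories is None:
        if config.histories_path is None:
            raise ValueError("no histories supplied (path or in-memory)")
        histories = read_capture_histories(config.histories_path, config.histories_dialect)
    counts = summarize(histories)
    bundle["summary"] = counts
    marr = build_marray(histories)

    if covariate_table is None and config.covariates_path:
        covariate_table = pd.read_csv(config.covariates_path)

    # -- GOF and chat ---------------------------------------------------------
    stage("gof")
    gof_result = gof.run_gof(histories)
    gof_result.to_frame().to_csv(out / "gof_components.csv", index=False)
    gof_result.to_json(out / "gof_summary.json")
    chat = _resolve_chat(config.chat_policy, gof_result)
    bundle["gof"] = gof_result
    bundle["chat"] = chat

    # -- resighting structure under phi(t) ------------------------------------
    stage("resighting selection")
    p_fits = [
        cjs.fit(marr, s, chat=chat) for s in cjs.resighting_candidates("t")
    ]
    p_table = cjs.rank_models(p_fits)
    p_table.to_csv(out / "resighting_models.csv", index=False)
    bundle["resighting_table"] = p_table
    best_p = cjs.ModelStructure.parse(p_table["model"].iloc[0]).p_spec
    bundle["best_p_spec"] = best_p
    best_t_fit = next(f for f in p_fits if f.structure.p_spec == best_p)

    # -- annual survival series ----------------------------------------------
    stage("survival series")
    series = cjs.survival_series(best_t_fit)
    series.to_csv(out / "survival_series.csv", index=False)
    bundle["survival_series"] = series

    # -- covariate models ------------------------------------------------------
    if covariate_table is None:
        log.warning("no covariate table supplied: fitting {., t} survival only")
        base_fits = [
            cjs.fit(marr, cjs.ModelStructure(s, best_p), chat=chat) for s in (".", "t")
        ]
        table = cjs.rank_models(base_fits)
        table.to_csv(out / "covariate_models.csv", index=False)
        bundle["covariate_table"] = table
        _write_log(out, config, chat, counts)
        return bundle

    stage("covariate models")
    cand_cfg = cjs.CandidateConfig(
        species=config.species,
        storminess="PC1" if "PC1" in covariate_table.columns else None,
        environmental=tuple(c for c in config.environmental if c in covariate_table.columns),
        include_population=config.include_population and "population" in covariate_table.columns,
        include_oil=config.include_oil and "oil" in covariate_table.columns,
        storm_variables=tuple(
            c for c in config.storm_variables if c in covariate_table.columns
        ),
    )
    structures = cjs.survival_candidates(cand_cfg, best_p)
    env_fits = {
        s.label: cjs.fit(marr, s, covariates=covariate_table, chat=chat)
        for s in structures
    }
    env_table = cjs.rank_models(list(env_fits.values()))
    env_table.to_csv(out / "covariate_models.csv", index=False)
    bundle["covariate_table"] = env_table

    stage("anodev")
    f_cst = env_fits[cjs.ModelStructure(".", best_p).label]
    f_time = env_fits[cjs.ModelStructure("t", best_p).label]
    anodev_rows = []
    for lab, fr in env_fits.items():
        if fr.n_slopes == 0:
            continue
        try:
            a = cjs.anodev(f_cst, fr, f_time)
        except ValueError as exc:
            log.warning("anodev failed for %s: %s", lab, exc)
            continue
        anodev_rows.append(
            {"model": lab, "r2": a.r2, "f": a.f, "df1": a.df1, "df2": a.df2, "p": a.p}
        )
    anodev_table = pd.DataFrame(anodev_rows)
    anodev_table.to_csv(out / "anodev.csv", index=False)
    bundle["anodev_table"] = anodev_table

    best_cov_label = next(
        (m for m in env_table["model"] if cjs.ModelStructure.parse(m).n_slopes > 0), None
    )
    if best_cov_label:
        effects = cjs.covariate_effect(env_fits[best_cov_label])
        effects.to_csv(out / "covariate_effects.csv", index=False)
        bundle["covariate_effects"] = effects
        bundle["best_covariate_model"] = best_cov_label

    # -- storm characteristics -------------------------------------------------
    if cand_cfg.storm_variables:
        stage("storm characteristics")
        singles = cjs.storm_candidates(cand_cfg, best_p)
        storm_fits = {
            s.label: cjs.fit(marr, s, covariates=covariate_table, chat=chat)
            for s in singles
        }
        ranked = cjs.rank_models(list(storm_fits.values()))
        best_storm = next(
            (
                cjs.ModelStructure.parse(m).phi_spec
                for m in ranked["model"]
                if cjs.ModelStructure.parse(m).phi_spec in cand_cfg.storm_variables
            ),
            None,
        )
        best_env = None
        if best_cov_label:
            terms = cjs.ModelStructure.parse(best_cov_label).phi_terms()
            best_env = next(
                (t for t in terms if ":" not in t and t != cand_cfg.storminess), None
            )
        if best_storm and best_env:
            for s in cjs.storm_candidates(cand_cfg, best_p, best_storm, best_env):
                if s.label not in storm_fits:
                    storm_fits[s.label] = cjs.fit(
                        marr, s, covariates=covariate_table, chat=chat
                    )
        storm_table = cjs.rank_models(list(storm_fits.values()))
        storm_table.to_csv(out / "storm_models.csv", index=False)
        bundle["storm_table"] = storm_table

    _write_log(out, config, chat, counts)
    return bundle


def _write_log(out: Path, config: RunConfig, chat: float, counts: dict) -> None:
    import stormsurv

    payload = {
        "package_version": stormsurv.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "chat": chat,
        "summary": counts,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(payload, fh, indent=2)
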