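"""End-to-end orchestration with auditable sample accounting.

``run_pipeline`` executes simulate/ingest -> deprivation scoring ->
vulnerability -> elasticity -> regressions -> inequality, writing every stage
artifact as CSV plus a single ``manifest.json`` whose row-count ledger makes
the exclusion cascade reconstructible (input n, each exclusion, analytic n).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import af_index, elasticity, inequality, logit, synthetic, vep
from .config import PipelineConfig

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.cause = cause


# ---------------------------------------------------------------------------
# sample-accounting ledger
# ---------------------------------------------------------------------------

def sample_ledger(total: int, exclusions: list[tuple[str, int]]) -> dict:
    """Apply exclusion counts to a starting total.

    Returns ``{"initial": total, "steps": [...], "analytic_n": remaining}``
    where each step records the label, the count removed and the running
    remainder, mirroring a sample-size-determination diagram.
    """
    if total < 0:
        raise ValueError("total must be nonnegative")
    remaining = int(total)
    steps = []
    for label, count in exclusions:
        if count < 0:
            raise ValueError(f"exclusion count for {label!r} is negative")
        if count > remaining:
            raise ValueError(f"exclusion {label!r} removes {count} from only "
                             f"{remaining} remaining rows")
        remaining -= int(count)
        steps.append({"label": label, "excluded": int(count),
                      "remaining": remaining})
    return {"initial": int(total), "steps": steps, "analytic_n": remaining}


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _config_dict(config), "stages": []}

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        _write_manifest(out, manifest)

    # -- stage 1: simulate or ingest ---------------------------------------
    stage = "simulate" if config.input_csv is None else "ingest"
    try:
        if config.input_csv is None:
            pop = dataclasses.replace(config.population, seed=config.seed)
            table = synthetic.generate_population(pop)
        else:
            table = synthetic.read_table(config.input_csv, validate=False)
        n_in = len(table)
        exclusions = []
        under_age = table["age"] < 16
        if under_age.any():
            table = table[~under_age]
        exclusions.append(("below working age (16)", int(under_age.sum())))
        key_cols = [c for c in synthetic.REQUIRED_COLUMNS if c in table.columns]
        missing = table[key_cols].isna().any(axis=1)
        if missing.any():
            table = table[~missing]
        exclusions.append(("missing values", int(missing.sum())))
        table = table.reset_index(drop=True)
        synthetic.validate_table(table)
        ledger = sample_ledger(n_in, exclusions)
        synthetic.write_table(table, out / "population.csv")
        record(stage, seed=config.seed, rows_in=n_in, rows_out=len(table),
               ledger=ledger, artifact="population.csv")
    except Exception as exc:  # noqa: BLE001 - halt with stage context
        raise PipelineError(stage, manifest, exc) from exc

    # -- stage 2: deprivation scoring ---------------------------------------
    try:
        php_spec, mhp_spec = af_index.builtin_specs()
        php = af_index.classify_table(table, php_spec, config.gamma)
        mhp = af_index.classify_table(table, mhp_spec, config.gamma)
        joint = af_index.combine_scores(php, mhp, config.combine_rule, config.gamma)
        scores = pd.DataFrame({
            "person_id": table["person_id"],
            "php_score": php["score"], "php_poor": php["poor"],
            "mhp_score": mhp["score"], "mhp_poor": mhp["poor"],
            "joint_score": joint["score"], "joint_poor": joint["poor"],
        })
        scores.to_csv(out / "af_scores.csv", index=False)
        record("af-score", gamma=config.gamma, combine_rule=config.combine_rule,
               rows_in=len(table), rows_out=len(scores),
               php_headcount=float(php["poor"].mean()),
               mhp_headcount=float(mhp["poor"].mean()),
               artifact="af_scores.csv")
    except Exception as exc:
        raise PipelineError("af-score", manifest, exc) from exc

    # -- stage 3: vulnerability ---------------------------------------------
    try:
        from .config import WELFARE_COLUMNS
        X = synthetic.welfare_design(table)
        cols = list(WELFARE_COLUMNS)
        if config.welfare_source == "af-score":
            ln_w = vep.af_welfare(joint["score"].to_numpy())
            line = (config.ln_poverty_line if config.ln_poverty_line is not None
                    else vep.af_poverty_line(config.gamma))
        else:
            col = config.welfare_source.split(":", 1)[1]
            if col not in table.columns:
                raise KeyError(f"welfare column {col!r} not in table")
            ln_w = table[col].to_numpy(float)
            line = (config.ln_poverty_line if config.ln_poverty_line is not None
                    else config.population.ln_poverty_line)
        model = vep.fit_welfare_fgls(ln_w, X, cols)
        vul = vep.predict_vulnerability(model, X, line)
        table["vulnerability"] = vul
        table["vep_hat"] = vep.binarize(vul, config.vep_cutoff)
        pd.DataFrame({"person_id": table["person_id"], "vulnerability": vul,
                      "vep_binary": table["vep_hat"]}
                     ).to_csv(out / "vep.csv", index=False)
        record("vep", welfare_source=config.welfare_source,
               ln_poverty_line=line, cutoff=config.vep_cutoff,
               rows_in=len(table), rows_out=len(table),
               vep_mean=float(table["vep_hat"].mean()),
               n_floored=model.n_floored, artifact="vep.csv")
    except Exception as exc:
        raise PipelineError("vep", manifest, exc) from exc

    # -- stage 4: elasticity -------------------------------------------------
    try:
        emodel = elasticity.fit_elasticity(
            table, strategy=config.elasticity_strategy,
            strata=tuple(config.elasticity_strata),
            min_stratum_n=config.min_stratum_n)
        table["e_h"] = elasticity.assign_eh(table, emodel)
        pd.DataFrame({"person_id": table["person_id"], "e_h": table["e_h"]}
                     ).to_csv(out / "elasticity.csv", index=False)
        record("elasticity", strategy=config.elasticity_strategy,
               strata=list(config.elasticity_strata),
               rows_in=len(table), rows_out=len(table),
               n_excluded_from_fit=emodel.n_excluded,
               pooled_beta=emodel.pooled_beta,
               eh_mean=float(table["e_h"].mean()),
               eh_sd=float(table["e_h"].std()),
               artifact="elasticity.csv")
    except Exception as exc:
        raise PipelineError("elasticity", manifest, exc) from exc

    # -- stage 5: regressions ------------------------------------------------
    try:
        outcome = config.outcome_column
        if outcome not in table.columns:
            raise KeyError(f"outcome column {outcome!r} not in table")
        suite = logit.run_table_suite(table, outcome=outcome, eh_column="e_h",
                                      fe_column=config.fe_column,
                                      designs=tuple(config.designs))
        report_lines = []
        fit_summary = {}
        for name, block in suite.items():
            report_lines.append(logit.format_report(name, block))
            fit_summary[name] = _summarise_block(block)
            for frame, label in _block_frames(name, block):
                frame.to_csv(out / f"fit_{label}.csv", index=False)
        (out / "fit_report.txt").write_text("\n".join(report_lines))
        record("fit", outcome=outcome, designs=list(config.designs),
               rows_in=len(table), summary=fit_summary,
               artifact="fit_report.txt")
    except Exception as exc:
        raise PipelineError("fit", manifest, exc) from exc

    # -- stage 6: inequality ---------------------------------------------------
    try:
        results = inequality.regional_gap_report(
            table, config.inequality_value, ("region", "province"))
        inequality.report_to_frame(results).to_csv(
            out / "inequality.csv", index=False)
        record("inequality", value=config.inequality_value,
               rows_in=len(table), rows_out=len(results),
               artifact="inequality.csv")
    except Exception as exc:
        raise PipelineError("inequality", manifest, exc) from exc

    return manifest


def _block_frames(name: str, block: dict):
    if "rows" in block:
        yield logit.results_to_frame(block), name
    elif "joint" in block:
        j = block["joint"]
        rows = [{"terms": "+".join(j.terms_tested), "chi2": j.statistic,
                 "df": j.df, "p": j.p_value}]
        rows += [{"terms": t, "chi2": w.statistic, "df": w.df, "p": w.p_value}
                 for t, w in block["per_term"].items()]
        yield pd.DataFrame(rows), name
    elif "error" not in block:
        for sub, b in block.items():
            yield from _block_frames(f"{name}_{sub}", b)


def _summarise_block(block: dict):
    if "error" in block:
        return {"error": block["error"]}
    if "rows" in block:
        return {"n_obs": block["n_obs"],
                "dydx": {r["term"]: r["dydx"] for r in block["rows"]}}
    if "joint" in block:
        return {"n_obs": block["n_obs"],
                "joint_chi2": block["joint"].statistic,
                "joint_p": block["joint"].p_value}
    return {sub: _summarise_block(b) for sub, b in block.items()}


def _config_dict(config: PipelineConfig) -> dict:
    from .config import _as_plain
    return _as_plain(config)


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
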