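"""Orchestration of the four-model mosaic-retention analysis.

Given a case table (the packaged literature table, an external CSV, or a
synthetic table with known truth) and per-model parameters, run_analysis
executes:

  1. the retention summary (lower / comparable / higher tallies),
  2. the binomial logistic retention-curve fit with deviation from y = x,
  3. the beta-binomial reduction test,
  4. the absorbing Markov chain trajectory and limit, and
  5. the agent-based parameter sweep,

and bundles everything into one JSON-serializable report.  A failed stage is
recorded as failed while the remaining stages still run.  Every stochastic
stage derives its seed deterministically from the master seed, so a config
plus seed reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import abm, bayes, cases, logistic, markov, synthgen

__all__ = ["default_config", "run_analysis", "report_to_json"]

logger = logging.getLogger(__name__)


def default_config() -> dict:
    return {
        "source": {"kind": "fixture"},
        "seed": 0,
        "tolerance": 0.10,
        "bayes": {
            "rule": "strict_lower",
            "prior": [1.0, 1.0],
            "threshold": 0.5,
            "level": 0.95,
        },
        "logistic": {
            "default_m": 30,
            "grid_size": 101,
            "bootstrap_reps": 1000,
        },
        "markov": {
            "p_clear": 0.2,
            "p_te": 0.2,
            "p_icm": 0.2,
            "p_stay": 0.4,
            "n_steps": 10,
        },
        "abm": {
            "p0_grid": [0.2, 0.4, 0.6, 0.8],
            "s_grid": [0.0, 0.05, 0.1, 0.2],
            "reps": 200,
            "n_founders": 8,
            "n_cycles": 5,
            "allocation_bias": 0.0,
            "icm_base_prob": 0.25,
        },
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def _load_cases(source: dict, seed: int) -> list[cases.TransmissionCase]:
    kind = source.get("kind", "fixture")
    if kind == "fixture":
        return cases.load_reference_table()
    if kind == "csv":
        text = Path(source["path"]).read_text(encoding="utf-8")
        return cases.parse_case_table(text)
    if kind == "synthetic":
        gp_kwargs = {k: v for k, v in source.items() if k != "kind"}
        gp_kwargs.setdefault("seed", seed)
        if "parent_beta_params" in gp_kwargs:
            gp_kwargs["parent_beta_params"] = tuple(gp_kwargs["parent_beta_params"])
        if "metaphase_range" in gp_kwargs:
            gp_kwargs["metaphase_range"] = tuple(gp_kwargs["metaphase_range"])
        table, _ = synthgen.generate_case_table(synthgen.GenParams(**gp_kwargs))
        return table
    raise ValueError(f"unknown case source kind {kind!r}")


def _stage(report: dict, name: str, fn) -> None:
    try:
        report["stages"][name] = {"status": "ok", "result": fn()}
    except Exception as exc:  # stage isolation: one failure must not stop the rest
        logger.exception("stage %s failed", name)
        report["stages"][name] = {"status": "failed", "error": str(exc)}


def run_analysis(config: dict | None = None) -> dict:
    """Run the full analysis; returns a JSON-serializable report dict.

    The report carries a top-level ``ok`` flag (False if any stage failed),
    the resolved config, and per-stage results keyed ``retention``,
    ``logistic``, ``bayes``, ``markov``, ``abm_sweep``.
    """
    cfg = _merge(default_config(), config or {})
    seed = int(cfg["seed"])
    tolerance = float(cfg["tolerance"])

    report: dict[str, Any] = {"config": cfg, "stages": {}}

    try:
        table = _load_cases(cfg["source"], seed)
    except Exception as exc:
        raise FileNotFoundError(f"cannot load case table: {exc}") from exc

    def retention_stage() -> dict:
        summary = cases.retention_summary(table, tolerance)
        return summary.to_dict()

    def bayes_stage() -> dict:
        bc = cfg["bayes"]
        prior = bayes.BetaPosterior(*bc["prior"])
        rule = bayes.ReductionRule(bc["rule"])
        res = bayes.reduction_test(
            table,
            prior=prior,
            rule=rule,
            tolerance=tolerance,
            threshold=float(bc["threshold"]),
            level=float(bc["level"]),
        )
        return res.to_dict()

    def logistic_stage() -> dict:
        lc = cfg["logistic"]
        pairs = [
            (cases.effective_ratio(c.parent_ratio), cases.effective_ratio(c.offspring_ratio))
            for c in table
        ]
        pairs = [(x, y) for x, y in pairs if x is not None and y is not None]
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        fit = logistic.fit_retention_curve(x, y, float(lc["default_m"]))
        dev = logistic.identity_deviation(
            fit,
            grid_size=int(lc["grid_size"]),
            bootstrap_reps=int(lc["bootstrap_reps"]),
            seed=seed + 1,
        )
        return {
            "beta0": fit.beta0,
            "beta1": fit.beta1,
            "se_beta0": fit.se_beta0,
            "se_beta1": fit.se_beta1,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_cases": fit.n_cases,
            "deviation": dev.to_dict(),
        }

    def markov_stage() -> dict:
        mc = cfg["markov"]
        spec = markov.TransitionSpec(
            p_clear=float(mc["p_clear"]),
            p_te=float(mc["p_te"]),
            p_icm=float(mc["p_icm"]),
            p_stay=float(mc["p_stay"]),
        )
        traj = markov.iterate(spec, int(mc["n_steps"]))
        return {
            "trajectory": [
                {"iteration": d.iteration, "mass": [float(v) for v in d.mass]}
                for d in traj
            ],
            "final_icm_mass": float(traj[-1][markov.State.ICM]),
            "absorbing_distribution": [
                float(v) for v in markov.absorbing_distribution(spec)
            ],
            "expected_absorption_time": markov.expected_absorption_time(spec),
        }

    def abm_stage() -> dict:
        ac = cfg["abm"]
        template = abm.ABMParams(
            p0=0.5,
            n_founders=int(ac["n_founders"]),
            n_cycles=int(ac["n_cycles"]),
            allocation_bias=float(ac["allocation_bias"]),
            icm_base_prob=float(ac["icm_base_prob"]),
        )
        sweep = abm.run_sweep(
            [float(v) for v in ac["p0_grid"]],
            [float(v) for v in ac["s_grid"]],
            int(ac["reps"]),
            seed + 2,
            template,
        )
        matrix = [
            [None if np.isnan(v) else float(v) for v in row]
            for row in sweep.mean_icm_fraction
        ]
        return {
            "p0_grid": list(sweep.p0_grid),
            "s_grid": list(sweep.s_grid),
            "mean_icm_fraction": matrix,
            "n_reps": sweep.n_reps,
            "base_seed": seed + 2,
        }

    _stage(report, "retention", retention_stage)
    _stage(report, "bayes", bayes_stage)
    _stage(report, "logistic", logistic_stage)
    _stage(report, "markov", markov_stage)
    _stage(report, "abm_sweep", abm_stage)

    report["ok"] = all(s["status"] == "ok" for s in report["stages"].values())
    return report


def report_to_json(report: dict) -> str:
    """Deterministic serialization (sorted keys) for reproducibility checks."""
    return json.dumps(report, indent=2, sort_keys=True)


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write report.json plus TSV artifacts to a directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report), encoding="utf-8")

    mk = report["stages"].get("markov")
    if mk and mk["status"] == "ok":
        lines = ["iteration\tproliferating\tcleared\tte\ticm"]
        for row in mk["result"]["trajectory"]:
            lines.append(
                str(row["iteration"])
                + "\t"
                + "\t".join(f"{v:.12f}" for v in row["mass"])
            )
        (out / "markov_trajectory.tsv").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )

    ab = report["stages"].get("abm_sweep")
    if ab and ab["status"] == "ok":
        res = ab["result"]
        lines = ["p0\\s\t" + "\t".join(f"{s:g}" for s in res["s_grid"])]
        for p0, row in zip(res["p0_grid"], res["mean_icm_fraction"]):
            lines.append(
                f"{p0:g}\t"
                + "\t".join("NA" if v is None else f"{v:.6f}" for v in row)
            )
        (out / "abm_sweep.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out
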