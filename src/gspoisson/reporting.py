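"""Rendering, serialization, and configurable runs.

Design records follow the standard tabular layout for group sequential
comparisons: K, spending vectors, group size, boundaries, maximal type-I
error, power, expected sample sizes under the null and alternative reporting
rates, and the maximal sample size.  Error rates and power are printed to 3
decimal places, expected sample sizes to 1, and real-valued boundaries to 2;
the underlying records keep full precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import pandas as pd
import yaml

from . import simulate, spending
from .evaluate import evaluate_design
from .types import (
    DesignProblem,
    GroupSequentialDesign,
    GroupSizeSearchFailure,
    Infeasible,
    OptimalityWeights,
    PoissonRates,
    SearchLimits,
    SpendingPlan,
)

logger = logging.getLogger(__name__)

__all__ = ["design_record", "render_table", "records_to_dataframe", "RunConfig", "run"]

_COLUMNS = ["K", "pi_A", "pi_R", "n", "a", "r", "alpha_max", "power", "ess_null", "ess_alt", "max_n"]


def design_record(
    design: GroupSequentialDesign,
    problem: DesignProblem,
    plan: Optional[SpendingPlan] = None,
    score: Optional[float] = None,
) -> Dict[str, Any]:
    """Evaluate a design and return a serializable record."""
    oc = evaluate_design(design, problem)
    return {
        "K": design.K,
        "engine": design.engine,
        "pi_A": list(plan.pi_A) if plan else None,
        "pi_R": list(plan.pi_R) if plan else None,
        "n": design.n,
        "a": list(design.a),
        "r": list(design.r),
        "alpha_max": oc.alpha_max,
        "power": 1.0 - oc.beta_max,
        "ess_null": oc.ess_null,
        "ess_alt": oc.ess_alt,
        "max_n": oc.max_n,
        "score": score,
    }


def _fmt_boundaries(values: Sequence[float], engine: str) -> str:
    if engine == "exact":
        parts = [str(int(v)) for v in values]
    else:
        parts = [f"{v:.2f}" for v in values]
    return parts[0] if len(parts) == 1 else "(" + ", ".join(parts) + ")"


def _fmt_vector(values: Optional[Sequence[float]]) -> str:
    if values is None:
        return "NA"
    parts = [f"{v:g}" for v in values]
    return parts[0] if len(parts) == 1 else "(" + ", ".join(parts) + ")"


def _fmt_float(value: Optional[float], ndigits: int) -> str:
    return "NA" if value is None else f"{value:.{ndigits}f}"


def records_to_dataframe(records: Sequence[Dict[str, Any]]) -> pd.DataFrame:
    """Display-precision table (3 dp errors/power, 1 dp ESS, 2 dp real boundaries)."""
    if not records:
        raise ValueError("no design records to render")
    rows = []
    for rec in records:
        rows.append(
            {
                "K": rec["K"],
                "pi_A": _fmt_vector(rec.get("pi_A")),
                "pi_R": _fmt_vector(rec.get("pi_R")),
                "n": rec["n"],
                "a": _fmt_boundaries(rec["a"], rec["engine"]),
                "r": _fmt_boundaries(rec["r"], rec["engine"]),
                "alpha_max": _fmt_float(rec.get("alpha_max"), 3),
                "power": _fmt_float(rec.get("power"), 3),
                "ess_null": _fmt_float(rec.get("ess_null"), 1),
                "ess_alt": _fmt_float(rec.get("ess_alt"), 1),
                "max_n": rec["max_n"],
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def render_table(records: Sequence[Dict[str, Any]], fmt: str = "text") -> str:
    """Render design records as an aligned text table or CSV."""
    df = records_to_dataframe(records)
    if fmt == "csv":
        return df.to_csv(index=False)
    if fmt == "text":
        return df.to_string(index=False)
    raise ValueError(f"fmt must be 'text' or 'csv', got {fmt!r}")


# ---------------------------------------------------------------------------
# configurable runs
# ---------------------------------------------------------------------------

_MODES = ("single_plan", "grid", "exhaustive", "validate")


@dataclass
class RunConfig:
    """A reproducible run: the design problem plus mode-specific settings."""

    problem: DesignProblem
    engine: str
    K: int
    mode: str
    plan: Optional[SpendingPlan] = None
    grid: Optional[List[SpendingPlan]] = None
    weights: Optional[OptimalityWeights] = None
    limits: SearchLimits = field(default_factory=SearchLimits)
    n_cap: Optional[int] = None
    design: Optional[GroupSequentialDesign] = None
    rates: Optional[PoissonRates] = None
    replicates: int = 10_000
    seed: int = 0
    out_csv: Optional[str] = None
    out_json: Optional[str] = None

    def validate(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.engine not in ("exact", "normal"):
            raise ValueError(f"engine must be 'exact' or 'normal', got {self.engine!r}")
        if self.mode == "single_plan" and self.plan is None:
            raise ValueError("mode 'single_plan' requires a spending plan")
        if self.mode == "grid":
            if not self.grid:
                raise ValueError("mode 'grid' requires a nonempty spending grid")
            if self.weights is None:
                raise ValueError("mode 'grid' requires optimality weights")
        if self.mode == "exhaustive":
            if self.weights is None:
                raise ValueError("mode 'exhaustive' requires optimality weights")
            if self.engine != "exact" or self.K != 2:
                raise ValueError("exhaustive search supports only engine='exact' with K=2")
        if self.mode == "validate":
            if self.design is None:
                raise ValueError("mode 'validate' requires a design")
            if self.rates is None:
                raise ValueError("mode 'validate' requires rates (lambda1, lambda2)")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "RunConfig":
        prob = raw["problem"]
        problem = DesignProblem(
            lambda_null=tuple(prob["lambda_null"]),
            lambda_alt=tuple(prob["lambda_alt"]),
            delta=prob["delta"],
            alpha=prob["alpha"],
            beta=prob["beta"],
            lambda_ess=prob["lambda_ess"],
        )
        kwargs: Dict[str, Any] = {
            "problem": problem,
            "engine": raw["engine"],
            "K": raw["K"],
            "mode": raw["mode"],
        }
        if "plan" in raw and raw["plan"] is not None:
            kwargs["plan"] = SpendingPlan(tuple(raw["plan"]["pi_A"]), tuple(raw["plan"]["pi_R"]))
        if "grid" in raw and raw["grid"] is not None:
            kwargs["grid"] = [SpendingPlan(tuple(p["pi_A"]), tuple(p["pi_R"])) for p in raw["grid"]]
        if "weights" in raw and raw["weights"] is not None:
            kwargs["weights"] = OptimalityWeights(*raw["weights"])
        if "limits" in raw and raw["limits"] is not None:
            kwargs["limits"] = SearchLimits(**raw["limits"])
        if "design" in raw and raw["design"] is not None:
            d = raw["design"]
            kwargs["design"] = GroupSequentialDesign(
                K=d["K"], n=d["n"], a=tuple(d["a"]), r=tuple(d["r"]), engine=d["engine"]
            )
        if "rates" in raw and raw["rates"] is not None:
            kwargs["rates"] = PoissonRates(*raw["rates"])
        for key in ("n_cap", "replicates", "seed", "out_csv", "out_json"):
            if key in raw and raw[key] is not None:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _write_outputs(config: RunConfig, report: Dict[str, Any]) -> None:
    if config.out_json:
        Path(config.out_json).write_text(json.dumps(report, indent=2))
    if config.out_csv and report.get("designs"):
        Path(config.out_csv).write_text(render_table(report["designs"], fmt="csv"))


def run(config: RunConfig) -> Dict[str, Any]:
    """Dispatch a configured run and return (and optionally write) its report."""
    config.validate()
    problem = config.problem
    report: Dict[str, Any] = {"mode": config.mode, "engine": config.engine, "feasible": True}

    if config.mode == "single_plan":
        n_cap = config.n_cap or 2 * spending._fixed_sample_group_size(problem, config.engine)
        result = spending.find_group_size(config.plan, problem, config.engine, n_cap)
        if isinstance(result, GroupSizeSearchFailure):
            report["feasible"] = False
            report["reason"] = result.reason
        else:
            report["designs"] = [design_record(result, problem, plan=config.plan)]
    elif config.mode == "grid":
        ranked = spending.grid_search(
            config.grid, config.weights, problem, config.engine, config.K, n_cap=config.n_cap
        )
        if not ranked:
            report["feasible"] = False
            report["reason"] = "no feasible design in the spending grid"
        else:
            report["designs"] = [
                design_record(x.design, problem, plan=x.plan, score=x.score) for x in ranked
            ]
    elif config.mode == "exhaustive":
        result = spending.exhaustive_search_k2(problem, config.weights, limits=config.limits)
        if isinstance(result, GroupSizeSearchFailure):
            report["feasible"] = False
            report["reason"] = result.reason
        else:
            score = spending.optimality_score(result, config.weights, problem)
            report["designs"] = [design_record(result, problem, score=score)]
    else:  # validate
        emp = simulate.empirical_error_rates(
            config.design, config.rates, config.replicates, config.seed
        )
        report["empirical"] = dataclasses.asdict(emp)
        report["design"] = dataclasses.asdict(config.design)

    _write_outputs(config, report)
    return report
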