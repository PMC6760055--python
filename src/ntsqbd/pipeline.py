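"""End-to-end analysis: characterise, fit, design space, grade, report.

``run_pipeline`` executes the stages in order on configured inputs (the
bundled study tables by default), writes every intermediate table, the model
JSON, the design-space grid and a plain-text summary into the output
directory, and returns the in-memory results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._exceptions import DomainError, NtsQbdError
from .design_space import (CqaLimit, ProbabilityGrid, SimulationSpec,
                           default_cpp_grid, export_grid,
                           monte_carlo_design_space)
from .doe import DesignTable, validate_dsd
from .grading import (FixedProcess, GradeDecision, classify_fixed,
                      derive_inequalities, feasibility_variable,
                      simplify_fixed)
from .io import (PipelineConfig, load_fixtures, provenance, read_table,
                 write_models, write_table, RESPONSE_COLUMNS)
from .quality_metrics import MaterialBatch
from .screening import (ScreeningModel, augment_and_refit, identify_critical,
                        stepwise_fit)


class StageError(NtsQbdError):
    """A pipeline stage failed; carries the stage name for the CLI."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineReport:
    """Everything one pipeline run produced."""

    data: pd.DataFrame
    models: dict[str, ScreeningModel]
    critical: object
    grids: dict[str, ProbabilityGrid]
    decisions: list[GradeDecision]
    summary: str
    out_dir: Path | None = None


def _load_inputs(cfg: PipelineConfig):
    fx = load_fixtures()
    factors = fx.factors
    design_df = (read_table(cfg.design_csv) if cfg.design_csv
                 else fx.design.to_frame())
    design = DesignTable.from_frame(design_df, factors)
    if cfg.batches_csv:
        bdf = read_table(cfg.batches_csv)
        batches = [MaterialBatch(r.batch_id,
                                 (r.Z1, r.Z2, r.Z3, r.Z4, r.Z5, r.Z6))
                   for r in bdf.itertuples()]
    else:
        batches = fx.batches
    responses = (read_table(cfg.responses_csv) if cfg.responses_csv
                 else fx.responses)
    grading = (read_table(cfg.grading_csv) if cfg.grading_csv
               else fx.grading_batches)
    zrows = pd.DataFrame([{"batch_id": b.batch_id, **b.as_dict()}
                          for b in batches])
    df = (design.to_frame().merge(zrows, on="batch_id")
          .merge(responses, on="run_id")
          .sort_values("run_id").reset_index(drop=True))
    for cqa in cfg.limits:
        if cqa in df.columns:
            continue
        pct = RESPONSE_COLUMNS.get(cqa)
        if pct and pct in df.columns:
            df[cqa] = df[pct] / 100.0
        else:
            raise DomainError(f"no response column found for CQA {cqa!r}")
    return factors, design, batches, df, grading


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None
                 ) -> PipelineReport:
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = provenance(cfg.seed, cfg.to_dict())
    lines: list[str] = [f"ntsqbd pipeline (seed={cfg.seed}, "
                        f"config={meta['config_sha256']})"]

    try:
        factors, design, batches, df, grading = _load_inputs(cfg)
        report = validate_dsd(design)
        lines.append(
            f"design: {report.n_runs} runs, {report.n_center} center "
            f"replicates, fold-over "
            f"{'complete' if report.foldover_complete else 'incomplete'}")
        write_table(df, out / "dataset.csv", meta)
    except NtsQbdError as e:
        raise StageError("characterize", e) from e

    try:
        models: dict[str, ScreeningModel] = {}
        for cqa in cfg.limits:
            m = stepwise_fit(df, cqa, cfg.candidates, factors=factors)
            if m.x_terms:
                m = augment_and_refit(m, df, factors)
            models[cqa] = m
        critical = identify_critical(models.values())
        write_models(models, out / "models.json")
        lines.append(f"CPPs: {', '.join(critical.cpps) or '(none)'}")
        lines.append(f"CMAs: {', '.join(critical.cmas) or '(none)'}")
        for cqa, m in models.items():
            r2 = m.stats.r2 if m.stats else float("nan")
            lines.append(f"model {cqa}: terms {list(m.coefficients)}, "
                         f"R2 = {r2:.4f}")
    except NtsQbdError as e:
        raise StageError("fit", e) from e

    limits = [CqaLimit(cqa, bound) for cqa, bound in cfg.limits.items()]
    sim = SimulationSpec(
        refit_terms={cqa: list(m.coefficients) for cqa, m in models.items()},
        n_sim=cfg.n_sim, rsd=cfg.rsd, seed=cfg.seed)
    grids: dict[str, ProbabilityGrid] = {}
    try:
        grid_axes = default_cpp_grid(factors, cfg.grid_steps)
        zmap = {b.batch_id: b.as_dict() for b in batches}
        for r in grading.itertuples():
            zmap.setdefault(r.batch_id, {f"Z{k}": getattr(r, f"Z{k}")
                                         for k in (1, 2, 4, 5, 6)})
        for mat in cfg.design_space_materials:
            if mat not in zmap:
                raise DomainError(f"unknown design-space material {mat!r}")
            g = monte_carlo_design_space(df, sim, limits, grid_axes,
                                         zmap[mat], threshold=cfg.threshold)
            grids[mat] = g
            write_table(export_grid(g), out / f"design_space_{mat}.csv", meta)
            frac = float(g.mask.mean())
            lines.append(f"design space for {mat}: {g.mask.sum()} of "
                         f"{g.prob.size} grid cells ({frac:.1%}) at "
                         f"P >= {cfg.threshold}")
    except NtsQbdError as e:
        raise StageError("design-space", e) from e

    try:
        ineqs = derive_inequalities(list(models.values()), limits)
        fixed = FixedProcess(cfg.fixed_process) if cfg.fixed_process else FixedProcess()
        simplified = simplify_fixed(ineqs, fixed)
        box = {s: (f.low, f.high) for s, f in factors.items()}
        decisions: list[GradeDecision] = []
        rows = []
        for r in grading.itertuples():
            z = {f"Z{k}": float(getattr(r, f"Z{k}")) for k in (1, 2, 4, 5, 6)
                 if hasattr(r, f"Z{k}")}
            var = feasibility_variable(ineqs, z, box, batch_id=r.batch_id)
            fix = classify_fixed(simplified, z, batch_id=r.batch_id)
            decisions += [var, fix]
            rows.append({
                "batch_id": r.batch_id,
                "variable_verdict": var.verdict,
                "fixed_verdict": fix.verdict,
                **{f"slack_{cqa}": s for cqa, s in fix.slacks.items()},
            })
            lines.append(f"grade {r.batch_id}: variable-parameter "
                         f"{var.verdict}, fixed-parameter {fix.verdict}")
        if rows:
            write_table(pd.DataFrame(rows), out / "grades.csv", meta)
    except NtsQbdError as e:
        raise StageError("grade", e) from e

    summary = "\n".join(lines) + "\n"
    (out / "summary.txt").write_text(summary)
    return PipelineReport(data=df, models=models, critical=critical,
                          grids=grids, decisions=decisions, summary=summary,
                          out_dir=out)
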