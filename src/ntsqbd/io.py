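"""Fixture bundle, table readers/writers, model serialization, pipeline config.

All tables travel as headered CSV (RFC-4180, '.' decimal).  Files store
purities as percent, matching how such tables are reported; the loaders
convert to fractions, which is the scale every model coefficient acts on.
Output tables carry '#'-prefixed header lines recording the package version,
the seed and a hash of the configuration, so identical configurations
reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from ._exceptions import ConfigError, CorruptFixtureError, DomainError
from .doe import DesignTable, FactorSpec
from .quality_metrics import MaterialBatch
from .screening import FitStats, ScreeningModel

_DATA = resources.files("ntsqbd") / "data"

#: Fixture responses: stored percent column -> (fraction column, divisor).
RESPONSE_COLUMNS = {"rd_purity": "SP5_pct", "total_saponin_purity": "TSP_pct"}

DEFAULT_CANDIDATES = [f"X{i}" for i in range(1, 11)] + [f"Z{k}" for k in range(1, 7)]


def _read_bundled(name: str) -> str:
    return (_DATA / name).read_text()


def _verify_checksums() -> None:
    expected = json.loads(_read_bundled("checksums.json"))
    for fname, digest in expected.items():
        actual = hashlib.sha256(_read_bundled(fname).encode()).hexdigest()
        if actual != digest:
            raise CorruptFixtureError(
                f"bundled fixture {fname} is corrupt "
                f"(sha256 {actual[:12]}... != {digest[:12]}...)")


def load_factor_specs() -> dict[str, FactorSpec]:
    df = pd.read_csv((_DATA / "factors.csv").open())
    return {row.symbol: FactorSpec(row.symbol, row.name, row.units,
                                   float(row.low), float(row.mid), float(row.high))
            for row in df.itertuples()}


def load_reference_models() -> dict[str, ScreeningModel]:
    """The published screening models (coefficients as printed)."""
    raw = json.loads(_read_bundled("reference_models.json"))
    out = {}
    for cqa, m in raw.items():
        out[cqa] = ScreeningModel(
            response=m["response"], intercept=float(m["intercept"]),
            coefficients={k: float(v) for k, v in m["coefficients"].items()},
            scale=m["scale"],
            stats=FitStats(r2=float(m["r2"]), adj_r2=float(m["adj_r2"]),
                           model_p=1e-4, coef_p=dict(m["p_values"]),
                           resid_sd=float("nan"), nobs=32,
                           df_resid=32 - 1 - len(m["coefficients"])))
    return out


@dataclass
class Fixtures:
    """The bundled experimental tables as typed objects."""

    factors: dict[str, FactorSpec]
    design: DesignTable
    batches: list[MaterialBatch]
    responses: pd.DataFrame                  # percent, as stored
    reference_models: dict[str, ScreeningModel]
    grading_batches: pd.DataFrame


def load_fixtures() -> Fixtures:
    """Load and checksum-verify the bundled study tables."""
    _verify_checksums()
    factors = load_factor_specs()
    design_df = pd.read_csv((_DATA / "design.csv").open())
    design = DesignTable.from_frame(design_df, factors)
    bdf = pd.read_csv((_DATA / "batches.csv").open())
    batches = [MaterialBatch(row.batch_id,
                             (row.Z1, row.Z2, row.Z3, row.Z4, row.Z5, row.Z6))
               for row in bdf.itertuples()]
    responses = pd.read_csv((_DATA / "responses.csv").open())
    grading = pd.read_csv((_DATA / "grading_batches.csv").open())
    known = {b.batch_id for b in batches}
    missing = {r.batch_id for r in design.runs} - known
    if missing:
        raise CorruptFixtureError(f"design references unknown batches {missing}")
    return Fixtures(factors=factors, design=design, batches=batches,
                    responses=responses,
                    reference_models=load_reference_models(),
                    grading_batches=grading)


def joined_dataset(fixtures: Fixtures | None = None) -> pd.DataFrame:
    """Runs joined with material attributes and fraction-scale CQA columns."""
    fx = fixtures or load_fixtures()
    zrows = pd.DataFrame([{"batch_id": b.batch_id, **b.as_dict()}
                          for b in fx.batches])
    df = (fx.design.to_frame().merge(zrows, on="batch_id")
          .merge(fx.responses, on="run_id")
          .sort_values("run_id").reset_index(drop=True))
    for cqa, col in RESPONSE_COLUMNS.items():
        df[cqa] = df[col] / 100.0
    return df


# ---------------------------------------------------------------------------
# model (de)serialization

def model_to_dict(model: ScreeningModel) -> dict[str, Any]:
    d: dict[str, Any] = {
        "response": model.response,
        "intercept": model.intercept,
        "coefficients": dict(model.coefficients),
        "scale": model.scale,
    }
    if model.stats is not None:
        s = model.stats
        d["fit_stats"] = {"r2": s.r2, "adj_r2": s.adj_r2, "model_p": s.model_p,
                          "coef_p": s.coef_p, "resid_sd": s.resid_sd,
                          "nobs": s.nobs, "df_resid": s.df_resid}
    return d


def model_from_dict(d: Mapping[str, Any],
                    factors: Mapping[str, FactorSpec] | None = None) -> ScreeningModel:
    stats = None
    if "fit_stats" in d:
        s = d["fit_stats"]
        stats = FitStats(r2=s["r2"], adj_r2=s["adj_r2"], model_p=s["model_p"],
                         coef_p=dict(s["coef_p"]), resid_sd=s["resid_sd"],
                         nobs=s["nobs"], df_resid=s["df_resid"])
    return ScreeningModel(response=d["response"], intercept=float(d["intercept"]),
                          coefficients={k: float(v)
                                        for k, v in d["coefficients"].items()},
                          scale=d.get("scale", ""), stats=stats,
                          factor_specs=dict(factors) if factors else None)


def write_models(models: Mapping[str, ScreeningModel], path: Path) -> None:
    payload = {cqa: model_to_dict(m) for cqa, m in models.items()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_models(path: Path,
                factors: Mapping[str, FactorSpec] | None = None
                ) -> dict[str, ScreeningModel]:
    payload = json.loads(Path(path).read_text())
    return {cqa: model_from_dict(d, factors) for cqa, d in payload.items()}


# ---------------------------------------------------------------------------
# provenance-stamped tables

def write_table(df: pd.DataFrame, path: Path, meta: Mapping[str, Any]) -> None:
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    body = df.to_csv(index=False, lineterminator="\n")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else "") + body)


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def config_hash(obj: Any) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def provenance(seed, cfg) -> dict[str, Any]:
    return {"ntsqbd_version": __version__, "seed": seed,
            "config_sha256": config_hash(cfg)}


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Everything one end-to-end analysis needs; omitted paths use fixtures."""

    design_csv: str | None = None
    batches_csv: str | None = None
    responses_csv: str | None = None
    grading_csv: str | None = None
    candidates: list[str] = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    limits: dict[str, float] = field(
        default_factory=lambda: {"rd_purity": 0.035,
                                 "total_saponin_purity": 0.85})
    n_sim: int = 1000
    rsd: float = 0.04
    seed: int = 0
    threshold: float = 0.90
    grid_steps: dict[str, float] = field(
        default_factory=lambda: {"X1": 1.0, "X9": 1.0, "X10": 5.0})
    fixed_process: dict[str, float] | None = None
    design_space_materials: list[str] = field(default_factory=lambda: ["PN20"])
    out_dir: str = "ntsqbd_out"

    def __post_init__(self):
        for cqa, bound in self.limits.items():
            if not 0.0 <= bound <= 1.0:
                raise ConfigError(
                    f"limit for {cqa} must be a fraction in [0, 1], got {bound}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config {path} must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
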