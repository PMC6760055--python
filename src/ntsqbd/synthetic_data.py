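"""Synthetic material lots, extraction records and DSD response data.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage can be exercised end to end without laboratory data:

* material lots with attributes Z1..Z6 drawn within the observed spans of
  the characterised lots (rejection-sampled so the saponins never outweigh
  the extractable dry matter), independently by default or tied to a single
  latent "lot richness" factor to mimic the strong inter-saponin
  correlation of real lots;
* pooled extraction records constructed to invert the characterisation
  formulas exactly (round-tripping a lot through a record recovers its Z);
* CQA responses from a linear truth model with multiplicative Gaussian
  noise of relative SD 0.04, truncated to stay positive — the same error
  model the Monte Carlo design-space computation assumes.

Default truth coefficients are the published screening models bundled with
the package; the default run layout is the bundled 32-run DSD with lots
re-assigned at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, DomainError
from .quality_metrics import ExtractionRecord, MaterialBatch
from .screening import ModelTerm, ScreeningModel

#: Observed spans of the sixteen characterised lots, mg/g.
DEFAULT_Z_RANGES = {
    "Z1": (7.2, 16.0),
    "Z2": (32.0, 59.0),
    "Z3": (3.2, 8.4),
    "Z4": (29.0, 53.0),
    "Z5": (5.0, 14.2),
    "Z6": (185.0, 387.0),
}

_MAX_REJECT = 0.99


def _default_truth() -> dict[str, ScreeningModel]:
    from .io import load_reference_models
    return load_reference_models()


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic data generator."""

    n_batches: int = 16
    z_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_Z_RANGES.items()})
    truth: dict[str, ScreeningModel] | None = None   # None: bundled models
    rsd: float = 0.04
    seed: int | None = None
    correlated: bool = False
    latent_weight: float = 0.7

    def __post_init__(self):
        if self.n_batches < 1:
            raise ConfigError("n_batches must be >= 1")
        if self.rsd < 0:
            raise ConfigError("rsd must be >= 0")
        for k, (lo, hi) in self.z_ranges.items():
            if not 0 <= lo < hi:
                raise ConfigError(f"invalid range for {k}: ({lo}, {hi})")

    def resolved_truth(self) -> dict[str, ScreeningModel]:
        return self.truth if self.truth is not None else _default_truth()


@dataclass
class SyntheticDataset:
    """A complete simulated study: lots, run table, responses, and the truth."""

    batches: list[MaterialBatch]
    design: pd.DataFrame            # run_id, batch_id, X1..X10 (uncoded)
    responses: pd.DataFrame         # run_id + one fraction column per CQA
    truth: dict[str, ScreeningModel]

    def joined(self) -> pd.DataFrame:
        zrows = pd.DataFrame([{"batch_id": b.batch_id, **b.as_dict()}
                              for b in self.batches])
        return (self.design.merge(zrows, on="batch_id")
                .merge(self.responses, on="run_id")
                .sort_values("run_id").reset_index(drop=True))


def generate_batches(spec: GeneratorSpec, rng=None) -> list[MaterialBatch]:
    """Draw lots uniformly within the configured spans.

    Rejection keeps sum(Z1..Z5) <= Z6; with the default spans the constraint
    is never active, but tight configurations are guarded by a rejection-rate
    cap.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(
        rng if rng is not None else spec.seed)
    keys = [f"Z{k}" for k in range(1, 7)]
    lo = np.array([spec.z_ranges[k][0] for k in keys])
    hi = np.array([spec.z_ranges[k][1] for k in keys])
    out: list[MaterialBatch] = []
    attempts = 0
    while len(out) < spec.n_batches:
        attempts += 1
        if attempts > 100 and 1 - len(out) / attempts > _MAX_REJECT:
            raise ConfigError(
                "z_ranges are nearly infeasible under sum(Z1..Z5) <= Z6 "
                f"(rejection rate > {_MAX_REJECT:.0%})")
        if spec.correlated:
            f = rng.uniform()
            u = (spec.latent_weight * f
                 + (1 - spec.latent_weight) * rng.uniform(size=6))
            z = lo + u * (hi - lo)
        else:
            z = rng.uniform(lo, hi)
        if z[:5].sum() <= z[5]:
            out.append(MaterialBatch(f"SYN{len(out) + 1}", tuple(z)))
    return out


def generate_extraction_record(batch: MaterialBatch,
                               material_mass: float = 100.0,
                               extract_mass: float = 500.0) -> ExtractionRecord:
    """Construct the pooled extraction record that characterises ``batch``.

    Concentrations are set so that the characterisation formulas recover the
    lot's Z1..Z6 exactly (to machine precision).
    """
    if material_mass <= 0 or extract_mass <= 0:
        raise DomainError("masses must be > 0")
    dm = batch.z[5] * material_mass / (1000.0 * extract_mass)
    if dm > 1.0:
        raise ConfigError(
            f"implied dry matter concentration {dm:.3f} g/g > 1; "
            "increase extract_mass or reduce material_mass")
    sc = tuple(zi * material_mass / extract_mass for zi in batch.z[:5])
    return ExtractionRecord(material_mass=material_mass,
                            extract_mass=extract_mass,
                            extract_dry_matter_conc=dm,
                            extract_saponin_conc=sc)


def generate_responses(design: pd.DataFrame, batches: Sequence[MaterialBatch],
                       truth: Mapping[str, ScreeningModel], rsd: float,
                       seed=None) -> pd.DataFrame:
    """Simulate CQA responses: y = (a0 + sum b_i X_i + sum c_k Z_k)(1 + eps).

    eps ~ Normal(0, rsd), redrawn for any draw that would leave y <= 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zmap = {b.batch_id: b.as_dict() for b in batches}
    missing = set(design["batch_id"]) - set(zmap)
    if missing:
        raise DomainError(f"design references unknown batches: {sorted(missing)}")
    rows = design.merge(
        pd.DataFrame([{"batch_id": k, **v} for k, v in zmap.items()]),
        on="batch_id")
    out = {"run_id": rows["run_id"].to_numpy()}
    for cqa, model in truth.items():
        for t in model.terms:
            if t.name not in rows.columns:
                raise DomainError(
                    f"truth model for {cqa} uses {t.name}, absent from design")
        mu = np.full(len(rows), model.intercept)
        for t in model.terms:
            mu = mu + model.coefficients[t.name] * rows[t.name].to_numpy(dtype=float)
        if np.any(mu <= 0) and rsd > 0:
            raise DomainError(
                f"truth model for {cqa} predicts non-positive means; "
                "relative noise is undefined there")
        y = mu * (1.0 + rng.normal(0.0, rsd, size=mu.shape))
        bad = y <= 0
        while np.any(bad):
            y[bad] = mu[bad] * (1.0 + rng.normal(0.0, rsd, size=int(bad.sum())))
            bad = y <= 0
        out[cqa] = y
    return pd.DataFrame(out)


def generate_dataset(spec: GeneratorSpec) -> SyntheticDataset:
    """One full simulated study on the bundled DSD run layout."""
    from .io import load_fixtures

    rng = np.random.default_rng(spec.seed)
    batches = generate_batches(spec, rng)
    design = load_fixtures().design.to_frame().copy()
    ids = [b.batch_id for b in batches]
    design["batch_id"] = rng.choice(ids, size=len(design))
    truth = spec.resolved_truth()
    responses = generate_responses(design, batches, truth, spec.rsd, rng)
    return SyntheticDataset(batches=batches, design=design,
                            responses=responses, truth=truth)
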