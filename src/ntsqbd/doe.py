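"""The ten-factor definitive screening design (DSD) and factor coding.

Ten process parameters across four unit operations (ethanol extraction,
concentration, water precipitation, resin chromatography) are varied on
three levels each.  Factor levels are stored uncoded (physical units) and
mapped to the coded scale [-1, +1] by the affine transform low -> -1,
mid -> 0, high -> +1.

The design itself is data, not something this module constructs: the
packaged 32-run table is loaded from the fixture bundle, or a user supplies
their own.  ``validate_dsd`` checks the structural fingerprints of a DSD —
center replicates, the one-mid-level-factor property of the classic DSD
rows, and fold-over pairing (every non-center run mirrored by its coded
negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import DomainError, RangeError

FACTOR_SYMBOLS = tuple(f"X{i}" for i in range(1, 11))

_CODED_TOL = 1e-9


@dataclass(frozen=True)
class FactorSpec:
    """One process parameter with its three investigated levels."""

    symbol: str
    name: str
    units: str
    low: float
    mid: float
    high: float

    def __post_init__(self):
        if not self.low < self.mid < self.high:
            raise DomainError(
                f"{self.symbol}: need low < mid < high, got "
                f"({self.low}, {self.mid}, {self.high})")

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0


def code(factor: FactorSpec, uncoded: float) -> float:
    """Map an uncoded level into [-1, +1]; low -> -1, mid -> 0, high -> +1."""
    x = np.asarray(uncoded, dtype=float)
    if np.any(x < factor.low - _CODED_TOL) or np.any(x > factor.high + _CODED_TOL):
        raise RangeError(
            f"{factor.symbol}={uncoded} outside investigated range "
            f"[{factor.low}, {factor.high}] {factor.units}")
    coded = (x - factor.mid) / factor.half_range
    return float(coded) if coded.ndim == 0 else coded


def uncode(factor: FactorSpec, coded: float) -> float:
    """Inverse of :func:`code`."""
    c = np.asarray(coded, dtype=float)
    if np.any(np.abs(c) > 1 + _CODED_TOL):
        raise RangeError(f"{factor.symbol}: coded value {coded} outside [-1, 1]")
    x = factor.mid + c * factor.half_range
    return float(x) if x.ndim == 0 else x


@dataclass(frozen=True)
class ProcessRun:
    """One experimental run: a material lot processed at uncoded settings."""

    run_id: int
    batch_id: str
    x: dict[str, float]

    def coded(self, specs: dict[str, FactorSpec]) -> dict[str, float]:
        return {s: code(specs[s], v) for s, v in self.x.items()}


@dataclass
class DesignTable:
    """An ordered run table together with its factor specifications."""

    runs: list[ProcessRun]
    factor_specs: dict[str, FactorSpec]

    def __post_init__(self):
        for run in self.runs:
            for sym, v in run.x.items():
                spec = self.factor_specs.get(sym)
                if spec is None:
                    raise DomainError(f"run {run.run_id}: unknown factor {sym}")
                if not spec.low - _CODED_TOL <= v <= spec.high + _CODED_TOL:
                    raise RangeError(
                        f"run {run.run_id}: {sym}={v} outside "
                        f"[{spec.low}, {spec.high}]")

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(self.factor_specs)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"run_id": r.run_id, "batch_id": r.batch_id, **r.x}
                for r in self.runs]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   factor_specs: dict[str, FactorSpec]) -> "DesignTable":
        syms = [s for s in factor_specs if s in df.columns]
        runs = [ProcessRun(int(row["run_id"]), str(row["batch_id"]),
                           {s: float(row[s]) for s in syms})
                for _, row in df.iterrows()]
        return cls(runs=runs, factor_specs=factor_specs)

    def coded_matrix(self) -> np.ndarray:
        out = np.empty((len(self.runs), len(self.factor_specs)))
        for i, run in enumerate(self.runs):
            for j, sym in enumerate(self.factor_specs):
                out[i, j] = code(self.factor_specs[sym], run.x[sym])
        return out


@dataclass
class DsdValidationReport:
    """Structural report on a candidate definitive screening design.

    Report-only: deviations are listed, never raised, because augmented DSDs
    (extra fold-over pairs, as in the packaged design) legitimately break the
    one-mid-factor rule on their added rows.
    """

    n_runs: int
    center_runs: list[int]
    mid_counts: dict[int, int] = field(repr=False)
    one_mid_violations: list[int] = field(default_factory=list)
    foldover_partner: dict[int, int | None] = field(default_factory=dict, repr=False)
    unpaired_runs: list[int] = field(default_factory=list)

    @property
    def n_center(self) -> int:
        return len(self.center_runs)

    @property
    def foldover_complete(self) -> bool:
        return not self.unpaired_runs


def validate_dsd(design: DesignTable) -> DsdValidationReport:
    """Enumerate center runs, mid-level counts and fold-over pairing."""
    if not design.runs:
        raise DomainError("cannot validate an empty design")
    coded = design.coded_matrix()
    ids = [r.run_id for r in design.runs]
    at_mid = np.abs(coded) <= _CODED_TOL
    mid_counts = {rid: int(c) for rid, c in zip(ids, at_mid.sum(axis=1))}
    k = coded.shape[1]
    center = [rid for rid, c in mid_counts.items() if c == k]
    noncenter = [rid for rid in ids if rid not in center]
    violations = [rid for rid in noncenter if mid_counts[rid] != 1]

    partner: dict[int, int | None] = {}
    rows = {rid: coded[i] for i, rid in enumerate(ids)}
    for rid in noncenter:
        mirror = None
        for other in noncenter:
            if other != rid and np.allclose(rows[other], -rows[rid], atol=_CODED_TOL):
                mirror = other
                break
        partner[rid] = mirror
    unpaired = [rid for rid, p in partner.items() if p is None]
    return DsdValidationReport(
        n_runs=len(ids), center_runs=center, mid_counts=mid_counts,
        one_mid_violations=violations, foldover_partner=partner,
        unpaired_runs=unpaired)
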