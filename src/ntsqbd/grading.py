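"""Raw-material grading from the fitted CQA models.

Substituting each CQA's lower specification limit into its linear model
turns the model into an acceptance inequality over process settings X and
material attributes Z.  Two grading modes follow:

* variable-parameter mode — a lot is *acceptable* if some process setting
  inside the investigated ranges satisfies every inequality simultaneously
  (an exact small linear feasibility problem, solved with HiGHS via
  scipy.optimize.linprog, returning a witness setting when feasible);
* fixed-parameter mode — with the plant's process settings frozen, the X
  terms fold into each inequality's constant, leaving inequalities over Z
  alone; a lot is *high quality* if it satisfies all of them and *low
  quality* (not to be released) otherwise.

Constants of the simplified inequalities are always recomputed from the
model coefficients rather than transcribed, and the boundary (zero slack)
counts as passing.  A mass-weighted blending helper supports reworking
low-quality lots into an acceptable mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from ._exceptions import DomainError
from .quality_metrics import MaterialBatch
from .screening import ModelTerm, ScreeningModel, predict
from .design_space import CqaLimit

_FEAS_TOL = 1e-9

#: Plant settings of the worked fixed-parameter example, on a 100 g material
#: basis (per-gram dosages scaled by the 100 g charge).
DEFAULT_FIXED_PROCESS = {
    "X1": 88.0, "X2": 6.0, "X3": 672.0, "X4": 131.0, "X5": 373.0,
    "X6": 1.7, "X7": 1.8, "X8": 2.0, "X9": 56.0, "X10": 133.0,
}


@dataclass(frozen=True)
class FixedProcess:
    """A frozen set of process parameters used by a parameter-fixing plant."""

    x: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_PROCESS))


@dataclass
class GradingInequality:
    """One CQA's acceptance inequality: x·b + z·c + a0 >= bound (fractions)."""

    cqa: str
    x_coeffs: dict[str, float]
    z_coeffs: dict[str, float]
    intercept: float
    bound: float

    def lhs(self, x: Mapping[str, float], z: Mapping[str, float]) -> float:
        total = self.intercept
        for sym, b in self.x_coeffs.items():
            if sym not in x:
                raise DomainError(f"missing process parameter {sym}")
            total += b * float(x[sym])
        for sym, c in self.z_coeffs.items():
            if sym not in z:
                raise DomainError(f"missing material attribute {sym}")
            total += c * float(z[sym])
        return total

    def slack(self, x: Mapping[str, float], z: Mapping[str, float]) -> float:
        return self.lhs(x, z) - self.bound


@dataclass
class SimplifiedInequality:
    """A grading inequality with the X terms folded into the constant.

    On the reporting scale: sum_k (scale*c_k) Z_k + constant >= 0, where
    constant = scale * (a0 + sum_i b_i X_i^fixed - bound).
    """

    cqa: str
    z_coeffs: dict[str, float]
    constant: float
    scale: float = 1.0

    def lhs(self, z: Mapping[str, float]) -> float:
        total = self.constant
        for sym, c in self.z_coeffs.items():
            if sym not in z:
                raise DomainError(f"missing material attribute {sym}")
            total += c * float(z[sym])
        return total

    def slack_fraction(self, z: Mapping[str, float]) -> float:
        """Slack on the CQA's own (fraction) scale."""
        return self.lhs(z) / self.scale


@dataclass
class GradeDecision:
    """Verdict for one lot, with the inequality slacks that justify it."""

    batch_id: str
    mode: str                      # "variable" | "fixed"
    verdict: str                   # "acceptable"/"unacceptable" | "high"/"low"
    slacks: dict[str, float]       # per-CQA slack, fraction scale
    witness_x: dict[str, float] | None = None

    @property
    def passed(self) -> bool:
        return self.verdict in ("acceptable", "high")


def derive_inequalities(models: Sequence[ScreeningModel],
                        limits: Sequence[CqaLimit]) -> list[GradingInequality]:
    """One inequality per CQA, coefficients taken verbatim from its model."""
    by_cqa = {m.response: m for m in models}
    out = []
    for limit in limits:
        model = by_cqa.get(limit.cqa)
        if model is None:
            raise DomainError(f"no model supplied for CQA {limit.cqa!r}")
        if not model.is_linear:
            raise DomainError(
                f"{limit.cqa}: grading inequalities require a linear model; "
                f"use the design-space grid for nonlinear models")
        out.append(GradingInequality(
            cqa=limit.cqa,
            x_coeffs={t: model.coefficients[t] for t in model.x_terms},
            z_coeffs={t: model.coefficients[t] for t in model.z_terms},
            intercept=model.intercept, bound=limit.bound))
    return out


def feasibility_variable(ineqs: Sequence[GradingInequality],
                         z: Mapping[str, float],
                         box: Mapping[str, tuple[float, float]],
                         batch_id: str = "") -> GradeDecision:
    """Can any process setting in ``box`` satisfy every inequality?

    Solved exactly as a linear program maximising the minimum slack over the
    box; the lot is acceptable iff the optimum slack is >= 0 (boundary
    included).  Returns the maximin witness setting when feasible.
    """
    syms = sorted({s for q in ineqs for s in q.x_coeffs},
                  key=lambda s: int(s[1:]))
    for s in syms:
        if s not in box:
            raise DomainError(f"box does not bound process parameter {s}")
        lo, hi = box[s]
        if not lo <= hi:
            raise DomainError(f"empty box for {s}: [{lo}, {hi}]")
    # variables v = (x_1..x_m, t); maximise t s.t. q.lhs(x, z) - bound >= t
    n = len(syms)
    c = np.zeros(n + 1)
    c[-1] = -1.0
    a_ub, b_ub = [], []
    for q in ineqs:
        row = np.zeros(n + 1)
        for j, s in enumerate(syms):
            row[j] = -q.x_coeffs.get(s, 0.0)
        row[-1] = 1.0
        const = q.intercept - q.bound
        for s, ck in q.z_coeffs.items():
            if s not in z:
                raise DomainError(f"missing material attribute {s}")
            const += ck * float(z[s])
        a_ub.append(row)
        b_ub.append(const)
    bounds = [box[s] for s in syms] + [(None, None)]
    res = linprog(c, A_ub=np.array(a_ub), b_ub=np.array(b_ub), bounds=bounds,
                  method="highs")
    if not res.success:
        raise DomainError(f"feasibility LP failed: {res.message}")
    t_opt = -res.fun
    witness = {s: float(v) for s, v in zip(syms, res.x[:n])}
    feasible = t_opt >= -_FEAS_TOL
    slacks = {q.cqa: q.slack(witness, z) for q in ineqs}
    return GradeDecision(
        batch_id=batch_id, mode="variable",
        verdict="acceptable" if feasible else "unacceptable",
        slacks=slacks, witness_x=witness if feasible else None)


def simplify_fixed(ineqs: Sequence[GradingInequality], fixed: FixedProcess,
                   scale: float = 1.0) -> list[SimplifiedInequality]:
    """Fold fixed process settings into each inequality's constant.

    ``scale`` is a pure reporting multiplier (e.g. 1e5 turns a Z5
    coefficient of 3.971e-3 into the printed 397.1); it cancels out of every
    grading verdict.
    """
    out = []
    for q in ineqs:
        const = q.intercept - q.bound
        for s, b in q.x_coeffs.items():
            if s not in fixed.x:
                raise DomainError(f"fixed process does not set {s}")
            const += b * float(fixed.x[s])
        out.append(SimplifiedInequality(
            cqa=q.cqa,
            z_coeffs={s: c * scale for s, c in q.z_coeffs.items()},
            constant=const * scale, scale=scale))
    return out


def classify_fixed(simplified: Sequence[SimplifiedInequality],
                   batch: MaterialBatch | Mapping[str, float],
                   batch_id: str = "") -> GradeDecision:
    """High quality iff every simplified inequality holds (zero slack passes)."""
    if isinstance(batch, MaterialBatch):
        z = batch.as_dict()
        batch_id = batch_id or batch.batch_id
    else:
        z = dict(batch)
    slacks = {q.cqa: q.slack_fraction(z) for q in simplified}
    ok = all(s >= 0.0 for s in slacks.values())
    return GradeDecision(batch_id=batch_id, mode="fixed",
                         verdict="high" if ok else "low", slacks=slacks)


def decision_slack_identity(model: ScreeningModel, limit: CqaLimit,
                            fixed: FixedProcess,
                            z: Mapping[str, float]) -> float:
    """Reference slack: model prediction at the fixed settings minus the bound."""
    return predict(model, fixed.x, z) - limit.bound


def blend(batches: Sequence[MaterialBatch],
          masses: Sequence[float]) -> MaterialBatch:
    """Mass-weighted mixture of lots; grading then applies to the blend."""
    if len(batches) != len(masses) or not batches:
        raise DomainError("need one positive mass per blended batch")
    w = np.asarray(masses, dtype=float)
    if np.any(w <= 0):
        raise DomainError("blend masses must be > 0")
    w = w / w.sum()
    z = tuple(float(np.dot(w, [b.z[k] for b in batches])) for k in range(6))
    name = "+".join(b.batch_id for b in batches)
    return MaterialBatch(batch_id=name, z=z)
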