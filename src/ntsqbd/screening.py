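"""Screening regression: identify critical process parameters and material
attributes, then build the predictive models for the process CQAs.

Each process CQA (here: ginsenoside Rd purity and total saponin purity of
the eluate, both as fractions) is modelled as a linear function of the ten
uncoded process parameters X1..X10 and the six material attributes Z1..Z6:

    Y = a0 + sum_i b_i X_i + sum_k c_k Z_k

Bidirectional stepwise selection at alpha = 0.05 (for both entry and
removal) prunes this to the significant terms; every retained X main effect
is a CPP, every retained Z main effect a CMA.  A second pass augments the
candidate set with squares and pairwise interactions of the retained CPPs
(built on the coded scale, where they are near-orthogonal to the main
effects) and re-runs the selection.

Selection starts from the full model by default.  The material attributes
are strongly inter-correlated (good lots are rich in every saponin), and a
forward search from the empty model latches onto the extractable dry matter
as a proxy for the saponin sum; eliminating from the full model resolves the
collinearity in favour of the individually significant attributes.

Ordinary least squares, ANOVA and partial t-tests are delegated to
statsmodels.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._exceptions import DomainError, SingularModelError
from .doe import FactorSpec, code

#: Canonical CQA names used across the pipeline.
CQA_RD_PURITY = "rd_purity"
CQA_TOTAL_SAPONIN_PURITY = "total_saponin_purity"

_TERM_RE = re.compile(r"^(X(\d+)|Z(\d+)|X(\d+)\^2|X(\d+)\*X(\d+))$")


@dataclass(frozen=True)
class ModelTerm:
    """A candidate regression term.

    ``kind`` is one of ``main_x``, ``main_z``, ``square``, ``interaction``;
    squares and interactions are defined over process parameters only and
    are evaluated on the coded factor scale.
    """

    kind: str
    indices: tuple[int, ...]

    @property
    def name(self) -> str:
        if self.kind == "main_x":
            return f"X{self.indices[0]}"
        if self.kind == "main_z":
            return f"Z{self.indices[0]}"
        if self.kind == "square":
            return f"X{self.indices[0]}^2"
        return f"X{self.indices[0]}*X{self.indices[1]}"

    @classmethod
    def parse(cls, name: str) -> "ModelTerm":
        m = _TERM_RE.match(name.replace(" ", ""))
        if not m:
            raise DomainError(f"unparseable model term {name!r}")
        if m.group(2):
            return cls("main_x", (int(m.group(2)),))
        if m.group(3):
            return cls("main_z", (int(m.group(3)),))
        if m.group(4):
            return cls("square", (int(m.group(4)),))
        i, j = sorted((int(m.group(5)), int(m.group(6))))
        return cls("interaction", (i, j))


@dataclass
class FitStats:
    """Ordinary ANOVA summary of a fitted screening model."""

    r2: float
    adj_r2: float
    model_p: float
    coef_p: dict[str, float]
    resid_sd: float
    nobs: int
    df_resid: int
    coef_se: dict[str, float] | None = None


@dataclass
class ScreeningModel:
    """A fitted (or transcribed) linear model for one process CQA.

    Coefficients act on uncoded X (physical units), Z in mg/g, and produce
    the CQA as a fraction.  Square/interaction coefficients, when present,
    act on coded products and need ``factor_specs`` to be evaluated.
    """

    response: str
    intercept: float
    coefficients: dict[str, float]
    scale: str = "uncoded-X, Z in mg/g, Y as fraction"
    stats: FitStats | None = None
    factor_specs: dict[str, FactorSpec] | None = None

    @property
    def terms(self) -> list[ModelTerm]:
        return [ModelTerm.parse(t) for t in self.coefficients]

    @property
    def x_terms(self) -> list[str]:
        return [t.name for t in self.terms if t.kind == "main_x"]

    @property
    def z_terms(self) -> list[str]:
        return [t.name for t in self.terms if t.kind == "main_z"]

    @property
    def is_linear(self) -> bool:
        return all(t.kind in ("main_x", "main_z") for t in self.terms)


@dataclass(frozen=True)
class CriticalSet:
    """Union of retained main effects across all CQA models."""

    cpps: tuple[str, ...]
    cmas: tuple[str, ...]


def term_column(data: pd.DataFrame, term: ModelTerm,
                factors: Mapping[str, FactorSpec] | None = None) -> np.ndarray:
    """Evaluate one term for every row of ``data``."""
    if term.kind in ("main_x", "main_z"):
        try:
            return data[term.name].to_numpy(dtype=float)
        except KeyError:
            raise DomainError(f"column {term.name} missing from data") from None
    if factors is None:
        raise DomainError(
            f"factor specs required to evaluate coded term {term.name}")
    cols = []
    for idx in term.indices:
        sym = f"X{idx}"
        spec = factors[sym]
        cols.append(np.asarray(code(spec, data[sym].to_numpy(dtype=float))))
    if term.kind == "square":
        return cols[0] ** 2
    return cols[0] * cols[1]


def design_matrix(data: pd.DataFrame, terms: Sequence[ModelTerm | str],
                  factors: Mapping[str, FactorSpec] | None = None
                  ) -> tuple[np.ndarray, list[str]]:
    """Intercept-plus-terms design matrix for OLS."""
    parsed = [t if isinstance(t, ModelTerm) else ModelTerm.parse(t) for t in terms]
    cols = [np.ones(len(data))]
    for t in parsed:
        cols.append(term_column(data, t, factors))
    return np.column_stack(cols), [t.name for t in parsed]


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise SingularModelError(names, rank, X.shape[1])
    return sm.OLS(y, X).fit()


def _stats_from(res, names: list[str]) -> FitStats:
    coef_p = {n: float(p) for n, p in zip(names, res.pvalues[1:])}
    model_p = float(res.f_pvalue) if names else float("nan")
    return FitStats(
        r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
        model_p=model_p, coef_p=coef_p,
        resid_sd=float(np.sqrt(res.mse_resid)),
        nobs=int(res.nobs), df_resid=int(res.df_resid),
        coef_se={n: float(s) for n, s in zip(names, res.bse[1:])})


def fit_fixed(data: pd.DataFrame, response: str,
              terms: Sequence[ModelTerm | str],
              factors: Mapping[str, FactorSpec] | None = None) -> ScreeningModel:
    """OLS of ``response`` on exactly the given terms (plus intercept)."""
    y = data[response].to_numpy(dtype=float)
    X, names = design_matrix(data, terms, factors)
    if len(y) < X.shape[1] + 1:
        raise DomainError(
            f"{len(y)} observations cannot support {X.shape[1]} parameters")
    res = _ols(y, X, names)
    coefs = {n: float(b) for n, b in zip(names, res.params[1:])}
    return ScreeningModel(
        response=response, intercept=float(res.params[0]), coefficients=coefs,
        stats=_stats_from(res, names),
        factor_specs=dict(factors) if factors else None)


def _check_candidates(data: pd.DataFrame, response: str,
                      candidates: list[ModelTerm],
                      factors: Mapping[str, FactorSpec] | None) -> None:
    for t in candidates:
        col = term_column(data, t, factors)
        if np.ptp(col) == 0:
            raise DomainError(f"candidate term {t.name} is constant")
    z_terms = [t for t in candidates if t.kind == "main_z"]
    if "batch_id" in data.columns and z_terms:
        if data["batch_id"].nunique() < len(z_terms):
            warnings.warn(
                f"only {data['batch_id'].nunique()} distinct material batches "
                f"for {len(z_terms)} Z candidates; Z columns risk collinearity",
                stacklevel=2)


def stepwise_fit(data: pd.DataFrame, response: str,
                 candidates: Sequence[ModelTerm | str],
                 alpha_enter: float = 0.05, alpha_remove: float = 0.05,
                 start: str = "full",
                 factors: Mapping[str, FactorSpec] | None = None) -> ScreeningModel:
    """Bidirectional p-value stepwise selection followed by a final OLS fit.

    Each cycle first purges included terms whose partial t-test p-value
    exceeds ``alpha_remove`` (worst first), then admits the excluded
    candidate with the smallest p-value if it is below ``alpha_enter``.
    Ties break toward the earlier candidate in the supplied order.  The
    intercept is always included.  A visited-state guard makes add/drop
    cycling impossible.

    ``start`` is ``"full"`` (default: begin from all candidates, resolving
    collinear candidate sets by elimination) or ``"empty"`` (classic forward
    first).
    """
    cand = [t if isinstance(t, ModelTerm) else ModelTerm.parse(t)
            for t in candidates]
    if len(set(t.name for t in cand)) != len(cand):
        raise DomainError("duplicate candidate terms")
    _check_candidates(data, response, cand, factors)
    y = data[response].to_numpy(dtype=float)
    if start not in ("full", "empty"):
        raise DomainError(f"unknown start {start!r}")
    included = list(range(len(cand))) if start == "full" else []
    if len(y) < len(included) + 3:
        raise DomainError(
            f"{len(y)} observations cannot support stepwise over "
            f"{len(included)} simultaneous terms")

    def fit_subset(idx: list[int]):
        terms = [cand[j] for j in idx]
        X, names = design_matrix(data, terms, factors)
        return _ols(y, X, names)

    seen: set[tuple[int, ...]] = set()
    while True:
        changed = False
        # backward purge: drop worst p > alpha_remove, one at a time
        while included:
            res = fit_subset(included)
            pv = res.pvalues[1:]
            worst = int(np.argmax(pv))
            if pv[worst] > alpha_remove:
                included.pop(worst)
                changed = True
            else:
                break
        # forward step: admit best p < alpha_enter
        best_j, best_p = None, np.inf
        for j in range(len(cand)):
            if j in included:
                continue
            if len(y) < len(included) + 4:
                break
            res = fit_subset(included + [j])
            p = float(res.pvalues[-1])
            if p < best_p:
                best_j, best_p = j, p
        if best_j is not None and best_p < alpha_enter:
            state = tuple(sorted(included + [best_j]))
            if state not in seen:
                seen.add(state)
                included.append(best_j)
                changed = True
        if not changed:
            break
    return fit_fixed(data, response, [cand[j] for j in sorted(included)], factors)


def augment_and_refit(model: ScreeningModel, data: pd.DataFrame,
                      factors: Mapping[str, FactorSpec],
                      alpha_enter: float = 0.05,
                      alpha_remove: float = 0.05) -> ScreeningModel:
    """Add squares and pairwise interactions of the retained CPPs and re-select.

    The augmented candidate set is the model's retained terms plus, for its
    CPPs, all squares and pairwise interaction products on the coded scale.
    """
    cpps = model.x_terms
    if not cpps:
        raise DomainError("model retains no process parameter to augment")
    cand: list[str] = list(model.coefficients)
    idx = [ModelTerm.parse(t).indices[0] for t in cpps]
    for i in idx:
        cand.append(f"X{i}^2")
    for i, j in itertools.combinations(idx, 2):
        cand.append(f"X{i}*X{j}")
    return stepwise_fit(data, model.response, cand, alpha_enter=alpha_enter,
                        alpha_remove=alpha_remove, start="full",
                        factors=factors)


def predict(model: ScreeningModel, x: Mapping[str, float],
            z: Mapping[str, float]) -> float:
    """Evaluate the model at uncoded process settings ``x`` and attributes ``z``."""
    total = model.intercept
    for term in model.terms:
        b = model.coefficients[term.name]
        if term.kind == "main_x":
            src, key = x, term.name
            if key not in src:
                raise DomainError(f"missing process parameter {key}")
            total += b * float(src[key])
        elif term.kind == "main_z":
            if term.name not in z:
                raise DomainError(f"missing material attribute {term.name}")
            total += b * float(z[term.name])
        else:
            if model.factor_specs is None:
                raise DomainError(
                    f"model has coded term {term.name} but no factor specs")
            vals = []
            for i in term.indices:
                sym = f"X{i}"
                if sym not in x:
                    raise DomainError(f"missing process parameter {sym}")
                vals.append(code(model.factor_specs[sym], float(x[sym])))
            total += b * (vals[0] ** 2 if term.kind == "square"
                          else vals[0] * vals[1])
    return total


def predict_frame(model: ScreeningModel, data: pd.DataFrame) -> np.ndarray:
    """Vectorised prediction over the rows of ``data``."""
    X, _ = design_matrix(data, list(model.coefficients), model.factor_specs)
    beta = np.concatenate([[model.intercept],
                           [model.coefficients[t] for t in model.coefficients]])
    return X @ beta


def identify_critical(models: Iterable[ScreeningModel]) -> CriticalSet:
    """CPPs and CMAs: unions of retained X and Z main effects across CQAs."""
    xs: set[int] = set()
    zs: set[int] = set()
    for m in models:
        for t in m.terms:
            if t.kind == "main_x":
                xs.add(t.indices[0])
            elif t.kind == "main_z":
                zs.add(t.indices[0])
    return CriticalSet(cpps=tuple(f"X{i}" for i in sorted(xs)),
                       cmas=tuple(f"Z{k}" for k in sorted(zs)))
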