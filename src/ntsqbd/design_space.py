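"""Monte Carlo probability-based design space over the CPP box.

Experimental error is propagated into the design space by resampling the
measured CQA responses: each observed value y is replaced by a draw from
Normal(mean = y, sd = rsd * y) with rsd = 0.04 by default, the CQA models
are refitted by OLS on their fixed, previously selected term sets, and the
refitted models are evaluated over a grid of candidate process settings for
one material's attributes.  A grid cell's probability is the fraction of
simulations (1000 by default) in which every CQA limit is met; the design
space is the cell set with probability >= 0.90.

The refits reuse the selected term sets rather than re-running the
selection — each simulation yields a new *equation*, not a new model form.
Because only the responses are perturbed, the design matrix is constant
across simulations and the 1000 refits reduce to a single pseudoinverse
applied to a response matrix, which keeps the full grid computation well
under a second.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import DomainError
from .doe import FactorSpec
from .screening import (CQA_RD_PURITY, CQA_TOTAL_SAPONIN_PURITY, ModelTerm,
                        design_matrix)

#: Lower CQA limits from the notoginseng-total-saponin standard, as fractions.
DEFAULT_LIMITS = {CQA_RD_PURITY: 0.035, CQA_TOTAL_SAPONIN_PURITY: 0.85}

DEFAULT_THRESHOLD = 0.90


@dataclass(frozen=True)
class CqaLimit:
    """A one-sided lower specification limit on a CQA (as a fraction)."""

    cqa: str
    bound: float

    def __post_init__(self):
        if not 0.0 <= self.bound <= 1.0:
            raise DomainError(f"{self.cqa}: bound must be a fraction in [0, 1]")


@dataclass
class SimulationSpec:
    """Monte Carlo settings: noise level, replication count, seed, term sets."""

    refit_terms: dict[str, list[str]]
    n_sim: int = 1000
    rsd: float = 0.04
    seed: int | None = None

    def __post_init__(self):
        if self.n_sim < 1:
            raise DomainError("n_sim must be >= 1")
        if self.rsd < 0:
            raise DomainError("rsd must be >= 0")


@dataclass
class ProbabilityGrid:
    """Acceptance probability over a CPP grid for one material's attributes."""

    axes: dict[str, np.ndarray]
    fixed_z: dict[str, float]
    prob: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    n_sim: int = 0
    seed: int | None = None

    @property
    def mask(self) -> np.ndarray:
        """Design-space membership: probability >= threshold."""
        return self.prob >= self.threshold


def perturb_responses(responses, rsd: float, seed=None) -> np.ndarray:
    """Resample measured responses: y -> Normal(mean=y, sd=rsd*y), elementwise.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if rsd < 0:
        raise DomainError("rsd must be >= 0")
    y = np.asarray(responses, dtype=float)
    if np.any(y <= 0):
        raise DomainError("responses must be > 0 for relative-error resampling")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return y * (1.0 + rng.normal(0.0, rsd, size=y.shape))


def default_cpp_grid(factors: Mapping[str, FactorSpec],
                     steps: Mapping[str, float] | None = None
                     ) -> dict[str, np.ndarray]:
    """Uncoded grid over the three CPPs: 1 v/v-% steps on the two ethanol
    concentrations and 5-min steps on elution time (11 x 11 x 13 points)."""
    steps = dict(steps or {"X1": 1.0, "X9": 1.0, "X10": 5.0})
    grid = {}
    for sym, step in steps.items():
        f = factors[sym]
        n = int(round((f.high - f.low) / step)) + 1
        grid[sym] = np.linspace(f.low, f.high, n)
    return grid


def monte_carlo_design_space(data: pd.DataFrame, spec: SimulationSpec,
                             limits: Sequence[CqaLimit],
                             grid: Mapping[str, Sequence[float]],
                             z: Mapping[str, float],
                             threshold: float = DEFAULT_THRESHOLD,
                             factors: Mapping[str, FactorSpec] | None = None
                             ) -> ProbabilityGrid:
    """Compute the acceptance-probability grid for one material.

    ``data`` holds the experimental runs (uncoded X columns, Z columns and
    one response column per CQA, as fractions); ``grid`` maps CPP symbols to
    their uncoded grid points; ``z`` fixes the material attributes at which
    the design space is evaluated.
    """
    if not limits:
        raise DomainError("at least one CQA limit is required")
    axes = {sym: np.asarray(pts, dtype=float) for sym, pts in grid.items()}
    if any(a.size == 0 for a in axes.values()):
        raise DomainError("empty grid axis")
    shape = tuple(a.size for a in axes.values())
    ncell = int(np.prod(shape))
    mesh = np.meshgrid(*axes.values(), indexing="ij")
    cell_x = {sym: m.reshape(-1) for sym, m in zip(axes, mesh)}

    rng = np.random.default_rng(spec.seed)
    ok = np.ones((ncell, spec.n_sim), dtype=bool)
    for limit in limits:
        if limit.cqa not in spec.refit_terms:
            raise DomainError(f"no refit term set for CQA {limit.cqa!r}")
        terms = [ModelTerm.parse(t) for t in spec.refit_terms[limit.cqa]]
        y = data[limit.cqa].to_numpy(dtype=float)
        X, names = design_matrix(data, terms, factors)
        # grid-point design matrix: X terms from the grid, Z terms from ``z``
        gcols = [np.ones(ncell)]
        for t in terms:
            if t.kind == "main_x":
                if t.name not in cell_x:
                    raise DomainError(
                        f"model term {t.name} is not a grid axis; add it to "
                        f"the grid or drop it from the term set")
                gcols.append(cell_x[t.name])
            elif t.kind == "main_z":
                if t.name not in z:
                    raise DomainError(f"missing material attribute {t.name}")
                gcols.append(np.full(ncell, float(z[t.name])))
            else:
                raise DomainError(
                    f"Monte Carlo refits require linear term sets, got {t.name}")
        G = np.column_stack(gcols)
        # fixed design matrix: refit all simulations with one pseudoinverse
        pinv = np.linalg.pinv(X)
        ysim = y[:, None] * (1.0 + rng.normal(0.0, spec.rsd,
                                              size=(y.size, spec.n_sim)))
        beta = pinv @ ysim                       # (k+1, n_sim)
        pred = G @ beta                          # (ncell, n_sim)
        ok &= pred >= limit.bound
    prob = ok.mean(axis=1).reshape(shape)
    return ProbabilityGrid(axes=axes, fixed_z=dict(z), prob=prob,
                           threshold=threshold, n_sim=spec.n_sim,
                           seed=spec.seed)


def central_mask(data: pd.DataFrame, spec: SimulationSpec,
                 limits: Sequence[CqaLimit],
                 grid: Mapping[str, Sequence[float]],
                 z: Mapping[str, float]) -> np.ndarray:
    """Indicator of the noise-free (central) models meeting every limit."""
    noiseless = SimulationSpec(refit_terms=spec.refit_terms, n_sim=1,
                               rsd=0.0, seed=0)
    g = monte_carlo_design_space(data, noiseless, limits, grid, z)
    return g.prob >= 1.0


def export_grid(grid: ProbabilityGrid) -> pd.DataFrame:
    """One row per grid cell, ordered lexicographically by the axes."""
    rows = list(itertools.product(*[range(a.size) for a in grid.axes.values()]))
    data = {sym: [grid.axes[sym][idx[d]] for idx in rows]
            for d, sym in enumerate(grid.axes)}
    flat_p = [float(grid.prob[idx]) for idx in rows]
    data["probability"] = flat_p
    data["in_design_space"] = [p >= grid.threshold for p in flat_p]
    return pd.DataFrame(data)


def plot_slice(grid: ProbabilityGrid, fix_axis: str, value: float, path=None):
    """Heatmap of one 2-D slice of the probability grid (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    syms = list(grid.axes)
    if fix_axis not in syms:
        raise DomainError(f"{fix_axis} is not a grid axis")
    d = syms.index(fix_axis)
    k = int(np.argmin(np.abs(grid.axes[fix_axis] - value)))
    sl = np.take(grid.prob, k, axis=d)
    rest = [s for s in syms if s != fix_axis]
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(sl.T, origin="lower", aspect="auto", vmin=0, vmax=1,
                   extent=(grid.axes[rest[0]][0], grid.axes[rest[0]][-1],
                           grid.axes[rest[1]][0], grid.axes[rest[1]][-1]))
    ax.set_xlabel(rest[0])
    ax.set_ylabel(rest[1])
    ax.set_title(f"P(all CQA limits) at {fix_axis}={grid.axes[fix_axis][k]:g}")
    fig.colorbar(im, ax=ax, label="probability")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
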