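# Methods

## Scope and data model

The package analyses one manufacturing study design: 32 runs of a
ten-factor, three-level definitive screening design (DSD) executed on 16
characterised lots of *Panax notoginseng*, with the chromatography eluate
of each run assayed for five saponins and dry matter. All purities are
dimensionless fractions internally and percent only in files and reports;
contents and yields are mg per g of raw material; masses are g; dry-matter
concentrations are mass fractions. This is the scale on which every model
coefficient in the package acts, and it is what makes the bundled
coefficient tables directly usable for prediction (the verification-lot
computation reproduces 4.83 % Rd purity from them exactly).

The bundled design deviates from a textbook 10-factor DSD: runs 1–20 form
ten fold-over pairs with exactly one mid-level factor per run (the classic
DSD fingerprint), runs 21–28 are four *additional* fold-over pairs with no
mid-level factor, and runs 29–32 are center replicates. `validate_dsd`
therefore reports structure — center count, per-run mid-level counts,
fold-over pairing — rather than asserting membership of any particular
catalog, and flags rather than rejects the extra pairs.

## Screening regression

Each process CQA is modelled linearly in the uncoded process parameters
and raw material attributes. Selection is bidirectional p-value stepwise
with α_enter = α_remove = 0.05, intercept always included, implemented as
an alternation of a backward purge (drop the worst p > α, one at a time)
and a forward step (admit the best candidate with p < α), with a
visited-state guard so add/drop cycling terminates. Ties break toward the
earlier candidate in the supplied order.

Selection starts from the **full** candidate model by default. The choice
is substantive, not cosmetic: the six material attributes are strongly
mutually correlated (saponin-rich lots are rich across the board), and a
forward search from the empty model admits extractable dry matter (Z6) as
a proxy for the saponin sum and then stops, producing a different and
inferior model for total saponin purity. Eliminating from the full model
resolves the collinearity in favour of the individually significant
attributes and reproduces the published term sets for both CQAs. A
`start="empty"` option retains the classic forward-first behaviour.

The augmentation pass adds squares and pairwise interactions of the
retained CPPs to the candidate set and re-runs the selection. These
nonlinear columns are built on the **coded** (±1) factor scale. On the
uncoded scale a square such as X₁² over [80, 90] is correlated > 0.9999
with X₁ itself and the selector arbitrarily swaps one for the other;
centering via coding is the standard design-of-experiments remedy and, on
the study data, cleanly reproduces the result that no nonlinear term
survives. Squares and interactions are offered only over process
parameters: material attributes enter linearly by design.

Selection at α = 0.05 over 16 candidates retains spurious terms at the
usual multiple-testing rate. Simulation against a pure-noise response on
this design gives a mean of about two retained terms and an empty model in
roughly 3 of 10 replicates — a property of any α = 0.05 stepwise variant
at this candidate count, worth knowing when interpreting small retained
sets. The test suite freezes these simulated rates.

OLS fitting, partial t-tests and ANOVA statistics are delegated to
statsmodels. Rank-deficient term sets raise a `SingularModelError` naming
the offending terms; constant candidates are rejected up front; datasets
with fewer distinct lots than Z candidates are allowed but warn about
collinearity risk.

## Monte Carlo design space

Measurement error is propagated through the *responses*: each simulation
replaces every measured CQA value y by a draw from Normal(y, 0.04·y),
refits each CQA by OLS **on its fixed, final term set** (a new equation,
not a new selection — re-selection per iteration is deliberately not the
default), predicts over the CPP grid at the chosen lot's attributes, and
scores whether every limit is met. The cell probability is the fraction of
1000 simulations meeting all limits; the design space is the cell set with
probability ≥ 0.90 (boundary included; the choice only affects cells at
exactly 0.90). Perturbations for the two CQAs are drawn independently —
the models share no residual structure, so joint perturbation would change
nothing material.

Because only responses are perturbed, the design matrix is constant and
the thousand refits collapse to one pseudoinverse applied to a response
matrix; the default 11 × 11 × 13 grid (1 v/v-% steps on the two ethanol
concentrations, 5-min steps on elution time) computes in well under a
second, and per-iteration singularity is impossible (rank is checked once
up front).

The probability surface behaves as theory requires — bounded, bit-identical
under a fixed seed, within binomial error across seeds, converging to the
central-model indicator as rsd → 0, and monotone along each CPP for the
Rd-purity constraint (all three of its CPP coefficients are positive).
These properties, not any published probability table, are the package's
acceptance surface for the design space. Note that a lot whose
total-saponin-purity margin is about one prediction SD (e.g. PN18 at its
best corner, margin ≈ 1.9 percentage points) can have an *empty* 0.90
design space even though the central model passes — the probabilistic
criterion is deliberately stricter than the mean prediction.

## Grading

Acceptance inequalities copy the model coefficients verbatim and compare
the linear predictor against each CQA limit. Variable-parameter grading
solves max-min-slack over the parameter box as a linear program (HiGHS via
scipy); this is exact for any sign pattern of the coefficients and returns
a witness setting when feasible. Fixed-parameter grading folds the plant's
settings into the constants; the reported reporting-scale coefficients
(×10⁵ for the Rd inequality, ×10³ for the total-saponin inequality) are a
pure display convention that cancels out of every verdict.

Constants of the simplified inequalities are always **recomputed** from
the model coefficients. The corresponding published constants are not
internally consistent: the first (730 on the ×10⁵ scale) is not derivable
from the coefficient table at the stated fixed process (direct
substitution gives ≈ 176), and the second (108.3) corresponds to a 90 %
extraction-ethanol setting rather than the stated 88 % (which gives
103.9). All four example-lot verdicts are identical under either choice;
the tests pin the recomputed values and reproduce the printed *Z*
coefficients (397, −8.61; 10.3, 5.291, −11.1) exactly.

Zero slack counts as passing in both modes, matching the ≥ signs of the
inequality systems. Blending is a mass-weighted mean of attribute vectors,
after which grading applies to the blend.

## Synthetic data

The generator emulates the study conditions: 16 lots with attributes drawn
uniformly within the observed spans of the characterised lots (Z₁ 7.2–16,
Z₂ 32–59, Z₃ 3.2–8.4, Z₄ 29–53, Z₅ 5.0–14.2, Z₆ 185–387 mg/g), rejection-
sampled so the saponins never outweigh the dry matter; the bundled 32-run
design layout with lots re-assigned at random; and responses
y = (a₀ + Σbᵢxᵢ + Σcₖzₖ)(1 + ε), ε ~ N(0, 0.04), redrawn if y ≤ 0, with
the published coefficient tables as the default truth. Extraction records
are constructed to invert the characterisation formulas exactly, so the
record → attribute round trip is machine-precision.

Independent uniform attributes are the default; real lots are strongly
inter-correlated, so a single-latent-factor mode (weight 0.7 on a common
"lot richness" factor) is available for realism. What passing tests on
synthetic data do show: the estimators are unbiased under the assumed
error model, coverage of ±3 SE intervals is nominal, selection recovers
the generating terms at the rates the effect sizes warrant (all five
Rd-purity terms in ≈ 79 % of replicates; the smallest effect, Z₆, is the
usual casualty), and the design-space machinery closes on the truth at
zero noise. What they do not show: robustness to attribute distributions,
error structures, or process behaviour (nonlinearities, interactions with
material) absent from the generating model.

## Numerical choices and limitations

* Problem sizes: 1000 Monte Carlo simulations on the 11 × 11 × 13 grid;
  200 replicate studies for the calibration checks; exhaustive 2¹²-subset
  enumeration for the best-subset oracle. All chosen to keep any single
  check in the seconds-to-a-minute range at full statistical resolution.
* Coded-level tolerance 1e-9; LP feasibility tolerance 1e-9; boundary
  slack compared with ≥ 0 exactly.
* Every random draw flows from `numpy.random.default_rng(seed)`; identical
  seed and configuration give byte-identical output files (provenance
  header lines record version, seed and config hash).
* The pipeline models only linear, additive effects of material
  attributes; interactions between material attributes and process
  parameters, and nonlinear attribute effects, are outside the model
  family (and with 32 runs, outside the data's power). Grading inherits
  this: verdicts extrapolate the linear model across the whole parameter
  box.
* The total-saponin-purity model explains only ~75 % of response variance;
  its grading inequality is correspondingly the binding and least certain
  one. A probabilistic grading mode (lot acceptable iff its 0.90 design
  space is non-empty) is available through the design-space API for a
  stricter decision.
* Ginsenoside Re (Z₃) is carried through the data model and generators for
  completeness even though no fitted model retains it and the example
  grading tables omit it.
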