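# ntsqbd

A quality-by-design (QbD) analysis pipeline for the manufacture of
notoginseng total saponins (NTS), the *Panax notoginseng* extract used in
the Xuesaitong injection. The package is aimed at process and quality
scientists who need to decide, from a screening study, **which process
parameters and which raw-material attributes actually drive product
quality — and then turn that knowledge into a release rule for incoming
material lots**.

## What it computes

**Quality attributes.** A lot of *P. notoginseng* is characterised by what a
standardized 80 % ethanol reflux extraction recovers from it: extractable
saponin contents Z₁…Z₅ (notoginsenoside R₁; ginsenosides Rg₁, Re, Rb₁, Rd)
and extractable dry matter Z₆, in mg/g,

    Z6 = M_EX · DM_EX / M_PN,   Z_i = M_EX · SC_EX,i / M_PN .

A manufacturing run (extraction → concentration → water precipitation →
resin chromatography) is judged on its eluate: per-saponin purities
SPᵢ = C_EL,i / DM_EL, total saponin purity TSP = Σ SPᵢ, dry-matter yield
DMY and total saponin yield TSY (TSY = TSP·DMY by construction). The two
process CQAs are the ginsenoside-Rd purity (limit ≥ 3.5 %) and the total
saponin purity (limit ≥ 85 %).

**Screening.** Ten process parameters X₁…X₁₀ (three levels each, 32-run
definitive screening design with fold-over pairs and four center
replicates) and the six material attributes are screened jointly per CQA:

    Y = a₀ + Σᵢ bᵢ Xᵢ + Σₖ cₖ Zₖ

with bidirectional stepwise selection at α = 0.05 for entry and removal,
followed by an augmentation pass offering squares and pairwise interactions
of the retained process parameters (built on the coded ±1 scale). Retained
X main effects are the critical process parameters (CPPs), retained Z main
effects the critical material attributes (CMAs).

**Design space.** Experimental error is propagated by Monte Carlo: the
measured responses are resampled with a 4 % relative SD, the models refit
on their fixed term sets, and predictions evaluated over a grid of CPP
settings for a given lot's attributes. A grid cell belongs to the design
space when the probability of meeting *all* CQA limits is ≥ 0.90 (1000
simulations by default).

**Grading.** Substituting each CQA limit into its model yields linear
acceptance inequalities over (X, Z). A lot is *acceptable* if some process
setting within the investigated ranges satisfies all of them (exact LP
feasibility, with a witness setting), and *high quality* for a
parameter-fixing plant if it satisfies the inequalities after the plant's
fixed settings are folded into the constants. Mass-weighted blending of
lots is supported.

## Worked example

```python
import ntsqbd as nq

report = nq.run_pipeline(nq.PipelineConfig(seed=1), out_dir="nts_out")
print(report.summary)
```

prints

```
ntsqbd pipeline (seed=1, config=0026d89e3d64)
design: 32 runs, 4 center replicates, fold-over complete
CPPs: X1, X9, X10
CMAs: Z1, Z2, Z4, Z5, Z6
model rd_purity: terms ['X1', 'X9', 'X10', 'Z5', 'Z6'], R2 = 0.9349
model total_saponin_purity: terms ['X1', 'Z1', 'Z2', 'Z4'], R2 = 0.7467
design space for PN20: 1573 of 1573 grid cells (100.0%) at P >= 0.9
grade PN17: variable-parameter unacceptable, fixed-parameter low
grade PN18: variable-parameter acceptable, fixed-parameter high
grade PN19: variable-parameter unacceptable, fixed-parameter low
grade PN20: variable-parameter acceptable, fixed-parameter high
```

Reading this: of the ten studied parameters only the extraction-ethanol
concentration (X₁), elution-ethanol concentration (X₉) and elution time
(X₁₀) matter; concentration and water precipitation contribute no critical
parameter. Rd purity is driven up by its own extractable content (Z₅) and
down by extractable dry matter (Z₆); total saponin purity by R₁ and Rg₁
contents (up) and Rb₁ content (down). Lot PN20 can be processed anywhere in
the investigated parameter box with ≥ 90 % probability of meeting both
specifications, while lots PN17 and PN19 cannot meet the total-saponin
limit at any admissible setting and should not be released.

The same stages are available from the shell:

```
ntsqbd fit --out models.json
ntsqbd design-space --material PN20 --out grid.csv
ntsqbd run --out nts_out
ntsqbd simulate --seed 5 --out synthetic/
```

Individual pieces are plain functions: `eluate_quality`, `stepwise_fit`,
`augment_and_refit`, `monte_carlo_design_space`, `derive_inequalities`,
`feasibility_variable`, `classify_fixed`, and the synthetic-data
generators in `ntsqbd.synthetic_data`.

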