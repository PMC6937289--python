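# Methods

## Mechanical model

Each elongated internode is idealized as a straight hollow circular
cylinder measured at mid-internode. All geometry comes from two caliper
readings — outer diameter (mm) and wall thickness (mm) — and one length
(cm). The derived quantities and their boundary units:

| quantity | formula | unit |
|---|---|---|
| section moment of area | I = π a⁴/4 · [1 − (1 − t/a)⁴] | mm⁴ |
| elastic modulus | E = F L³ / (48 δ I) | GPa |
| flexural rigidity (bending stiffness) | E · I | 10⁻³ N·m² |
| bending moment | (distance to panicle tip) × (fresh weight above) | gf·cm |
| breaking bending moment | F_break · span/4 (force in gf) | gf·cm |
| lodging index | bending moment / breaking resistance | cm·g·g⁻¹ |
| culm volume | π L (2at − t²) ≡ π L (a² − (a−t)²) | cm³ |
| plumpness | dry weight / length; dry weight / volume | mg·cm⁻¹; mg·cm⁻³ |

Internal computation is SI throughout; 1 gf = 9.80665 × 10⁻³ N. The span
*L* in the elastic-modulus formula is the distance between the two supports
of the bending tester (default 5 cm), not the internode length; breaking
resistance is undefined (and rejected by validation) for internodes shorter
than the span. The solid-rod limit t = a is valid and reduces I to π a⁴/4.

Two conventions that field reports leave ambiguous are handled explicitly:

- *Bending stiffness.* Some reports word it as "section modulus × section
  moment of area"; dimensional analysis and the magnitude of printed values
  (tens of 10⁻³ N·m²) identify it as the flexural rigidity E·I, which is
  what `flexural_rigidity` computes.
- *Lodging index.* The literal reading — bending moment (gf·cm) divided by
  breaking force converted to gram-force — is the default (`mode="force"`,
  units cm·g·g⁻¹). A dimensionless alternative dividing by the mid-span
  breaking moment F·span/4 is provided as `mode="moment"`; the mode used is
  recorded in the profile. Published lodging-index magnitudes in this
  literature (order 150–200) are not recoverable from the same tables'
  printed bending moments and breaking forces under either convention, so
  lodging-index magnitudes are consumed, never asserted; comparisons between
  managements are unaffected because both modes are monotone transformations
  of the same ratio for a fixed span.

Absent measurements propagate as absent: a profile field whose inputs were
not measured is `None`/NaN, never a silent zero, and downstream summaries
use available-case counts.

## Field-trial statistics

The trial design is a split-plot: nitrogen management (FFP vs OPT) is
randomized to whole plots within replicate blocks, variety to subplots. The
ANOVA decomposes the per-plot means into block, whole-plot (N), block × N
(whole-plot error), subplot (variety), N × variety and residual strata; the
N effect is tested against the block × N mean square, variety and the
interaction against the residual. Balanced layouts only — unbalanced input
is an error, never imputed.

Summaries average culms within a plot first, then report mean ± SE over the
n plot means (SE = sd/√n). Percent change is (OPT − FFP)/FFP × 100 from
group means, rounded to one decimal as in trial tables; "average" percent
changes over several internodes are the unweighted mean of per-internode
percent changes (mean of ratios, matching how such averages are reported).
Significance letters use Fisher's LSD at α = 0.05 with the subplot residual
as the error term for within-variety N contrasts — with only two managements
compared per variety no further multiplicity adjustment is applied. Letters
are assigned to maximal runs of mutually non-significant groups ranked by
descending mean (ties broken by label order).

Harvest index is grain yield / total above-ground biomass. Note that trial
reports typically give grain yield at 14 % moisture but biomass oven-dry,
so a printed harvest index can differ from the ratio of the printed
components; the function computes the stated ratio of its inputs.

## Two-color array pipeline

One hybridization compares the two managements on one slide (control
labelled Cy3, optimized Cy5; no dye swap — the pipeline preserves that
orientation). Per replicate: flagged probes are dropped, intensities are
floored at 1, and M = log2(Cy5/Cy3), A = ½·log2(Cy5·Cy3). The
intensity-dependent dye bias is removed by robust locally weighted linear
regression of M on A (tricube weights, span 0.3, 3 robustness iterations,
global fit — print-tip layout is not modelled), implemented with the
lowess smoother from statsmodels using its interpolation speedup (delta =
1 % of the A range); the normalized log ratio is M minus the fitted trend.
A span below 10 points per window is rejected, as is any input under 50
probes.

Replicate-level inference is a per-probe two-sided one-sample t-test of the
normalized log ratios against zero (the conventional criteria state a
fold-change and p cut-off but not the statistic; a one-sample t across
biological replicates is the minimal choice consistent with "mean of three
biological replicates"). Probes with fewer than two finite replicates or
zero variance are flagged degenerate with p = NaN — flagged, never
fabricated — and are never called. A probe is called up when its mean
log2 ratio ≥ 1 and p ≤ 0.05, down when ≤ −1 and p ≤ 0.05; raw p-values are
used for calling (no FDR), matching the conventional joint criterion.

GO over-representation uses the upper-tail hypergeometric test per term
(overlap ≥ k out of a size-n list against a size-N universe with K
annotated genes) with Benjamini–Hochberg adjustment across terms. qPCR
concordance regresses qPCR log2 ratios on array log2 ratios by OLS and
reports slope, intercept and R²; qPCR log2 fold changes come from the
ΔΔCt rule (log2FC = −ΔΔCt) with a user-named reference gene.

## Synthetic-data generators

All generators are pure functions of (config, seed) using numpy's
`default_rng`; identical inputs give identical outputs.

**Field trial.** Defaults (shipped in `data/trial_defaults.yaml`,
transcribed from a published two-variety trial and freely editable) give
per (variety, management, internode) means and SEs for internode length,
diameter, wall thickness, dry weight and — for the second and third lower
internodes — breaking force, elastic modulus and bending moment, plus plant
height. Sampling is hierarchical: a per-trait plot effect ~ N(0, sd_plot)
with sd_plot = SE·√(n plots), then culm values ~ N(plot mean, sd_culm) with
sd_culm = 2 × sd_plot (plot-level dispersion is what trial tables print;
the culm-level factor of 2 is a realistic within-plot excess and makes the
plot-averaging step consequential). Invariants (positive values, wall ≤
radius, no breaking test below the 5 cm span) are enforced by rejection
resampling. The distance to the panicle tip is derived from plant height
minus the lengths below the internode, and the fresh weight above is set to
(bending moment)/(distance), so the configured bending-moment distribution
is reproduced exactly; the deflection of the elastic test is back-computed
from the sampled modulus under a 1 N load so the analysis recovers E.

What the generator does **not** emulate: trait–trait correlation within a
culm, spatial field trends, non-normal measurement error, and
internode-to-internode correlation. Passing recovery tests therefore shows
the statistics are correctly implemented and calibrated for the assumed
error structure, not that real trials satisfy it.

**Arrays.** Per probe and replicate: latent A ~ Uniform(6, 14); true M is
the planted log2FC (0 for background probes); observed M adds Gaussian
noise and a smooth dye bias b(A) = 0.2 + 0.4·sin(A/2) (magnitude ≤ 0.6 —
large enough that un-normalized calls are visibly biased, smooth enough for
loess to remove); channels are reconstructed as Cy5 = 2^(A + M/2),
Cy3 = 2^(A − M/2). Defaults mirror the emulated experiment: 45,018
features, 3 replicates, 665 up + 713 down planted with |log2FC| ~
Uniform(1.5, 3), noise sd 0.15. Not emulated: spatial artifacts,
background structure, probe-sequence effects, intensity-dependent variance.

**GO universes.** Each term annotates a uniform random gene subset; planted
enrichment inserts an exact overlap count into the gene list, and
over-constrained plants are rejected.

## Numerical choices and problem sizes

- Closed-form geometry is validated against Simpson quadrature of
  ∫y² dA over the annulus (relative error < 10⁻⁶) and the volume identity
  π L (2at − t²) = π L (a² − (a−t)²) to machine precision.
- ANOVA sums of squares are checked against direct enumeration (10⁻⁹
  relative) and the whole-plot test's type-I error against a 2000-run null
  simulation (0.05 ± 0.015).
- Hypergeometric p-values are checked against exact rational enumeration
  for universes up to 25 genes.
- The loess stage is checked to leave per-A-decile mean residuals below
  0.05 on 10,000 null probes with an injected 0.5·sin(A/2) bias.
- Null-array calibration uses 20,000 probes at noise sd 0.25: raw p ≤ 0.05
  rate ≈ 5 %, joint two-fold + p calls < 10⁻⁴.
- The full-scale recovery check runs the complete 45,018-feature, 3-replicate
  pipeline (a few seconds); Monte-Carlo recovery of a configured −20 %
  length effect uses 500 single-variety trial simulations.

## Known limitations

- Elastic moduli can only be consumed from (F, δ) bending tests; published
  tables print E but not the raw test pairs, so printed E values cannot be
  re-derived, only used as inputs.
- The lodging-index unit convention in the emulated literature is
  unresolved (see above); both implemented modes are self-consistent but
  neither reproduces printed magnitudes from printed components.
- The split-plot model assumes homoscedastic normal errors and complete
  balance; REML-based mixed models, spatial corrections and multi-season
  analyses are out of scope.
- DEG calling uses raw p-values by design; the false-discovery rate is
  controlled only for GO terms.
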