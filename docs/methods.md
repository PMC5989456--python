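# Methods

## The stoichiometric model

Bifidobacteria ferment hexoses through the fructose-6-phosphate
phosphoketolase pathway (the "bifid shunt"). Per 2 mol hexose, the
phosphoketolase reactions yield 3 mol acetyl-phosphate — dephosphorylated
to acetate by acetate kinase with one ATP each — and 2 mol
glyceraldehyde-3-phosphate oxidized to pyruvate. We follow the single-ATP
convention for the GAP→pyruvate step (one ATP per triose, configurable via
`atp_per_gap`; classical lower glycolysis would count substrate-level
phosphorylation differently, but the single-ATP bookkeeping is the
convention this analysis community uses for the pathway). With lactate
dehydrogenase closing the redox balance, the canonical yield is
3 acetate : 2 lactate (ratio 1.5) and, net of one activation ATP per
hexose, 1.5 ATP per hexose.

Two partition fractions extend the canonical model at the pyruvate node:

| parameter | meaning | range | default |
|---|---|---|---|
| `f` | pyruvate fraction routed through pyruvate-formate-lyase (PFL) | [0, 1] | 0 |
| `g` | acetyl-CoA fraction converted to acetate (rest → ethanol) | [0, 1] | — |

Each PFL-diverted pyruvate yields one formate plus one acetyl-CoA; acetate
conversion gains one ATP, ethanol reduction regenerates two NAD⁺ per mole.
Per mole of substrate with H hexose equivalents and N GlcNAc residues:

    lactate  = H(1−f)            formate = Hf
    acetate  = (3/2)H + Hfg + N  ethanol = Hf(1−g)
    ATP      = (3/2)H + H + Hfg − a·H      (a = activation ATP/hexose, default 1)
    NADH residual (produced − consumed) = Hf(2g−1)

The N term is the free acetate released by GlcNAc deacetylation; it
carries no ATP and the GlcNAc backbone enters the pathway as one hexose
equivalent (its phosphorylation cost is folded into the activation term).
A fractional `glcnac_bypass` (default 0) diverts GlcNAc backbones to
anabolism instead. Carbon is conserved identically: 2·acetate +
3·lactate + formate + 2·ethanol = 6H + 2N for every (f, g), which is the
carbon count of the substrate (6 per plain hexose, 8 per GlcNAc). The
residual NADH term is zero iff f = 0 or g = 1/2; setting
`enforce_redox_balance` pins g at 1/2 whenever f > 0.

The printed theoretical ratios fall out as special cases: acetate:lactate
= 1.5 at f = 0 on plain hexose; formate:acetate = 2:5 at f = 1, g = 1
(the "more than 50% conversion" phrasing of the source statement is
ambiguous; full conversion is the parameterization that reproduces 2:5
exactly); ethanol:lactate = 1:1 at f = 2/3, g = 1/2 (one consistent
reading of the "50% of acetyl-CoA to ethanol" statement — the statement
alone does not pin f down).

## Inverse estimation

`fit_shunt` estimates (f, g, S) — S the mM of substrate consumed — by
bounded least squares on the observed endproduct panel against S times the
per-mole yields, multi-started from a 5×5 grid over (f, g) (25 starts);
ties are broken by smallest residual, then smallest f. The panel must
contain lactate plus at least one further endproduct. When formate and
ethanol are both absent the shunt is off: f = 0 is returned with a
closed-form S and `g_identifiable=False` (g is structurally
unidentifiable there). The independent check in the test suite is an
exhaustive 101×101 grid search with closed-form S. Noiseless forward
panels are recovered to 1e-6; at 5% multiplicative noise the mean
absolute error of f stays below 0.1 over 100 panels.

## Growth model

OD600 curves are fitted to the zero-anchored logistic

    dOD(t) = dOD_asym · [ 1/(1+exp(k(tc−t))) − 1/(1+exp(k·tc)) ]

with dOD_asym the stationary-phase level (OD units), k the growth rate
(h⁻¹) and tc the inflection time (h). The plateau is
dOD_asym·(1 − 1/(1+e^{k·tc})), slightly below dOD_asym; the reported
asymptote is the fitted dOD_asym. Time is measured from the first
observation, so the fit is exactly invariant to a uniform time-axis
offset (tc is mapped back to the input coordinates). Initialization:
dOD_asym ← max(od), tc ← time of steepest finite-difference slope,
k ← 4·slope/dOD_asym (logistic maximum-slope identity), refined by
bounded least squares with small multi-start perturbations. Curves whose
range is below the no-growth floor (default 0.05 OD, configurable; the
source gives none) return a "no growth" record rather than a fit. Blank
correction subtracts the no-carbohydrate control mean and clips at zero;
the replicate-outlier rule removes the single farthest-from-mean replicate
only if it deviates by more than 3× the SD of the others and at least
three replicates remain.

## Quantitation

Calibration lines are ordinary least squares with intercept (zero-intercept
mode by flag); r² below 0.99 warns. Quantified concentrations below zero
are clipped to 0 with a flag. Technical duplicates are averaged with a
>10% discordance flag. Sugar consumption is 100(pre − post)/pre, reported
negative (with a warning) if post exceeds pre. Carbon recovery divides
metabolite carbon (lactate 3, acetate 2, formate 1, ethanol 2 carbons)
by consumed-substrate carbon; on any noiseless forward-model panel it is
exactly 100%, which ties the quantitation module to the stoichiometric
model as an end-to-end test. Real fermentations can exceed 100%.

## Statistics

Ratios are computed per replicate, never as ratios of group means; a zero
denominator flags the ratio undefined and it is excluded (not zero-filled)
downstream. One-way ANOVA is computed from the sums of squares directly;
two-way designs use an OLS fit with type-II sums of squares (the balanced
triplicate designs make the type choice immaterial, but type II is the
documented default for unbalanced cells). Tukey HSD uses the numerical
studentized-range distribution (Tukey-Kramer for unbalanced groups), with
simple-effects comparisons within each level of the other factor in
two-way designs. Zero residual variance is reported as a boundary case
(F = ∞, p = 0), not an error. PCA centers (optionally unit-scales)
columns and decomposes by SVD; loading signs are canonicalized so each
component's largest-magnitude element is positive. Hierarchical
clustering is Ward/Euclidean; merge heights are monotone and the
dendrogram is serialized as an ultrametric Newick string. Heatmap-style
scaling (per-variable z-scores) is provided as `zscore_scale`.

## Synthetic data

The generators emulate the three assay designs with one integer seed
driving all randomness (identical seeds ⇒ identical tables):

- growth: model curves plus i.i.d. additive Gaussian OD noise (default
  sd 0.02, about the read-to-read scatter of a plate reader), clipped at
  zero, three replicates on a 0–48 h hourly grid, plus a blank series
  using the same noise model;
- fermentation: S × per-mole yields with multiplicative lognormal noise
  (unit mean, default CV 5% — concentrations are positive, so the error
  model is multiplicative); residual substrate = pre − consumed;
- qPCR: control Cts near 20 cycles, target Cts offset by a base dCt of 3
  minus log2(fold), one biological shift per sample (default sd 0.3
  cycles) shared across three technical replicates;
- calibration: linear responses at the six standard levels
  (0.5–50 mM).

Default presets mimic the four study substrates for one strain: growth
near the lactose condition (asymptote 1.27, k 0.56 h⁻¹), an LNnT-like
shift (f = 0.5, g = 0.9) giving measurable formate and an elevated
acetate:lactate ratio, and GlcNAc-catabolism fold changes near 19–22.
These are illustrative study conditions, not fitted ground truth. The
generators produce none of real data's structure beyond this: no lag or
diauxic phases, no heteroscedastic plate-edge effects, no chromatogram
co-elution, no qPCR efficiency drift. Passing tests therefore demonstrate
correctness of the computations under the stated error models, not
robustness to those artifacts.

## Problem sizes and numerical choices

Simulation-based checks use 100 repetitions (parameter-recovery suites)
or 50 seeds (clustering oracle), sizes at which the Monte-Carlo error of
the checked means is an order of magnitude below the asserted bounds.
Optimizer tolerances are set to 1e-14/1e-15 so noiseless round trips reach
1e-6 comfortably; boundary hits in (f, g) are flagged rather than
silently accepted. Outputs are serialized with 12 significant digits,
making write→read round trips the identity at that precision.

## Known limitations

- The forward model is a yield (endpoint) model: no kinetics of product
  formation, no genome-scale constraints, no enzyme thermodynamics.
- g is unidentifiable when the shunt is off, and weakly identified when
  formate and ethanol are small relative to noise; the fit flags but does
  not regularize this.
- ATP bookkeeping is a convention (single ATP per triose); the absolute
  ATP numbers shift under other conventions, the endproduct stoichiometry
  does not.
- Acetate measured in real supernatants includes any carried-over medium
  acetate; the model assumes a fully defined, acetate-free medium.
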