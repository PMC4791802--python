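# Methods

This note records the model, the estimation procedures, the synthetic data
generator, and the numerical and design choices behind `flux13c`. It states
no empirical results; the numbers the package produces come from its tests
and from `scripts/acceptance.py`.

## The central-carbon network

The bundled model (`flux13c/data/yeast_cc.txt`) is an atom-mapped
stoichiometric description of *S. cerevisiae* central carbon metabolism:
glycolysis, the oxidative and non-oxidative pentose-phosphate (PP) pathway,
the glycerol branch, the pyruvate-dehydrogenase bypass
(pyruvate → acetaldehyde → acetate → cytosolic acetyl-CoA), the ethanol
branch, the TCA cycle with separate cytosolic and mitochondrial pyruvate
and oxaloacetate pools, anaplerotic pyruvate carboxylase, malic enzyme, PEP
carboxykinase, serine/glycine metabolism (including threonine aldolase as a
second glycine source), and a biomass drain on eleven precursor pools. The
malonyl-CoA route to 3-hydroxypropionate (acetyl-CoA carboxylase, then the
bifunctional malonyl-CoA reductase consuming two NADPH per 3HP) is added by
`add_3hp_pathway`. The glyoxylate shunt is not included: it is repressed
under the glucose-limited growth this model describes.

Key conventions:

- Carbon indices are 1-based from the most-oxidized end (glucose C1 is the
  aldehyde carbon). Atom maps follow the standard central-carbon
  chemistry; e.g. aldolase sends fructose-1,6-bisphosphate C1–C3 to DHAP
  and C4–C6 to GAP, the two first-turn TCA decarboxylations release the
  oxaloacetate carboxyls, and succinate/fumarate symmetry is expressed as
  two half-weight atom-map variants of succinate dehydrogenase.
- Mass balances exist only for *balanced* pools. CO2, the one-carbon
  (methylene-THF) pool, extracellular species and biomass are unbalanced:
  CO2/O2/ATP/NADPH balances are deliberately absent from the flux
  estimation; cofactor stoichiometries are annotations only. The CO2 and
  one-carbon pools act as fixed-labeling sources (natural abundance by
  default) for carboxylation and serine synthesis from glycine.
- Biomass precursor coefficients (mmol per gDW) are a literature-typical
  yeast composition, shipped as an editable block in the model file; the
  biomass drain is exempt from the per-reaction carbon-balance audit.

## Labeling simulation (EMU)

Steady-state labeling is solved with the elementary-metabolite-unit
decomposition: backward traversal from the required carbon subsets,
grouping by EMU size, and one linear solve per size tier; condensation
reactions contribute convolutions of smaller EMUs. Reversible reactions
carry a nonnegative *exchange* flux `x`: forward labeling flux
`max(v,0)+x`, reverse `max(-v,0)+x` with the inverted atom map. Exchange
defaults are zero except for the non-oxidative PP reactions (0.3 × glucose
uptake) and fumarase (0.5 ×) — the steps whose reversibility measurably
reshapes labeling at these conditions; all other reversibility is absorbed
into the ratio formalism. An exhaustive positional-isotopomer fixed-point
simulator (in `tests/_oracle.py`, deliberately naive) is the independent
oracle the EMU path is verified against on every bundled toy network.

## Synthetic GC–MS data

The generator emulates the study conditions: glucose-limited chemostats at
dilution rate D = 0.04 1/h, labeled either with 100 % 1-¹³C glucose (99 %
isotopic purity) or with 20 % (n/n) uniformly ¹³C-labeled plus 80 %
naturally labeled glucose; proteinogenic amino acids are measured as TBDMS
derivatives. Two strain parameter sets are bundled:

- **reference** (non-producer): biomass yield 0.50 g DW/g glucose, PP
  split 0.25 of glucose uptake, TCA (citrate synthase) flux 0.90.
- **producer**: biomass yield 0.40, 3HP yield 0.02 g/g glucose
  (≈ 0.04 mol/mol), PP split × 1.23 and TCA flux × 1.12 relative to the
  reference, lower acetate secretion.

The yields, the 3HP flux and the +23 %/+12 % PP/TCA contrasts are the
macroscopic observations the study itself reports; the remaining free
fluxes (small anaplerotic/cataplerotic cycling, trace ethanol, minor
serine/glycine interconversion, pyruvate secretion as the carbon-balance
residual) are field-typical values fixed once in
`flux13c.synthetic.StrainSpec`. `build_strain_fluxes` turns a parameter
set into an exactly balanced flux vector by walking the network's balance
equations (anaplerosis is forced to equal cataplerosis plus biosynthetic
drains — a structural identity of the network).

Measurement emulation: fragment carbon-skeleton MDVs (the bundled fragment
set covers Ala, Gly, Ser, Thr, Asp, Glu with [M-57], [M-85] and f302 ions,
plus Val and Phe f302 — the fragments the TBDMS chemistry reliably yields;
formulas in `flux13c/data/fragments.tsv`), convolution with the natural
isotope background of the derivative atoms (H, N, O, Si and derivative
carbons), additive Gaussian channel noise with sd 0.004 mole fraction
(typical GC–MS performance), clipping at zero and renormalization. The
background matrix is lower-triangular, so the natural-abundance correction
inverts it exactly; noise-induced negative channels are clipped with a
flag.

What the generator does **not** emulate: chromatographic artifacts,
detector nonlinearity and ion statistics (noise is homoscedastic
Gaussian), inter-batch drift, incomplete hydrolysis or derivatization, and
amino-acid pools fed by protein turnover rather than current metabolism.
Passing tests therefore demonstrate correctness of the inference chain
under a faithful error model, not robustness to every real-data pathology.

## Flux ratios

Each of the eight branch-point quantities is estimated by expressing the
corrected MDV of a product fragment as a two-source mixture
`m = r·a + (1−r)·b`, with the source MDVs built from other measured
fragments via the network's atom maps (carbon-subset selection,
convolution with the CO2/one-carbon pools, single-carbon deconvolution
under a positional-independence assumption). The mixture fraction is a
closed-form least squares over all channels of every tracer experiment in
which the sources are distinguishable; its sd is propagated from the
channel noise by finite differences through the complete estimator
(including the correction step). Probes that extend fragments by
single-carbon convolution assume positional independence, which holds for
the positionally labeled design but not for the uniformly labeled mixture
with its correlated intact units; such probes are restricted to the 1-¹³C
experiment. The identifiability pre-check requires the source separation
to exceed 5 times the correction-amplified channel noise of the fragments
involved (with a √2 for the two noisy sources); otherwise the ratio is
reported undetermined with the full [0, 1] interval.

The malic-enzyme contribution is reported as an interval, not a point:
the positional labeling of the malate carbon lost on decarboxylation is
not observable from the fragment set, so the estimate is computed under
bracketing assumptions (terminal carbon unlabeled vs. carrying twice the
mean per-carbon enrichment; glycolytic C3 probe from serine vs. alanine)
and the spread is the reported bound pair.

Ratios become linear constraints: a point ratio `r` over inflow routes A
and B yields `(1−r)·Σv_A − r·Σv_B = 0`; the malic-enzyme bounds yield two
inequalities. A full set is exactly eight constraints.

### The PP-pathway probe

The eight branch-point ratios contain no pentose-phosphate quantity, and
rank analysis of the bundled network shows the resulting system is
structurally one dimension short: without gas or redox balances, the
PP-split/respiration trade-off is uninformed by the extracellular rates.
The information does exist in the 1-¹³C design — oxidative decarboxylation
destroys the labeled glucose C1, which otherwise arrives at serine C3 —
so the package estimates an auxiliary *intact-triose fraction* from the
Ser M-57 reporter (divided by the serine-from-glycolysis ratio to undo
glycine-route dilution). Its flux interpretation,
`s·v_TPI/v_GAPDH` with `s = v_PGI/(v_PGI+v_TAL+v_TKL2)`, is bilinear; the
estimator linearizes in `s` and finds the self-consistent value by a
bracketed scalar root solve, choosing among multiple roots by the weighted
residual. The probe's two-source model neglects label redistribution by
reversible non-oxidative-PP exchange, whose magnitude is not observable
here; a model-uncertainty floor of 0.02 (absolute, combined in quadrature
with the propagated noise) accounts for that approximation in the probe's
reported sd.

## Net-flux estimation

Weighted least squares `min ‖W(Av−b)‖²` subject to the balanced-metabolite
mass balances `S v = 0`, the malic-enzyme and irreversibility
inequalities, solved exactly in the null space of the hard constraints;
active inequalities are handled by a KKT-based active-set loop with an
SLSQP fallback. Measured rates and ratio equalities enter as soft rows
weighted by 1/sd (a dimensionless ratio sd is scaled by the glucose uptake
to express it in flux units); ratio equalities without an sd are enforced
exactly. Soft equalities were chosen over hard ones because the
serine-node ratios are complements of each other — with independent noisy
estimates, hard versions of both would admit only the zero solution.
Degrees of freedom and the informed rank are checked explicitly; an
underdetermined system raises (naming the uninformed directions) unless
the caller opts into the minimum-norm solution, which the Monte-Carlo
resampler does so that a single trial with an undetermined ratio cannot
abort an uncertainty analysis.

Rates: at chemostat steady state the growth rate equals the dilution
rate; secretion rates are `D·c/X` converted to mmol/gDW/h; glucose uptake
uses feed minus residual concentration. Default synthetic measurement
errors: 3 % relative on rates, 1 % on the growth rate. Ethanol is present
in the network but defaults to a (near-)zero measured rate at D = 0.04 —
fully respiratory growth.

Confidence intervals: parametric resampling of rates, determined ratio
values and the PP probe by their sds, re-estimation, and 2.5/97.5
percentiles per reaction; deterministic under a fixed seed; aborts when
more than half the draws are infeasible. Strain comparison divides
normalized (glucose uptake = 1) group fluxes — PP = oxidative-PP entry
(ZWF), TCA = citrate synthase — and reports percent change.

## Genome-scale stage

The central-carbon result constrains a genome-scale model: mapped
reactions receive the scaled, sign-adjusted CI endpoints as bounds
(`apply_13c_bounds`, copy semantics, optional uniform relaxation as the
explicit escape hatch when the ¹³C ranges and the genome-scale lumping
admit no common point — the reconciliation policy is otherwise to error).
Parsimonious FBA maximizes the objective, fixes it within a relative
slack of 1e-6, and minimizes total absolute flux via the standard
split into nonnegative forward/reverse parts. Unlike the central-carbon
stage, every metabolite the genome-scale model declares — including NADH,
NADPH and ATP — is balanced, which is where redox enforcement happens.
SBML I/O goes through COBRApy; both LPs are solved with scipy's HiGHS.
A self-contained miniature yeast-style model with explicit redox
(`toy_yeast_gsm`, purely synthetic, lumped consistently with the
central-carbon network) serves as the default genome-scale stage and as
the brute-force-verifiable fixture.

## Numerical choices

- EMU linear solves: dense LU per size tier; solutions clipped at 0 and
  renormalized (guard against 1e-16-scale negatives).
- Flux steady-state tolerance for simulation inputs: 1e-8 relative to the
  largest flux; estimator balance residual asserted < 1e-6.
- WLS: lstsq on the null-space-projected system; active-set adds the most
  violated constraint, drops constraints with negative multipliers, and
  falls back to SLSQP (ftol 1e-14) on cycling.
- PP-probe root solve: brentq (xtol 1e-8) on a 7-point bracket grid;
  residual-based root selection.
- pFBA: HiGHS, objective slack 1e-6 relative; default bounds ±1000.
- Noise clipping and renormalization reshape the channel noise (first
  order: `var_i = σ²(1 − 2x_i + n x_i²)`); tests assert against this
  expectation rather than the raw σ.

## Problem sizes

The test suite runs the oracle-equivalence checks on all bundled toys
(≤ 12 carbons), ratio recovery over 100 seeded trials (both strains), and
CI coverage over 200 trials with 64 Monte-Carlo draws each.
`scripts/acceptance.py` re-derives the same quantities at 40 ratio trials
and 60 coverage trials — sizes chosen to keep a complete re-run in the
minutes range while leaving the statistics stable to a few percent; the
reported JSON records the `n` used for every quantity.

## Known limitations

- The exact reaction content of the historical yeast central-carbon model
  this network emulates is not recoverable; the bundled model documents
  its own content (topology fixed by the study's flux map).
- Single-precursor fragments only: ions spanning several precursor pools
  (e.g. the full valine or phenylalanine skeletons) are not modeled; the
  bundled set uses their pep/pyruvate-derived f302 ions instead.
- The malic-enzyme bounds and the PP probe rest on documented positional
  assumptions; their intervals/uncertainty floors encode that, but a
  systematic bias within those floors remains possible. Measurably, the
  probe's neglect of non-oxidative-PP exchange overestimates the oxidative
  split more strongly at low PP flux, which compresses the recovered
  PP-pathway contrast between strains (the reported percent increase is
  biased toward zero while the TCA contrast is essentially unbiased).
- `compare_strains` reports point percent changes; its uncertainty must be
  read off the underlying flux CIs.
- The minimum-norm fallback, when triggered, biases the reactions along
  the uninformed direction; the manifest and logs record when it fired.
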