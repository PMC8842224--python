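# Methods

This note documents the models, estimators, numerical choices and known
limitations of `adenofep`. Units are kcal/mol for free energies, nM for
Ki, and K for temperature throughout. R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹.

## Binding table and structure assembly

Each receptor cell of the library's binding tables is one of two kinds:

* *quantitative*: a fitted inhibition constant `Ki ± SEM` in nM from a
  full displacement curve;
* *percent*: the percent displacement of specific radioligand binding at
  a single 1 μM test concentration, reported when no curve could be
  fitted.

The parser is intentionally strict — a cell must match
`<number> ± <number>` (the ASCII alias `+/-` is accepted) or
`<number>%`; anything else is an error rather than a silent skip, so a
transcription defect in the packaged CSV cannot pass unnoticed. Percent
cells are stored exactly as printed. They are never converted to a Ki:
the only downstream interpretation is the *bound* Ki > 1000 nM used when
a selectivity ratio needs a numerator, and that ratio is flagged as a
lower bound.

Structures are assembled from the substituent codes onto the
2-aminopyrimidine-5-carbonitrile scaffold (`N#Cc1c(R4)nc(R2)nc1R6`) and
canonicalized by RDKit, which makes the assembled strings independent of
fragment writing order. The "3,4-OCH2O-Ph" code is modeled as
benzo[d][1,3]dioxol-5-yl (piperonyl). Reference ligands (XAC, DPCPX,
ZM241385) are not scaffold compounds; they carry affinity rows and
literature SMILES and are kept separate from the 108-compound library.

## Selectivity classification

Profile classes depend only on *which* receptors have a fitted Ki, not on
the percent magnitudes — a compound displacing 41% at 1 μM is treated
the same as one displacing 1%, because in both cases the assay could not
fit a curve. Rule order: inactive (no Ki anywhere) → A1-selective (Ki
only at A1) → A2A-selective (Ki only at A2A) → dual A2A/A2B (Ki at A2A
and A2B only) → dual A1/A2A (Ki at both A1 and A2A, other receptors
unrestricted) → other. The order matters: a compound with fitted A1 and
A2B Ki but not A2A falls to "other", not to any selective class. The
default "high affinity" cut for headline counts is Ki < 50 nM at the
profile's target receptor.

Ki → ΔG conversion uses T = 298.15 K, matching the 25 °C binding-assay
incubation.

## Perturbation map design

Morgan fingerprints (default radius 2, 2048 bits — the conventional
similarity setting; both configurable) feed a Tanimoto similarity matrix
over the selection. The map backbone is the maximum-similarity spanning
tree (Kruskal with deterministic tie-break on (min id, max id)), since
high-similarity transformations converge best. Closure edges are then
added greedily: candidates whose induced cycle would cover at least one
currently cycle-free node take priority; within a priority class the
highest-similarity pair wins, ties broken lexicographically. The design
is therefore deterministic and invariant to input order.

For the default 18-compound selection, 11 closure edges give a
28-comparison map with 11 independent cycles. Greedy augmentation does
not guarantee that *every* node lands on a cycle with a fixed closure
budget; `validate_network` reports uncovered nodes (one pendant node, the
piperonyl compound 19ao, remains uncovered in the default map).

## BAR estimation

For one window pair, forward samples are U(λ_{k+1})−U(λ_k) in ensemble k
and reverse samples U(λ_k)−U(λ_{k+1}) in ensemble k+1. The BAR estimate
is the root of the maximum-likelihood balance condition

    Σ_F f(β(W_F − C)) = Σ_R f(β(W_R + C)),  C = ΔG − RT·ln(n_F/n_R),

with f(x) = 1/(1+eˣ). The left-minus-right residual is strictly
increasing in ΔG, so the root is bracketed from the sample extrema
(expanding if needed) and solved with Brent's method to 10⁻⁷ kcal/mol
(max 200 iterations). Constant samples with equal counts are handled by
the analytic root (W_F − W_R)/2. The standard error is Bennett's
asymptotic variance evaluated at the fitted Fermi weights. Note the sign
of the ln(n_F/n_R) offset: the balance condition above follows from the
logistic-regression (maximum-likelihood) derivation and was verified
numerically on unequal-count Crooks-consistent Gaussian samples, where
the opposite sign produces a 2·RT·ln(n_F/n_R) bias.

A note on the one-sided estimators: the forward and (negated) reverse
exponential averages acquire large biases of opposite sign in dissipative
regimes and then straddle both the truth and the BAR estimate — but this
straddling is a statistical tendency, not a per-sample guarantee; at low
dissipation all three estimators agree to within noise and their ordering
is essentially random. The test suite asserts the tendency, not a
per-sample bracket.

The λ schedule offered for window placement is the scaled inverse
logistic λ(t) = σ(a(2t−1)) renormalized to [0, 1] (a = 4 by default),
which is symmetric and denser near the end states; a linear schedule is
also provided. Legs sum window free energies; the binding cycle is
ΔΔG_bind = ΔG_complex − ΔG_water; replicates aggregate to mean ± SEM
(sample SD over √n; a single replicate reports SEM 0 with a warning).

## Cycle closure

Edge estimates on the map are generally cycle-inconsistent; the signed
sum around a cycle (hysteresis) measures the inconsistency. Node free
energies minimize Σ_e w_e (ΔG_j − ΔG_i − ΔΔG_e)² with
w_e = 1/max(SEM_e, σ_floor)² and σ_floor = 0.05 kcal/mol (prevents
infinite weight on zero-scatter edges). The gauge is fixed by assigning
the anchor compound its experimental ΔG exactly; node standard errors
come from the covariance of the reduced weighted normal equations and
deliberately exclude the anchor's assay uncertainty, keeping FEP
precision distinguishable from assay precision. Re-derived edge values
ΔG_j − ΔG_i close every cycle by construction (hysteresis < 10⁻⁹ in
tests). Shifting the anchor value, or changing the anchor at fixed
weights, shifts all nodes uniformly (pure gauge).

**Anchor choice.** Each node's statistical error grows with its effective
resistance to the anchor in the precision-weighted map, so anchoring at a
structurally peripheral compound is wasteful: a pendant node's single
edge error enters every other node's estimate. The default anchor is
therefore the fitted-Ki candidate with the smallest mean effective
resistance to the rest of the map (computed from the unweighted map
Laplacian, so the choice is independent of the simulated data), with the
smallest assay SEM as tie-break. In the default 18-compound map this
selects 19a (a hub) rather than 19ao (the most precisely measured but
pendant compound); measured ground-truth recovery improves markedly
(P(RMSE < 0.5 kcal/mol) from ≈0.82 to ≈1.0 under the default noise
model). When no map is available the smallest-SEM rule is used, and the
CLI `--anchor` flag overrides either default.

## Synthetic data generator

The generator replaces the MD engine with the smallest statistical model
that preserves what the downstream machinery consumes:

* **Ground truth.** Per-compound ΔG = RT·ln(Ki·10⁻⁹) at 298.15 K from
  the experimental A1 Ki. One selection member (19ax) has no fitted Ki;
  it receives a configurable surrogate ΔG of −8.3 kcal/mol, slightly
  weaker than the ≈−8.2 kcal/mol of the 1 μM measurability bound.
* **Edge replicates.** For edge (i, j): ΔΔG_r = (ΔG_j − ΔG_i) + b_e +
  ε_r, with a per-edge systematic bias b_e ~ N(0, τ²) drawn once and
  per-replicate noise ε_r ~ N(0, σ_rep²). Defaults: σ_rep = 0.4
  kcal/mol, 10 replicates, τ_A = 0.3 (correct pose) and τ_B = 1.5
  kcal/mol (misposed ligand). The A/B gap is illustrative of a
  correct-vs-incorrect binding-mode contrast, not fitted to any real FEP
  output.
* **Work samples.** Forward ~ N(ΔG + σ_w²/2RT, σ_w²), reverse ~
  N(−ΔG + σ_w²/2RT, σ_w²): the equal-width Gaussian pair satisfying the
  Crooks relation, so the exact free energy is ΔG and BAR has a known
  closed-form target (μ_F − σ_w²/2RT).

What the synthetic data do **not** model: conformational sampling,
correlated window errors within a leg, non-Gaussian work tails,
hysteresis that correlates with transformation size, or any pose
geometry. Passing the recovery and discrimination tests therefore shows
the estimation machinery is correct and well-conditioned under the
assumed noise model — it says nothing about force-field or sampling
errors in real FEP.

## Scoring and binding-mode comparison

MUE = mean |pred − exp|, RMSE = √(mean (pred−exp)²), mean SEM = mean of
per-compound propagated standard errors (per-compound, not per-edge).
The anchor is excluded from scoring since its prediction equals its
experimental value by construction (17 scored compounds in the default
selection). Confidence intervals are 2.5/97.5 percentile bootstrap over
compounds (default 1000 resamples, seeded); bootstrap dispersions
(half-widths) are reported alongside. The mode comparison picks the
lower MUE, breaking ties by RMSE, then mean SEM; ties on all three are
declared indeterminate rather than forced.

## Problem sizes and determinism

Default analysis sizes: 108-compound table, 18-node/28-edge map,
10 replicates per edge, 1000 bootstrap resamples; the acceptance script
uses 10⁵ work samples for the BAR check, 20 simulation seeds for
recovery and 40 paired seeds for mode discrimination. Every stochastic
step takes an explicit seed (numpy `default_rng`); CLI runs log the
resolved config and its hash, and same-seed runs produce byte-identical
artifacts.

## Known limitations

* The published 28-comparison map itself is not available, so edge
  identity in the designed map may differ from the original even though
  node and edge counts match; the design rule (similarity tree + greedy
  closure) is a documented stand-in.
* Percent-displacement cells carry no potency information here beyond
  the Ki > 1 μM bound; no Cheng–Prusoff style modeling is attempted.
* The real study's error metrics cannot be reproduced without the
  original MD sampling; all quantitative pipeline results are properties
  of the synthetic noise model.
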