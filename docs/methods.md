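# Methods

## Data model and scope

The observational unit is an incubation *treatment*: one population of
eggs held at one constant temperature, with counts of female, male, and
unidentified hatchlings. Unidentified hatchlings are carried through the
data model but excluded from every statistic; this convention is
validated by the packaged dataset, whose published per-treatment
chi-square values (e.g. 5.232 from 44:25 with 2 unidentified) are
reproduced exactly only when unidentified hatchlings are dropped and no
continuity correction is applied. Eggs are treated as independent;
clutch structure (geckos lay two-egg clutches) is not modelled, because
sex-ratio inference here conditions only on per-treatment totals.

Two small egg-geometry helpers support the upstream measurement protocol:
ellipsoid egg volume V = 4/3 π (length/2)(width/2)², and apportioning a
jointly-weighed clutch mass across eggs in proportion to volume.

## Reaction norms

All curves return the **male** proportion. This makes the female-to-male
(FM) limb increasing (positive scale/slope) and the male-to-female (MF)
limb decreasing (negative), which is the convention used consistently in
types, priors, and outputs.

* **Logistic**: sr(T) = 1/(1 + exp((P − T)/S)). P is the pivotal
  temperature (sr(P) = 1/2 exactly); |S| controls the transitional range:
  TRT(l) = 2 |S| ln((1−l)/l), with l = 0.05 by default (the 5–95%
  definition). l is configurable.
* **Flexit**: a two-shape asymmetric generalisation pinned to
  sr(P) = 1/2 with pivot slope S_slope. Below the pivot,
  sr = (1 + (2^K1 − 1) exp(4 S1 (P − T)))^(−1/K1) with
  S1 = S_slope·K1/(2(1 − 2^−K1)), and symmetrically above with K2/S2 on
  1 − sr. The construction guarantees continuity at the pivot, derivative
  S_slope there, and exact reduction to the logistic with S = 1/(4
  S_slope) at K1 = K2 = 1 (verified numerically to 1e−10 in the tests).
  Note the two halves are *not* mirror images for a decreasing curve; the
  closed-form TRT therefore assigns the l and 1−l crossings to limbs
  according to the curve's direction, and is cross-checked against
  bracketed root-finding.

Numerical safety: exponent arguments are clipped at ±500 and returned
proportions at [1e−15, 1 − 1e−15], so any finite temperature yields a
finite, strictly interior sex ratio and a finite log-likelihood. Flexit
tail expressions use log1p/logaddexp forms. Inverting a curve near its
saturated tails is ill-conditioned in temperature space; the inversion
contract is therefore stated in sex-ratio space (|sr(T*) − target| ≤
1e−9).

## Likelihood, ML fitting, and model selection

The grouped binomial log-likelihood omits binomial coefficients (constant
in the parameters; they cancel in every AICc difference and Akaike
weight). Maximum-likelihood fits use multi-start Nelder–Mead on (P,
log|scale|) — ten deterministic starts spanning the temperature range for
the logistic, six shape-seeded starts for the flexit — with the limb
direction enforced through the sign of the scale, preventing a noisy MF
limb from flipping to an FM solution. An all-male or all-female limb has
its optimum on the parameter boundary; it returns a steep placeholder fit
flagged `converged=False` rather than raising.

AICc uses n = the number of sexed individuals on the limb, not the number
of temperature groups: with three groups and k = 2 the group-count
convention makes the correction undefined, whereas individual-level n is
well-defined and matches the reported feasibility of AICc selection on
limbs of this size. Model selection fits logistic (k = 2) and flexit
(k = 4), ranks by AICc with ties broken toward fewer parameters, and
drops a candidate (with a warning) only if its correction is undefined on
that limb.

## Limb splitting for FMF data

An FMF dataset must be divided into two monotone limbs before fitting;
the division is a modelling choice, not an observable. The default
`crossing` rule assigns each limb the temperatures from its female-biased
extreme through the observed sex-ratio reversal: FM takes temperatures up
to and including the *first* treatment with an observed male majority, MF
takes temperatures from the *last* male-majority treatment upward.
Interior plateau treatments between the two crossings (male-biased but
past the FM crossing) inform neither limb. For the packaged dataset this
yields FM limbs {24, 26, 28} (Yancheng, Chuzhou) and {24, 26} (Wenzhou),
and MF limb {30, 32} for all three. Two alternatives are retained:
`middle` (split at the median-ranked temperature, shared by both limbs)
and `peak` (split at the male-proportion maximum, shared). The crossing
rule was adopted because, uniquely among the rules tried, the resulting
per-limb maximum-likelihood pivots and posterior quantiles reproduce the
published Bayesian summaries for this dataset; the original analysis did
not document its split. A limb is always padded to at least two
temperatures, and populations with fewer than three distinct temperatures
are rejected.

## Priors and MCMC

The sampler is a single-chain component-wise Gaussian random-walk
Metropolis–Hastings over (P, S) — or (P, S_slope, K1, K2) for a flexit
limb — with log-target = log-likelihood + log prior. Defaults: 60,000
iterations, 10,000 burn-in, thinning 5 (10,000 retained draws), proposal
standard deviations 0.3 °C (P) and 0.2 °C (S), and a mandatory explicit
seed; a fixed seed reproduces the chain bit for bit. The chain starts at
the MLE clipped inside the prior box (at the box centre for prior-only
runs). On the packaged limbs acceptance rates are 0.6–0.8 and split-half
potential-scale-reduction factors are below 1.05.

Priors: P ~ Uniform(20, 35) °C — spanning all incubation temperatures
with margin — and |S| half-normal with scale 1.0 °C, truncated at 5,
signed by the limb direction. The original analysis reports no priors, so
the S prior was chosen by comparing standard weakly-informative scale
priors (flat, log-uniform, half-normal, half-Cauchy) against the full set
of published posterior quantiles using exact grid integration of the
two-parameter posterior; the half-normal(1 °C) matched best. It encodes
that a constant-temperature design spanning 8 °C cannot resolve
transitions much wider than itself (prior median TRT ≈ 4 °C, 97.5% ≈
13 °C), while the likelihood can still pull TRT well past that where the
data demand it (the widest packaged limb posterior reaches ≈ 16 °C at its
97.5% quantile). A flat S prior is available (`PriorSpec(S_scale=None)`)
but puts half its prior mass on TRT > 14.7 °C, which two- and three-point
limbs rarely overcome; flexit shape constants use a uniform box.

TRT is computed per retained draw (closed form for logistic chains) and
then summarised at the 2.5/50/97.5% quantiles; transforming quantiles of
S instead would not guarantee ordered TRT quantiles. Diagnostics report
the acceptance rate, lag-1 autocorrelation, and split-half R̂ per
parameter, flagging R̂ > 1.05 or degenerate chains. A single chain with
the split-half check was judged sufficient for a two-parameter, smooth,
unimodal posterior.

## Synthetic data and what it does (not) show

The generator draws, per temperature, n_sexed ~ Binomial(eggs, 1 −
unidentified_prob) and males ~ Binomial(n_sexed, m(T)), where the joint
FMF truth curve is the product of the two limb logistics
m(T) = logistic(P_fm, S_fm)(T) · logistic(P_mf, S_mf)(T). The product is
the simplest curve that vanishes at both extremes, peaks strictly below 1
between the pivots, and coincides with each limb's logistic away from the
opposite pivot. Defaults mirror the packaged experiment: five
temperatures 24–32 °C, 60 eggs per temperature, 2% sex-independent
dropout. The generator matches the analysis model's assumptions exactly
(binomial sampling, independent eggs, constant temperatures), so passing
recovery tests demonstrate the estimation machinery, not robustness to
clutch effects, temperature fluctuation, or differential mortality —
none of which are simulated.

When the two transitions overlap, the joint curve's 1:1 crossings sit
slightly inside the limb parameters (for the default truth
(26.5, 1.6, 30.7, −1.1): crossings at 26.58 and 30.52 °C). The recovery
harness therefore scores pivotal-temperature estimates against the joint
curve's actual crossings (`FmfTruth.joint_pivots`) — the quantity a sexed
hatchling experiment probes — and TRT estimates against the limb values
2 ln 19 |S|. At the default design the pipeline's FM pivot bias is below
0.1 °C with 95%-interval coverage ≈ 0.9 for both pivots; the 2-point MF
limb's TRT posterior is right-skewed and its median overshoots the truth
by ~1.5 °C at n = 60 eggs/temperature, shrinking with sample size.

## Problem sizes and reproducibility

Default analyses (three populations × two limbs at the full 60,000
iteration budget) run in well under a minute on one core; the test
suite's simulation studies use shortened chains (5,000–12,000 iterations)
and 12–50 replicates, sizes at which the checked properties are already
unambiguous. Every stochastic entry point takes an explicit seed, derived
seeds are offset deterministically per population and limb, and result
files rewrite byte-identically under the same seed.

## Known limitations

* The limb split and the S prior are reconstructions of undocumented
  analysis settings, selected by agreement with the published summaries
  for the packaged dataset; on other datasets the `crossing` rule and the
  half-normal scale are reasonable but not privileged choices.
* The two-point MF limbs leave the posterior scale heavily
  prior-influenced; TRT medians from such limbs should be read alongside
  their wide intervals.
* One published pivotal-temperature median (Chuzhou MF, 30.9 °C) is not
  reproducible from the printed counts under any split or prior family
  tried (every reconstruction centres near 30.5 °C); the discrepancy is
  documented rather than fitted.
* No joint four-parameter double-logistic fit across both limbs; no
  fluctuating-temperature or field nest-temperature projections.
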