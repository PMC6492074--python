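# Methods

This note documents the models, statistics and numerical choices behind
`cipasim`, and what the synthetic-data tests do and do not establish
about real patch-clamp data.

## Cell models

### Production model (`"cipaordv1.0"`)

The electrophysiology is the endocardial human ventricular myocyte of
the O'Hara–Rudy family: 48 state variables — membrane potential, eight
ionic concentrations (intracellular/subspace Na, K, Ca and the two SR Ca
pools), Hodgkin–Huxley gates for INa, INaL, Ito, ICaL, IKs and IK1,
CaMKII activation, two SR-release fluxes — plus a 9-state IKr Markov
scheme. The optimized-variant conductance rescalings are applied to the
currents that dominate TdP risk discrimination: INaL ×2.661, ICaL
×1.007, IKr ×1.013, IKs ×1.870, IK1 ×1.698.

The IKr scheme has two gating rows (closed C1–C2–O and inactivated
IC1–IC2–IO, connected columnwise) plus three drug-bound states. All
gating rates have the form `A·exp(B·V)` with a Q10-style factor
`q^((37−20)/10)` mapping 20 °C kinetics to body temperature. Drug
effects enter through five parameters with the semantics described in
the README. Two choices deserve emphasis:

* **Inactivated-state unbinding.** Unbinding from the
  inactivated-open-bound state is `Ku` scaled by the ratio of the O→IO
  recovery and inactivation rates, i.e. slower while inactivation is
  favoured. This implements drug trapping by inactivation; the scheme
  remains a valid (conservative) Markov model for any parameter values.
* **Trapping.** Both bound states exchange with a closed-bound state at
  a fixed rate of 3.5e-5/ms; release is sigmoidal in voltage with
  midpoint `Vhalf` and slope 6.789 mV, so hyperpolarization between
  beats can retain drug in the closed channel (pharmacological trapping).

This scheme is the package's own implementation of the published
dynamic-IKr model family; its behaviour is validated internally by
invariants (occupancy conservation to <1e-6 along every trace, bit-exact
null-drug equivalence, monotone APD prolongation and qNet depression
with binding potency) and by the physiological plausibility of its
paced steady state (resting potential −88 mV, APD90 ≈ 293 ms and qNet ≈
0.068 µC/µF at cycle length 2000 ms), rather than by file-level
comparison against an external reference implementation.

Drug effects on INaL, INa, ICaL (and optionally IKs, IK1, Ito) are
static conductance multipliers `1 − block(C)`; IKr accepts no static
multiplier, only the dynamic parameters.

### Toy model (`"toy"`)

Three linear ODEs — membrane potential relaxing toward a plateau set by
a phase variable `w`, `w` decaying with time constant `τ0(1+κ·b)`, and
hERG drug occupancy `b` with the same `k_on`/`Ku` kinetics as the
production model. All currents are proportional to `w`, so the paced
periodic solution and qNet have closed forms
(`cipasim.models.toy.closed_form_qnet`), qNet is provably strictly
decreasing in occupancy, and a beat simulates in ~2 ms. INa block scales
the upstroke drive, so near-total INa block reproduces depolarization
failure. The toy model is first-class: the UQ, threshold and evaluation
layers are model-agnostic and run identically on either model.

## Pacing, steady state and initial conditions

Default protocol: cycle length 2000 ms, stimulus −80 µA/µF for 0.5 ms,
1000 beats to steady state; all configurable. The stored initial
condition of the production model is its own drug-free steady state
after 1000 beats (maximum relative state change per beat 1.4e-6),
regenerable with `python -m cipasim.models.ord`. Because drug runs start
from this state, short continuation runs (tens of beats) suffice for
drug-free quantities, while drugged runs should pace long enough for
binding and ionic re-equilibration; `run_to_steady_state` reports the
per-beat convergence diagnostic in `meta["beat_convergence"]` so the
adequacy of any beat count is observable rather than assumed.

## Numerics

The integrator is a fixed-step scheme compiled with numba: exact
exponential (Rush–Larsen) updates for all Hodgkin–Huxley gates, forward
Euler for voltage, concentrations and CaMK, and 4× sub-stepped Euler for
the Markov scheme (whose pairwise fluxes conserve occupancy exactly up
to round-off). Default step 0.01 ms (toy: 0.1 ms). Measured accuracy:
halving the step moves qNet by ≈0.2–0.5% (part of which is
re-equilibration of the stored steady state at the finer step); the test
suite asserts <1%. Traces are recorded at 1 ms (toy 0.5 ms) with linear
interpolation for APD crossings. The GHK-type flux expressions use an
`u/(e^u−1)` helper continuous through u = 0. Non-finite states abort the
run with a `SimulationError` carrying drug/concentration context.

## Metrics

* `qNet`: trapezoidal integral of ICaL+INaL+IKr+IKs+IK1+Ito over the
  recorded beat, divided by 1000 to convert (µA/µF)·ms to µC/µF.
* `APD50/APD90`: from the time of maximum upstroke velocity to the
  interpolated crossing of `peak − level%·amplitude`, baseline = the
  pre-upstroke minimum.
* Depolarization failure: peak V < 0 mV after the stimulus (robustly
  separates full APs from stimulus artifacts); no threshold crossing
  before the beat ends = repolarization failure. Either failure makes
  qNet and the torsade metric score undefined for that sample: failing
  samples are excluded from the score distribution and counted, never
  imputed.
* Torsade metric score: mean qNet at integer multiples {1,2,3,4} of free
  Cmax (configurable).

## Pharmacology and uncertainty quantification

Hill fits optimize log10(IC50) with the Hill coefficient constrained to
(0, 5] — unconstrained fits on sparse noisy panels are unstable.
Responses all below 1% block yield the "no measurable block" sentinel
(IC50 = ∞). The bootstrap resamples cells (not points) with replacement,
preserving within-cell correlation, and refits each replicate; failed
refits are redrawn with a cap. Joint per-drug sample sets pair
independent draws across channels (channels are measured in separate
experiments; no cross-channel correlation structure is claimed —
`assemble_sample_set` accepts precomputed joint samples unchanged if a
correlated scheme is wanted). IC50s are stored in nM; table readers
convert from µM columns. Where only point estimates of the five hERG
parameters exist, `jitter_herg_samples` provides lognormal parameter
scatter (default relative sd 0.15–0.25) as a stand-in for a real
refitting bootstrap; it is labelled synthetic and used only by the
synthetic pipelines.

## Thresholds

Proportional-odds cumulative-logit model with the score as single
covariate, fit by maximum likelihood (Nelder–Mead polish + BFGS,
tolerance 1e-8) on the pooled training distributions with per-drug
weights 1/n, so every drug contributes equally regardless of its sample
count (`use_medians=True` switches to one median per drug). Scores are
standardized internally, which makes the fitted thresholds exactly
scale-equivariant; thresholds are the scores where adjacent cumulative
probabilities equal 0.5, i.e. `alpha_k / beta` mapped back to the score
scale. Boundary ties classify as intermediate (measure-zero for
continuous scores). On perfectly separated training groups the MLE slope
diverges but the threshold ratios converge to values bracketed by the
groups, which is the behaviour the tests pin down.

## Performance measures

One score per drug per iteration is drawn uniformly with replacement
from its distribution (default 10,000 iterations); measures are
summarized as median and 2.5/97.5 percentiles (the record also carries
the mean, which is the quantity that equals analytic off-category
masses). AUC is computed by pair counting with ties at 0.5 under the
global convention lower score = higher risk; it provably equals
trapezoidal integration of the empirical ROC curve, and the tests verify
that equality on random panels. Likelihood ratios substitute 1e-6 for
any zero probability among sensitivity, specificity and their
complements before forming ratios, making perfect classification finite
(e.g. 0.75/1e-6 = 7.5e5). Mean classification error is unweighted 0/1
across the three categories. Leave-one-out cross-validation refits
thresholds per fold and applies each drug's own held-out thresholds to
the classification measures, while ranking measures use the full panel;
folds whose training part lacks a category are skipped with a warning
and listed in the report metadata.

## Synthetic data: what it does and does not show

The generators produce (i) Hill-curve patch-clamp panels with truncated
Gaussian noise, (ii) Gaussian score panels with category-level
means/sds (closed-form tail masses make classification-error oracles
exact), and (iii) toy-model drug panels whose risk structure is induced
mechanistically through hERG binding potency. They are pure functions of
their seeds. Real concentration–response data have heteroscedastic,
sometimes non-Gaussian errors, cell-level potency heterogeneity, and
real score distributions are skewed; passing tests therefore establish
correctness of the algorithms and their oracles under controlled
conditions, not field performance on laboratory data. The production
drug panels of the original qualification exercise are inputs, not
package contents: given their tables in the drug-table CSV dialect, the
identical pipeline runs on the mechanistic model unchanged.

## Problem sizes

Defaults follow the qualification practice (2000 UQ samples, 10,000
evaluation iterations, 1000 pre-pacing beats). The shipped acceptance
computation uses the package's scaled sizes — 200 UQ samples, 1000
iterations, toy-model panels of 12 training + 16 validation drugs, and
short continuation runs from the stored steady state for the myocyte
quantities — chosen so a complete from-scratch reproduction is a
one-minute, single-CPU exercise while every stage of the full-scale
pipeline is still executed.

## Known limitations

* The dynamic-IKr rate constants are the package's reconstruction of the
  published model family; absolute APD/qNet values may differ from other
  implementations by more than the within-package numerical error, so
  cross-implementation comparisons should re-baseline on the drug-free
  steady state.
* Endocardial single cell only; no transmural heterogeneity, tissue
  coupling, temperature correction, or pharmacokinetic effects
  (metabolites, drug–drug interactions, protein binding).
* Early-afterdepolarization detection is out of scope; extreme hERG
  block manifests as repolarization failure of the beat instead.
* The fixed-step integrator trades ~0.5% qNet accuracy for a large speed
  gain; conclusions that hinge on sub-percent score differences should
  be checked at dt = 0.005 ms.
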