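# Methods note

This note records the modeling assumptions, default settings and numerical
choices behind the package, and their known limitations. Quantitative
statements here are reproduced by the test suite (`tests/`) or by
`scripts/acceptance.py`; nothing below rests on unrecorded experiments.

## Forward model

A spectrum is the complex relative permittivity `eps*(f) = eps' - j eps''`
sampled on a strictly increasing frequency grid. The forward model is the
sum of two Cole-Cole dispersions:

    eps*(w) = eps_inf + sum_i d_eps_i / (1 + (j w tau_i)^(1 - alpha_i)),
    i = 1, 2,   w = 2 pi f.

* `eps_inf` — permittivity at the high-frequency limit of the band.
* `d_eps_i` — dispersion strengths; the static permittivity is
  `eps_inf + d_eps1 + d_eps2` (verified as the low-frequency limit of the
  implementation).
* `tau_i` — relaxation times; dispersion 1 is the slow process (bound
  water / interfacial polarization, hundreds of ps), dispersion 2 the fast
  free-water process (several ps). Fits relabel so `tau1 > tau2`.
* `alpha_i` in [0, 0.5) — symmetric broadening; `alpha = 0` reduces the
  term to a Debye dispersion (checked against an arbitrary-precision
  oracle).

Ionic (DC) conductivity is **not** modeled: the generator produces spectra
without a `sigma_dc / (w eps0)` loss term, and the fitter assumes its
absence. Dielectric conductivity is purely derived: `sigma = eps'' * eps0 *
2 pi f` with `eps0 = 8.8541878128e-12 F/m`.

## Anchored tissue states

Nine parameter sets anchor the generator: `Control`, ischemia at 1, 4, 5
and 6 h, and four reperfusion arms (3 h or 4 h ischemia followed by 1 h or
3 h reperfusion). Each anchor prescribes `d_eps1`, `d_eps2`, `tau1`,
`tau2`. Values not individually anchored use shared defaults chosen to be
physiologically unremarkable for high-water-content tissue in this band:
`eps_inf = 7.0`, `alpha1 = 0.10`, `alpha2 = 0.02`. These three defaults are
package choices, not measurements; analyses that depend on them (e.g.
noiseless recovery tests) treat them as ground truth of the simulation
only.

Intermediate time points interpolate the anchored parameters linearly in
elapsed time within a phase, clamped at the anchor span; reperfusion
records use the branch (3 h or 4 h ischemic history) matching their
schedule.

## Noise and variability model

Measurement noise is multiplicative Gaussian per frequency point and
channel: relative standard deviation 1.7 % below 5 GHz and 3.5 % at and
above (the split reflects decreasing probe sensitivity toward the top of
the band). Between-subject variability multiplies each subject's anchor
parameters by unit-mean lognormal factors with 5 % coefficient of
variation. Empirical coefficients of variation of simulated spectra are
verified against these targets by Monte-Carlo tests.

Dataset bookkeeping: the default design enumerates a four-arm measurement
schedule (control, serial ischemia, two reperfusion arms) over subjects and
replicates, then pads or truncates each phase deterministically to the
configured totals — 700 control, 1490 ischemia, 830 reperfusion records
(3020 in total) on a 167-point linear grid from 200 MHz to 14 GHz. The
totals are configuration, not a consequence of the schedule; padding and
truncation are recorded in a provenance log. The binary label is *viable*
iff elapsed ischemic exposure is under 4 h; reperfusion records carry the
ischemic duration that preceded reperfusion.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`,
method `trf`) on the stacked, unweighted `[eps'; eps'']` residual.
Numerical choices:

* `tau` is optimized as `log10(tau)` — relaxation times span decades and
  are strictly positive.
* Bounds: `eps_inf` in [1, 20], `d_eps` in (1e-6, 200], `tau` in
  [0.05 ps, 50 ns], `alpha` in [0, 0.5]. These comfortably bracket the
  anchored states while excluding unphysical values.
* Multi-start: a data-driven heuristic start (plateau-based `eps_inf`,
  loss-peak-based `tau`) plus seeded jittered restarts; the best final cost
  wins. A brute-force lattice oracle in the tests confirms the returned
  cost is never worse than nearby parameter candidates.
* `R^2` is computed on the stacked vector about its grand mean.

Identifiability: with a single noisy spectrum the strength/broadening
parameters (`d_eps_i`, `alpha_i`, `eps_inf`) trade off against each other;
the fitted cost is at or below the cost of the true generating parameters,
so tighter recovery from one spectrum is not attainable by a better
optimizer. Averaging replicate spectra before fitting restores accurate
parameter recovery (both facts are asserted by tests). Consequently the
headline fit-quality statistic (minimum `R^2` over 180 noisy fits,
`scripts/acceptance.py`) sits at the noise ceiling and varies by a few
parts in 10^4 with the seed.

## Classification

Spectra are classified viable / non-viable with the non-viable class
positive. Evaluation uses nested stratified 5-fold cross-validation:
hyperparameters are selected on inner folds by validation accuracy and
evaluated once on the outer held-out fold, so no test record influences
selection (leakage is asserted structurally in the tests). Features are
standardized per frequency and channel with training-fold statistics only.
An optional group-aware mode splits by (subject, case) instead.

Sequence families — LSTM, weight-tied bidirectional LSTM, residual
bidirectional LSTM, and a 1-D CNN — are implemented in NumPy with analytic
backpropagation (verified against central differences). The bidirectional
variants share direction weights and sum direction outputs, making
predictions exactly invariant to frequency reversal. The default
hyperparameter search space is learning rate {1e-6 … 1e-2}, ridge penalty
{1e-6 … 1e-3}, batch size {8, 16, 32, 64}, units {8, 16, 32, 64}, dropout
{0.1, 0.2, 0.3}; the pipeline subsamples this grid seededly because the
full nested search is beyond desk scale. Flat baselines (logistic
regression, SVM, random forest) use small fixed grids.

Band comparison pairs whole-band (0.2–14 GHz) against reduced-band
(6–14 GHz) evaluation with identical fold assignments, so per-fold
accuracy differences are paired observations.

## Frequency importance

Two complementary views: (i) PCA over standardized per-frequency variables
(loadings sign-fixed, verified against a direct eigendecomposition at
1e-8); (ii) Shapley attribution of a classifier's non-viable probability by
permutation sampling with interventional background-mean replacement. With
mean replacement the efficiency identity (attributions sum to
`f(x) - f(background mean)`) holds exactly per sampled permutation;
Monte-Carlo error affects only the per-feature split and is reported as a
standard error. Sampled values are checked against exact subset-enumeration
Shapley values on small problems. The recommended band is the smallest
contiguous interval covering the dominant PCA frequencies and the
top-decile mean-|attribution| frequencies, with a full-band fallback when
attributions are uniform.

## Limitations

* The generator is a smooth two-dispersion idealization: no DC
  conductivity, no electrode polarization, no temperature drift, and linear
  time interpolation between anchored states.
* `eps_inf` and the `alpha_i` defaults are package choices (see above);
  conclusions about those parameters reflect the simulation, not tissue.
* The phase totals are decreed configuration; padding/truncation to reach
  them is deterministic but arbitrary in which schedule slots it repeats.
* Shapley attributions use background-mean replacement, which ignores
  feature correlation within a coalition; attributions on strongly
  correlated frequency grids should be read as a ranking, not a
  decomposition of physical effect.
* Single-spectrum parameter recovery is noise-limited (see Fitting);
  parameter tables should be produced from replicate-averaged spectra, as
  the pipeline's fit stage does.
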