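# drsviab

Dielectric relaxation spectroscopy analysis of intestinal tissue viability.

Microwave-band (0.2–14 GHz) permittivity spectra of small-intestinal tissue
change systematically with ischemic injury: free and bound tissue water
redistribute as cells swell and membranes fail, shifting both dispersion
strengths and relaxation times. This package provides the full analysis
chain for that signal:

* a **double Cole-Cole forward model** and a robust bounded least-squares
  fitter for complex permittivity spectra;
* a **synthetic data generator** anchored at nine experimentally motivated
  tissue states (control, 1–6 h ischemia, and four ischemia/reperfusion
  arms), with a frequency-dependent measurement-noise model and
  between-subject variability;
* **viable / non-viable classification** (threshold: 4 h of ischemia) under
  nested stratified cross-validation, with sequence networks (LSTM,
  bidirectional LSTM, residual bidirectional LSTM, 1-D CNN) implemented in
  pure NumPy alongside linear, margin and tree-ensemble baselines;
* **frequency-importance analysis** combining standardized PCA loadings and
  permutation-sampling Shapley attributions into a reduced-band
  recommendation;
* a **pipeline and CLI** that tie the stages together reproducibly: every
  artifact is a pure function of a YAML config and one seed.

## The model

Each spectrum is the complex relative permittivity `eps*(f) = eps' - j eps''`
on a frequency grid. The forward model is a sum of two Cole-Cole
dispersions,

    eps*(w) = eps_inf + d_eps1 / (1 + (j w tau1)^(1 - alpha1))
                      + d_eps2 / (1 + (j w tau2)^(1 - alpha2)),

with `w = 2 pi f`. The slow dispersion (`tau1`, hundreds of ps) tracks bound
water and interfacial polarization; the fast dispersion (`tau2`, ~7–9 ps) is
free-water orientational relaxation. Dielectric conductivity is derived as
`sigma = eps'' * eps0 * 2 pi f` and never stored separately. Fits run as
bounded trust-region least squares on the stacked `[eps'; eps'']` residual,
with `tau` optimized in log10 space and a data-driven start plus seeded
random restarts; dispersions are relabeled so `tau1 > tau2`.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite covers unit oracles (arbitrary-precision forward-model checks,
eigendecomposition and brute-force fit oracles, analytic Shapley closed
forms), statistical properties (noise magnitudes, permuted-label chance
bands, cross-validation leakage checks) and end-to-end pipeline
reproducibility, plus a dedicated acceptance module (`tests/test_acceptance.py`).

## Worked example: fit one spectrum

```python
import numpy as np
from drsviab import ColeColeModel
from drsviab.simulate import NoiseModel, build_state_library, simulate_spectrum
from drsviab.spectra import default_grid

library = build_state_library()           # nine anchored tissue states
grid = default_grid()                     # 167 points, 200 MHz - 14 GHz
rng = np.random.default_rng(42)
spectrum = simulate_spectrum(library["I-4h"], grid, NoiseModel(), rng)

result = ColeColeModel(spectrum).fit(seed=0)
print(result.summary())
```

Output:

```
Cole-Cole fit (2 dispersion(s))
============================================
eps_inf           4.3670
delta_eps1       17.6949
tau1 [ps]       655.3994
alpha1            0.0556
delta_eps2       60.1037
tau2 [ps]         6.5663
alpha2            0.0444
--------------------------------------------
R^2             0.997261
resid norm    2.0735e+01
converged           True
restarts               5
```

The generating state `I-4h` has `delta_eps1 = 18.99`, `delta_eps2 = 56.93`,
`tau1 = 655.82 ps`, `tau2 = 6.89 ps`; a single noisy spectrum recovers the
relaxation times well while the strength/`alpha` split absorbs part of the
noise (averaging replicate spectra before fitting tightens all parameters).

## Worked example: the pipeline CLI

With a small configuration file `demo.yaml`:

```yaml
seed: 11
grid: {n_points: 40}
design:
  n_subjects: 2
  reps_per_hour: 1
  phase_totals: {control: 40, ischemia: 80, reperfusion: 48}
classify: {families: [linear_baseline], k_outer: 3, k_inner: 3}
explain: {n_records: 6, n_background: 20, n_permutations: 32}
```

```bash
drsviab run-all --config demo.yaml --out demo_out
```

writes `spectra.csv`, `labels.csv`, `fit_report.csv`,
`evaluation_report.csv`, `importance.csv` and a run log:

```
drsviab 0.1.0
seed: 11
grid: 40 points, 2e+08-1.4e+10 Hz
simulate: 168 records, phases {'control': 40, 'ischemia': 80, 'reperfusion': 48} -> spectra.csv, labels.csv
fit: 9 conditions, min R^2 0.999248 -> fit_report.csv
classify: 2 (family, band) rows -> evaluation_report.csv
explain: dominant frequencies 4.09 GHz, 12.58 GHz; recommended band 0.20-13.29 GHz -> importance.csv
```

First rows of `fit_report.csv` from that run:

```
condition,n_spectra,eps_inf,delta_eps1,delta_eps2,tau1_ps,tau2_ps,alpha1,alpha2,r_squared,converged
Control,40,7.206378,21.179628,46.999682,818.640238,8.168974,0.114484,0.018372,0.999939,True
I-1h,16,10.005738,21.070629,56.014211,684.893577,7.218185,0.132995,0.001248,0.999807,True
I-4h,11,3.514132,18.391069,63.777113,678.792210,6.180294,0.069871,0.042701,0.999709,True
```

(This desk-scale demo is deliberately tiny; classification accuracy at full
experiment scale requires the default design, `drsviab run-all --seed 0`.)

Subcommands `simulate`, `fit`, `classify` (with `--band` / `--family`) and
`explain` run individual stages; all accept `--config`, `--seed`, `--out`.

## Package layout

```
src/drsviab/
  spectra.py     grids, spectra, unit conversions, CSV I/O
  colecole.py    forward model, fitter, Model/Results interface
  simulate.py    state library, time interpolation, noise, dataset builder
  dataset.py     labeled collections, viability labeling
  nets.py        NumPy sequence networks (LSTM/BiLSTM/residual/CNN)
  classify.py    metrics, nested stratified CV, band comparison
  importance.py  PCA loadings, Shapley attribution, band selection
  config.py      validated YAML run configuration
  pipeline.py    stage orchestration and artifacts
  cli.py         click command group
docs/methods.md  methods note (assumptions, defaults, limitations)
scripts/acceptance.py  headline-figure reproduction
```
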