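# ambifocal

Analysis of free-viewing eye movements through the lens of the
**ambient → focal** two-mode hypothesis.  During free viewing of a scene
with discrete objects, primates first explore globally — large saccades
hopping *across* objects with short fixations — and later settle into
focal scrutiny — small saccades *within* a single object with long
fixations.  `ambifocal` provides a tested pipeline for characterizing this
shift directly from where saccades start and land (on which object, or on
the background), and for fitting a generative model in which the shift is
an abrupt, single, irreversible switch at a random time.

The package is aimed at oculomotor/vision researchers who have raw gaze
traces (degrees of visual angle, uniform sampling) and stimulus layouts
(object centers and radii), and at modellers who want the saccade-sequence
model itself.  Because no public dataset accompanies the original
experiments, a first-class synthetic-data generator reproduces the study
conditions end to end, so every stage is validated against known ground
truth.

## What is in the box

- **Event detection** (`ambifocal.detection`): Savitzky–Golay velocity and
  acceleration estimation (10 ms window, order 2), saccade periods from
  supra-threshold kinematics (30 deg/s, 8,000 deg/s²) with artifact
  rejection (peaks above 1,500 deg/s or 120,000 deg/s², durations outside
  5–100 ms, gaze shifts under 0.1 deg), fixations between saccades with a
  1 deg drift limit, and removal of events initiated within 150 ms of
  stimulus onset.
- **Object-based classification** (`ambifocal.classify`): the *shortest
  object distance* of a fixation labels it as an object fixation
  (< 1.5 deg, strict) or a background fixation; saccades are typed
  *intra-object*, *trans-object*, *object→background*,
  *background→object*, *background→background*.
- **Descriptive dynamics** (`ambifocal.descriptive`): onset-time
  histograms by type, binned fixation-duration and saccade-amplitude
  curves, fixated-object counts per 1-s interval, per-order type-ratio
  curves, and a permutation test for the excess of immediate same-type
  repetitions.
- **The two-mode model** (`ambifocal.model`): a four-state Markov chain —
  intra-/trans-saccade generation states in an *early* and a *late* mode —
  with an irreversible switch of probability `p_sw` per step and a
  background-flip probability `p_bg` for saccadic endpoint error.  Exact
  expected per-order type curves and fast vectorized simulation.
- **Fitting and inference** (`ambifocal.fitting`): the inverse
  mean-deviation goodness of fit

  GoF = [ (1/(N_fix−1)) Σᵢ | rᵢᵉᵐᵖ − rᵢᵐᵒᵈ |₁ ]⁻¹,

  exhaustive grid search of (p_sw, p_intra^E, p_trans^E, p_intra^L,
  p_trans^L) in steps of 0.05, AIC comparison of the switch model (k = 5)
  against the single-mode model (k = 2), and a forward-filtering posterior
  over the switch step for a single trial.
- **Synthetic data** (`ambifocal.stimuli`, `ambifocal.synth`): random
  object layouts (34.8 × 26.1 deg², ≥ 4 deg separation), model-driven
  ground-truth event sequences, and rendered 20 kHz gaze traces with
  raised-cosine saccade velocity profiles.
- **I/O and pipeline** (`ambifocal.io`, `ambifocal.pipeline`,
  `ambifocal` CLI): HDF5/TSV traces, TSV event tables, YAML/JSON
  parameters and configuration, a deterministic end-to-end driver, and
  figures for every analysis.

## Worked example

Simulate 10,000 trials from the object-start reference parameter set
(p_sw = 0.20, early stay probabilities (0.00, 1.00), late (0.90, 0.55),
p_bg = 0.23, 21 fixations per trial), refit the model from scratch, and
locate the switch in a single trial:

```python
from ambifocal import (
    EXAMPLE_PARAMS_OBJECT_START, simulate_trials,
    ratio_curves_from_type_sequences, grid_search_fit, fit_no_switch,
    aic_compare, infer_switch_posterior,
)

truth = EXAMPLE_PARAMS_OBJECT_START
sim = simulate_trials(truth, 10_000, seed=7)
emp = ratio_curves_from_type_sequences(sim["types"].tolist())

fit = grid_search_fit(emp, truth.p_bg, truth.n_fix, truth.initial_condition)
fit_n = fit_no_switch(emp, truth.p_bg, truth.n_fix, truth.initial_condition)
cmp_ = aic_compare(sim["types"].tolist(), fit, fit_n)

bp = fit.best_params
print((bp.p_sw, bp.p_intra_e, bp.p_trans_e, bp.p_intra_l, bp.p_trans_l))
print("GoF = %.1f" % fit.gof)
print("AIC switch = %.0f, no-switch = %.0f -> %s"
      % (cmp_.aic_switch, cmp_.aic_no_switch, cmp_.preferred))

post = infer_switch_posterior(sim["types"][0].tolist(), bp)
print("MAP switch step =", post.map_step)
```

Output:

```
(0.2, 0.0, 1.0, 0.9, 0.55)
GoF = 70.0
AIC switch = 548896, no-switch = 590694 -> switch
MAP switch step = 16
```

The grid search recovers the generating parameter vector exactly; the GoF
of 70 means the fitted curves deviate from the empirical ones by ~0.014
(L1 over the five types) per saccade order, which is the Monte Carlo noise
floor at 10,000 trials.  The switch model wins the AIC comparison by a
wide margin, as it should for data that do switch.  The inferred switch
step for the first simulated trial (an unusually late switch — the trial
is a long run of trans-object saccades) has its posterior mode at
saccade 16.  The expected switch order is 1/p_sw = 5: on average the
mode switch happens around the fifth saccade.

The same pipeline runs from the shell:

```bash
ambifocal report --config config.yaml --seed 1 --out results/ --plots
```

## Notes

See `docs/methods.md` for the model definition, the fitting procedure,
the synthetic-data design, numerical choices, and known limitations
(including a shallow identifiability ridge of the marginal-curve fit).
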