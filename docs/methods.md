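# Methods

This note documents the models and procedures implemented in
`ambifocal`, the choices made where the design was open, and what the
synthetic-data validation does and does not establish.

## The two-mode saccade-generation model

A free-viewing trial is modelled as a discrete-time Markov chain over
four saccade-generation states: an **intra-object** state and a
**trans-object** state in each of two modes, **early** (ambient) and
**late** (focal).  One saccade is emitted per step; a trial has
`n_fix` fixations and therefore `n_fix − 1` steps.

- **Initialization.**  The chain starts in the early mode.  The first
  state is drawn from the stationary distribution of the early-mode
  dynamics: P(intra) = (1 − p_trans^E) / (2 − p_intra^E − p_trans^E).
  The degenerate corner p_intra^E = p_trans^E = 1 has no stationary
  distribution and is rejected (and excluded from grid searches).
- **Within-mode dynamics.**  In mode m, the chain repeats the intra-state
  with probability p_intra^m and the trans-state with p_trans^m,
  otherwise it moves to the other state.
- **The switch.**  At each transition out of an early-mode state the
  chain switches irreversibly to the late mode with probability `p_sw`
  (within-early transition probabilities are multiplied by 1 − p_sw).
  *Semantics:* the transition into the switch step already uses the
  late-mode stay probabilities, so the first step that can be spent in
  the late mode is step 2.  The number of transition attempts before the
  switch is geometric with mean 1/p_sw, which is the "expected switch
  order" quoted throughout (5 for p_sw = 0.2); `StateSequence.switch_step`
  itself (the 1-based index of the first late step) equals that count
  plus one.
- **Fixation sequence.**  States map to fixations in a two-object world:
  intra keeps the current object, trans toggles it.  With an object
  start, fixation 1 is on object 1.  With a background start, fixation 1
  is forced background and the putative sequence enters object 1 at
  fixation 2 regardless of the first state — the realized first saccade
  is background→object either way, so type statistics are unaffected.
- **Background flips.**  Saccadic endpoint error is modelled by flipping
  each non-protected fixation to a background fixation independently with
  probability `p_bg` (fixation 1 is protected on an object start and
  forced on a background start).  Realized saccade types are re-derived
  from the flipped fixation sequence with the same rules used for
  empirical data.

### Exact expected curves

The observable fitted by the model is the per-order distribution of the
five saccade types.  Propagating the joint (mode, state) occupancy gives
s_i = P(state_i = intra) exactly; with flip probabilities b_i (b_1 ∈
{0, 1} by the initial condition, b_i = p_bg otherwise), the type
probabilities at order i are

- intra: s_i (1 − b_i)(1 − b_{i+1})
- trans: (1 − s_i)(1 − b_i)(1 − b_{i+1})
- object→background: (1 − b_i) b_{i+1}
- background→object: b_i (1 − b_{i+1})
- background→background: b_i b_{i+1}

These exact curves replace Monte Carlo simulation inside the fit, making
the grid-search arg-max deterministic given the data; Monte Carlo curves
(`simulate_ratio_curves`) are retained as an option and as an independent
cross-check (the test suite verifies agreement to < 0.01 max-abs at 10⁵
trials).

## Fitting

`p_bg` is fixed to the empirical proportion of background fixations
before fitting and never searched.  The remaining five probabilities are
searched exhaustively on a grid in steps of 0.05 (21⁵ combinations),
maximizing

GoF = [ (1/(N_fix − 1)) Σᵢ ‖rᵢ^emp − rᵢ^mod‖ ]⁻¹ ,

with the L1 norm over the five components by default (an L2 option is
exposed; the two rarely disagree on the arg-max).  Ties are broken
lexicographically — smallest p_sw, then the stay probabilities in
early-intra, early-trans, late-intra, late-trans order — and the tie
count is reported.  The grid evaluation is vectorized: the state
occupancies over the whole grid depend only on the grid geometry and are
cached across fits (float32, ~330 MB for 20 orders), so one full search
takes a few seconds after the first.

**Model comparison.**  The no-switch model pins p_sw = 0, leaving a
single mode whose two stay probabilities are the only free parameters
(k = 2, against k = 5 for the switch model; p_bg is pre-fixed in both and
not counted).  Because the method fits marginal curves, the likelihood
used for AIC treats each saccade order as an independent draw from the
model's marginal type distribution at that order — an
independent-across-orders multinomial.  This is the largest interpretive
choice in the package: it ignores within-trial sequential dependence, so
the absolute AIC values should be read as fit indices under that
surrogate likelihood, while the *difference* between the two models is
informative because both use the same construction.

**Switch-step posterior.**  For one trial's type sequence, the prior over
the switch step s is the geometric law P(s) = p_sw (1 − p_sw)^(s−2)
for s = 2..n plus P(no switch within the n observed saccades) =
(1 − p_sw)^(n−1).  The likelihood of the observed types given s runs
early dynamics before s and late dynamics from s, integrating over the
hidden putative states and flip indicators with a forward pass over the
joint variable (state, flip of current fixation).  The forward pass is
verified against brute-force enumeration in the tests.

### Identifiability

The marginal per-order curves carry a shallow ridge: a larger p_sw
combined with slower late-mode mixing (higher stay probabilities)
produces curves nearly identical to a smaller p_sw with faster mixing —
e.g. (p_sw, p_intra^L, p_trans^L) = (0.40, 0.95, 0.80) lies within 0.009
max-abs of (0.20, 0.90, 0.55) for the object-start condition.  With 10⁴
trials the multinomial noise (~0.005 per component) occasionally tips the
arg-max onto the rival grid point (measured: ~1 in 15 seeds for the
object-start condition, ~1 in 5 for the background-start condition).
More trials, or likelihoods using within-trial transitions, would resolve
the ridge; the grid fit itself is faithful to the curve-matching method.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated:

- **Layouts:** 5 objects of 1 deg radius placed uniformly in a
  34.8 × 26.1 deg² image with ≥ 4 deg center separation; the object-start
  condition pins object 1 to the image center.
- **Trials:** fixation labels and the true switch step come from the
  model above.  Object fixations land uniformly within the object's
  radius; background fixations are rejection-sampled with a nearest-
  object-center distance in (1.5, 3.0] deg — unambiguously background
  under the 1.5 deg rule yet spatially plausible.  Consecutive fixation
  positions are kept ≥ 0.5 deg apart, the lower edge of the renderer's
  detectability guarantee, so every generated saccade is in principle
  detectable.
- **Durations:** gamma-distributed (shape 10) with mean 0.15 s at trial
  start growing by 0.04 s per second of trial time, floored at 0.05 s.
  This reproduces the qualitative increase of fixation duration over a
  trial (0.15 → ~0.35 s across 5 s); with 21 fixations it also yields
  ~5 s trials.  The decrease of saccade amplitude over the trial is not
  imposed; it emerges from the mode dynamics (early trans-object saccades
  span objects ≥ 4 deg apart, late intra-object saccades stay within a
  1 deg-radius object).
- **Rendering:** fixations are stationary epochs (plus optional white
  position noise); saccades follow a straight line with a raised-cosine
  velocity profile, for which peak velocity = 2A/D and peak acceleration
  = 2πA/D² in closed form.  The main-sequence rule D = 0.012 s +
  0.0012 s/deg · A guarantees that every saccade of amplitude 0.5–15 deg
  clears the detection thresholds (peak velocity ≥ 62 deg/s, peak
  acceleration ≥ 12,000 deg/s² at A = 0.5 even after the 10 ms smoothing
  window) while staying below the artifact caps (1,071 deg/s and
  105,000 deg/s² at A = 15).  Default sampling is the native 20 kHz; the
  test suite mostly renders at 2 kHz, which the time-specified filters
  make equivalent and which keeps the suite fast.

What the synthetic validation shows: the detector, classifier,
descriptive statistics and fitting recover known ground truth under
realistic geometry, kinematics and noise levels.  What it does not show:
robustness to real-data phenomena the generator omits — blinks, drift and
smooth pursuit within fixations, curved saccade trajectories, overshoot
dynamics, measurement dropouts, and saliency-driven (non-Markov) target
selection.

## Event detection: numerical choices

- Velocity/acceleration via Savitzky–Golay derivative filters specified
  in time (10 ms, order 2) and scaled to an odd sample count at the
  trace's rate (199 samples at 20 kHz).  Half-window edge samples are
  excluded from segment formation.
- **Acceleration criterion.**  The acceleration magnitude of any smooth
  saccade passes through zero at peak velocity, so demanding
  supra-threshold acceleration at *every* sample of a segment would split
  each saccade into two sub-segments (each typically shorter than the
  5 ms minimum) and detect nothing.  Candidate periods are therefore
  maximal runs of supra-threshold *speed* whose *peak* acceleration
  magnitude exceeds 8,000 deg/s²; the acceleration criterion thus rejects
  slow coherent drifts that exceed the speed threshold without saccadic
  dynamics.
- **Leading interval.**  The fixation in progress at stimulus onset is
  treated as initiated before onset (it continues the pre-stimulus
  fixation): it is clipped to start at stimulus onset and is *not*
  removed by the 150 ms exclusion, which applies to events whose onset
  falls strictly after stimulus onset.  The trailing interval before the
  trace end becomes a fixation under the same drift rule.
- Fixation drift is measured as the exact diameter of the gaze point set
  (convex hull; degenerate sets fall back to extreme-point enumeration).
- Ties in the nearest object are broken toward the lowest object id, and
  the 1.5 deg object threshold is strict (a distance of exactly 1.5 deg
  is background).

## Descriptive statistics

Ratio curves at order i use all trials with at least i classified
saccades (trials are re-indexed over classified saccades after the
150 ms and drift exclusions).  Ratios in bins or at orders with zero
events are NaN (undefined), never zero.  The repetition-excess test
shuffles each trial's type sequence independently (preserving per-trial
type counts) and reports one-sided add-one-corrected p-values for the
count of immediate same-type successions; this is a deliberately simple
operationalization of "more repetitions than chance" and is labelled as
such.

## Problem sizes

The shipped validation uses: 10⁵ state sequences for the switch-time
Monte Carlo; 10⁴ trials per condition for parameter recovery; 10⁵ trials
per vector for the Monte Carlo/exact cross-check (10 random vectors);
2,000 trials × 20 replicates per condition for the AIC selection study;
600 ground-truth trials for the classification-threshold robustness
check; and 30 rendered trials at 2 kHz for the end-to-end round-trip
suite.  These sizes put Monte Carlo error well below every asserted
tolerance.

## Known limitations

- The AIC likelihood is a marginal surrogate (see above).
- The grid fit inherits the identifiability ridge of the marginal-curve
  method (see above).
- The generator draws trans-object targets uniformly among the other
  objects; type statistics — all the fitting consumes — are unaffected,
  but spatial scanpath statistics (e.g. revisitation patterns) are not
  calibrated to real data.
- Only an abrupt one-way switch is implemented; gradual-shift
  (time-inhomogeneous) variants are out of scope.
- No blink handling or torsional components; traces are assumed clean and
  uniformly sampled.
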