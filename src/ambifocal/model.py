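"""Two-mode Markov model of saccade sequence generation during free viewing.

The model formalizes the ambient-to-focal shift of visual exploration as a
discrete-time Markov chain over four saccade-generation states: an
*intra-object* state and a *trans-object* state in each of two modes, an
*early* (ambient) mode and a *late* (focal) mode.  At every step the chain
emits one saccade of the type given by its current state.  The chain starts
in the early mode, drawn from the stationary distribution of the early-mode
dynamics, and at each subsequent step may switch irreversibly to the late
mode with probability ``p_sw``.  Within a mode, the chain repeats the
intra-state with its stay probability (``p_intra_e`` / ``p_intra_l``) and
the trans-state likewise (``p_trans_e`` / ``p_trans_l``).

A state sequence is turned into a fixation sequence in a two-object world
(intra keeps the current object, trans toggles it), each non-protected
fixation is flipped to a background fixation independently with probability
``p_bg`` (modelling saccadic endpoint error), and the realized saccade types
are re-derived from the flipped fixation sequence exactly as empirical
saccades are classified.  The observable signature of the model is the set
of per-order saccade-type probability curves, for which both a Monte Carlo
estimate and an exact closed-form propagation are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SACCADE_TYPES",
    "ModelParams",
    "StateSequence",
    "TypeProbabilityCurves",
    "EXAMPLE_PARAMS_OBJECT_START",
    "EXAMPLE_PARAMS_BACKGROUND_START",
    "initial_state_distribution",
    "expected_switch_step",
    "simulate_state_sequence",
    "simulate_trials",
    "states_to_fixation_sequence",
    "simulate_ratio_curves",
    "expected_ratio_curves",
]

#: Canonical component order of all 5-vectors of saccade-type statistics.
SACCADE_TYPES = (
    "intra_object",
    "trans_object",
    "object_to_background",
    "background_to_object",
    "background_to_background",
)

# integer state codes used in vectorized simulation
_INTRA, _TRANS = 0, 1


class DegenerateModelError(ValueError):
    """Both early stay probabilities are 1: the early-mode chain has no
    unique stationary distribution."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the two-mode saccade-generation model.

    Parameters
    ----------
    p_sw:
        Per-step probability of the irreversible early-to-late mode switch.
    p_intra_e, p_trans_e:
        Stay probabilities of the intra- and trans-state in the early mode.
    p_intra_l, p_trans_l:
        Stay probabilities of the intra- and trans-state in the late mode.
    p_bg:
        Probability of flipping a fixation to a background fixation,
        modelling saccadic endpoint error.  Fixed from the empirical
        background-fixation proportion before fitting, never searched.
    n_fix:
        Number of fixations per simulated trial (the chain runs for
        ``n_fix - 1`` steps, one per saccade).
    initial_condition:
        ``"object"`` if the first fixation is on an object (stimulus with a
        central object: the pre-stimulus fixation lands on it), or
        ``"background"`` if the first fixation is on the background.
    """

    p_sw: float
    p_intra_e: float
    p_trans_e: float
    p_intra_l: float
    p_trans_l: float
    p_bg: float = 0.0
    n_fix: int = 21
    initial_condition: Literal["object", "background"] = "object"

    def __post_init__(self) -> None:
        for name in ("p_sw", "p_intra_e", "p_trans_e", "p_intra_l", "p_trans_l", "p_bg"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} is not a probability in [0, 1]")
        if self.n_fix < 2:
            raise ValueError(f"n_fix must be >= 2, got {self.n_fix}")
        if self.initial_condition not in ("object", "background"):
            raise ValueError(f"unknown initial_condition {self.initial_condition!r}")

    @property
    def n_steps(self) -> int:
        """Number of saccades (chain steps) per trial."""
        return self.n_fix - 1

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


#: Representative best-fitting parameter set for a macaque free-viewing
#: session whose stimuli always contain an object at the center of the
#: image, so that the first fixation is an object fixation (21 fixations
#: per 5-s trial on average, empirical background-fixation rate 0.23).
EXAMPLE_PARAMS_OBJECT_START = ModelParams(
    p_sw=0.20, p_intra_e=0.00, p_trans_e=1.00, p_intra_l=0.90, p_trans_l=0.55,
    p_bg=0.23, n_fix=21, initial_condition="object",
)

#: Representative best-fitting parameter set for a session without a
#: central object, so that the first fixation falls on the background
#: (16 fixations per trial on average, background-fixation rate 0.21).
EXAMPLE_PARAMS_BACKGROUND_START = ModelParams(
    p_sw=0.25, p_intra_e=0.05, p_trans_e=0.50, p_intra_l=0.90, p_trans_l=0.55,
    p_bg=0.21, n_fix=16, initial_condition="background",
)


@dataclass
class StateSequence:
    """A simulated sequence of (mode, state) pairs, one per saccade.

    ``modes[i]`` / ``states[i]`` describe the chain at step ``i + 1``
    (1-based saccade order).  ``switch_step`` is the 1-based order of the
    first step spent in the late mode, or ``None`` if the switch did not
    occur within the sequence.  The switch is a geometric first-success
    process over the transitions between steps, so
    ``switch_step - 1`` counts the Bernoulli trials until the first
    success and has expectation ``1 / p_sw``.
    """

    modes: np.ndarray  # 0 = early, 1 = late
    states: np.ndarray  # 0 = intra, 1 = trans
    switch_step: int | None

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class TypeProbabilityCurves:
    """Per-saccade-order 5-vectors of saccade-type probabilities.

    ``probs[i - 1]`` is the distribution of the type of the i-th saccade
    over the five types in :data:`SACCADE_TYPES` order.
    """

    probs: np.ndarray  # shape (n_orders, 5)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 5:
            raise ValueError("probs must have shape (n_orders, 5)")

    @property
    def n_orders(self) -> int:
        return self.probs.shape[0]


def initial_state_distribution(params: ModelParams) -> tuple[float, float]:
    """Stationary distribution ``(P(intra), P(trans))`` of the early-mode
    chain, used as the distribution of the first state.

    For stay probabilities ``(p_intra_e, p_trans_e)`` the stationary
    occupancy of the intra-state is
    ``(1 - p_trans_e) / (2 - p_intra_e - p_trans_e)``, and the complement
    for the trans-state.
    """
    denom = 2.0 - params.p_intra_e - params.p_trans_e
    if denom <= 0.0:
        raise DegenerateModelError(
            "p_intra_e = p_trans_e = 1: the early-mode chain never leaves its "
            "initial state and has no unique stationary distribution"
        )
    p_intra = (1.0 - params.p_trans_e) / denom
    return p_intra, 1.0 - p_intra


def expected_switch_step(p_sw: float) -> float:
    """Expected number of saccades generated before the mode switch.

    The switch is the first success of a Bernoulli(``p_sw``) process over
    successive transitions, so the expectation is ``1 / p_sw`` (geometric
    mean first-success time).  Returns ``inf`` for ``p_sw = 0``.
    """
    if not (0.0 <= p_sw <= 1.0):
        raise ValueError(f"p_sw={p_sw!r} is not a probability")
    if p_sw == 0.0:
        return float("inf")
    return 1.0 / p_sw


def _rng(seed: int | np.random.Generator | np.random.SeedSequence) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_trials(
    params: ModelParams,
    n_trials: int,
    seed: int | np.random.Generator,
    events: bool = True,
) -> dict[str, np.ndarray]:
    """Vectorized simulation of ``n_trials`` trials of the full model.

    Returns a dict with arrays over trials:

    - ``modes``: (n_trials, n_steps) int8, 0 = early, 1 = late
    - ``states``: (n_trials, n_steps) int8, 0 = intra, 1 = trans
    - ``switch_step``: (n_trials,) int, 1-based order of the first late
      step, or 0 where no switch occurred within the trial
    - ``objects``: (n_trials, n_fix) int8, putative object identity (1/2)
    - ``background``: (n_trials, n_fix) bool, realized background flips
    - ``types``: (n_trials, n_steps) int8, realized saccade-type codes in
      :data:`SACCADE_TYPES` order

    With ``events=False`` only the chain itself is simulated (``objects``,
    ``background`` and ``types`` are omitted), which is cheaper for
    switch-timing studies on long chains.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = _rng(seed)
    n_steps = params.n_steps

    modes = np.zeros((n_trials, n_steps), dtype=np.int8)
    states = np.zeros((n_trials, n_steps), dtype=np.int8)

    p_intra0, _ = initial_state_distribution(params)
    states[:, 0] = (rng.random(n_trials) >= p_intra0).astype(np.int8)  # 0 intra, 1 trans

    stay_early = np.array([params.p_intra_e, params.p_trans_e])
    stay_late = np.array([params.p_intra_l, params.p_trans_l])

    for k in range(1, n_steps):
        prev_mode = modes[:, k - 1]
        prev_state = states[:, k - 1]
        switching = (prev_mode == 0) & (rng.random(n_trials) < params.p_sw)
        mode_now = np.where((prev_mode == 1) | switching, 1, 0).astype(np.int8)
        # the transition into the switch step already uses late-mode dynamics
        p_stay = np.where(mode_now == 1, stay_late[prev_state], stay_early[prev_state])
        stay = rng.random(n_trials) < p_stay
        states[:, k] = np.where(stay, prev_state, 1 - prev_state).astype(np.int8)
        modes[:, k] = mode_now

    late_any = modes == 1
    switch_step = np.where(late_any.any(axis=1), late_any.argmax(axis=1) + 1, 0)

    out = {"modes": modes, "states": states, "switch_step": switch_step}
    if events:
        objects, background = _realize_fixations(params, states, rng)
        out["objects"] = objects
        out["background"] = background
        out["types"] = derive_saccade_types(objects, background)
    return out


def _realize_fixations(
    params: ModelParams, states: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Map state sequences to putative object identities and background flips.

    Two-object world: intra keeps the current object, trans toggles it.
    With a background start the first fixation is forced background and the
    putative sequence enters object 1 at fixation 2 (whatever the first
    state is, the realized first saccade is background-to-object); states
    from step 2 onward drive the toggling.
    """
    n_trials, n_steps = states.shape
    n_fix = n_steps + 1
    objects = np.ones((n_trials, n_fix), dtype=np.int8)
    if params.initial_condition == "object":
        # fixation j+1 toggles the object when state j is trans
        toggles = np.cumsum(states, axis=1) % 2
        objects[:, 1:] = 1 + toggles
    else:
        # fixation 1 is background; putative object sequence starts at
        # fixation 2 on object 1, driven by states 2..n_steps
        if n_steps >= 2:
            toggles = np.cumsum(states[:, 1:], axis=1) % 2
            objects[:, 2:] = 1 + toggles

    flips = rng.random((n_trials, n_fix)) < params.p_bg
    if params.initial_condition == "object":
        flips[:, 0] = False  # first fixation protected
    else:
        flips[:, 0] = True  # first fixation forced background
    return objects, flips


def derive_saccade_types(objects: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Classify saccades from consecutive (object id, background flag) pairs.

    Mirrors the classification of empirical saccades: both fixations on the
    same object -> intra, different objects -> trans, and the four
    object/background combinations otherwise.
    """
    prev_bg = background[..., :-1]
    next_bg = background[..., 1:]
    same_obj = objects[..., :-1] == objects[..., 1:]
    types = np.empty(prev_bg.shape, dtype=np.int8)
    both_obj = ~prev_bg & ~next_bg
    types[both_obj & same_obj] = 0
    types[both_obj & ~same_obj] = 1
    types[~prev_bg & next_bg] = 2
    types[prev_bg & ~next_bg] = 3
    types[prev_bg & next_bg] = 4
    return types


def simulate_state_sequence(
    params: ModelParams, n_steps: int | None = None, seed: int | np.random.Generator = 0
) -> StateSequence:
    """Simulate a single sequence of (mode, state) pairs.

    ``n_steps`` defaults to ``params.n_steps``.
    """
    n_steps = params.n_steps if n_steps is None else int(n_steps)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    sim = simulate_trials(params.with_(n_fix=n_steps + 1), 1, seed, events=False)
    switch = int(sim["switch_step"][0])
    return StateSequence(
        modes=sim["modes"][0],
        states=sim["states"][0],
        switch_step=switch if switch > 0 else None,
    )


def states_to_fixation_sequence(
    states: StateSequence | np.ndarray,
    params: ModelParams,
    seed: int | np.random.Generator = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Turn one state sequence into fixation labels and realized saccade types.

    Returns ``(putative_fixations, simulated_fixations, simulated_types)``
    where fixation labels are ``"object1"`` / ``"object2"`` /
    ``"background"`` and types are names from :data:`SACCADE_TYPES`.
    """
    arr = states.states if isinstance(states, StateSequence) else np.asarray(states)
    if arr.ndim != 1:
        raise ValueError("expected a single state sequence")
    if len(arr) != params.n_steps:
        raise ValueError(
            f"state sequence has {len(arr)} steps but params.n_fix={params.n_fix} "
            f"implies {params.n_steps}"
        )
    rng = _rng(seed)
    objects, flips = _realize_fixations(params, arr[None, :], rng)
    putative = [f"object{o}" for o in objects[0]]
    if params.initial_condition == "background":
        putative[0] = "background"
    simulated = [
        "background" if f else f"object{o}" for o, f in zip(objects[0], flips[0])
    ]
    types = derive_saccade_types(objects, flips)[0]
    return putative, simulated, [SACCADE_TYPES[t] for t in types]


def simulate_ratio_curves(
    params: ModelParams, n_trials: int, seed: int | np.random.Generator = 0
) -> TypeProbabilityCurves:
    """Monte Carlo estimate of the per-order saccade-type probabilities."""
    sim = simulate_trials(params, n_trials, seed)
    types = sim["types"]
    n_steps = types.shape[1]
    counts = np.zeros((n_steps, 5))
    for t in range(5):
        counts[:, t] = (types == t).sum(axis=0)
    return TypeProbabilityCurves(counts / n_trials)


def state_intra_probabilities(params: ModelParams, n_orders: int | None = None) -> np.ndarray:
    """Exact ``P(state_i = intra)`` for i = 1..n_orders.

    Propagates the joint (mode, state) occupancy through the four-state
    chain.  The transition into the switch step already uses late-mode stay
    probabilities.
    """
    n_orders = params.n_steps if n_orders is None else int(n_orders)
    p_intra0, p_trans0 = initial_state_distribution(params)
    psw = params.p_sw
    pie, pte = params.p_intra_e, params.p_trans_e
    pil, ptl = params.p_intra_l, params.p_trans_l

    # occupancy vector: [early-intra, early-trans, late-intra, late-trans]
    d = np.array([p_intra0, p_trans0, 0.0, 0.0])
    out = np.empty(n_orders)
    out[0] = d[0] + d[2]
    for i in range(1, n_orders):
        ei, et, li, lt = d
        new_ei = (1 - psw) * (ei * pie + et * (1 - pte))
        new_et = (1 - psw) * (et * pte + ei * (1 - pie))
        influx_i = psw * (ei * pil + et * (1 - ptl))
        influx_t = psw * (et * ptl + ei * (1 - pil))
        new_li = li * pil + lt * (1 - ptl) + influx_i
        new_lt = lt * ptl + li * (1 - pil) + influx_t
        d = np.array([new_ei, new_et, new_li, new_lt])
        out[i] = d[0] + d[2]
    return out


def background_flip_probabilities(params: ModelParams, n_fix: int | None = None) -> np.ndarray:
    """Per-fixation background probabilities ``b[j]`` for j = 1..n_fix.

    The first fixation is deterministic (protected object fixation or
    forced background fixation); every later fixation flips independently
    with probability ``p_bg``.
    """
    n_fix = params.n_fix if n_fix is None else int(n_fix)
    b = np.full(n_fix, params.p_bg)
    b[0] = 0.0 if params.initial_condition == "object" else 1.0
    return b


def expected_ratio_curves(params: ModelParams) -> TypeProbabilityCurves:
    """Exact per-order saccade-type probability curves.

    Combines the putative state probabilities with the independent
    background flips: for saccade order i flanked by fixations i and i+1
    with background probabilities ``b_i`` and ``b_{i+1}``,

    - P(intra)  = P(state_i = intra) (1 - b_i)(1 - b_{i+1})
    - P(trans)  = P(state_i = trans) (1 - b_i)(1 - b_{i+1})
    - P(obj->bg) = (1 - b_i) b_{i+1}
    - P(bg->obj) = b_i (1 - b_{i+1})
    - P(bg->bg)  = b_i b_{i+1}
    """
    n = params.n_steps
    s = state_intra_probabilities(params, n)
    b = background_flip_probabilities(params)
    b_prev, b_next = b[:-1], b[1:]
    both = (1 - b_prev) * (1 - b_next)
    probs = np.column_stack(
        [
            s * both,
            (1 - s) * both,
            (1 - b_prev) * b_next,
            b_prev * (1 - b_next),
            b_prev * b_next,
        ]
    )
    return TypeProbabilityCurves(probs)
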