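"""Fitting the two-mode model to per-order saccade-type ratio curves.

The fit quality is an inverse mean-deviation goodness-of-fit

    GoF = ( (1 / (N_fix - 1)) * sum_i | r_i_emp - r_i_model | )^-1

where ``r_i_emp`` is the empirical 5-vector of saccade-type ratios at
saccade order i, ``r_i_model`` the model's exact expected 5-vector, and
``|.|`` the L1 norm over the five components (an L2 option is exposed).
The five free parameters (p_sw and the four stay probabilities) are fitted
by exhaustive grid search in steps of 0.05 while the background-flip
probability is pre-fixed to the empirical background-fixation proportion.

Model comparison between the full (switching) model and a single-mode
(no-switch) model uses AIC with an independent-across-orders multinomial
likelihood built from the same expected curves.  A forward-filtering
routine turns the fitted model into a posterior over the switch step for a
single trial's saccade-type sequence.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .model import (
    SACCADE_TYPES,
    ModelParams,
    TypeProbabilityCurves,
    background_flip_probabilities,
    expected_ratio_curves,
    initial_state_distribution,
)

__all__ = [
    "FitResult",
    "AICComparison",
    "SwitchPosterior",
    "NO_SWITCH",
    "goodness_of_fit",
    "grid_search_fit",
    "fit_no_switch",
    "sequence_log_likelihood",
    "type_counts_by_order",
    "aic_compare",
    "infer_switch_posterior",
]

#: Key used for the "no switch within this trial" event in posteriors.
NO_SWITCH = "no_switch"

_PARAM_ORDER = ("p_sw", "p_intra_e", "p_trans_e", "p_intra_l", "p_trans_l")


class ModelInconsistencyError(ValueError):
    """The observed sequence has probability zero under the given model."""


def _as_ratio_array(r_emp, n_orders: int) -> np.ndarray:
    """Coerce empirical curves to a dense (n_orders, 5) array."""
    raw = getattr(r_emp, "ratios", getattr(r_emp, "probs", r_emp))
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 5:
        raise ValueError("empirical ratio curves must have shape (n_orders, 5)")
    if arr.shape[0] < n_orders:
        raise ValueError(
            f"empirical curves cover {arr.shape[0]} orders but {n_orders} are required"
        )
    arr = arr[:n_orders]
    if not np.isfinite(arr).all():
        raise ValueError("empirical ratio curves contain undefined (NaN) orders")
    return arr


def goodness_of_fit(
    r_emp,
    r_model: TypeProbabilityCurves,
    n_fix: int,
    norm: Literal["l1", "l2"] = "l1",
) -> float:
    """Inverse mean per-order deviation between empirical and model curves.

    Perfect agreement yields ``inf``.
    """
    n_orders = n_fix - 1
    emp = _as_ratio_array(r_emp, n_orders)
    mod = np.asarray(r_model.probs, dtype=float)
    if mod.shape[0] < n_orders:
        raise ValueError("model curves cover fewer orders than n_fix - 1")
    diff = emp - mod[:n_orders]
    if norm == "l1":
        dev = np.abs(diff).sum(axis=1)
    elif norm == "l2":
        dev = np.sqrt((diff**2).sum(axis=1))
    else:
        raise ValueError(f"unknown norm {norm!r}")
    mean_dev = float(dev.mean())
    return float("inf") if mean_dev == 0.0 else 1.0 / mean_dev


def _grid_values(grid_step: float) -> np.ndarray:
    n = round(1.0 / grid_step)
    if abs(n * grid_step - 1.0) > 1e-9:
        raise ValueError(f"grid_step={grid_step} does not divide 1 evenly")
    return np.round(np.linspace(0.0, 1.0, n + 1), 12)


@functools.lru_cache(maxsize=4)
def _intra_occupancy_grid(n_orders: int, grid_step: float) -> np.ndarray:
    """Exact P(state_i = intra) on the full 5-parameter grid.

    Returns a float32 array of shape ``(n_orders, G, G, G, G, G)`` with
    axes (order; p_sw, p_intra_e, p_trans_e, p_intra_l, p_trans_l).  The
    degenerate grid points with p_intra_e = p_trans_e = 1 (no stationary
    early-mode distribution) are filled with NaN.  Cached because the
    occupancies depend only on the grid geometry, never on the data.
    """
    g = _grid_values(grid_step)
    G = len(g)
    psw = g.reshape(G, 1, 1, 1, 1)
    pie = g.reshape(1, G, 1, 1, 1)
    pte = g.reshape(1, 1, G, 1, 1)
    pil = g.reshape(1, 1, 1, G, 1)
    ptl = g.reshape(1, 1, 1, 1, G)

    denom = 2.0 - pie - pte
    ok = denom > 0
    pi0 = np.where(ok, (1.0 - pte) / np.where(ok, denom, 1.0), np.nan)

    # early-mode occupancy depends only on (p_sw, p_intra_e, p_trans_e)
    ei = np.broadcast_to(pi0, (G, G, G, 1, 1)).copy()
    et = 1.0 - ei
    li = np.zeros((G, G, G, G, G))
    lt = np.zeros((G, G, G, G, G))

    out = np.empty((n_orders, G, G, G, G, G), dtype=np.float32)
    out[0] = (ei + li).astype(np.float32)
    keep = 1.0 - psw
    for i in range(1, n_orders):
        new_li = li * pil + lt * (1.0 - ptl) + psw * (ei * pil + et * (1.0 - ptl))
        new_lt = lt * ptl + li * (1.0 - pil) + psw * (et * ptl + ei * (1.0 - pil))
        new_ei = keep * (ei * pie + et * (1.0 - pte))
        new_et = keep * (et * pte + ei * (1.0 - pie))
        ei, et, li, lt = new_ei, new_et, new_li, new_lt
        out[i] = (ei + li).astype(np.float32)
    return out


@dataclass
class FitResult:
    """Outcome of a grid search over the model's transition probabilities.

    ``gof_profile`` gives, for each grid value of ``p_sw``, the maximum GoF
    over the remaining varied parameters.  ``plane_early`` and
    ``plane_late`` are GoF maps over the (intra, trans) stay-probability
    planes of each mode with all other parameters held at their best
    values.  ``n_ties`` counts grid points sharing the maximal GoF (ties
    are broken lexicographically, smallest p_sw first, then the stay
    probabilities in early-intra, early-trans, late-intra, late-trans
    order).  ``log_likelihood`` and ``aic`` are filled by
    :func:`aic_compare`.
    """

    best_params: ModelParams
    gof: float
    grid: np.ndarray
    gof_profile: np.ndarray
    plane_early: np.ndarray
    plane_late: np.ndarray
    n_ties: int
    k_effective: int
    norm: str
    log_likelihood: float | None = None
    aic: float | None = None


def grid_search_fit(
    r_emp,
    p_bg_fixed: float,
    n_fix: int,
    initial_condition: Literal["object", "background"] = "object",
    grid_step: float = 0.05,
    norm: Literal["l1", "l2"] = "l1",
) -> FitResult:
    """Exhaustive grid search of the five transition probabilities.

    Evaluates the exact expected ratio curves at every combination of
    (p_sw, p_intra_e, p_trans_e, p_intra_l, p_trans_l) on the grid and
    returns the GoF-maximizing combination.  ``p_bg_fixed`` is the
    pre-fixed background-flip probability (empirical background-fixation
    proportion).
    """
    dev = _grid_deviation(
        r_emp, p_bg_fixed, n_fix, initial_condition, grid_step, norm
    )
    return _fit_from_deviation(
        dev, p_bg_fixed, n_fix, initial_condition, grid_step, norm, k_effective=5
    )


def _grid_deviation(
    r_emp,
    p_bg: float,
    n_fix: int,
    initial_condition: str,
    grid_step: float,
    norm: str,
) -> np.ndarray:
    """Sum over orders of the per-order deviation, over the full grid."""
    n_orders = n_fix - 1
    emp = _as_ratio_array(r_emp, n_orders)
    ref = ModelParams(
        p_sw=0, p_intra_e=0, p_trans_e=0, p_intra_l=0, p_trans_l=0,
        p_bg=p_bg, n_fix=n_fix, initial_condition=initial_condition,
    )
    b = background_flip_probabilities(ref)
    occ = _intra_occupancy_grid(n_orders, float(grid_step))

    dev = np.zeros(occ.shape[1:], dtype=np.float64)
    for i in range(n_orders):
        b_prev, b_next = b[i], b[i + 1]
        both = (1.0 - b_prev) * (1.0 - b_next)
        fixed = np.array(
            [(1.0 - b_prev) * b_next, b_prev * (1.0 - b_next), b_prev * b_next]
        )
        s = occ[i].astype(np.float64)
        m_intra = s * both
        m_trans = both - m_intra
        if norm == "l1":
            dev += np.abs(m_intra - emp[i, 0])
            dev += np.abs(m_trans - emp[i, 1])
            dev += np.abs(fixed - emp[i, 2:]).sum()
        elif norm == "l2":
            const = ((fixed - emp[i, 2:]) ** 2).sum()
            dev += np.sqrt(
                (m_intra - emp[i, 0]) ** 2 + (m_trans - emp[i, 1]) ** 2 + const
            )
        else:
            raise ValueError(f"unknown norm {norm!r}")
    return dev


def _fit_from_deviation(
    dev: np.ndarray,
    p_bg: float,
    n_fix: int,
    initial_condition: str,
    grid_step: float,
    norm: str,
    k_effective: int,
    fixed_axes: Mapping[int, float] | None = None,
) -> FitResult:
    g = _grid_values(grid_step)
    n_orders = n_fix - 1
    mean_dev = dev / n_orders
    with np.errstate(divide="ignore"):
        gof = np.where(mean_dev > 0, 1.0 / mean_dev, np.inf)
    gof = np.where(np.isnan(mean_dev), -np.inf, gof)  # degenerate grid points

    flat = np.nan_to_num(dev, nan=np.inf).ravel()
    best_flat = int(np.argmin(flat))  # first occurrence = lexicographic tie-break
    n_ties = int((flat == flat[best_flat]).sum())
    idx = np.unravel_index(best_flat, dev.shape)
    values = dict(zip(_PARAM_ORDER, (float(g[j]) for j in idx)))
    if fixed_axes:
        for ax, val in fixed_axes.items():
            values[_PARAM_ORDER[ax]] = val

    best_params = ModelParams(
        p_sw=values["p_sw"],
        p_intra_e=values["p_intra_e"],
        p_trans_e=values["p_trans_e"],
        p_intra_l=values["p_intra_l"],
        p_trans_l=values["p_trans_l"],
        p_bg=p_bg,
        n_fix=n_fix,
        initial_condition=initial_condition,  # type: ignore[arg-type]
    )
    profile = gof.max(axis=(1, 2, 3, 4))
    plane_early = gof[idx[0], :, :, idx[3], idx[4]]
    plane_late = gof[idx[0], idx[1], idx[2], :, :]
    return FitResult(
        best_params=best_params,
        gof=float(gof[idx]),
        grid=g,
        gof_profile=profile,
        plane_early=plane_early,
        plane_late=plane_late,
        n_ties=n_ties,
        k_effective=k_effective,
        norm=norm,
    )


def fit_no_switch(
    r_emp,
    p_bg_fixed: float,
    n_fix: int,
    initial_condition: Literal["object", "background"] = "object",
    grid_step: float = 0.05,
    norm: Literal["l1", "l2"] = "l1",
) -> FitResult:
    """Grid search of the single-mode (no-switch) model.

    With ``p_sw = 0`` the late-mode parameters have no effect, so only the
    two early-mode stay probabilities are varied (k_effective = 2).  The
    returned parameters mirror the fitted single mode into both mode slots.
    """
    n_orders = n_fix - 1
    emp = _as_ratio_array(r_emp, n_orders)
    g = _grid_values(grid_step)
    G = len(g)
    ref = ModelParams(
        p_sw=0, p_intra_e=0, p_trans_e=0, p_intra_l=0, p_trans_l=0,
        p_bg=p_bg_fixed, n_fix=n_fix, initial_condition=initial_condition,
    )
    b = background_flip_probabilities(ref)

    pie = g.reshape(G, 1)
    pte = g.reshape(1, G)
    denom = 2.0 - pie - pte
    ok = denom > 0
    ei = np.where(ok, (1.0 - pte) / np.where(ok, denom, 1.0), np.nan)
    dev = np.zeros((G, G))
    s = ei
    for i in range(n_orders):
        b_prev, b_next = b[i], b[i + 1]
        both = (1.0 - b_prev) * (1.0 - b_next)
        fixed = np.array(
            [(1.0 - b_prev) * b_next, b_prev * (1.0 - b_next), b_prev * b_next]
        )
        m_intra = s * both
        m_trans = both - m_intra
        if norm == "l1":
            dev += (
                np.abs(m_intra - emp[i, 0])
                + np.abs(m_trans - emp[i, 1])
                + np.abs(fixed - emp[i, 2:]).sum()
            )
        else:
            const = ((fixed - emp[i, 2:]) ** 2).sum()
            dev += np.sqrt(
                (m_intra - emp[i, 0]) ** 2 + (m_trans - emp[i, 1]) ** 2 + const
            )
        s = s * pie + (1.0 - s) * (1.0 - pte)

    mean_dev = dev / n_orders
    with np.errstate(divide="ignore"):
        gof = np.where(mean_dev > 0, 1.0 / mean_dev, np.inf)
    gof = np.where(np.isnan(mean_dev), -np.inf, gof)
    flat = np.nan_to_num(dev, nan=np.inf).ravel()
    best_flat = int(np.argmin(flat))
    n_ties = int((flat == flat[best_flat]).sum())
    i_ie, i_te = np.unravel_index(best_flat, dev.shape)
    best_params = ModelParams(
        p_sw=0.0,
        p_intra_e=float(g[i_ie]),
        p_trans_e=float(g[i_te]),
        p_intra_l=float(g[i_ie]),
        p_trans_l=float(g[i_te]),
        p_bg=p_bg_fixed,
        n_fix=n_fix,
        initial_condition=initial_condition,  # type: ignore[arg-type]
    )
    return FitResult(
        best_params=best_params,
        gof=float(gof[i_ie, i_te]),
        grid=g,
        gof_profile=np.array([gof[i_ie, i_te]]),
        plane_early=gof,
        plane_late=gof,
        n_ties=n_ties,
        k_effective=2,
        norm=norm,
    )


_TYPE_CODE = {name: i for i, name in enumerate(SACCADE_TYPES)}


def _coerce_types(trial: Sequence) -> np.ndarray:
    arr = np.asarray(
        [_TYPE_CODE[t] if isinstance(t, str) else int(t) for t in trial], dtype=np.int8
    )
    if arr.size and (arr.min() < 0 or arr.max() > 4):
        raise ValueError("saccade-type codes must lie in 0..4")
    return arr


def type_counts_by_order(trials: Sequence[Sequence], n_orders: int) -> np.ndarray:
    """Count observed saccade types per order: shape ``(n_orders, 5)``."""
    counts = np.zeros((n_orders, 5), dtype=np.int64)
    for trial in trials:
        arr = _coerce_types(trial)
        if len(arr) > n_orders:
            raise ValueError(
                f"trial has {len(arr)} saccades but the model allows {n_orders}"
            )
        for i, t in enumerate(arr):
            counts[i, t] += 1
    return counts


def sequence_log_likelihood(trials: Sequence[Sequence], params: ModelParams) -> float:
    """Log-likelihood of observed type sequences under the expected curves.

    Treats each saccade order as an independent draw from the model's
    marginal type distribution at that order (the same curves the GoF is
    computed from).  Types observed where the model assigns probability
    zero make the log-likelihood ``-inf``.
    """
    if len(trials) == 0:
        raise ValueError("no trials given")
    n_orders = params.n_steps
    counts = type_counts_by_order(trials, n_orders)
    q = expected_ratio_curves(params).probs
    mask = counts > 0
    if np.any(mask & (q <= 0.0)):
        return float("-inf")
    ll = float(np.sum(counts[mask] * np.log(q[mask])))
    return ll


@dataclass
class AICComparison:
    """AIC comparison between the switching and the no-switch model."""

    aic_switch: float
    aic_no_switch: float
    log_likelihood_switch: float
    log_likelihood_no_switch: float
    preferred: Literal["switch", "no_switch"]


def aic_compare(
    trials: Sequence[Sequence], fit_switch: FitResult, fit_no_switch: FitResult
) -> AICComparison:
    """Compare the two fitted models by AIC = 2 k - 2 ln L on the trials.

    The switching model has k = 5 effective parameters, the no-switch
    model k = 2 (p_sw pinned to zero leaves a single mode whose two stay
    probabilities are the only free parameters); the background-flip
    probability is pre-fixed in both and not counted.  Ties in AIC prefer
    the smaller model.
    """
    ll_s = sequence_log_likelihood(trials, fit_switch.best_params)
    ll_n = sequence_log_likelihood(trials, fit_no_switch.best_params)
    aic_s = 2.0 * fit_switch.k_effective - 2.0 * ll_s
    aic_n = 2.0 * fit_no_switch.k_effective - 2.0 * ll_n
    fit_switch.log_likelihood, fit_switch.aic = ll_s, aic_s
    fit_no_switch.log_likelihood, fit_no_switch.aic = ll_n, aic_n
    return AICComparison(
        aic_switch=aic_s,
        aic_no_switch=aic_n,
        log_likelihood_switch=ll_s,
        log_likelihood_no_switch=ll_n,
        preferred="switch" if aic_s < aic_n else "no_switch",
    )


@dataclass
class SwitchPosterior:
    """Posterior over the switch step for a single trial.

    ``posterior`` maps each candidate switch step s (the 1-based order of
    the first saccade generated in the late mode, s = 2 .. trial length)
    and the :data:`NO_SWITCH` event (no switch within the observed trial)
    to its posterior probability.  ``map_step`` is the maximum a
    posteriori candidate (smallest step on ties, with within-trial steps
    preferred over :data:`NO_SWITCH`).
    """

    posterior: dict
    map_step: int | str
    log_evidence: float


def _emission_ok(t: int, z: int, f_prev: int, f_next: int) -> bool:
    if t == 0:
        return f_prev == 0 and f_next == 0 and z == 0
    if t == 1:
        return f_prev == 0 and f_next == 0 and z == 1
    if t == 2:
        return f_prev == 0 and f_next == 1
    if t == 3:
        return f_prev == 1 and f_next == 0
    return f_prev == 1 and f_next == 1


def _forward_likelihood(
    types: np.ndarray, params: ModelParams, switch_step: int | None
) -> float:
    """Probability of the observed types with an early->late switch at the
    given step (``None``: all-early).  Forward pass over the joint hidden
    variable (putative state, background flag of the current fixation)."""
    n = len(types)
    pi0 = initial_state_distribution(params)
    t_early = np.array(
        [
            [params.p_intra_e, 1.0 - params.p_intra_e],
            [1.0 - params.p_trans_e, params.p_trans_e],
        ]
    )
    t_late = np.array(
        [
            [params.p_intra_l, 1.0 - params.p_intra_l],
            [1.0 - params.p_trans_l, params.p_trans_l],
        ]
    )
    pf = np.array([1.0 - params.p_bg, params.p_bg])

    alpha = np.zeros((2, 2))  # (state, background flag of fixation i)
    f1 = 0 if params.initial_condition == "object" else 1
    alpha[:, f1] = pi0

    beta = np.zeros((2, 2))
    for i in range(n):
        t = int(types[i])
        beta[:] = 0.0
        for z in range(2):
            for f_next in range(2):
                acc = 0.0
                for f_prev in range(2):
                    if _emission_ok(t, z, f_prev, f_next):
                        acc += alpha[z, f_prev]
                beta[z, f_next] = acc * pf[f_next]
        if i + 1 < n:
            trans = t_late if (switch_step is not None and (i + 2) >= switch_step) else t_early
            alpha = trans.T @ beta
    return float(beta.sum())


def infer_switch_posterior(trial_types: Sequence, params: ModelParams) -> SwitchPosterior:
    """Posterior over the switch step given one trial's saccade types.

    The prior over the switch step is the geometric first-success law of
    the Bernoulli(p_sw) switch process: P(s) = p_sw (1 - p_sw)^(s - 2) for
    s = 2 .. n and P(no switch within the n observed saccades) =
    (1 - p_sw)^(n - 1).  The likelihood of the observed type sequence
    conditional on each s runs early-mode dynamics before s and late-mode
    dynamics from s onward (the transition into step s already uses
    late-mode stay probabilities).
    """
    types = _coerce_types(trial_types)
    n = len(types)
    if n < 1:
        raise ValueError("trial must contain at least one saccade")
    if n > params.n_steps:
        raise ValueError(
            f"trial has {n} saccades but params.n_fix={params.n_fix} allows "
            f"at most {params.n_steps}"
        )
    p = params.p_sw
    candidates: list[int | str] = list(range(2, n + 1)) + [NO_SWITCH]
    priors = np.array(
        [p * (1.0 - p) ** (s - 2) for s in range(2, n + 1)] + [(1.0 - p) ** (n - 1)]
    )
    likes = np.array(
        [_forward_likelihood(types, params, s) for s in range(2, n + 1)]
        + [_forward_likelihood(types, params, None)]
    )
    joint = priors * likes
    total = joint.sum()
    if total <= 0.0:
        raise ModelInconsistencyError(
            "observed saccade-type sequence has probability zero under the model"
        )
    post = joint / total
    map_idx = int(np.argmax(post))
    return SwitchPosterior(
        posterior=dict(zip(candidates, post.tolist())),
        map_step=candidates[map_idx],
        log_evidence=float(np.log(total)),
    )
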