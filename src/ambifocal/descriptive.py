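"""Descriptive dynamics of free-viewing eye movements.

Trial-time histograms of fixation and saccade types, binned eye-event
parameters (fixation duration, saccade amplitude), per-interval counts of
fixated objects, the per-saccade-order type-ratio curves consumed by model
fitting, and a permutation test for the excess of immediate same-type
saccade repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import LabeledFixation, SaccadeType, TypedSaccade
from .model import SACCADE_TYPES

__all__ = [
    "ClassifiedTrial",
    "BinnedCurve",
    "RatioByOrderCurves",
    "event_time_histograms",
    "binned_eye_parameters",
    "fixated_object_counts",
    "saccade_type_ratios_by_order",
    "ratio_curves_from_type_sequences",
    "repetition_excess_test",
]

_TYPE_INDEX = {name: i for i, name in enumerate(SACCADE_TYPES)}


@dataclass
class ClassifiedTrial:
    """All labelled events of one trial.

    Event times are absolute trace times; ``stimulus_onset`` anchors them
    to trial time.
    """

    trial_id: int
    stimulus_onset: float
    fixations: list[LabeledFixation]
    saccades: list[TypedSaccade]

    def classified_types(self) -> list[str]:
        """Type names of the classified saccades, in trial order."""
        return [
            s.saccade_type.value
            for s in sorted(self.saccades, key=lambda s: s.onset)
            if s.saccade_type is not None
        ]


@dataclass
class BinnedCurve:
    """Mean +/- SEM of a quantity in consecutive trial-time bins."""

    bin_edges: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    count: np.ndarray


@dataclass
class RatioByOrderCurves:
    """Empirical 5-vectors of saccade-type ratios per saccade order.

    ``ratios[i - 1]`` is the distribution of the type of the i-th
    classified saccade over trials with at least i classified saccades
    (components in :data:`~ambifocal.model.SACCADE_TYPES` order; NaN
    where no trial reaches the order).  ``n_at_order`` counts the
    contributing trials.
    """

    ratios: np.ndarray
    n_at_order: np.ndarray

    @property
    def n_orders(self) -> int:
        return self.ratios.shape[0]


def _relative_onsets(trial: ClassifiedTrial, events) -> np.ndarray:
    onsets = np.array([e.onset for e in events]) - trial.stimulus_onset
    if np.any(onsets < 0):
        raise ValueError(
            f"trial {trial.trial_id}: event onset before stimulus onset"
        )
    return onsets


def event_time_histograms(
    trials: Sequence[ClassifiedTrial],
    bin_width: float = 0.025,
    t_max: float = 5.0,
) -> dict:
    """Histograms of event onset times per fixation kind and saccade type.

    Counts use trial time relative to stimulus onset.  Per-bin ratios are
    type count over total count in the bin; bins with zero total have NaN
    ratios (undefined, not zero).
    """
    edges = np.arange(0.0, t_max + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    fix_counts = np.zeros((2, n_bins))  # object, background
    sac_counts = np.zeros((5, n_bins))
    for trial in trials:
        f_on = _relative_onsets(trial, trial.fixations)
        for fix, on in zip(trial.fixations, f_on):
            b = min(int(on // bin_width), n_bins - 1)
            fix_counts[0 if fix.kind == "object" else 1, b] += 1
        classified = [s for s in trial.saccades if s.saccade_type is not None]
        s_on = _relative_onsets(trial, classified)
        for sac, on in zip(classified, s_on):
            b = min(int(on // bin_width), n_bins - 1)
            sac_counts[_TYPE_INDEX[sac.saccade_type.value], b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        fix_ratios = fix_counts / fix_counts.sum(axis=0, keepdims=True)
        sac_ratios = sac_counts / sac_counts.sum(axis=0, keepdims=True)
    return {
        "bin_edges": edges,
        "fixation_counts": fix_counts,
        "fixation_ratios": fix_ratios,
        "saccade_counts": sac_counts,
        "saccade_ratios": sac_ratios,
    }


def _binned(values: np.ndarray, onsets: np.ndarray, edges: np.ndarray) -> BinnedCurve:
    n_bins = len(edges) - 1
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    which = np.clip((onsets // (edges[1] - edges[0])).astype(int), 0, n_bins - 1)
    for b in range(n_bins):
        v = values[which == b]
        count[b] = len(v)
        if len(v):
            mean[b] = v.mean()
            sem[b] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
    return BinnedCurve(bin_edges=edges, mean=mean, sem=sem, count=count)


def binned_eye_parameters(
    trials: Sequence[ClassifiedTrial],
    bin_width: float = 0.5,
    t_max: float = 5.0,
) -> dict[str, BinnedCurve]:
    """Mean +/- SEM of fixation duration and saccade amplitude over trial
    time (events assigned to bins by onset time)."""
    edges = np.arange(0.0, t_max + bin_width / 2, bin_width)
    fd_vals, fd_on, sa_vals, sa_on = [], [], [], []
    for trial in trials:
        f_on = _relative_onsets(trial, trial.fixations)
        fd_vals.extend(f.base.duration for f in trial.fixations)
        fd_on.extend(f_on)
        s_on = _relative_onsets(trial, trial.saccades)
        sa_vals.extend(s.base.amplitude for s in trial.saccades)
        sa_on.extend(s_on)
    return {
        "fixation_duration": _binned(np.array(fd_vals), np.array(fd_on), edges),
        "saccade_amplitude": _binned(np.array(sa_vals), np.array(sa_on), edges),
    }


def fixated_object_counts(
    trials: Sequence[ClassifiedTrial],
    interval: float = 1.0,
    t_max: float = 5.0,
) -> dict:
    """Distinct fixated objects, fixation counts and fixations per object
    within consecutive trial intervals, averaged over trials with SEM.

    Intervals with no object fixation contribute zero distinct objects;
    their fixations-per-object ratio is undefined and excluded from the
    trial average of that interval.
    """
    n_int = int(round(t_max / interval))
    per_trial_objects = np.zeros((len(trials), n_int))
    per_trial_fix = np.zeros((len(trials), n_int))
    per_trial_ratio = np.full((len(trials), n_int), np.nan)
    for k, trial in enumerate(trials):
        onsets = _relative_onsets(trial, trial.fixations)
        which = np.clip((onsets // interval).astype(int), 0, n_int - 1)
        for b in range(n_int):
            sel = [f for f, w in zip(trial.fixations, which) if w == b]
            objs = {f.fixated_object for f in sel if f.fixated_object is not None}
            per_trial_objects[k, b] = len(objs)
            per_trial_fix[k, b] = len(sel)
            if objs:
                per_trial_ratio[k, b] = len(sel) / len(objs)

    def summarize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = np.sum(np.isfinite(a), axis=0)
        mean = np.full(a.shape[1], np.nan)
        sem = np.full(a.shape[1], np.nan)
        for b in np.flatnonzero(n > 0):
            col = a[np.isfinite(a[:, b]), b]
            mean[b] = col.mean()
            sem[b] = col.std(ddof=1) / np.sqrt(len(col)) if len(col) > 1 else 0.0
        return mean, sem

    obj_mean, obj_sem = summarize(per_trial_objects)
    fix_mean, fix_sem = summarize(per_trial_fix)
    ratio_mean, ratio_sem = summarize(per_trial_ratio)
    return {
        "interval_edges": np.arange(0.0, t_max + interval / 2, interval),
        "objects_mean": obj_mean,
        "objects_sem": obj_sem,
        "fixations_mean": fix_mean,
        "fixations_sem": fix_sem,
        "fixations_per_object_mean": ratio_mean,
        "fixations_per_object_sem": ratio_sem,
        "per_trial_objects": per_trial_objects,
    }


def _coerce_sequences(trials) -> list[list[int]]:
    """Per-trial type-code sequences from trials or raw sequences."""
    out: list[list[int]] = []
    for trial in trials:
        if isinstance(trial, ClassifiedTrial):
            seq = [_TYPE_INDEX[t] for t in trial.classified_types()]
        else:
            seq = [
                _TYPE_INDEX[t.value if isinstance(t, SaccadeType) else t]
                if isinstance(t, (str, SaccadeType))
                else int(t)
                for t in trial
            ]
        out.append(seq)
    return out


def ratio_curves_from_type_sequences(
    sequences: Sequence[Sequence], max_order: int | None = None
) -> RatioByOrderCurves:
    """Per-order type ratios from per-trial saccade-type sequences.

    Order i pools the i-th saccade of every trial with at least i
    saccades; ratios are NaN beyond the longest trial.
    """
    seqs = _coerce_sequences(sequences)
    longest = max((len(s) for s in seqs), default=0)
    if longest == 0:
        raise ValueError("no trial contains a classified saccade")
    n_orders = longest if max_order is None else min(max_order, longest)
    counts = np.zeros((n_orders, 5))
    for seq in seqs:
        for i, t in enumerate(seq[:n_orders]):
            counts[i, t] += 1
    n_at_order = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = counts / n_at_order[:, None]
    return RatioByOrderCurves(ratios=ratios, n_at_order=n_at_order.astype(int))


def saccade_type_ratios_by_order(
    trials: Sequence[ClassifiedTrial], max_order: int | None = None
) -> RatioByOrderCurves:
    """Empirical ratio curves over classified saccades, indexed 1..k per
    trial in time order."""
    return ratio_curves_from_type_sequences(trials, max_order)


def repetition_excess_test(
    trials,
    n_permutations: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Permutation test for excess immediate same-type saccade repetitions.

    The observed statistic per type is the number of immediate same-type
    successions pooled over trials.  The null shuffles each trial's type
    sequence independently (preserving per-trial type counts); p-values
    are one-sided with the add-one correction.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seqs = [np.array(s, dtype=int) for s in _coerce_sequences(trials) if len(s) >= 2]

    def rep_counts(sequences) -> np.ndarray:
        c = np.zeros(5, dtype=int)
        for s in sequences:
            same = s[:-1] == s[1:]
            for t in s[:-1][same]:
                c[t] += 1
        return c

    observed = rep_counts(seqs)
    exceed = np.zeros(5, dtype=int)
    for _ in range(n_permutations):
        shuffled = [rng.permutation(s) for s in seqs]
        exceed += rep_counts(shuffled) >= observed
    p_values = (1 + exceed) / (1 + n_permutations)
    return {
        "types": list(SACCADE_TYPES),
        "observed_repetitions": observed,
        "p_values": p_values,
        "n_permutations": n_permutations,
        "n_trials_used": len(seqs),
    }
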