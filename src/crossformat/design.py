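"""Task designs, trial tables, and time conventions.

Two paradigms are represented:

* the **main task** — a fully crossed 2 (hand) x 3 (action) x 2 (direction)
  design run under two formats (blocks): *intention* (the participant
  internally generates / executes the cued action) and *observation*
  (the participant passively views the same video);
* the **dissociation tasks** — 2 (action) x 2 (hand) x 4 (conflict) designs
  in which the video shown during the go phase can be incongruent with the
  instructed action, separating motor-intention from visual-observation
  signals.  The *no-probe* variant has intention and observation blocks;
  the *probe* variant adds a post-video report of the observed action,
  making the video behaviorally relevant on every trial.

All times are trial-relative seconds; the hand cue defines t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

MAIN = "main"
DISSOCIATION_NOPROBE = "dissociation_noprobe"
DISSOCIATION_PROBE = "dissociation_probe"
VARIANTS = (MAIN, DISSOCIATION_NOPROBE, DISSOCIATION_PROBE)

MAIN_FACTORS: Dict[str, Tuple[str, ...]] = {
    "hand": ("left", "right"),
    "action": ("lift", "slide", "rotate"),
    "direction": ("left", "right"),
}
DISSOCIATION_FACTORS: Dict[str, Tuple[str, ...]] = {
    "action": ("slide", "rotate"),
    "hand": ("left", "right"),
    "conflict": ("congruent", "action_incong", "hand_incong", "both_incong"),
}

INTENTION = "intention"
OBSERVATION = "observation"
FORMATS = (INTENTION, OBSERVATION)

REGIONS = ("MC", "MCM", "MCL", "SPL")

#: columns every trial table carries in addition to the factor columns
TABLE_BASE_COLUMNS = ("trial_id", "session_id", "format", "included", "relevance")


@dataclass
class TaskDesign:
    """Immutable description of one task variant.

    ``event_times_s`` holds the nominal timeline: hand cue at 0 s, symbolic
    action/direction cue at 0.5 s, go cue at 1.5 s, end of the action video
    at 2.5 s (probe onset at 2.5 s in the probe variant).  The go-cue time is
    configurable because published timelines are not fully consistent about
    it; 1.5 s is the default used throughout.
    """

    variant: str = MAIN
    factors: Dict[str, Tuple[str, ...]] = field(default_factory=lambda: dict(MAIN_FACTORS))
    formats: Tuple[str, ...] = FORMATS
    event_times_s: Dict[str, float] = field(
        default_factory=lambda: {"hand_cue": 0.0, "action_cue": 0.5, "go": 1.5, "video_end": 2.5}
    )
    trial_window_s: Tuple[float, float] = (-0.5, 3.0)
    reps_per_condition: int = 12

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        times = [self.event_times_s[k] for k in sorted(self.event_times_s, key=self.event_times_s.get)]
        lo, hi = self.trial_window_s
        if any(t < lo or t > hi for t in times):
            raise ValueError("event times must lie inside the trial window")
        if not all(b > a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    @property
    def factor_names(self) -> Tuple[str, ...]:
        return tuple(self.factors)

    def conditions(self) -> List[Tuple[str, ...]]:
        """All factor-level combinations, in declared order."""
        return list(product(*self.factors.values()))

    @property
    def n_conditions(self) -> int:
        return int(np.prod([len(v) for v in self.factors.values()]))

    def condition_labels(self, trials: pd.DataFrame) -> pd.Series:
        """One string label per trial joining all factor levels."""
        cols = [trials[f].astype(str) for f in self.factor_names]
        out = cols[0]
        for c in cols[1:]:
            out = out + "|" + c
        return out.rename("condition")


def make_task_design(variant: str = MAIN, reps_per_condition: int = 12, **overrides) -> TaskDesign:
    """Construct the canonical :class:`TaskDesign` for a variant."""
    if variant == MAIN:
        return TaskDesign(variant=variant, reps_per_condition=reps_per_condition, **overrides)
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    events = {"hand_cue": 0.0, "action_cue": 0.5, "go": 1.5, "video_end": 2.5}
    formats: Tuple[str, ...] = FORMATS
    if variant == DISSOCIATION_PROBE:
        # the probe appears as the video ends; keep one event for that instant
        del events["video_end"]
        events["probe_onset"] = 2.5
        formats = ("probe",)
    return TaskDesign(
        variant=variant,
        factors=dict(DISSOCIATION_FACTORS),
        formats=formats,
        event_times_s=events,
        reps_per_condition=reps_per_condition,
        **overrides,
    )


def validate_trial_table(design: TaskDesign, trials: pd.DataFrame) -> None:
    """Raise ``ValueError`` if the table violates the design's invariants."""
    missing = [c for c in TABLE_BASE_COLUMNS if c not in trials.columns]
    missing += [f for f in design.factor_names if f not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    for name, levels in design.factors.items():
        bad = set(trials[name].unique()) - set(levels)
        if bad:
            raise ValueError(
                f"factor {name!r} has labels {sorted(bad)} not in the declared levels {list(levels)}"
            )
    bad_fmt = set(trials["format"].unique()) - set(design.formats)
    if bad_fmt:
        raise ValueError(f"unknown format/block labels {sorted(bad_fmt)}; declared {list(design.formats)}")
    dup = trials.groupby("session_id")["trial_id"].apply(lambda s: s.duplicated().any())
    if dup.any():
        raise ValueError(f"duplicate trial_id within session(s): {list(dup[dup].index)}")


def included_mask(trials: pd.DataFrame) -> np.ndarray:
    """Boolean mask of trials that may reach statistics."""
    return trials["included"].to_numpy(dtype=bool)


VIDEO_ACTION_FLIP = {"slide": "rotate", "rotate": "slide"}
VIDEO_HAND_FLIP = {"left": "right", "right": "left"}


def derive_video_labels(trials: pd.DataFrame) -> pd.DataFrame:
    """Video-side action/hand labels implied by the conflict type.

    In the dissociation designs the instructed cue and the displayed video
    coincide on congruent trials, the video action flips on action-incongruent
    trials, the video hand flips on hand-incongruent trials, and both flip on
    fully incongruent trials.  Returns a copy of ``trials`` with
    ``video_action`` and ``video_hand`` columns.
    """
    if "conflict" not in trials.columns:
        raise ValueError("video labels are defined only for dissociation trial tables (missing 'conflict')")
    out = trials.copy()
    conflict = trials["conflict"].to_numpy()
    known = {"congruent", "action_incong", "hand_incong", "both_incong"}
    bad = set(conflict) - known
    if bad:
        raise ValueError(f"unknown conflict level(s) {sorted(bad)}")
    flip_a = np.isin(conflict, ("action_incong", "both_incong"))
    flip_h = np.isin(conflict, ("hand_incong", "both_incong"))
    out["video_action"] = np.where(flip_a, trials["action"].map(VIDEO_ACTION_FLIP), trials["action"])
    out["video_hand"] = np.where(flip_h, trials["hand"].map(VIDEO_HAND_FLIP), trials["hand"])
    return out
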