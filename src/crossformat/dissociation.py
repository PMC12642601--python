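"""End-to-end dissociation-task analyses.

The dissociation designs (2 action x 2 hand x 4 conflict) let the
instructed action and the concurrently shown video disagree, so separate
label streams exist for what the participant was told to do and what they
saw.  This module derives the video-side labels from the conflict type,
runs two-way (action x hand) tuning timecourses for both label sources,
decodes instructed / video / 16-trial-type / conflict labels per block, and
reruns the video decoding on incongruent trials only -- the control that
shows video decoding cannot be inherited from the instructed stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import pandas as pd

from .design import (
    DISSOCIATION_NOPROBE,
    DISSOCIATION_PROBE,
    TaskDesign,
    derive_video_labels,
)
from .decoding import DecodingResult, dissociation_decode
from .session import BinnedRates
from .tuning import TuningTimecourse, anova_timecourse


@dataclass
class DissociationReport:
    tuning: Dict[str, TuningTimecourse]          # (source, block) -> timecourse
    decoding: Dict[str, DecodingResult]          # (source, block) -> result
    trialtype16: Dict[str, DecodingResult]
    conflict: Dict[str, DecodingResult]
    incongruent_only: Dict[str, DecodingResult]  # video decoding, congruent trials removed
    variant: str = ""


def run_dissociation(
    design: TaskDesign,
    trials: pd.DataFrame,
    rates: BinnedRates,
    seed: int = 0,
    folds: int = 10,
    min_trials_per_class: int = 10,
) -> DissociationReport:
    """Compose the dissociation-task tuning and decoding analyses per block."""
    if design.variant not in (DISSOCIATION_NOPROBE, DISSOCIATION_PROBE):
        raise ValueError("run_dissociation requires a dissociation-variant session")
    vt = derive_video_labels(trials)
    tuning: Dict[str, TuningTimecourse] = {}
    decoding: Dict[str, DecodingResult] = {}
    tt16: Dict[str, DecodingResult] = {}
    conflict: Dict[str, DecodingResult] = {}
    incong: Dict[str, DecodingResult] = {}
    for block in design.formats:
        blk = vt[vt["format"] == block].reset_index(drop=True)
        bsel = (vt["format"] == block).to_numpy()
        brates = BinnedRates(
            rates.values[:, bsel], rates.bin_centers_s, rates.bin_width_s,
            rates.baseline_window_s, rates.window_s, rates.unit_ids,
        )
        tuning[f"instructed|{block}"] = anova_timecourse(
            brates, blk, design, factors=["action", "hand"]
        )
        tuning[f"video|{block}"] = anova_timecourse(
            brates, blk, design, factors=["video_action", "video_hand"]
        )
        for source in ("instructed", "video"):
            decoding[f"{source}|{block}"] = dissociation_decode(
                brates, blk, design, source=source, folds=folds, seed=seed
            )
        tt16[block] = dissociation_decode(
            brates, blk, design, source="trialtype16",
            folds=min(folds, design.reps_per_condition), seed=seed,
        )
        conflict[block] = dissociation_decode(
            brates, blk, design, source="conflict", folds=folds, seed=seed
        )
        inc_blk = blk[blk["conflict"] != "congruent"].reset_index(drop=True)
        isel = bsel & (vt["conflict"] != "congruent").to_numpy()
        irates = BinnedRates(
            rates.values[:, isel], rates.bin_centers_s, rates.bin_width_s,
            rates.baseline_window_s, rates.window_s, rates.unit_ids,
        )
        incong[block] = dissociation_decode(
            irates, inc_blk, design, source="video", folds=folds, seed=seed
        )
    return DissociationReport(
        tuning=tuning,
        decoding=decoding,
        trialtype16=tt16,
        conflict=conflict,
        incongruent_only=incong,
        variant=design.variant,
    )
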