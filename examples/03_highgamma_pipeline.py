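"""Channel-level high-gamma analysis of simulated LFP.

Simulates channels whose high-gamma amplitude is modulated on right-hand
trials, preprocesses (line-noise removal, 2 Hz high-pass, artifact flags),
extracts the unified high-gamma envelope, selects task-relevant channels,
and decodes the effector from the envelope.
"""

import numpy as np

from crossformat import (
    LFPChannelSpec,
    hg_channel_selection,
    hg_decode,
    hg_unified_envelope,
    make_design,
    preprocess_lfp,
    simulate_lfp,
)

design, trials = make_design("main", reps_per_condition=6, seed=11)
channels = [LFPChannelSpec(tuned_factor="hand", tuned_level="right",
                           hg_modulation_depth=1.5, region="SPL") for _ in range(5)]
channels += [LFPChannelSpec(tuned_factor=None, hg_modulation_depth=0.0, region="SPL")
             for _ in range(3)]
lfp = simulate_lfp(design, trials, channels, seed=12)

clean, flagged = preprocess_lfp(lfp)
trials.loc[flagged, "included"] = False
print(f"trials flagged as artifacts: {int(flagged.sum())}/{len(trials)}")

env = hg_unified_envelope(clean, car=False)
keep = hg_channel_selection(env, trials)
print(f"task-relevant channels (paired t, task 1-2 s vs baseline 0-0.5 s): {keep.tolist()}")

res = hg_decode(env, trials, design, "hand", format="intention", channels=keep, folds=5, seed=13)
print(f"hand decoding from high gamma: peak accuracy {res.peak_accuracy:.2f} "
      f"at {res.peak_window_s:.2f} s (chance {res.chance:.2f})")
# The five planted channels are always retained (null channels slip in at
# the test's alpha rate) and the effector is decodable from the unified
# envelope during the response window.
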