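"""Choice-related discriminability of single units, with a shuffle null.

Plants a choice signal (a 25 Hz rate step on lick trials starting 150 ms
after tone onset) and shows that the false-alarm vs correct-reject AUC
trace turns significant at that latency.
"""

import numpy as np

import neurodisc as nd

bp = nd.BehaviorParams(n_trials=500, d_easy=1.0, d_hard=1.0, c_bias=-0.5)
up = nd.UnitParams(n_units=3, choice_gain=25.0, choice_onset=0.15)
session, truth = nd.simulate_session(bp, up, seed=2)

fa, cr = nd.contrast_builder(session.trials, "choice")[0]  # easy-task pair
print(f"{len(fa)} false-alarm vs {len(cr)} correct-reject trials")

for k, unit in enumerate(session.units):
    trace = nd.auc_timecourse(unit, fa, cr, seed=k)
    null_mean, null_sd = nd.shuffle_null(unit, fa, cr, seed=100 + k)
    nd.attach_null(trace, null_mean, null_sd)
    m = nd.discrimination_metrics(trace)
    onset = "none" if m.onset_latency is None else f"{m.onset_latency * 1e3:.0f} ms"
    print(
        f"unit {unit.unit_id}: onset {onset}, max AUC {m.max_auc:.2f}, "
        f"duration {m.duration * 1e3:.0f} ms"
    )
# Onsets should cluster at the planted 150 ms; max AUC well above the
# 0.5 chance level marks units carrying the choice signal.
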