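"""LDA decoding of hit vs correct-reject population activity.

Simulates a 25-unit session with frequency-tuned responses (hits and
correct rejects hear different tones, so the population separates them),
then decodes, measures the Fisher separation and the decoding latency.
"""

import neurodisc as nd

bp = nd.BehaviorParams(n_trials=400, d_easy=2.0, d_hard=1.5, c_bias=0.0)
up = nd.UnitParams(n_units=25, evoked_gain=20.0, tuning_sd_oct=0.4, bf_spread_oct=0.5)
session, truth = nd.simulate_session(bp, up, seed=5)

responsive = nd.responsive_units(session)
print(f"{len(responsive)} of {len(session.units)} units auditory responsive")

pm = nd.build_population(session, task="easy", units=responsive)
acc = nd.lda_decode(pm, seed=0)
sep = nd.fisher_separation(pm)
stv = nd.single_trial_variance(pm)
lat = nd.decoding_latency(session, "easy", units=responsive, seed=1)

print(f"held-out accuracy (first 200 ms): {acc:.3f}")
print(f"Fisher separation S: {sep.S:.1f}")
print(f"single-trial variance: hit {stv['hit']:.2f}, cr {stv['cr']:.2f}")
print(f"decoding latency: {lat * 1e3:.0f} ms")
# Accuracy near 1 and a latency near the evoked response latency (~15 ms)
# reflect the strong planted stimulus signal; z-scored within-class
# variance below 1 shows part of the total variance is between classes.
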