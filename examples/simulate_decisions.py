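"""Simulate decision trials near the tricritical point and summarize them.

Runs an event-driven (Gillespie) ensemble of a 100-spin circuit with a
small bias toward option I, then reports the error rate, mean reaction
time, and the correct/wrong RT ratio. A second, stronger-bias ensemble
shows the speed-accuracy effect of learning: both error and RT drop.
"""

from isingdm import ModelParams, simulate_ensemble_arrays, summarize

for eps1 in (0.01, 0.04):
    params = ModelParams(T=0.29, eta=0.44, eps1=eps1, N=100, L=5.0)
    decisions, rts, n_events, _ = simulate_ensemble_arrays(
        params, n_trials=2000, seed=42
    )
    s = summarize((decisions, rts))
    print(f"bias eps1 = {eps1}:")
    print(f"  error rate          {s.error_rate:.3f} +- {s.se_error:.3f}")
    print(f"  mean RT             {s.rt_mean:.1f} rate units")
    print(f"  RT correct / wrong  {s.rt_ratio_cw:.3f}")
    print(f"  events per trial    {n_events.mean():.0f}")

# The velocity of the decision variable telegraphs between the two
# mean-field values (run-and-tumble motion) at these parameters; a larger
# bias favors runs toward the correct threshold, so the error rate and
# the mean RT decrease together -- the signature that distinguishes bias
# from the other control parameters.
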