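"""Estimate an instantaneous conditional mutual information.

Uses the scenario where X copies Y both instantaneously and with a lag
(X_i = Y_i + Y_{i-1} + noise) while Y is driven by lagged Z.  The CMI
I(X_1; Y_1 | Z_1) between same-time samples has the closed form
(d/2) log(1 + (sy^2 + sz^2)/(sx^2 + sy^2 + sz^2)); the estimator works
on the order-0 embedding, i.e. plain (X_i, Y_i, Z_i) triples.
"""

from causalinfo import (
    ClassifierConfig,
    embed_for_cmi,
    estimate_cmi,
    instant_cmi_spec,
    oracle_cmi_instant,
    simulate_linear,
)
from causalinfo.batching import benchmark_batch_config

sx, sy, sz = 1.0, 2.0, 2.0
spec = instant_cmi_spec(sx, sy, sz)
data = simulate_linear(spec, n=10_000, seed=0)
emb = embed_for_cmi(data, "X", "Y", ["Z"], order=0)

est = estimate_cmi(
    emb,
    benchmark_batch_config(emb.n_e, 0),
    ClassifierConfig(epochs=50, seed=0),
    T=3,
    seed=0,
)
true = oracle_cmi_instant(sx, sy, sz).value
print(f"closed form : {true:.4f} nats")
print(f"estimate    : {est.mean:.4f} +/- {est.std:.4f} nats  (T={est.T})")
print(
    "\nThe estimate should track the closed form to within a few"
    "\nhundredths of a nat at this sample size."
)
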