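"""Estimate directed information rates with the neural DV-bound estimator.

Trains the ratio classifier on isolated-kNN batches from simulated
chain data and compares the estimates with the closed forms.  A
positive link (X -> Y), the strongest link (Y -> Z) and an anti-causal
null (Y -> X) are shown.  Runs in a couple of minutes at this reduced
scale; estimates carry a small downward bias from finite training.
"""

from causalinfo import (
    ClassifierConfig,
    BENCHMARK_CHAIN_PARAMS,
    chain_spec,
    estimate_dir,
    oracle_dir_chain,
    simulate_linear,
)
from causalinfo.batching import benchmark_batch_config

data = simulate_linear(chain_spec(**BENCHMARK_CHAIN_PARAMS), n=10_000, seed=1)
truth = oracle_dir_chain(**BENCHMARK_CHAIN_PARAMS)

batch_cfg = benchmark_batch_config(data.n - 2, seed=1)
clf_cfg = ClassifierConfig(epochs=50, seed=1)

print(f"{'link':<8}{'true':>8}{'estimate':>10}{'std':>8}")
for src, tgt in (("X", "Y"), ("Y", "Z"), ("Y", "X")):
    est = estimate_dir(data, src, tgt, order=2,
                       batch_config=batch_cfg, clf_config=clf_cfg,
                       T=3, seed=1)
    true = truth[f"{src}->{tgt}"].value
    print(f"{src}->{tgt:<5}{true:>8.3f}{est.mean:>10.3f}{est.std:>8.3f}")

print(
    "\nEach estimate averages T=3 sampling trials (fresh batches, fresh"
    "\nclassifier). Nonzero links should be recovered to within a few"
    "\nhundredths of a nat; the anti-causal link should sit near zero."
)
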