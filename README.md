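# causalinfo

Neural estimation of conditional mutual information and directed
information for stationary Markov time series.

## The problem

Given jointly stationary processes **X**, **Y**, **Z** observed as a
multivariate time series, how strongly — and in which direction — does
one process causally influence another?  The natural
information-theoretic answers are the **directed information rate**
(DIR)

    I(X -> Y || Z) = lim (1/n) Σᵢ I(Xⁱ; Yᵢ | Yⁱ⁻¹, Zⁱ)

and the **transfer entropy** T_{X→Y} = I(X_{i−J}^{i−1}; Y_i |
Y_{i−L}^{i−1}).  For Markov sources of maximum order *l* the DIR
collapses to a single conditional mutual information (CMI) on
lag-embedded blocks,

    I(X -> Y || Z) = I(X^{l+1}; Y_{l+1} | Y^l, Z^{l+1}),

so one good CMI estimator covers all of these measures.  Directed
information graphs built from these quantities distinguish direct
influence from *proxy* effects: a link X→Z that exists only because X
drives Y and Y drives Z vanishes once Y's causal history enters the
conditioning set.

## The estimator

CMI is the KL divergence between the joint law p(x,y,z) and the product
law p(x|z)·p(y,z).  The package estimates it with the Donsker–Varadhan
(DV) variational bound, tight at f\* = log of the density ratio Γ:

1. **Joint batch** — embedded rows selected by independent
   Bernoulli(α) draws: samples of p(x,y,z).
2. **Product batch (isolated k-NN)** — a subset of rows is *isolated*;
   each isolated row contributes its (y, z) paired with the x values of
   its k nearest neighbours in z among the non-isolated rows: samples
   approximating p(x|z)·p(y,z).
3. **Ratio classifier** — a feed-forward network (two ReLU layers of
   64, sigmoid head) is trained with binary cross-entropy to separate
   the batches; its odds ω/(1−ω), clipped via τ, estimate Γ̂.
4. **DV evaluation** — on held-out halves of both batches:
   Î = mean_joint log Γ̂ − log( mean_prod Γ̂ ), averaged over T
   re-sampling trials.

A linear-Gaussian simulator (structural VAR with instantaneous and
lag-1 couplings) provides ground truth: its stationary covariance is
solved exactly (discrete Lyapunov equation), so every CMI/DIR of
interest has a closed form against which the pipeline is validated.

## Worked example

```python
from causalinfo import (ClassifierConfig, BENCHMARK_CHAIN_PARAMS, chain_spec,
                        estimate_dir, oracle_dir_chain, simulate_linear)
from causalinfo.batching import benchmark_batch_config

data = simulate_linear(chain_spec(**BENCHMARK_CHAIN_PARAMS), n=10_000, seed=1)
bc  = benchmark_batch_config(data.n - 2, seed=1)
clf = ClassifierConfig(epochs=50, seed=1)
est = estimate_dir(data, "X", "Y", order=2, batch_config=bc,
                   clf_config=clf, T=3, seed=1)
print(est.mean, est.std)
```

Running `python examples/estimate_directed_information.py` (which does
exactly this for three links) prints:

```
link        true  estimate     std
X->Y       0.589     0.535   0.016
Y->Z       1.985     1.899   0.033
Y->X       0.000    -0.028   0.002
```

The `true` column is the closed-form DIR of the chain model
X→Y→Z; the estimate column is the trained DV bound (mean over T=3
trials, in nats).  Causal links are recovered to within a few
hundredths of a nat — the small downward bias is the expected
lower-bound character of the DV objective under finite training — and
the anti-causal link sits at zero.  The other scripts in `examples/`
demonstrate the closed-form oracles, instantaneous CMI estimation, and
proxy-edge pruning in directed-information graphs.

A thin CLI mirrors the library for shell use:

```bash
causalinfo simulate -n 20000 --seed 1 --out chain.csv
causalinfo estimate --data chain.csv --measure dir --source X --target Y \
    --order 2 -T 5 --seed 1 --out dir_xy.json
causalinfo benchmark --scale reduced --seed 1 --out report.json
```

`benchmark --scale full` reruns the full-size experiment
(n = 2×10⁵, T = 20, 200 epochs); the default reduced scale uses
n = 2×10⁴, T = 5, 50 epochs.

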