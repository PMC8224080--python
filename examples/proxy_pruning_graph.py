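"""Directed-information graphs: pairwise edges vs causally conditioned.

Builds both graph modes on simulated chain data.  The pairwise graph
keeps the proxy edge X -> Z (X influences Z, but only through Y); the
causally conditioned graph conditions every pair on the remaining
process and prunes it, recovering the true wiring X -> Y -> Z.
"""

from causalinfo import (
    ClassifierConfig,
    chain_spec,
    build_di_graph,
    simulate_linear,
)
from causalinfo.batching import benchmark_batch_config

data = simulate_linear(chain_spec(), n=10_000, seed=0)
batch_cfg = benchmark_batch_config(data.n - 2, seed=0)
clf_cfg = ClassifierConfig(epochs=50, seed=0)

for mode in ("pairwise", "causally-conditioned"):
    g = build_di_graph(data, order=2, mode=mode, threshold=0.1,
                       batch_config=batch_cfg, clf_config=clf_cfg,
                       T=1, seed=0)
    print(f"\n{mode} graph (threshold 0.1 nats):")
    for (s, t), est in sorted(g.edges.items()):
        kept = "kept  " if (s, t) in g.kept_edges else "pruned"
        print(f"  {s}->{t}: {est.mean:+.3f}  {kept}")

print(
    "\nThe proxy edge X->Z survives in the pairwise graph but is pruned"
    "\nunder causal conditioning on Y: its conditioned DIR is zero."
)
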