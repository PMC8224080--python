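"""Directed information rate, causal conditioning, transfer entropy, graphs.

For jointly stationary Markov processes with maximum Markov order
``l = o_max``, the directed information rate collapses to a single CMI,

    I(X -> Y || Z) = I(X^{l+1}; Y_{l+1} | Y^l, Z^{l+1}),

so every directed measure here is a lag embedding followed by the DV
CMI estimator.  A directed-information graph evaluates the measure for
every ordered pair of processes; causally conditioning each pair on all
remaining processes prunes *proxy* edges — links whose pairwise DIR is
positive only because the influence is mediated by a third process.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .batching import BatchConfig, default_batch_config
from .classifier import ClassifierConfig
from .dv import CMIEstimate, estimate_cmi
from .timeseries import TimeSeriesDataset, embed_for_cmi, embed_for_te

__all__ = [
    "DIGraphResult",
    "estimate_dir",
    "estimate_causal_cond_dir",
    "estimate_te",
    "build_di_graph",
]


@dataclass
class DIGraphResult:
    """All-pairs directed-information estimates plus the thresholded graph."""

    nodes: list[str]
    mode: str  # "pairwise" or "causally-conditioned"
    order: int
    edges: dict[tuple[str, str], CMIEstimate]
    threshold: float
    kept_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kept_edges = [
            (s, t) for (s, t), est in self.edges.items() if est.mean > self.threshold
        ]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(mode=self.mode, order=self.order, threshold=self.threshold)
        g.add_nodes_from(self.nodes)
        for (s, t) in self.kept_edges:
            est = self.edges[(s, t)]
            g.add_edge(s, t, mean=est.mean, std=est.std)
        return g

    def to_edge_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["src", "tgt", "mean", "std", "kept"])
            for (s, t), est in self.edges.items():
                writer.writerow([s, t, est.mean, est.std, (s, t) in self.kept_edges])

    def to_json(self, path) -> None:
        g = nx.DiGraph(mode=self.mode, order=self.order, threshold=self.threshold)
        g.add_nodes_from(self.nodes)
        for (s, t), est in self.edges.items():
            g.add_edge(s, t, mean=est.mean, std=est.std,
                       kept=(s, t) in self.kept_edges)
        with open(path, "w") as fh:
            json.dump(nx.node_link_data(g, edges="links"), fh, indent=2)


def _run(
    data: TimeSeriesDataset,
    source: str,
    target: str,
    extras: tuple[str, ...],
    order: int,
    batch_config: BatchConfig | None,
    clf_config: ClassifierConfig | None,
    T: int,
    seed: int,
    measure: str,
) -> CMIEstimate:
    emb = embed_for_cmi(data, source, target, extras, order)
    est = estimate_cmi(emb, batch_config, clf_config, T=T, seed=seed)
    est.config_snapshot.update(
        measure=measure, source=source, target=target,
        condition=list(extras), order=order,
    )
    return est


def estimate_dir(
    data: TimeSeriesDataset,
    source: str,
    target: str,
    order: int,
    batch_config: BatchConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    T: int = 20,
    seed: int = 0,
) -> CMIEstimate:
    """Pairwise DIR ``I(source -> target)`` at Markov order ``order``."""
    if source == target:
        raise ValueError("self-links have no directed information rate")
    if order < 1:
        raise ValueError("order must be >= 1 for a directed measure")
    return _run(data, source, target, (), order, batch_config, clf_config,
                T, seed, "dir")


def estimate_causal_cond_dir(
    data: TimeSeriesDataset,
    source: str,
    target: str,
    condition: list[str],
    order: int,
    batch_config: BatchConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    T: int = 20,
    seed: int = 0,
) -> CMIEstimate:
    """Causally conditioned DIR ``I(source -> target || condition)``."""
    if source == target:
        raise ValueError("self-links have no directed information rate")
    if not condition:
        raise ValueError("condition must name at least one process")
    if source in condition or target in condition:
        raise ValueError("condition must be disjoint from source and target")
    if order < 1:
        raise ValueError("order must be >= 1 for a directed measure")
    return _run(data, source, target, tuple(condition), order, batch_config,
                clf_config, T, seed, "cond_dir")


def estimate_te(
    data: TimeSeriesDataset,
    source: str,
    target: str,
    J: int,
    L: int,
    batch_config: BatchConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    T: int = 20,
    seed: int = 0,
) -> CMIEstimate:
    """Stationary transfer entropy ``T_{source -> target}`` with memories J, L."""
    if source == target:
        raise ValueError("self-links have no transfer entropy")
    emb = embed_for_te(data, source, target, J, L)
    est = estimate_cmi(emb, batch_config, clf_config, T=T, seed=seed)
    est.config_snapshot.update(
        measure="te", source=source, target=target, J=J, L=L,
    )
    return est


def build_di_graph(
    data: TimeSeriesDataset,
    order: int,
    mode: str = "pairwise",
    threshold: float = 0.05,
    batch_config: BatchConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    T: int = 20,
    seed: int = 0,
) -> DIGraphResult:
    """Directed-information graph over all ordered pairs of processes.

    ``mode="pairwise"`` estimates the plain DIR per pair;
    ``mode="causally-conditioned"`` conditions each pair on all remaining
    processes jointly, which removes proxy edges.  Edges with mean
    estimate above ``threshold`` (nats) are retained.
    """
    names = data.names
    if len(names) < 2:
        raise ValueError("need at least two processes for a graph")
    if mode not in ("pairwise", "causally-conditioned"):
        raise ValueError("mode must be 'pairwise' or 'causally-conditioned'")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")

    edges: dict[tuple[str, str], CMIEstimate] = {}
    for e, src in enumerate(names):
        for f, tgt in enumerate(names):
            if src == tgt:
                continue
            pair_seed = int(np.random.SeedSequence(
                [seed, e * len(names) + f]).generate_state(1)[0] % (2**31))
            if mode == "pairwise":
                est = estimate_dir(data, src, tgt, order, batch_config,
                                   clf_config, T, pair_seed)
            else:
                rest = [p for p in names if p not in (src, tgt)]
                est = estimate_causal_cond_dir(data, src, tgt, rest, order,
                                               batch_config, clf_config, T,
                                               pair_seed)
            edges[(src, tgt)] = est
    return DIGraphResult(
        nodes=names, mode=mode, order=order, edges=edges, threshold=threshold
    )

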