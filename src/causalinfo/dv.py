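"""Donsker–Varadhan estimation of conditional mutual information.

The DV variational bound states, for distributions P (joint) and Q
(product),

    I(X; Y | Z) = D(P || Q) >= E_P[f] - log E_Q[exp f],

with equality at ``f* = log dP/dQ``.  Plugging the classifier's
approximation ``f = log Gamma_hat`` and replacing expectations by
empirical averages over the evaluation halves of the joint and product
batches yields the estimator

    I_hat = (1/|B_joint|) sum_joint log Gamma_hat
            - log[(1/|B_prod|) sum_prod Gamma_hat].

The product-batch average enters inside a single logarithm with a minus
sign, per the bound's form; this makes the estimator exactly invariant
to rescaling ``Gamma_hat`` by a positive constant.

A full estimate repeats the pipeline over ``T`` sampling trials — fresh
batches, a fresh random half/half train–evaluation split, a freshly
trained classifier — and reports the mean and sample standard deviation
over trials.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .batching import (
    BatchConfig,
    JointBatch,
    ProductBatch,
    benchmark_batch_config,
    build_joint_batch,
    build_product_batch,
)
from .classifier import ClassifierConfig, empirical_loss, init_model, train_model
from .timeseries import EmbeddedCMIDataset

__all__ = [
    "CMIEstimate",
    "dv_bound_value",
    "estimate_cmi",
    "estimate_mi",
    "mi_diff_estimate",
]


@dataclass
class CMIEstimate:
    """Aggregated multi-trial estimate of a CMI-type quantity, in nats."""

    mean: float
    std: float
    per_trial: list[float]
    T: int
    config_snapshot: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def from_trials(
        cls, per_trial: list[float], config_snapshot: dict, warns: list[str]
    ) -> "CMIEstimate":
        arr = np.asarray(per_trial, dtype=float)
        std = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(
            mean=float(arr.mean()),
            std=std,
            per_trial=[float(v) for v in per_trial],
            T=len(per_trial),
            config_snapshot=config_snapshot,
            warnings=warns,
        )

    def clamped(self) -> "CMIEstimate":
        """Copy with mean and trials clamped at zero (CMI is non-negative)."""
        return CMIEstimate(
            mean=max(self.mean, 0.0),
            std=self.std,
            per_trial=[max(v, 0.0) for v in self.per_trial],
            T=self.T,
            config_snapshot=self.config_snapshot,
            warnings=self.warnings,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def dv_bound_value(model, joint_eval: JointBatch, prod_eval: ProductBatch) -> float:
    """Empirical DV bound from a ratio model and evaluation batches.

    ``model`` is anything exposing ``log_ratio(stacked_rows)`` — a
    trained :class:`~causalinfo.classifier.RatioModel` or an analytic
    ratio oracle.  Emits a RuntimeWarning when the ratio is degenerate
    (all evaluations pinned at the clipping bounds).
    """
    if len(joint_eval) == 0 or len(prod_eval) == 0:
        raise ValueError("evaluation batches must be non-empty")
    lj = np.asarray(model.log_ratio(_stack(joint_eval)))
    lp = np.asarray(model.log_ratio(_stack(prod_eval)))
    if np.ptp(lj) == 0.0 and np.ptp(lp) == 0.0 and lj[0] == lp[0] and abs(lj[0]) > 5.0:
        warnings.warn(
            "density ratio is constant at a clipped value; estimate unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    # log-mean-exp of lp, stable against large ratios
    hi = lp.max()
    log_mean_prod = hi + np.log(np.mean(np.exp(lp - hi)))
    return float(lj.mean() - log_mean_prod)


def _stack(batch) -> np.ndarray:
    return np.hstack([batch.x, batch.y, batch.z])


def _trial_seeds(seed: int, t: int, count: int) -> list[int]:
    """Deterministic per-trial child seeds via indexed seed-sequence hashing."""
    ss = np.random.SeedSequence([int(seed), int(t)])
    return [int(s) for s in ss.generate_state(count) % (2**31)]


def _split_half(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    half = n // 2
    return perm[:half], perm[half:]


def _take(batch: JointBatch | ProductBatch, sel: np.ndarray):
    if isinstance(batch, JointBatch):
        return JointBatch(
            batch.x[sel], batch.y[sel], batch.z[sel], batch.indices[sel]
        )
    return ProductBatch(
        batch.x[sel], batch.y[sel], batch.z[sel], batch.pairs[sel], batch.isolated
    )


def estimate_cmi(
    data: EmbeddedCMIDataset,
    batch_config: BatchConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    T: int = 20,
    seed: int = 0,
) -> CMIEstimate:
    """Multi-trial DV estimate of I(X; Y | Z) on embedded triples.

    Each trial re-selects the joint and product batches from the fixed
    dataset, splits each randomly in half into train/evaluation sets,
    trains a fresh classifier on the train halves and evaluates the DV
    bound on the evaluation halves.  When no batch configuration is
    given, the finite-sample :func:`~causalinfo.batching.benchmark_batch_config`
    (small neighbour count) is used; the asymptotically motivated
    square-root rule remains available via
    :func:`~causalinfo.batching.default_batch_config`.
    """
    if T < 1:
        raise ValueError("need at least one trial")
    if batch_config is None:
        batch_config = benchmark_batch_config(data.n_e, seed)
    if clf_config is None:
        clf_config = ClassifierConfig()
    batch_config.validate(data.n_e)

    per_trial: list[float] = []
    warns: list[str] = []
    for t in range(T):
        s_joint, s_prod, s_split, s_init = _trial_seeds(seed, t, 4)
        joint = build_joint_batch(data, batch_config.alpha, s_joint)
        trial_bc = BatchConfig(
            alpha=batch_config.alpha,
            alpha_prime=batch_config.alpha_prime,
            s=batch_config.s,
            k=batch_config.k,
            seed=s_prod,
        )
        prod = build_product_batch(data, trial_bc)

        rng = np.random.default_rng(s_split)
        jtr, jev = _split_half(len(joint), rng)
        ptr, pev = _split_half(len(prod), rng)
        trial_cc = ClassifierConfig(**{**asdict(clf_config), "seed": s_init})
        model = init_model(trial_cc, data.dims)
        model = train_model(model, _take(joint, jtr), _take(prod, ptr), trial_cc)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            value = dv_bound_value(model, _take(joint, jev), _take(prod, pev))
        warns += [f"trial {t}: {w.message}" for w in caught]
        per_trial.append(value)

    snapshot = {
        "measure": "cmi",
        "batch_config": asdict(batch_config),
        "classifier_config": asdict(clf_config),
        "T": T,
        "seed": seed,
        "n_e": data.n_e,
        "dims": list(data.dims),
    }
    return CMIEstimate.from_trials(per_trial, snapshot, warns)


def estimate_mi(
    x: np.ndarray,
    v: np.ndarray,
    batch_config: BatchConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    T: int = 20,
    seed: int = 0,
) -> CMIEstimate:
    """Multi-trial DV estimate of the unconditional MI ``I(X; V)``.

    Uses the same classifier/DV machinery, but the product batch is a
    uniform random re-pairing of x rows with v rows (a derangement-free
    permutation): the product density ``p(x) p(v)`` has no conditioning
    variable, so no nearest-neighbour search is involved.
    """
    if T < 1:
        raise ValueError("need at least one trial")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if x.shape[0] != v.shape[0]:
        raise ValueError("x and v must have the same number of rows")
    n = x.shape[0]
    if clf_config is None:
        clf_config = ClassifierConfig()
    alpha = batch_config.alpha if batch_config is not None else 0.5
    dims = (x.shape[1], v.shape[1], 0)

    per_trial: list[float] = []
    warns: list[str] = []
    empty_z = np.empty((0, 0))
    for t in range(T):
        s_joint, s_prod, s_split, s_init = _trial_seeds(seed, t, 4)
        rngj = np.random.default_rng(s_joint)
        j_idx = np.flatnonzero(rngj.random(n) < alpha)
        rngp = np.random.default_rng(s_prod)
        p_idx = np.flatnonzero(rngp.random(n) < alpha)
        perm = rngp.permutation(p_idx)
        joint = JointBatch(x[j_idx], v[j_idx], np.empty((j_idx.size, 0)), j_idx)
        prod = ProductBatch(
            x[perm],
            v[p_idx],
            np.empty((p_idx.size, 0)),
            np.column_stack([p_idx, perm]),
            isolated=p_idx,
        )
        rng = np.random.default_rng(s_split)
        jtr, jev = _split_half(len(joint), rng)
        ptr, pev = _split_half(len(prod), rng)
        trial_cc = ClassifierConfig(**{**asdict(clf_config), "seed": s_init})
        model = init_model(trial_cc, dims)
        model = train_model(model, _take(joint, jtr), _take(prod, ptr), trial_cc)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            value = dv_bound_value(model, _take(joint, jev), _take(prod, pev))
        warns += [f"trial {t}: {w.message}" for w in caught]
        per_trial.append(value)

    snapshot = {
        "measure": "mi",
        "alpha": alpha,
        "classifier_config": asdict(clf_config),
        "T": T,
        "seed": seed,
        "n": n,
        "dims": list(dims),
    }
    return CMIEstimate.from_trials(per_trial, snapshot, warns)


def mi_diff_estimate(
    data: EmbeddedCMIDataset,
    batch_config: BatchConfig | None = None,
    clf_config: ClassifierConfig | None = None,
    T: int = 20,
    seed: int = 0,
) -> CMIEstimate:
    """Baseline CMI estimate via ``I(X; Y, Z) - I(X; Z)``.

    Each MI term is estimated with its own classifiers; the per-trial
    differences are aggregated.  Direct CMI estimation is typically less
    variable because it trains a single ratio instead of differencing
    two independently trained ones.
    """
    yz = np.hstack([data.y_block, data.z_block])
    first = estimate_mi(data.x_block, yz, batch_config, clf_config, T, seed)
    second = estimate_mi(
        data.x_block, data.z_block, batch_config, clf_config, T, seed + 1
    )
    per_trial = [a - b for a, b in zip(first.per_trial, second.per_trial)]
    snapshot = {
        "measure": "mi_diff",
        "term_xyz": first.config_snapshot,
        "term_xz": second.config_snapshot,
        "T": T,
        "seed": seed,
    }
    return CMIEstimate.from_trials(per_trial, snapshot, first.warnings + second.warnings)
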