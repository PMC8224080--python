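"""Linear stochastic dynamics and closed-form information ground truths.

The benchmark generative model is the structural vector autoregression

    S_i = A S_i + B S_{i-1} + N_i,   i.e.   S_i = (I-A)^{-1} (B S_{i-1} + N_i),

where ``S_i`` stacks one sample per process, ``A`` (zero diagonal) holds
instantaneous couplings, ``B`` lag-1 couplings, and ``N_i`` is white
Gaussian noise with per-process variances.  Each of the ``d`` vector
components evolves independently under the same couplings.  Because the
model is linear-Gaussian, every CMI / DIR of interest has a closed form;
those oracles anchor the estimator's tests.

Two named scenarios recur:

* the *chain* model ``X -> Y -> Z`` (``A = 0``; ``B`` has ``b1`` from X
  to Y and ``b2`` from Y to Z), whose pairwise DIR exhibits a proxy edge
  X -> Z that causal conditioning on Y removes;
* a small instantaneous+lagged model (X white noise, Z = X + noise,
  Y autoregressive driven by lagged Z) where the pairwise DIR X -> Y is
  positive yet vanishes once causally conditioned on Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .timeseries import TimeSeriesDataset

__all__ = [
    "LinearDynamicsSpec",
    "OracleValues",
    "chain_spec",
    "instant_cmi_spec",
    "example1_spec",
    "simulate_linear",
    "simulate_example1",
    "stationary_covariance",
    "embedded_covariance",
    "embedded_triple_covariance",
    "oracle_cmi_instant",
    "oracle_dir_chain",
    "oracle_cond_dir_chain",
    "oracle_example1",
    "gaussian_cmi_from_cov",
    "AnalyticGaussianRatio",
]

BENCHMARK_CHAIN_PARAMS = dict(b1=1.0, b2=2.0, sigma_x=3.0, sigma_y=2.0, sigma_z=1.0)
"""Chain-model parameters used by the reference benchmark tables."""


@dataclass
class LinearDynamicsSpec:
    """Specification of the linear dynamics.

    ``noise_std[i]`` is the noise standard deviation of process ``i``;
    ``d`` is the number of independent vector components per process.
    ``truncate_at`` (in units of each sigma) enables truncated-Gaussian
    noise by rejection; stationarity requires the spectral radius of
    ``(I-A)^{-1} B`` to be below 1.
    """

    process_names: tuple[str, ...]
    A: np.ndarray
    B: np.ndarray
    noise_std: np.ndarray
    d: int = 1
    truncate_at: float | None = None

    def __post_init__(self) -> None:
        m = len(self.process_names)
        self.A = np.asarray(self.A, dtype=float).reshape(m, m)
        self.B = np.asarray(self.B, dtype=float).reshape(m, m)
        self.noise_std = np.asarray(self.noise_std, dtype=float).ravel()
        if self.noise_std.shape != (m,) or np.any(self.noise_std <= 0):
            raise ValueError("noise_std must give one positive sigma per process")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("A must have a zero diagonal (no instantaneous self-loop)")
        eye = np.eye(m)
        if abs(np.linalg.det(eye - self.A)) < 1e-12:
            raise ValueError("(I - A) is singular; the model is ill-posed")
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if np.max(np.abs(np.linalg.eigvals(self.transition))) >= 1.0:
            raise ValueError(
                "spectral radius of (I-A)^{-1} B is >= 1; the model is not stationary"
            )

    @property
    def m(self) -> int:
        return len(self.process_names)

    @property
    def mixing(self) -> np.ndarray:
        """(I - A)^{-1}."""
        return np.linalg.inv(np.eye(self.m) - self.A)

    @property
    def transition(self) -> np.ndarray:
        """Equivalent VAR(1) transition matrix (I-A)^{-1} B."""
        return self.mixing @ self.B


def chain_spec(
    b1: float = 1.0,
    b2: float = 2.0,
    sigma_x: float = 3.0,
    sigma_y: float = 2.0,
    sigma_z: float = 1.0,
    d: int = 1,
) -> LinearDynamicsSpec:
    """Chain model X -> Y -> Z with lag-1 couplings b1, b2 (defaults: benchmark)."""
    B = np.array([[0.0, 0.0, 0.0], [b1, 0.0, 0.0], [0.0, b2, 0.0]])
    return LinearDynamicsSpec(
        process_names=("X", "Y", "Z"),
        A=np.zeros((3, 3)),
        B=B,
        noise_std=np.array([sigma_x, sigma_y, sigma_z]),
        d=d,
    )


def instant_cmi_spec(
    sigma_x: float = 1.0, sigma_y: float = 2.0, sigma_z: float = 2.0, d: int = 1
) -> LinearDynamicsSpec:
    """The instantaneous-CMI scenario: X driven by Y now, Y and Z by lag-1 terms."""
    A = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    B = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [0.0, 0.0, 0.0]])
    return LinearDynamicsSpec(
        process_names=("X", "Y", "Z"),
        A=A,
        B=B,
        noise_std=np.array([sigma_x, sigma_y, sigma_z]),
        d=d,
    )


def example1_spec(
    a: float = 0.5, sigma_x: float = 1.0, sigma_y: float = 1.0,
    sigma_z: float = 1.0
) -> LinearDynamicsSpec:
    """The instantaneous+lagged model as a :class:`LinearDynamicsSpec`.

    X white noise; Z = X + noise (instantaneous coupling); Y
    autoregressive with coefficient ``a``, driven by lagged Z.  Its
    maximum Markov order is 1.  Equivalent to
    :func:`simulate_example1`'s recursion, but in matrix form so the
    stationary-covariance machinery applies.
    """
    A = np.array([[0.0, 0.0, 0.0],   # X exogenous
                  [0.0, 0.0, 0.0],   # Y has no instantaneous parents
                  [1.0, 0.0, 0.0]])  # Z <- X instantaneously
    B = np.array([[0.0, 0.0, 0.0],
                  [0.0, a, 1.0],     # Y <- a*Y_prev + Z_prev
                  [0.0, 0.0, 0.0]])
    return LinearDynamicsSpec(("X", "Y", "Z"), A, B,
                              np.array([sigma_x, sigma_y, sigma_z]))


def simulate_linear(
    spec: LinearDynamicsSpec,
    n: int,
    seed: int = 0,
    burn_in: int = 1000,
) -> TimeSeriesDataset:
    """Iterate ``S_i = (I-A)^{-1}(B S_{i-1} + N_i)`` and keep ``n`` samples.

    Starts from the zero state and discards ``burn_in`` initial steps so
    the retained samples approximate the stationary law (the dynamics
    are geometrically ergodic, so the transient decays exponentially).
    """
    if n < 2:
        raise ValueError("need n >= 2 samples")
    rng = np.random.default_rng(seed)
    M = spec.mixing
    F = spec.transition
    total = n + burn_in
    noise = rng.normal(size=(total, spec.m, spec.d)) * spec.noise_std[None, :, None]
    if spec.truncate_at is not None:
        bound = spec.truncate_at * spec.noise_std[None, :, None]
        bad = np.abs(noise) > bound
        while np.any(bad):
            redraw = rng.normal(size=int(bad.sum())) * np.broadcast_to(
                spec.noise_std[None, :, None], noise.shape
            )[bad]
            noise[bad] = redraw
            bad = np.abs(noise) > bound
    out = np.empty((total, spec.m, spec.d))
    state = np.zeros((spec.m, spec.d))
    for i in range(total):
        state = F @ state + M @ noise[i]
        out[i] = state
    out = out[burn_in:]
    processes = {
        name: out[:, p, :] for p, name in enumerate(spec.process_names)
    }
    meta = {
        "model": "linear_dynamics",
        "seed": seed,
        "burn_in": burn_in,
        "process_names": list(spec.process_names),
        "d": spec.d,
    }
    return TimeSeriesDataset(processes, meta=meta)


def simulate_example1(
    a: float,
    sigmas: tuple[float, float, float],
    n: int,
    seed: int = 0,
    burn_in: int = 1000,
) -> TimeSeriesDataset:
    """Simulate X_i = W_i;  Z_i = X_i + W''_i;  Y_i = a Y_{i-1} + Z_{i-1} + W'_i.

    ``sigmas = (sigma_x, sigma_y, sigma_z)`` are the standard deviations
    of the white noises W, W', W''.  Requires ``|a| < 1`` for a
    stationary Y.
    """
    if not abs(a) < 1:
        raise ValueError("|a| must be < 1 for stationarity")
    sx, sy, sz = (float(s) for s in sigmas)
    if min(sx, sy, sz) <= 0:
        raise ValueError("all sigmas must be positive")
    rng = np.random.default_rng(seed)
    total = n + burn_in
    w = rng.normal(0.0, sx, total)
    w_prime = rng.normal(0.0, sy, total)
    w_dprime = rng.normal(0.0, sz, total)
    x = w
    z = x + w_dprime
    y = np.empty(total)
    y_prev = 0.0
    z_prev = 0.0
    for i in range(total):
        y[i] = a * y_prev + z_prev + w_prime[i]
        y_prev, z_prev = y[i], z[i]
    sl = slice(burn_in, None)
    meta = {"model": "example1", "a": a, "sigmas": [sx, sy, sz], "seed": seed,
            "burn_in": burn_in}
    return TimeSeriesDataset({"X": x[sl], "Y": y[sl], "Z": z[sl]}, meta=meta)


def stationary_covariance(spec: LinearDynamicsSpec) -> np.ndarray:
    """Lag-0 stationary covariance of one vector component (m x m).

    Solves the discrete Lyapunov equation ``Sigma = F Sigma F' + Q`` with
    ``F = (I-A)^{-1} B`` and ``Q = (I-A)^{-1} diag(sigma^2) (I-A)^{-T}``.
    Components are independent, so the full covariance is this matrix
    replicated per dimension.
    """
    F = spec.transition
    M = spec.mixing
    Q = M @ np.diag(spec.noise_std**2) @ M.T
    return solve_discrete_lyapunov(F, Q)


def embedded_covariance(spec: LinearDynamicsSpec, lags: int) -> np.ndarray:
    """Covariance of the stacked window ``(S_t, S_{t+1}, ..., S_{t+lags})``.

    One vector component; ordering is time-major then process, so row
    ``h * m + p`` is process ``p`` at offset ``h``.  Uses
    ``Cov(S_{t+h}, S_t) = F^h Sigma_0``.
    """
    m = spec.m
    F = spec.transition
    sigma0 = stationary_covariance(spec)
    blocks = [[None] * (lags + 1) for _ in range(lags + 1)]
    powers = [np.linalg.matrix_power(F, h) for h in range(lags + 1)]
    for r in range(lags + 1):
        for c in range(lags + 1):
            if r >= c:
                blocks[r][c] = powers[r - c] @ sigma0
            else:
                blocks[r][c] = sigma0 @ powers[c - r].T
    return np.block(blocks)


def embedded_triple_covariance(
    spec: LinearDynamicsSpec,
    source: str,
    target: str,
    extra_condition: tuple[str, ...] = (),
    order: int = 1,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Stationary covariance of the embedded (x, y, z) triple, ``[x|y|z]`` order.

    Matches the block layout produced by
    :func:`causalinfo.timeseries.embed_for_cmi`: x is the source window
    ``(t..t+order)``, y the target at ``t+order``, z the target history
    followed by each extra process's full window.  Restricted to
    ``d = 1`` (components are i.i.d. copies, so one component carries
    all the information structure).  Returns ``(cov, (D_x, D_y, D_z))``.
    """
    if spec.d != 1:
        raise ValueError("embedded covariance helper supports d = 1 only")
    names = list(spec.process_names)
    p_src, p_tgt = names.index(source), names.index(target)
    p_ext = [names.index(e) for e in extra_condition]
    m = spec.m
    big = embedded_covariance(spec, order)  # index = offset * m + process
    x_idx = [h * m + p_src for h in range(order + 1)]
    y_idx = [order * m + p_tgt]
    z_idx = [h * m + p_tgt for h in range(order)]
    for p in p_ext:
        z_idx += [h * m + p for h in range(order + 1)]
    sel = np.array(x_idx + y_idx + z_idx)
    cov = big[np.ix_(sel, sel)]
    return cov, (len(x_idx), 1, len(z_idx))


@dataclass
class OracleValues:
    """A single closed-form information value in nats."""

    measure: str
    link: str
    value: float
    formula_id: str

    def __post_init__(self) -> None:
        if self.value < 0 or not np.isfinite(self.value):
            raise ValueError("oracle values must be finite and non-negative")


def oracle_cmi_instant(
    sigma_x: float, sigma_y: float, sigma_z: float, d: int = 1
) -> OracleValues:
    """Closed-form I(X_1; Y_1 | Z_1) of the instantaneous-CMI scenario.

    ``(d/2) log(1 + (sigma_y^2 + sigma_z^2) / (sigma_x^2 + sigma_y^2 + sigma_z^2))``.
    """
    _check_sigmas(sigma_x, sigma_y, sigma_z)
    sy2z2 = sigma_y**2 + sigma_z**2
    val = 0.5 * d * np.log(1.0 + sy2z2 / (sigma_x**2 + sy2z2))
    return OracleValues("cmi", "X;Y|Z", float(val), "instant_cmi")


def oracle_dir_chain(
    b1: float, b2: float, sigma_x: float, sigma_y: float, sigma_z: float
) -> dict[str, OracleValues]:
    """Closed-form pairwise DIR for every ordered link of the chain model.

    Forward links:
    ``I(X->Y) = 1/2 log(1 + b1^2 sx^2 / sy^2)``,
    ``I(Y->Z) = 1/2 log(1 + (b1^2 b2^2 sx^2 + b2^2 sy^2) / sz^2)``,
    ``I(X->Z) = 1/2 log(1 + b1^2 b2^2 sx^2 / (b2^2 sy^2 + sz^2))``;
    all reverse links are zero.
    """
    _check_sigmas(sigma_x, sigma_y, sigma_z)
    sx2, sy2, sz2 = sigma_x**2, sigma_y**2, sigma_z**2
    vals = {
        "X->Y": 0.5 * np.log(1.0 + b1**2 * sx2 / sy2),
        "Y->Z": 0.5 * np.log(1.0 + (b1**2 * b2**2 * sx2 + b2**2 * sy2) / sz2),
        "X->Z": 0.5 * np.log(1.0 + b1**2 * b2**2 * sx2 / (b2**2 * sy2 + sz2)),
        "Y->X": 0.0,
        "Z->X": 0.0,
        "Z->Y": 0.0,
    }
    return {
        link: OracleValues("dir", link, float(v), "chain_dir")
        for link, v in vals.items()
    }


def oracle_cond_dir_chain(
    b1: float, b2: float, sigma_x: float, sigma_y: float, sigma_z: float
) -> dict[str, OracleValues]:
    """Closed-form causally conditioned DIR for the chain model.

    Conditioning each link on the remaining process:
    ``I(X->Y||Z)`` equals the pairwise ``I(X->Y)`` (Z never enters Y's
    equation), ``I(Y->Z||X) = 1/2 log(1 + b2^2 sy^2 / sz^2)``, and the
    proxy link ``I(X->Z||Y)`` is exactly zero, as are all reverse links.
    """
    _check_sigmas(sigma_x, sigma_y, sigma_z)
    sx2, sy2, sz2 = sigma_x**2, sigma_y**2, sigma_z**2
    vals = {
        "X->Y||Z": 0.5 * np.log(1.0 + b1**2 * sx2 / sy2),
        "X->Z||Y": 0.0,
        "Y->Z||X": 0.5 * np.log(1.0 + b2**2 * sy2 / sz2),
        "Y->X||Z": 0.0,
        "Z->X||Y": 0.0,
        "Z->Y||X": 0.0,
    }
    return {
        link: OracleValues("cond_dir", link, float(v), "chain_cond_dir")
        for link, v in vals.items()
    }


def oracle_example1(
    a: float, sigma_x: float, sigma_y: float, sigma_z: float
) -> tuple[OracleValues, OracleValues]:
    """Closed forms for the instantaneous+lagged model.

    ``I(X->Y) = 1/2 log(1 + sigma_x^2 / (sigma_y^2 + sigma_z^2))`` and
    ``I(X->Y||Z) = 0``: X influences Y only through Z, so causally
    conditioning on Z severs the link.
    """
    if not abs(a) < 1:
        raise ValueError("|a| must be < 1")
    _check_sigmas(sigma_x, sigma_y, sigma_z)
    pairwise = 0.5 * np.log(1.0 + sigma_x**2 / (sigma_y**2 + sigma_z**2))
    return (
        OracleValues("dir", "X->Y", float(pairwise), "example1_dir"),
        OracleValues("cond_dir", "X->Y||Z", 0.0, "example1_cond_dir"),
    )


def gaussian_cmi_from_cov(
    cov: np.ndarray,
    x_idx: np.ndarray,
    y_idx: np.ndarray,
    z_idx: np.ndarray = (),
) -> float:
    """Exact Gaussian CMI from a joint covariance matrix (nats).

    ``1/2 [logdet S_xz + logdet S_yz - logdet S_xyz - logdet S_z]``;
    with an empty Z this reduces to the mutual information I(X;Y).
    """
    cov = np.asarray(cov, dtype=float)
    x_idx = np.asarray(x_idx, dtype=int)
    y_idx = np.asarray(y_idx, dtype=int)
    z_idx = np.asarray(z_idx, dtype=int)
    all_idx = np.concatenate([x_idx, y_idx, z_idx])
    if len(set(all_idx.tolist())) != all_idx.size:
        raise ValueError("x, y, z index sets must be disjoint")

    def logdet(idx: np.ndarray) -> float:
        if idx.size == 0:
            return 0.0
        sign, ld = np.linalg.slogdet(cov[np.ix_(idx, idx)])
        if sign <= 0:
            raise ValueError("covariance is not positive definite on the given blocks")
        return ld

    return 0.5 * (
        logdet(np.concatenate([x_idx, z_idx]))
        + logdet(np.concatenate([y_idx, z_idx]))
        - logdet(all_idx)
        - logdet(z_idx)
    )


class AnalyticGaussianRatio:
    """Exact log density ratio ``log Gamma`` for a known Gaussian law.

    Substituted for the trained classifier to test the DV-bound stage in
    isolation: ``log Gamma(x,y,z) = log p(x,y,z) - log p(x|z) - log p(y,z)``
    computed from the joint covariance via log-determinants and
    quadratic forms.  Exposes the same ``log_ratio(inputs)`` interface
    as :class:`~causalinfo.classifier.RatioModel` with inputs stacked
    ``[x | y | z]``.
    """

    def __init__(self, cov: np.ndarray, dims: tuple[int, int, int]):
        self.dims = tuple(int(d) for d in dims)
        dx, dy, dz = self.dims
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (dx + dy + dz, dx + dy + dz):
            raise ValueError("covariance shape does not match dims")
        ix = np.arange(dx)
        iy = np.arange(dx, dx + dy)
        iz = np.arange(dx + dy, dx + dy + dz)
        self._parts = [
            (np.concatenate([ix, iy, iz]), +1.0),  # log p(x,y,z)
            (np.concatenate([ix, iz]), -1.0),      # -log p(x,z)
            (np.concatenate([iy, iz]), -1.0),      # -log p(y,z)
            (iz, +1.0),                            # +log p(z)
        ]
        self._cached = [
            (idx, sgn, np.linalg.inv(cov[np.ix_(idx, idx)]),
             np.linalg.slogdet(cov[np.ix_(idx, idx)])[1])
            for idx, sgn in self._parts
            if idx.size > 0
        ]

    def log_ratio(self, inputs: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(inputs, dtype=float))
        total = np.zeros(u.shape[0])
        for idx, sgn, prec, ld in self._cached:
            v = u[:, idx]
            quad = np.einsum("ij,jk,ik->i", v, prec, v)
            total += sgn * (-0.5 * (quad + ld + idx.size * np.log(2 * np.pi)))
        return total


def _check_sigmas(*sigmas: float) -> None:
    if any(s <= 0 for s in sigmas):
        raise ValueError("all noise standard deviations must be positive")
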