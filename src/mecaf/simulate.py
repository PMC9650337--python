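"""Synthetic log-normal abundance generator and Monte-Carlo test harness.

Data model
----------
Latent log absolute abundances are Gaussian per group,
``L^g ~ N(mu_L^g, Sigma_L^g)``; absolute abundances are ``A = exp(L)``,
observed compositions ``R`` close each row of ``A`` to the simplex, and
``X`` is the CLR of ``R`` (identically the row-centered ``L``).

Group-1 means are drawn Uniform(0, 10) per component. Under an
alternative, ``s = floor(sparsity_fraction * p)`` randomly chosen signal
components get

    mu_L:j^2 = mu_L:j^1 - delta_j * sqrt(sigma_L:jj^2) * sqrt(log(p) / n),

with ``delta_j ~ Uniform(signal_low, signal_high)`` and ``n = n1 + n2``;
``sparsity_fraction = 0`` is the null. The default signal endpoints are
+/- 2*sqrt(2).

Covariance scenarios: ``"unequal"`` pairs a banded structure (group 1)
with a random sparse structure (group 2); ``"equal_banded"`` and
``"equal_sparse"`` share one structure. Each base matrix has unit
diagonal (:func:`make_banded_cov`, :func:`make_sparse_cov`) and is then
scaled component-wise to heterogeneous variances
``Sigma = D^{1/2} Sigma* D^{1/2}`` with ``d_j ~ Uniform(var_low,
var_high)`` (defaults 0.5, 2.5) — one independent variance draw per
covariance matrix, so the unequal scenario differs between groups in both
correlation structure and per-component variances. Set
``heterogeneous_var=False`` for unit variances.

The harness (:func:`estimate_rejection_rate`, :func:`run_grid`,
:func:`mock_split_type1`) estimates empirical type I error / power for
the tests in :mod:`mecaf.dtest`; everything is a pure function of the
configured seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from scipy.spatial.distance import pdist, squareform

from . import dtest
from .compositions import AbundanceTable, impute_zeros, to_composition

__all__ = [
    "SimulationConfig",
    "RejectionSummary",
    "METHODS",
    "make_banded_cov",
    "make_sparse_cov",
    "scenario_covariances",
    "draw_dataset",
    "estimate_rejection_rate",
    "run_grid",
    "mock_split_type1",
    "load_grid_config",
]

METHODS = ("mecaf", "mec", "mec-raw", "mec-log", "mec-oracle", "permanova")
SCENARIOS = ("unequal", "equal_banded", "equal_sparse")

_SIGNAL_DEFAULT = 2 * math.sqrt(2)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation cell: dimensions, scenario, signal and seeds.

    ``sparsity_fraction`` in {0, 0.05, 0.1, 0.2} matches the standard benchmark
    grid; any value in [0, 1] is allowed. Scenario tags: ``"unequal"``
    (banded vs sparse covariance), ``"equal_banded"``, ``"equal_sparse"``.
    """

    p: int
    n1: int
    n2: int
    sparsity_fraction: float = 0.0
    scenario: str = "unequal"
    alpha: float = 0.05
    n_reps: int = 1000
    seed: int = 0
    signal_low: float = -_SIGNAL_DEFAULT
    signal_high: float = _SIGNAL_DEFAULT
    mu1_low: float = 0.0
    mu1_high: float = 10.0
    # covariance structure
    rho: float = 0.5
    bandwidth: int = 3
    density: float = 0.05
    magnitude: float = 0.3
    var_low: float = 0.5
    var_high: float = 2.5
    heterogeneous_var: bool = True
    # variance-reduction switches (default: redraw per replication)
    freeze_signal: bool = False
    freeze_mu: bool = False
    # method knobs used inside the harness
    n_perm: int = 199
    mec_calibration: str = "asymptotic"

    def __post_init__(self):
        if self.p < 3:
            raise ValueError("p must be >= 3")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if not 0.0 <= self.sparsity_fraction <= 1.0:
            raise ValueError("sparsity_fraction must lie in [0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def s(self) -> int:
        """Number of signal taxa, floor(sparsity_fraction * p)."""
        return int(math.floor(self.sparsity_fraction * self.p))


@dataclass(frozen=True)
class RejectionSummary:
    """Monte-Carlo rejection-rate estimate for one (method, config) cell."""

    method: str
    config: SimulationConfig
    rejection_rate: float
    mc_std_error: float
    n_reps_done: int

    def __post_init__(self):
        expected = math.sqrt(self.rejection_rate * (1 - self.rejection_rate) / self.n_reps_done)
        if abs(self.mc_std_error - expected) > 1e-12:
            raise ValueError("mc_std_error inconsistent with rejection_rate and n_reps_done")


def make_banded_cov(p: int, rho: float = 0.5, bandwidth: int = 3) -> np.ndarray:
    """Unit-diagonal banded matrix, sigma_jk = rho^|j-k| for |j-k| <= bandwidth.

    Positive-definiteness is verified; if the band truncation breaks it, a
    diagonal bump (<= 0.05) is added and the matrix renormalized.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    if bandwidth < 0:
        raise ValueError("bandwidth must be >= 0")
    idx = np.arange(p)
    lag = np.abs(idx[:, None] - idx[None, :])
    cov = np.where(lag <= bandwidth, rho ** lag.astype(float), 0.0)
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    if lam_min <= 0:
        eps = abs(lam_min) + 1e-6
        if eps > 0.05:
            raise ValueError("banded construction is not positive definite within eps <= 0.05")
        cov = (cov + eps * np.eye(p)) / (1 + eps)
    return cov


def make_sparse_cov(p: int, density: float = 0.05, magnitude: float = 0.3, seed: int = 0) -> np.ndarray:
    """Unit-diagonal sparse matrix with random +/-magnitude off-diagonals.

    Each upper-triangle entry is +/-magnitude independently with
    probability ``density``, mirrored; the matrix is shifted by
    ``(|lambda_min| + 0.05) I`` when needed and rescaled to unit diagonal.
    Deterministic given ``seed``.
    """
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie in (0, 1)")
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    rng = np.random.default_rng(seed)
    upper = np.triu(
        (rng.random((p, p)) < density) * np.where(rng.random((p, p)) < 0.5, -1.0, 1.0) * magnitude,
        k=1,
    )
    cov = upper + upper.T + np.eye(p)
    lam_min = float(np.linalg.eigvalsh(cov)[0])
    if lam_min <= 0:
        delta = abs(lam_min) + 0.05
        cov = cov + delta * np.eye(p)
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
    return cov


def scenario_covariances(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(Sigma_L^1, Sigma_L^2) for the configured scenario.

    Base structures come from :func:`make_banded_cov` /
    :func:`make_sparse_cov`; heterogeneous per-component variances are
    applied as ``D^{1/2} Sigma* D^{1/2}`` with an independent
    ``d_j ~ Uniform(var_low, var_high)`` draw per matrix. Covariances are
    fixed per config (drawn from ``config.seed``) and shared across
    replications.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0_FFEE]))
    banded = make_banded_cov(config.p, config.rho, config.bandwidth)
    sparse = make_sparse_cov(config.p, config.density, config.magnitude, seed=int(config.seed) + 1)

    def scaled(base: np.ndarray) -> np.ndarray:
        if not config.heterogeneous_var:
            return base
        d = rng.uniform(config.var_low, config.var_high, size=config.p)
        sq = np.sqrt(d)
        return base * np.outer(sq, sq)

    if config.scenario == "unequal":
        return scaled(banded), scaled(sparse)
    if config.scenario == "equal_banded":
        s1 = scaled(banded)
    else:  # equal_sparse
        s1 = scaled(sparse)
    return s1, s1.copy()


class DrawnData(NamedTuple):
    """All eight matrices of one simulated two-group dataset."""

    L1: np.ndarray
    L2: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    X1: np.ndarray
    X2: np.ndarray


def _cholesky_pair(config: SimulationConfig):
    s1, s2 = scenario_covariances(config)
    return np.linalg.cholesky(s1), np.linalg.cholesky(s2), np.diag(s2).copy()


def _rep_rngs(config: SimulationConfig, rep_seed: int):
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(rep_seed)]))
    cfg_rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5EED]))
    return rng, cfg_rng


def _location_draw(config: SimulationConfig, rng, cfg_rng, diag2: np.ndarray):
    p, n = config.p, config.n1 + config.n2
    mu1 = (cfg_rng if config.freeze_mu else rng).uniform(config.mu1_low, config.mu1_high, size=p)
    delta = np.zeros(p)
    s = config.s
    if s > 0:
        sig_rng = cfg_rng if config.freeze_signal else rng
        positions = sig_rng.choice(p, size=s, replace=False)
        delta[positions] = sig_rng.uniform(config.signal_low, config.signal_high, size=s)
    mu2 = mu1 - delta * np.sqrt(diag2) * math.sqrt(math.log(p) / n)
    return mu1, mu2, delta


def draw_location_params(config: SimulationConfig, rep_seed: int):
    """(mu_L^1, mu_L^2, delta) exactly as :func:`draw_dataset` uses them."""
    rng, cfg_rng = _rep_rngs(config, rep_seed)
    _, _, diag2 = _cholesky_pair(config)
    return _location_draw(config, rng, cfg_rng, diag2)


def draw_dataset(config: SimulationConfig, rep_seed: int, _chols=None) -> DrawnData:
    """Draw one dataset; fully reproducible from (config.seed, rep_seed).

    ``_chols`` lets the harness reuse the per-config Cholesky factors.
    """
    if _chols is None:
        _chols = _cholesky_pair(config)
    chol1, chol2, diag2 = _chols
    p, n1, n2 = config.p, config.n1, config.n2
    rng, cfg_rng = _rep_rngs(config, rep_seed)
    mu1, mu2, delta = _location_draw(config, rng, cfg_rng, diag2)

    L1 = mu1 + rng.standard_normal((n1, p)) @ chol1.T
    L2 = mu2 + rng.standard_normal((n2, p)) @ chol2.T
    A1, A2 = np.exp(L1), np.exp(L2)
    R1 = A1 / A1.sum(axis=1, keepdims=True)
    R2 = A2 / A2.sum(axis=1, keepdims=True)
    X1 = np.log(R1)
    X1 -= X1.mean(axis=1, keepdims=True)
    X2 = np.log(R2)
    X2 -= X2.mean(axis=1, keepdims=True)
    return DrawnData(L1, L2, A1, A2, R1, R2, X1, X2)


def _apply_method(method: str, data: DrawnData, config: SimulationConfig, rep_seed: int) -> bool:
    """Run one test on one drawn dataset; return the rejection indicator."""
    alpha = config.alpha
    if method == "mecaf":
        return dtest.mecaf_test(data.X1, data.X2, alpha=alpha).reject
    if method == "mec":
        return dtest.mec_test(
            data.X1, data.X2, alpha=alpha, calibration=config.mec_calibration,
            n_perm=config.n_perm, seed=np.random.SeedSequence([config.seed, rep_seed, 7]),
        ).reject
    if method == "mec-raw":
        return dtest.mec_variant_test(data.R1, data.R2, "raw", alpha=alpha).reject
    if method == "mec-log":
        return dtest.mec_variant_test(data.R1, data.R2, "log", alpha=alpha).reject
    if method == "mec-oracle":
        return dtest.mec_variant_test(data.A1, data.A2, "oracle", alpha=alpha).reject
    if method == "permanova":
        return dtest.permanova_test(
            data.R1, data.R2, n_perm=config.n_perm, alpha=alpha,
            seed=np.random.SeedSequence([config.seed, rep_seed, 11]),
        ).reject
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def estimate_rejection_rate(method: str, config: SimulationConfig) -> RejectionSummary:
    """Empirical rejection rate of ``method`` over ``config.n_reps`` draws."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    chols = _cholesky_pair(config)
    rejections = 0
    for rep in range(config.n_reps):
        data = draw_dataset(config, rep, _chols=chols)
        rejections += bool(_apply_method(method, data, config, rep))
    rate = rejections / config.n_reps
    return RejectionSummary(
        method=method,
        config=config,
        rejection_rate=rate,
        mc_std_error=math.sqrt(rate * (1 - rate) / config.n_reps),
        n_reps_done=config.n_reps,
    )


def run_grid(configs: Sequence[SimulationConfig], methods: Sequence[str]) -> pd.DataFrame:
    """Cross-product of configs x methods as a long-format summary table.

    Per-cell failures are recorded in the ``error`` column and do not stop
    the remaining cells.
    """
    if not len(configs) or not len(methods):
        raise ValueError("configs and methods must be nonempty")
    rows = []
    for config in configs:
        chols = None
        for method in methods:
            row = {
                "method": method,
                "scenario": config.scenario,
                "p": config.p,
                "n1": config.n1,
                "n2": config.n2,
                "sparsity": config.sparsity_fraction,
                "alpha": config.alpha,
                "n_reps": config.n_reps,
                "seed": config.seed,
                "rejection_rate": np.nan,
                "mc_se": np.nan,
                "error": "",
            }
            try:
                if chols is None:
                    chols = _cholesky_pair(config)
                rejections = 0
                for rep in range(config.n_reps):
                    data = draw_dataset(config, rep, _chols=chols)
                    rejections += bool(_apply_method(method, data, config, rep))
                rate = rejections / config.n_reps
                row["rejection_rate"] = rate
                row["mc_se"] = math.sqrt(rate * (1 - rate) / config.n_reps)
            except Exception as exc:  # noqa: BLE001 - resumable grid
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def mock_split_type1(
    table: AbundanceTable,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    methods: Sequence[str] = ("mecaf", "mec", "mec-log", "mec-raw", "permanova"),
    pseudo: float = 0.5,
    n_perm: int = 199,
    split: str = "random",
) -> pd.DataFrame:
    """Type I error by repeatedly splitting one homogeneous table in two.

    Each replication partitions the samples into two mock groups
    (as-even-as-possible random split, or deterministic ``"alternating"``
    for diagnostics) and runs every requested test; the rejection
    fraction per method estimates its real-data type I error. The oracle
    variant is unavailable (absolute abundances are unobservable).
    """
    if table.n_samples < 4:
        raise ValueError("mock-split needs at least 4 samples")
    if "mec-oracle" in methods:
        raise ValueError("MEC-Oracle is unavailable on observed tables")
    if split not in ("random", "alternating"):
        raise ValueError("split must be 'random' or 'alternating'")
    comp = to_composition(impute_zeros(table, pseudo))
    R = comp.values
    X = np.log(R) - np.log(R).mean(axis=1, keepdims=True)
    n = table.n_samples
    n1 = n // 2
    rng = np.random.default_rng(seed)
    d2 = None
    if "permanova" in methods:
        d2 = squareform(pdist(R, metric="braycurtis")) ** 2
    counts = {m: 0 for m in methods}
    for rep in range(n_reps):
        if split == "alternating":
            g1, g2 = np.arange(n)[0::2], np.arange(n)[1::2]
        else:
            idx = rng.permutation(n)
            g1, g2 = idx[:n1], idx[n1:]
        for m in methods:
            if m == "mecaf":
                rej = dtest.mecaf_test(X[g1], X[g2], alpha=alpha).reject
            elif m == "mec":
                rej = dtest.mec_test(X[g1], X[g2], alpha=alpha).reject
            elif m == "mec-log":
                rej = dtest.mec_variant_test(R[g1], R[g2], "log", alpha=alpha).reject
            elif m == "mec-raw":
                rej = dtest.mec_variant_test(R[g1], R[g2], "raw", alpha=alpha).reject
            elif m == "permanova":
                labels = np.zeros(n, dtype=int)
                labels[g1] = 1
                f_obs = dtest.pseudo_f(d2, labels)
                perm_rng = np.random.default_rng(np.random.SeedSequence([seed, rep, 11]))
                count = 0
                for _ in range(n_perm):
                    z = np.zeros(n, dtype=int)
                    z[perm_rng.permutation(n)[: len(g1)]] = 1
                    if dtest.pseudo_f(d2, z) >= f_obs - 1e-12:
                        count += 1
                rej = (1 + count) / (1 + n_perm) <= alpha
            else:
                raise ValueError(f"unknown method {m!r}")
            counts[m] += bool(rej)
    rows = []
    for m in methods:
        rate = counts[m] / n_reps
        rows.append(
            {
                "method": m,
                "n_reps": n_reps,
                "alpha": alpha,
                "seed": seed,
                "rejection_rate": rate,
                "mc_se": math.sqrt(rate * (1 - rate) / n_reps),
            }
        )
    return pd.DataFrame(rows)


def load_grid_config(path) -> tuple[list[SimulationConfig], list[str]]:
    """Read a YAML grid file: a ``methods`` list plus a ``cells`` list of
    SimulationConfig keyword mappings (shared ``defaults`` supported)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    defaults = raw.get("defaults", {})
    methods = list(raw.get("methods", ["mecaf"]))
    configs = [SimulationConfig(**{**defaults, **cell}) for cell in raw["cells"]]
    return configs, methods
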