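"""Two-sample mean tests for high-dimensional CLR compositions.

The primary test (MECAF: max-type, equal-covariance-assumption-free)
compares the mean CLR vectors of two independent groups,

    T = max_{1<=j<=p-1} ( sqrt(n1+n2) (xbar_j^1 - xbar_j^2) / sqrt(sigma_jj) )^2,

with the Welch-type per-component variance

    sigma_jj = (n1+n2)/n1 * s_jj^1 + (n1+n2)/n2 * s_jj^2,

where ``s_jj^g`` is the biased (1/n_g) sample variance of CLR component j
in group g. Because CLR rows sum to zero, equality of all p component
means is equivalent to equality of the first p-1, so the maximum runs
over the first p-1 components; no equal-covariance assumption is needed.

Under the null the statistic, centered and scaled by the closed-form
constants of :func:`null_calibration`, converges to the standard Gumbel
law ``exp(-exp(-t))``, giving an analytic p-value with no resampling.

Also provided: the pooled-variance max-type competitor (MEC) and its
representation variants (raw compositions, log compositions, oracle
absolute abundances), with a Gumbel-type asymptotic calibration or a
label-permutation fallback, and a seeded permutational MANOVA
(pseudo-F on Bray-Curtis distances).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .compositions import CLRMatrix, CompositionMatrix

__all__ = [
    "NullCalibration",
    "TestResult",
    "DegenerateVarianceError",
    "null_calibration",
    "gumbel_quantile",
    "mecaf_statistic",
    "mecaf_test",
    "mec_statistic",
    "mec_test",
    "mec_variant_test",
    "permanova_test",
    "pseudo_f",
]

VARIANT_LABELS = {
    "clr": "MEC",
    "mec": "MEC",
    "raw": "MEC-Raw",
    "mec-raw": "MEC-Raw",
    "log": "MEC-Log",
    "mec-log": "MEC-Log",
    "oracle": "MEC-Oracle",
    "mec-oracle": "MEC-Oracle",
}


class DegenerateVarianceError(ValueError):
    """A component has zero estimated variance but a nonzero mean difference."""


@dataclass(frozen=True)
class NullCalibration:
    """Closed-form Gumbel calibration constants for the max-type statistic.

    The standardized statistic ``(T - shift) / scale`` is asymptotically
    standard Gumbel. ``shift = h_p + log 4 - log 4 / (2 log(p-1))`` and
    ``scale = 2 - 1/log(p-1)`` with

        h_p = 2 log(p-1) - [log log(p-1) + log 4 pi]
              + [log log(p-1) + log 4 pi] / (2 log(p-1)).
    """

    p: int
    h_p: float
    scale: float
    shift: float

    def standardize(self, statistic: float) -> float:
        return (statistic - self.shift) / self.scale

    def critical_value(self, alpha: float) -> float:
        return self.scale * gumbel_quantile(alpha) + self.shift

    def pvalue(self, statistic: float) -> float:
        return _gumbel_sf(self.standardize(statistic))


@dataclass
class TestResult:
    """Outcome of one two-sample differential-abundance test.

    ``per_component`` holds the squared standardized per-component mean
    differences (length p-1 for MECAF, p for MEC-family; absent for
    PERMANOVA); ``statistic`` is their maximum (or the pseudo-F).
    ``standardized`` is the Gumbel-standardized statistic when an
    asymptotic calibration was used.
    """

    method: str
    statistic: float
    p_value: float
    reject: bool
    n1: int
    n2: int
    p: int
    alpha: float
    standardized: float | None = None
    per_component: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def gumbel_quantile(alpha: float) -> float:
    """(1 - alpha)-quantile of the standard Gumbel law exp(-exp(-t)).

    q_alpha = -log log (1/(1-alpha)); e.g. alpha = 0.05 gives ~2.9702.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return -math.log(-math.log1p(-alpha))


def _gumbel_sf(t: float) -> float:
    """1 - exp(-exp(-t)), evaluated in survival form to avoid cancellation."""
    if t < -700:  # exp(-t) overflows; the CDF is 0 to double precision
        return 1.0
    return float(-math.expm1(-math.exp(-min(t, 745.0))))


def null_calibration(p: int) -> NullCalibration:
    """Gumbel centering/scaling constants for a max over p-1 components.

    Requires p >= 3 (the constants involve log(p-1) > 0); the asymptotic
    approximation is poor for small p, so a warning is issued for p < 10.
    """
    p = int(p)
    if p < 3:
        raise ValueError("asymptotic calibration requires p >= 3")
    if p < 10:
        warnings.warn(
            f"asymptotic Gumbel calibration is a poor approximation for p = {p} (< 10)",
            stacklevel=2,
        )
    lp = math.log(p - 1)
    bracket = math.log(lp) + math.log(4 * math.pi)
    h_p = 2 * lp - bracket + bracket / (2 * lp)
    scale = 2 - 1 / lp
    shift = h_p + math.log(4) - math.log(4) / (2 * lp)
    return NullCalibration(p=p, h_p=h_p, scale=scale, shift=shift)


def _as_array(X) -> np.ndarray:
    if isinstance(X, (CLRMatrix, CompositionMatrix)):
        return X.values
    return np.asarray(X, dtype=float)


def _check_pair(X1, X2) -> tuple[np.ndarray, np.ndarray]:
    A1, A2 = _as_array(X1), _as_array(X2)
    t1 = getattr(X1, "taxon_ids", None)
    t2 = getattr(X2, "taxon_ids", None)
    if t1 is not None and t2 is not None and list(t1) != list(t2):
        raise ValueError("taxon order differs between the two groups")
    if A1.ndim != 2 or A2.ndim != 2 or A1.shape[1] != A2.shape[1]:
        raise ValueError("groups must be 2-D with identical taxon dimension")
    if A1.shape[0] < 2 or A2.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    if A1.shape[1] < 2:
        raise ValueError("at least 2 components are required")
    return A1, A2


def _squared_components(diff: np.ndarray, var: np.ndarray, scale: float) -> np.ndarray:
    """scale * diff^2 / var, with 0/0 -> 0 and x/0 (x != 0) -> error."""
    zero_var = var <= 0
    if np.any(zero_var & (diff != 0)):
        j = int(np.argwhere(zero_var & (diff != 0))[0][0])
        raise DegenerateVarianceError(
            f"component {j} has zero variance but nonzero mean difference"
        )
    out = np.zeros_like(diff)
    ok = ~zero_var
    out[ok] = scale * diff[ok] ** 2 / var[ok]
    return out


def mecaf_statistic(X1, X2, max_over_all: bool = False) -> tuple[float, np.ndarray]:
    """Welch-type max statistic over the first p-1 CLR components.

    Returns ``(statistic, per_component)`` where ``per_component`` is the
    length-(p-1) vector of squared standardized mean differences (length p
    with ``max_over_all=True``, a diagnostic that ignores the zero-sum
    redundancy). Variances use the biased 1/n_g denominator. The dropped
    component is the *last* column in input order; finite-sample values
    therefore depend on column order (the zero-sum constraint makes the
    choice asymptotically immaterial).
    """
    A1, A2 = _check_pair(X1, X2)
    n1, n2 = A1.shape[0], A2.shape[0]
    n = n1 + n2
    diff = A1.mean(axis=0) - A2.mean(axis=0)
    v1 = A1.var(axis=0)  # 1/n_g denominator
    v2 = A2.var(axis=0)
    sigma = (n / n1) * v1 + (n / n2) * v2
    comps = _squared_components(diff, sigma, float(n))
    if not max_over_all:
        comps = comps[:-1]
    return float(comps.max()), comps


def mecaf_test(X1, X2, alpha: float = 0.05, max_over_all: bool = False) -> TestResult:
    """MECAF test with the closed-form asymptotic Gumbel p-value.

    Rejects when the statistic reaches the critical value
    ``scale * q_alpha + shift`` (ties reject), equivalently when the
    Gumbel p-value is <= alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    stat, comps = mecaf_statistic(X1, X2, max_over_all=max_over_all)
    A1, A2 = _as_array(X1), _as_array(X2)
    p = A1.shape[1]
    cal = null_calibration(p)
    z = cal.standardize(stat)
    if abs(z) > 700:
        warnings.warn("standardized statistic beyond +/-700; p-value saturates", stacklevel=2)
    pval = _gumbel_sf(z)
    reject = stat >= cal.critical_value(alpha)
    return TestResult(
        method="MECAF",
        statistic=stat,
        standardized=z,
        p_value=pval,
        reject=bool(reject),
        per_component=comps,
        n1=A1.shape[0],
        n2=A2.shape[0],
        p=p,
        alpha=alpha,
    )


def mec_statistic(X1, X2) -> tuple[float, np.ndarray]:
    """Pooled-variance max statistic over all p components.

    Per component: ``(n1 n2/(n1+n2)) (xbar^1 - xbar^2)^2 / sigma0_jj`` with
    the pooled 1/(n1+n2) variance of the two centered groups. Valid
    calibration requires equal group covariances.
    """
    A1, A2 = _check_pair(X1, X2)
    n1, n2 = A1.shape[0], A2.shape[0]
    n = n1 + n2
    diff = A1.mean(axis=0) - A2.mean(axis=0)
    pooled = (A1.var(axis=0) * n1 + A2.var(axis=0) * n2) / n
    comps = _squared_components(diff, pooled, n1 * n2 / n)
    return float(comps.max()), comps


def _mec_asymptotic_pvalue(stat: float, p: int) -> tuple[float, float]:
    """Gumbel-type survival p-value for the pooled max-type statistic.

    Centering 2 log p - log log p; limiting law exp(-pi^{-1/2} e^{-t/2}).
    Returns (p_value, centered statistic).
    """
    if p < 3:
        raise ValueError("asymptotic calibration requires p >= 3")
    t = stat - 2 * math.log(p) + math.log(math.log(p))
    arg = math.exp(-t / 2) / math.sqrt(math.pi) if t / 2 < 745 else math.inf
    pval = float(-math.expm1(-arg)) if np.isfinite(arg) else 1.0
    return pval, t


def _permutation_pvalue(A1, A2, stat_fn, n_perm: int, seed) -> float:
    """Label-permutation p-value of max-type statistics, (1 + #>=)/(1 + B)."""
    rng = np.random.default_rng(seed)
    pooled = np.vstack([A1, A2])
    n1 = A1.shape[0]
    obs, _ = stat_fn(A1, A2)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        s, _ = stat_fn(pooled[idx[:n1]], pooled[idx[n1:]])
        if s >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def mec_test(
    X1,
    X2,
    alpha: float = 0.05,
    calibration: str = "asymptotic",
    n_perm: int = 999,
    seed=None,
    method_label: str = "MEC",
) -> TestResult:
    """Pooled max-type test with asymptotic or permutation calibration."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    stat, comps = mec_statistic(X1, X2)
    A1, A2 = _as_array(X1), _as_array(X2)
    p = A1.shape[1]
    if calibration == "asymptotic":
        pval, z = _mec_asymptotic_pvalue(stat, p)
    elif calibration == "permutation":
        pval = _permutation_pvalue(A1, A2, mec_statistic, n_perm, seed)
        z = None
    else:
        raise ValueError("calibration must be 'asymptotic' or 'permutation'")
    return TestResult(
        method=method_label,
        statistic=stat,
        standardized=z,
        p_value=pval,
        reject=bool(pval <= alpha),
        per_component=comps,
        n1=A1.shape[0],
        n2=A2.shape[0],
        p=p,
        alpha=alpha,
    )


def mec_variant_test(
    data1,
    data2,
    variant: str,
    alpha: float = 0.05,
    calibration: str = "asymptotic",
    n_perm: int = 999,
    seed=None,
    simulation: bool = True,
) -> TestResult:
    """Pooled max-type test on a chosen data representation.

    variant:
        ``"clr"``/``"mec"``     data are CLR matrices (plain MEC);
        ``"raw"``               data are relative-abundance compositions;
        ``"log"``               data are compositions, tested on log(R);
        ``"oracle"``            data are absolute abundances (simulation
                                only); the statistic is applied on the log
                                scale, where the abundance model is
                                Gaussian.
    """
    key = variant.lower()
    if key not in VARIANT_LABELS:
        raise ValueError(f"unknown variant {variant!r}")
    label = VARIANT_LABELS[key]
    if label == "MEC-Oracle" and not simulation:
        raise ValueError(
            "MEC-Oracle needs absolute abundances, which are unobservable in real data; "
            "it is available in simulation only"
        )
    A1, A2 = _as_array(data1), _as_array(data2)
    if label == "MEC-Log":
        if np.any(A1 <= 0) or np.any(A2 <= 0):
            raise ValueError("log representation requires strictly positive compositions")
        A1, A2 = np.log(A1), np.log(A2)
    elif label == "MEC-Oracle":
        if np.any(A1 <= 0) or np.any(A2 <= 0):
            raise ValueError("absolute abundances must be strictly positive")
        A1, A2 = np.log(A1), np.log(A2)
    res = mec_test(
        A1, A2, alpha=alpha, calibration=calibration, n_perm=n_perm, seed=seed,
        method_label=label,
    )
    return res


def pseudo_f(sq_dists: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a matrix of squared distances and 0/1 labels."""
    z = labels.astype(float)
    n = len(z)
    n1 = z.sum()
    n2 = n - n1
    total = sq_dists.sum() / (2 * n)
    within1 = z @ sq_dists @ z / 2
    within0 = (1 - z) @ sq_dists @ (1 - z) / 2
    ss_within = within1 / n1 + within0 / n2
    ss_between = total - ss_within
    return float(ss_between / (ss_within / (n - 2)))


def permanova_test(
    comp1,
    comp2,
    n_perm: int = 999,
    seed=None,
    alpha: float = 0.05,
    metric: str = "braycurtis",
    exact: bool = False,
) -> TestResult:
    """Permutational MANOVA (pseudo-F on Bray-Curtis) for two groups.

    The null covers both location and dispersion of the community
    profiles: unequal covariances alone suffice for rejection. p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``, or the exact enumeration
    fraction over all label assignments with ``exact=True`` (small n only).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    A1, A2 = _as_array(comp1), _as_array(comp2)
    if A1.shape[0] < 2 or A2.shape[0] < 2:
        raise ValueError("each group needs at least 2 samples")
    if not exact and n_perm < 99:
        raise ValueError("use at least 99 permutations")
    pooled = np.vstack([A1, A2])
    n1, n = A1.shape[0], A1.shape[0] + A2.shape[0]
    d2 = squareform(pdist(pooled, metric=metric)) ** 2
    labels = np.zeros(n, dtype=int)
    labels[:n1] = 1
    f_obs = pseudo_f(d2, labels)
    if exact:
        combos = list(combinations(range(n), n1))
        if len(combos) > 200_000:
            raise ValueError("exact enumeration too large; use permutations")
        count = 0
        for c in combos:
            z = np.zeros(n, dtype=int)
            z[list(c)] = 1
            if pseudo_f(d2, z) >= f_obs - 1e-12:
                count += 1
        pval = count / len(combos)
        n_done = len(combos)
    else:
        rng = np.random.default_rng(seed)
        # all permuted labelings at once: F is a ratio of quadratic forms in z
        Z = np.zeros((n, n_perm))
        for b in range(n_perm):
            Z[rng.permutation(n)[:n1], b] = 1.0
        within1 = np.einsum("ib,ib->b", Z, d2 @ Z) / 2
        Zc = 1.0 - Z
        within0 = np.einsum("ib,ib->b", Zc, d2 @ Zc) / 2
        total = d2.sum() / (2 * n)
        ss_w = within1 / n1 + within0 / (n - n1)
        f_perm = (total - ss_w) / (ss_w / (n - 2))
        pval = (1 + int(np.sum(f_perm >= f_obs - 1e-12))) / (1 + n_perm)
        n_done = n_perm
    return TestResult(
        method="PERMANOVA",
        statistic=f_obs,
        standardized=None,
        p_value=pval,
        reject=bool(pval <= alpha),
        per_component=None,
        n1=A1.shape[0],
        n2=A2.shape[0],
        p=A1.shape[1],
        alpha=alpha,
    )
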