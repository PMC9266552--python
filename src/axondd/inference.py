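"""Resampling-based uncertainty and hypothesis testing.

Group sizes in tract-level morphometry studies are small (6-7 animals per
group), so parametric reference distributions are replaced by resampling:

* leave-one-animal-out jackknife for the variance of pooled ADD features,
* permutation distributions of the one-way F, the pooled-variance t and the
  two-way (Freedman-Lane) F for hypothesis tests,
* Spearman rank correlation with a Fisher-z interval.

Permutation p-values are exact (full enumeration of distinct label
arrangements) whenever the arrangement count is small, and Monte-Carlo with
the add-one convention ``(1 + exceedances) / (1 + n_perms)`` otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

__all__ = [
    "JackknifeEstimate",
    "PermutationTestResult",
    "CorrelationResult",
    "jackknife_feature",
    "permutation_anova",
    "permutation_ttest",
    "permutation_two_way",
    "spearman",
]

DEFAULT_SEED = 20220702
DEFAULT_N_PERMS = 10_000
EXACT_LIMIT = 20_000
_TIE_TOL = 1e-12  # float-safe ">= observed" comparisons


@dataclass(frozen=True)
class JackknifeEstimate:
    point: float
    se: float
    ci_lo: float
    ci_hi: float
    n_leaveouts: int
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if not self.ci_lo <= self.point <= self.ci_hi:
            raise ValueError("point estimate must lie inside its CI")


@dataclass(frozen=True)
class PermutationTestResult:
    test: str
    statistic: float
    df: tuple
    p: float
    n_perms: int
    exact: bool
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "n_perms": self.n_perms,
            "exact": self.exact,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_lo: float
    ci_hi: float
    n: int

    def __post_init__(self) -> None:
        if not -1 <= self.rho <= 1:
            raise ValueError("rho must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------


def jackknife_feature(
    per_animal_data: list, feature_fn, log_scale: bool = False
) -> JackknifeEstimate:
    """Leave-one-animal-out jackknife of a pooled-sample feature.

    ``feature_fn`` maps a list of per-animal diameter vectors to a scalar
    (typically a pooled-fit feature).  The jackknife variance is
    ``(n-1)/n * sum((theta_i - mean(theta_i))^2)`` and the 95% interval is
    ``point +/- 1.96 se``.  For strictly positive multiplicative features
    (GM, GSD) pass ``log_scale=True``: the interval is built on the log scale
    and exponentiated.
    """
    n = len(per_animal_data)
    if n < 3:
        raise ValueError("jackknife needs at least 3 animals")

    def evaluate(data, which) -> float:
        try:
            value = float(feature_fn(data))
        except Exception as exc:
            raise RuntimeError(f"feature_fn failed on leave-out set {which!r}") from exc
        if log_scale:
            if value <= 0:
                raise ValueError("log_scale jackknife needs positive feature values")
            return float(np.log(value))
        return value

    point = evaluate(per_animal_data, "full")
    leave_outs = np.array(
        [
            evaluate(per_animal_data[:i] + per_animal_data[i + 1 :], i)
            for i in range(n)
        ]
    )
    var = (n - 1) / n * float(np.sum((leave_outs - leave_outs.mean()) ** 2))
    se = float(np.sqrt(var))
    lo, hi = point - 1.96 * se, point + 1.96 * se
    if log_scale:
        return JackknifeEstimate(
            point=float(np.exp(point)),
            se=se,
            ci_lo=float(np.exp(lo)),
            ci_hi=float(np.exp(hi)),
            n_leaveouts=n,
            log_scale=True,
        )
    return JackknifeEstimate(
        point=point, se=se, ci_lo=lo, ci_hi=hi, n_leaveouts=n, log_scale=False
    )


# ---------------------------------------------------------------------------
# one-way permutation ANOVA
# ---------------------------------------------------------------------------


def _as_groups(values, labels):
    v = np.asarray(values, dtype=float).ravel()
    lab = np.asarray(labels).ravel()
    if v.size != lab.size:
        raise ValueError("values and labels must have equal length")
    names, inverse = np.unique(lab, return_inverse=True)
    sizes = np.bincount(inverse)
    # reorder values so groups are contiguous: F under permutation then only
    # depends on which values land in which slot
    order = np.argsort(inverse, kind="stable")
    return v[order], names, sizes


def _oneway_f(matrix: np.ndarray, sizes: np.ndarray, sst: float, grand: float):
    """Vectorized one-way F over rows of permuted value matrices."""
    k = sizes.size
    n = int(sizes.sum())
    ssb = np.zeros(matrix.shape[0])
    start = 0
    for ng in sizes:
        gmean = matrix[:, start : start + ng].sum(axis=1) / ng
        ssb += ng * (gmean - grand) ** 2
        start += ng
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    return np.where(ssw <= _TIE_TOL, np.inf, f)


def _count_arrangements(sizes: np.ndarray) -> int:
    total = int(sizes.sum())
    count = 1
    remaining = total
    for ng in sizes[:-1]:
        count *= comb(remaining, int(ng))
        remaining -= int(ng)
    return count


def _enumerate_assignments(n: int, sizes: np.ndarray):
    """All distinct ways to place n indices into ordered groups of given sizes."""

    def rec(free: tuple, remaining_sizes):
        if not remaining_sizes:
            yield ()
            return
        size = remaining_sizes[0]
        for pick in itertools.combinations(free, size):
            rest = tuple(x for x in free if x not in pick)
            for tail in rec(rest, remaining_sizes[1:]):
                yield pick + tail

    yield from rec(tuple(range(n)), [int(s) for s in sizes])


def permutation_anova(
    values,
    labels,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = DEFAULT_SEED,
    exact_limit: int = EXACT_LIMIT,
) -> PermutationTestResult:
    """One-way ANOVA F with a permutation p-value over group relabelings."""
    v, names, sizes = _as_groups(values, labels)
    if names.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sizes < 2):
        raise ValueError("each group needs at least 2 observations")
    grand = float(v.mean())
    sst = float(np.sum((v - grand) ** 2))
    if sst <= _TIE_TOL:
        raise ValueError("constant values: F statistic undefined")
    f_obs = float(_oneway_f(v[None, :], sizes, sst, grand)[0])
    n = v.size
    n_arr = _count_arrangements(sizes)
    if n_arr <= exact_limit:
        idx = np.array(list(_enumerate_assignments(n, sizes)))
        f_perm = _oneway_f(v[idx], sizes, sst, grand)
        p = float(np.mean(f_perm >= f_obs - _TIE_TOL))
        return PermutationTestResult(
            "one_way_anova", f_obs, (names.size - 1, n - names.size), p, n_arr, True
        )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perms)])
    f_perm = _oneway_f(v[perms], sizes, sst, grand)
    p = float((1 + np.sum(f_perm >= f_obs - _TIE_TOL)) / (1 + n_perms))
    return PermutationTestResult(
        "one_way_anova", f_obs, (names.size - 1, n - names.size), p, n_perms, False, seed
    )


# ---------------------------------------------------------------------------
# permutation t-test
# ---------------------------------------------------------------------------


def _pooled_t(sum_a, na, nb, total_sum, sst, grand):
    """Pooled-variance t from group-A subset sums (vectorized)."""
    n = na + nb
    mean_a = sum_a / na
    mean_b = (total_sum - sum_a) / nb
    ssb = na * (mean_a - grand) ** 2 + nb * (mean_b - grand) ** 2
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ssw / (n - 2)
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        return np.where(ssw <= _TIE_TOL, np.sign(mean_a - mean_b) * np.inf, t)


def permutation_ttest(
    a,
    b=None,
    paired: bool = False,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = DEFAULT_SEED,
    exact_limit: int = EXACT_LIMIT,
) -> PermutationTestResult:
    """Two-sided pooled-variance t-test with a permutation p-value.

    Unpaired: relabel observations across the two groups (exact when
    ``C(na+nb, na)`` is small).  Paired: sign-flip the within-pair
    differences (exact when ``2^n`` is small).
    """
    a = np.asarray(a, dtype=float).ravel()
    if paired:
        if b is None:
            d = a
        else:
            b = np.asarray(b, dtype=float).ravel()
            if b.size != a.size:
                raise ValueError("paired test needs equal-length samples")
            d = a - b
        n = d.size
        if n < 2:
            raise ValueError("need at least 2 pairs")
        sd = d.std(ddof=1)
        if sd <= _TIE_TOL:
            if abs(d.mean()) <= _TIE_TOL:
                return PermutationTestResult("paired_t", 0.0, (n - 1,), 1.0, 2**n, True)
            raise ValueError("degenerate paired sample: zero variance, nonzero mean")
        t_obs = float(d.mean() / (sd / np.sqrt(n)))
        if 2**n <= exact_limit:
            signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
            flipped = signs * d
            t_perm = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(n))
            p = float(np.mean(np.abs(t_perm) >= abs(t_obs) - _TIE_TOL))
            return PermutationTestResult("paired_t", t_obs, (n - 1,), p, 2**n, True)
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perms, n))
        flipped = signs * d
        t_perm = flipped.mean(axis=1) / (flipped.std(axis=1, ddof=1) / np.sqrt(n))
        exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs) - _TIE_TOL))
        return PermutationTestResult(
            "paired_t", t_obs, (n - 1,), (1 + exceed) / (1 + n_perms), n_perms, False, seed
        )

    b = np.asarray(b, dtype=float).ravel()
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    v = np.concatenate([a, b])
    n = na + nb
    grand = float(v.mean())
    sst = float(np.sum((v - grand) ** 2))
    if sst <= _TIE_TOL:
        return PermutationTestResult("pooled_t", 0.0, (n - 2,), 1.0, comb(n, na), True)
    total = float(v.sum())
    t_obs = float(_pooled_t(a.sum(), na, nb, total, sst, grand))
    n_arr = comb(n, na)
    if n_arr <= exact_limit:
        picks = np.array(list(itertools.combinations(range(n), na)))
        sums = v[picks].sum(axis=1)
        t_perm = _pooled_t(sums, na, nb, total, sst, grand)
        p = float(np.mean(np.abs(t_perm) >= abs(t_obs) - _TIE_TOL))
        return PermutationTestResult("pooled_t", t_obs, (n - 2,), p, n_arr, True)
    rng = np.random.default_rng(seed)
    sums = np.array(
        [v[rng.permutation(n)[:na]].sum() for _ in range(n_perms)]
    )
    t_perm = _pooled_t(sums, na, nb, total, sst, grand)
    exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs) - _TIE_TOL))
    return PermutationTestResult(
        "pooled_t", t_obs, (n - 2,), (1 + exceed) / (1 + n_perms), n_perms, False, seed
    )


# ---------------------------------------------------------------------------
# two-way permutation ANOVA (Freedman-Lane)
# ---------------------------------------------------------------------------


def _effect_design(fa: np.ndarray, fb: np.ndarray) -> dict[str, np.ndarray]:
    """Effect-coded (+/-1) design columns for a 2x2 layout."""
    ca = np.where(fa == np.unique(fa)[0], -1.0, 1.0)
    cb = np.where(fb == np.unique(fb)[0], -1.0, 1.0)
    return {"a": ca, "b": cb, "interaction": ca * cb}


def _rss_maker(X: np.ndarray) -> np.ndarray:
    """Residual-maker matrix M = I - X (X'X)^-1 X'."""
    n = X.shape[0]
    return np.eye(n) - X @ np.linalg.pinv(X)


def permutation_two_way(
    values,
    factor_a,
    factor_b,
    n_perms: int = DEFAULT_N_PERMS,
    seed: int = DEFAULT_SEED,
    method: str = "freedman_lane",
) -> dict[str, PermutationTestResult]:
    """Two-way fixed-effects ANOVA (2x2) with permutation p-values per effect.

    F statistics come from the effect-coded least-squares decomposition
    (valid for unbalanced cells).  Under ``freedman_lane`` the residuals of
    the reduced model (full minus the tested term) are permuted and added
    back to the reduced fit; ``labels`` permutes the raw responses instead.
    """
    y = np.asarray(values, dtype=float).ravel()
    fa = np.asarray(factor_a).ravel()
    fb = np.asarray(factor_b).ravel()
    if not (y.size == fa.size == fb.size):
        raise ValueError("values and factors must have equal length")
    if np.unique(fa).size != 2 or np.unique(fb).size != 2:
        raise ValueError("both factors must have exactly 2 levels")
    for la in np.unique(fa):
        for lb in np.unique(fb):
            if not np.any((fa == la) & (fb == lb)):
                raise ValueError(f"empty cell: {la!r} x {lb!r}")
    if method not in {"freedman_lane", "labels"}:
        raise ValueError("method must be 'freedman_lane' or 'labels'")
    n = y.size
    cols = _effect_design(fa, fb)
    intercept = np.ones(n)
    X_full = np.column_stack([intercept, cols["a"], cols["b"], cols["interaction"]])
    M_full = _rss_maker(X_full)
    df_err = n - 4
    if df_err < 1:
        raise ValueError("no error degrees of freedom in the 2x2 design")
    rss_full_obs = float(np.sum((M_full @ y) ** 2))
    rng = np.random.default_rng(seed)
    results: dict[str, PermutationTestResult] = {}
    for name in ("a", "b", "interaction"):
        others = [c for k, c in cols.items() if k != name]
        X_red = np.column_stack([intercept] + others)
        M_red = _rss_maker(X_red)
        rss_red_obs = float(np.sum((M_red @ y) ** 2))
        num_obs = max(rss_red_obs - rss_full_obs, 0.0)
        if rss_full_obs <= _TIE_TOL:
            f_obs = 0.0 if num_obs <= _TIE_TOL else np.inf
        else:
            f_obs = (num_obs / 1.0) / (rss_full_obs / df_err)
        if f_obs == 0.0 and rss_full_obs <= _TIE_TOL:
            results[name] = PermutationTestResult(
                f"two_way_{name}", 0.0, (1, df_err), 1.0, n_perms, False, seed
            )
            continue
        if method == "freedman_lane":
            fitted_red = y - M_red @ y
            resid_red = M_red @ y
            idx = np.array([rng.permutation(n) for _ in range(n_perms)])
            y_star = fitted_red[None, :] + resid_red[idx]
        else:
            idx = np.array([rng.permutation(n) for _ in range(n_perms)])
            y_star = y[idx]
        rss_full = np.sum((y_star @ M_full.T) ** 2, axis=1)
        rss_red = np.sum((y_star @ M_red.T) ** 2, axis=1)
        num = np.maximum(rss_red - rss_full, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = num / (rss_full / df_err)
        f_perm = np.where(rss_full <= _TIE_TOL, np.inf, f_perm)
        exceed = int(np.sum(f_perm >= f_obs - _TIE_TOL))
        results[name] = PermutationTestResult(
            f"two_way_{name}",
            float(f_obs),
            (1, df_err),
            (1 + exceed) / (1 + n_perms),
            n_perms,
            False,
            seed,
        )
    return results


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a Fisher-z 95% interval.

    Average ranks on ties; CI uses ``SE = 1.03 / sqrt(n - 3)`` on the
    z-transformed coefficient.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    if x.size > 3 and abs(rho) < 1:
        z = np.arctanh(rho)
        se = 1.03 / np.sqrt(x.size - 3)
        lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
    else:  # degenerate: CI collapses at the point
        lo = hi = rho
    return CorrelationResult(rho=rho, ci_lo=float(lo), ci_hi=float(hi), n=x.size)
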