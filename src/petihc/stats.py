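"""Statistical tests and power analysis used by the cohort workflow.

Thin, contract-checked wrappers around scipy/pingouin for the standard
procedures (Spearman, tau-b, one-way and mixed ANOVA with Tukey HSD,
unpaired t), plus two pieces authored here because no library provides them
in the required form:

* an exact two-sided p for Kendall's tau at small n without ties, from the
  Mahonian (inversion-count) null distribution;
* the exact power of the two-sided test of a Pearson correlation under a
  bivariate-normal model, integrating the exact non-null sampling density
  of r (the "exact" method of standard power software), with a Fisher-z
  approximate mode alongside.

All tests are two-sided; significance is conventionally read at α = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import integrate, special, stats as sps

__all__ = [
    "CorrelationResult",
    "KSResult",
    "ANOVAResult",
    "PowerResult",
    "spearman",
    "kendall_tau",
    "ks_two_sample",
    "one_way_anova",
    "mixed_anova",
    "unpaired_t",
    "correlation_power",
    "required_n_correlation",
    "percent_change",
]


@dataclass
class CorrelationResult:
    method: str  # "spearman" | "kendall"
    estimate: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"method": self.method, "estimate": self.estimate,
                "p_value": self.p_value, "n": self.n}


@dataclass
class KSResult:
    D: float
    p_value: float
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {"D": self.D, "p_value": self.p_value, "n1": self.n1, "n2": self.n2}


@dataclass
class ANOVAResult:
    #: list of (effect name, F, df_num, df_den, p)
    effects: list[tuple[str, float, float, float, float]]
    #: list of (group_i, group_j, mean_diff, adjusted_p)
    posthoc: list[tuple[str, str, float, float]]

    def to_dict(self) -> dict:
        return {
            "effects": [
                {"name": e[0], "F": e[1], "df_num": e[2], "df_den": e[3], "p": e[4]}
                for e in self.effects
            ],
            "posthoc": [
                {"group_i": p[0], "group_j": p[1], "mean_diff": p[2], "adjusted_p": p[3]}
                for p in self.posthoc
            ],
        }


@dataclass
class PowerResult:
    rho: float
    alpha: float
    power: float
    n_required: int

    def to_dict(self) -> dict:
        return {"rho": self.rho, "alpha": self.alpha, "power": self.power,
                "n_required": self.n_required}


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    return x, y


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the two-sided t-approximation p."""
    x, y = _check_pair(x, y)
    res = sps.spearmanr(x, y)
    return CorrelationResult("spearman", float(res.statistic), float(res.pvalue), x.size)


@lru_cache(maxsize=32)
def _mahonian(n: int) -> np.ndarray:
    """Counts of permutations of n items by inversion number (null tau law)."""
    poly = np.ones(1, dtype=float)
    for i in range(1, n + 1):
        poly = np.convolve(poly, np.ones(i, dtype=float))
    return poly


def _kendall_exact_p(n: int, tau: float) -> float:
    """Two-sided exact p for tie-free tau: P(|C−D| ≥ observed) by enumeration.

    C−D = binom(n,2) − 2·(inversions); the inversion-count distribution over
    the n! permutations is the Mahonian distribution, built by polynomial
    convolution rather than literal enumeration.
    """
    m = n * (n - 1) // 2
    counts = _mahonian(n)
    cd = m - 2 * np.arange(counts.size)  # C−D for each inversion count
    obs = round(tau * m)
    p = counts[np.abs(cd) >= abs(obs) - 1e-9].sum() / counts.sum()
    return float(min(1.0, p))


def kendall_tau(x, y, *, method: str = "auto", n_perm: int = 100_000,
                seed: int = 0) -> CorrelationResult:
    """Kendall's tau-b with an exact two-sided p at small n.

    ``method="auto"``: exact enumeration when n ≤ 10 and there are no ties,
    otherwise the normal approximation.  ``method="permutation"`` draws
    ``n_perm`` seeded permutations (the fallback when exactness is wanted
    despite ties).
    """
    x, y = _check_pair(x, y)
    n = x.size
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    tau = float(sps.kendalltau(x, y).statistic)

    if method == "permutation" or (method == "exact" and ties):
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            t = sps.kendalltau(x, rng.permutation(y)).statistic
            if abs(t) >= abs(tau) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    elif (method in ("auto", "exact")) and n <= 10 and not ties:
        p = _kendall_exact_p(n, tau)
    else:
        p = float(sps.kendalltau(x, y, method="asymptotic").pvalue)
    return CorrelationResult("kendall", tau, float(p), n)


def ks_two_sample(a, b, *, method: str = "asymp", n_perm: int = 100_000,
                  seed: int = 0) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test.

    D is the supremum over thresholds of |ECDF_a − ECDF_b|, computed here
    directly from the pooled order statistics.  The default p evaluates the
    finite-sample Kolmogorov–Smirnov distribution at the effective size
    n1·n2/(n1+n2); ``method="permutation"`` gives a seeded resampling p for
    verification at small n.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    d = _ks_statistic(a, b)
    en = a.size * b.size / (a.size + b.size)
    if method == "asymp":
        p = float(sps.kstwo.sf(d, int(round(en))))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if _ks_statistic(np.sort(perm[: a.size]), np.sort(perm[a.size:])) >= d - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSResult(float(d), min(1.0, p), a.size, b.size)


def _ks_statistic(a_sorted: np.ndarray, b_sorted: np.ndarray) -> float:
    pts = np.concatenate([a_sorted, b_sorted])
    cdf_a = np.searchsorted(a_sorted, pts, side="right") / a_sorted.size
    cdf_b = np.searchsorted(b_sorted, pts, side="right") / b_sorted.size
    return float(np.abs(cdf_a - cdf_b).max())


def one_way_anova(groups: list, labels: list[str] | None = None) -> ANOVAResult:
    """One-way ANOVA with Tukey HSD post hoc.

    F = MS_between / MS_within; Tukey adjusted p from the studentized-range
    distribution with df = N − k.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrs):
        raise ValueError("zero within-group variance in every group; F undefined")
    labels = labels or [f"group{i}" for i in range(len(arrs))]

    f = sps.f_oneway(*arrs)
    k = len(arrs)
    n_tot = sum(a.size for a in arrs)
    tk = sps.tukey_hsd(*arrs)
    posthoc = []
    for i in range(k):
        for j in range(i + 1, k):
            posthoc.append((labels[i], labels[j],
                            float(arrs[i].mean() - arrs[j].mean()),
                            float(tk.pvalue[i, j])))
    effects = [("group", float(f.statistic), float(k - 1), float(n_tot - k),
                float(f.pvalue))]
    return ANOVAResult(effects, posthoc)


def mixed_anova(table: pd.DataFrame, *, dv: str, between: str, within: str,
                subject: str) -> ANOVAResult:
    """Two-way mixed ANOVA (between-subject × repeated within-subject factor).

    Standard SS partition, no sphericity correction.  The design must be
    balanced: every subject measured at every within level; missing cells are
    named in the error.  Post hoc: Tukey HSD across between-groups at each
    within level.
    """
    req = {dv, between, within, subject}
    if not req.issubset(table.columns):
        raise ValueError(f"table missing columns {sorted(req - set(table.columns))}")
    levels = sorted(table[within].unique())
    missing = []
    for sid, g in table.groupby(subject):
        absent = set(levels) - set(g[within])
        missing += [(sid, lv) for lv in sorted(absent)]
    if missing:
        raise ValueError(f"unbalanced design; missing (subject, {within}) cells: {missing}")

    import pingouin as pg  # deferred: slow import

    aov = pg.mixed_anova(data=table, dv=dv, between=between, within=within,
                         subject=subject)
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    # degenerate (zero-variance) designs: pingouin omits the all-NaN F/p columns
    effects = [
        (str(r["Source"]), float(r.get("F", np.nan)), float(r["DF1"]),
         float(r["DF2"]), float(r.get(p_col, np.nan)))
        for _, r in aov.iterrows()
    ]
    posthoc = []
    for lv in levels:
        sub = table[table[within] == lv]
        glabels = sorted(sub[between].unique())
        arrs = [sub.loc[sub[between] == g, dv].to_numpy(float) for g in glabels]
        if len(arrs) < 2 or any(a.size < 2 for a in arrs) or all(np.ptp(a) == 0 for a in arrs):
            continue
        tk = sps.tukey_hsd(*arrs)
        for i in range(len(arrs)):
            for j in range(i + 1, len(arrs)):
                posthoc.append((f"{glabels[i]}@{within}={lv}", f"{glabels[j]}@{within}={lv}",
                                float(arrs[i].mean() - arrs[j].mean()),
                                float(tk.pvalue[i, j])))
    return ANOVAResult(effects, posthoc)


def unpaired_t(a, b) -> tuple[float, float, float]:
    """Student's two-sample t (pooled variance), two-sided. Returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(a.size + b.size - 2), float(res.pvalue)


# ---------------------------------------------------------------------------
# Power of the test of a Pearson correlation


def _r_density(r: float, rho: float, n: int) -> float:
    """Exact sampling density of Pearson's r under bivariate normality."""
    log_c = (
        math.log(n - 2)
        + special.gammaln(n - 1)
        + 0.5 * (n - 1) * math.log1p(-rho * rho)
        + 0.5 * (n - 4) * np.log1p(-(r * r))
        - 0.5 * math.log(2 * math.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return np.exp(log_c) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)


def correlation_power(rho: float, n: int, alpha: float = 0.05,
                      method: str = "exact") -> float:
    """Power of the two-sided test of H0: ρ = 0 at sample size n.

    ``method="exact"`` rejects when |r| exceeds the null critical value
    (equivalently |t| > t_crit with n−2 df) and integrates the exact non-null
    density of r over the rejection region.  ``method="fisher-z"`` uses the
    normal approximation on arctanh(r) with SE 1/sqrt(n−3).
    """
    if not 0 < abs(rho) < 1:
        raise ValueError("rho must satisfy 0 < |rho| < 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if method == "exact":
        if n < 4:
            raise ValueError("exact power needs n >= 4")
        t_crit = sps.t.ppf(1 - alpha / 2, n - 2)
        r_crit = t_crit / math.sqrt(n - 2 + t_crit**2)
        upper, _ = integrate.quad(_r_density, r_crit, 1.0, args=(rho, n))
        lower, _ = integrate.quad(_r_density, -1.0, -r_crit, args=(rho, n))
        return float(upper + lower)
    if method == "fisher-z":
        if n < 4:
            raise ValueError("fisher-z power needs n >= 4")
        z_a = sps.norm.ppf(1 - alpha / 2)
        shift = math.atanh(rho) * math.sqrt(n - 3)
        return float(sps.norm.sf(z_a - shift) + sps.norm.cdf(-z_a - shift))
    raise ValueError(f"unknown method {method!r}")


def required_n_correlation(rho: float, alpha: float = 0.05, power: float = 0.80,
                           method: str = "exact", n_max: int = 100_000) -> PowerResult:
    """Smallest n at which the correlation test reaches the target power.

    Power is monotone in n, so the minimum is found by doubling then
    bisection.  Raises if the target is still unreached at ``n_max``.
    """
    if not alpha < power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    lo, hi = 4, 8
    if correlation_power(rho, lo, alpha, method) >= power:
        return PowerResult(rho, alpha, power, lo)
    while correlation_power(rho, hi, alpha, method) < power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError(f"target power unreachable for |rho|={abs(rho)} below n_max={n_max}")
    while hi - lo > 1:  # invariant: power(lo) < target <= power(hi)
        mid = (lo + hi) // 2
        if correlation_power(rho, mid, alpha, method) >= power:
            hi = mid
        else:
            lo = mid
    return PowerResult(rho, alpha, power, hi)


def percent_change(v_from: float, v_to: float) -> float:
    """Relative change from ``v_from`` to ``v_to`` in percent."""
    if v_from == 0:
        raise ValueError("percent change undefined from a zero baseline")
    return 100.0 * (v_to - v_from) / v_from
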