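"""Two-group statistical comparison of barcode summaries.

The comparison mirrors a standard topological group analysis:

* pooled bar-length distributions per (group, dimension), compared with a
  two-sample Kolmogorov-Smirnov test (asymptotic two-sided p);
* per-subject persistent entropies, checked for normality per group with a
  Lilliefors test (Monte-Carlo p), then compared with a pooled-variance
  two-sample t-test and Cohen's d with the root-mean-square of the two
  sample standard deviations as denominator, d = |x1 - x2| / sqrt((s1^2 + s2^2)/2);
* an OLS regression e_i = b0 + b1*sex + b2*age + b3*diagnostic controlling
  for demographic covariates (sex 0 = male, 1 = female; diagnostic
  0 = control, 1 = case).

The KS distance, Lilliefors distance and t statistic are computed here in
closed form (p-values via scipy distribution functions or Monte Carlo) and
are verified in the test suite against scipy/statsmodels; the OLS fit is
delegated to statsmodels.  All p-values are reported unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PooledLengths",
    "GroupComparison",
    "RegressionResult",
    "pool_lengths",
    "ks_two_sample",
    "lilliefors",
    "t_and_d",
    "entropy_regression",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sided two-sample KS test: (D, asymptotic p).

    D = sup |ECDF_a - ECDF_b|; p from the Smirnov asymptotic null with
    effective size n_a*n_b/(n_a+n_b).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs two nonempty samples")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    en = a.size * b.size / (a.size + b.size)
    p = float(sps.kstwo.sf(d, int(np.round(en))))
    return d, min(max(p, 0.0), 1.0)


@lru_cache(maxsize=32)
def _lilliefors_null(n: int, n_mc: int, seed: int) -> tuple[float, ...]:
    """Monte-Carlo null distribution of the Lilliefors distance at size n."""
    rng = np.random.default_rng(seed)
    x = np.sort(rng.standard_normal((n_mc, n)), axis=1)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = sps.norm.cdf((x - mu) / sd)
    i = np.arange(1, n + 1)
    d_plus = (i / n - z).max(axis=1)
    d_minus = (z - (i - 1) / n).max(axis=1)
    return tuple(np.maximum(d_plus, d_minus))


def lilliefors(
    values, n_mc: int = 2000, seed: int = 12345
) -> tuple[float, float]:
    """Lilliefors normality test: (D, Monte-Carlo p).

    D is the KS distance between the sample ECDF and the normal with the
    sample's estimated mean and (n-1) standard deviation.  The p-value is
    the fraction of `n_mc` seeded Gaussian samples of the same size whose
    distance is at least as large (add-one estimator), so the method is
    Monte Carlo, deterministic given the seed.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"Lilliefors test needs n >= 4, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Lilliefors test undefined for a constant sample")
    z = sps.norm.cdf((x - x.mean()) / sd)
    i = np.arange(1, n + 1)
    d = float(max((i / n - z).max(), (z - (i - 1) / n).max()))
    null = np.array(_lilliefors_null(n, n_mc, seed))
    p = (1.0 + (null >= d - 1e-15).sum()) / (n_mc + 1.0)
    return d, float(p)


def t_and_d(control, case) -> dict[str, float]:
    """Pooled-variance two-sample t-test and Cohen's d.

    Returns t (control minus case), two-sided p, degrees of freedom, d,
    group means, sample SDs and standard errors of the means.
    """
    x1 = np.asarray(control, dtype=float)
    x2 = np.asarray(case, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    m1, m2 = x1.mean(), x2.mean()
    s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("degenerate (zero) pooled variance")
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df)
    d = abs(m1 - m2) / np.sqrt((s1**2 + s2**2) / 2)
    return {
        "t": float(t),
        "p": float(p),
        "df": float(df),
        "cohen_d": float(d),
        "mean_control": float(m1),
        "mean_case": float(m2),
        "sd_control": float(s1),
        "sd_case": float(s2),
        "sem_control": float(s1 / np.sqrt(n1)),
        "sem_case": float(s2 / np.sqrt(n2)),
        "n_control": int(n1),
        "n_case": int(n2),
    }


# ---------------------------------------------------------------------------
# cohort-level containers and operations
# ---------------------------------------------------------------------------


@dataclass
class PooledLengths:
    """Bar lengths of all subjects, keyed by (group, dimension)."""

    pools: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)

    def get(self, group: str, dim: int) -> np.ndarray:
        return self.pools[(group, dim)]

    def sizes(self) -> dict[str, int]:
        return {f"{g}_dim{d}": int(v.size) for (g, d), v in self.pools.items()}


def pool_lengths(
    length_sets: dict[str, dict[int, np.ndarray]],
    groups: dict[str, str],
    dims: tuple[int, ...] = (0, 1),
) -> PooledLengths:
    """Concatenate per-subject bar lengths into per-(group, dim) multisets.

    Parameters
    ----------
    length_sets
        subject_id -> {dim -> array of bar lengths}.
    groups
        subject_id -> "control" | "case".
    """
    pools: dict[tuple[str, int], list[np.ndarray]] = {
        (g, d): [] for g in ("control", "case") for d in dims
    }
    for sid, per_dim in length_sets.items():
        g = groups[sid]
        for d in dims:
            pools[(g, d)].append(np.asarray(per_dim[d], dtype=float))
    out: dict[tuple[str, int], np.ndarray] = {}
    for key, chunks in pools.items():
        if not chunks:
            raise ValueError(f"no subjects contribute to pool {key}")
        out[key] = np.sort(np.concatenate(chunks))
    return PooledLengths(out)


@dataclass
class GroupComparison:
    """Full two-group report for one homology dimension."""

    dim: int
    ks_D: float
    ks_p: float
    lilliefors_control: tuple[float, float]
    lilliefors_case: tuple[float, float]
    ttest: dict[str, float]
    pooled_sizes: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "ks": {"D": self.ks_D, "p": self.ks_p,
                   "pooled_sizes": self.pooled_sizes},
            "lilliefors": {
                "method": "monte-carlo",
                "control": {"D": self.lilliefors_control[0],
                            "p": self.lilliefors_control[1]},
                "case": {"D": self.lilliefors_case[0],
                         "p": self.lilliefors_case[1]},
            },
            "entropy_ttest": self.ttest,
            "p_values_adjusted": False,
        }


@dataclass
class RegressionResult:
    """OLS fit of entropy on sex, age and diagnostic."""

    dim: int
    scaling: str  # "none" or "minmax"
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "std_err": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "scaling": self.scaling,
            "n": self.n,
            "r_squared": self.rsquared,
            "r_squared_adj": self.rsquared_adj,
            "coefficients": self.to_frame().to_dict(orient="index"),
        }


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max scale a constant column")
    return (x - lo) / (hi - lo)


def entropy_regression(
    table: pd.DataFrame, dim: int, scaling: str = "none"
) -> RegressionResult:
    """OLS of e_dim on sex, age and diagnostic with intercept.

    `table` needs columns group, sex, age and e{dim}.  Complete cases only.
    With ``scaling="minmax"`` the response and age are scaled to [0, 1]
    (sex and diagnostic are already 0/1 indicators); signs, t and p are
    unaffected for the indicator coefficients.
    """
    col = f"e{dim}"
    df = table[["group", "sex", "age", col]].dropna()
    n = len(df)
    if n <= 4:
        raise ValueError(f"regression needs n > 4 complete cases, got {n}")
    y = df[col].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)
    if scaling == "minmax":
        y = _minmax(y)
        age = _minmax(age)
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    X = pd.DataFrame(
        {
            "sex": df["sex"].to_numpy(dtype=float),
            "age": age,
            "diagnostic": (df["group"] == "case").astype(float).to_numpy(),
        }
    )
    X = sm.add_constant(X, prepend=True, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        dim=dim,
        scaling=scaling,
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        rsquared=float(fit.rsquared),
        rsquared_adj=float(fit.rsquared_adj),
        n=n,
    )


def compare_groups(
    entropy_table: pd.DataFrame,
    pooled: PooledLengths,
    dim: int,
    lilliefors_mc: int = 2000,
    lilliefors_seed: int = 12345,
) -> GroupComparison:
    """Assemble the full per-dimension comparison report."""
    ctrl = entropy_table.loc[entropy_table["group"] == "control", f"e{dim}"]
    case = entropy_table.loc[entropy_table["group"] == "case", f"e{dim}"]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("each group needs at least 2 subjects")
    D, p = ks_two_sample(pooled.get("control", dim), pooled.get("case", dim))

    def _lillie(values) -> tuple[float, float]:
        # undefined for n < 4 or constant samples; report NaN rather than
        # blocking the rest of the report on tiny toy cohorts
        try:
            return lilliefors(values, lilliefors_mc, lilliefors_seed)
        except ValueError:
            return (float("nan"), float("nan"))

    return GroupComparison(
        dim=dim,
        ks_D=D,
        ks_p=p,
        lilliefors_control=_lillie(ctrl),
        lilliefors_case=_lillie(case),
        ttest=t_and_d(ctrl, case),
        pooled_sizes={
            "control": int(pooled.get("control", dim).size),
            "case": int(pooled.get("case", dim).size),
        },
    )
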