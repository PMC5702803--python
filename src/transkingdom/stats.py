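"""Two-group differential statistics with cross-experiment meta-analysis.

The experimental design is two independent mouse experiments, each with one
control group and several antibiotic-treated groups.  For every feature
(a metabolic parameter, a qPCR gene, or a log OTU abundance) each treated
group is compared against control *within* each experiment with an
empirical-Bayes moderated t-statistic; the two per-experiment p-values are
combined with Fisher's method and a Benjamini-Hochberg FDR is computed over
the combined p-values of one comparison.  A feature is called differential
only when a conjunction of criteria holds: consistent fold-change direction
in both experiments, individual p below a per-experiment cutoff, combined p
below its cutoff, and FDR q below its cutoff.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Thresholds",
    "ModeratedFit",
    "grubbs_remove_outlier",
    "log2_transform",
    "fit_moderated",
    "fisher_combine",
    "bh_fdr",
    "call_differential",
    "permutation_t_test",
]

#: direction is treated as undefined below this |log2 FC|
SIGN_EPS = 1e-9


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs of the composite significance criterion.

    The default profile is the one used for phenotypes and OTU abundances;
    :meth:`diversity` returns the stricter profile used for the Shannon
    diversity meta-test.
    """

    grubbs_alpha: float = 0.05
    p_individual: float = 0.20
    p_combined: float = 0.05
    fdr: float = 0.10
    #: FDR cutoff for correlation edges with a microbial node (class iv)
    fdr_microbial: float = 0.01

    def __post_init__(self) -> None:
        for name in ("grubbs_alpha", "p_individual", "p_combined", "fdr", "fdr_microbial"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"threshold {name}={v} outside (0, 1]")

    @classmethod
    def diversity(cls) -> "Thresholds":
        """Stricter profile: p < 2% per experiment, combined p < 0.1%, FDR < 0.1%."""
        return cls(p_individual=0.02, p_combined=0.001, fdr=0.001)

    def replace(self, **kw) -> "Thresholds":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# outlier handling


def grubbs_remove_outlier(values, alpha: float = 0.05):
    """Two-sided Grubbs test; remove at most one extreme value.

    Returns ``(kept_values, removed_index)`` where ``removed_index`` indexes
    the input array (``None`` when nothing was removed).  The critical value
    is ((N-1)/sqrt(N)) * sqrt(t^2 / (N-2+t^2)) with t the upper alpha/(2N)
    quantile of Student's t on N-2 degrees of freedom.  With n < 3 the test
    cannot run and the data pass through unchanged.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("grubbs_remove_outlier requires finite values")
    n = x.size
    if n < 3:
        warnings.warn(f"Grubbs test needs n >= 3 (got n={n}); no outlier test performed")
        return x, None
    s = x.std(ddof=1)
    if s == 0:
        return x, None
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = dev[i] / s
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))
    if g > crit:
        return np.delete(x, i), i
    return x, None


def log2_transform(matrix: pd.DataFrame, allow_nan: bool = False) -> pd.DataFrame:
    """Element-wise log2 of a samples x features matrix of positive values.

    ``allow_nan=True`` passes NaN entries through (values removed as
    outliers upstream); otherwise they are an error like nonpositives.
    """
    bad = matrix <= 0 if allow_nan else (matrix <= 0) | matrix.isna()
    if bad.any().any():
        rows, cols = np.where(bad.to_numpy())
        sample, feature = int(rows[0]), int(cols[0])
        raise ValueError(
            "nonpositive value for feature "
            f"{matrix.columns[feature]!r} in sample {matrix.index[sample]!r}"
        )
    return np.log2(matrix)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated two-group fit


@dataclass
class ModeratedFit:
    """Result of a moderated two-group comparison (one experiment).

    ``fold_change`` is the difference of group means on the log2 scale,
    i.e. log2 of the ratio of geometric means (treated / control).
    """

    features: pd.Index
    fold_change: np.ndarray
    s2: np.ndarray
    df_residual: np.ndarray
    df_prior: float
    s2_prior: float
    s2_posterior: np.ndarray
    t: np.ndarray
    p: np.ndarray
    n_treated: np.ndarray
    n_control: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold_change": self.fold_change,
                "t": self.t,
                "p": self.p,
                "s2": self.s2,
                "s2_posterior": self.s2_posterior,
            },
            index=self.features,
        )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def _estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square prior.

    Matches the first two moments of log(s2) using digamma/trigamma
    identities for log chi-square variates.  Returns (df_prior, s2_prior);
    df_prior is +inf when the observed spread of log(s2) is no larger than
    expected under a common variance.
    """
    ok = s2 > 0
    if not np.any(ok):
        raise ValueError("all features have zero residual variance")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return math.inf, float(np.exp(emean))
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0)


def fit_moderated(
    log2_matrix: pd.DataFrame,
    groups: pd.Series,
    group: str,
    control: str,
    df_prior: float | None = None,
) -> ModeratedFit:
    """Moderated two-group comparison of ``group`` vs ``control``.

    ``log2_matrix`` is samples x features (NaN entries mark values removed
    as outliers), ``groups`` maps sample -> group label.  Per feature the
    ordinary difference of means and pooled variance are computed; the
    variance prior (df_prior d0, s2_prior s0^2) is estimated across all
    features of the matrix and each feature's variance is shrunk to
    s2_post = (d0*s0^2 + d*s2) / (d0 + d).  The moderated t is referred to
    Student's t on d0 + d degrees of freedom.

    ``df_prior`` overrides the estimated prior df; 0 disables shrinkage
    (ordinary pooled t), +inf gives complete pooling to s2_prior.
    """
    if log2_matrix.shape[1] < 2:
        raise ValueError("variance moderation pools across features; need >= 2 features")
    groups = groups.reindex(log2_matrix.index)
    a = log2_matrix.loc[groups == group].to_numpy(dtype=float)
    b = log2_matrix.loc[groups == control].to_numpy(dtype=float)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError(f"empty group in comparison {group!r} vs {control!r}")
    n1 = np.sum(~np.isnan(a), axis=0).astype(float)
    n2 = np.sum(~np.isnan(b), axis=0).astype(float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError(
            f"comparison {group!r} vs {control!r}: a group has < 2 usable samples "
            "for some feature after outlier removal"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        v1 = np.nanvar(a, axis=0, ddof=1)
        v2 = np.nanvar(b, axis=0, ddof=1)
    fc = m1 - m2
    df = n1 + n2 - 2.0
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df

    if df_prior is None:
        d0, s0 = _estimate_prior(s2, df)
    elif df_prior == 0:
        d0, s0 = 0.0, float("nan")
    else:
        d0 = float(df_prior)
        _, s0 = _estimate_prior(s2, df)
    if d0 == 0:
        s2_post = s2.copy()
        df_total = df
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, np.where(np.abs(fc) > 0, np.inf * np.sign(fc), 0.0))
    finite_df = np.isfinite(df_total)
    p = np.where(
        finite_df,
        2.0 * sps.t.sf(np.abs(t), np.where(finite_df, df_total, 1.0)),
        2.0 * sps.norm.sf(np.abs(t)),
    )
    return ModeratedFit(
        features=log2_matrix.columns,
        fold_change=fc,
        s2=s2,
        df_residual=df,
        df_prior=d0,
        s2_prior=s0,
        s2_posterior=s2_post,
        t=t,
        p=np.clip(p, 0.0, 1.0),
        n_treated=n1,
        n_control=n2,
    )


# ---------------------------------------------------------------------------
# meta-analysis


def fisher_combine(p_values) -> float:
    """Fisher's combined probability: -2 sum(ln p) ~ chi-square on 2k df.

    Zero p-values are clamped to the smallest positive normal float with a
    warning; p > 1 is a validation error.  A singleton list is returned
    unchanged (the chi-square on 2 df inverts the transform).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("fisher_combine needs at least one p-value")
    if np.any(p > 1) or np.any(p < 0) or np.any(~np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0, 1]: {p!r}")
    tiny = np.finfo(float).tiny
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive normal float")
        p = np.maximum(p, tiny)
    x2 = -2.0 * np.sum(np.log(p))
    return float(np.clip(sps.chi2.sf(x2, 2 * p.size), tiny, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    results_exp1: pd.DataFrame,
    results_exp2: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Meta-analysis of one comparison across the two experiments.

    Inputs are per-experiment frames indexed by feature with columns
    ``fold_change`` and ``p`` (as from :meth:`ModeratedFit.to_frame`).  The
    FDR family is all features of this comparison.  Returns a frame with
    fold changes, p-values, combined p, q and the composite ``significant``
    call: same fold-change direction in both experiments, individual p below
    cutoff in each, combined p and q below their cutoffs.
    """
    common = results_exp1.index.intersection(results_exp2.index)
    dropped = results_exp1.index.symmetric_difference(results_exp2.index)
    if len(dropped):
        warnings.warn(
            f"{len(dropped)} feature(s) present in only one experiment excluded: "
            f"{list(dropped[:5])}..."
        )
    if len(common) == 0:
        raise ValueError("no features shared between experiments")
    r1 = results_exp1.loc[common]
    r2 = results_exp2.loc[common]
    p_comb = np.array(
        [fisher_combine([p1, p2]) for p1, p2 in zip(r1["p"], r2["p"])]
    )
    q = bh_fdr(p_comb)
    fc1 = r1["fold_change"].to_numpy()
    fc2 = r2["fold_change"].to_numpy()
    sign1 = np.where(np.abs(fc1) < SIGN_EPS, 0, np.sign(fc1))
    sign2 = np.where(np.abs(fc2) < SIGN_EPS, 0, np.sign(fc2))
    significant = (
        (sign1 == sign2)
        & (sign1 != 0)
        & (r1["p"].to_numpy() < thresholds.p_individual)
        & (r2["p"].to_numpy() < thresholds.p_individual)
        & (p_comb < thresholds.p_combined)
        & (q < thresholds.fdr)
    )
    return pd.DataFrame(
        {
            "fc_1": fc1,
            "fc_2": fc2,
            "p_1": r1["p"].to_numpy(),
            "p_2": r2["p"].to_numpy(),
            "p_combined": p_comb,
            "q": q,
            "significant": significant,
        },
        index=common,
    )


# ---------------------------------------------------------------------------
# non-parametric t-test


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = a.size, b.size
    v1 = a.var(ddof=1) if n1 > 1 else 0.0
    v2 = b.var(ddof=1) if n2 > 1 else 0.0
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    diff = a.mean() - b.mean()
    se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return diff / se


def permutation_t_test(group_a, group_b, n_perm: int = 10_000, seed=None) -> float:
    """Two-sided permutation (non-parametric) t-test.

    All label arrangements are enumerated exhaustively when there are at
    most 20,000 of them, giving an exact p; otherwise ``n_perm`` random
    permutations are drawn and p = (1 + #extreme) / (1 + n_perm).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if pooled.var() == 0:
        return 1.0
    t_obs = abs(_t_stat(a, b))
    n, n1 = pooled.size, a.size
    n_arrangements = math.comb(n, n1)
    tol = 1e-12
    if n_arrangements <= 20_000:
        extreme = 0
        idx = np.arange(n)
        for comb in itertools.combinations(idx, n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(comb)] = True
            if abs(_t_stat(pooled[sel], pooled[~sel])) >= t_obs - tol:
                extreme += 1
        return extreme / n_arrangements
    if n_perm < 999:
        raise ValueError("n_perm must be >= 999")
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(_t_stat(perm[:n1], perm[n1:])) >= t_obs - tol:
            extreme += 1
    return (1 + extreme) / (1 + n_perm)
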