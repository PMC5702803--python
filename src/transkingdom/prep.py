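"""OTU count-table preparation: abundance filtering, CSS + quantile
normalization, rarefaction and Shannon alpha diversity.

Two branches leave this module.  The analysis branch feeds the differential
meta-analysis and the correlation network: OTUs are filtered to the set
covering 99% of cumulative abundance in an experiment, normalized by
cumulative sum scaling (CSS) and then quantile normalization, and log2
transformed with a pseudo-count.  The diversity branch rarefies the raw
counts to a fixed depth and computes the Shannon index (base 2), which is
meta-tested across experiments under a stricter significance profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import Thresholds, bh_fdr, call_differential, fisher_combine, fit_moderated, permutation_t_test, SIGN_EPS

__all__ = [
    "NormalizedOtuTable",
    "cumulative_abundance_filter",
    "css_normalize",
    "quantile_normalize",
    "rarefy",
    "shannon_index",
    "diversity_meta_test",
    "differential_otus",
]


@dataclass
class NormalizedOtuTable:
    """CSS + quantile normalized abundances with filter provenance."""

    abundances: pd.DataFrame  # OTUs x samples, non-negative reals
    provenance: dict = field(default_factory=dict)
    css_percentile: float = 0.5
    css_scale: float = 1000.0


def cumulative_abundance_filter(counts: pd.DataFrame, threshold: float = 0.99):
    """Keep the most abundant OTUs covering ``threshold`` of all counts.

    OTUs are ordered by total count across all samples of the experiment
    (descending) and the smallest prefix whose cumulative share reaches the
    threshold is retained; OTUs tied with the boundary total are all kept.
    Returns ``(filtered_counts, provenance)``.
    """
    if counts.size == 0 or counts.shape[0] == 0:
        raise ValueError("empty OTU table")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    totals = counts.sum(axis=1)
    order = totals.sort_values(ascending=False, kind="stable")
    share = order.cumsum() / order.sum()
    # first position reaching the threshold, then absorb boundary ties
    k = int(np.searchsorted(share.to_numpy(), threshold)) + 1
    k = min(k, len(order))
    boundary = order.iloc[k - 1]
    retained = order.index[order >= boundary]
    provenance = {
        "filter": "cumulative_abundance",
        "threshold": float(threshold),
        "n_input": int(counts.shape[0]),
        "n_retained": int(len(retained)),
        "n_removed": int(counts.shape[0] - len(retained)),
        "removed": [str(i) for i in counts.index.difference(retained)],
    }
    return counts.loc[counts.index.intersection(retained, sort=False)], provenance


def css_normalize(
    counts: pd.DataFrame, percentile: float = 0.5, scale: float = 1000.0
) -> pd.DataFrame:
    """Cumulative sum scaling with a fixed quantile of nonzero counts.

    For sample j the scaling factor s_j is the sum of all counts not
    exceeding q_j, the ``percentile`` quantile of the sample's nonzero
    counts; normalized abundance is count / s_j * scale.  Dividing by a
    partial sum rather than the total damps the influence of a few
    dominant taxa on sequencing-depth correction.
    """
    out = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy(dtype=float)
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero counts")
        q = np.quantile(nonzero, percentile)
        s = col[col <= q].sum()
        if s == 0:
            raise ValueError(f"sample {sample!r} has zero CSS scaling factor")
        out[sample] = col / s * scale
    return pd.DataFrame(out, index=counts.index)


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Force all sample columns to share one value distribution.

    Each column is sorted, values are averaged across columns at each sorted
    position, and every original entry receives the average at its rank;
    ties within a column receive the mean over their tied positions (this is
    what a fractional average rank interpolates to).  The procedure is
    idempotent.
    """
    if table.shape[1] < 2:
        warnings.warn("quantile normalization of a single sample is the identity")
        return table.copy()
    x = table.to_numpy(dtype=float)
    n = x.shape[0]
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    ranks = pd.DataFrame(x).rank(axis=0, method="average").to_numpy()
    positions = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j] = np.interp(ranks[:, j], positions, mean_sorted)
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def rarefy(counts: pd.DataFrame, depth: int = 200_000, seed=None):
    """Subsample every sample to ``depth`` reads without replacement.

    Samples whose total is below the depth are dropped and recorded.
    Returns ``(rarefied_counts, dropped_samples)``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=0)
    keep = totals[totals >= depth].index
    dropped = [str(s) for s in counts.columns if s not in set(keep)]
    if len(keep) == 0:
        raise ValueError(f"all samples fall below the rarefaction depth {depth}")
    out = {}
    for sample in keep:
        col = counts[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    return pd.DataFrame(out, index=counts.index), dropped


def shannon_index(sample_counts) -> float:
    """Shannon diversity H = -sum p_i log2 p_i, in bits."""
    c = np.asarray(sample_counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon index of an all-zero sample is undefined")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def diversity_meta_test(
    shannon: dict[int, pd.Series],
    groups: dict[int, pd.Series],
    control: str,
    thresholds: Thresholds | None = None,
    n_perm: int = 10_000,
    seed=None,
) -> pd.DataFrame:
    """Cross-experiment meta-test of Shannon diversity per comparison.

    ``shannon`` maps experiment id -> per-sample H; ``groups`` maps
    experiment id -> per-sample group label.  Each treated group is compared
    with control by a permutation t-test within each experiment; the
    direction (difference of mean H), the two p-values, Fisher's combined p
    and a BH FDR over the comparisons enter the same conjunction as the
    differential criterion, under the stricter diversity profile.
    """
    if thresholds is None:
        thresholds = Thresholds.diversity()
    exps = sorted(shannon)
    if len(exps) != 2:
        raise ValueError("diversity_meta_test expects exactly two experiments")
    e1, e2 = exps
    treated = sorted(
        (set(groups[e1].unique()) & set(groups[e2].unique())) - {control}
    )
    skipped = sorted(
        (set(groups[e1].unique()) ^ set(groups[e2].unique())) - {control}
    )
    if skipped:
        warnings.warn(f"groups missing from one experiment excluded: {skipped}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in treated:
        stats_per_exp = {}
        for e in (e1, e2):
            h = shannon[e]
            lab = groups[e].reindex(h.index)
            a = h[lab == g].to_numpy()
            b = h[lab == control].to_numpy()
            p = permutation_t_test(a, b, n_perm=n_perm, seed=rng.integers(2**31))
            stats_per_exp[e] = (a.mean() - b.mean(), p)
        d1, p1 = stats_per_exp[e1]
        d2, p2 = stats_per_exp[e2]
        rows.append(
            {"comparison": g, "delta_1": d1, "delta_2": d2, "p_1": p1, "p_2": p2,
             "p_combined": fisher_combine([p1, p2])}
        )
    result = pd.DataFrame(rows).set_index("comparison")
    if len(result):
        result["q"] = bh_fdr(result["p_combined"].to_numpy())
        s1 = np.where(np.abs(result["delta_1"]) < SIGN_EPS, 0, np.sign(result["delta_1"]))
        s2 = np.where(np.abs(result["delta_2"]) < SIGN_EPS, 0, np.sign(result["delta_2"]))
        result["significant"] = (
            (s1 == s2)
            & (s1 != 0)
            & (result["p_1"] < thresholds.p_individual)
            & (result["p_2"] < thresholds.p_individual)
            & (result["p_combined"] < thresholds.p_combined)
            & (result["q"] < thresholds.fdr)
        )
    return result


def differential_otus(
    normalized: dict[int, NormalizedOtuTable],
    groups: dict[int, pd.Series],
    group: str,
    control: str,
    thresholds: Thresholds = Thresholds(),
    log2_offset: float = 1.0,
) -> pd.DataFrame:
    """Differential-abundance meta-analysis of normalized OTU tables.

    log2(abundance + offset) per experiment feeds the same moderated-fit /
    Fisher / FDR machinery used for phenotypes, with the phenotype
    significance profile.  Only OTUs surviving the abundance filter in both
    experiments are tested.
    """
    exps = sorted(normalized)
    if len(exps) != 2:
        raise ValueError("differential_otus expects exactly two experiments")
    fits = {}
    for e in exps:
        table = normalized[e].abundances
        log2_abund = np.log2(table + log2_offset).T  # samples x OTUs
        fits[e] = fit_moderated(log2_abund, groups[e], group, control).to_frame()
    return call_differential(fits[exps[0]], fits[exps[1]], thresholds)
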