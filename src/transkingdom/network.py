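"""Transkingdom correlation-network reconstruction.

Nodes are host genes, host metabolic parameters and microbial OTUs.
Spearman rank correlations are computed for every admissible pair within
each experiment, across all samples and within each treatment group.  The
two per-experiment p-values are Fisher-combined and a BH FDR is computed
separately within four edge classes: (i) gene-gene, (ii)
metabolic-metabolic, (iii) gene-metabolic, (iv) OTU-phenotype (a phenotype
being a gene or a metabolic parameter).  OTU-OTU pairs are never
correlated.

Retention is a pure conjunction of filters, so order is irrelevant to the
result; every candidate carries a verdict for each filter in the output
ledger.  Edges without a microbial node use an FDR gate of 10%, edges with
one use 1%.  OTU-phenotype edges additionally pass an abundance gate
(>0.5% median relative abundance across experiments in at least one group),
a causality-compliancy check (the correlation sign must match the product
of the endpoints' antibiotic-vs-control fold-change directions in at least
one group of both experiments) and per-group correlation-sign consistency
(within-group correlation signs agree between experiments and across
groups).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import SIGN_EPS, Thresholds, bh_fdr, fisher_combine

__all__ = [
    "EDGE_CLASSES",
    "spearman",
    "spearman_matrix",
    "classify_edge",
    "combine_edges",
    "retain_edges",
    "abundance_gate",
    "per_group_abundance",
    "causality_compliance",
    "per_group_sign_consistency",
    "build_network",
]

EDGE_CLASSES = ("gene-gene", "metabolic-metabolic", "gene-metabolic", "otu-phenotype")

#: exact permutation p-value below this sample size, t-approximation above
EXACT_P_MAX_N = 8


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, axis=-1)


def _standardize_rows(r: np.ndarray) -> np.ndarray:
    """Center and unit-normalize rank rows; zero-variance rows become NaN."""
    r = r - r.mean(axis=-1, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, r / norm, np.nan)


def spearman(x, y, exact_max_n: int = EXACT_P_MAX_N) -> tuple[float, float]:
    """Spearman rank correlation with a small-sample exact p-value.

    rho is the Pearson correlation of mid-ranks (average ranks for ties).
    The two-sided p-value is exact — obtained by enumerating all n!
    pairings of the observed rank vectors — when n <= ``exact_max_n``;
    otherwise the t-approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df
    is used.  Zero variance in either vector yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("spearman needs paired vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("spearman requires finite values")
    zx = _standardize_rows(_midranks(x))
    zy = _standardize_rows(_midranks(y))
    if np.any(np.isnan(zx)) or np.any(np.isnan(zy)):
        return float("nan"), float("nan")
    rho = float(zx @ zy)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        null = zx[perms] @ zy
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = _t_approx_p(np.array(rho), n)
    return rho, float(p)


def _t_approx_p(rho, n: int):
    rho_c = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c**2))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(rho_c) >= 1.0, 0.0, p)


def spearman_matrix(
    a: pd.DataFrame, b: pd.DataFrame, exact: bool | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman between rows of ``a`` and rows of ``b``.

    Both frames are features x samples over identical sample columns.
    Returns (rho, p) frames indexed by a-features with b-features as
    columns.  ``exact=None`` chooses the exact enumeration automatically
    for n <= EXACT_P_MAX_N.  Pairs involving a zero-variance feature get
    NaN in both outputs.
    """
    if list(a.columns) != list(b.columns):
        raise ValueError("sample columns must match")
    n = a.shape[1]
    za = _standardize_rows(_midranks(a.to_numpy(dtype=float)))
    zb = _standardize_rows(_midranks(b.to_numpy(dtype=float)))
    rho = za @ zb.T
    if exact is None:
        exact = n <= EXACT_P_MAX_N
    if exact:
        if n > EXACT_P_MAX_N:
            raise ValueError(f"exact enumeration limited to n <= {EXACT_P_MAX_N}")
        perms = np.array(list(itertools.permutations(range(n))))
        p = np.empty_like(rho)
        for i in range(za.shape[0]):
            if np.any(np.isnan(za[i])):
                p[i] = np.nan
                continue
            null = za[i][perms] @ zb.T  # (n!, n_b)
            p[i] = np.mean(np.abs(null) >= np.abs(rho[i]) - 1e-12, axis=0)
    else:
        p = _t_approx_p(rho, n)
    p = np.where(np.isnan(rho), np.nan, p)
    return (
        pd.DataFrame(rho, index=a.index, columns=b.index),
        pd.DataFrame(p, index=a.index, columns=b.index),
    )


def classify_edge(kind_a: str, kind_b: str) -> str | None:
    """Map endpoint kinds to one of the four edge classes; OTU-OTU -> None."""
    kinds = frozenset((kind_a, kind_b)) if kind_a != kind_b else frozenset((kind_a,))
    table = {
        frozenset(("gene",)): "gene-gene",
        frozenset(("metabolic",)): "metabolic-metabolic",
        frozenset(("gene", "metabolic")): "gene-metabolic",
        frozenset(("otu", "gene")): "otu-phenotype",
        frozenset(("otu", "metabolic")): "otu-phenotype",
        frozenset(("otu",)): None,
    }
    try:
        return table[kinds]
    except KeyError:
        raise ValueError(f"unknown node kinds: {kind_a!r}, {kind_b!r}") from None


def combine_edges(candidates: pd.DataFrame) -> pd.DataFrame:
    """Fisher-combined p and class-specific BH FDR for edge candidates.

    ``candidates`` must carry columns ``edge_class``, ``rho_1``, ``p_1``,
    ``rho_2``, ``p_2`` (per-experiment all-sample statistics).  Pairs with
    an undefined correlation in either experiment are dropped with a
    record.  q-values are computed independently within each edge class.
    """
    defined = candidates[["rho_1", "rho_2", "p_1", "p_2"]].notna().all(axis=1)
    if (~defined).any():
        warnings.warn(
            f"{int((~defined).sum())} pair(s) with undefined correlation dropped"
        )
    out = candidates.loc[defined].copy()
    tiny = np.finfo(float).tiny
    p12 = out[["p_1", "p_2"]].to_numpy().clip(tiny, 1.0)
    x2 = -2.0 * np.log(p12).sum(axis=1)
    out["p_combined"] = np.clip(sps.chi2.sf(x2, 4), tiny, 1.0)
    out["q"] = np.nan
    for cls, idx in out.groupby("edge_class").groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p_combined"].to_numpy())
    return out


def retain_edges(candidates: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Apply the all-sample retention conjunction, recording each verdict.

    Adds boolean columns ``ok_sign``, ``ok_p_individual``, ``ok_p_combined``,
    ``ok_fdr`` and their conjunction ``retained``.  The FDR gate is
    ``thresholds.fdr`` for phenotype-only classes and
    ``thresholds.fdr_microbial`` for the OTU-phenotype class.
    """
    out = candidates.copy()
    s1 = np.where(np.abs(out["rho_1"]) < SIGN_EPS, 0, np.sign(out["rho_1"]))
    s2 = np.where(np.abs(out["rho_2"]) < SIGN_EPS, 0, np.sign(out["rho_2"]))
    out["ok_sign"] = (s1 == s2) & (s1 != 0)
    out["ok_p_individual"] = (out["p_1"] < thresholds.p_individual) & (
        out["p_2"] < thresholds.p_individual
    )
    out["ok_p_combined"] = out["p_combined"] < thresholds.p_combined
    fdr_gate = np.where(
        out["edge_class"] == "otu-phenotype", thresholds.fdr_microbial, thresholds.fdr
    )
    out["ok_fdr"] = out["q"] < fdr_gate
    out["retained"] = (
        out["ok_sign"] & out["ok_p_individual"] & out["ok_p_combined"] & out["ok_fdr"]
    )
    return out


def per_group_abundance(
    counts: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-group median relative abundance (OTUs x groups) in one experiment."""
    rel = counts / counts.sum(axis=0)
    out = {}
    for g, samples in groups.groupby(groups).groups.items():
        cols = [s for s in samples if s in rel.columns]
        out[g] = rel[cols].median(axis=1)
    return pd.DataFrame(out)


def abundance_gate(
    otu: str,
    per_group_abund: dict[int, pd.DataFrame],
    threshold: float = 0.005,
) -> tuple[bool, pd.Series]:
    """Gate OTUs on >0.5% median relative abundance in at least one group.

    ``per_group_abund`` maps experiment id -> OTUs x groups frame of
    per-group median relative abundances.  For each group the median across
    the two experiments is taken; the gate passes iff any group's value
    strictly exceeds the threshold.  Returns (verdict, per-group medians).
    """
    exps = sorted(per_group_abund)
    frames = []
    for e in exps:
        tbl = per_group_abund[e]
        frames.append(tbl.loc[otu] if otu in tbl.index else None)
    if any(f is None for f in frames):
        return False, pd.Series(dtype=float)
    cross = pd.concat(frames, axis=1).median(axis=1)
    return bool((cross > threshold).any()), cross


def causality_compliance(
    edge_sign: float,
    fc_a: dict[int, pd.Series],
    fc_b: dict[int, pd.Series],
) -> tuple[bool, list[str]]:
    """Check the fold-change relationship implied by the correlation sign.

    ``fc_a``/``fc_b`` map experiment id -> per-group log2 fold change
    (treated vs control) of the two endpoints.  In group g and experiment e
    the edge is compliant iff sign(FC_a) * sign(FC_b) equals the edge's
    correlation sign, with both fold changes nonzero.  The edge passes if
    some group is compliant in both experiments.  Returns
    (verdict, supporting groups).
    """
    if edge_sign == 0 or not np.isfinite(edge_sign):
        return False, []
    exps = sorted(fc_a)
    supporting = []
    groups = set.intersection(*(set(fc_a[e].index) for e in exps)) & set.intersection(
        *(set(fc_b[e].index) for e in exps)
    )
    for g in sorted(groups):
        ok = True
        for e in exps:
            a, b = fc_a[e].get(g, np.nan), fc_b[e].get(g, np.nan)
            if not (np.isfinite(a) and np.isfinite(b)):
                ok = False
                break
            sa = 0 if abs(a) < SIGN_EPS else math.copysign(1, a)
            sb = 0 if abs(b) < SIGN_EPS else math.copysign(1, b)
            if sa == 0 or sb == 0 or sa * sb != math.copysign(1, edge_sign):
                ok = False
                break
        if ok:
            supporting.append(str(g))
    return bool(supporting), supporting


def per_group_sign_consistency(
    rho_by_group: dict[int, pd.Series],
) -> tuple[bool, list[str]]:
    """Per-group correlation signs must agree between experiments and across groups.

    ``rho_by_group`` maps experiment id -> per-group Spearman rho.  Groups
    with an undefined rho (zero within-group variance) in either experiment
    are skipped and recorded.  The check passes iff every remaining group
    has the same sign in both experiments and all those signs are
    identical; with no usable group it fails.  Returns
    (verdict, skipped groups).
    """
    exps = sorted(rho_by_group)
    groups = sorted(set.intersection(*(set(rho_by_group[e].index) for e in exps)))
    skipped, signs = [], []
    for g in groups:
        vals = [rho_by_group[e].get(g, np.nan) for e in exps]
        if any(not np.isfinite(v) for v in vals):
            skipped.append(str(g))
            continue
        s = [0 if abs(v) < SIGN_EPS else math.copysign(1, v) for v in vals]
        if len(set(s)) != 1:
            return False, skipped
        signs.append(s[0])
    if not signs:
        return False, skipped
    return len(set(signs)) == 1 and signs[0] != 0, skipped


@dataclass
class TranskingdomNetwork:
    """Final network plus the full candidate-edge audit ledger."""

    graph: nx.Graph
    ledger: pd.DataFrame


def build_network(
    phenotype_edges: pd.DataFrame,
    otu_edges: pd.DataFrame,
    node_attrs: dict[str, dict] | None = None,
    visualization_rule: str = "either_endpoint",
) -> TranskingdomNetwork:
    """Assemble the transkingdom network and flag visualization phenotype edges.

    ``phenotype_edges`` and ``otu_edges`` are ledgers with columns
    ``node_a``, ``node_b``, ``rho_median`` (cross-experiment median
    all-sample rho) and ``retained`` (all filters applied for OTU edges).
    A retained phenotype edge is flagged ``visualization=True`` when its
    |rho_median| exceeds the minimum |rho_median| among retained
    OTU-phenotype edges incident to either endpoint
    (``visualization_rule='either_endpoint'``) or to both endpoints
    (``'both_endpoints'``); with no incident OTU edge the flag is False.
    """
    if visualization_rule not in ("either_endpoint", "both_endpoints"):
        raise ValueError(f"unknown visualization rule {visualization_rule!r}")
    g = nx.Graph()
    kept_otu = otu_edges[otu_edges["retained"]]
    incident: dict[str, list[float]] = {}
    for _, row in kept_otu.iterrows():
        phen = row["node_b"] if row.get("kind_b") != "otu" else row["node_a"]
        incident.setdefault(str(phen), []).append(abs(row["rho_median"]))
    kept_phen = phenotype_edges[phenotype_edges["retained"]]
    for _, row in kept_phen.iterrows():
        a, b = str(row["node_a"]), str(row["node_b"])
        if visualization_rule == "either_endpoint":
            pool = incident.get(a, []) + incident.get(b, [])
            viz = bool(pool) and abs(row["rho_median"]) > min(pool)
        else:
            viz = bool(incident.get(a)) and bool(incident.get(b)) and abs(
                row["rho_median"]
            ) > min(min(incident[a]), min(incident[b]))
        g.add_edge(
            a, b,
            sign=int(np.sign(row["rho_median"])),
            rho_1=float(row["rho_1"]), rho_2=float(row["rho_2"]),
            q=float(row["q"]), edge_class=row["edge_class"],
            visualization_only=bool(viz),
        )
    for _, row in kept_otu.iterrows():
        g.add_edge(
            str(row["node_a"]), str(row["node_b"]),
            sign=int(np.sign(row["rho_median"])),
            rho_1=float(row["rho_1"]), rho_2=float(row["rho_2"]),
            q=float(row["q"]), edge_class="otu-phenotype",
            visualization_only=False,
        )
    for node, attrs in (node_attrs or {}).items():
        if node in g:
            g.nodes[node].update(attrs)
    ledger = pd.concat([phenotype_edges, otu_edges], ignore_index=True)
    return TranskingdomNetwork(graph=g, ledger=ledger)
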