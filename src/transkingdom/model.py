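"""The end-to-end model: two-experiment study in, fitted results out.

``TranskingdomModel`` wraps a two-experiment dataset (phenotype matrices,
OTU count tables, sample metadata) and a :class:`~transkingdom.io.PipelineConfig`.
``fit()`` executes the full procedure:

1. phenotype differential testing — Grubbs outlier removal per group and
   experiment, log2 transform, per-experiment moderated fits, Fisher
   meta-analysis with the composite significance criterion, one comparison
   per treated group;
2. microbiome preparation — 99% cumulative-abundance filter, CSS +
   quantile normalization, rarefaction, Shannon diversity with its
   stricter meta-test, differential OTU meta-analysis;
3. network inference — all-sample and per-group Spearman correlations,
   class-specific FDR, edge retention, abundance gate, causality
   compliancy, per-group sign consistency;
4. edge ranking and topology.

The returned :class:`TranskingdomResults` carries every intermediate table
and a ``summary()``.
"""

from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tkio
from . import network as net
from . import prep, topology
from .stats import (
    call_differential,
    fit_moderated,
    grubbs_remove_outlier,
    log2_transform,
)

__all__ = ["TranskingdomModel", "TranskingdomResults"]


@dataclass
class TranskingdomResults:
    """Everything the fitted pipeline produced."""

    config: tkio.PipelineConfig
    control: str
    comparisons: list[str]
    phenotype_differential: pd.DataFrame  # indexed (comparison, feature)
    otu_differential: pd.DataFrame
    diversity: pd.DataFrame
    shannon: dict[int, pd.Series]
    normalized: dict[int, prep.NormalizedOtuTable]
    edge_ledger: pd.DataFrame
    network: "net.TranskingdomNetwork"
    ranked_edges: pd.DataFrame
    topology: pd.DataFrame
    outliers_removed: pd.DataFrame
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def graph(self):
        return self.network.graph

    def summary(self) -> str:
        """Human-readable run summary."""
        lines = ["Transkingdom network meta-analysis", "=" * 36]
        pd_sig = self.phenotype_differential.groupby("comparison")["significant"].sum()
        od_sig = self.otu_differential.groupby("comparison")["significant"].sum()
        lines.append(f"control group: {self.control}")
        lines.append("differential phenotypes per comparison (vs control):")
        for c in self.comparisons:
            lines.append(f"  {c:<14} {int(pd_sig.get(c, 0))}")
        lines.append("differential OTUs per comparison (vs control):")
        for c in self.comparisons:
            lines.append(f"  {c:<14} {int(od_sig.get(c, 0))}")
        sig_div = self.diversity[self.diversity["significant"]].index.tolist() if len(self.diversity) else []
        lines.append(f"Shannon diversity shifts (strict meta-test): {sig_div or 'none'}")
        led = self.edge_ledger
        lines.append(f"edge candidates: {len(led)}")
        for cls, sub in led.groupby("edge_class"):
            lines.append(
                f"  {cls:<22} {len(sub):>5} candidates, {int(sub['retained'].sum()):>3} retained"
            )
        g = self.graph
        lines.append(f"network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
        if len(self.ranked_edges):
            lines.append("top ranked microbe-phenotype edges (S = max abundance x |median rho|):")
            for _, r in self.ranked_edges.head(5).iterrows():
                lines.append(
                    f"  {r['rank']:>2}. {r['otu']} -- {r['phenotype']}: S={r['score']:.4f} "
                    f"(a_max={r['max_abundance']:.4f}, median rho={r['median_correlation']:+.2f})"
                )
        if len(self.topology):
            top = self.topology.sort_values(["degree", "betweenness"], ascending=False).head(5)
            lines.append("highest-degree nodes (figure network):")
            for n, r in top.iterrows():
                lines.append(
                    f"  {n}: degree={int(r['degree'])}, BC={r['betweenness']:.3f}"
                )
        return "\n".join(lines)

    def save(self, directory) -> list[Path]:
        """Write all result tables, the network files and the manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []

        def _tsv(frame: pd.DataFrame, name: str, index=True):
            path = directory / name
            frame.to_csv(path, sep="\t", index=index, float_format="%.10g")
            written.append(path)

        _tsv(self.phenotype_differential, "differential_phenotypes.tsv")
        _tsv(self.otu_differential, "differential_otus.tsv")
        _tsv(self.diversity, "diversity_meta_test.tsv")
        for e, h in self.shannon.items():
            _tsv(h.rename("shannon_bits").to_frame(), f"shannon_exp{e}.tsv")
        for e, norm in self.normalized.items():
            _tsv(norm.abundances, f"normalized_otus_exp{e}.tsv")
        _tsv(self.edge_ledger, "edge_ledger.tsv", index=False)
        _tsv(self.ranked_edges, "ranked_edges.tsv", index=False)
        _tsv(self.topology, "topology.tsv")
        written += tkio.write_network(self.graph, directory)
        (directory / "summary.txt").write_text(self.summary() + "\n")
        written.append(directory / "summary.txt")
        return written


class TranskingdomModel:
    """Two-experiment transkingdom meta-analysis model.

    Parameters
    ----------
    phenotypes
        experiment id -> samples x phenotypes frame (positive values).
    otu_counts
        experiment id -> OTUs x samples frame (non-negative integers).
    metadata
        frame with columns ``sample``, ``experiment``, ``group``.
    config
        pipeline configuration; defaults to :class:`PipelineConfig`.
    control
        label of the control group (default ``"control"``).
    """

    def __init__(
        self,
        phenotypes: dict[int, pd.DataFrame],
        otu_counts: dict[int, pd.DataFrame],
        metadata: pd.DataFrame,
        config: tkio.PipelineConfig | None = None,
        control: str = "control",
    ):
        if sorted(phenotypes) != sorted(otu_counts) or len(phenotypes) != 2:
            raise ValueError("expected the same two experiment ids in both inputs")
        self.config = config or tkio.PipelineConfig()
        self.control = control
        self.experiments = sorted(phenotypes)
        self.phenotypes = phenotypes
        self.otu_counts = otu_counts
        self.metadata = metadata
        self.groups: dict[int, pd.Series] = {}
        for e in self.experiments:
            sub = metadata[metadata["experiment"] == e]
            g = pd.Series(sub["group"].to_numpy(), index=sub["sample"])
            missing = [s for s in phenotypes[e].index if s not in g.index]
            if missing:
                raise ValueError(f"samples without metadata in experiment {e}: {missing[:5]}")
            self.groups[e] = g.reindex(phenotypes[e].index)
            if self.groups[e].isna().any():
                raise ValueError(f"missing group labels in experiment {e}")
        all_groups = set(self.metadata["group"])
        if control not in all_groups:
            raise ValueError(f"control group {control!r} absent from metadata")
        self.comparisons = sorted(all_groups - {control})
        met = set(self.config.metabolic_phenotypes)
        self.kinds = {
            p: ("metabolic" if p in met else "gene")
            for p in phenotypes[self.experiments[0]].columns
        }

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_study(cls, study, config=None, **kw) -> "TranskingdomModel":
        """Build from a :class:`~transkingdom.synthetic.SyntheticStudy`."""
        return cls(
            phenotypes=study.phenotypes,
            otu_counts=study.otu_counts,
            metadata=study.metadata,
            config=config,
            control=study.design.control,
            **kw,
        )

    @classmethod
    def from_directory(cls, directory, config=None, control="control") -> "TranskingdomModel":
        """Build from the on-disk layout written by the simulator / writers."""
        directory = Path(directory)
        meta = tkio.read_metadata(directory / "metadata.tsv")
        phen, counts = {}, {}
        for e in sorted(meta["experiment"].unique()):
            e = int(e)
            table, _tax = tkio.read_otu_table(directory / f"otu_counts_exp{e}.tsv")
            counts[e] = table
            per_exp, _ = tkio.read_phenotypes(
                directory / f"phenotypes_exp{e}.csv", directory / "metadata.tsv"
            )
            phen[e] = per_exp[e]
        return cls(phen, counts, meta, config=config, control=control)

    # -- pipeline stages ----------------------------------------------------

    def _grubbs_log2(self):
        """Outlier removal on the original scale, then log2 (NaN marks removals)."""
        alpha = self.config.grubbs_alpha
        log2_tables, removed = {}, []
        for e in self.experiments:
            data = self.phenotypes[e].copy()
            groups = self.groups[e]
            for feature in data.columns:
                for g, samples in groups.groupby(groups).groups.items():
                    vals = data.loc[samples, feature]
                    _, idx = grubbs_remove_outlier(vals.to_numpy(), alpha)
                    if idx is not None:
                        sample = vals.index[idx]
                        removed.append(
                            {"experiment": e, "feature": feature, "group": g,
                             "sample": sample, "value": float(vals.iloc[idx])}
                        )
                        data.loc[sample, feature] = np.nan
            log2_tables[e] = log2_transform(data, allow_nan=True)
        cols = ["experiment", "feature", "group", "sample", "value"]
        return log2_tables, pd.DataFrame(removed, columns=cols)

    def _differential(self, log2_tables: dict[int, pd.DataFrame], thresholds) -> pd.DataFrame:
        frames = []
        e1, e2 = self.experiments
        for comp in self.comparisons:
            fits = {
                e: fit_moderated(log2_tables[e], self.groups[e], comp, self.control).to_frame()
                for e in self.experiments
            }
            res = call_differential(fits[e1], fits[e2], thresholds)
            res.insert(0, "comparison", comp)
            frames.append(res)
        out = pd.concat(frames)
        out.index.name = "feature"
        return out.set_index("comparison", append=True).swaplevel()

    def _prepare_otus(self):
        cfg = self.config
        normalized = {}
        for e in self.experiments:
            filtered, provenance = prep.cumulative_abundance_filter(
                self.otu_counts[e], cfg.cumulative_abundance
            )
            css = prep.css_normalize(filtered, cfg.css_percentile, cfg.css_scale)
            qn = prep.quantile_normalize(css)
            normalized[e] = prep.NormalizedOtuTable(
                abundances=qn,
                provenance=provenance,
                css_percentile=cfg.css_percentile,
                css_scale=cfg.css_scale,
            )
        return normalized

    def _diversity(self, filtered_counts: dict[int, pd.DataFrame], rng) -> tuple[pd.DataFrame, dict]:
        cfg = self.config
        shannon = {}
        for e in self.experiments:
            rarefied, dropped = prep.rarefy(
                filtered_counts[e], cfg.rarefaction_depth, seed=rng.integers(2**31)
            )
            if dropped:
                warnings.warn(
                    f"experiment {e}: {len(dropped)} sample(s) below rarefaction depth dropped"
                )
            shannon[e] = pd.Series(
                {s: prep.shannon_index(rarefied[s]) for s in rarefied.columns},
                name="shannon",
            )
        groups = {e: self.groups[e] for e in self.experiments}
        verdicts = prep.diversity_meta_test(
            shannon, groups, self.control,
            thresholds=cfg.diversity_thresholds(),
            n_perm=cfg.n_perm, seed=rng.integers(2**31),
        )
        return verdicts, shannon

    # -- correlation network ------------------------------------------------

    def _node_fold_changes(self, log2_phen, log2_otu):
        """Per-group median log2 fold change (vs control) per node and experiment."""
        fc: dict[int, pd.DataFrame] = {}
        for e in self.experiments:
            tables = pd.concat([log2_phen[e], log2_otu[e]], axis=1)
            groups = self.groups[e]
            med = tables.groupby(groups).median()
            out = med.subtract(med.loc[self.control], axis=1)
            fc[e] = out.drop(index=self.control).T  # nodes x groups
        return fc

    def _correlations(self, log2_phen, log2_otu, otus):
        """All-sample candidate ledger and per-group rho/p for OTU-phenotype pairs."""
        phen_names = list(self.phenotypes[self.experiments[0]].columns)
        rho_all, p_all = {}, {}
        for e in self.experiments:
            phen_t = log2_phen[e].T  # features x samples
            otu_t = log2_otu[e].T
            both = pd.concat([phen_t, otu_t])
            rho, p = net.spearman_matrix(both, both, exact=False)
            rho_all[e], p_all[e] = rho, p

        rows = []
        kinds = dict(self.kinds)
        kinds.update({o: "otu" for o in otus})
        pairs = list(itertools.combinations(phen_names, 2)) + [
            (o, ph) for o in otus for ph in phen_names
        ]
        e1, e2 = self.experiments
        for a, b in pairs:
            cls = net.classify_edge(kinds[a], kinds[b])
            if cls is None:
                continue
            rows.append(
                {
                    "node_a": a, "node_b": b,
                    "kind_a": kinds[a], "kind_b": kinds[b],
                    "edge_class": cls,
                    "rho_1": rho_all[e1].at[a, b], "p_1": p_all[e1].at[a, b],
                    "rho_2": rho_all[e2].at[a, b], "p_2": p_all[e2].at[a, b],
                }
            )
        return pd.DataFrame(rows)

    def _per_group_correlations(self, log2_phen, log2_otu, otus):
        """Per-(experiment, group) Spearman rho/p between OTUs and phenotypes."""
        out = {}
        for e in self.experiments:
            groups = self.groups[e]
            for g in sorted(groups.unique()):
                samples = groups.index[groups == g]
                if len(samples) < 3:
                    out[(e, g)] = None
                    continue
                otu_t = log2_otu[e].loc[samples].T
                phen_t = log2_phen[e].loc[samples].T
                rho, p = net.spearman_matrix(otu_t, phen_t)
                out[(e, g)] = (rho, p)
        return out

    # -- fit ----------------------------------------------------------------

    def fit(self, seed: int | None = None) -> TranskingdomResults:
        """Run the full pipeline; ``seed`` overrides the config seed."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        timings: dict[str, float] = {}
        t0 = time.perf_counter()

        # 1. phenotype differential meta-analysis
        log2_phen_outlier, outliers = self._grubbs_log2()
        phen_diff = self._differential(log2_phen_outlier, cfg.thresholds())
        timings["phenotypes"] = time.perf_counter() - t0

        # 2. microbiome preparation, diversity, differential OTUs
        t0 = time.perf_counter()
        normalized = self._prepare_otus()
        filtered_counts = {
            e: self.otu_counts[e].loc[normalized[e].abundances.index]
            for e in self.experiments
        }
        diversity, shannon = self._diversity(filtered_counts, rng)
        e1, e2 = self.experiments
        otus = [
            o for o in normalized[e1].abundances.index
            if o in set(normalized[e2].abundances.index)
        ]
        excluded = set(normalized[e1].abundances.index) ^ set(normalized[e2].abundances.index)
        if excluded:
            warnings.warn(
                f"{len(excluded)} OTU(s) present in only one experiment's filtered set excluded"
            )
        otu_frames = []
        for comp in self.comparisons:
            res = prep.differential_otus(
                normalized, self.groups, comp, self.control,
                thresholds=cfg.thresholds(), log2_offset=cfg.log2_offset,
            )
            res = res.loc[[o for o in res.index if o in set(otus)]]
            res.insert(0, "comparison", comp)
            otu_frames.append(res)
        otu_diff = pd.concat(otu_frames)
        otu_diff.index.name = "feature"
        otu_diff = otu_diff.set_index("comparison", append=True).swaplevel()
        timings["microbiome"] = time.perf_counter() - t0

        # 3. network inference
        t0 = time.perf_counter()
        log2_phen = {e: log2_transform(self.phenotypes[e]) for e in self.experiments}
        log2_otu = {
            e: np.log2(normalized[e].abundances.loc[otus] + cfg.log2_offset).T
            for e in self.experiments
        }
        candidates = self._correlations(log2_phen, log2_otu, otus)
        candidates = net.combine_edges(candidates)
        candidates["rho_median"] = candidates[["rho_1", "rho_2"]].median(axis=1)
        candidates = net.retain_edges(candidates, cfg.thresholds())

        is_otu_edge = candidates["edge_class"] == "otu-phenotype"
        phen_edges = candidates[~is_otu_edge].copy()
        otu_edges = candidates[is_otu_edge].copy()

        # per-group statistics feed the microbial filters and the ranking
        pg = self._per_group_correlations(log2_phen, log2_otu, otus)
        group_names = sorted(self.metadata["group"].unique())
        fc = self._node_fold_changes(log2_phen, log2_otu)
        gate_abund = {
            e: net.per_group_abundance(normalized[e].abundances, self.groups[e])
            for e in self.experiments
        }
        rank_counts = filtered_counts if cfg.ranking_abundance == "relative" else {
            e: normalized[e].abundances for e in self.experiments
        }
        rank_abund = {
            e: net.per_group_abundance(rank_counts[e], self.groups[e])
            for e in self.experiments
        }

        # vectorized filter evaluation (the scalar operations abundance_gate,
        # causality_compliance and per_group_sign_consistency define the
        # semantics; agreement is covered by tests)
        eps = 1e-9
        otu_list = otu_edges["node_a"].to_numpy()
        phen_list = otu_edges["node_b"].to_numpy()

        # abundance gate: cross-experiment median (of two = mean) of the
        # per-experiment per-group median relative abundance
        gate_cross = (
            gate_abund[e1].reindex(index=otus, columns=group_names)
            + gate_abund[e2].reindex(index=otus, columns=group_names)
        ) / 2.0
        gate_pass = (gate_cross > cfg.abundance_gate).any(axis=1)
        otu_edges["ok_abundance"] = gate_pass.reindex(otu_list).to_numpy()

        # per-group rho tensor: (experiment, group, edge)
        n_edges = len(otu_edges)
        rho_pg = np.full((2, len(group_names), n_edges), np.nan)
        for ei, e in enumerate(self.experiments):
            for gi, g in enumerate(group_names):
                entry = pg.get((e, g))
                if entry is None:
                    continue
                rho_frame = entry[0]
                oi = rho_frame.index.get_indexer(otu_list)
                pi = rho_frame.columns.get_indexer(phen_list)
                rho_pg[ei, gi] = rho_frame.to_numpy()[oi, pi]
        signs = np.where(np.isnan(rho_pg), np.nan, np.where(np.abs(rho_pg) < eps, 0.0, np.sign(rho_pg)))
        usable = np.isfinite(signs).all(axis=0)  # (group, edge)
        agree = np.where(usable, signs[0] == signs[1], True)
        ref = np.where(usable, signs[0], np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ref_max = np.nanmax(np.where(usable, ref, -np.inf), axis=0)
            ref_min = np.nanmin(np.where(usable, ref, np.inf), axis=0)
        any_usable = usable.any(axis=0)
        otu_edges["ok_group_sign"] = (
            any_usable & agree.all(axis=0) & (ref_max == ref_min) & (ref_max != 0)
        )

        # causality compliancy: correlation sign must equal the product of the
        # endpoint fold-change directions in some group, in both experiments
        edge_sign = np.sign(otu_edges["rho_median"].to_numpy())
        fc_groups = self.comparisons  # fold changes are treated-vs-control
        fc_o = np.stack(
            [fc[e].loc[otu_list, fc_groups].to_numpy() for e in self.experiments]
        )  # (exp, edge, group)
        fc_p = np.stack(
            [fc[e].loc[phen_list, fc_groups].to_numpy() for e in self.experiments]
        )
        so = np.where(np.abs(fc_o) < eps, 0.0, np.sign(fc_o))
        sp = np.where(np.abs(fc_p) < eps, 0.0, np.sign(fc_p))
        compliant = (
            (so != 0) & (sp != 0) & (so * sp == edge_sign[None, :, None])
            & np.isfinite(fc_o) & np.isfinite(fc_p)
        )
        otu_edges["ok_causality"] = compliant.all(axis=0).any(axis=1) & (edge_sign != 0)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rho_pg_median = np.nanmean(rho_pg, axis=0)  # median of two experiments
        for gi, g in enumerate(group_names):
            otu_edges[f"rho_{g}"] = rho_pg_median[gi]
        otu_edges["retained"] = (
            otu_edges["retained"]
            & otu_edges["ok_abundance"]
            & otu_edges["ok_causality"]
            & otu_edges["ok_group_sign"]
        )

        node_attrs = {}
        for node in list(log2_phen[e1].columns) + otus:
            kind = self.kinds.get(node, "otu")
            tissue = "none"
            if isinstance(node, str) and node.startswith("liver_"):
                tissue = "liver"
            elif isinstance(node, str) and node.startswith("ileum_"):
                tissue = "ileum"
            med_fc = float(
                np.median(np.concatenate([fc[e].loc[node].to_numpy() for e in self.experiments]))
            )
            node_attrs[node] = {"kind": kind, "tissue": tissue, "median_fc": med_fc}

        network = net.build_network(
            phen_edges, otu_edges, node_attrs, cfg.visualization_rule
        )
        timings["network"] = time.perf_counter() - t0

        # 4. ranking and topology
        t0 = time.perf_counter()
        kept = otu_edges[otu_edges["retained"]]
        rank_input = pd.DataFrame(
            {"otu": kept["node_a"].to_numpy(), "phenotype": kept["node_b"].to_numpy()}
        )
        abundance = {}
        for otu in rank_input["otu"].unique():
            per_exp = pd.concat([rank_abund[e].loc[otu] for e in self.experiments], axis=1)
            abundance[str(otu)] = per_exp.median(axis=1)
        correlation = {
            (str(r["node_a"]), str(r["node_b"])): pd.Series(
                {g: r[f"rho_{g}"] for g in group_names}
            )
            for _, r in kept.iterrows()
        }
        ranked = topology.rank_edges(rank_input, abundance, correlation)
        topo = topology.topology_report(network.graph, cfg.topology_mode)
        timings["ranking_topology"] = time.perf_counter() - t0

        return TranskingdomResults(
            config=cfg,
            control=self.control,
            comparisons=self.comparisons,
            phenotype_differential=phen_diff,
            otu_differential=otu_diff,
            diversity=diversity,
            shannon=shannon,
            normalized=normalized,
            edge_ledger=pd.concat([phen_edges, otu_edges], ignore_index=True),
            network=network,
            ranked_edges=ranked,
            topology=topo,
            outliers_removed=outliers,
            timings=timings,
        )
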