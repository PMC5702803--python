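"""File formats, pipeline configuration and run manifests.

Input formats:

* OTU table — TSV, first column OTU id, one integer-count column per
  sample, optional trailing ``taxonomy`` column;
* phenotype matrix — CSV, rows = samples, columns = phenotypes;
* metadata — TSV with columns ``sample``, ``experiment``, ``group``.

Outputs are TSV ledgers plus SIF/GraphML serializations of the network.
Every run directory receives a single YAML manifest recording the config
snapshot, input digests and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .stats import Thresholds

__all__ = [
    "PipelineConfig",
    "read_otu_table",
    "read_metadata",
    "read_phenotypes",
    "write_network",
    "write_manifest",
]


@dataclass
class PipelineConfig:
    """Every numeric knob of the pipeline, serializable to one YAML document."""

    # composite significance criterion (phenotypes, OTU abundances, edges)
    grubbs_alpha: float = 0.05
    p_individual: float = 0.20
    p_combined: float = 0.05
    fdr: float = 0.10
    fdr_microbial: float = 0.01
    # stricter profile for the Shannon diversity meta-test
    diversity_p_individual: float = 0.02
    diversity_p_combined: float = 0.001
    diversity_fdr: float = 0.001
    # OTU table preparation
    cumulative_abundance: float = 0.99
    css_percentile: float = 0.5
    css_scale: float = 1000.0
    rarefaction_depth: int = 200_000
    log2_offset: float = 1.0
    # network filters
    abundance_gate: float = 0.005
    visualization_rule: str = "either_endpoint"
    topology_mode: str = "figure"
    # abundance table used for the ranking score: 'relative' (filtered raw
    # counts) or 'normalized'
    ranking_abundance: str = "relative"
    # phenotype kinds
    metabolic_phenotypes: tuple[str, ...] = (
        "body_weight", "fasting_glucose", "gtt_auc", "fasting_insulin",
    )
    # randomness
    seed: int = 0
    n_perm: int = 10_000

    def thresholds(self) -> Thresholds:
        return Thresholds(
            grubbs_alpha=self.grubbs_alpha,
            p_individual=self.p_individual,
            p_combined=self.p_combined,
            fdr=self.fdr,
            fdr_microbial=self.fdr_microbial,
        )

    def diversity_thresholds(self) -> Thresholds:
        return Thresholds(
            grubbs_alpha=self.grubbs_alpha,
            p_individual=self.diversity_p_individual,
            p_combined=self.diversity_p_combined,
            fdr=self.diversity_fdr,
        )

    def to_yaml(self, path=None) -> str:
        doc = dataclasses.asdict(self)
        doc["metabolic_phenotypes"] = list(self.metabolic_phenotypes)
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "metabolic_phenotypes" in doc:
            doc["metabolic_phenotypes"] = tuple(doc["metabolic_phenotypes"])
        return cls(**doc)


# ---------------------------------------------------------------------------
# readers


def read_otu_table(path):
    """Read an OTU count TSV; returns (counts, taxonomy-or-None)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df["taxonomy"].astype(str)
        df = df.drop(columns=["taxonomy"])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate OTU id {dup!r} in {path}")
    if pd.Index(df.columns).has_duplicates:
        raise ValueError(f"duplicate sample id in {path}")
    if df.isna().any().any():
        raise ValueError(f"missing/ragged values in OTU table {path}")
    arr = df.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere(arr != np.round(arr))[0]
        raise ValueError(
            f"non-integer count at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative count at OTU {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df.astype(np.int64), taxonomy


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample", "experiment", "group"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns {sorted(missing)}")
    if meta["sample"].duplicated().any():
        raise ValueError("duplicate sample in metadata")
    return meta


def read_phenotypes(path, metadata_path, known_groups=None):
    """Read a phenotype CSV and split it per experiment via the metadata.

    Returns ``(per_experiment, metadata)`` where ``per_experiment`` maps
    experiment id -> samples x phenotypes frame restricted to that
    experiment's samples.  Samples missing from the metadata (or vice
    versa) are an error; group labels outside ``known_groups`` (when
    given) are an error.
    """
    data = pd.read_csv(path, index_col=0)
    meta = read_metadata(metadata_path)
    meta_samples = set(meta["sample"])
    data_samples = set(data.index)
    extra = sorted(data_samples - meta_samples)
    if extra:
        raise ValueError(f"samples absent from metadata: {extra[:5]}")
    if known_groups is not None:
        bad = sorted(set(meta["group"]) - set(known_groups))
        if bad:
            raise ValueError(f"group labels absent from configured groups: {bad}")
    if (data <= 0).any().any():
        warnings.warn("nonpositive phenotype values present; log2 will fail on them")
    out = {}
    for e, sub in meta.groupby("experiment"):
        samples = [s for s in sub["sample"] if s in data_samples]
        out[int(e)] = data.loc[samples]
    return out, meta


# ---------------------------------------------------------------------------
# writers


def write_network(graph: nx.Graph, directory, formats=("sif", "graphml", "tsv")) -> list[Path]:
    """Serialize the network as SIF, GraphML and/or an edge-attribute TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if graph.number_of_edges() == 0:
        warnings.warn("writing an empty network")
    written = []
    for fmt in formats:
        if fmt == "sif":
            path = directory / "network.sif"
            lines = [
                f"{u}\t{'pos' if d.get('sign', 0) >= 0 else 'neg'}\t{v}"
                for u, v, d in graph.edges(data=True)
            ]
            path.write_text("\n".join(lines) + ("\n" if lines else ""))
        elif fmt == "graphml":
            path = directory / "network.graphml"
            g = nx.Graph()
            g.add_nodes_from(
                (n, {k: v for k, v in d.items() if v is not None})
                for n, d in graph.nodes(data=True)
            )
            g.add_edges_from((u, v, d) for u, v, d in graph.edges(data=True))
            nx.write_graphml(g, path)
        elif fmt == "tsv":
            path = directory / "network_edges.tsv"
            rows = [
                {"source": u, "target": v, **d} for u, v, d in graph.edges(data=True)
            ]
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        else:
            raise ValueError(f"unknown network format {fmt!r}")
        written.append(path)
    return written


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(directory, config: PipelineConfig, inputs, seed, timings=None) -> Path:
    """Write the run manifest (one per output directory)."""
    from . import __version__

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc = {
        "config": yaml.safe_load(config.to_yaml()),
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
        "seed": int(seed),
        "timings_s": {k: round(float(v), 3) for k, v in (timings or {}).items()},
        "version": __version__,
    }
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path
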