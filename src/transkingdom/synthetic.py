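"""Synthetic two-experiment mouse-study generator with planted structure.

Emulates the data shape of an antibiotic-perturbation study: two independent
experiments, six treatment groups (control plus five antibiotic regimens),
five mice per group, a positive-valued phenotype matrix (metabolic
parameters and qPCR gene expression) and an OTU count table per experiment.
Ground truth — differential phenotypes, differential OTUs and
microbe-phenotype correlations — is planted so every downstream stage has a
recovery test.

Generative law (identical in both experiments, independent draws):

* phenotypes: value = 2^(baseline + group effect + noise), log2-scale
  Gaussian noise;
* OTU counts: per-sample relative composition from
  2^(baseline + group effect + noise), multiplied by a log-uniform library
  size and sampled from a negative binomial (gamma-Poisson) with
  configurable dispersion;
* planted microbe-phenotype correlations: a latent per-mouse Gaussian is
  shared between the OTU's log-abundance and the phenotype's log-value.
  The shared fraction is scaled so that the expected Spearman correlation
  of the *observed* values approximates the target: the target Spearman is
  mapped to a latent Pearson correlation via rho_P = 2 sin(pi rho_S / 6)
  and inflated to offset the attenuation caused by negative-binomial
  counting noise.  Targets that would require a latent correlation above 1
  raise a validation error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import special

__all__ = [
    "GROUPS",
    "StudyDesign",
    "GroundTruth",
    "PlantedEdge",
    "SyntheticStudy",
    "generate_group_fold_changes",
    "generate_study",
    "default_truth",
    "write_study",
]

GROUPS = ("control", "cocktail", "ampicillin", "metronidazole", "neomycin", "vancomycin")

_METABOLIC = ("body_weight", "fasting_glucose", "gtt_auc", "fasting_insulin")
_GENES = ("Fxr", "Shp", "G6pase", "Pck1", "Hk1", "Hk2", "Glut1", "Insr", "Tgr5", "Fgf15")


def phenotype_names(n: int) -> list[str]:
    """Phenotype identifiers: 4 metabolic parameters then liver/ileum genes."""
    canonical = list(_METABOLIC) + [f"liver_{g}" for g in _GENES] + [f"ileum_{g}" for g in _GENES]
    if n <= len(canonical):
        return canonical[:n]
    return canonical + [f"gene_extra_{i}" for i in range(n - len(canonical))]


def phenotype_kinds(names) -> dict[str, str]:
    """Map phenotype name -> 'metabolic' or 'gene' (by the canonical 4)."""
    return {n: ("metabolic" if n in _METABOLIC else "gene") for n in names}


@dataclass(frozen=True)
class StudyDesign:
    """Dimensions and noise model of a synthetic study."""

    groups: tuple[str, ...] = GROUPS
    control: str = "control"
    mice_per_group: int = 5
    n_phenotypes: int = 24
    n_otus: int = 200
    n_experiments: int = 2
    seed: int = 0
    library_size_range: tuple[int, int] = (200_000, 1_000_000)
    nb_dispersion: float = 0.5
    phenotype_noise_sd: float = 0.5  # log2 units
    otu_noise_sd: float = 1.0  # log2 units, ordinary taxa
    planted_otu_noise_sd: float = 4.0  # log2 units, planted-edge taxa
    between_experiment_heterogeneity: float = 0.0  # sd of per-experiment effect jitter

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        if self.control not in self.groups:
            raise ValueError(f"control group {self.control!r} not among groups")
        if self.mice_per_group < 3:
            raise ValueError("mice_per_group must be >= 3")
        if self.n_otus < 1 or self.n_phenotypes < 1:
            raise ValueError("need at least one OTU and one phenotype")
        if self.n_experiments != 2:
            raise ValueError("the design is a two-experiment replication study")
        lo, hi = self.library_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid library size range")

    @property
    def phenotypes(self) -> list[str]:
        return phenotype_names(self.n_phenotypes)

    @property
    def otus(self) -> list[str]:
        return [f"otu_{i:04d}" for i in range(1, self.n_otus + 1)]


@dataclass(frozen=True)
class PlantedEdge:
    otu: str
    phenotype: str
    rho: float  # signed target Spearman correlation, |rho| in (0, 1]


@dataclass
class GroundTruth:
    """Planted effects: feature -> {group -> log2 fold change}; planted edges."""

    differential_phenotypes: dict[str, dict[str, float]] = field(default_factory=dict)
    differential_otus: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_edges: list[PlantedEdge] = field(default_factory=list)

    def validate(self, design: StudyDesign) -> None:
        phens, otus = set(design.phenotypes), set(design.otus)
        for name, effects in self.differential_phenotypes.items():
            if name not in phens:
                raise ValueError(f"unknown phenotype in truth: {name!r}")
            self._check_effects(name, effects, design)
        for name, effects in self.differential_otus.items():
            if name not in otus:
                raise ValueError(f"unknown OTU in truth: {name!r}")
            self._check_effects(name, effects, design)
        for e in self.planted_edges:
            if e.otu not in otus or e.phenotype not in phens:
                raise ValueError(f"planted edge references unknown feature: {e}")
            if not 0 < abs(e.rho) <= 1:
                raise ValueError(f"planted |rho| must be in (0, 1]: {e}")

    @staticmethod
    def _check_effects(name: str, effects: dict[str, float], design: StudyDesign) -> None:
        for g, v in effects.items():
            if g not in design.groups:
                raise ValueError(f"unknown group {g!r} in effects of {name!r}")
            if g == design.control and v != 0:
                raise ValueError(f"control group cannot carry an effect ({name!r})")
            if not math.isfinite(v):
                raise ValueError(f"non-finite effect for {name!r}/{g!r}")


def generate_group_fold_changes(
    magnitude: float,
    affected_groups,
    groups=GROUPS,
    control: str = "control",
) -> dict[str, float]:
    """Per-group log2 effect map: control 0, affected groups +/-magnitude."""
    if not math.isfinite(magnitude):
        raise ValueError("magnitude must be finite")
    affected = set(affected_groups)
    if control in affected:
        raise ValueError("control group cannot be listed as affected")
    unknown = affected - set(groups)
    if unknown:
        raise ValueError(f"unknown affected groups: {sorted(unknown)}")
    return {g: (magnitude if g in affected else 0.0) for g in groups}


@dataclass
class SyntheticStudy:
    design: StudyDesign
    truth: GroundTruth
    phenotypes: dict[int, pd.DataFrame]  # experiment -> samples x phenotypes
    otu_counts: dict[int, pd.DataFrame]  # experiment -> OTUs x samples
    metadata: pd.DataFrame  # sample, experiment, group
    taxonomy: pd.Series  # OTU -> lineage string

    def groups_of(self, experiment: int) -> pd.Series:
        meta = self.metadata[self.metadata["experiment"] == experiment]
        return pd.Series(meta["group"].to_numpy(), index=meta["sample"])

    @property
    def kinds(self) -> dict[str, str]:
        return phenotype_kinds(self.design.phenotypes)


def _effect_matrix(design: StudyDesign, effects: dict[str, dict[str, float]], features) -> np.ndarray:
    """groups x features matrix of log2 effects (0 where unplanted)."""
    out = np.zeros((len(design.groups), len(features)))
    gi = {g: i for i, g in enumerate(design.groups)}
    fi = {f: i for i, f in enumerate(features)}
    for f, per_group in effects.items():
        for g, v in per_group.items():
            out[gi[g], fi[f]] = v
    return out


def generate_study(design: StudyDesign, truth: GroundTruth | None = None) -> SyntheticStudy:
    """Draw a complete two-experiment study from the generative law."""
    truth = truth or GroundTruth()
    truth.validate(design)
    d = design
    ss = np.random.SeedSequence(d.seed)
    base_stream, *exp_streams = ss.spawn(1 + d.n_experiments)
    base_rng = np.random.default_rng(base_stream)

    phens, otus = d.phenotypes, d.otus
    n_p, n_o = len(phens), len(otus)
    # baselines shared across experiments (same biology, replicated study)
    baseline_p = base_rng.uniform(3.0, 10.0, size=n_p)
    logw = base_rng.normal(0.0, 2.0, size=n_o)
    oi = {o: i for i, o in enumerate(otus)}
    pi = {p: i for i, p in enumerate(phens)}
    # planted OTUs sit at ~1% baseline share: abundant enough for low counting
    # noise, mobile enough in the within-sample ranking to transmit their
    # variation through rank-based normalization
    planted_idx = sorted({oi[e.otu] for e in truth.planted_edges})
    if planted_idx:
        others = np.delete(2.0**logw, planted_idx).sum()
        share = 0.01
        w = share / (1.0 - share * len(planted_idx)) * others
        for i in planted_idx:
            logw[i] = math.log2(w) + 0.25 * base_rng.standard_normal()

    # shared-latent loadings compensating NB attenuation of the rank correlation
    rel_ref = 2.0**logw / (2.0**logw).sum()
    l_ref = math.sqrt(d.library_size_range[0] * d.library_size_range[1])
    ln2 = math.log(2.0)
    load_p = np.zeros((n_p, len(truth.planted_edges)))
    load_o = np.zeros((n_o, len(truth.planted_edges)))
    # planted-edge taxa are modelled as high-variability microbes: a strong
    # rank correlation with a host phenotype requires the microbe's biological
    # variation to dominate its counting noise
    sigma_otu = np.full(n_o, d.otu_noise_sd)
    for e in truth.planted_edges:
        sigma_otu[oi[e.otu]] = d.planted_otu_noise_sd
    # non-biological log2 variance of a relative abundance: gamma-Poisson
    # counting noise (log-gamma variance = trigamma(1/dispersion)) plus the
    # compositional denominator's variation (delta method over the baseline
    # composition)
    if d.nb_dispersion > 0:
        var_count = float(special.polygamma(1, 1.0 / d.nb_dispersion))
    else:
        var_count = 0.0
    var_comp_all = float(np.sum(rel_ref**2 * sigma_otu**2))
    for k, e in enumerate(truth.planted_edges):
        rho_pearson = 2.0 * math.sin(math.pi * abs(e.rho) / 6.0)
        i_otu = oi[e.otu]
        mu_ref = rel_ref[i_otu] * l_ref
        # the OTU's own term in the denominator is self-correlated, not noise
        var_comp = var_comp_all - float(rel_ref[i_otu] ** 2 * sigma_otu[i_otu] ** 2)
        sigma_nb2 = (var_count + 1.0 / mu_ref) / ln2**2 + var_comp
        s_o = sigma_otu[i_otu]
        atten = s_o / math.sqrt(s_o**2 + sigma_nb2)
        # rank-transmission loss of the CSS + quantile-normalization chain,
        # estimated once by simulation; keeps the realized downstream
        # Spearman at the stated target
        atten *= 0.97
        c = rho_pearson / atten
        if c > 1.0:
            # compensation saturates: plant the strongest achievable coupling
            warnings.warn(
                f"target |rho|={abs(e.rho)} for ({e.otu}, {e.phenotype}) slightly "
                "exceeds what the counting-noise model can transmit; planting the "
                "maximum achievable coupling"
            )
            c = 1.0
        load_p[pi[e.phenotype], k] = math.sqrt(c)
        load_o[oi[e.otu], k] = math.copysign(math.sqrt(c), e.rho)
    res_p = np.sqrt(np.clip(1.0 - (load_p**2).sum(axis=1), 0.0, None))
    res_o = np.sqrt(np.clip(1.0 - (load_o**2).sum(axis=1), 0.0, None))
    if np.any((load_p**2).sum(axis=1) > 1.0 + 1e-12) or np.any((load_o**2).sum(axis=1) > 1.0 + 1e-12):
        raise ValueError("planted edges over-allocate shared variance on a feature")

    eff_p = _effect_matrix(d, truth.differential_phenotypes, phens)
    eff_o = _effect_matrix(d, truth.differential_otus, otus)

    n_samples = len(d.groups) * d.mice_per_group
    group_idx = np.repeat(np.arange(len(d.groups)), d.mice_per_group)

    phen_tables, count_tables, meta_rows = {}, {}, []
    for e_num, stream in enumerate(exp_streams, start=1):
        rng = np.random.default_rng(stream)
        ep, eo = eff_p, eff_o
        if d.between_experiment_heterogeneity > 0:
            jitter = d.between_experiment_heterogeneity
            ep = eff_p + np.where(eff_p != 0, rng.normal(0, jitter, eff_p.shape), 0.0)
            eo = eff_o + np.where(eff_o != 0, rng.normal(0, jitter, eff_o.shape), 0.0)

        samples = [
            f"exp{e_num}_{d.groups[g]}_m{m + 1}"
            for g in range(len(d.groups))
            for m in range(d.mice_per_group)
        ]
        z = rng.standard_normal((n_samples, len(truth.planted_edges)))

        log2_phen = (
            baseline_p[None, :]
            + ep[group_idx, :]
            + d.phenotype_noise_sd
            * (z @ load_p.T + res_p[None, :] * rng.standard_normal((n_samples, n_p)))
        )
        phen_tables[e_num] = pd.DataFrame(2.0**log2_phen, index=samples, columns=phens)

        log2_abund = (
            logw[None, :]
            + eo[group_idx, :]
            + sigma_otu[None, :]
            * (z @ load_o.T + res_o[None, :] * rng.standard_normal((n_samples, n_o)))
        )
        rel = 2.0**log2_abund
        rel /= rel.sum(axis=1, keepdims=True)
        lo, hi = d.library_size_range
        libsize = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_samples))
        mu = rel * libsize[:, None]
        if d.nb_dispersion > 0:
            r = 1.0 / d.nb_dispersion
            lam = rng.gamma(shape=r, scale=mu / r)
        else:
            lam = mu
        counts = rng.poisson(lam)
        count_tables[e_num] = pd.DataFrame(counts.T, index=otus, columns=samples)
        meta_rows += [
            {"sample": s, "experiment": e_num, "group": d.groups[g]}
            for s, g in zip(samples, group_idx)
        ]

    taxonomy = pd.Series(
        {
            o: f"k__Bacteria; p__Phylum{i % 6}; o__Order{i % 20}; g__Genus{i}"
            for i, o in enumerate(otus)
        },
        name="taxonomy",
    )
    return SyntheticStudy(
        design=d,
        truth=truth,
        phenotypes=phen_tables,
        otu_counts=count_tables,
        metadata=pd.DataFrame(meta_rows),
        taxonomy=taxonomy,
    )


def default_truth(design: StudyDesign, effect_sd_units: float = 1.5) -> GroundTruth:
    """The canonical planted scenario used for recovery experiments.

    Eight phenotypes carry effects of ``effect_sd_units`` noise SDs in the
    strong-perturbation groups (cocktail, ampicillin, vancomycin), ten OTUs
    are differential, and three microbe-phenotype edges of |rho| = 0.9 are
    planted with fold-change directions aligned so the edges are
    causality-compliant (correlation sign equals the product of the
    endpoint effect signs).
    """
    mag = effect_sd_units * design.phenotype_noise_sd
    strong = ("cocktail", "ampicillin", "vancomycin")
    down = lambda m: generate_group_fold_changes(-m, strong, design.groups, design.control)
    up = lambda m: generate_group_fold_changes(m, strong, design.groups, design.control)
    phen_effects = {
        "fasting_glucose": down(mag),
        "gtt_auc": down(mag),
        "fasting_insulin": down(mag),
        "liver_G6pase": down(mag),
        "liver_Pck1": down(mag),
        "liver_Shp": up(mag),
        "ileum_Fgf15": up(mag),
        "ileum_Tgr5": up(mag),
    }
    phen_effects = {k: v for k, v in phen_effects.items() if k in design.phenotypes}
    otu_effects = {}
    for i, otu in enumerate(design.otus[:10]):
        if i < 3:
            # planted-edge endpoints: large perturbation so the fold-change
            # direction is identifiable despite their high variability
            otu_effects[otu] = up(3.0)
        elif i < 6:
            otu_effects[otu] = down(3.0)
        else:
            otu_effects[otu] = generate_group_fold_changes(
                -2.0, ("cocktail",), design.groups, design.control
            )
    edges = [
        PlantedEdge("otu_0001", "fasting_glucose", -0.9),
        PlantedEdge("otu_0002", "gtt_auc", -0.9),
        PlantedEdge("otu_0003", "ileum_Fgf15", +0.9),
    ]
    edges = [
        e for e in edges
        if e.otu in design.otus and e.phenotype in design.phenotypes
    ]
    return GroundTruth(
        differential_phenotypes=phen_effects,
        differential_otus=otu_effects,
        planted_edges=edges,
    )


def write_study(study: SyntheticStudy, directory) -> list[Path]:
    """Write the study in the pipeline's input formats; returns written paths.

    Per experiment: ``otu_counts_exp{e}.tsv`` (first column OTU id, one
    column per sample, final taxonomy column) and ``phenotypes_exp{e}.csv``
    (rows = samples); plus ``metadata.tsv`` and ``truth.yaml``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for e, counts in study.otu_counts.items():
        if counts.size == 0:
            raise ValueError("refusing to write an empty OTU table")
        out = counts.copy()
        out["taxonomy"] = study.taxonomy
        path = directory / f"otu_counts_exp{e}.tsv"
        out.to_csv(path, sep="\t", index_label="otu_id")
        written.append(path)
        path = directory / f"phenotypes_exp{e}.csv"
        study.phenotypes[e].to_csv(path, index_label="sample")
        written.append(path)
    path = directory / "metadata.tsv"
    study.metadata.to_csv(path, sep="\t", index=False)
    written.append(path)
    truth_doc = {
        "differential_phenotypes": study.truth.differential_phenotypes,
        "differential_otus": study.truth.differential_otus,
        "planted_edges": [
            {"otu": e.otu, "phenotype": e.phenotype, "rho": e.rho}
            for e in study.truth.planted_edges
        ],
    }
    path = directory / "truth.yaml"
    path.write_text(yaml.safe_dump(truth_doc, sort_keys=True))
    written.append(path)
    return written
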