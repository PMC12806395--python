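"""Seeded synthetic gastric-cancer cohorts with subtype-specific structure.

The generator emulates the DNA-alteration signatures of the four TCGA
molecular subtypes: MSI hypermutation, CIN copy-number burden, EBV
hypermethylation, and a genomically quiet GS class, together with
subtype-linked survival hazards and missing methylation values.  Default
intensities follow the per-subtype alteration rates and hazard ratios
observed in TCGA gastric-cancer cohorts, at a desk scale of 1,000 genes
per modality.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .omics_io import (ClinicalTable, GeneSampleMatrix, OmicsCohort, SUBTYPES)


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator.

    Per-subtype vectors are ordered (CIN, GS, MSI, EBV).  Alteration
    intensities default to the per-subtype rates seen in TCGA gastric
    cancer: MSI hypermutated (~0.10 vs ~0.012 background), CIN CNA-heavy
    (~0.54 of genes altered), EBV hypermethylated (mean beta ~0.33 vs
    ~0.25-0.28).
    """

    n_samples: int = 600
    subtype_proportions: tuple = (0.67, 0.11, 0.15, 0.07)
    n_genes: int = 1000                      # per modality
    mutation_rates: tuple = (0.0123, 0.0044, 0.0998, 0.0140)
    cna_event_rates: tuple = (0.544, 0.0245, 0.097, 0.0433)
    methylation_means: tuple = (0.254, 0.271, 0.281, 0.326)
    methylation_concentration: float = 30.0  # beta distribution a+b
    cna_jitter_sd: float = 0.1               # around the +/-1, +/-2 call levels
    # per-sample burden overdispersion: tumours of one subtype differ widely
    # in total alteration load, so no single modality separates perfectly
    mutation_dispersion: float = 0.3         # lognormal sigma on the rate
    # genes differ widely in mutability (length, sequence context, hotspots);
    # the per-gene multiplier is a fixed property of the gene, shared by all
    # cohorts from one config
    mutation_gene_heterogeneity: float = 1.0
    cna_dispersion: float = 0.6
    methylation_sample_sd: float = 0.05      # global per-sample beta-mean shift
    n_marker_genes: int = 5                  # per subtype per modality
    marker_mutation_rate: float = 0.08
    marker_cna_rate: float = 0.15
    marker_meth_shift: float = 0.08
    # each subtype's defining modality carries proportionally stronger
    # markers (MSI - mutation, CIN - CNA, EBV - methylation)
    marker_home_boost: float = 5.0
    baseline_hazard: float = 0.02            # events per month
    hazard_multipliers: tuple = (1.0, 1.23, 0.64, 0.69)
    age_hazard_ratio: float = 1.3            # age >= 65 vs < 65
    male_hazard_ratio: float = 1.1
    censoring_rate: float = 0.4              # P(censored) for a baseline subject
    missing_rate: float = 0.05               # methylation cells masked
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        for p in (*self.subtype_proportions, *self.mutation_rates,
                  *self.cna_event_rates, self.marker_mutation_rate,
                  self.marker_cna_rate, self.missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(h <= 0 for h in self.hazard_multipliers):
            raise ValueError("hazard multipliers must be > 0")
        if 4 * self.n_marker_genes > self.n_genes:
            raise ValueError("more marker genes requested than genes available")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("subtype_proportions", "mutation_rates", "cna_event_rates",
                    "methylation_means", "hazard_multipliers"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """What the generator planted: true labels and marker genes."""

    labels: pd.Series                       # sample -> subtype
    markers: pd.DataFrame                   # columns: gene, modality, subtype, direction

    def to_tsv(self, path) -> None:
        self.markers.to_csv(path, sep="\t", index=False)


def _draw_labels(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    return rng.choice(len(SUBTYPES), size=cfg.n_samples, p=cfg.subtype_proportions)


# which subtypes carry planted markers in which modality, mirroring the
# alteration classes in which subtype-specific markers are actually found:
# GS and MSI are marked by mutations, CIN by copy number, and CIN, GS and
# EBV by methylation
MARKER_SUPPORT = {
    "mutation": ("GS", "MSI"),
    "cna": ("CIN",),
    "methylation": ("CIN", "GS", "EBV"),
}


def _plant_markers(cfg: SimulationConfig) -> pd.DataFrame:
    """Reserve disjoint marker gene blocks per subtype within each modality.

    The layout is a deterministic function of the config alone (not the seed)
    so independently seeded cohorts from the same config share the same
    informative genes — the analogue of a train and a test cohort assayed on
    one platform.
    """
    rows = []
    for modality in ("mutation", "cna", "methylation"):
        for s_idx, subtype in enumerate(SUBTYPES):
            if subtype not in MARKER_SUPPORT[modality]:
                continue
            block = range(s_idx * cfg.n_marker_genes, (s_idx + 1) * cfg.n_marker_genes)
            for pos, g in enumerate(block):
                if modality == "mutation":
                    direction = "+"
                elif subtype == "EBV" and modality == "methylation":
                    direction = "+"  # EBV markers are hypermethylated (CIMP-like)
                else:
                    direction = "+" if pos % 2 == 0 else "-"
                rows.append({"gene": f"g{g:04d}", "gene_idx": int(g),
                             "modality": modality, "subtype": subtype,
                             "direction": direction})
    return pd.DataFrame(rows, columns=["gene", "gene_idx", "modality",
                                       "subtype", "direction"])


def simulate_cohort(config: SimulationConfig) -> tuple[OmicsCohort, GroundTruth]:
    """Generate a labelled multi-omics cohort, deterministically from the seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    label_idx = _draw_labels(rng, cfg)
    samples = [f"s{i:04d}" for i in range(cfg.n_samples)]
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    labels = pd.Series([SUBTYPES[i] for i in label_idx], index=samples, name="subtype")
    markers = _plant_markers(cfg)

    # mutation: Bernoulli per cell with subtype-dependent rate scaled by a
    # per-sample lognormal burden factor; marker genes get an elevated rate
    # inside their subtype
    # lognormal factors are mean-normalised so configured rates stay the
    # expected realized rates
    sig = cfg.mutation_dispersion
    mut_factor = rng.lognormal(-sig * sig / 2.0, sig, size=cfg.n_samples)
    sig_g = cfg.mutation_gene_heterogeneity
    # gene mutability comes from a fixed stream so train and test cohorts
    # share the same per-gene profile
    gene_rng = np.random.default_rng(987654321)
    gene_mult = gene_rng.lognormal(-sig_g * sig_g / 2.0, sig_g,
                                   size=cfg.n_genes)
    mut_base = np.take(cfg.mutation_rates, label_idx) * mut_factor
    mut_p = np.clip(gene_mult[:, None] * mut_base[None, :], 0.0, 1.0)
    for _, row in markers[markers.modality == "mutation"].iterrows():
        in_sub = label_idx == SUBTYPES.index(row.subtype)
        boost = cfg.marker_home_boost if row.subtype == "MSI" else 1.0
        mut_p[row.gene_idx, in_sub] = min(cfg.marker_mutation_rate * boost, 1.0)
    mutation = (rng.random((cfg.n_genes, cfg.n_samples)) < mut_p).astype(float)

    # CNA: sparse events with signed discrete magnitudes plus jitter, with a
    # per-sample lognormal burden factor
    sig_c = cfg.cna_dispersion
    cna_factor = rng.lognormal(-sig_c * sig_c / 2.0, sig_c, size=cfg.n_samples)
    cna_base = np.clip(np.take(cfg.cna_event_rates, label_idx) * cna_factor,
                       0.0, 1.0)
    cna_p = cna_base[None, :].repeat(cfg.n_genes, axis=0)
    # each gene has a locus-consistent event direction (amplification or
    # deletion), alternating across the gene index so both occur
    gene_sign = np.where(np.arange(cfg.n_genes) % 2 == 0, 1.0, -1.0)
    sign = gene_sign[:, None].repeat(cfg.n_samples, axis=1)
    for _, row in markers[markers.modality == "cna"].iterrows():
        in_sub = label_idx == SUBTYPES.index(row.subtype)
        boost = cfg.marker_home_boost if row.subtype == "CIN" else 1.0
        cna_p[row.gene_idx, in_sub] = min(cfg.marker_cna_rate * boost, 1.0)
        sign[row.gene_idx, in_sub] = 1.0 if row.direction == "+" else -1.0
    event = rng.random((cfg.n_genes, cfg.n_samples)) < cna_p
    level = rng.choice([1.0, 2.0], size=event.shape)
    jitter = rng.normal(0.0, cfg.cna_jitter_sd, size=event.shape)
    cna = np.where(event, sign * level + jitter, 0.0)

    # methylation: Beta draws with subtype-dependent mean shifted globally per
    # sample (tumour-wide methylation level varies); marker genes get an extra
    # shift in their subtype
    meth_sample = rng.normal(0.0, cfg.methylation_sample_sd, size=cfg.n_samples)
    meth_mean = np.clip(np.take(cfg.methylation_means, label_idx) + meth_sample,
                        0.02, 0.98)[None, :].repeat(cfg.n_genes, axis=0)
    for _, row in markers[markers.modality == "methylation"].iterrows():
        in_sub = label_idx == SUBTYPES.index(row.subtype)
        base = meth_mean[row.gene_idx, in_sub]
        boost = cfg.marker_home_boost if row.subtype == "EBV" else 1.0
        shift = cfg.marker_meth_shift * boost
        if row.direction == "-":
            shift = -shift
        meth_mean[row.gene_idx, in_sub] = np.clip(base + shift, 0.02, 0.98)
    conc = cfg.methylation_concentration
    a = meth_mean * conc
    b = (1.0 - meth_mean) * conc
    methylation = rng.beta(a, b)

    clinical = simulate_survival(labels, cfg, seed=int(rng.integers(2**31)))

    cohort = OmicsCohort(
        GeneSampleMatrix(pd.DataFrame(mutation, index=genes, columns=samples), "mutation"),
        GeneSampleMatrix(pd.DataFrame(cna, index=genes, columns=samples), "cna"),
        GeneSampleMatrix(pd.DataFrame(methylation, index=genes, columns=samples), "methylation"),
        clinical,
        labels,
    )
    if cfg.missing_rate > 0:
        masked = inject_missing(cohort.methylation, cfg.missing_rate,
                                seed=int(rng.integers(2**31)))
        cohort = OmicsCohort(cohort.mutation, cohort.cna, masked, clinical, labels)
    truth = GroundTruth(labels=labels, markers=markers.drop(columns="gene_idx"))
    return cohort, truth


def simulate_survival(labels: pd.Series, config: SimulationConfig,
                      seed: Optional[int] = None) -> ClinicalTable:
    """Exponential event times under subtype/age/sex proportional hazards.

    The event hazard is baseline x subtype multiplier x age/sex effects; an
    independent exponential censoring time is calibrated so that a baseline
    subject is censored with probability ``censoring_rate``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = len(labels)
    label_idx = np.array([SUBTYPES.index(l) for l in labels])
    age = np.clip(rng.normal(62.0, 10.0, size=n), 30.0, 90.0)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    hazard = (cfg.baseline_hazard
              * np.take(cfg.hazard_multipliers, label_idx)
              * np.where(age >= 65.0, cfg.age_hazard_ratio, 1.0)
              * np.where(sex == "male", cfg.male_hazard_ratio, 1.0))
    event_time = rng.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        c_rate = cfg.baseline_hazard * cfg.censoring_rate / (1.0 - cfg.censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)
    df = pd.DataFrame({
        "age": age, "sex": sex,
        "os_time": np.maximum(os_time, 1e-6), "os_event": os_event,
    }, index=labels.index)
    return ClinicalTable(df)


def inject_missing(matrix: GeneSampleMatrix, rate: float,
                   seed: int = 0) -> GeneSampleMatrix:
    """Mask each cell independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return matrix
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.values.shape) < rate
    vals = matrix.values.mask(pd.DataFrame(mask, index=matrix.values.index,
                                           columns=matrix.values.columns))
    return GeneSampleMatrix(vals, matrix.modality)


def train_test_cohorts(config: SimulationConfig, n_test: int
                       ) -> tuple[OmicsCohort, OmicsCohort, GroundTruth, GroundTruth]:
    """Two independent cohorts from one config (seed and seed+1), sharing genes."""
    train_cohort, train_truth = simulate_cohort(config)
    test_cfg = SimulationConfig(**{**asdict(config),
                                   "n_samples": n_test, "seed": config.seed + 1})
    test_cohort, test_truth = simulate_cohort(test_cfg)
    return train_cohort, test_cohort, train_truth, test_truth
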