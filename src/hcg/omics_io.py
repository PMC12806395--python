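"""Reading, alignment, imputation and scaling of DNA-alteration matrices.

Three gene-by-sample modalities are handled: somatic mutation (boolean),
copy-number aberration (real-valued, gene-level) and methylation (beta
values in [0, 1], possibly probe-level).  All matrices are stored
genes-as-rows, samples-as-columns; missing values are NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

logger = logging.getLogger(__name__)

MODALITIES = ("mutation", "cna", "methylation")
SUBTYPES = ("CIN", "GS", "MSI", "EBV")


class OmicsError(ValueError):
    """Raised on malformed or contract-violating omics input."""


@dataclass
class GeneSampleMatrix:
    """A gene-by-sample alteration table for one modality.

    ``values`` is a DataFrame indexed by gene identifier with sample
    identifiers as columns; missing cells are NaN.
    """

    values: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise OmicsError(f"unknown modality {self.modality!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise OmicsError(f"duplicate gene identifiers: {dups[:5]}")
        if self.values.columns.has_duplicates:
            raise OmicsError("duplicate sample identifiers")
        vals = self.values.to_numpy(dtype=float)
        if self.modality == "mutation":
            if np.isnan(vals).any():
                raise OmicsError("mutation matrix must not contain missing values")
            if not np.isin(vals, (0.0, 1.0)).all():
                raise OmicsError("mutation values must be 0 or 1")
        elif self.modality == "methylation":
            obs = vals[~np.isnan(vals)]
            if obs.size and (obs.min() < 0 or obs.max() > 1):
                raise OmicsError("methylation beta values must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def subset_samples(self, samples: Iterable[str]) -> "GeneSampleMatrix":
        return GeneSampleMatrix(self.values.loc[:, list(samples)], self.modality)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations: age, sex, overall survival."""

    data: pd.DataFrame  # index: sample; columns: age, sex, os_time, os_event [, dataset]

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise OmicsError("duplicate sample identifiers in clinical table")
        required = {"age", "sex", "os_time", "os_event"}
        missing = required - set(self.data.columns)
        if missing:
            raise OmicsError(f"clinical table missing columns {sorted(missing)}")
        bad_sex = set(self.data["sex"].dropna()) - {"female", "male"}
        if bad_sex:
            raise OmicsError(f"unknown sex values {sorted(bad_sex)}")
        times = self.data["os_time"].dropna()
        if (times <= 0).any():
            raise OmicsError("os_time must be > 0 where present")
        events = set(self.data["os_event"].dropna().astype(int)) - {0, 1}
        if events:
            raise OmicsError("os_event must be 0 or 1")

    @property
    def samples(self) -> pd.Index:
        return self.data.index

    def subset_samples(self, samples: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)])


@dataclass
class OmicsCohort:
    """Aligned multi-modal cohort: the three matrices share one sample order."""

    mutation: GeneSampleMatrix
    cna: GeneSampleMatrix
    methylation: GeneSampleMatrix
    clinical: ClinicalTable
    labels: Optional[pd.Series] = None  # sample -> subtype

    def __post_init__(self) -> None:
        ref = list(self.mutation.samples)
        for mat in (self.cna, self.methylation):
            if list(mat.samples) != ref:
                raise OmicsError("matrices do not share an identical ordered sample set")
        if list(self.clinical.samples) != ref:
            raise OmicsError("clinical table sample set differs from matrices")
        if self.labels is not None:
            if list(self.labels.index) != ref:
                raise OmicsError("label sample set differs from matrices")
            bad = set(self.labels.dropna()) - set(SUBTYPES)
            if bad:
                raise OmicsError(f"unknown subtype labels {sorted(bad)}")

    @property
    def samples(self) -> pd.Index:
        return self.mutation.samples

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def matrix(self, modality: str) -> GeneSampleMatrix:
        return {"mutation": self.mutation, "cna": self.cna,
                "methylation": self.methylation}[modality]

    def feature_table(self, modalities: Iterable[str] = MODALITIES) -> pd.DataFrame:
        """Concatenated sample-by-feature table; feature names are prefixed
        with the modality so the combined space has length m across samples."""
        blocks = []
        for mod in modalities:
            mat = self.matrix(mod)
            block = mat.values.T
            block.columns = [f"{mod}:{g}" for g in mat.genes]
            blocks.append(block)
        return pd.concat(blocks, axis=1)

    def subset_samples(self, samples: Iterable[str]) -> "OmicsCohort":
        samples = list(samples)
        return OmicsCohort(
            self.mutation.subset_samples(samples),
            self.cna.subset_samples(samples),
            self.methylation.subset_samples(samples),
            self.clinical.subset_samples(samples),
            None if self.labels is None else self.labels.loc[samples],
        )


@dataclass
class ScalerParams:
    """Per-feature min/max learned on a designated training sample set."""

    min: pd.Series
    max: pd.Series

    def __post_init__(self) -> None:
        if not (self.max >= self.min).all():
            raise OmicsError("scaler max < min for some feature")


# ---------------------------------------------------------------------------
# readers

def _read_table(path, sep: str = "\t") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise OmicsError(f"empty or unreadable file: {path}") from exc
    if df.shape[1] == 0:
        raise OmicsError(f"no sample columns in {path}")
    return df


def read_matrix(path, modality: str, sep: str = "\t",
                transposed: bool = False) -> GeneSampleMatrix:
    """Read a gene-by-sample matrix (first column gene id, header sample ids).

    Mutation inputs may instead be MAF-like per-variant records with columns
    ``sample``, ``gene`` (and anything else); those are collapsed so a cell is
    1 iff the gene carries at least one variant in that sample.
    """
    if modality == "mutation":
        head = pd.read_csv(path, sep=sep, nrows=0)
        if {"sample", "gene"} <= set(head.columns):
            return read_maf(path, sep=sep)
    df = _read_table(path, sep=sep)
    if transposed:
        df = df.T
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gene, sample = next(zip(*np.nonzero(bad.to_numpy())))
        raise OmicsError(
            f"malformed numeric cell at gene {df.index[gene]!r}, "
            f"sample {df.columns[sample]!r} in {path}")
    if modality == "cna" and numeric.index.has_duplicates:
        raise OmicsError("duplicate gene rows in CNA matrix")
    return GeneSampleMatrix(numeric, modality)


def read_maf(path, sep: str = "\t") -> GeneSampleMatrix:
    """Collapse MAF-like per-variant records to a boolean gene-by-sample matrix."""
    records = pd.read_csv(path, sep=sep)
    if not {"sample", "gene"} <= set(records.columns):
        raise OmicsError("MAF-like input needs 'sample' and 'gene' columns")
    mat = pd.crosstab(records["gene"], records["sample"]).clip(upper=1)
    mat.index.name = None
    mat.columns.name = None
    return GeneSampleMatrix(mat.astype(float), "mutation")


def read_clinical(path, sep: str = "\t") -> ClinicalTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if "os_months" in df.columns and "os_time" not in df.columns:
        df = df.rename(columns={"os_months": "os_time"})
    return ClinicalTable(df)


def read_labels(path, sep: str = "\t") -> pd.Series:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.iloc[:, 0]


def write_matrix(mat: GeneSampleMatrix, path, sep: str = "\t") -> None:
    mat.values.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# probe collapse and imputation

def collapse_probes(probe_matrix: pd.DataFrame,
                    probe_map: Mapping[str, str]) -> GeneSampleMatrix:
    """Average probe-level methylation to gene level.

    Each gene's row is the arithmetic mean of its probes over non-missing
    probe values per sample; a gene cell is missing only when all its probes
    are missing for that sample.  Probes absent from the map are dropped and
    counted in the log.
    """
    probe_map = dict(probe_map)
    known = [p for p in probe_matrix.index if p in probe_map]
    dropped = len(probe_matrix.index) - len(known)
    if dropped:
        logger.info("collapse_probes: dropped %d probes with no gene mapping", dropped)
    sub = probe_matrix.loc[known]
    genes = pd.Series([probe_map[p] for p in known], index=sub.index)
    collapsed = sub.groupby(genes).mean()
    collapsed.index.name = None
    return GeneSampleMatrix(collapsed, "methylation")


def impute_knn(matrix: GeneSampleMatrix, k: int = 10,
               max_missing_fraction: float = 0.5) -> GeneSampleMatrix:
    """KNN-impute missing methylation values.

    Features (genes) missing in more than ``max_missing_fraction`` of samples
    are removed.  Each remaining missing cell is replaced by the mean of the
    value in the ``k`` nearest samples, with nearness measured by Euclidean
    distance over mutually observed features (normalised by the number of
    shared features so distances are comparable across missingness patterns).
    """
    if matrix.modality != "methylation":
        raise OmicsError("impute_knn expects a methylation matrix")
    vals = matrix.values
    frac_missing = vals.isna().mean(axis=1)
    keep = frac_missing <= max_missing_fraction
    removed = int((~keep).sum())
    if removed:
        logger.info("impute_knn: removed %d genes with >%.0f%% missing",
                    removed, 100 * max_missing_fraction)
    vals = vals.loc[keep]
    if not vals.isna().to_numpy().any():
        return GeneSampleMatrix(vals, "methylation")
    n_samples = vals.shape[1]
    if n_samples < 2:
        raise OmicsError("no neighbor samples available for imputation")
    k_eff = min(k, n_samples - 1)
    if k_eff < k:
        logger.info("impute_knn: only %d neighbor samples available, using all", k_eff)
    # samples are the imputation units -> impute on the sample-by-gene transpose
    imputer = KNNImputer(n_neighbors=k_eff, weights="uniform")
    imputed = imputer.fit_transform(vals.T.to_numpy(dtype=float))
    if imputed.shape[1] != vals.shape[0]:  # all-NaN columns silently dropped
        raise OmicsError("imputation dropped features; tighten max_missing_fraction")
    out = pd.DataFrame(imputed.T, index=vals.index, columns=vals.columns)
    # beta values can only be convex combinations of betas, but guard anyway
    return GeneSampleMatrix(out.clip(0.0, 1.0), "methylation")


# ---------------------------------------------------------------------------
# min-max scaling

def fit_scaler(matrix: GeneSampleMatrix,
               train_samples: Optional[Iterable[str]] = None) -> ScalerParams:
    """Learn per-feature min/max on the training samples only."""
    vals = matrix.values if train_samples is None else matrix.values.loc[:, list(train_samples)]
    if vals.shape[1] == 0:
        raise OmicsError("fit_scaler: empty training sample set")
    return ScalerParams(min=vals.min(axis=1), max=vals.max(axis=1))


def apply_scaler(matrix: GeneSampleMatrix, params: ScalerParams,
                 clip: bool = True) -> GeneSampleMatrix:
    """Apply min-max scaling, (x - min) / (max - min).

    Constant features (max == min) map to 0.  Values outside the training
    range (possible on test samples) are clipped to [0, 1].
    """
    missing = matrix.genes.difference(params.min.index)
    if len(missing):
        raise OmicsError(f"scaler params missing features: {list(missing[:5])}")
    lo = params.min.loc[matrix.genes]
    hi = params.max.loc[matrix.genes]
    span = hi - lo
    safe = span.replace(0.0, 1.0)
    scaled = matrix.values.sub(lo, axis=0).div(safe, axis=0)
    scaled.loc[span == 0.0] = 0.0
    if clip:
        scaled = scaled.clip(0.0, 1.0)
    return GeneSampleMatrix(scaled, matrix.modality)


def scale_cohort(cohort: OmicsCohort, train_samples: Iterable[str]
                 ) -> tuple[OmicsCohort, dict[str, ScalerParams]]:
    """Fit min-max scalers on the training samples and apply cohort-wide."""
    train_samples = list(train_samples)
    scalers: dict[str, ScalerParams] = {}
    mats = {}
    for mod in MODALITIES:
        params = fit_scaler(cohort.matrix(mod), train_samples)
        scalers[mod] = params
        mats[mod] = apply_scaler(cohort.matrix(mod), params)
    scaled = OmicsCohort(mats["mutation"], mats["cna"], mats["methylation"],
                         cohort.clinical, cohort.labels)
    return scaled, scalers


# ---------------------------------------------------------------------------
# assembly

def assemble_cohort(mut: GeneSampleMatrix, cna: GeneSampleMatrix,
                    meth: GeneSampleMatrix, clinical: ClinicalTable,
                    labels: Optional[pd.Series] = None) -> OmicsCohort:
    """Align inputs on their shared samples, in a canonical (sorted) order."""
    shared = set(mut.samples) & set(cna.samples) & set(meth.samples) & set(clinical.samples)
    if labels is not None:
        shared &= set(labels.index)
    if not shared:
        raise OmicsError("no samples shared between all inputs")
    order = sorted(shared)
    return OmicsCohort(
        mut.subset_samples(order),
        cna.subset_samples(order),
        meth.subset_samples(order),
        clinical.subset_samples(order),
        None if labels is None else labels.loc[order],
    )
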