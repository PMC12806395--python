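"""Subtype alteration-rate statistics and subtype-specific marker discovery.

Per-subtype rates are cohort-level summaries of each modality:

* mutation rate  — mean of the boolean cells over a subtype's samples x genes,
* CNA rate       — fraction of cells with a nonzero copy-number call,
* methylation rate — mean beta value.

Markers are found one-vs-rest per feature: Fisher's exact test for
mutations, Welch's two-sample t-test for CNA and methylation, BH-adjusted
within each modality, kept below an adjusted-p threshold, then deduplicated
to the most significant row per (gene, modality).  A one-way MANOVA on
per-sample summary variables serves as a dataset-integration check.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.manova import MANOVA

from .clinical_eval import bh_adjust
from .omics_io import MODALITIES, OmicsCohort, SUBTYPES

logger = logging.getLogger(__name__)

CNA_EPSILON = 1e-9          # |value| above this counts as an event (discrete calls)
CNA_CALL_THRESHOLD = 0.3    # applied first when input is continuous log-ratio


class MarkerError(ValueError):
    pass


def _cna_indicator(values: np.ndarray, continuous: bool = False) -> np.ndarray:
    if continuous:
        return (np.abs(values) >= CNA_CALL_THRESHOLD).astype(float)
    return (np.abs(values) > CNA_EPSILON).astype(float)


def alteration_rates(cohort: OmicsCohort, labels: Optional[pd.Series] = None,
                     cna_continuous: bool = False) -> pd.DataFrame:
    """Per-subtype x modality alteration rates.

    Returns a DataFrame indexed by subtype with columns mutation, cna,
    methylation; an empty subtype's rates are NaN.
    """
    labels = cohort.labels if labels is None else labels
    if labels is None:
        raise MarkerError("labels required")
    labels = labels.loc[cohort.samples]
    rows = {}
    mats = {
        "mutation": cohort.mutation.values.to_numpy(dtype=float),
        "cna": _cna_indicator(cohort.cna.values.to_numpy(dtype=float),
                              cna_continuous),
        "methylation": cohort.methylation.values.to_numpy(dtype=float),
    }
    for subtype in SUBTYPES:
        in_sub = (labels == subtype).to_numpy()
        if in_sub.sum() == 0:
            rows[subtype] = {m: np.nan for m in MODALITIES}
            continue
        rows[subtype] = {m: float(np.nanmean(mats[m][:, in_sub]))
                         for m in MODALITIES}
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(SUBTYPES)]


def per_sample_rates(cohort: OmicsCohort, cna_continuous: bool = False
                     ) -> pd.DataFrame:
    """Per-sample summary variables: mutation burden, CNA fraction, mean beta."""
    return pd.DataFrame({
        "mutation_rate": cohort.mutation.values.mean(axis=0),
        "cna_rate": _cna_indicator(cohort.cna.values.to_numpy(dtype=float),
                                   cna_continuous).mean(axis=0),
        "methylation_rate": cohort.methylation.values.mean(axis=0),
    }, index=cohort.samples)


def difference_tests(cohort: OmicsCohort, labels: Optional[pd.Series] = None,
                     feature_subset: Optional[Sequence[str]] = None,
                     alpha: float = 1e-5,
                     cna_continuous: bool = False) -> pd.DataFrame:
    """One-vs-rest marker tests per feature x subtype.

    ``feature_subset`` is a list of modality-prefixed feature names
    (``mutation:GENE``, ``cna:GENE``, ``methylation:GENE``), typically the
    features selected by the fitted cascade; ``None`` tests all features.

    Returns the MarkerTable: rows (subtype, modality, gene, direction,
    raw_p, adjusted_p, effect), adjusted p < ``alpha``, at most one row per
    (gene, modality).
    """
    labels = cohort.labels if labels is None else labels
    if labels is None:
        raise MarkerError("labels required")
    labels = labels.loc[cohort.samples]
    counts = labels.value_counts().reindex(SUBTYPES).fillna(0)
    testable = [s for s in SUBTYPES if counts[s] >= 2]
    if len(testable) < len(SUBTYPES):
        skipped = sorted(set(SUBTYPES) - set(testable))
        logger.warning("subtypes with < 2 samples skipped in OVR tests: %s",
                       skipped)
    if len(testable) < 2:
        raise MarkerError("need >= 2 subtypes with >= 2 samples each")

    wanted: Optional[dict] = None
    if feature_subset is not None:
        wanted = {m: set() for m in MODALITIES}
        for f in feature_subset:
            mod, _, gene = f.partition(":")
            if mod in wanted:
                wanted[mod].add(gene)

    records = []
    for modality in MODALITIES:
        mat = cohort.matrix(modality).values
        if wanted is not None:
            keep = [g for g in mat.index if g in wanted[modality]]
            mat = mat.loc[keep]
        vals = mat.to_numpy(dtype=float)
        for subtype in testable:
            in_sub = (labels == subtype).to_numpy()
            out_sub = ~in_sub
            for gi, gene in enumerate(mat.index):
                x = vals[gi]
                if modality == "mutation":
                    a = int(np.nansum(x[in_sub]))           # altered in subtype
                    b = int(in_sub.sum()) - a
                    c = int(np.nansum(x[out_sub]))
                    d = int(out_sub.sum()) - c
                    _, p = stats.fisher_exact([[a, b], [c, d]],
                                              alternative="two-sided")
                    effect = a / in_sub.sum() - c / out_sub.sum()
                else:
                    xi = x[in_sub]
                    xo = x[out_sub]
                    xi = xi[~np.isnan(xi)]
                    xo = xo[~np.isnan(xo)]
                    if xi.std(ddof=1) == 0 and xo.std(ddof=1) == 0:
                        logger.info("skipping zero-variance feature %s:%s (%s)",
                                    modality, gene, subtype)
                        continue
                    _, p = stats.ttest_ind(xi, xo, equal_var=False)
                    effect = float(xi.mean() - xo.mean())
                records.append({
                    "subtype": subtype, "modality": modality, "gene": gene,
                    "direction": "+" if effect >= 0 else "-",
                    "raw_p": float(p), "effect": effect,
                })
    table = pd.DataFrame(records)
    if table.empty:
        return pd.DataFrame(columns=["subtype", "modality", "gene", "direction",
                                     "raw_p", "adjusted_p", "effect"])
    # BH within each modality across all its feature x subtype tests
    table["adjusted_p"] = np.nan
    for modality in MODALITIES:
        sel = table["modality"] == modality
        if sel.any():
            table.loc[sel, "adjusted_p"] = bh_adjust(table.loc[sel, "raw_p"])
    table = table[table["adjusted_p"] < alpha]
    # deduplicate: keep the most significant row per (gene, modality)
    table = (table.sort_values(["adjusted_p", "raw_p"])
             .drop_duplicates(subset=["gene", "modality"], keep="first")
             .reset_index(drop=True))
    return table[["subtype", "modality", "gene", "direction",
                  "raw_p", "adjusted_p", "effect"]]


def manova_check(features_a: pd.DataFrame, features_b: pd.DataFrame
                 ) -> tuple[float, float]:
    """One-way MANOVA of group membership on shared summary variables.

    Returns (Wilks' lambda, p).  Used to check that two sample sets (e.g.
    the CIN stratum of two datasets) are statistically indistinguishable on
    per-sample alteration summaries before pooling them.
    """
    if list(features_a.columns) != list(features_b.columns):
        raise MarkerError("variable sets must match")
    n_a, n_b = len(features_a), len(features_b)
    n_vars = features_a.shape[1]
    if min(n_a, n_b) <= n_vars:
        raise MarkerError("each group needs n > number of variables")
    # exactly equal group means: zero between-group dispersion, Wilks = 1
    if np.allclose(features_a.mean(axis=0), features_b.mean(axis=0),
                   rtol=0.0, atol=1e-12):
        return 1.0, 1.0
    stacked = pd.concat([features_a, features_b], axis=0, ignore_index=True)
    stacked["group"] = ["a"] * n_a + ["b"] * n_b
    endog = stacked[features_a.columns.tolist()]
    if np.linalg.matrix_rank(np.cov(endog.to_numpy().T)) < n_vars:
        raise MarkerError("singular within-group covariance; reduce variables")
    formula = " + ".join(f"Q('{c}')" for c in features_a.columns) + " ~ group"
    mv = MANOVA.from_formula(formula, data=stacked)
    res = mv.mv_test()
    tab = res.results["group"]["stat"]
    wilks = float(tab.loc["Wilks' lambda", "Value"])
    p = float(tab.loc["Wilks' lambda", "Pr > F"])
    return wilks, p
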