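import numpy as np
import pandas as pd
import pytest

from hcg.omics_io import ClinicalTable, GeneSampleMatrix, OmicsCohort


@pytest.fixture
def tiny_cohort():
    """6-sample, 4-gene cohort with two subtypes, for exact-arithmetic tests."""
    samples = [f"s{i}" for i in range(6)]
    genes = ["gA", "gB", "gC", "gD"]
    rng = np.random.default_rng(7)
    mut = pd.DataFrame(rng.integers(0, 2, (4, 6)).astype(float),
                       index=genes, columns=samples)
    cna = pd.DataFrame(rng.choice([0.0, 0.0, 1.0, -2.0], (4, 6)),
                       index=genes, columns=samples)
    meth = pd.DataFrame(rng.random((4, 6)), index=genes, columns=samples)
    clin = pd.DataFrame({
        "age": [55, 70, 61, 66, 48, 72],
        "sex": ["female", "male", "female", "male", "female", "male"],
        "os_time": [10.0, 22.0, 5.0, 31.0, 12.0, 8.0],
        "os_event": [1, 0, 1, 0, 1, 1],
    }, index=samples)
    labels = pd.Series(["CIN", "CIN", "CIN", "MSI", "MSI", "MSI"],
                       index=samples)
    return OmicsCohort(GeneSampleMatrix(mut, "mutation"),
                       GeneSampleMatrix(cna, "cna"),
                       GeneSampleMatrix(meth, "methylation"),
                       ClinicalTable(clin), labels)


def roc_auc_oracle(y_true, scores):
    """Mann-Whitney pair counting with ties counted 1/2."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pr_auc_oracle(y_true, scores):
    """Exhaustive threshold sweep; step-wise sum of (dr) * precision."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    area = 0.0
    prev_recall = 0.0
    for thr in sorted(set(s), reverse=True):
        pred = s >= thr
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        recall = tp / n_pos
        precision = tp / (tp + fp) if tp + fp else 0.0
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
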