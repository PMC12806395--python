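"""SMOTE class balancing of the training set.

Synthetic minority samples are linear interpolations between a minority
sample and one of its k nearest same-class neighbours:

    x_new = x + u * (x_nn - x),   u ~ Uniform[0, 1]

so every synthetic coordinate lies between the two parents'.  Original rows
pass through bit-identically and are flagged as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


class BalancingError(ValueError):
    pass


@dataclass
class BalancedSet:
    features: pd.DataFrame          # samples x features
    labels: pd.Series
    provenance: pd.Series           # "original" | "synthetic"

    def __post_init__(self) -> None:
        counts = self.labels.value_counts()
        if counts.nunique() > 1:
            raise BalancingError("balanced set has unequal class counts")


def smote_balance(features: pd.DataFrame, labels: pd.Series, k: int = 5,
                  seed: int = 0, target_count: Optional[int] = None) -> BalancedSet:
    """Upsample every minority class to the majority count (or ``target_count``).

    Deterministic given ``seed``.  A class with a single sample is an error;
    ``k`` is reduced (and logged) when a class has fewer than k+1 samples.
    """
    if features.isna().to_numpy().any():
        raise BalancingError("features must not contain missing values")
    labels = labels.loc[features.index]
    counts = labels.value_counts()
    target = int(target_count) if target_count is not None else int(counts.max())
    if target < counts.max():
        raise BalancingError("target_count below majority class size; "
                             "undersampling is not supported")
    rng = np.random.default_rng(seed)

    out_X = [features]
    out_y = [labels]
    out_prov = [pd.Series("original", index=features.index)]
    for cls in sorted(counts.index):
        n_cls = int(counts[cls])
        need = target - n_cls
        if need <= 0:
            continue
        if n_cls < 2:
            raise BalancingError(f"class {cls!r} has a single sample; cannot interpolate")
        X_cls = features.loc[labels == cls].to_numpy(dtype=float)
        k_eff = min(k, n_cls - 1)
        if k_eff < k:
            logger.info("smote_balance: class %s has %d samples, using k=%d",
                        cls, n_cls, k_eff)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_cls)
        neigh = nn.kneighbors(X_cls, return_distance=False)[:, 1:]
        base_idx = rng.integers(0, n_cls, size=need)
        nn_choice = rng.integers(0, k_eff, size=need)
        u = rng.random(need)
        base = X_cls[base_idx]
        partner = X_cls[neigh[base_idx, nn_choice]]
        synth = base + u[:, None] * (partner - base)
        idx = [f"synthetic_{cls}_{i}" for i in range(need)]
        out_X.append(pd.DataFrame(synth, index=idx, columns=features.columns))
        out_y.append(pd.Series(cls, index=idx))
        out_prov.append(pd.Series("synthetic", index=idx))

    return BalancedSet(pd.concat(out_X), pd.concat(out_y), pd.concat(out_prov))
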