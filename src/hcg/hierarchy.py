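"""Hierarchical classification strategies over the four molecular subtypes.

A strategy is a tree whose root handles {CIN, GS, MSI, EBV}; each internal
node partitions its subtype set into >= 2 disjoint groups and delegates
each non-singleton group to a child node.  One sparse logistic model is
trained per internal node (on the samples of that node's subtype set,
relabelled by group), and 4-class probabilities are composed as the product
of node-model group probabilities along each root-to-leaf path — so they
always form a proper distribution.

Three named strategies are provided:

* ``I-MC``  — one-step multi-class: a single 4-way node.
* ``II-HC`` — two-step: {EBV, MSI} vs {CIN, GS}, then two binary splits.
* ``III-HC``— three-step chain: EBV vs rest, then MSI vs {CIN, GS},
  then GS vs CIN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .omics_io import SUBTYPES
from .sparse_linear import (CvResult, SparseLinearModel, cv_select_lambda,
                            fit_lasso_logistic, predict_proba)

logger = logging.getLogger(__name__)

# fixed tie-break order for argmax predictions
SUBTYPE_ORDER = {s: i for i, s in enumerate(SUBTYPES)}


class TreeError(ValueError):
    pass


def _group_label(group: tuple) -> str:
    return "+".join(group)


@dataclass
class SplitNode:
    name: str
    subtypes: tuple                 # subtype set handled by this node
    groups: tuple                   # ordered partition into >= 2 disjoint tuples

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise TreeError(f"node {self.name}: needs >= 2 groups")
        flat = [s for g in self.groups for s in g]
        if len(flat) != len(set(flat)):
            raise TreeError(f"node {self.name}: groups overlap")
        if set(flat) != set(self.subtypes):
            raise TreeError(f"node {self.name}: groups must union to the node set")


@dataclass
class SplitTree:
    """A classification strategy: nodes keyed by their subtype set."""

    name: str
    nodes: dict                     # frozenset(subtypes) -> SplitNode

    def __post_init__(self) -> None:
        root_key = frozenset(SUBTYPES)
        if root_key not in self.nodes:
            raise TreeError("root must handle all four subtypes")
        # every non-singleton group must have a child node
        for node in self.nodes.values():
            for group in node.groups:
                if len(group) > 1 and frozenset(group) not in self.nodes:
                    raise TreeError(
                        f"group {group} of node {node.name} has no child node")

    @property
    def root(self) -> SplitNode:
        return self.nodes[frozenset(SUBTYPES)]

    @property
    def internal_nodes(self) -> list:
        return list(self.nodes.values())

    @property
    def depth(self) -> int:
        def _depth(key: frozenset) -> int:
            node = self.nodes[key]
            sub = [_depth(frozenset(g)) for g in node.groups if len(g) > 1]
            return 1 + (max(sub) if sub else 0)
        return _depth(frozenset(SUBTYPES))

    def path(self, subtype: str) -> list:
        """(node, group) pairs from the root to the subtype's leaf."""
        out = []
        key = frozenset(SUBTYPES)
        while True:
            node = self.nodes[key]
            group = next(g for g in node.groups if subtype in g)
            out.append((node, group))
            if len(group) == 1:
                return out
            key = frozenset(group)

    def to_yaml(self, path=None) -> str:
        payload = {"name": self.name,
                   "nodes": [{"name": n.name, "groups": [list(g) for g in n.groups]}
                             for n in self.nodes.values()]}
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "SplitTree":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        nodes = {}
        for spec in payload["nodes"]:
            groups = tuple(tuple(g) for g in spec["groups"])
            subtypes = tuple(s for g in groups for s in g)
            node = SplitNode(spec["name"], subtypes, groups)
            nodes[frozenset(subtypes)] = node
        return cls(payload["name"], nodes)


def make_tree(name: str, partitions: Sequence[Sequence[Sequence[str]]]) -> SplitTree:
    """Build a tree from a list of group partitions (root first)."""
    nodes = {}
    for i, groups in enumerate(partitions):
        groups = tuple(tuple(g) for g in groups)
        subtypes = tuple(s for g in groups for s in g)
        node = SplitNode(f"{name}.{i}", subtypes, groups)
        nodes[frozenset(subtypes)] = node
    return SplitTree(name, nodes)


def strategy_catalog() -> dict:
    """The three candidate strategies, keyed by name."""
    i_mc = make_tree("I-MC", [[["CIN"], ["GS"], ["MSI"], ["EBV"]]])
    ii_hc = make_tree("II-HC", [
        [["EBV", "MSI"], ["CIN", "GS"]],
        [["EBV"], ["MSI"]],
        [["CIN"], ["GS"]],
    ])
    iii_hc = make_tree("III-HC", [
        [["EBV"], ["MSI", "CIN", "GS"]],
        [["MSI"], ["CIN", "GS"]],
        [["GS"], ["CIN"]],
    ])
    return {"I-MC": i_mc, "II-HC": ii_hc, "III-HC": iii_hc}


def random_tree(rng: np.random.Generator, name: str = "random") -> SplitTree:
    """A random valid strategy tree, for property testing of composition."""
    partitions = []

    def _split(subtypes: tuple) -> None:
        k = int(rng.integers(2, len(subtypes) + 1))
        perm = list(rng.permutation(list(subtypes)))
        cuts = sorted(rng.choice(range(1, len(subtypes)), size=k - 1, replace=False))
        groups = []
        prev = 0
        for c in list(cuts) + [len(subtypes)]:
            groups.append(tuple(perm[prev:c]))
            prev = c
        partitions.append(groups)
        for g in groups:
            if len(g) > 1:
                _split(g)

    _split(tuple(SUBTYPES))
    return make_tree(name, partitions)


# ---------------------------------------------------------------------------
# cascade fitting and prediction

@dataclass
class CascadeModel:
    """A fitted strategy: one sparse model per internal node."""

    strategy: SplitTree
    node_models: dict               # frozenset(subtypes) -> SparseLinearModel
    node_cv: dict                   # frozenset(subtypes) -> CvResult
    feature_names: list

    def selected_features(self) -> list:
        """Union of features with nonzero coefficients across node models."""
        from .sparse_linear import selected_features as _sel
        out: list = []
        seen = set()
        for model in self.node_models.values():
            for f in _sel(model):
                if f not in seen:
                    seen.add(f)
                    out.append(f)
        return out


def fit_cascade(features: pd.DataFrame, labels: pd.Series, tree: SplitTree,
                grid: Optional[Sequence[float]] = None, folds: int = 5,
                seed: int = 0, smote_k: Optional[int] = 5,
                cv_tol: float = 1e-4, cv_max_iter: int = 20,
                fit_tol: float = 1e-5, max_iter: int = 300,
                fit_dtype=np.float32) -> CascadeModel:
    """Train one CV-tuned lasso-logistic model per internal node.

    ``features``/``labels`` are the raw (unbalanced) training set.  The full
    4-class set is SMOTE-balanced once and each node's final model trains on
    the relevant balanced subset, relabelled by group.  Lambda selection
    cross-validates on the node's original samples only, balancing within
    each training fold, so synthetic points never leak into held-out folds.
    Pass ``smote_k=None`` to disable balancing.
    """
    labels = labels.loc[features.index]
    missing = set(SUBTYPES) - set(labels.unique())
    if missing:
        raise TreeError(f"training labels missing subtypes {sorted(missing)}")
    if smote_k is not None:
        from .balancing import smote_balance
        balanced = smote_balance(features, labels, k=smote_k, seed=seed)
        bal_X, bal_y = balanced.features, balanced.labels
        logger.info("balanced training set: %d per class",
                    int(bal_y.value_counts().iloc[0]))
    else:
        bal_X, bal_y = features, labels
    node_models, node_cv = {}, {}
    for key, node in tree.nodes.items():
        group_of = {s: _group_label(g) for g in node.groups for s in g}
        in_node_raw = labels.isin(node.subtypes)
        X_raw = features.loc[in_node_raw]
        y_raw = labels.loc[in_node_raw].map(group_of)
        in_node_bal = bal_y.isin(node.subtypes)
        X_bal = bal_X.loc[in_node_bal]
        y_bal = bal_y.loc[in_node_bal].map(group_of)
        present = set(y_raw.unique())
        wanted = {_group_label(g) for g in node.groups}
        if present != wanted:
            raise TreeError(f"node {node.name}: missing groups {wanted - present}")
        cv = cv_select_lambda(X_raw, y_raw, grid=grid, folds=folds, seed=seed,
                              tol=cv_tol, max_iter=cv_max_iter,
                              balance_k=smote_k,
                              balance_labels=labels.loc[in_node_raw])
        model = fit_lasso_logistic(X_bal, y_bal, cv.chosen, tol=fit_tol,
                                   max_iter=max_iter, dtype=fit_dtype)
        logger.info("node %s: lambda=%.4g, cv auROC=%.3f, %d samples",
                    node.name, cv.chosen, cv.scores.max(), len(X_bal))
        node_models[key] = model
        node_cv[key] = cv
    return CascadeModel(strategy=tree, node_models=node_models,
                        node_cv=node_cv, feature_names=list(features.columns))


def predict_subtype_proba(cascade: CascadeModel, X: pd.DataFrame) -> pd.DataFrame:
    """Compose node-model group probabilities down each path.

    P(subtype) is the product over the root-to-leaf path of the node model's
    probability of the group containing the subtype; the four values sum to
    1 by telescoping.
    """
    if list(X.columns) != list(cascade.feature_names):
        raise TreeError("feature names do not align with the cascade")
    node_proba = {key: predict_proba(model, X)
                  for key, model in cascade.node_models.items()}
    out = pd.DataFrame(1.0, index=X.index, columns=list(SUBTYPES))
    for subtype in SUBTYPES:
        for node, group in cascade.strategy.path(subtype):
            p = node_proba[frozenset(node.subtypes)][_group_label(group)]
            out[subtype] = out[subtype] * p.to_numpy()
    return out


def predict_subtype(cascade: CascadeModel, X: pd.DataFrame) -> pd.Series:
    """Argmax subtype; exact ties break by the fixed order CIN<GS<MSI<EBV."""
    proba = predict_subtype_proba(cascade, X)
    proba = proba[list(SUBTYPES)]       # column order encodes the tie-break
    idx = proba.to_numpy().argmax(axis=1)
    return pd.Series([SUBTYPES[i] for i in idx], index=X.index, name="subtype")
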