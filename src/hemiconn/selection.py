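"""Random-forest out-of-bag permutation importance for edge screening.

A bagged regression forest is grown over subjects: each tree is fit on a
bootstrap sample (N draws with replacement) and the subjects it never saw
form that tree's out-of-bag (OOB) set. A feature's importance is

    X_k = sum_t (errOOB2_{t,k} - errOOB1_t) / n_trees

where ``errOOB1_t`` is tree t's mean squared error on its OOB subjects and
``errOOB2_{t,k}`` the same error after perturbing feature column k among the
OOB rows — by default a random within-OOB permutation (the classic Breiman
procedure); an additive-Gaussian perturbation is available via config.
Edges whose importance exceeds a threshold (default 0.005 on the raw
MSE-difference scale, with the outcome expressed as a fraction in [0, 1])
are retained for the downstream ridge model.

The bootstrap/OOB bookkeeping, the RNG stream discipline and the importance
statistic live here; individual trees are CART regression trees
(``sklearn.tree.DecisionTreeRegressor``).

RNG streams: the bootstrap draws come from ``default_rng([seed, 0])``; the
perturbation of feature k on tree t comes from ``default_rng([seed, 1, t, k])``,
so importances are reproducible and independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .atlas import Edge, Network

__all__ = [
    "ForestConfig",
    "ForestModel",
    "ImportanceTable",
    "fit_forest",
    "oob_importance",
    "select_features",
    "write_importance_table",
]

_MAX_BOOTSTRAP_RETRIES = 100


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters; only ``n_trees = 20`` is dictated by the
    modeling protocol, the rest are conventional regression-forest defaults
    (unlimited depth, ceil(d/3) candidate features per split, leaves of at
    least 2 samples)."""

    n_trees: int = 20
    max_depth: int | None = None
    max_features: int | None = None  # None -> ceil(d / 3)
    min_samples_leaf: int = 2
    seed: int = 0
    importance_threshold: float = 0.005
    perturbation: Literal["permute", "gaussian_noise"] = "permute"
    noise_sd: float = 1.0  # only for perturbation="gaussian_noise"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.importance_threshold < 0:
            raise ValueError("importance_threshold must be >= 0")
        if self.perturbation not in ("permute", "gaussian_noise"):
            raise ValueError(f"unknown perturbation {self.perturbation!r}")

    def resolve_max_features(self, d: int) -> int:
        if self.max_features is not None:
            return min(self.max_features, d)
        return max(1, math.ceil(d / 3))


@dataclass
class ForestModel:
    trees: list[DecisionTreeRegressor]
    bootstrap_indices: list[np.ndarray]
    oob_indices: list[np.ndarray]
    config: ForestConfig
    n_samples: int
    n_features: int


@dataclass
class ImportanceTable:
    """Per-edge OOB permutation importances for one network."""

    network: Network | None
    edges: tuple[Edge, ...] | None
    importance: np.ndarray
    err_oob_baseline: np.ndarray  # per-tree errOOB1
    threshold: float

    @property
    def selected(self) -> np.ndarray:
        return self.importance > self.threshold

    def to_frame(self) -> pd.DataFrame:
        d = len(self.importance)
        edges = self.edges if self.edges is not None else [(0, k) for k in range(d)]
        return pd.DataFrame({
            "network": [self.network or ""] * d,
            "i": [e[0] for e in edges],
            "j": [e[1] for e in edges],
            "importance": self.importance,
            "selected": self.selected,
        })


def fit_forest(X, y, config: ForestConfig) -> ForestModel:
    """Grow the bagged forest and record every tree's OOB subject set.

    A bootstrap whose OOB set would be empty is redrawn (up to 100 times).
    Deterministic given ``config.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (subjects x features)")
    n, d = X.shape
    if n < 5:
        raise ValueError(f"need at least 5 subjects to fit the forest, got {n}")
    if y.shape != (n,):
        raise ValueError("y length must match the number of rows of X")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values in forest input")

    rng = np.random.default_rng([config.seed, 0])
    max_features = config.resolve_max_features(d)
    trees, boots, oobs = [], [], []
    for _t in range(config.n_trees):
        for _attempt in range(_MAX_BOOTSTRAP_RETRIES):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size:
                break
        else:
            raise RuntimeError(
                f"no non-empty OOB set in {_MAX_BOOTSTRAP_RETRIES} bootstrap draws"
            )
        tree = DecisionTreeRegressor(
            max_depth=config.max_depth,
            max_features=max_features,
            min_samples_leaf=config.min_samples_leaf,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)
        oobs.append(oob)
    return ForestModel(
        trees=trees, bootstrap_indices=boots, oob_indices=oobs,
        config=config, n_samples=n, n_features=d,
    )


def _perturbed_column(
    col: np.ndarray, rng: np.random.Generator, config: ForestConfig
) -> np.ndarray:
    if config.perturbation == "permute":
        return col[rng.permutation(col.size)]
    return col + rng.normal(0.0, config.noise_sd, size=col.size)


def oob_importance(
    model: ForestModel,
    X,
    y,
    edges: Sequence[Edge] | None = None,
    network: Network | None = None,
) -> ImportanceTable:
    """Compute X_k = sum_t (errOOB2_{t,k} - errOOB1_t) / n_trees per column."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if (n, d) != (model.n_samples, model.n_features):
        raise ValueError("X shape does not match the fitted forest")
    config = model.config
    n_trees = len(model.trees)
    err1 = np.empty(n_trees)
    delta = np.zeros(d)
    # batch the d perturbed OOB matrices through one predict call per chunk
    chunk = max(1, int(4e6 / max(1, d * n)))
    for t, tree in enumerate(model.trees):
        oob = model.oob_indices[t]
        Xo, yo = X[oob], y[oob]
        m = oob.size
        pred = tree.predict(Xo)
        err1[t] = float(np.mean((pred - yo) ** 2))
        for start in range(0, d, chunk):
            feats = range(start, min(start + chunk, d))
            blocks = []
            for k in feats:
                Xp = Xo.copy()
                rng_k = np.random.default_rng([config.seed, 1, t, k])
                Xp[:, k] = _perturbed_column(Xo[:, k], rng_k, config)
                blocks.append(Xp)
            preds = tree.predict(np.vstack(blocks)).reshape(len(blocks), m)
            delta[list(feats)] += np.mean((preds - yo) ** 2, axis=1) - err1[t]
    importance = delta / n_trees
    return ImportanceTable(
        network=network,
        edges=tuple(edges) if edges is not None else None,
        importance=importance,
        err_oob_baseline=err1,
        threshold=config.importance_threshold,
    )


def select_features(
    table: ImportanceTable, threshold: float | None = None
) -> list[int]:
    """Column indices with importance strictly above the threshold, sorted by
    descending importance; ties broken by canonical edge order (or column
    index when the table carries no edges). May be empty."""
    thr = table.threshold if threshold is None else threshold
    idx = np.flatnonzero(table.importance > thr)
    if table.edges is not None:
        keys = [table.edges[k] for k in idx]
    else:
        keys = list(idx)
    order = sorted(
        range(len(idx)), key=lambda p: (-table.importance[idx[p]], keys[p])
    )
    return [int(idx[p]) for p in order]


def write_importance_table(table: ImportanceTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
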