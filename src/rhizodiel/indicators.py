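"""AM/PM indicator taxa by random-forest permutation importance.

A bootstrap-bagged ensemble of decision trees classifies samples into AM
vs PM from genus abundances. Importance is the classical mean decrease in
accuracy (MDA): for each tree, the drop in that tree's out-of-bag (OOB)
accuracy when one genus's values are permuted among the tree's OOB
samples, averaged over trees. The bagging, OOB bookkeeping and permutation
are implemented here (individual trees are scikit-learn CART trees) so
that every random draw is driven by a single integer seed and results are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .core_data import SampleMetadata, metadata_to_frame
from .normalization import AbundanceMatrix
from .rhythm import RhythmCall, RhythmDetectionResult

__all__ = [
    "PhaseForest",
    "ImportanceRecord",
    "fit_phase_forest",
    "mean_decrease_accuracy",
    "top_indicators",
    "circadian_indicator_overlap",
]


@dataclass
class ImportanceRecord:
    """Permutation importance of one genus."""

    genus_id: str
    mda: float
    mda_se: float
    rank: int


@dataclass
class PhaseForest:
    """Fitted bagged-tree ensemble with OOB bookkeeping."""

    trees: list[DecisionTreeClassifier]
    bootstrap_indices: list[np.ndarray]
    X: np.ndarray
    y: np.ndarray
    classes: np.ndarray
    genus_ids: list[str]
    sample_ids: list[str]
    oob_votes: np.ndarray  # samples × classes
    oob_predictions: np.ndarray  # predicted class index per sample (-1 never OOB)
    oob_accuracy: float
    seed: int


def fit_phase_forest(
    abund: AbundanceMatrix,
    meta: Iterable[SampleMetadata] | pd.DataFrame,
    regime: str,
    n_trees: int = 1000,
    seed: int = 0,
    compartment: str | None = "rhizosphere",
    max_features: str | int | None = "sqrt",
    labels: str = "phase",
) -> PhaseForest:
    """Fit a bagged decision-tree ensemble predicting the diel phase.

    Each tree is grown without depth limit on a bootstrap resample
    (``max_features`` candidate genera per split, √p by default); OOB
    accuracy is the majority-vote accuracy of each sample over the trees
    for which it was out of bag. Deterministic given ``seed``.
    """
    mdf = metadata_to_frame(meta)
    mask = mdf["regime"] == regime
    if compartment is not None:
        mask &= mdf["compartment"] == compartment
    sel = mdf[mask]
    if sel.empty:
        raise ValueError(f"no samples for regime={regime!r}, compartment={compartment!r}")
    idx = abund.sample_index(list(sel["sample_id"]))
    X = abund.values[idx]
    y_labels = sel[labels].to_numpy()
    classes, y = np.unique(y_labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError(f"labels {labels!r} have a single class in this group")
    if np.bincount(y).min() < 2:
        raise ValueError("need ≥ 2 samples per class")

    rng = np.random.default_rng(seed)
    n = len(y)
    trees: list[DecisionTreeClassifier] = []
    boot: list[np.ndarray] = []
    votes = np.zeros((n, len(classes)), dtype=np.int64)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)
    for b in range(n_trees):
        indices = rng.integers(0, n, size=n)
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(tree_seeds[b])
        )
        tree.fit(X[indices], y[indices])
        oob = np.setdiff1d(np.arange(n), indices)
        if oob.size:
            pred = tree.predict(X[oob]).astype(int)
            votes[oob, pred] += 1
        trees.append(tree)
        boot.append(indices)

    covered = votes.sum(axis=1) > 0
    oob_pred = np.where(covered, votes.argmax(axis=1), -1)
    oob_acc = float((oob_pred[covered] == y[covered]).mean()) if covered.any() else float("nan")
    return PhaseForest(
        trees=trees,
        bootstrap_indices=boot,
        X=X,
        y=y,
        classes=classes,
        genus_ids=list(abund.genus_ids),
        sample_ids=list(sel["sample_id"]),
        oob_votes=votes,
        oob_predictions=oob_pred,
        oob_accuracy=oob_acc,
        seed=seed,
    )


def mean_decrease_accuracy(forest: PhaseForest, seed: int | None = None) -> list[ImportanceRecord]:
    """Classical per-tree OOB permutation importance.

    Per tree and genus: (tree's OOB accuracy) − (tree's OOB accuracy after
    permuting that genus's values among the tree's OOB samples), averaged
    over trees; ``mda_se`` is the standard error of that per-tree mean.
    Raw accuracy decrease, not normalized by its SD.
    """
    if seed is None:
        seed = forest.seed + 1
    rng = np.random.default_rng(seed)
    n, p = forest.X.shape
    decreases = np.zeros((len(forest.trees), p))
    used = np.zeros(len(forest.trees), dtype=bool)
    for b, (tree, indices) in enumerate(zip(forest.trees, forest.bootstrap_indices)):
        oob = np.setdiff1d(np.arange(n), indices)
        m = oob.size
        if m == 0:
            continue
        used[b] = True
        X_oob = forest.X[oob]
        y_oob = forest.y[oob]
        base_acc = (tree.predict(X_oob).astype(int) == y_oob).mean()
        # one permutation of the OOB rows reused for every genus; each
        # genus's column is shuffled independently in a single batch predict
        perm = rng.permutation(m)
        big = np.repeat(X_oob[None, :, :], p, axis=0)
        for f in range(p):
            big[f, :, f] = X_oob[perm, f]
        pred = tree.predict(big.reshape(p * m, p)).astype(int).reshape(p, m)
        decreases[b] = base_acc - (pred == y_oob[None, :]).mean(axis=1)
    k = int(used.sum())
    if k == 0:
        raise ValueError("no tree has out-of-bag samples")
    mda = decreases[used].mean(axis=0)
    se = decreases[used].std(axis=0, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(p)
    order = sorted(range(p), key=lambda f: (-mda[f], forest.genus_ids[f]))
    ranks = np.empty(p, dtype=int)
    for r, f in enumerate(order, start=1):
        ranks[f] = r
    return [
        ImportanceRecord(genus_id=forest.genus_ids[f], mda=float(mda[f]), mda_se=float(se[f]), rank=int(ranks[f]))
        for f in range(p)
    ]


def top_indicators(records: Sequence[ImportanceRecord], n: int = 30) -> list[ImportanceRecord]:
    """Highest-``n`` genera by MDA; ties broken by genus id (ascending)."""
    if n > len(records):
        raise ValueError(f"n={n} exceeds the {len(records)} available genera")
    return sorted(records, key=lambda r: (-r.mda, r.genus_id))[:n]


def circadian_indicator_overlap(
    indicators: Sequence[ImportanceRecord],
    rhythm_calls: Sequence[RhythmCall] | RhythmDetectionResult,
) -> tuple[list[str], float]:
    """Genera that are both indicator and circadian taxa, with their MDA sum."""
    if isinstance(rhythm_calls, RhythmDetectionResult):
        circadian = set(rhythm_calls.circadian_genera)
    else:
        circadian = {c.genus_id for c in rhythm_calls if c.is_circadian}
    shared = sorted(r.genus_id for r in indicators if r.genus_id in circadian)
    mda_sum = float(sum(r.mda for r in indicators if r.genus_id in circadian))
    return shared, mda_sum
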