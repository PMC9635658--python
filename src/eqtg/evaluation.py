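"""Extended cross-validation, hyperparameter search and feature importance.

The evaluation framework re-splits the positive genes into training and
validation sets at a 4:1 ratio ``n_positive_splits`` times; within each
split, training and validation negatives are drawn ``n_negative_samplings``
times (disjoint draws at the configured positive:negative ratio).  One
classifier is trained and one ROC AUC recorded per (split, sampling) pair
— 50 x 50 = 2,500 evaluations at the defaults — so that every negative
gene co-occurs with the positives at least once with high probability.

The same seed schedule is shared across hyperparameter grid points and
across full/reduced models in the leave-one-out importance analysis, so
AUC differences are paired and their variance shrinks accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ensemble import Hyperparameters, train_member, _positive_proba
from .table import FeatureTable, LabeledGeneSet

__all__ = [
    "CVConfig",
    "CVResult",
    "ImportanceResult",
    "auc_roc",
    "extended_cv",
    "permutation_control",
    "grid_search",
    "loo_importance",
    "cluster_features",
]

# integer tags namespacing the derived RNG streams
_TAG_SPLIT = 11
_TAG_SAMPLING = 12
_TAG_PERMUTE = 13


@dataclass(frozen=True)
class CVConfig:
    """Configuration of the extended resampling cross-validation."""

    n_positive_splits: int = 50
    n_negative_samplings: int = 50
    train_fraction: float = 0.8  # the 4:1 split
    hp: Hyperparameters = field(default_factory=Hyperparameters)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive_splits < 1 or self.n_negative_samplings < 1:
            raise ValueError("split and sampling counts must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def n_repetitions(self) -> int:
        return self.n_positive_splits * self.n_negative_samplings


@dataclass
class CVResult:
    """Vector of per-repetition AUCs with its mean and standard deviation."""

    aucs: np.ndarray
    mean_auc: float
    sd_auc: float

    @classmethod
    def from_aucs(cls, aucs: np.ndarray) -> "CVResult":
        aucs = np.asarray(aucs, dtype=float)
        return cls(aucs=aucs, mean_auc=float(aucs.mean()),
                   sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"repetition": np.arange(len(self.aucs)), "auc": self.aucs})


def auc_roc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve, rank-based with ties counted 1/2.

    Equivalent to the normalized Mann-Whitney U statistic: the probability
    that a random positive outscores a random negative, ties worth half.
    Requires both classes to be present.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC is undefined with a single class present")
    return float(roc_auc_score(y, s))


def _split_positives(
    positives: list[str], train_fraction: float, rng: np.random.Generator
) -> tuple[list[str], list[str]]:
    n = len(positives)
    n_val = max(1, int(round(n * (1.0 - train_fraction))))
    if n_val >= n:
        raise ValueError("too few positives for a train/validation split")
    perm = rng.permutation(n)
    val = [positives[i] for i in perm[:n_val]]
    train = [positives[i] for i in perm[n_val:]]
    return train, val


def _run_cv(
    table: FeatureTable,
    positives: list[str],
    pool: list[str],
    cfg: CVConfig,
    permute_labels: bool,
) -> CVResult:
    """Shared engine behind extended_cv and permutation_control.

    All randomness is drawn from streams keyed by (master_seed, tag,
    indices), never by hyperparameters or the feature set, which is what
    makes seed schedules shareable across grid points and reduced models.
    """
    if len(positives) < 5:
        raise ValueError("need >= 5 positives so a 4:1 split keeps a validation positive")
    ratio = cfg.hp.pos_neg_ratio
    aucs = np.empty(cfg.n_repetitions, dtype=float)
    universe = sorted(positives) + sorted(pool)
    n_pos = len(positives)
    k = 0
    for i in range(cfg.n_positive_splits):
        if permute_labels:
            # re-deal the positive label uniformly over the gene universe,
            # once per repetition, before splitting
            rng_p = np.random.default_rng([cfg.master_seed, _TAG_PERMUTE, i])
            idx = rng_p.choice(len(universe), size=n_pos, replace=False)
            chosen = set(idx)
            rep_pos = sorted(universe[j] for j in chosen)
            rep_pool = sorted(g for j, g in enumerate(universe) if j not in chosen)
        else:
            rep_pos = sorted(positives)
            rep_pool = sorted(pool)
        rng_split = np.random.default_rng([cfg.master_seed, _TAG_SPLIT, i])
        train_pos, val_pos = _split_positives(rep_pos, cfg.train_fraction, rng_split)
        need_train = ratio * len(train_pos)
        need_val = ratio * len(val_pos)
        if need_train + need_val > len(rep_pool):
            raise ValueError(
                "negative pool too small for disjoint train/validation draws: "
                f"need {need_train + need_val}, have {len(rep_pool)}"
            )
        for j in range(cfg.n_negative_samplings):
            rng_ij = np.random.default_rng([cfg.master_seed, _TAG_SAMPLING, i, j])
            draw = rng_ij.choice(len(rep_pool), size=need_train + need_val, replace=False)
            train_neg = [rep_pool[t] for t in draw[:need_train]]
            val_neg = [rep_pool[t] for t in draw[need_train:]]
            member_seed = int(rng_ij.integers(2 ** 31))
            clf = train_member(table, train_pos, train_neg, cfg.hp, member_seed)
            val_genes = sorted(val_pos) + sorted(val_neg)
            X = table.matrix(val_genes)
            y = np.array([1] * len(val_pos) + [0] * len(val_neg))
            scores = _positive_proba(clf, X)
            aucs[k] = auc_roc(y, scores)
            k += 1
    return CVResult.from_aucs(aucs)


def extended_cv(table: FeatureTable, labels: LabeledGeneSet, cfg: CVConfig) -> CVResult:
    """Run the extended resampling CV and return all per-repetition AUCs."""
    labels.check_in_table(table)
    return _run_cv(
        table, sorted(labels.positives), sorted(labels.negative_pool), cfg,
        permute_labels=False,
    )


def permutation_control(
    table: FeatureTable, labels: LabeledGeneSet, cfg: CVConfig
) -> CVResult:
    """Chance-level control: the same CV after randomly permuting class labels.

    The positive label is re-dealt uniformly over the combined gene universe
    once per positive-split repetition; everything downstream is identical
    to :func:`extended_cv`.  Mean AUC converges to 0.5 on any data.
    """
    labels.check_in_table(table)
    return _run_cv(
        table, sorted(labels.positives), sorted(labels.negative_pool), cfg,
        permute_labels=True,
    )


def grid_search(
    table: FeatureTable,
    labels: LabeledGeneSet,
    grid: Sequence[Hyperparameters],
    cv_template: CVConfig,
) -> tuple[Hyperparameters, dict[Hyperparameters, CVResult]]:
    """Evaluate every grid point under a shared seed schedule; return the best.

    All points see identical positive splits and negative draws (the seed
    streams depend only on the master seed and repetition indices), so AUC
    comparisons are paired.  The point maximizing mean AUC wins; ties are
    broken by fewer trees, then smaller positive:negative ratio.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    results: dict[Hyperparameters, CVResult] = {}
    for hp in grid:
        cfg = replace(cv_template, hp=hp)
        results[hp] = extended_cv(table, labels, cfg)

    def sort_key(hp: Hyperparameters):
        return (
            -results[hp].mean_auc,
            hp.n_trees,
            hp.pos_neg_ratio,
            hp.min_samples_split,
            str(hp.max_features_rule),
        )

    best = min(grid, key=sort_key)
    return best, results


def default_grid() -> list[Hyperparameters]:
    """The default hyperparameter grid (overridable from configuration)."""
    grid = []
    for n_trees in (100, 200, 500):
        for mss in (2, 5, 10):
            for mf in ("sqrt", 0.25, 0.5):
                for ratio in (1, 5, 10, 50):
                    grid.append(
                        Hyperparameters(
                            n_trees=n_trees,
                            min_samples_split=mss,
                            max_features_rule=mf,
                            pos_neg_ratio=ratio,
                        )
                    )
    return grid


@dataclass
class ImportanceResult:
    """Leave-one-out importance: per unit, the paired mean AUC drop.

    A unit is a single feature or a cluster of correlated features; every
    feature belongs to exactly one unit.  ``mean_drop`` is mean AUC of the
    full model minus mean AUC of the model retrained without the unit,
    under the same seed schedule; the SD is that of the paired differences.
    A positive drop means the unit helps prediction.
    """

    table: pd.DataFrame  # unit_id, members, mean_drop, sd, n_reps
    full_result: CVResult

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["members"] = out["members"].map(lambda m: ",".join(m))
        out.to_csv(path, sep="\t", index=False)


def loo_importance(
    table: FeatureTable,
    labels: LabeledGeneSet,
    cfg: CVConfig,
    units: Sequence[tuple[str, Sequence[str]]] | None = None,
) -> ImportanceResult:
    """Leave-one-out feature (or feature-cluster) importance by AUC drop.

    Iteratively removes each unit's features, reruns the extended CV on the
    reduced table with the identical seed schedule, and reports the paired
    per-repetition AUC differences (full minus reduced).  With ``units``
    omitted every feature is its own unit.
    """
    if len(table.feature_names) < 2:
        raise ValueError("need at least 2 features for leave-one-out importance")
    if units is None:
        units = [(name, [name]) for name in table.feature_names]
    covered: list[str] = []
    for _, members in units:
        covered.extend(members)
    if len(covered) != len(set(covered)):
        raise ValueError("units must be disjoint")
    unknown = set(covered) - set(table.feature_names)
    if unknown:
        raise KeyError(f"unknown features in units: {sorted(unknown)}")

    full = extended_cv(table, labels, cfg)
    rows = []
    for unit_id, members in units:
        reduced = extended_cv(table.drop_features(members), labels, cfg)
        diff = full.aucs - reduced.aucs
        rows.append(
            {
                "unit_id": unit_id,
                "members": list(members),
                "mean_drop": float(diff.mean()),
                "sd": float(diff.std(ddof=1)) if len(diff) > 1 else 0.0,
                "n_reps": len(diff),
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["mean_drop", "unit_id"], ascending=[False, True], ignore_index=True
    )
    return ImportanceResult(table=frame, full_result=full)


def cluster_features(
    corr: pd.DataFrame, threshold: float = 0.6, absolute: bool = False
) -> list[tuple[str, list[str]]]:
    """Group features into connected components of the thresholded correlation graph.

    An edge joins two features whenever their Pearson correlation is
    **equal to or larger than** the threshold (signed by default; set
    ``absolute`` to threshold |r| instead).  Missing correlations count as
    below threshold.  Components mean clustering is transitive: r(a,b) and
    r(b,c) above threshold place a, b, c together even if r(a,c) is low.

    Returns (unit_id, members) pairs covering every feature exactly once,
    suitable for :func:`loo_importance`; unit ids join the sorted members.
    """
    if not corr.index.equals(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    values = corr.to_numpy(dtype=float)
    if not np.allclose(values, values.T, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    graph = nx.Graph()
    names = list(corr.index)
    graph.add_nodes_from(names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            r = values[i, j]
            if np.isnan(r):
                continue
            if (abs(r) if absolute else r) >= threshold:
                graph.add_edge(a, names[j])
    clusters = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        clusters.append(("|".join(members), members))
    clusters.sort(key=lambda c: c[0])
    return clusters
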