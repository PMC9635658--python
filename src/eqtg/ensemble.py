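"""Negative-resampling random-forest ensemble for causal-gene scoring.

Known causal genes are rare (hundreds) against a genome-scale background
(tens of thousands), so a single classifier trained on all genes would be
swamped by the negative class.  Instead, M forests are trained, each on the
full positive set plus an independently resampled negative set at a fixed
positive:negative ratio (default 1:200, approximating the causal fraction
in a real eQTL region).  A gene's causality score is the mean predicted
positive-class probability over the M members.

Determinism contract: per-member seeds are derived from the master seed via
``numpy.random.SeedSequence`` spawning, so any member can be reconstructed
in isolation and scores are invariant to member order.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .table import FeatureTable, LabeledGeneSet

__all__ = [
    "Hyperparameters",
    "EnsembleModel",
    "sample_negatives",
    "train_member",
    "train_ensemble",
    "predict_mean_probability",
    "genome_wide_summary",
    "save_ensemble",
    "load_ensemble",
]

DEFAULT_M = 5000  #: production ensemble size
TEST_M = 100      #: reduced size for quick runs


@dataclass(frozen=True)
class Hyperparameters:
    """Forest and resampling hyperparameters.

    ``max_features_rule`` is either the name ``"sqrt"`` (square root of the
    feature count, the conventional forest default) or a fraction in (0, 1]
    of features considered per split.  ``pos_neg_ratio`` is the number of
    negatives sampled per positive for each member's training set.
    """

    n_trees: int = 200
    min_samples_split: int = 2
    max_features_rule: str | float = "sqrt"
    pos_neg_ratio: int = 200

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if isinstance(self.max_features_rule, str):
            if self.max_features_rule != "sqrt":
                raise ValueError("named max_features_rule must be 'sqrt'")
        elif not 0.0 < float(self.max_features_rule) <= 1.0:
            raise ValueError("fractional max_features_rule must lie in (0, 1]")
        if self.pos_neg_ratio < 1:
            raise ValueError("pos_neg_ratio must be a positive integer")

    @property
    def sklearn_max_features(self) -> str | float:
        return self.max_features_rule


@dataclass
class EnsembleModel:
    """M fitted forests sharing one feature order, plus training metadata."""

    members: list[RandomForestClassifier]
    feature_names: list[str]
    hyperparameters: Hyperparameters
    member_seeds: list[int]
    ratio_used: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if len(set(self.member_seeds)) != len(self.member_seeds):
            raise ValueError("member seeds must be unique")

    @property
    def n_members(self) -> int:
        return len(self.members)


def derive_member_seeds(master_seed: int, m: int) -> list[int]:
    """Deterministic unique per-member seeds from a master seed.

    Uses SeedSequence spawning so member k is reconstructible knowing only
    (master_seed, k); seeds are kept below 2**31 for portability.
    """
    children = np.random.SeedSequence(master_seed).spawn(m)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]
    # spawn-key collisions at 31 bits are vanishingly rare; resolve if seen
    seen: set[int] = set()
    out = []
    for s in seeds:
        while s in seen:
            s = (s + 1) % (2 ** 31)
        seen.add(s)
        out.append(s)
    return out


def sample_negatives(
    pool: Iterable[str], n_required: int, rng: np.random.Generator
) -> list[str]:
    """Uniform sample without replacement, capped at the pool size.

    When the requested count exceeds the pool (e.g. 200 positives at ratio
    1:200 against a ~27k-gene pool) the whole pool is returned; members then
    differ only in RNG draw order.  Deterministic given the generator state.
    """
    pool = sorted(pool)
    if not pool:
        raise ValueError("negative pool is empty")
    if n_required < 0:
        raise ValueError("n_required must be nonnegative")
    n = min(n_required, len(pool))
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def _training_arrays(
    table: FeatureTable, positives: Sequence[str], negatives: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    pos = sorted(positives)
    neg = sorted(negatives)
    overlap = set(pos) & set(neg)
    if overlap:
        raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:5]}")
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    X = table.matrix(pos + neg)
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return X, y


def train_member(
    table: FeatureTable,
    positives: Sequence[str],
    negatives: Sequence[str],
    hp: Hyperparameters,
    seed: int,
) -> RandomForestClassifier:
    """Fit one forest on the given positive/negative gene ids.

    Rows are assembled in sorted gene-id order, so training is invariant to
    the row order of the feature table itself.
    """
    X, y = _training_arrays(table, positives, negatives)
    clf = RandomForestClassifier(
        n_estimators=hp.n_trees,
        min_samples_split=hp.min_samples_split,
        max_features=hp.sklearn_max_features,
        random_state=int(seed),
        n_jobs=1,
    )
    clf.fit(X, y)
    return clf


def _positive_proba(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return clf.predict_proba(X)[:, pos_col]


def train_ensemble(
    table: FeatureTable,
    labels: LabeledGeneSet,
    hp: Hyperparameters | None = None,
    m: int = DEFAULT_M,
    seed: int = 0,
) -> EnsembleModel:
    """Train M members, each on all positives plus a fresh negative sample.

    Each member's negative set has size min(ratio x |positives|, |pool|);
    with the production 1:200 ratio and a genome-scale pool the cap binds
    and every member sees the whole pool (only tree randomness and draw
    order differ).  With smaller ratios the member sets differ materially,
    which is what drives the ensemble averaging.
    """
    if m < 1:
        raise ValueError("ensemble size must be >= 1")
    hp = hp or Hyperparameters()
    labels.check_in_table(table)
    pool = sorted(labels.negative_pool)
    positives = sorted(labels.positives)
    need = hp.pos_neg_ratio * len(positives)
    if need > len(pool):
        import logging
        logging.getLogger(__name__).warning(
            "negative demand %d exceeds pool size %d; capping at the pool "
            "(members differ only by RNG draw order)", need, len(pool),
        )
    seeds = derive_member_seeds(seed, m)
    members = []
    for member_seed in seeds:
        rng = np.random.default_rng(member_seed)
        negatives = sample_negatives(pool, need, rng)
        members.append(train_member(table, positives, negatives, hp, member_seed))
    return EnsembleModel(
        members=members,
        feature_names=table.feature_names,
        hyperparameters=hp,
        member_seeds=seeds,
        ratio_used=hp.pos_neg_ratio,
    )


def predict_mean_probability(
    model: EnsembleModel, table: FeatureTable, genes: Sequence[str]
) -> pd.Series:
    """Mean predicted causality probability over all ensemble members.

    The arithmetic mean of per-member positive-class probabilities; values
    lie in [0, 1] and are invariant to member ordering.  Unknown gene ids
    raise with the offending ids listed.
    """
    table.check_same_features(model.feature_names)
    X = table.matrix(genes)  # raises KeyError listing unknown ids
    total = np.zeros(len(genes))
    for clf in model.members:
        total += _positive_proba(clf, X)
    return pd.Series(total / model.n_members, index=list(genes), name="mean_probability")


def genome_wide_summary(
    scores: pd.Series | Mapping[str, float], quantile: float = 0.05
) -> tuple[float, list[str], list[str]]:
    """Median score plus the top- and bottom-quantile gene lists.

    Tails contain the ceil(q*n) highest/lowest scoring genes; ties are
    broken by gene id so the lists are deterministic.
    """
    scores = pd.Series(dict(scores)) if not isinstance(scores, pd.Series) else scores
    if scores.empty:
        raise ValueError("scores must be non-empty")
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must lie in (0, 1]")
    k = math.ceil(quantile * len(scores))
    frame = scores.rename("score").rename_axis("gene_id").reset_index()
    top = frame.sort_values(["score", "gene_id"], ascending=[False, True])
    bottom = frame.sort_values(["score", "gene_id"], ascending=[True, True])
    return (
        float(scores.median()),
        top["gene_id"].head(k).tolist(),
        bottom["gene_id"].head(k).tolist(),
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def table_checksum(table: FeatureTable) -> str:
    """Checksum binding a saved model to its training table's feature order."""
    h = hashlib.sha256()
    h.update("\t".join(table.feature_names).encode())
    return h.hexdigest()


def save_ensemble(model: EnsembleModel, out_dir: str | Path, table: FeatureTable | None = None) -> None:
    """Persist an ensemble: metadata JSON plus joblib-serialized members."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_members": model.n_members,
        "feature_names": model.feature_names,
        "hyperparameters": asdict(model.hyperparameters),
        "member_seeds": model.member_seeds,
        "ratio_used": model.ratio_used,
        "feature_checksum": hashlib.sha256("\t".join(model.feature_names).encode()).hexdigest(),
    }
    if table is not None:
        meta["training_table_checksum"] = table_checksum(table)
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(model.members, out / "members.joblib")


def load_ensemble(model_dir: str | Path) -> EnsembleModel:
    """Load a persisted ensemble, verifying the feature-order checksum."""
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "metadata.json").read_text())
    expected = hashlib.sha256("\t".join(meta["feature_names"]).encode()).hexdigest()
    if meta["feature_checksum"] != expected:
        raise ValueError("feature-order checksum mismatch in saved ensemble")
    members = joblib.load(model_dir / "members.joblib")
    hp = Hyperparameters(**meta["hyperparameters"])
    return EnsembleModel(
        members=members,
        feature_names=meta["feature_names"],
        hyperparameters=hp,
        member_seeds=meta["member_seeds"],
        ratio_used=meta["ratio_used"],
    )
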