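"""Forest prediction by majority vote and batched library screening.

Every tree classifies a compound by root-to-leaf traversal ("go left iff
value <= threshold"); the forest's label is the class with the most votes,
with exact ties resolved to *active* so that no potentially active compound
is discarded by a coin flip.  The vote fraction (active votes / trees) is
exposed as a ranking score for ROC evaluation.

Large libraries are screened as a stream of fixed-size batches: memory use
is bounded by the batch size and the per-compound output is independent of
how the stream was partitioned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .descriptors import (
    ACTIVE,
    INACTIVE,
    DescriptorError,
    FeatureTable,
    MoleculeRecord,
    compute_descriptors,
)
from .forest import DecisionTree, ForestModel

logger = logging.getLogger("rfscreen")


@dataclass
class VoteTally:
    votes_active: int
    votes_inactive: int

    @property
    def score(self) -> float:
        return self.votes_active / (self.votes_active + self.votes_inactive)


@dataclass
class ScreeningReport:
    """Per-compound predictions plus stream-level totals."""

    ids: list[str] = field(default_factory=list)
    labels: list[Optional[int]] = field(default_factory=list)
    scores: list[Optional[float]] = field(default_factory=list)
    votes_active: list[Optional[int]] = field(default_factory=list)
    status: list[str] = field(default_factory=list)  # "ok" | "failed"
    batch_count: int = 0
    n_trees: int = 0

    @property
    def n_screened(self) -> int:
        return sum(1 for s in self.status if s == "ok")

    @property
    def n_failed(self) -> int:
        return sum(1 for s in self.status if s == "failed")

    @property
    def n_predicted_active(self) -> int:
        return sum(1 for lab, s in zip(self.labels, self.status) if s == "ok" and lab == ACTIVE)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "predicted_label": self.labels,
                "score": self.scores,
                "n_votes_active": self.votes_active,
                "n_trees": self.n_trees,
                "status": self.status,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_tree(tree: DecisionTree, x: np.ndarray) -> int:
    """Classify one descriptor vector by deterministic root-to-leaf traversal."""
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.feature_count,):
        raise ValueError(
            f"descriptor vector has length {x.shape[0] if x.ndim == 1 else x.shape}, "
            f"tree expects {tree.feature_count}"
        )
    node = tree.nodes[tree.root_id]
    while node.kind != "leaf":
        node = tree.nodes[node.left_child if x[node.feature_index] <= node.threshold else node.right_child]
    return node.label


def _predict_tree_batch(tree: DecisionTree, X: np.ndarray) -> np.ndarray:
    """Vectorized traversal of all rows through one tree."""
    arr = tree.as_arrays()
    pos = np.full(X.shape[0], tree.root_id, dtype=np.int64)
    while True:
        at_leaf = arr["is_leaf"][pos]
        if at_leaf.all():
            break
        feat = arr["feature"][pos]
        thr = arr["threshold"][pos]
        go_left = X[np.arange(X.shape[0]), feat] <= thr
        nxt = np.where(go_left, arr["left"][pos], arr["right"][pos])
        pos = np.where(at_leaf, pos, nxt)
    return arr["label"][pos]


def predict_forest(model: ForestModel, X: FeatureTable | np.ndarray) -> tuple[np.ndarray, list[VoteTally]]:
    """Majority-vote prediction: per-row labels and vote tallies.

    Exact vote ties are declared active.  Per-tree evaluations are
    independent, so any evaluation order yields identical output.
    """
    matrix = X.matrix if isinstance(X, FeatureTable) else np.asarray(X, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != model.feature_count:
        raise ValueError(
            f"input has {matrix.shape[1] if matrix.ndim == 2 else matrix.shape} columns, "
            f"model expects {model.feature_count}"
        )
    votes_active = np.zeros(matrix.shape[0], dtype=np.int64)
    for tree in model.trees:
        votes_active += _predict_tree_batch(tree, matrix) == ACTIVE
    n_trees = model.n_trees
    labels = np.where(2 * votes_active >= n_trees, ACTIVE, INACTIVE)
    tallies = [VoteTally(int(v), n_trees - int(v)) for v in votes_active]
    return labels, tallies


def predict_scores(model: ForestModel, X: FeatureTable | np.ndarray) -> np.ndarray:
    """Vote-fraction ranking scores in [0, 1]."""
    _, tallies = predict_forest(model, X)
    return np.array([t.score for t in tallies])


# ---------------------------------------------------------------------------
# Batched screening
# ---------------------------------------------------------------------------

def _batches(stream: Iterable[MoleculeRecord], batch_size: int) -> Iterator[list[MoleculeRecord]]:
    batch: list[MoleculeRecord] = []
    for rec in stream:
        batch.append(rec)
        if len(batch) == batch_size:
            yield batch
            batch = []
    if batch:
        yield batch


def screen_stream(
    model: ForestModel,
    mols: Iterable[MoleculeRecord],
    batch_size: int = 4096,
) -> ScreeningReport:
    """Screen a molecule stream in successive batches of <= batch_size.

    Compounds whose featurization fails are recorded with status "failed"
    and screening continues; memory use is bounded by the batch size and the
    report is independent of the partitioning.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    report = ScreeningReport(n_trees=model.n_trees)
    for batch in _batches(mols, batch_size):
        report.batch_count += 1
        ok: list[tuple[MoleculeRecord, np.ndarray]] = []
        for rec in batch:
            try:
                ok.append((rec, compute_descriptors(rec)))
            except DescriptorError as exc:
                logger.warning("screening failure: %s", exc)
                report.ids.append(rec.id)
                report.labels.append(None)
                report.scores.append(None)
                report.votes_active.append(None)
                report.status.append("failed")
        if ok:
            matrix = np.vstack([vec for _, vec in ok])
            labels, tallies = predict_forest(model, matrix)
            for (rec, _), lab, tally in zip(ok, labels, tallies):
                report.ids.append(rec.id)
                report.labels.append(int(lab))
                report.scores.append(tally.score)
                report.votes_active.append(tally.votes_active)
                report.status.append("ok")
    logger.info(
        "screened %d compounds in %d batches (%d predicted active, %d failed)",
        report.n_screened, report.batch_count, report.n_predicted_active, report.n_failed,
    )
    return report


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model: ForestModel, path: str | Path) -> None:
    """Serialize a forest to versioned JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path: str | Path) -> ForestModel:
    """Load a forest saved by :func:`save_model`; rejects unknown versions."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"model file {path} is not valid JSON: {exc}") from exc
    return ForestModel.from_dict(payload)
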