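"""Fall vs. non-fall classification of spatiotemporal skeleton graphs.

A window of thermal frames becomes one spatiotemporal graph, the graph
is embedded with :class:`~thermofall.embedding.Graph2Vec` (k=30 by grid
search), and a random forest separates the falling and non-falling
classes. Evaluation is stratified k-fold cross-validation reporting
precision, sensitivity and specificity with *fall* as the positive
class; the embedding itself is trained without labels on all graphs, so
only the forest is cross-validated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import skeleton as sk
from .embedding import Graph2Vec
from .frames import LabeledWindow
from .graphs import DEFAULT_STRIDE, frames_to_graph

POSITIVE_LABEL = "fall"
DEFAULT_N_TREES = 200


@dataclass
class EvalReport:
    """Cross-validated confusion counts and the three headline metrics
    (percent), with fall as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    sensitivity: float
    specificity: float
    folds: int
    seed: int
    fold_assignments: list[int] = field(default_factory=list)

    @classmethod
    def from_counts(
        cls,
        tp: int,
        fp: int,
        tn: int,
        fn: int,
        folds: int = 0,
        seed: int = 0,
        fold_assignments: Sequence[int] = (),
    ) -> "EvalReport":
        precision = 100.0 * tp / (tp + fp) if (tp + fp) else float("nan")
        sensitivity = 100.0 * tp / (tp + fn) if (tp + fn) else float("nan")
        specificity = 100.0 * tn / (tn + fp) if (tn + fp) else float("nan")
        return cls(
            tp=tp, fp=fp, tn=tn, fn=fn,
            precision=precision, sensitivity=sensitivity, specificity=specificity,
            folds=folds, seed=seed, fold_assignments=list(fold_assignments),
        )

    @property
    def n_windows(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n_windows

    def to_dict(self) -> dict:
        return asdict(self)


def _as_graphs(windows, **graph_kwargs) -> list[nx.Graph]:
    out = []
    for w in windows:
        if isinstance(w, nx.Graph):
            out.append(w)
        else:
            vals = w.values if isinstance(w, LabeledWindow) else w
            out.append(frames_to_graph(vals, **graph_kwargs))
    return out


class FallDetector(BaseEstimator, ClassifierMixin):
    """End-to-end fall classifier over frame windows.

    ``fit`` accepts windows (LabeledWindow, (n,24,32) arrays, or
    pre-built graphs) and labels; internally it builds spatiotemporal
    graphs, trains the Graph2Vec embedding and a random forest.
    ``predict`` embeds unseen windows in inference mode (frozen label
    vectors) and applies the forest.
    """

    def __init__(
        self,
        k: int = 30,
        wl_depth: int = 2,
        epochs: int = 400,
        learning_rate: float = 0.05,
        negative: int = 5,
        min_count: int = 2,
        degree_bucket_max: int = 12,
        stride: int = DEFAULT_STRIDE,
        fixed_threshold: float = sk.DEFAULT_THRESHOLD,
        min_component_px: int = sk.DEFAULT_MIN_COMPONENT_PX,
        max_spur_px: int = sk.DEFAULT_MAX_SPUR_PX,
        n_estimators: int = DEFAULT_N_TREES,
        max_depth: int | None = None,
        random_state: int = 0,
    ) -> None:
        self.k = k
        self.wl_depth = wl_depth
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.negative = negative
        self.min_count = min_count
        self.degree_bucket_max = degree_bucket_max
        self.stride = stride
        self.fixed_threshold = fixed_threshold
        self.min_component_px = min_component_px
        self.max_spur_px = max_spur_px
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state

    def _graph_kwargs(self) -> dict:
        return dict(
            stride=self.stride,
            fixed_threshold=self.fixed_threshold,
            min_component_px=self.min_component_px,
            max_spur_px=self.max_spur_px,
        )

    def fit(self, X, y) -> "FallDetector":
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels must contain both classes")
        graphs = _as_graphs(X, **self._graph_kwargs())
        self.embedder_ = Graph2Vec(
            k=self.k,
            wl_depth=self.wl_depth,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            negative=self.negative,
            min_count=self.min_count,
            degree_bucket_max=self.degree_bucket_max,
            random_state=self.random_state,
        )
        emb = self.embedder_.fit_transform(graphs)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=1,
        )
        self.forest_.fit(emb, y)
        self.classes_ = self.forest_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        graphs = _as_graphs(X, **self._graph_kwargs())
        return self.forest_.predict(self.embedder_.transform(graphs))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        graphs = _as_graphs(X, **self._graph_kwargs())
        return self.forest_.predict_proba(self.embedder_.transform(graphs))


def train_classifier(
    embeddings: np.ndarray,
    labels: Sequence[str],
    rf_params: Mapping | None = None,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit the random forest on precomputed graph embeddings."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels must contain both classes")
    params = dict(n_estimators=DEFAULT_N_TREES, max_depth=None)
    params.update(rf_params or {})
    forest = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    forest.fit(np.asarray(embeddings), labels)
    return forest


def evaluate(
    windows,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    embedder: Graph2Vec | None = None,
    rf_params: Mapping | None = None,
    **graph_kwargs,
) -> EvalReport:
    """Stratified k-fold cross-validated confusion counts and metrics.

    The Graph2Vec embedding is trained once, unsupervised, on all
    graphs (the transductive protocol of the method: the embedding sees
    every graph but no labels); the random forest is fit and scored per
    fold. Positive class is "fall".
    """
    labels = np.asarray(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("evaluation needs both classes")
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` members")
    graphs = _as_graphs(windows, **graph_kwargs)
    if embedder is None:
        embedder = Graph2Vec(random_state=seed)
    emb = embedder.fit_transform(graphs)
    return cv_report(emb, labels, folds=folds, seed=seed, rf_params=rf_params)


def cv_report(
    embeddings: np.ndarray,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    rf_params: Mapping | None = None,
) -> EvalReport:
    """Stratified k-fold CV of the random forest on precomputed graph
    embeddings; confusion counts pooled over folds."""
    labels = np.asarray(labels)
    emb = np.asarray(embeddings)
    params = dict(n_estimators=DEFAULT_N_TREES, max_depth=None)
    params.update(rf_params or {})

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assign = np.zeros(len(labels), dtype=int)
    tp = fp = tn = fn = 0
    for fold, (tr, te) in enumerate(skf.split(emb, labels)):
        assign[te] = fold
        forest = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
        forest.fit(emb[tr], labels[tr])
        pred = forest.predict(emb[te])
        truth = labels[te]
        tp += int(np.sum((pred == POSITIVE_LABEL) & (truth == POSITIVE_LABEL)))
        fp += int(np.sum((pred == POSITIVE_LABEL) & (truth != POSITIVE_LABEL)))
        tn += int(np.sum((pred != POSITIVE_LABEL) & (truth != POSITIVE_LABEL)))
        fn += int(np.sum((pred != POSITIVE_LABEL) & (truth == POSITIVE_LABEL)))
    return EvalReport.from_counts(
        tp, fp, tn, fn, folds=folds, seed=seed, fold_assignments=assign.tolist()
    )


def grid_search_k(
    graphs: Sequence[nx.Graph],
    labels: Sequence[str],
    k_grid: Sequence[int],
    seed: int = 0,
    folds: int = 5,
) -> tuple[int, dict[int, float]]:
    """Grid-search the embedding dimensionality k by CV accuracy.

    Returns the best k (ties broken toward the smallest k) and the
    per-k accuracy scores (percent).
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    scores: dict[int, float] = {}
    best_k, best_score = None, -np.inf
    for k in k_grid:
        report = evaluate(
            list(graphs), labels, folds=folds, seed=seed,
            embedder=Graph2Vec(k=k, random_state=seed),
        )
        scores[k] = report.accuracy
        if report.accuracy > best_score:
            best_k, best_score = k, report.accuracy
    return best_k, scores


# ---------------------------------------------------------------------------
# alert protocol


@dataclass
class FallAlert:
    """One fall-alert record of the notification protocol: recipient and
    response status, event start/end, notification time, and a free-form
    reviewer comment."""

    recipient: str
    response_status: str
    start: datetime
    end: datetime
    notification: datetime
    comment: str = ""

    def __post_init__(self) -> None:
        if not (self.start <= self.end <= self.notification):
            raise ValueError("alert times must satisfy start <= end <= notification")

    def to_json(self) -> str:
        d = asdict(self)
        for key in ("start", "end", "notification"):
            d[key] = d[key].isoformat()
        return json.dumps(d, sort_keys=True)


def emit_alert(
    window_start: datetime,
    window_end: datetime,
    prediction: str,
    clock: datetime,
    recipient: str = "call-center",
    comment: str = "",
    log_path: str | Path | None = None,
) -> FallAlert | None:
    """Emit (and optionally append to an NDJSON log) an alert iff the
    window was classified as a fall."""
    if prediction != POSITIVE_LABEL:
        return None
    if clock < window_start:
        raise ValueError("notification clock precedes the window start")
    alert = FallAlert(
        recipient=recipient,
        response_status="pending",
        start=window_start,
        end=window_end,
        notification=clock,
        comment=comment,
    )
    if log_path is not None:
        with open(log_path, "a") as fh:
            fh.write(alert.to_json() + "\n")
    return alert
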