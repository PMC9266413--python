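"""Interface labeling, patch sampling, training loop and evaluation.

A surface vertex of protein A is an *interface* vertex when it lies within
``cutoff`` (default 1.4 A) of the nearest surface vertex of partner B, and
symmetrically. Training items are sampled balanced (equal numbers of
positive and negative patches/pairs). Models are fitted by minimizing mean
binary cross-entropy with the AMSGrad variant of Adam, with a seeded 10%
validation split and early stopping on the validation loss; the parameters
from the best-validation epoch are returned.

AUROC is computed as the Mann-Whitney rank statistic: the probability that
a random positive outscores a random negative, counting ties one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from . import autodiff as ad
from . import network as net
from .network import ModelState
from .surfacing import SurfaceMesh

__all__ = [
    "DEFAULT_INTERFACE_CUTOFF",
    "UndefinedMetricError",
    "SamplingError",
    "TrainConfig",
    "TrainLog",
    "EvalReport",
    "label_interface",
    "sample_sites",
    "sample_pairs",
    "auroc",
    "train",
    "evaluate_pair",
    "evaluate_sites",
    "confusion_matrix",
]

DEFAULT_INTERFACE_CUTOFF = 1.4


class UndefinedMetricError(ValueError):
    """AUROC needs at least one positive and one negative label."""


class SamplingError(ValueError):
    """Positive-pair sampling failed (no interface vertices)."""


def _as_points(mesh) -> np.ndarray:
    return mesh.vertices if isinstance(mesh, SurfaceMesh) else np.atleast_2d(mesh)


def label_interface(
    mesh_a, mesh_b, cutoff: float = DEFAULT_INTERFACE_CUTOFF
) -> tuple[np.ndarray, np.ndarray]:
    """Binary interface labels for both surfaces (vertex-to-vertex rule).

    A vertex is labeled 1 iff its distance to the nearest vertex of the
    partner surface is <= ``cutoff``. Accepts meshes or raw point arrays.
    Zero positives is a legal outcome.
    """
    from . import geometry

    pa, pb = _as_points(mesh_a), _as_points(mesh_b)
    _, d_ab = geometry.knn(pa, pb, k=1)
    _, d_ba = geometry.knn(pb, pa, k=1)
    return (d_ab[:, 0] <= cutoff).astype(np.int64), (d_ba[:, 0] <= cutoff).astype(np.int64)


def sample_sites(
    labels: np.ndarray, n_items: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced site items: n_items/2 positive and n_items/2 negative vertex
    indices (drawn with replacement when a class is scarce)."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    negv = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(negv) == 0:
        raise SamplingError("site sampling requires both classes present")
    half = n_items // 2
    idx = np.concatenate([
        rng.choice(pos, size=half, replace=True),
        rng.choice(negv, size=half, replace=True),
    ])
    y = np.concatenate([np.ones(half, dtype=np.int64), np.zeros(half, dtype=np.int64)])
    return idx, y


def sample_pairs(
    labels_a: np.ndarray,
    labels_b: np.ndarray,
    points_a: np.ndarray,
    points_b: np.ndarray,
    n_pairs: int,
    rng: np.random.Generator,
    pair_name: str = "pair",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balanced patch-pair items ``(idx_a, idx_b, label)``.

    Positives match a positive vertex of A with its nearest positive vertex
    of B; negatives are uniform vertex pairs constrained to contain at least
    one non-interface vertex.
    """
    from . import geometry

    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    pos_a = np.flatnonzero(labels_a == 1)
    pos_b = np.flatnonzero(labels_b == 1)
    if len(pos_a) == 0 or len(pos_b) == 0:
        raise SamplingError(f"{pair_name}: no interface vertices to sample positives from")
    half = n_pairs // 2
    pa = rng.choice(pos_a, size=half, replace=True)
    nn, _ = geometry.knn(np.atleast_2d(points_a)[pa], np.atleast_2d(points_b)[pos_b], k=1)
    pb = pos_b[nn[:, 0]]

    na = np.empty(half, dtype=np.int64)
    nb = np.empty(half, dtype=np.int64)
    filled = 0
    while filled < half:
        ca = rng.integers(0, len(labels_a), size=half - filled)
        cb = rng.integers(0, len(labels_b), size=half - filled)
        ok = (labels_a[ca] == 0) | (labels_b[cb] == 0)
        n_ok = int(ok.sum())
        na[filled:filled + n_ok] = ca[ok]
        nb[filled:filled + n_ok] = cb[ok]
        filled += n_ok
    idx_a = np.concatenate([pa, na])
    idx_b = np.concatenate([pb, nb])
    y = np.concatenate([np.ones(half, dtype=np.int64), np.zeros(half, dtype=np.int64)])
    return idx_a, idx_b, y


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"AUROC undefined: {n_pos} positives, {n_neg} negatives"
        )
    ranks = rankdata(scores)  # average ranks give the half-tie credit
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def confusion_matrix(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> dict[str, int]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    return {
        "TP": int(np.sum(pred & (labels == 1))),
        "FP": int(np.sum(pred & (labels == 0))),
        "TN": int(np.sum(~pred & (labels == 0))),
        "FN": int(np.sum(~pred & (labels == 1))),
    }


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainConfig:
    max_epochs: int = 300
    patience: int = 10
    lr: float = 1e-3
    batch_size: int = 16
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class TrainLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)
    stopping_epoch: int = 0
    best_epoch: int = 0
    seed: int = 0


def _site_logits(state: ModelState, protein) -> ad.Tensor:
    emb = net.forward_embeddings(protein.chem, protein.k1, protein.k2,
                                 protein.graphs, state)
    return net.site_head(emb, state)


def _site_item_loss(state: ModelState, protein) -> tuple[ad.Tensor, np.ndarray, np.ndarray]:
    logits = _site_logits(state, protein)
    idx, y = protein.site_items
    picked = ad.gather_rows(logits, np.asarray(idx))
    return ad.bce_with_logits(picked, y), picked.data.reshape(-1), np.asarray(y)


def _pair_item_loss(state: ModelState, pair) -> tuple[ad.Tensor, np.ndarray, np.ndarray]:
    emb_a = net.forward_embeddings(pair.a.chem, pair.a.k1, pair.a.k2, pair.a.graphs, state)
    emb_b = net.forward_embeddings(pair.b.chem, pair.b.k1, pair.b.k2, pair.b.graphs, state)
    idx_a, idx_b, y = pair.pair_items
    logits = net.interaction_head(
        ad.gather_rows(emb_a, np.asarray(idx_a)),
        ad.gather_rows(emb_b, np.asarray(idx_b)),
        state,
    )
    return ad.bce_with_logits(logits, y), logits.data.reshape(-1), np.asarray(y)


def _make_batches(items: list, batch_size: int, task: str) -> list:
    """Partition items into mini-batches, merging pipeline items into
    block-diagonal graphs so each batch is one forward pass."""
    from . import pipeline as _pl

    mergeable = (_pl.FeaturizedProtein if task == "site" else _pl.FeaturizedPair)
    merge = _pl.merge_proteins if task == "site" else _pl.merge_pairs
    batches: list = []
    for start in range(0, len(items), batch_size):
        chunk = items[start:start + batch_size]
        if len(chunk) > 1 and all(isinstance(i, mergeable) for i in chunk):
            batches.append(merge(chunk))
        else:
            batches.extend(chunk)
    return batches


def train(
    state: ModelState,
    dataset: Sequence,
    config: TrainConfig,
    task: str = "interaction",
) -> tuple[ModelState, TrainLog]:
    """Fit ``state`` in place; returns it (at the best-validation epoch).

    ``dataset`` is a list of featurized proteins (``task='site'``, each with
    ``site_items``) or featurized pairs (``task='interaction'``, each with
    ``pair_items``). A seeded ``val_fraction`` of the items is held out; the
    optimizer steps on mini-batches of the remaining items; training stops
    when the validation loss has not improved for ``patience`` consecutive
    epochs or at ``max_epochs``.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    item_loss = _site_item_loss if task == "site" else _pair_item_loss
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n_val = max(1, int(round(config.val_fraction * len(dataset)))) if len(dataset) > 1 else 0
    val_items = [dataset[i] for i in order[:n_val]]
    train_items = [dataset[i] for i in order[n_val:]]

    # items produced by the featurization pipeline are merged into fixed
    # block-diagonal mini-batch graphs (single forward/backward per batch);
    # other item types fall back to one-item "batches"
    train_batches = _make_batches(train_items, config.batch_size, task)
    val_batches = _make_batches(val_items, len(val_items) or 1, task)

    optimizer = ad.Amsgrad(state.parameters(), lr=config.lr)
    log = TrainLog(seed=config.seed)
    best_val = np.inf
    best_values = state.copy_values()
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(len(train_batches))
        epoch_losses = []
        for b in perm:
            optimizer.zero_grad()
            total, _, _ = item_loss(state, train_batches[b])
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={float(total.data)})"
                )
            total.backward()
            optimizer.step()
            epoch_losses.append(float(total.data))
        log.train_loss.append(float(np.mean(epoch_losses)))

        if val_batches:
            v_losses, v_scores, v_labels = [], [], []
            for item in val_batches:
                loss, logits, y = item_loss(state, item)
                v_losses.append(float(loss.data))
                v_scores.append(logits)
                v_labels.append(y)
            val_loss = float(np.mean(v_losses))
            scores = np.concatenate(v_scores)
            labels = np.concatenate(v_labels)
            try:
                val_auc = auroc(scores, labels)
            except UndefinedMetricError:
                val_auc = float("nan")
        else:
            val_loss, val_auc = log.train_loss[-1], float("nan")
        log.val_loss.append(val_loss)
        log.val_auroc.append(val_auc)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_values = state.copy_values()
            log.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        log.stopping_epoch = epoch
        if since_best >= config.patience:
            break

    state.load_values(best_values)
    state.check_finite()
    return state, log


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Per-pair AUROC summary with 0.5-threshold confusion counts."""

    per_pair: list[dict] = field(default_factory=list)

    @property
    def mean_auroc(self) -> float:
        return float(np.mean([e["auroc"] for e in self.per_pair]))

    @property
    def confusion(self) -> dict[str, int]:
        total = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for e in self.per_pair:
            for k in total:
                total[k] += e["confusion"][k]
        return total

    def to_dict(self) -> dict:
        return {
            "mean_auroc": self.mean_auroc,
            "confusion": self.confusion,
            "per_pair": self.per_pair,
        }


def evaluate_pair(
    state: ModelState,
    pair,
    n_eval_pairs: int = 64,
    seed: int = 0,
    scores_fn=None,
) -> dict:
    """Balanced interaction AUROC + confusion entry for one featurized pair.

    ``scores_fn(idx_a, idx_b, pair) -> scores`` may replace the network (an
    oracle or baseline) while keeping the sampling and metric identical.
    """
    rng = np.random.default_rng(seed)
    idx_a, idx_b, y = sample_pairs(
        pair.a.labels, pair.b.labels, pair.a.graphs.points, pair.b.graphs.points,
        n_eval_pairs, rng, pair_name=getattr(pair, "name", "pair"),
    )
    if scores_fn is not None:
        scores = np.asarray(scores_fn(idx_a, idx_b, pair), dtype=float)
    else:
        emb_a = net.forward_embeddings(pair.a.chem, pair.a.k1, pair.a.k2,
                                       pair.a.graphs, state)
        emb_b = net.forward_embeddings(pair.b.chem, pair.b.k1, pair.b.k2,
                                       pair.b.graphs, state)
        scores = net.interaction_scores(
            ad.gather_rows(emb_a, idx_a), ad.gather_rows(emb_b, idx_b), state
        )
    return {
        "name": getattr(pair, "name", "pair"),
        "auroc": auroc(scores, y),
        "confusion": confusion_matrix(scores, y),
        "n_items": int(len(y)),
    }


def evaluate_sites(state: ModelState, protein) -> dict:
    """Site AUROC of one protein over all of its surface points."""
    emb = net.forward_embeddings(protein.chem, protein.k1, protein.k2,
                                 protein.graphs, state)
    scores = net.site_scores(emb, state)
    return {
        "auroc": auroc(scores, protein.labels),
        "confusion": confusion_matrix(scores, protein.labels),
        "n_items": int(len(protein.labels)),
    }
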