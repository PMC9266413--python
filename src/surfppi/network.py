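"""Trainable surface network: chemistry/geometry embeddings, radius
convolution with a learned scalar kernel, and the prediction heads.

Architecture (per surface point):

1. *Chemistry stream* — each of the k nearest-atom records (element one-hot,
   Fourier distance features, hydropathy, h-bond potential) is transformed by
   a small MLP, mean-pooled over the k atoms, then refined by one elementary
   graph-convolution layer over the point k-NN graph (learned self and
   neighbor-mean transforms).
2. *Geometry stream* — the principal curvatures (k1, k2) pass through a
   shallow two-layer MLP.
3. The two embeddings are concatenated and processed by ``n_conv_layers``
   radius convolutions: for receiver i and neighbors j within
   ``conv_radius``, a kernel MLP maps the raw differences
   ``(p_j - p_i, n_j - n_i)`` to a scalar weight ``w_ij``, and
   ``out_i = post(sum_j w_ij * pre(f_j))``. The point itself is one of its
   neighbors. This is translation-invariant by construction; an optional
   mode feeds the kernel rotation-invariant scalars of the pair geometry
   (normal/tangential components of the offset, normal alignment) instead
   of raw differences, making predictions exactly rigid-motion invariant.
4. Heads: a per-point logistic *site head* on the final 8-dim vector, and a
   symmetric *interaction head* on patch-embedding pairs,
   ``MLP([e_a + e_b, |e_a - e_b|])``, so the protein order cannot change the
   score.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import geometry
from .autodiff import SparsePattern, Tensor
from .chemfeat import VertexChemInput

__all__ = [
    "ModelConfig",
    "ModelState",
    "ConvGraph",
    "PointGraphs",
    "init_model",
    "build_point_graphs",
    "embed_chemistry",
    "embed_geometry",
    "radius_convolution",
    "site_head",
    "site_scores",
    "interaction_head",
    "interaction_scores",
    "forward_embeddings",
    "save_model",
    "load_model",
]

SCHEMA_TAG = "surfppi-model-v1"


@dataclass
class ModelConfig:
    """Hyper-parameters of the site/interaction networks.

    ``out_dim`` is fixed at 8 (the per-point descriptor the heads consume).
    ``use_chem`` / ``use_geom`` ablate a stream by replacing its embedding
    with zeros (dimensions are kept so the rest of the net is unchanged).
    """

    chem_embed_dim: int = 8
    geom_embed_dim: int = 8
    conv_radius: float = 12.0
    n_conv_layers: int = 3
    hidden_dim: int = 16
    kernel_hidden_dim: int = 8
    out_dim: int = 8
    k_atoms: int = 16
    # curvature neighborhood for featurization: ~4 A patch scale on 0.7 A
    # meshes, where curvature reflects interface-sized shape features rather
    # than atomic granularity (the estimator itself defaults to k=16)
    k_geom: int = 256
    F: int = 4
    gcn_k: int = 8
    use_chem: bool = True
    use_geom: bool = True
    rotation_invariant_kernel: bool = False

    def __post_init__(self) -> None:
        if self.out_dim != 8:
            raise ValueError("out_dim is fixed at 8")
        for name in ("chem_embed_dim", "geom_embed_dim", "n_conv_layers",
                     "hidden_dim", "kernel_hidden_dim", "k_atoms", "k_geom",
                     "gcn_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.conv_radius <= 0:
            raise ValueError("conv_radius must be positive")
        if self.F < 0:
            raise ValueError("F must be >= 0")

    @property
    def chem_record_dim(self) -> int:
        # one-hot(6) + gamma(1 + 2(F+1)) + hydropathy + hbond
        return 6 + 1 + 2 * (self.F + 1) + 2

    @property
    def fused_dim(self) -> int:
        return self.chem_embed_dim + self.geom_embed_dim


@dataclass
class ModelState:
    """All trainable parameter blocks plus the config that shaped them."""

    config: ModelConfig
    params: dict[str, Tensor]

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def check_finite(self) -> None:
        for name, p in self.params.items():
            if not np.all(np.isfinite(p.data)):
                raise FloatingPointError(f"non-finite parameter block {name}")

    def copy_values(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_values(self, values: dict[str, np.ndarray]) -> None:
        for k, v in values.items():
            self.params[k].data = v.copy()


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def init_model(config: ModelConfig, seed: int = 0) -> ModelState:
    """Seeded Glorot-normal initialization of every parameter block."""
    rng = np.random.default_rng(seed)
    p: dict[str, Tensor] = {}

    def lin(name: str, n_in: int, n_out: int, scale: float = 1.0) -> None:
        p[f"{name}.W"] = ad.param(_glorot(rng, n_in, n_out) * scale)
        p[f"{name}.b"] = ad.param(np.zeros(n_out))

    h = config.hidden_dim
    lin("chem_mlp.0", config.chem_record_dim, h)
    lin("chem_mlp.1", h, config.chem_embed_dim)
    lin("chem_gcn.self", config.chem_embed_dim, config.chem_embed_dim)
    lin("chem_gcn.neigh", config.chem_embed_dim, config.chem_embed_dim)
    lin("geom_mlp.0", 2, h)
    lin("geom_mlp.1", h, config.geom_embed_dim)
    dims = [config.fused_dim] + [h] * (config.n_conv_layers - 1) + [config.out_dim]
    for layer in range(config.n_conv_layers):
        lin(f"conv{layer}.kernel.0", 6, config.kernel_hidden_dim)
        # small kernel output so early weighted sums over O(100) neighbors
        # do not saturate the heads
        lin(f"conv{layer}.kernel.1", config.kernel_hidden_dim, 1, scale=0.1)
        lin(f"conv{layer}.pre", dims[layer], h)
        lin(f"conv{layer}.post", h, dims[layer + 1])
    lin("site.0", config.out_dim, h)
    lin("site.1", h, 1)
    lin("inter.0", 2 * config.out_dim, h)
    lin("inter.1", h, 1)
    return ModelState(config=config, params=p)


# ---------------------------------------------------------------------------
# point-graph construction


@dataclass
class ConvGraph:
    """Radius graph with per-edge geometric kernel input (E, 6)."""

    pattern: SparsePattern
    edge_feat: np.ndarray


@dataclass
class PointGraphs:
    """Precomputed graph structure of one protein's surface point set."""

    points: np.ndarray
    normals: np.ndarray
    gcn_pattern: SparsePattern
    gcn_values: np.ndarray
    conv: ConvGraph


def build_point_graphs(
    points: np.ndarray, normals: np.ndarray, config: ModelConfig
) -> PointGraphs:
    """Build the k-NN graph (chemistry GCN) and the radius graph (conv).

    The radius graph includes the self edge. With
    ``rotation_invariant_kernel`` the 6 kernel inputs per edge are the
    rotation-invariant scalars of the pair geometry (offset along the
    receiver normal, tangential offset magnitude, offset along the sender
    normal, normal alignment, normal-change projection onto the offset, and
    the plain distance) instead of the raw coordinate differences.
    """
    n = len(points)
    k = min(config.gcn_k + 1, n)
    nbr, _ = geometry.knn(points, points, k=k)
    dst = np.repeat(np.arange(n), k - 1)
    src = np.empty((n, k - 1), dtype=np.int64)
    for i in range(n):
        row = nbr[i][nbr[i] != i][: k - 1]
        src[i] = row
    src = src.reshape(-1)
    gcn_pattern = SparsePattern(dst, src, n, n)
    gcn_values = np.full(len(dst), 1.0 / (k - 1))

    lists = geometry.radius_neighbors(points, points, radius=config.conv_radius)
    counts = np.array([len(l) for l in lists])
    cdst = np.repeat(np.arange(n), counts)
    csrc = np.concatenate(lists) if counts.sum() else np.empty(0, dtype=np.int64)
    dp = points[csrc] - points[cdst]
    dn = normals[csrc] - normals[cdst]
    if config.rotation_invariant_kernel:
        ni, nj = normals[cdst], normals[csrc]
        t_normal = np.einsum("ej,ej->e", dp, ni)
        dist = np.linalg.norm(dp, axis=1)
        t_tang = np.sqrt(np.maximum(dist ** 2 - t_normal ** 2, 0.0))
        edge_feat = np.stack([
            t_normal,
            t_tang,
            np.einsum("ej,ej->e", dp, nj),
            np.einsum("ej,ej->e", ni, nj),
            np.einsum("ej,ej->e", dn, dp),
            dist,
        ], axis=1)
    else:
        edge_feat = np.concatenate([dp, dn], axis=1)
    conv = ConvGraph(pattern=SparsePattern(cdst, csrc, n, n), edge_feat=edge_feat)
    return PointGraphs(points=np.asarray(points, float), normals=np.asarray(normals, float),
                       gcn_pattern=gcn_pattern, gcn_values=gcn_values, conv=conv)


# ---------------------------------------------------------------------------
# forward passes


def _linear(state: ModelState, name: str, x: Tensor) -> Tensor:
    return x @ state.params[f"{name}.W"] + state.params[f"{name}.b"]


def embed_chemistry(
    chem: VertexChemInput, graphs: PointGraphs, state: ModelState
) -> Tensor:
    """Chemistry embedding: record MLP -> mean over k atoms -> one GCN layer."""
    cfg = state.config
    packed = chem.packed()
    p, k, d = packed.shape
    if d != cfg.chem_record_dim:
        raise ValueError(
            f"chem record dim {d} does not match config ({cfg.chem_record_dim}); "
            "check F"
        )
    x = ad.constant(packed.reshape(p * k, d))
    h = ad.relu(_linear(state, "chem_mlp.0", x))
    h = _linear(state, "chem_mlp.1", h)
    pooled = ad.mean_pool(h, k)
    neigh = ad.spmm(graphs.gcn_pattern, ad.constant(graphs.gcn_values), pooled)
    out = _linear(state, "chem_gcn.self", pooled) + (neigh @ state.params["chem_gcn.neigh.W"])
    return ad.relu(out)


def embed_geometry(k1: np.ndarray, k2: np.ndarray, state: ModelState) -> Tensor:
    """Geometry embedding: shallow MLP on the principal-curvature pair."""
    kk = np.stack([np.asarray(k1, float), np.asarray(k2, float)], axis=1)
    if not np.all(np.isfinite(kk)):
        raise ValueError("non-finite principal curvatures")
    h = ad.relu(_linear(state, "geom_mlp.0", ad.constant(kk)))
    return _linear(state, "geom_mlp.1", h)


def radius_convolution(graphs: PointGraphs, feats: Tensor, state: ModelState) -> Tensor:
    """Stacked radius convolutions; returns the final (P, out_dim) features."""
    cfg = state.config
    x = feats
    for layer in range(cfg.n_conv_layers):
        g = ad.relu(_linear(state, f"conv{layer}.pre", x))
        e = ad.constant(graphs.conv.edge_feat)
        w = ad.tanh(_linear(state, f"conv{layer}.kernel.0", e))
        w = _linear(state, f"conv{layer}.kernel.1", w)
        agg = ad.spmm(graphs.conv.pattern, w, g)
        x = _linear(state, f"conv{layer}.post", agg)
        if layer < cfg.n_conv_layers - 1:
            x = ad.relu(x)
    return x


def forward_embeddings(
    chem: VertexChemInput,
    k1: np.ndarray,
    k2: np.ndarray,
    graphs: PointGraphs,
    state: ModelState,
) -> Tensor:
    """Full per-point pipeline: stream embeddings -> fusion -> convolutions."""
    cfg = state.config
    p = len(graphs.points)
    if cfg.use_chem:
        c = embed_chemistry(chem, graphs, state)
    else:
        c = ad.constant(np.zeros((p, cfg.chem_embed_dim)))
    if cfg.use_geom:
        g = embed_geometry(k1, k2, state)
    else:
        g = ad.constant(np.zeros((p, cfg.geom_embed_dim)))
    fused = ad.concat([c, g], axis=1)
    return radius_convolution(graphs, fused, state)


def site_head(embeddings: Tensor, state: ModelState) -> Tensor:
    """Per-point site logits (apply a logistic to get scores in (0, 1))."""
    h = ad.relu(_linear(state, "site.0", embeddings))
    return _linear(state, "site.1", h)


def site_scores(embeddings: Tensor, state: ModelState) -> np.ndarray:
    return ad.sigmoid(site_head(embeddings, state)).data.reshape(-1)


def interaction_head(emb_a: Tensor, emb_b: Tensor, state: ModelState) -> Tensor:
    """Symmetric pair logits from two patch embeddings (order-invariant)."""
    s = emb_a + emb_b
    d = ad.absolute(emb_a - emb_b)
    h = ad.relu(_linear(state, "inter.0", ad.concat([s, d], axis=1)))
    return _linear(state, "inter.1", h)


def interaction_scores(emb_a: Tensor, emb_b: Tensor, state: ModelState) -> np.ndarray:
    return ad.sigmoid(interaction_head(emb_a, emb_b, state)).data.reshape(-1)


# ---------------------------------------------------------------------------
# serialization


def save_model(state: ModelState, path: str | Path) -> None:
    """Single-archive serialization (NPZ with an embedded config record)."""
    meta = {"schema": SCHEMA_TAG, "config": asdict(state.config)}
    arrays = {k.replace(".", "__"): v.data for k, v in state.params.items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path: str | Path) -> ModelState:
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta.get("schema") != SCHEMA_TAG:
            raise ValueError(f"unknown model schema in {path}")
        config = ModelConfig(**meta["config"])
        state = init_model(config, seed=0)
        for k in state.params:
            state.params[k].data = archive[k.replace(".", "__")].copy()
    return state
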