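"""End-to-end featurization glue: atoms -> surface -> network-ready graphs.

The surface mesh is built at full resolution (labels and interface geometry
use every vertex); the network then operates on a seeded uniform subsample
of the vertices (``n_points``), which keeps radius-graph sizes tractable
while the subsampled points remain true mesh vertices and inherit their
full-resolution interface labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chemfeat, geometry, network, surfacing, train_eval
from .network import ModelConfig, PointGraphs
from .structures_io import AtomCloud

__all__ = [
    "PipelineConfig",
    "FeaturizedProtein",
    "FeaturizedPair",
    "featurize_protein",
    "featurize_pair",
    "merge_proteins",
    "merge_pairs",
]


@dataclass
class PipelineConfig:
    """Featurization parameters (Angstrom units throughout)."""

    spacing: float = surfacing.DEFAULT_SPACING
    probe_radius: float = surfacing.DEFAULT_PROBE_RADIUS
    interface_cutoff: float = train_eval.DEFAULT_INTERFACE_CUTOFF
    hbond_cutoff: float = chemfeat.DEFAULT_HBOND_CUTOFF
    n_points: int = 256
    n_site_items: int = 64
    n_pair_items: int = 32


@dataclass
class FeaturizedProtein:
    """One protein's network inputs at the subsampled surface points."""

    graphs: PointGraphs
    chem: chemfeat.VertexChemInput
    k1: np.ndarray
    k2: np.ndarray
    labels: np.ndarray | None = None
    site_items: tuple[np.ndarray, np.ndarray] | None = None
    point_indices: np.ndarray | None = None
    mesh: surfacing.SurfaceMesh | None = None

    @property
    def n_points(self) -> int:
        return len(self.graphs.points)


@dataclass
class FeaturizedPair:
    """A featurized protein pair with balanced sampled training items."""

    a: FeaturizedProtein
    b: FeaturizedProtein
    pair_items: tuple[np.ndarray, np.ndarray, np.ndarray]
    name: str = "pair"


def _subsample(n_total: int, n_points: int, rng: np.random.Generator) -> np.ndarray:
    if n_total <= n_points:
        return np.arange(n_total)
    return np.sort(rng.choice(n_total, size=n_points, replace=False))


def _labeled_subsample(
    labels: np.ndarray, n_points: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform vertex subsample with a minimal guarantee: if the uniform
    draw misses the interface entirely (possible for very small contact
    patches) but the full mesh has positives, up to four positive vertices
    replace random picks. The subsample must stay essentially uniform —
    enriching interface points noticeably would imprint a local
    point-density signature that the radius convolution can read directly,
    short-circuiting the chemical/geometric features."""
    n_total = len(labels)
    if n_total <= n_points:
        return np.arange(n_total)
    idx = rng.choice(n_total, size=n_points, replace=False)
    pos = np.flatnonzero(labels == 1)
    if len(pos) > 0 and not np.any(labels[idx] == 1):
        add = rng.choice(pos, size=min(4, len(pos)), replace=False)
        idx[rng.choice(n_points, size=len(add), replace=False)] = add
        idx = np.unique(idx)
    return np.sort(idx)


def featurize_protein(
    cloud: AtomCloud,
    model_config: ModelConfig,
    pipe: PipelineConfig,
    rng: np.random.Generator,
    mesh: surfacing.SurfaceMesh | None = None,
    keep_mesh: bool = False,
    indices: np.ndarray | None = None,
) -> FeaturizedProtein:
    """Surface, subsample, and featurize one protein.

    A precomputed ``mesh`` (e.g. loaded from an external surfacer) bypasses
    the distance-field surfacing step; explicit vertex ``indices`` bypass
    the uniform subsample.
    """
    if mesh is None:
        mesh = surfacing.build_surface(
            cloud, spacing=pipe.spacing, probe_radius=pipe.probe_radius
        )
    idx = indices if indices is not None \
        else _subsample(mesh.n_vertices, pipe.n_points, rng)
    points = mesh.vertices[idx]
    normals = mesh.normals[idx]
    k_geom = min(model_config.k_geom, mesh.n_vertices - 1)
    k1, k2, _ = geometry.principal_curvatures(mesh, indices=idx, k_geom=k_geom)
    chem = chemfeat.gather_vertex_chem_inputs(
        points, cloud, k=min(model_config.k_atoms, cloud.n_atoms),
        F=model_config.F, hbond_cutoff=pipe.hbond_cutoff,
    )
    graphs = network.build_point_graphs(points, normals, model_config)
    return FeaturizedProtein(
        graphs=graphs, chem=chem, k1=k1, k2=k2, point_indices=idx,
        mesh=mesh if keep_mesh else None,
    )


def featurize_pair(
    cloud_a: AtomCloud,
    cloud_b: AtomCloud,
    model_config: ModelConfig,
    pipe: PipelineConfig,
    rng: np.random.Generator,
    name: str = "pair",
    sample_items: bool = True,
) -> FeaturizedPair:
    """Featurize both partners, label interfaces, and sample training items.

    Interface labels are computed on the full meshes (vertex-to-vertex,
    ``interface_cutoff``) before subsampling; the (uniform) subsampled
    points inherit their full-mesh labels. Site items (balanced vertex/label
    draws) and pair items (balanced positive/negative patch pairs) are
    sampled with the supplied generator.
    """
    mesh_a = surfacing.build_surface(cloud_a, spacing=pipe.spacing,
                                     probe_radius=pipe.probe_radius)
    mesh_b = surfacing.build_surface(cloud_b, spacing=pipe.spacing,
                                     probe_radius=pipe.probe_radius)
    full_a, full_b = train_eval.label_interface(
        mesh_a, mesh_b, cutoff=pipe.interface_cutoff
    )
    idx_a = _labeled_subsample(full_a, pipe.n_points, rng)
    idx_b = _labeled_subsample(full_b, pipe.n_points, rng)
    fa = featurize_protein(cloud_a, model_config, pipe, rng, mesh=mesh_a,
                           indices=idx_a)
    fb = featurize_protein(cloud_b, model_config, pipe, rng, mesh=mesh_b,
                           indices=idx_b)
    fa.labels = full_a[fa.point_indices]
    fb.labels = full_b[fb.point_indices]
    pair_items = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64))
    if sample_items:
        fa.site_items = train_eval.sample_sites(fa.labels, pipe.n_site_items, rng)
        fb.site_items = train_eval.sample_sites(fb.labels, pipe.n_site_items, rng)
        pair_items = train_eval.sample_pairs(
            fa.labels, fb.labels, fa.graphs.points, fb.graphs.points,
            pipe.n_pair_items, rng, pair_name=name,
        )
    return FeaturizedPair(a=fa, b=fb, pair_items=pair_items, name=name)


# ---------------------------------------------------------------------------
# graph batching: several proteins merged into one block-diagonal graph, so a
# whole mini-batch runs as a single forward/backward pass


def _merge_patterns(
    patterns: list[network.SparsePattern], offsets: np.ndarray, n_total: int
) -> network.SparsePattern:
    dst = np.concatenate([p.dst + off for p, off in zip(patterns, offsets)])
    src = np.concatenate([p.src + off for p, off in zip(patterns, offsets)])
    return network.SparsePattern(dst, src, n_total, n_total)


def merge_proteins(proteins: list[FeaturizedProtein]) -> FeaturizedProtein:
    """Concatenate several featurized proteins into one disconnected graph.

    Point indices in ``site_items`` are shifted by the per-protein offsets;
    the result forwards through the network exactly as the separate
    proteins would (the graphs share no edges). The merged ``chem`` keeps
    only the arrays the network consumes; per-protein atom neighbor indices
    are not meaningful after merging.
    """
    sizes = np.array([p.n_points for p in proteins])
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    n_total = int(sizes.sum())
    chem = chemfeat.VertexChemInput(
        neighbor_indices=np.concatenate([p.chem.neighbor_indices for p in proteins]),
        distances=np.concatenate([p.chem.distances for p in proteins]),
        element_onehot=np.concatenate([p.chem.element_onehot for p in proteins]),
        fourier=np.concatenate([p.chem.fourier for p in proteins]),
        hydrophobicity=np.concatenate([p.chem.hydrophobicity for p in proteins]),
        hbond=np.concatenate([p.chem.hbond for p in proteins]),
        rel_pos=np.concatenate([p.chem.rel_pos for p in proteins]),
    )
    graphs = network.PointGraphs(
        points=np.concatenate([p.graphs.points for p in proteins]),
        normals=np.concatenate([p.graphs.normals for p in proteins]),
        gcn_pattern=_merge_patterns([p.graphs.gcn_pattern for p in proteins],
                                    offsets, n_total),
        gcn_values=np.concatenate([p.graphs.gcn_values for p in proteins]),
        conv=network.ConvGraph(
            pattern=_merge_patterns([p.graphs.conv.pattern for p in proteins],
                                    offsets, n_total),
            edge_feat=np.concatenate([p.graphs.conv.edge_feat for p in proteins]),
        ),
    )
    labels = None
    if all(p.labels is not None for p in proteins):
        labels = np.concatenate([p.labels for p in proteins])
    site_items = None
    if all(p.site_items is not None for p in proteins):
        site_items = (
            np.concatenate([p.site_items[0] + off
                            for p, off in zip(proteins, offsets)]),
            np.concatenate([p.site_items[1] for p in proteins]),
        )
    return FeaturizedProtein(graphs=graphs, chem=chem,
                             k1=np.concatenate([p.k1 for p in proteins]),
                             k2=np.concatenate([p.k2 for p in proteins]),
                             labels=labels, site_items=site_items)


def merge_pairs(pairs: list[FeaturizedPair]) -> FeaturizedPair:
    """Merge featurized pairs (A-sides together, B-sides together)."""
    merged_a = merge_proteins([p.a for p in pairs])
    merged_b = merge_proteins([p.b for p in pairs])
    off_a = np.concatenate([[0], np.cumsum([p.a.n_points for p in pairs])[:-1]])
    off_b = np.concatenate([[0], np.cumsum([p.b.n_points for p in pairs])[:-1]])
    items = (
        np.concatenate([p.pair_items[0] + oa for p, oa in zip(pairs, off_a)]),
        np.concatenate([p.pair_items[1] + ob for p, ob in zip(pairs, off_b)]),
        np.concatenate([p.pair_items[2] for p in pairs]),
    )
    return FeaturizedPair(a=merged_a, b=merged_b, pair_items=items,
                          name="+".join(p.name for p in pairs[:3]))
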