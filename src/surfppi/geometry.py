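"""Spatial queries and discrete curvature estimation.

Curvature is obtained from a least-squares estimate of the shape operator:
around each vertex, relative positions and relative normals of the k nearest
mesh vertices are projected into the vertex's tangent plane, and the 2x2
linear map best explaining "normal change per unit tangent step" is fitted.
Its symmetrized eigenvalues are the principal curvatures k1 <= k2 (1/A).

Sign convention: with outward normals a convex surface (sphere of radius r)
has k1 = k2 = +1/r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .surfacing import SurfaceMesh

__all__ = [
    "TangentFrame",
    "ShapeOperatorEstimate",
    "knn",
    "radius_neighbors",
    "build_tangent_frame",
    "build_tangent_frames",
    "estimate_shape_operator",
    "principal_curvatures",
    "write_curvatures_csv",
]

_RIDGE = 1e-8
_DEGENERACY_RTOL = 1e-6


@dataclass
class TangentFrame:
    """Right-handed orthonormal frame {u, v, n} at a surface point."""

    origin: np.ndarray
    n: np.ndarray
    u: np.ndarray
    v: np.ndarray


@dataclass
class ShapeOperatorEstimate:
    """Symmetrized 2x2 shape operator in the {u, v} basis with eigenvalues."""

    S: np.ndarray
    k1: float
    k2: float
    degenerate: bool = False


def knn(query_points: np.ndarray, ref_points: np.ndarray, k: int):
    """Exact k nearest references per query point.

    Ties are broken deterministically toward the lower reference index by
    over-querying a small margin and re-sorting candidates on
    (distance, index); this reproduces brute-force ``argsort`` semantics.

    Returns ``(indices, distances)``, both (M, k).
    """
    query_points = np.atleast_2d(np.asarray(query_points, dtype=float))
    ref_points = np.atleast_2d(np.asarray(ref_points, dtype=float))
    n_ref = len(ref_points)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n_ref:
        raise ValueError(f"k={k} exceeds the {n_ref} reference points")
    k_eff = min(n_ref, k + 8)
    dist, idx = cKDTree(ref_points).query(query_points, k=k_eff)
    if k_eff == 1:
        dist, idx = dist[:, None], idx[:, None]
    order = np.lexsort((idx, dist), axis=-1)
    rows = np.arange(len(query_points))[:, None]
    return idx[rows, order][:, :k], dist[rows, order][:, :k]


def radius_neighbors(
    query_points: np.ndarray,
    ref_points: np.ndarray,
    radius: float,
    exclude_self: bool = False,
) -> list[np.ndarray]:
    """All reference points within ``radius`` (inclusive) of each query.

    ``exclude_self`` removes the identity match and only applies when the
    query and reference arrays are the very same array object. Empty
    neighborhoods are returned as empty arrays.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    query_points = np.atleast_2d(np.asarray(query_points, dtype=float))
    same = ref_points is query_points or (
        isinstance(ref_points, np.ndarray) and ref_points.base is query_points
    )
    ref_arr = np.atleast_2d(np.asarray(ref_points, dtype=float))
    lists = cKDTree(ref_arr).query_ball_point(query_points, r=radius)
    out = []
    for i, lst in enumerate(lists):
        arr = np.sort(np.asarray(lst, dtype=np.int64))
        if exclude_self and same:
            arr = arr[arr != i]
        out.append(arr)
    return out


def build_tangent_frame(normal: np.ndarray, origin: np.ndarray | None = None) -> TangentFrame:
    """Deterministic orthonormal frame from a unit normal.

    u = normalize(e x n) with e the global axis least parallel to n
    (ties resolved x before y before z); v = n x u closes a right-handed
    triple with det[u v n] = +1.
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("cannot build a tangent frame from a zero normal")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"normal must be unit length, |n|={norm:.6f}")
    axis = int(np.argmin(np.abs(n)))
    e = np.zeros(3)
    e[axis] = 1.0
    u = np.cross(e, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    if origin is None:
        origin = np.zeros(3)
    return TangentFrame(origin=np.asarray(origin, dtype=float), n=n, u=u, v=v)


def build_tangent_frames(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tangent bases: returns (u, v), each (N, 3)."""
    n = np.asarray(normals, dtype=float)
    axis = np.argmin(np.abs(n), axis=1)
    e = np.eye(3)[axis]
    u = np.cross(e, n)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(n, u)
    return u, v


def principal_curvatures(
    mesh: SurfaceMesh,
    indices: np.ndarray | None = None,
    k_geom: int = 16,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal curvatures (k1 <= k2, 1/A) at selected mesh vertices.

    Vectorized shape-operator fit over all requested vertices; the self
    vertex is excluded from its own neighbor set. Near-rank-deficient
    neighborhoods (collinear tangent projections) are stabilized with an
    L2 ridge of 1e-8 and flagged.

    Returns ``(k1, k2, degenerate_mask)``.
    """
    if mesh.normals is None:
        raise ValueError("mesh needs vertex normals; run compute_vertex_normals first")
    if k_geom < 4:
        raise ValueError(f"k_geom must be >= 4, got {k_geom}")
    verts = mesh.vertices
    if indices is None:
        indices = np.arange(len(verts))
    indices = np.asarray(indices, dtype=np.int64)

    nbr_idx, _ = knn(verts[indices], verts, k=k_geom + 1)
    # drop the self column (distance zero, lowest index order puts it first
    # only among exact ties; mask explicitly instead)
    keep = nbr_idx != indices[:, None]
    # each row keeps exactly k_geom entries; if a row has no self match
    # (duplicate vertices), drop its last entry
    out_idx = np.empty((len(indices), k_geom), dtype=np.int64)
    for r in range(len(indices)):
        row = nbr_idx[r][keep[r]]
        out_idx[r] = row[:k_geom]
    nbr_idx = out_idx

    p0 = verts[indices]
    n0 = mesh.normals[indices]
    u, v = build_tangent_frames(n0)

    dp = verts[nbr_idx] - p0[:, None, :]          # (P, k, 3)
    dn = mesh.normals[nbr_idx] - n0[:, None, :]   # (P, k, 3)
    X = np.stack([np.einsum("pkd,pd->pk", dp, u),
                  np.einsum("pkd,pd->pk", dp, v)], axis=-1)  # (P, k, 2)
    Y = np.stack([np.einsum("pkd,pd->pk", dn, u),
                  np.einsum("pkd,pd->pk", dn, v)], axis=-1)  # (P, k, 2)

    XtX = np.einsum("pki,pkj->pij", X, X)          # (P, 2, 2)
    XtY = np.einsum("pki,pkj->pij", X, Y)          # (P, 2, 2)

    tr = XtX[:, 0, 0] + XtX[:, 1, 1]
    det = XtX[:, 0, 0] * XtX[:, 1, 1] - XtX[:, 0, 1] * XtX[:, 1, 0]
    # eigenvalue lower bound of the 2x2 Gram matrix
    lam_min = tr / 2 - np.sqrt(np.maximum((tr / 2) ** 2 - det, 0.0))
    degenerate = lam_min <= _DEGENERACY_RTOL * np.maximum(tr, 1e-30)

    XtX = XtX + _RIDGE * np.eye(2)
    # closed-form 2x2 inverse
    det_r = XtX[:, 0, 0] * XtX[:, 1, 1] - XtX[:, 0, 1] * XtX[:, 1, 0]
    inv = np.empty_like(XtX)
    inv[:, 0, 0] = XtX[:, 1, 1]
    inv[:, 1, 1] = XtX[:, 0, 0]
    inv[:, 0, 1] = -XtX[:, 0, 1]
    inv[:, 1, 0] = -XtX[:, 1, 0]
    inv /= det_r[:, None, None]

    At = inv @ XtY            # A^T, rows solve X A^T ~ Y
    A = np.swapaxes(At, 1, 2)
    S = 0.5 * (A + At)        # symmetrized shape operator in {u, v}

    mean = 0.5 * (S[:, 0, 0] + S[:, 1, 1])
    half_diff = 0.5 * (S[:, 0, 0] - S[:, 1, 1])
    rad = np.sqrt(half_diff ** 2 + S[:, 0, 1] ** 2)
    return mean - rad, mean + rad, degenerate


def estimate_shape_operator(
    mesh: SurfaceMesh, vertex_index: int, k_geom: int = 16
) -> ShapeOperatorEstimate:
    """Shape-operator estimate at a single vertex (see module docstring)."""
    k1, k2, degenerate = principal_curvatures(
        mesh, indices=np.array([vertex_index]), k_geom=k_geom
    )
    # rebuild S for reporting: S has eigenvalues (k1, k2); recompute directly
    S = _shape_matrix(mesh, vertex_index, k_geom)
    return ShapeOperatorEstimate(
        S=S, k1=float(k1[0]), k2=float(k2[0]), degenerate=bool(degenerate[0])
    )


def _shape_matrix(mesh: SurfaceMesh, vertex_index: int, k_geom: int) -> np.ndarray:
    verts = mesh.vertices
    nbr_idx, _ = knn(verts[[vertex_index]], verts, k=k_geom + 1)
    row = nbr_idx[0][nbr_idx[0] != vertex_index][:k_geom]
    n0 = mesh.normals[vertex_index]
    frame = build_tangent_frame(n0, origin=verts[vertex_index])
    dp = verts[row] - verts[vertex_index]
    dn = mesh.normals[row] - n0
    X = np.stack([dp @ frame.u, dp @ frame.v], axis=-1)
    Y = np.stack([dn @ frame.u, dn @ frame.v], axis=-1)
    At = np.linalg.solve(X.T @ X + _RIDGE * np.eye(2), X.T @ Y)
    return 0.5 * (At.T + At)


def write_curvatures_csv(
    path, indices: np.ndarray, k1: np.ndarray, k2: np.ndarray
) -> None:
    """Per-vertex curvature sidecar: ``vertex_index,k1,k2`` (1/A)."""
    with open(path, "w") as fh:
        fh.write("vertex_index,k1,k2\n")
        for i, a, b in zip(np.asarray(indices), k1, k2):
            fh.write(f"{int(i)},{a:.6f},{b:.6f}\n")
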