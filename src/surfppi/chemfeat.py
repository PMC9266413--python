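"""Per-vertex chemical inputs aggregated from nearby atoms.

For every surface point the k nearest atoms contribute a record of:

* element one-hot over ``{C, N, O, S, H, other}``,
* Fourier distance features ``gamma(d) = (d, cos(d/2^0), sin(d/2^0), ...,
  cos(d/2^F), sin(d/2^F))`` encoding the vertex-atom distance at F+1
  dyadic scales,
* the Kyte-Doolittle hydropathy of the atom's residue, rescaled to [-1, 1],
* a hydrogen-bond potential at the vertex (distance-weighted
  donor/acceptor surrogate; no angular term), and
* the relative atom position (Angstrom).

These form a directed vertex<-atom k-NN graph consumed by the chemistry
embedding stream of the network. All quantities are relative, so the whole
feature block is invariant under joint rigid translation of mesh and atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import geometry
from .structures_io import AtomCloud
from .surfacing import SurfaceMesh

__all__ = [
    "KYTE_DOOLITTLE",
    "FourierConfig",
    "VertexChemInput",
    "fourier_distance_features",
    "residue_hydrophobicity",
    "hbond_potential",
    "hbond_potentials",
    "gather_vertex_chem_inputs",
]

#: Kyte-Doolittle hydropathy index (raw scale, -4.5 .. +4.5).
KYTE_DOOLITTLE: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5, "MET": 1.9,
    "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8, "TRP": -0.9,
    "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5, "GLN": -3.5,
    "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

_KD_SCALE = 4.5

DEFAULT_HBOND_CUTOFF = 3.0


@dataclass(frozen=True)
class FourierConfig:
    """Order of the Fourier distance featurization (output length 1+2(F+1))."""

    F: int = 4

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError(f"Fourier order F must be >= 0, got {self.F}")

    @property
    def n_features(self) -> int:
        return 1 + 2 * (self.F + 1)


def fourier_distance_features(d, F: int = 4) -> np.ndarray:
    """Fourier featurization of a non-negative distance (Angstrom).

    ``gamma(d) = (d, cos(d/2^0), sin(d/2^0), ..., cos(d/2^F), sin(d/2^F))``
    with dyadically growing length scales. Accepts scalars or arrays; the
    feature axis is appended last.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    scales = 2.0 ** np.arange(F + 1)
    phases = d[..., None] / scales  # (..., F+1)
    out = np.empty(d.shape + (1 + 2 * (F + 1),))
    out[..., 0] = d
    out[..., 1::2] = np.cos(phases)
    out[..., 2::2] = np.sin(phases)
    return out


def residue_hydrophobicity(residue_name: str) -> float:
    """Kyte-Doolittle hydropathy rescaled to [-1, 1] (ILE -> +1, ARG -> -1).

    Unknown residue codes (modified residues, pseudo-residues) map to 0.0
    with a warning.
    """
    key = residue_name.upper().strip()
    if key not in KYTE_DOOLITTLE:
        warnings.warn(f"unknown residue {residue_name!r}; hydrophobicity set to 0")
        return 0.0
    return KYTE_DOOLITTLE[key] / _KD_SCALE


def _residue_hydropathies(cloud: AtomCloud) -> np.ndarray:
    vals = np.empty(cloud.n_atoms)
    unknown: set[str] = set()
    for i, name in enumerate(cloud.residue_names):
        key = name.upper().strip()
        if key in KYTE_DOOLITTLE:
            vals[i] = KYTE_DOOLITTLE[key] / _KD_SCALE
        else:
            vals[i] = 0.0
            unknown.add(name)
    for name in sorted(unknown):
        warnings.warn(f"unknown residue {name!r}; hydrophobicity set to 0")
    return vals


def hbond_potentials(
    positions: np.ndarray, cloud: AtomCloud, cutoff: float = DEFAULT_HBOND_CUTOFF
) -> np.ndarray:
    """Hydrogen-bond potential in [-1, 1] at each query position.

    Donor proximity (nitrogen atoms) contributes ``+max(0, 1 - d/cutoff)``
    and acceptor proximity (oxygen atoms) ``-max(0, 1 - d/cutoff)``, each
    evaluated at the nearest atom of its class; the two terms are summed and
    clamped. This is a deliberately simple geometric surrogate for a full
    donor/acceptor geometry model: no angular (ideal-geometry) weighting.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    codes = cloud.element_codes
    out = np.zeros(len(positions))
    for code, sign in ((1, +1.0), (2, -1.0)):  # N donors, O acceptors
        atom_pos = cloud.positions[codes == code]
        if len(atom_pos) == 0:
            continue
        _, dist = geometry.knn(positions, atom_pos, k=1)
        out += sign * np.maximum(0.0, 1.0 - dist[:, 0] / cutoff)
    return np.clip(out, -1.0, 1.0)


def hbond_potential(
    position: np.ndarray, cloud: AtomCloud, cutoff: float = DEFAULT_HBOND_CUTOFF
) -> float:
    """Scalar convenience wrapper around :func:`hbond_potentials`."""
    return float(hbond_potentials(np.asarray(position)[None, :], cloud, cutoff)[0])


@dataclass
class VertexChemInput:
    """Directed vertex<-atom k-NN feature graph (arrays share leading (P, k)).

    ``element_onehot`` (P, k, 6), ``fourier`` (P, k, 1+2(F+1)),
    ``hydrophobicity`` (P, k), ``hbond`` (P, k), ``rel_pos`` (P, k, 3),
    ``neighbor_indices``/``distances`` (P, k) with distances ascending.
    """

    neighbor_indices: np.ndarray
    distances: np.ndarray
    element_onehot: np.ndarray
    fourier: np.ndarray
    hydrophobicity: np.ndarray
    hbond: np.ndarray
    rel_pos: np.ndarray

    @property
    def k(self) -> int:
        return self.neighbor_indices.shape[1]

    def packed(self) -> np.ndarray:
        """(P, k, D) concatenation of the scalar/vector chemical features
        (one-hot + Fourier + hydropathy + h-bond), excluding rel_pos."""
        return np.concatenate(
            [
                self.element_onehot,
                self.fourier,
                self.hydrophobicity[..., None],
                self.hbond[..., None],
            ],
            axis=-1,
        )


def gather_vertex_chem_inputs(
    mesh: SurfaceMesh | np.ndarray,
    cloud: AtomCloud,
    k: int = 16,
    F: int = 4,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> VertexChemInput:
    """Assemble the chemical input graph for every surface point.

    ``mesh`` may be a :class:`SurfaceMesh` or a plain (P, 3) position array.
    Each point receives its ``k`` nearest atoms sorted by ascending distance.
    The vertex-level h-bond potential is replicated across the k entries.
    """
    points = mesh.vertices if isinstance(mesh, SurfaceMesh) else np.atleast_2d(mesh)
    if k > cloud.n_atoms:
        raise ValueError(f"k={k} exceeds the {cloud.n_atoms} atoms in the cloud")
    idx, dist = geometry.knn(points, cloud.positions, k=k)
    onehot = np.zeros((len(points), k, 6))
    codes = cloud.element_codes[idx]
    p_idx, k_idx = np.meshgrid(np.arange(len(points)), np.arange(k), indexing="ij")
    onehot[p_idx, k_idx, codes] = 1.0
    hydro = _residue_hydropathies(cloud)[idx]
    hb = hbond_potentials(points, cloud, cutoff=hbond_cutoff)
    return VertexChemInput(
        neighbor_indices=idx,
        distances=dist,
        element_onehot=onehot,
        fourier=fourier_distance_features(dist, F=F),
        hydrophobicity=hydro,
        hbond=np.repeat(hb[:, None], k, axis=1),
        rel_pos=cloud.positions[idx] - points[:, None, :],
    )
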