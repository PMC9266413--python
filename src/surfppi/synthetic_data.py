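"""Seeded pseudo-protein pairs with planted interface complementarity.

The generator emits "lock" and "key" blobs: atoms quasi-uniformly covering
a jittered sphere, with a polar cap carrying a smooth radial bump (lock) or
a matching depression (key), and with hydrophobic residues concentrated in
the cap. Complementarity is therefore both geometric (a curvature signal
for the geometry stream) and chemical (a hydropathy signal for the
chemistry stream). Pairs are posed so the bump sits in the depression with
a configurable surface gap, then given a random global rigid motion.

Mirroring the diversity of real interfaces — some are dominated by shape
complementarity, others by hydrophobic chemistry — each generated pair
draws an interface *kind*: ``both`` (full bump + hydrophobic cap),
``geometric`` (bump only, no hydrophobic bias), or ``chemical``
(hydrophobic cap with only a shallow contact dome that keeps the surfaces
conformal but carries almost no curvature signal). A model must therefore
exploit both feature streams to score well across a dataset; ablating
either stream loses the pairs of the kind that stream alone cannot see.

Atoms are serialized as ordinary PDB ATOM records with pseudo-residues
(one residue per atom), so the full real-data path — PDB parsing,
surfacing, featurization — runs unchanged on synthetic data.

Also provides exact parametric meshes (sphere, plane, cylinder, saddle)
with analytic normals for curvature testing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .structures_io import Atom, AtomCloud, ProteinPair, write_pdb
from .surfacing import SurfaceMesh, VDW_RADII, DEFAULT_PROBE_RADIUS, atom_radii

__all__ = [
    "HYDROPHOBIC_RESIDUES",
    "ALL_RESIDUES",
    "SynthConfig",
    "SynthPair",
    "make_blob",
    "pose_pair",
    "make_pair",
    "make_dataset",
    "analytic_fixture",
]

#: Kyte-Doolittle-positive residues planted in the interface cap.
HYDROPHOBIC_RESIDUES = ("ILE", "VAL", "LEU", "PHE", "ALA", "MET")

ALL_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: element palette draw weights, roughly protein heavy-atom composition
_ELEMENTS = ("C", "N", "O", "S")
_ELEMENT_WEIGHTS = (0.62, 0.17, 0.20, 0.01)


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters of one pseudo-protein blob.

    ``cap_angle`` is the angular radius (radians) of the interface cap
    around the +z pole; ``bump_height`` is the peak radial offset (A), added
    for a lock and subtracted for a key; ``hydrophobic_correlation`` is the
    probability that a cap atom draws its residue from the hydrophobic set.

    ``kind_probs`` are the draw probabilities of the interface kinds
    (both, geometric, chemical) for generated pairs; ``contact_dome_height``
    is the shallow complementary dome (A) that keeps chemical-kind surfaces
    in conformal contact without a usable curvature signal.
    """

    n_atoms: int = 300
    blob_radius: float = 12.0
    cap_angle: float = 0.7
    bump_height: float = 3.0
    hydrophobic_correlation: float = 0.85
    noise_sigma: float = 0.1
    gap: float = 1.0
    kind_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    contact_dome_height: float = 0.5

    def __post_init__(self) -> None:
        if self.n_atoms < 20:
            raise ValueError("n_atoms must be >= 20")
        if self.blob_radius <= 0:
            raise ValueError("blob_radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.hydrophobic_correlation <= 1.0:
            raise ValueError("hydrophobic_correlation must be in [0, 1]")
        if self.cap_angle > np.pi / 2:
            raise ValueError("cap_angle must not exceed a hemisphere (pi/2)")
        if abs(sum(self.kind_probs) - 1.0) > 1e-9 or min(self.kind_probs) < 0:
            raise ValueError("kind_probs must be non-negative and sum to 1")


@dataclass
class SynthPair:
    """A posed pseudo-protein pair with ground-truth interface atom sets."""

    pair: ProteinPair
    interface_a: np.ndarray
    interface_b: np.ndarray
    config: SynthConfig
    seed: int
    kind: str = "both"


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z * z)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def make_blob(
    config: SynthConfig, role: str, rng: np.random.Generator
) -> tuple[AtomCloud, np.ndarray]:
    """One pseudo-protein with its interface cap at the +z pole.

    Returns the atom cloud and the index array of cap ("interface") atoms.
    The cap carries a cosine-tapered radial bump (``role='lock'``) or
    depression (``role='key'``) and hydrophobically biased residues.
    """
    if role not in ("lock", "key"):
        raise ValueError(f"role must be 'lock' or 'key', got {role!r}")
    dirs = _fibonacci_sphere(config.n_atoms)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    in_cap = theta < config.cap_angle
    profile = np.where(
        in_cap, 0.5 * (1.0 + np.cos(np.pi * theta / config.cap_angle)), 0.0
    )
    sign = 1.0 if role == "lock" else -1.0
    radius = config.blob_radius + sign * config.bump_height * profile
    pos = dirs * radius[:, None]
    pos = pos + rng.normal(0.0, config.noise_sigma, size=pos.shape)

    elements = rng.choice(_ELEMENTS, size=config.n_atoms, p=_ELEMENT_WEIGHTS)
    residues = rng.choice(ALL_RESIDUES, size=config.n_atoms)
    hydro_draw = rng.random(config.n_atoms) < config.hydrophobic_correlation
    cap_hydro = rng.choice(HYDROPHOBIC_RESIDUES, size=config.n_atoms)
    residues = np.where(in_cap & hydro_draw, cap_hydro, residues)

    atoms = [
        Atom(
            element=str(elements[i]),
            atom_name=str(elements[i]),
            residue_name=str(residues[i]),
            residue_seq=i + 1,
            chain_id="A",
            position=tuple(pos[i]),
        )
        for i in range(config.n_atoms)
    ]
    return AtomCloud(atoms), np.flatnonzero(in_cap)


def _rotation_about_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _transform_cloud(cloud: AtomCloud, rot: np.ndarray, shift: np.ndarray) -> AtomCloud:
    pos = cloud.positions @ rot.T + shift
    atoms = [
        Atom(a.element, a.atom_name, a.residue_name, a.residue_seq, a.chain_id,
             tuple(pos[i]))
        for i, a in enumerate(cloud.atoms)
    ]
    return AtomCloud(atoms)


def _envelope_separation(
    a: AtomCloud,
    b: AtomCloud,
    probe: float,
    subset_a: np.ndarray | None = None,
    subset_b: np.ndarray | None = None,
    reduce: str = "min",
) -> float:
    """Separation of the probe-inflated atom envelopes (A).

    ``reduce='min'`` gives the closest approach; ``reduce='median'`` the
    median of the per-atom (subset of a) nearest separations, i.e. how far
    apart the two envelopes typically sit across the facing region.
    """
    pa = a.positions if subset_a is None else a.positions[subset_a]
    pb = b.positions if subset_b is None else b.positions[subset_b]
    ra = atom_radii(a) if subset_a is None else atom_radii(a)[subset_a]
    rb = atom_radii(b) if subset_b is None else atom_radii(b)[subset_b]
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    sep = d - ra[:, None] - rb[None, :] - 2.0 * probe
    if reduce == "min":
        return float(sep.min())
    return float(np.median(sep.min(axis=1)))


def pose_pair(
    lock: AtomCloud,
    key: AtomCloud,
    gap: float,
    seed: int,
    interface_lock: np.ndarray | None = None,
    interface_key: np.ndarray | None = None,
    config: SynthConfig | None = None,
    probe: float = DEFAULT_PROBE_RADIUS,
    max_attempts: int = 10,
) -> SynthPair:
    """Pose key against lock so the planted caps face with surface gap ~gap.

    The key is flipped so its depression faces the lock's bump, the axial
    offset is calibrated so the *median* separation of the probe-inflated
    atomic envelopes across the facing caps equals ``gap``: the bulk of the
    two cap surfaces then sits at the requested gap, in snug contact like a
    bound complex, while the closest approach lands below it by the
    granularity of the atomic envelopes. A random global rigid motion is
    applied to the assembled pair. Poses with atomic clashes (any interatomic distance
    < 1.5 A) are retried up to ``max_attempts`` times.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    flip = _rotation_about_x(np.pi)
    for _ in range(max_attempts):
        # initial guess from nominal geometry, then exact envelope calibration
        r_lock = float(np.linalg.norm(lock.positions, axis=1).max())
        r_key = float(np.linalg.norm(key.positions, axis=1).max())
        d0 = r_lock + r_key + 2.0 * (probe + max(VDW_RADII.values())) + gap
        key_posed = _transform_cloud(key, flip, np.array([0.0, 0.0, d0]))
        sep = _envelope_separation(
            lock, key_posed, probe,
            subset_a=interface_lock, subset_b=interface_key, reduce="median",
        )
        key_posed = _transform_cloud(key_posed, np.eye(3), np.array([0.0, 0.0, gap - sep]))

        rot = _random_rotation(rng)
        shift = rng.uniform(-20.0, 20.0, size=3)
        a = _transform_cloud(lock, rot, shift)
        b = _transform_cloud(key_posed, rot, shift)
        dmin = np.linalg.norm(
            a.positions[:, None, :] - b.positions[None, :, :], axis=2
        ).min()
        if dmin >= 1.5:
            pair = ProteinPair(a=a, b=b, id_a="lock", id_b="key")
            return SynthPair(
                pair=pair,
                interface_a=np.asarray(interface_lock if interface_lock is not None else []),
                interface_b=np.asarray(interface_key if interface_key is not None else []),
                config=config if config is not None else SynthConfig(),
                seed=seed,
            )
    raise RuntimeError(f"could not pose pair without clashes in {max_attempts} attempts")


def make_pair(config: SynthConfig, seed: int) -> SynthPair:
    """Generate and pose one lock/key pair from a single seed.

    The pair's interface kind is drawn from ``config.kind_probs``:
    ``geometric`` pairs carry the full bump but no hydrophobic bias,
    ``chemical`` pairs carry the hydrophobic cap over a shallow contact
    dome (conformal contact, negligible curvature signal), and ``both``
    pairs carry both signals.
    """
    import dataclasses

    rng = np.random.default_rng(seed)
    kind = rng.choice(["both", "geometric", "chemical"], p=config.kind_probs)
    blob_cfg = config
    if kind == "geometric":
        blob_cfg = dataclasses.replace(config, hydrophobic_correlation=0.0)
    elif kind == "chemical":
        blob_cfg = dataclasses.replace(config,
                                       bump_height=config.contact_dome_height)
    lock, cap_lock = make_blob(blob_cfg, "lock", rng)
    key, cap_key = make_blob(blob_cfg, "key", rng)
    posed = pose_pair(
        lock, key, gap=config.gap, seed=seed + 1,
        interface_lock=cap_lock, interface_key=cap_key, config=config,
    )
    posed.kind = str(kind)
    return posed


def make_dataset(
    n_pairs: int,
    config: SynthConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[SynthPair], list[dict]]:
    """Independent pairs with a deterministic 80/20 train/test split.

    When ``out_dir`` is given, each protein is written as a PDB file, the
    ground-truth interface atom indices as CSV sidecars, and a manifest CSV
    (``pdb_path_a, chains_a, pdb_path_b, chains_b, split``) alongside.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    ss = np.random.SeedSequence(seed)
    pair_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_pairs)]
    pairs = [make_pair(config, s) for s in pair_seeds]
    n_train = int(round(0.8 * n_pairs))
    manifest = []
    for i, sp in enumerate(pairs):
        split = "train" if i < n_train else "test"
        entry = {
            "pdb_path_a": f"pair{i:04d}_a.pdb",
            "chains_a": "A",
            "pdb_path_b": f"pair{i:04d}_b.pdb",
            "chains_b": "A",
            "split": split,
        }
        manifest.append(entry)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, sp in enumerate(pairs):
            write_pdb(sp.pair.a, out_dir / manifest[i]["pdb_path_a"])
            write_pdb(sp.pair.b, out_dir / manifest[i]["pdb_path_b"])
            np.savetxt(out_dir / f"pair{i:04d}_interface_a.csv",
                       sp.interface_a, fmt="%d", header="atom_index", comments="")
            np.savetxt(out_dir / f"pair{i:04d}_interface_b.csv",
                       sp.interface_b, fmt="%d", header="atom_index", comments="")
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(manifest[0].keys()))
            writer.writeheader()
            writer.writerows(manifest)
    return pairs, manifest


def analytic_fixture(kind: str, size: float = 2.0, resolution: int = 4) -> SurfaceMesh:
    """Exact parametric test meshes with analytic normals attached.

    ``sphere``: icosphere of radius ``size`` (``resolution`` subdivisions);
    ``plane``: triangulated square grid in z=0, half-width ``size``,
    ``resolution`` x ``resolution`` vertices, normals (0, 0, 1);
    ``cylinder``: open tube of radius ``size`` along z, radial normals;
    ``saddle``: z = (x^2 - y^2)/2 over a grid, analytic normals.
    """
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    if kind == "sphere":
        tm = trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
        verts = np.asarray(tm.vertices)
        verts = verts / np.linalg.norm(verts, axis=1, keepdims=True)
        return SurfaceMesh(verts * size, np.asarray(tm.faces), verts)
    if kind in ("plane", "saddle"):
        ticks = np.linspace(-size, size, resolution)
        x, y = np.meshgrid(ticks, ticks, indexing="xy")
        x, y = x.ravel(), y.ravel()
        if kind == "plane":
            z = np.zeros_like(x)
            normals = np.tile([0.0, 0.0, 1.0], (len(x), 1))
        else:
            z = (x ** 2 - y ** 2) / 2.0
            normals = np.stack([-x, y, np.ones_like(x)], axis=1)
            normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        verts = np.stack([x, y, z], axis=1)
        faces = []
        n = resolution
        for i in range(n - 1):
            for j in range(n - 1):
                a = i * n + j
                faces.append([a, a + 1, a + n + 1])
                faces.append([a, a + n + 1, a + n])
        return SurfaceMesh(verts, np.array(faces), normals)
    if kind == "cylinder":
        n_around = max(resolution * 8, 24)
        n_along = max(resolution * 4, 12)
        phi = np.linspace(0.0, 2 * np.pi, n_around, endpoint=False)
        z = np.linspace(-2 * size, 2 * size, n_along)
        pp, zz = np.meshgrid(phi, z, indexing="xy")
        pp, zz = pp.ravel(), zz.ravel()
        verts = np.stack([size * np.cos(pp), size * np.sin(pp), zz], axis=1)
        normals = np.stack([np.cos(pp), np.sin(pp), np.zeros_like(pp)], axis=1)
        faces = []
        for i in range(n_along - 1):
            for j in range(n_around):
                a = i * n_around + j
                b = i * n_around + (j + 1) % n_around
                faces.append([a, b, b + n_around])
                faces.append([a, b + n_around, a + n_around])
        return SurfaceMesh(verts, np.array(faces), normals)
    raise ValueError(f"unknown fixture kind {kind!r}")
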