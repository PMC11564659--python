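"""Ground-truth synthetic inputs: capsid-like C-alpha clouds and pose ensembles.

These generators emulate the two kinds of real input the analysis consumes —
VIPER-aligned capsid coordinates and rigid-body docking pose ensembles —
with known ground truth, so junction-point fitting and screw-map analysis
are testable end to end without structure downloads or a docking engine.
They are deliberately geometric: points are sampled uniformly inside a known
tile at a fixed radius, with isotropic jitter, and carry none of the shape,
density or chemistry of real protein chains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from string import ascii_lowercase, ascii_uppercase, digits

import numpy as np
from scipy.spatial.transform import Rotation as R

from .geometry import IcosahedralAxes, rotation_about, rotation_group, viper_axes
from .tiling import JunctionPoint, Tile, build_tile, generate_tiling, interface_lengths

__all__ = [
    "CHAIN_ALPHABET",
    "SynthCapsidSpec",
    "SyntheticCapsid",
    "synth_capsid",
    "SynthPoseSpec",
    "synth_poses",
]

#: 62-character chain-ID alphabet for one chain per subunit
CHAIN_ALPHABET = ascii_uppercase + ascii_lowercase + digits


@dataclass(frozen=True)
class SynthCapsidSpec:
    """Conditions for one synthetic capsid.

    Defaults are the study conditions used throughout the test-suite:
    150 points per subunit on a 100 Angstrom shell with 0.5 Angstrom
    isotropic jitter.
    """

    junction: JunctionPoint
    n_points: int = 150
    radius: float = 100.0
    jitter: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 10:
            raise ValueError("n_points must be >= 10")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass
class SyntheticCapsid:
    """60 chains of synthetic C-alpha positions plus the generating ground truth."""

    chains: dict  # chain id -> (n, 3) array
    ground_truth: dict
    spec: SynthCapsidSpec

    def chain(self, cid: str) -> np.ndarray:
        return self.chains[cid]

    def write_pdb(self, path) -> None:
        """Write as a PDB file: CA-only GLY residues, one chain per subunit."""
        from Bio.PDB import PDBIO, StructureBuilder

        sb = StructureBuilder.StructureBuilder()
        sb.init_structure("synt")
        sb.init_model(0)
        serial = 1
        for cid, coords in self.chains.items():
            sb.init_chain(cid)
            sb.init_seg("    ")
            for i, xyz in enumerate(coords, start=1):
                sb.init_residue("GLY", " ", i, " ")
                sb.init_atom("CA", np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                             " CA ", serial_number=serial, element="C")
                serial += 1
        io = PDBIO()
        io.set_structure(sb.get_structure())
        io.save(str(path))

    def write_ground_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.ground_truth, fh, indent=2, sort_keys=True)


def _sample_directions_in_tile(tile: Tile, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-in-area directions inside a tile, by rejection from its bounding cap."""
    verts = tile.vertices_distinct
    center = verts.mean(axis=0)
    center /= np.linalg.norm(center)
    cos_max = float(np.min(verts @ center)) - 1e-9  # cap just covering the tile
    # frame around the cap center
    e1 = np.cross([0.0, 0.0, 1.0], center)
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([1.0, 0.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(center, e1)
    tiling = generate_tiling(tile)
    base_index = None
    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = max(4 * (n - got), 64)
        z = rng.uniform(cos_max, 1.0, size=m)  # uniform area on the cap
        az = rng.uniform(0.0, 2.0 * np.pi, size=m)
        s = np.sqrt(1.0 - z**2)
        cand = (z[:, None] * center[None, :]
                + (s * np.cos(az))[:, None] * e1[None, :]
                + (s * np.sin(az))[:, None] * e2[None, :])
        idx = tiling.locate(cand)
        if base_index is None:
            # the base tile is the one rotated by the identity
            base_index = int(np.argmax([np.allclose(rot, np.eye(3)) for rot in tiling.rotations]))
        keep = cand[idx == base_index]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out


def synth_capsid(spec: SynthCapsidSpec, axes: IcosahedralAxes | None = None,
                 group: list | None = None) -> SyntheticCapsid:
    """Synthesize a 60-chain capsid from a known junction point.

    Directions are rejection-sampled uniformly inside the generating tile
    (PCG64 generator seeded from ``spec.seed``), scaled to the shell radius,
    jittered isotropically, then copied by all 60 group rotations into chains
    A..9.  The ground-truth record carries sigma, (x, y), the dominant axis
    and the sampling metadata.
    """
    j = spec.junction
    tile = build_tile(j, axes)
    if group is None:
        group = rotation_group(tile.axes)
    rng = np.random.default_rng(spec.seed)
    dirs = _sample_directions_in_tile(tile, spec.n_points, rng)
    base = dirs * spec.radius
    if spec.jitter > 0:
        base = base + rng.normal(0.0, spec.jitter, size=base.shape)
    # chain A is the generating subunit: identity rotation first
    ident = next(i for i, rot in enumerate(group) if np.allclose(rot, np.eye(3), atol=1e-9))
    ordered = [group[ident]] + [rot for i, rot in enumerate(group) if i != ident]
    chains = {}
    for cid, rot in zip(CHAIN_ALPHABET, ordered):
        chains[cid] = base @ rot.T
    ifl = interface_lengths(j, tile.axes)
    truth = {
        "sigma": j.sigma,
        "x": j.x,
        "y": j.y,
        "dominant_axis": ifl.dominant,
        "degeneracy": tile.degeneracy,
        "n_points": spec.n_points,
        "radius": spec.radius,
        "jitter": spec.jitter,
        "seed": spec.seed,
        "rng": "numpy PCG64 (default_rng)",
        "sampling": "rejection from tile bounding spherical cap, uniform in area",
    }
    return SyntheticCapsid(chains=chains, ground_truth=truth, spec=spec)


@dataclass(frozen=True)
class SynthPoseSpec:
    """Conditions for a synthetic docking-pose ensemble.

    ``n_near`` poses sit at the exact symmetry step about ``true_axis``
    perturbed by rotations of sd ``noise_deg``; ``n_decoys`` are uniform
    random rigid poses.  Near poses score ``score_gap`` above the decoys on
    average (unit score sd).
    """

    true_axis: str = "5fold"
    n_near: int = 30
    n_decoys: int = 200
    noise_deg: float = 1.0
    score_gap: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_axis not in ("2fold", "3fold", "5fold"):
            raise ValueError("true_axis must be one of 2fold/3fold/5fold")
        if self.n_near < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_deg < 0:
            raise ValueError("noise_deg must be non-negative")


_AXIS_ANGLE = {"2fold": np.pi, "3fold": 2.0 * np.pi / 3.0, "5fold": 2.0 * np.pi / 5.0}


def synth_poses(spec: SynthPoseSpec, monomer: np.ndarray | None = None,
                axes: IcosahedralAxes | None = None) -> tuple[list, list]:
    """Pose ensemble with a planted symmetry signal.

    Returns ``(transforms, scores)`` where each transform is an ``(R, t)``
    pair suitable for :func:`capsidtile.screw.write_poses_tsv`; ``monomer``
    is unused for generation but accepted for interface symmetry with the
    reader side.
    """
    axes = axes or viper_axes()
    axis_vec = {"2fold": axes.axis2, "3fold": axes.axis3, "5fold": axes.axis5}[spec.true_axis]
    base_rot = rotation_about(axis_vec, _AXIS_ANGLE[spec.true_axis])
    rng = np.random.default_rng(spec.seed)
    transforms, scores = [], []
    base_score = 10.0
    for _ in range(spec.n_near):
        if spec.noise_deg > 0:
            pert = R.from_rotvec(rng.normal(0.0, np.radians(spec.noise_deg), size=3)).as_matrix()
        else:
            pert = np.eye(3)
        transforms.append((pert @ base_rot, np.zeros(3)))
        scores.append(base_score + spec.score_gap + rng.normal())
    for _ in range(spec.n_decoys):
        rot = R.random(random_state=rng).as_matrix()
        t = rng.uniform(-30.0, 30.0, size=3)
        transforms.append((rot, t))
        scores.append(base_score + rng.normal())
    return transforms, scores
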