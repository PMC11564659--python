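"""Screw-motion decomposition of rigid subunit-pair poses.

Any rigid displacement mapping monomer 1 onto monomer 2 is a screw motion: a
rotation by phi about an axis (direction omega through point rho) followed by
a translation d_par along that axis.  The solved parameters satisfy the
Rodriguez relations

    p2 - p1 = tan(phi/2) omega x (p2 + p1 - 2 rho) + d_par omega

for every point pair.  Symmetry-related subunit pairs of an icosahedral
capsid have d_par = 0 and phi in {72, 120, 144, 180} degrees, so heatmaps of
docking score and of RMSD-to-reference over (phi, d_par) reveal which
symmetry axis a docked ensemble favours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as R

from .geometry import IcosahedralAxes, rotation_group, viper_axes

__all__ = [
    "PosePair",
    "ScrewMotion",
    "ReferenceSet",
    "ScrewMaps",
    "solve_screw",
    "superpose",
    "reference_pairs",
    "pair_rmsd",
    "build_maps",
    "read_poses_tsv",
    "write_poses_tsv",
    "poses_to_pairs",
]

POSE_COLUMNS = [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz", "score"]


@dataclass
class PosePair:
    """One rigid pose: two same-length point sets (Angstrom) plus a docking score."""

    monomer1: np.ndarray
    monomer2: np.ndarray
    score: float = 0.0

    def __post_init__(self) -> None:
        m1 = np.atleast_2d(np.asarray(self.monomer1, dtype=float))
        m2 = np.atleast_2d(np.asarray(self.monomer2, dtype=float))
        if m1.shape != m2.shape or m1.shape[0] < 3 or m1.shape[1] != 3:
            raise ValueError("monomers must be equal-length (n>=3, 3) arrays")
        self.monomer1, self.monomer2 = m1, m2


@dataclass
class ScrewMotion:
    """Screw parameters: unit axis ``omega`` through ``rho`` (Angstrom),
    rotation ``phi`` in degrees in [0, 180], axial translation ``d_par`` (Angstrom).

    ``degenerate`` marks an identity displacement (axis undefined)."""

    omega: np.ndarray
    rho: np.ndarray
    phi: float
    d_par: float
    degenerate: bool = False

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the screw motion: rotate about the axis, then translate along it."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        rot = R.from_rotvec(self.omega * np.radians(self.phi)).as_matrix()
        return (points - self.rho) @ rot.T + self.rho + self.d_par * self.omega

    def as_dict(self) -> dict:
        return {"omega": self.omega.tolist(), "rho": self.rho.tolist(),
                "phi_deg": self.phi, "d_par": self.d_par, "degenerate": self.degenerate}


def superpose(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition (Kabsch): returns (R, t) with dst ~ src @ R.T + t."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    c1 = src.mean(axis=0)
    c2 = dst.mean(axis=0)
    h = (src - c1).T @ (dst - c2)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("near-collinear point set: superposition ill-conditioned")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = c2 - rot @ c1
    return rot, t


def _screw_from_rt(rot: np.ndarray, t: np.ndarray, anchor: np.ndarray,
                   tol: float = 1e-9) -> ScrewMotion:
    rv = R.from_matrix(rot).as_rotvec()
    phi = float(np.linalg.norm(rv))
    if phi < tol:
        tn = float(np.linalg.norm(t))
        if tn < tol:
            return ScrewMotion(omega=np.array([1.0, 0.0, 0.0]), rho=anchor.copy(),
                               phi=0.0, d_par=0.0, degenerate=True)
        omega = t / tn
        return ScrewMotion(omega=omega, rho=anchor.copy(), phi=0.0, d_par=tn)
    omega = rv / phi
    if abs(phi - np.pi) < 1e-9:
        # (omega, phi) <-> (-omega, -phi) ambiguity: first nonzero component positive
        for c in omega:
            if abs(c) > 1e-9:
                if c < 0:
                    omega = -omega
                break
    d_par = float(t @ omega)
    t_perp = t - d_par * omega
    # solve (I - R) rho = t_perp for rho perpendicular to omega
    rho0 = 0.5 * (t_perp + np.cross(omega, t_perp) / np.tan(phi / 2.0))
    rho = rho0 + ((anchor - rho0) @ omega) * omega  # axis point nearest the anchor
    return ScrewMotion(omega=omega, rho=rho, phi=float(np.degrees(phi)), d_par=d_par)


def solve_screw(pair: PosePair) -> ScrewMotion:
    """Screw parameters of the displacement carrying monomer 1 onto monomer 2.

    The relative rotation/translation comes from least-squares superposition
    over all supplied points, then is converted to screw form; for noiseless
    rigid pairs the result satisfies the Rodriguez relations to machine
    precision at every point.  phi is reported in [0, 180] degrees and rho is
    the axis point nearest monomer 1's centroid.
    """
    rot, t = superpose(pair.monomer1, pair.monomer2)
    anchor = pair.monomer1.mean(axis=0)
    return _screw_from_rt(rot, t, anchor)


@dataclass
class ReferenceSet:
    """All ordered pairs of distinct subunits of a 60-subunit capsid (3540 pairs)."""

    subunit: np.ndarray  # (n, 3)
    rotations: list  # the 60 group rotations

    def __post_init__(self) -> None:
        self.subunit = np.atleast_2d(np.asarray(self.subunit, dtype=float))
        if len(self.rotations) != 60:
            raise ValueError("expected the 60-element rotation group")

    @property
    def n_pairs(self) -> int:
        n = len(self.rotations)
        return n * (n - 1)

    def pairs(self):
        """Iterate the 3540 reference PosePairs (R_i subunit, R_j subunit), i != j."""
        copies = [self.subunit @ rot.T for rot in self.rotations]
        for i in range(len(self.rotations)):
            for j in range(len(self.rotations)):
                if i != j:
                    yield PosePair(monomer1=copies[i], monomer2=copies[j])

    @cached_property
    def relative_rotations(self) -> list[np.ndarray]:
        """The 59 distinct non-identity relative rotations R_i^T R_j.

        Each occurs for exactly 60 of the 3540 ordered pairs, so anchored
        RMSD minimization over all references reduces to these 59 elements.
        """
        seen = {}
        for rot in self.rotations:
            key = tuple((np.round(rot, 6) + 0.0).ravel())
            seen[key] = rot
        ident = tuple((np.round(np.eye(3), 6) + 0.0).ravel())
        return [m for k, m in sorted(seen.items()) if k != ident]

    def min_rmsd(self, pose: PosePair) -> float:
        """Minimum anchored RMSD of a pose to any reference pair.

        Requires pose.monomer1 to be the same subunit the references were
        built from (the usual docking setup); falls back to the generic
        pairwise path otherwise.
        """
        return float(self.min_rmsd_batch([pose])[0])

    def min_rmsd_batch(self, poses: list) -> np.ndarray:
        s = self.subunit
        fast = all(p.monomer1.shape == s.shape and np.allclose(p.monomer1, s, atol=1e-6)
                   for p in poses)
        if fast:
            m2 = np.stack([p.monomer2 for p in poses])  # (P, n, 3)
            best = np.full(len(poses), np.inf)
            for q in self.relative_rotations:
                # anchored rmsd = rms(Q m2 - S) since anchoring depends on R_j^T R_i only
                diff = np.einsum("ab,pnb->pna", q, m2) - s[None]
                rms = np.sqrt((diff**2).sum(axis=-1).mean(axis=-1))
                best = np.minimum(best, rms)
            return best
        out = np.empty(len(poses))
        for k, p in enumerate(poses):
            out[k] = min(pair_rmsd(p, ref) for ref in self.pairs())
        return out


def reference_pairs(capsid_subunit: np.ndarray, group: list | None = None) -> ReferenceSet:
    """Reference set of all 60 x 59 ordered symmetry-related subunit pairs."""
    if group is None:
        group = rotation_group()
    return ReferenceSet(subunit=capsid_subunit, rotations=list(group))


def pair_rmsd(pose: PosePair, ref: PosePair) -> float:
    """Anchored RMSD: superpose pose.monomer1 exactly onto ref.monomer1, then
    measure the RMSD of pose.monomer2 against ref.monomer2 without refitting."""
    if pose.monomer1.shape != ref.monomer1.shape or pose.monomer2.shape != ref.monomer2.shape:
        raise ValueError("pose and reference point counts differ")
    rot, t = superpose(pose.monomer1, ref.monomer1)
    moved = pose.monomer2 @ rot.T + t
    diff = moved - ref.monomer2
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def _smooth_map(grid: np.ndarray, window: int, fill: str) -> np.ndarray:
    """Boxcar average along axis 0 (the rotation axis) of a sparse extremum grid.

    Empty (NaN) cells are filled with a neutral baseline first — the grid
    minimum for a max-score map, the maximum for a min-RMSD map — matching
    the filled-contour reading of the heatmaps; an all-NaN grid stays NaN.
    """
    if np.all(np.isnan(grid)):
        return grid.copy()
    baseline = np.nanmin(grid) if fill == "min" else np.nanmax(grid)
    filled = np.where(np.isnan(grid), baseline, grid)
    if window <= 1:
        return filled
    half = window // 2
    out = np.empty_like(filled)
    n = filled.shape[0]
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = filled[lo:hi].mean(axis=0)
    return out


@dataclass
class ScrewMaps:
    """Max-score and min-RMSD heatmaps over screw (rotation, translation) space.

    ``max_score``/``min_rmsd`` are raw per-cell extrema (NaN where no pose
    fell); the ``*_smooth`` grids are boxcar-averaged along the rotation axis
    over ``smoothing_window`` degrees.  Shapes are (n_phi_bins, n_d_bins).
    """

    phi_edges: np.ndarray
    d_edges: np.ndarray
    max_score: np.ndarray
    min_rmsd: np.ndarray
    max_score_smooth: np.ndarray
    min_rmsd_smooth: np.ndarray
    smoothing_window: float
    rmsd_convention: str = "anchored (monomer1 superposed exactly, no refit)"

    @property
    def phi_centers(self) -> np.ndarray:
        return 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])

    @property
    def d_centers(self) -> np.ndarray:
        return 0.5 * (self.d_edges[:-1] + self.d_edges[1:])

    def peak_phi(self) -> float:
        """Rotation angle (deg) of the global maximum of the smoothed score map."""
        g = self.max_score_smooth
        if np.all(np.isnan(g)):
            raise ValueError("empty score map")
        idx = np.unravel_index(np.nanargmax(g), g.shape)
        return float(self.phi_centers[idx[0]])

    def nearest_symmetry_axis(self) -> str:
        peaks = {"5fold": 72.0, "3fold": 120.0, "2fold": 180.0}
        p = self.peak_phi()
        return min(peaks, key=lambda k: abs(peaks[k] - p))

    def to_dataframe(self, which: str = "max_score") -> pd.DataFrame:
        grid = getattr(self, which)
        return pd.DataFrame(grid, index=self.phi_centers, columns=self.d_centers)

    def summary(self) -> dict:
        out = {"peak_phi_deg": self.peak_phi(),
               "nearest_symmetry_axis": self.nearest_symmetry_axis(),
               "smoothing_window_deg": self.smoothing_window,
               "rmsd_convention": self.rmsd_convention}
        if not np.all(np.isnan(self.min_rmsd)):
            idx = np.unravel_index(np.nanargmin(self.min_rmsd_smooth), self.min_rmsd.shape)
            out["min_rmsd"] = float(np.nanmin(self.min_rmsd))
            out["min_rmsd_phi_deg"] = float(self.phi_centers[idx[0]])
        return out

    def plot(self, axs=None):
        import matplotlib.pyplot as plt

        if axs is None:
            _, axs = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
        for ax, grid, title in zip(axs, (self.max_score_smooth, self.min_rmsd_smooth),
                                   ("max docking score", "min RMSD (A)")):
            pc = ax.pcolormesh(self.phi_centers, self.d_centers, grid.T, shading="auto")
            for phi0, color in ((72, "red"), (120, "blue"), (180, "gold")):
                ax.axvline(phi0, ls="--", color=color, lw=0.8)
            ax.set_xlabel("screw rotation (deg)")
            ax.set_title(title)
            plt.colorbar(pc, ax=ax)
        axs[0].set_ylabel("screw translation (A)")
        return axs


def build_maps(poses: list, refs: ReferenceSet | None = None, phi_bin: float = 1.0,
               d_bin: float = 0.5, smooth_deg: float = 5.0,
               top_k: int | None = None) -> ScrewMaps:
    """Heatmaps of max docking score and min reference RMSD over screw space.

    Each pose is decomposed into its screw motion and binned by (phi, d_par);
    per cell the maximum score over poses is kept and, if a reference set is
    supplied, the minimum anchored RMSD of the ``top_k`` best-scoring poses
    (default: all) to any symmetry-related reference pair.  Both maps are
    boxcar-smoothed over ~``smooth_deg`` degrees along the rotation axis.
    """
    if not poses:
        raise ValueError("empty pose list")
    screws = [solve_screw(p) for p in poses]
    phis = np.array([s.phi for s in screws])
    ds = np.array([s.d_par for s in screws])
    scores = np.array([p.score for p in poses])

    phi_edges = np.arange(0.0, 180.0 + phi_bin, phi_bin)
    d_lo = np.floor(ds.min() / d_bin) * d_bin
    d_hi = np.ceil(ds.max() / d_bin) * d_bin + d_bin
    d_edges = np.arange(d_lo, d_hi + 0.5 * d_bin, d_bin)

    pi = np.clip(np.digitize(phis, phi_edges) - 1, 0, len(phi_edges) - 2)
    di = np.clip(np.digitize(ds, d_edges) - 1, 0, len(d_edges) - 2)

    shape = (len(phi_edges) - 1, len(d_edges) - 1)
    max_score = np.full(shape, np.nan)
    for k in range(len(poses)):
        cur = max_score[pi[k], di[k]]
        if np.isnan(cur) or scores[k] > cur:
            max_score[pi[k], di[k]] = scores[k]

    min_rmsd = np.full(shape, np.nan)
    if refs is not None:
        order = np.argsort(scores)[::-1]
        if top_k is not None:
            order = order[:top_k]
        sel = list(order)
        rmsds = refs.min_rmsd_batch([poses[k] for k in sel])
        for r, k in zip(rmsds, sel):
            cur = min_rmsd[pi[k], di[k]]
            if np.isnan(cur) or r < cur:
                min_rmsd[pi[k], di[k]] = r

    window = max(1, int(round(smooth_deg / phi_bin)))
    return ScrewMaps(
        phi_edges=phi_edges, d_edges=d_edges, max_score=max_score, min_rmsd=min_rmsd,
        max_score_smooth=_smooth_map(max_score, window, fill="min"),
        min_rmsd_smooth=_smooth_map(min_rmsd, window, fill="max"),
        smoothing_window=window * phi_bin,
    )


# --- pose file I/O ---------------------------------------------------------

def write_poses_tsv(path, transforms: list, scores) -> None:
    """Write poses as TSV: 9 row-major rotation entries, 3 translation components
    (Angstrom) and one score per line, with a header."""
    rows = []
    for (rot, t), s in zip(transforms, scores):
        rows.append(list(np.asarray(rot, float).ravel()) + list(np.asarray(t, float)) + [float(s)])
    df = pd.DataFrame(rows, columns=POSE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_poses_tsv(path) -> pd.DataFrame:
    """Read a pose TSV (see :func:`write_poses_tsv` for the layout)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose file missing columns: {missing}")
    return df


def poses_to_pairs(monomer: np.ndarray, poses: pd.DataFrame) -> list:
    """Apply each pose transform to ``monomer`` to form PosePairs
    (monomer1 = monomer, monomer2 = R monomer + t)."""
    monomer = np.atleast_2d(np.asarray(monomer, dtype=float))
    out = []
    for _, row in poses.iterrows():
        rot = row[POSE_COLUMNS[:9]].to_numpy(dtype=float).reshape(3, 3)
        t = row[["tx", "ty", "tz"]].to_numpy(dtype=float)
        out.append(PosePair(monomer1=monomer, monomer2=monomer @ rot.T + t,
                            score=float(row["score"])))
    return out
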