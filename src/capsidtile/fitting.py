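"""Fit the dihedron-unfolding model to subunit C-alpha coordinates.

The subunit silhouette is the union of discs (effective amino-acid radius)
around the gnomonically projected C-alpha directions; the model tile is the
projected unfolded-dihedron polygon.  Chirality is decided first by the
minimax axis-distance criterion, then the junction point is estimated by
maximizing the Dice coefficient between silhouette and tile, with a constant
penalty keeping the search on valid (simple, in-hemisphere) unfoldings.

Exposed in the statsmodels idiom: :class:`DihedronModel` holds the data,
``.fit()`` returns a :class:`DihedronFitResults` with the estimates,
diagnostics, ``summary()`` and ``plot()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution, minimize
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .geometry import IcosahedralAxes, gnomonic_project, rotation_group, viper_axes
from .tiling import (
    InterfaceLengths,
    JunctionPoint,
    build_tile,
    degeneracy,
    interface_lengths,
    is_valid_junction,
)

__all__ = [
    "SubunitCloud",
    "Silhouette",
    "AmbiguousChiralityError",
    "read_calpha_pdb",
    "reorient_to_fundamental",
    "project_subunit",
    "determine_chirality",
    "silhouette_region",
    "tile_polygon",
    "dice",
    "objective",
    "DihedronModel",
    "DihedronFitResults",
    "fit_junction",
]

#: default effective amino-acid radius (Angstrom)
DEFAULT_RADIUS = 3.3


class AmbiguousChiralityError(ValueError):
    """The left/right chirality criteria are equal within tolerance."""


@dataclass
class SubunitCloud:
    """C-alpha positions of one subunit (or dimer) in the VIPER-aligned frame.

    ``radius_r`` is the effective amino-acid radius in Angstrom used to build
    the silhouette discs.
    """

    calpha: np.ndarray  # (n, 3), Angstrom
    chain_ids: tuple = ()
    radius_r: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.calpha, dtype=float))
        if p.shape[0] < 3 or p.shape[1] != 3:
            raise ValueError("need at least 3 C-alpha positions")
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite coordinates")
        if np.any(np.linalg.norm(p, axis=1) < 1e-6):
            raise ValueError("atom at the origin cannot be projected")
        self.calpha = p


@dataclass
class Silhouette:
    """Projected subunit: disc centers and per-disc radii in the gnomonic plane."""

    centers: np.ndarray  # (n, 2)
    radii: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if len(self.centers) != len(self.radii):
            raise ValueError("one radius per center required")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")


def read_calpha_pdb(path, chains, radius_r: float = DEFAULT_RADIUS) -> SubunitCloud:
    """Read C-alpha atoms of the named chain(s) from a PDB file.

    Takes the first model and, for disordered atoms, the first altloc.  Two
    chain IDs concatenate into one cloud (dimer-as-tile mode, used when a
    subunit pair acts as a single tile).
    """
    from Bio.PDB import PDBParser

    if isinstance(chains, str):
        chains = [c for c in chains.split(",") if c]
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("subunit", str(path))
    model = next(structure.get_models())
    available = [c.id for c in model]
    coords = []
    for cid in chains:
        if cid not in [c.id for c in model]:
            raise KeyError(f"chain {cid!r} not found; available chains: {available}")
        for residue in model[cid]:
            if "CA" in residue:
                atom = residue["CA"]
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]
                coords.append(atom.get_coord())
    if not coords:
        raise ValueError(f"no C-alpha atoms found in chains {list(chains)}")
    return SubunitCloud(calpha=np.asarray(coords, dtype=float),
                        chain_ids=tuple(chains), radius_r=radius_r)


def _fundamental_target(axes: IcosahedralAxes) -> np.ndarray:
    # midpoint of the right- and left-handed triangle centroids: canonical,
    # chirality-neutral re-orientation target in the xz plane
    m = axes.mirrored()
    s = axes.axis2 + axes.axis3 + axes.axis5 + m.axis2 + m.axis3 + m.axis5
    return s / np.linalg.norm(s)


def reorient_to_fundamental(cloud: SubunitCloud, axes: IcosahedralAxes | None = None,
                            group: list | None = None) -> tuple[SubunitCloud, np.ndarray]:
    """Map the subunit into the fundamental domain around the projection pole.

    Deposited chains may occupy any of the 60 symmetry-equivalent domains;
    this applies the group rotation bringing the mean atom direction closest
    to the fundamental-triangle region and returns (rotated cloud, rotation).
    """
    axes = axes or viper_axes()
    group = group if group is not None else rotation_group(axes)
    dirs = cloud.calpha / np.linalg.norm(cloud.calpha, axis=1, keepdims=True)
    c = dirs.mean(axis=0)
    c = c / np.linalg.norm(c)
    target = _fundamental_target(axes)
    best = max(group, key=lambda rot: float((rot @ c) @ target))
    rotated = SubunitCloud(calpha=cloud.calpha @ best.T, chain_ids=cloud.chain_ids,
                           radius_r=cloud.radius_r)
    return rotated, best


def project_subunit(cloud: SubunitCloud, axes: IcosahedralAxes | None = None) -> Silhouette:
    """Gnomonic projection of the subunit onto the z=1 plane.

    Each C-alpha is radially normalized to the unit sphere; the effective
    radius becomes an angular radius r/|x_i| whose projected disc is
    approximated by a planar circle of radius tan(r/|x_i|) / cos(theta)^1.5,
    the equal-area magnification of the gnomonic map at colatitude theta.
    """
    p = cloud.calpha
    norms = np.linalg.norm(p, axis=1)
    dirs = p / norms[:, None]
    if np.any(dirs[:, 2] <= 1e-9):
        raise ValueError(
            "atoms span both projection hemispheres; re-orient into the "
            "fundamental domain first (see reorient_to_fundamental)")
    centers = gnomonic_project(dirs)
    cos_theta = dirs[:, 2]
    ang = cloud.radius_r / norms
    radii = np.tan(ang) / cos_theta**1.5
    return Silhouette(centers=centers, radii=radii)


def _projected_axis_points(axes: IcosahedralAxes) -> np.ndarray:
    return gnomonic_project(np.stack(axes.points()))


def determine_chirality(sil: Silhouette, axes: IcosahedralAxes | None = None,
                        tol: float = 1e-9) -> str:
    """Minimax chirality criterion.

    The tile boundary passes through all three axis points, so the correct
    handedness is the one for which the farthest axis point still has a
    nearby atom: for each handedness sigma compute
    max_j min_i dist(p_i, X_j^sigma) over the three projected axis points and
    return the sigma minimizing it.  Ties raise AmbiguousChiralityError.
    """
    axes = axes or viper_axes()
    if axes.handedness != "right":
        axes = axes.mirrored()
    crit = {}
    for sigma, ax in (("right", axes), ("left", axes.mirrored())):
        X = _projected_axis_points(ax)
        d = np.linalg.norm(sil.centers[:, None, :] - X[None, :, :], axis=-1)
        crit[sigma] = float(d.min(axis=0).max())
    if abs(crit["right"] - crit["left"]) <= tol:
        raise AmbiguousChiralityError(
            f"chirality criteria tie at {crit['right']:.6g}; force sigma explicitly")
    return min(crit, key=crit.get)


def silhouette_region(sil: Silhouette, quad_segs: int = 16):
    """Shapely region: union of the silhouette discs in the gnomonic plane."""
    discs = [Point(c).buffer(r, quad_segs=quad_segs) for c, r in zip(sil.centers, sil.radii)]
    return unary_union(discs)


def tile_polygon(j: JunctionPoint, axes: IcosahedralAxes | None = None) -> Polygon | None:
    """Projected tile polygon (gnomonic, pole +z), or None if invalid there."""
    tile = build_tile(j, axes)
    v = tile.vertices_distinct
    if np.any(v[:, 2] <= 1e-9) or len(v) < 3:
        return None
    poly = Polygon(gnomonic_project(v))
    if not poly.is_valid or poly.area <= 0.0:
        return None
    return poly


def dice(region_a, region_b) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|) of two planar regions, in [0, 1].

    Accepts shapely geometries; an empty union is defined as 0.
    """
    area_a = region_a.area
    area_b = region_b.area
    if area_a + area_b <= 0.0:
        return 0.0
    inter = region_a.intersection(region_b).area
    return 2.0 * inter / (area_a + area_b)


def objective(x: float, y: float, sigma: str, sil_or_region,
              axes: IcosahedralAxes | None = None) -> float:
    """1 - Dice + P(x, y); P = 1 on invalid junctions (self-intersecting or
    out-of-hemisphere unfoldings), 0 elsewhere."""
    region = silhouette_region(sil_or_region) if isinstance(sil_or_region, Silhouette) \
        else sil_or_region
    j = JunctionPoint(float(x), float(y), sigma)
    poly = tile_polygon(j, axes)
    if poly is None:  # invalid unfolding: D = 0, P = 1
        return 2.0
    return 1.0 - dice(region, poly)


_VALID_BOX_CACHE: dict[str, tuple] = {}


def _search_bounds(sigma: str, pad: float = 0.2) -> tuple:
    """Bounding box of the valid-junction region for one chirality, padded.

    Determined once per handedness by scanning a coarse grid of candidate
    junctions for validity.
    """
    if sigma in _VALID_BOX_CACHE:
        return _VALID_BOX_CACHE[sigma]
    xs = np.linspace(-1.2, 1.6, 57)
    ys = np.linspace(-1.6, 1.6, 65)
    pts = []
    for x in xs:
        for y in ys:
            if is_valid_junction(JunctionPoint(x, y, sigma)):
                pts.append((x, y))
    pts = np.asarray(pts)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    bounds = ((lo[0] - pad * span[0], hi[0] + pad * span[0]),
              (lo[1] - pad * span[1], hi[1] + pad * span[1]))
    _VALID_BOX_CACHE[sigma] = bounds
    return bounds


@dataclass
class DihedronFitResults:
    """Results of fitting the dihedron-unfolding model to one subunit.

    Carries the estimated chirality and junction point, the achieved Dice
    coefficient, interface lengths with the dominant-axis class, the
    optimizer trace and the seed used.
    """

    sigma: str
    junction: JunctionPoint
    dice: float
    interface: InterfaceLengths
    objective_trace: list = field(default_factory=list)
    seed: int = 0
    n_points: int = 0
    degeneracy: str = "generic"

    @property
    def dominant_axis(self) -> str:
        return self.interface.dominant

    def as_dict(self) -> dict:
        return {
            "sigma": self.sigma,
            "junction": {"x": self.junction.x, "y": self.junction.y},
            "dice": self.dice,
            "degeneracy": self.degeneracy,
            "interface_lengths": self.interface.as_dict(),
            "dominant_axis": self.dominant_axis,
            "seed": self.seed,
            "n_points": self.n_points,
        }

    def summary(self) -> str:
        il = self.interface
        lines = [
            "Dihedron-unfolding model fit",
            "=" * 44,
            f"{'C-alpha points':<26}{self.n_points:>18}",
            f"{'Chirality (sigma)':<26}{self.sigma:>18}",
            f"{'Junction x (plane units)':<26}{self.junction.x:>18.6f}",
            f"{'Junction y (plane units)':<26}{self.junction.y:>18.6f}",
            f"{'Dice coefficient':<26}{self.dice:>18.4f}",
            f"{'Degeneracy class':<26}{self.degeneracy:>18}",
            "-" * 44,
            f"{'Interface L2 (rad)':<26}{il.L2:>18.6f}",
            f"{'Interface L3 (rad)':<26}{il.L3:>18.6f}",
            f"{'Interface L5 (rad)':<26}{il.L5:>18.6f}",
            f"{'Dominant axis':<26}{il.dominant:>18}",
            "=" * 44,
        ]
        return "\n".join(lines)

    def plot(self, sil: Silhouette | None = None, ax=None):
        """Overlay of silhouette discs, fitted tile and fundamental triangle."""
        import matplotlib.pyplot as plt
        from matplotlib.patches import Circle

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        axes = viper_axes(self.sigma)
        tri = _projected_axis_points(axes)
        ax.fill(tri[:, 0], tri[:, 1], facecolor="none", edgecolor="tab:blue", lw=1.0)
        if sil is not None:
            for c, r in zip(sil.centers, sil.radii):
                ax.add_patch(Circle(c, r, facecolor="0.8", edgecolor="none", alpha=0.6))
            ax.plot(sil.centers[:, 0], sil.centers[:, 1], "k.", ms=1.5)
        poly = tile_polygon(self.junction, axes)
        if poly is not None:
            xx, yy = poly.exterior.xy
            ax.plot(xx, yy, "r-", lw=1.5)
        ax.plot([self.junction.x], [self.junction.y], "r*", ms=10)
        ax.set_aspect("equal")
        ax.set_xlabel("x (gnomonic plane)")
        ax.set_ylabel("y (gnomonic plane)")
        return ax


class DihedronModel:
    """Dihedron-unfolding model bound to one subunit's C-alpha cloud.

    Parameters
    ----------
    cloud : SubunitCloud
        C-alpha positions (VIPER-aligned frame).
    axes : IcosahedralAxes, optional
        Fundamental axis triple; defaults to the right-handed VIPER triple.
    reorient : bool
        Map the subunit into the fundamental domain before projection
        (recommended for deposited coordinates, which may occupy any of the
        60 symmetry copies).
    """

    def __init__(self, cloud: SubunitCloud, axes: IcosahedralAxes | None = None,
                 reorient: bool = True):
        self.axes = axes or viper_axes()
        self.reorientation = np.eye(3)
        if reorient:
            cloud, self.reorientation = reorient_to_fundamental(cloud, self.axes)
        self.cloud = cloud
        self.silhouette = project_subunit(cloud, self.axes)
        self._region = silhouette_region(self.silhouette)

    @classmethod
    def from_pdb(cls, path, chains, radius: float = DEFAULT_RADIUS, **kwargs) -> "DihedronModel":
        return cls(read_calpha_pdb(path, chains, radius_r=radius), **kwargs)

    def objective(self, x: float, y: float, sigma: str) -> float:
        return objective(x, y, sigma, self._region, self.axes)

    def fit(self, seed: int = 0, sigma: str | None = None, popsize: int = 16,
            maxiter: int = 60, refine: bool = True) -> DihedronFitResults:
        """Global junction-point estimation.

        Chirality is fixed first (minimax criterion) unless forced via
        ``sigma``; the 2-parameter objective 1 - Dice + P is then minimized
        by seeded differential evolution over the valid region's padded
        bounding box, followed by a Nelder-Mead refinement.  Deterministic
        for a given seed.
        """
        sigma = sigma or determine_chirality(self.silhouette, self.axes)
        bounds = _search_bounds(sigma)
        trace: list[float] = []

        def f(v):
            return self.objective(v[0], v[1], sigma)

        res = differential_evolution(
            f, bounds=bounds, seed=int(seed), popsize=popsize, maxiter=maxiter,
            tol=1e-8, mutation=(0.4, 1.0), recombination=0.8, polish=False,
            init="sobol", updating="deferred",
            callback=lambda xk, convergence=None: trace.append(float(f(xk))) or False,
        )
        best_x, best_val = res.x, float(res.fun)
        if refine:
            local = minimize(f, best_x, method="Nelder-Mead",
                             options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
            if local.fun <= best_val:
                best_x, best_val = local.x, float(local.fun)
        if best_val >= 1.0:
            raise RuntimeError("optimizer found no valid tile overlapping the silhouette")
        j = JunctionPoint(float(best_x[0]), float(best_x[1]), sigma)
        return DihedronFitResults(
            sigma=sigma,
            junction=j,
            dice=1.0 - best_val,
            interface=interface_lengths(j),
            objective_trace=trace,
            seed=int(seed),
            n_points=len(self.cloud.calpha),
            degeneracy=degeneracy(j),
        )


def fit_junction(cloud: SubunitCloud, axes: IcosahedralAxes | None = None,
                 config: dict | None = None) -> DihedronFitResults:
    """Functional wrapper around :class:`DihedronModel` fitting."""
    config = dict(config or {})
    reorient = config.pop("reorient", True)
    model = DihedronModel(cloud, axes=axes, reorient=reorient)
    return model.fit(**config)
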