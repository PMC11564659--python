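"""Dihedron unfolding: tile construction, validation, tiling, graphs and classification.

A T=1 icosahedral capsid is modelled as 60 congruent spherical tiles.  Each
tile is the unfolding of a dihedron (the doubly-covered fundamental triangle,
1/120 of the sphere) cut along a Y-shaped tree of geodesics meeting at a
single *junction point*.  The tile shape is therefore parameterized by just
the junction point's two gnomonic-plane coordinates and the handedness
(chirality) of the underlying triangle.

The tile polygon alternates the three symmetry-axis vertices with the three
mirror images of the junction point across the triangle edges:

    axis2, m23, axis3, m35, axis5, m52

where m_AB is the reflection of the junction point in the great circle
through axisA and axisB.  The 2-fold axis point is always a straight
(angle pi) vertex whenever the junction is not on it, which is why generic
tiles are geometrically pentagonal (pentagonal hexecontahedron faces).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation as R
from shapely import contains_xy
from shapely.geometry import Polygon

from .geometry import (
    IcosahedralAxes,
    geodesic_distance,
    gnomonic_project,
    gnomonic_unproject,
    reflect_across_great_circle,
    rotation_about,
    rotation_group,
    spherical_polygon_area,
    viper_axes,
)

__all__ = [
    "ROLES",
    "JunctionPoint",
    "Tile",
    "Tiling",
    "ContactGraph",
    "InterfaceLengths",
    "build_tile",
    "is_valid_junction",
    "degeneracy",
    "generate_tiling",
    "contact_graph",
    "dual_face_census",
    "interface_lengths",
    "triangulation_number",
]

ROLES = ("axis2", "mirror23", "axis3", "mirror35", "axis5", "mirror52")

#: angular tolerance (rad) below which the junction is considered on an axis
DEGENERACY_TOL = 1e-6


@dataclass(frozen=True)
class JunctionPoint:
    """Junction of the Y-shaped cut tree, in gnomonic-plane coordinates.

    ``(x, y)`` are coordinates in the plane tangent at +z (the projection
    pole); ``sigma`` selects the left- or right-handed fundamental triangle.
    Together these are the model's only parameters.
    """

    x: float
    y: float
    sigma: str = "right"

    def __post_init__(self) -> None:
        if self.sigma not in ("right", "left"):
            raise ValueError("sigma must be 'right' or 'left'")

    def sphere_point(self) -> np.ndarray:
        return gnomonic_unproject(self.x, self.y)

    def mirrored(self) -> "JunctionPoint":
        """Mirror image across the xz plane, with flipped chirality."""
        return JunctionPoint(self.x, -self.y, "left" if self.sigma == "right" else "right")


def _axes_for(j: JunctionPoint, axes: IcosahedralAxes | None) -> IcosahedralAxes:
    if axes is None:
        return viper_axes(j.sigma)
    if axes.handedness != j.sigma:
        return axes.mirrored()
    return axes


@dataclass(frozen=True)
class Tile:
    """One spherical tile: ordered vertices with role tags and a degeneracy label.

    ``vertices`` always carries the six role positions (axis2, mirror23,
    axis3, mirror35, axis5, mirror52); in degenerate placements some of them
    coincide.  ``vertices_distinct`` merges coincident cyclic neighbours,
    ``corners`` additionally absorbs straight (angle pi) vertices into their
    edge, giving the geometric polygon the tile actually is.
    """

    vertices: np.ndarray  # (6, 3)
    junction: JunctionPoint
    axes: IcosahedralAxes
    degeneracy: str
    roles: tuple = ROLES

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        v.setflags(write=False)

    def _distinct(self, tol: float = 1e-9) -> tuple[np.ndarray, tuple]:
        keep, roles = [], []
        n = len(self.vertices)
        for i in range(n):
            nxt = self.vertices[(i + 1) % n]
            if geodesic_distance(self.vertices[i], nxt) > tol:
                keep.append(self.vertices[i])
                roles.append(self.roles[i])
        return np.asarray(keep), tuple(roles)

    @cached_property
    def vertices_distinct(self) -> np.ndarray:
        """Vertices with cyclically-coincident duplicates merged."""
        return self._distinct()[0]

    @cached_property
    def corners(self) -> np.ndarray:
        """Geometric corners: coincident vertices merged, straight vertices absorbed."""
        v, _ = self._distinct()
        keep = []
        n = len(v)
        for i in range(n):
            a, b, c = v[(i - 1) % n], v[i], v[(i + 1) % n]
            # interior angle pi <=> b lies on the geodesic a-c
            ta = np.cross(b, a)
            tc = np.cross(b, c)
            s = np.linalg.norm(np.cross(ta, tc))
            d = np.dot(ta, tc)
            if not (s < 1e-9 * max(np.linalg.norm(ta) * np.linalg.norm(tc), 1e-30) and d < 0):
                keep.append(b)
        return np.asarray(keep)

    @property
    def area(self) -> float:
        """Spherical area of the tile; 4*pi/60 for every valid junction."""
        return spherical_polygon_area(self.vertices_distinct)

    def projected(self, recenter: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Gnomonic projection of the distinct vertices.

        With ``recenter`` the tile's vertex centroid is first rotated to the
        projection pole (avoids hemisphere clipping for arbitrary tiles);
        returns (2d vertices, rotation matrix applied).
        """
        v = self.vertices_distinct
        if recenter:
            c = v.mean(axis=0)
            c = c / np.linalg.norm(c)
            rot, _ = R.align_vectors(np.array([[0.0, 0.0, 1.0]]), c[None, :])
            q = rot.as_matrix()
        else:
            q = np.eye(3)
        return gnomonic_project(v @ q.T), q


def build_tile(j: JunctionPoint, axes: IcosahedralAxes | None = None,
               tol: float = DEGENERACY_TOL) -> Tile:
    """Construct the unfolded tile for a junction point.

    The polygon alternates the three symmetry-axis vertices with the three
    mirror images of the junction point across the edges of the fundamental
    triangle.  ``axes`` defaults to the VIPER triple matching ``j.sigma``
    (and is mirrored automatically if its handedness disagrees).
    """
    ax = _axes_for(j, axes)
    js = j.sphere_point()
    a2, a3, a5 = ax.points()
    m23 = reflect_across_great_circle(js, a2, a3)
    m35 = reflect_across_great_circle(js, a3, a5)
    m52 = reflect_across_great_circle(js, a5, a2)
    verts = np.stack([a2, m23, a3, m35, a5, m52])
    return Tile(vertices=verts, junction=j, axes=ax, degeneracy=degeneracy(j, ax, tol))


def degeneracy(j: JunctionPoint, axes: IcosahedralAxes | None = None,
               tol: float = DEGENERACY_TOL) -> str:
    """'generic', or 'on2fold'/'on3fold'/'on5fold' when the junction sits on an axis.

    ``tol`` is the angular tolerance in radians.
    """
    ax = _axes_for(j, axes)
    js = j.sphere_point()
    for name, a in zip(("on2fold", "on3fold", "on5fold"), ax.points()):
        if geodesic_distance(js, a) <= tol:
            return name
    return "generic"


def _projected_ring(tile: Tile) -> np.ndarray | None:
    """Distinct vertices projected from the +z pole, or None on hemisphere violation."""
    v = tile.vertices_distinct
    if np.any(v[:, 2] <= 1e-9):
        return None
    return gnomonic_project(v)


def is_valid_junction(j: JunctionPoint, axes: IcosahedralAxes | None = None) -> bool:
    """True iff the unfolded tile is a simple (non-self-intersecting) polygon
    with all vertices strictly inside the projection hemisphere.

    Junctions outside the fundamental triangle can still be valid (concave
    tiles); far enough out, mirror-reflected edges cross and the unfolding
    self-intersects.
    """
    try:
        tile = build_tile(j, axes)
    except ValueError:
        return False
    ring = _projected_ring(tile)
    if ring is None:
        return False
    if len(ring) < 3:
        return False
    poly = Polygon(ring)
    return bool(poly.is_valid and poly.area > 0.0)


@dataclass(frozen=True)
class InterfaceLengths:
    """Arc lengths of the shared boundary with the 2-, 3- and 5-fold neighbours.

    L3 and L5 equal the geodesic distance from the junction point to the
    respective axis; L2 is twice the distance to the 2-fold axis because that
    contact is face-to-face between a single pair of tiles.  ``dominant`` is
    the axis with the longest interface; ``ambiguous`` flags a tie at 1e-9.
    """

    L2: float
    L3: float
    L5: float
    dominant: str
    ambiguous: bool = False

    def as_dict(self) -> dict:
        return {"L2": self.L2, "L3": self.L3, "L5": self.L5,
                "dominant": self.dominant, "ambiguous": self.ambiguous}


def interface_lengths(j: JunctionPoint, axes: IcosahedralAxes | None = None) -> InterfaceLengths:
    ax = _axes_for(j, axes)
    js = j.sphere_point()
    L2 = 2.0 * float(geodesic_distance(ax.axis2, js))
    L3 = float(geodesic_distance(ax.axis3, js))
    L5 = float(geodesic_distance(ax.axis5, js))
    lengths = {"2fold": L2, "3fold": L3, "5fold": L5}
    best = max(lengths.values())
    tied = [k for k, v in lengths.items() if best - v <= 1e-9]
    # tie-break toward the lower fold, flagged
    order = {"2fold": 0, "3fold": 1, "5fold": 2}
    dominant = min(tied, key=lambda k: order[k])
    return InterfaceLengths(L2=L2, L3=L3, L5=L5, dominant=dominant, ambiguous=len(tied) > 1)


@dataclass
class Tiling:
    """The 60-tile tiling: one base tile plus the rotation mapping it to each copy."""

    base: Tile
    rotations: list  # 60 rotation matrices; rotations[i] maps base -> tile i

    def __post_init__(self) -> None:
        self.vertices_all = np.einsum("nij,vj->nvi", np.stack(self.rotations), self.base.vertices)

    def __len__(self) -> int:
        return len(self.rotations)

    def tile_vertices(self, i: int) -> np.ndarray:
        return self.vertices_all[i]

    @cached_property
    def _base_poly(self) -> tuple[Polygon, np.ndarray]:
        ring, q = self.base.projected(recenter=True)
        return Polygon(ring), q

    def _membership(self, points: np.ndarray, buffer: float = 0.0) -> np.ndarray:
        """(n_points, 60) boolean membership matrix.

        ``buffer`` grows (+) or shrinks (-) the tile polygon in the recentred
        gnomonic plane; useful for excluding a boundary band.
        """
        poly, q = self._base_poly
        if buffer:
            poly = poly.buffer(buffer)
        points = np.asarray(points, dtype=float)
        out = np.zeros((len(points), len(self)), dtype=bool)
        for i, rot in enumerate(self.rotations):
            local = points @ rot @ q.T  # rot^-1 then recentre: (q @ rot.T @ p)
            ok = local[:, 2] > 1e-9
            if np.any(ok):
                xy = np.stack([local[ok, 0] / local[ok, 2], local[ok, 1] / local[ok, 2]], axis=-1)
                out[np.flatnonzero(ok), i] = contains_xy(poly, xy[:, 0], xy[:, 1])
        return out

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Index of the tile strictly containing each point (-1 if none/boundary)."""
        m = self._membership(points)
        counts = m.sum(axis=1)
        idx = np.where(counts == 1, m.argmax(axis=1), -1)
        return idx

    def membership_counts(self, points: np.ndarray, buffer: float = 0.0) -> np.ndarray:
        return self._membership(points, buffer=buffer).sum(axis=1)


def generate_tiling(tile_or_junction, group: list | None = None) -> Tiling:
    """60 rotated copies of a valid tile under the chiral icosahedral group."""
    if isinstance(tile_or_junction, JunctionPoint):
        tile = build_tile(tile_or_junction)
    else:
        tile = tile_or_junction
    if not is_valid_junction(tile.junction, tile.axes):
        raise ValueError("refusing to tile from an invalid (self-intersecting) junction")
    if group is None:
        group = rotation_group(tile.axes)
    if len(group) != 60:
        raise ValueError("rotation group must have 60 elements")
    return Tiling(base=tile, rotations=list(group))


@dataclass
class ContactGraph:
    """Polyhedral (tile-adjacency) graph of a tiling and its dual spherical map.

    ``graph`` has the 60 tiles as nodes; each edge carries an ``axis``
    attribute ('2fold'/'3fold'/'5fold') naming the symmetry generating the
    contact.  ``dual_faces`` lists the face sizes of the dual map (one face
    per tiling vertex where >= 3 tiles meet); V, E, F describe the primal
    spherical map (F = 60 tiles) and satisfy Euler's formula V - E + F = 2.
    """

    graph: nx.Graph
    dual_faces: list[int] = field(default_factory=list)
    n_vertices: int = 0
    n_edges: int = 0
    n_faces: int = 60

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def face_census(self) -> dict[int, int]:
        return dict(sorted(Counter(self.dual_faces).items()))


def contact_graph(tiling: Tiling, length_tol: float = 1e-8) -> ContactGraph:
    """Build the contact graph and the dual map of a tiling.

    Adjacency: tile i touches the images of itself under its local 2-, 3- and
    5-fold generators; a contact counts only if the corresponding interface
    arc has positive length (degenerate junctions collapse one contact type
    to a point).  The dual faces are found geometrically by clustering the
    tiles' vertex images: every cluster where k >= 3 distinct tiles meet is a
    tiling vertex and contributes one k-sided dual face.
    """
    base = tiling.base
    ax = base.axes
    ifl = interface_lengths(base.junction, ax)
    gens: list[tuple[np.ndarray, str]] = []
    if ifl.L2 > length_tol:
        gens.append((rotation_about(ax.axis2, np.pi), "2fold"))
    if ifl.L3 > length_tol:
        for s in (1, -1):
            gens.append((rotation_about(ax.axis3, s * 2.0 * np.pi / 3.0), "3fold"))
    if ifl.L5 > length_tol:
        for s in (1, -1):
            gens.append((rotation_about(ax.axis5, s * 2.0 * np.pi / 5.0), "5fold"))

    def key(m):
        return tuple((np.round(m, 6) + 0.0).ravel())

    index = {key(rot): i for i, rot in enumerate(tiling.rotations)}
    g = nx.Graph()
    g.add_nodes_from(range(len(tiling)))
    for i, rot in enumerate(tiling.rotations):
        for gen, label in gens:
            jdx = index.get(key(rot @ gen))
            if jdx is None:
                raise RuntimeError("tiling rotations do not form a group closure")
            if i != jdx:
                g.add_edge(i, jdx, axis=label)

    # --- dual map from vertex clustering --------------------------------
    pts = tiling.vertices_all.reshape(-1, 3)
    tile_of = np.repeat(np.arange(len(tiling)), tiling.vertices_all.shape[1])
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=1e-6, output_type="ndarray")
    parent = np.arange(len(pts))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.array([find(i) for i in range(len(pts))])
    clusters: dict[int, set[int]] = {}
    for i, r in enumerate(roots):
        clusters.setdefault(r, set()).add(int(tile_of[i]))

    dual_faces = []
    tiles_vertex_count = np.zeros(len(tiling), dtype=int)
    for tiles in clusters.values():
        if len(tiles) >= 3:
            dual_faces.append(len(tiles))
            for t in tiles:
                tiles_vertex_count[t] += 1
    v = len(dual_faces)
    e2 = int(tiles_vertex_count.sum())
    if e2 % 2:
        raise RuntimeError("inconsistent tiling map: odd boundary-vertex total")
    return ContactGraph(graph=g, dual_faces=sorted(dual_faces), n_vertices=v,
                        n_edges=e2 // 2, n_faces=len(tiling))


def dual_face_census(graph: ContactGraph) -> dict[int, int]:
    """Face-size census of the dual spherical map, e.g. {3: 80, 5: 12} for generic tilings."""
    return graph.face_census()


def triangulation_number(h: int, k: int) -> int:
    """Caspar-Klug triangulation number T = h^2 + hk + k^2 (60T subunits per capsid)."""
    if h != int(h) or k != int(k):
        raise ValueError("h and k must be integers")
    h, k = int(h), int(k)
    if h < 0 or k < 0:
        raise ValueError("h and k must be non-negative")
    if h == 0 and k == 0:
        raise ValueError("(h, k) = (0, 0) has no triangulation number")
    return h * h + h * k + k * k
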