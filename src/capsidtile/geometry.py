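"""Icosahedral symmetry in the VIPER convention and spherical-geometry primitives.

The VIPER convention orients an icosahedral particle so that two of its
2-fold axes coincide with the z and x coordinate axes, with 3-fold and
5-fold axes lying between them in the xz plane.  All downstream analysis
(tile construction, gnomonic projection, fitting) works in this frame.

The fundamental spherical triangle used throughout has its 2-fold vertex at
+z, the adjacent 3-fold axis point in the xz half-plane (x >= 0), and the
adjacent 5-fold axis point just off that plane; the three points are pairwise
adjacent axes of the icosahedron (angular separations 20.905, 31.717 and
37.377 degrees) and bound 1/120 of the sphere.  Mirroring the triangle across
the xz plane swaps its handedness.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.transform import Rotation as R

__all__ = [
    "PHI",
    "IcosahedralAxes",
    "viper_axes",
    "rotation_group",
    "rotation_about",
    "gnomonic_project",
    "gnomonic_unproject",
    "geodesic_distance",
    "reflect_across_great_circle",
    "spherical_triangle_area",
    "spherical_polygon_area",
    "HemisphereError",
]

#: golden ratio
PHI = (1.0 + np.sqrt(5.0)) / 2.0

_Z = np.array([0.0, 0.0, 1.0])


class HemisphereError(ValueError):
    """Raised when a point to be projected lies outside the projection hemisphere."""


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-300):
        raise ValueError("cannot normalize zero vector")
    return v / n


@dataclass(frozen=True)
class IcosahedralAxes:
    """One fundamental triple of mutually adjacent 2-, 3- and 5-fold axis points.

    The three unit vectors bound a single fundamental spherical triangle
    (1/120 of the sphere).  ``handedness`` is 'right' when the vertices
    2, 3, 5 appear counterclockwise viewed from outside the sphere
    (positive scalar triple product), 'left' otherwise.
    """

    axis2: np.ndarray
    axis3: np.ndarray
    axis5: np.ndarray

    def __post_init__(self) -> None:
        for name in ("axis2", "axis3", "axis5"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a unit 3-vector")
            object.__setattr__(self, name, v)
            v.setflags(write=False)

    @property
    def handedness(self) -> str:
        return "right" if np.linalg.det(np.stack([self.axis2, self.axis3, self.axis5])) > 0 else "left"

    def mirrored(self) -> "IcosahedralAxes":
        """The mirror triple across the xz plane (swaps handedness)."""
        m = np.array([1.0, -1.0, 1.0])
        return IcosahedralAxes(self.axis2 * m, self.axis3 * m, self.axis5 * m)

    def points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (self.axis2, self.axis3, self.axis5)

    @property
    def triangle_area(self) -> float:
        return spherical_triangle_area(self.axis2, self.axis3, self.axis5)


def viper_axes(handedness: str = "right") -> IcosahedralAxes:
    """Fundamental axis triple in the VIPER orientation.

    axis2 is +z (an icosahedral 2-fold axis; another lies along +x), axis3 is
    the adjacent face axis in the xz half-plane at 20.905 deg from z, and
    axis5 the adjacent vertex axis at 31.717 deg from z, tilted off the xz
    plane toward +y ('right') or -y ('left').
    """
    if handedness not in ("right", "left"):
        raise ValueError("handedness must be 'right' or 'left'")
    s = 1.0 if handedness == "right" else -1.0
    axes = IcosahedralAxes(
        axis2=_Z.copy(),
        axis3=_unit([1.0, 0.0, PHI**2]),
        axis5=_unit([0.0, s, PHI]),
    )
    assert axes.handedness == handedness
    return axes


def rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Proper rotation matrix by ``angle`` radians about ``axis`` (through the origin)."""
    return R.from_rotvec(_unit(axis) * float(angle)).as_matrix()


def _mat_key(m: np.ndarray) -> tuple:
    # canonical dedup/sort key; +0.0 collapses -0.0
    return tuple((np.round(m, 6) + 0.0).ravel())


@lru_cache(maxsize=4)
def _cached_group(handedness: str) -> tuple[np.ndarray, ...]:
    axes = viper_axes(handedness)
    g5 = rotation_about(axes.axis5, 2.0 * np.pi / 5.0)
    g2 = rotation_about(axes.axis2, np.pi)
    elems: dict[tuple, np.ndarray] = {_mat_key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    for _ in range(100):
        if not frontier:
            break
        new = []
        for m in frontier:
            for g in (g5, g2):
                p = g @ m
                k = _mat_key(p)
                if k not in elems:
                    elems[k] = p
                    new.append(p)
        frontier = new
        if len(elems) > 60:
            raise RuntimeError("group closure exceeded 60 elements; inconsistent axes")
    if len(elems) != 60:
        raise RuntimeError(f"group closure terminated with {len(elems)} elements, expected 60")
    ordered = [elems[k] for k in sorted(elems)]
    for m in ordered:
        m.setflags(write=False)
    return tuple(ordered)


def rotation_group(axes: IcosahedralAxes | None = None) -> list[np.ndarray]:
    """The 60 proper rotations of the chiral icosahedral group.

    Generated by closure from the 72 deg rotation about axis5 and the 180 deg
    rotation about axis2; returned in a deterministic order (lexicographic on
    rounded matrix entries), identity included.
    """
    handedness = axes.handedness if axes is not None else "right"
    if axes is not None:
        ref = viper_axes(handedness)
        for a, b in zip(axes.points(), ref.points()):
            if not np.allclose(a, b, atol=1e-9):
                # recompute for a non-standard (but valid) axis set
                return _closure_from(axes)
    return list(_cached_group(handedness))


def _closure_from(axes: IcosahedralAxes) -> list[np.ndarray]:
    g5 = rotation_about(axes.axis5, 2.0 * np.pi / 5.0)
    g2 = rotation_about(axes.axis2, np.pi)
    elems = {_mat_key(np.eye(3)): np.eye(3)}
    frontier = [np.eye(3)]
    while frontier:
        new = []
        for m in frontier:
            for g in (g5, g2):
                p = g @ m
                k = _mat_key(p)
                if k not in elems:
                    elems[k] = p
                    new.append(p)
        frontier = new
        if len(elems) > 60:
            raise RuntimeError("group closure exceeded 60 elements; inconsistent axes")
    if len(elems) != 60:
        raise RuntimeError(f"group closure terminated with {len(elems)} elements, expected 60")
    return [elems[k] for k in sorted(elems)]


def _pole_frame(pole: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic tangent basis (e1, e2) at the projection pole.

    For the default +z pole this is (x, y), so plane coordinates agree with
    the intuitive reading of the z=1 projection plane.
    """
    pole = _unit(pole)
    if abs(pole[2]) > 1.0 - 1e-12:
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = _unit(np.cross(_Z, pole))
    e2 = np.cross(pole, e1)
    return e1, e2


def gnomonic_project(p: np.ndarray, pole: np.ndarray | None = None) -> np.ndarray:
    """Central (gnomonic) projection onto the plane tangent at ``pole``.

    Great circles map to straight lines.  ``p`` may be a single 3-vector or an
    (n, 3) array.  Raises :class:`HemisphereError` if any point is not strictly
    on the pole's open hemisphere.
    """
    pole = _Z if pole is None else _unit(pole)
    p = np.asarray(p, dtype=float)
    e1, e2 = _pole_frame(pole)
    denom = p @ pole
    if np.any(denom <= 1e-12):
        raise HemisphereError("point(s) outside the projection hemisphere")
    out = np.stack([(p @ e1) / denom, (p @ e2) / denom], axis=-1)
    return out


def gnomonic_unproject(x, y, pole: np.ndarray | None = None) -> np.ndarray:
    """Inverse gnomonic projection; result is a unit vector on the pole's hemisphere."""
    pole = _Z if pole is None else _unit(pole)
    e1, e2 = _pole_frame(pole)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v = pole + x[..., None] * e1 + y[..., None] * e2 if x.ndim else pole + x * e1 + y * e2
    return _unit(v)


def geodesic_distance(u: np.ndarray, v: np.ndarray) -> float | np.ndarray:
    """Arc distance in [0, pi] between unit vectors, in the numerically stable atan2 form."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    cross = np.cross(u, v)
    sin = np.linalg.norm(cross, axis=-1)
    cos = np.sum(u * v, axis=-1)
    return np.arctan2(sin, cos)


def reflect_across_great_circle(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mirror image of ``p`` in the great circle through ``a`` and ``b``.

    Householder reflection about the plane spanned by a and b (normal a x b).
    """
    n = np.cross(a, b)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("a and b are parallel/antiparallel: great circle undefined")
    n = n / nn
    p = np.asarray(p, dtype=float)
    return p - 2.0 * np.dot(p, n) * n


def signed_spherical_excess(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Signed spherical excess (= signed area on the unit sphere) of triangle abc.

    Positive when a, b, c are counterclockwise viewed from outside.
    Uses the Eriksson/van Oosterom-Strackee half-angle formula.
    """
    num = np.linalg.det(np.stack([a, b, c]))
    den = 1.0 + np.dot(a, b) + np.dot(b, c) + np.dot(c, a)
    return 2.0 * np.arctan2(num, den)


def spherical_triangle_area(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Unsigned spherical-excess area of the triangle with unit-vector vertices a, b, c."""
    return abs(signed_spherical_excess(a, b, c))


def spherical_polygon_area(vertices: np.ndarray) -> float:
    """Area of a simple spherical polygon with geodesic edges (unit sphere).

    Computed as a fan of signed excesses from the first vertex, so concave
    simple polygons are handled correctly.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape[0] < 3:
        return 0.0
    total = 0.0
    for i in range(1, v.shape[0] - 1):
        total += signed_spherical_excess(v[0], v[i], v[i + 1])
    return abs(total)
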