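"""Neighborhood selection and alpha-complex filtrations on C-alpha clouds.

The alpha complex of a 3D point cloud is the subcomplex of its Delaunay
triangulation whose simplices admit an empty circumscribing sphere of
radius at most r; each simplex carries the squared radius of its smallest
empty circumscribing sphere as filtration value. A paper radius r maps to
the boundary-inclusive threshold ``alpha_value <= r**2``.

Two independent routes are provided: :func:`build_alpha_complex` computes
the filtration from the Delaunay triangulation with the standard
downward-propagation/Gabriel algorithm, while :func:`alpha_oracle`
enumerates candidate circumscribing spheres directly and checks the
empty-sphere condition by brute force (usable up to 10 points only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import PslflexError

#: numerical slack, in A^2, for boundary-inclusive radius thresholds and
#: for strict-inside circumsphere predicates
ALPHA_TOL = 1e-9

#: magnitude of the deterministic jitter applied when Qhull rejects an
#: exactly degenerate (collinear/coplanar/cospherical) configuration
DEGENERACY_JITTER = 1e-6


@dataclass
class LabeledPointCloud:
    """Points with per-point sheaf labels q_i.

    In protein mode the focal C-alpha has label 0 and its neighbors label 1,
    which is what localizes the sheaf spectra at that atom.
    """

    points: np.ndarray
    labels: np.ndarray
    focal_index: Optional[int] = None
    source_indices: Optional[np.ndarray] = None  # original C-alpha indices

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels must have equal length")
        if self.focal_index is not None and self.labels[self.focal_index] != 0.0:
            raise ValueError("focal point must carry label 0")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Simplex:
    """A simplex of dimension <= 2 with its alpha filtration value (A^2)."""

    vertices: tuple
    alpha_value: float

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1


@dataclass
class FiltrationComplex:
    """Face-closed simplicial complex of dimension <= 2."""

    n_points: int
    simplices: list[Simplex] = field(default_factory=list)

    def simplex_tuples(self, dim: Optional[int] = None) -> list[tuple]:
        if dim is None:
            return [s.vertices for s in self.simplices]
        return sorted(s.vertices for s in self.simplices if s.dim == dim)

    def alpha_of(self, vertices: tuple) -> float:
        for s in self.simplices:
            if s.vertices == tuple(vertices):
                return s.alpha_value
        raise KeyError(vertices)


def select_neighborhood(structure, atom_index: int, cutoff: float) -> LabeledPointCloud:
    """The focal C-alpha plus every C-alpha within ``cutoff`` angstroms.

    The focal point gets label 0, all neighbors label 1. A lone focal atom
    is a valid one-point cloud.
    """
    coords = structure.ca_coordinates
    if not 0 <= atom_index < len(coords):
        raise IndexError(f"atom index {atom_index} out of range")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dist = np.linalg.norm(coords - coords[atom_index], axis=1)
    keep = np.flatnonzero(dist <= cutoff)
    labels = np.ones(len(keep))
    focal = int(np.flatnonzero(keep == atom_index)[0])
    labels[focal] = 0.0
    return LabeledPointCloud(
        points=coords[keep],
        labels=labels,
        focal_index=focal,
        source_indices=keep,
    )


def _circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest sphere through all given points (center in their affine hull).

    Returns (center, squared radius). Raises ``np.linalg.LinAlgError`` for
    affinely dependent configurations.
    """
    p0 = points[0]
    if len(points) == 1:
        return p0.copy(), 0.0
    v = points[1:] - p0
    gram = 2.0 * v @ v.T
    rhs = np.einsum("ij,ij->i", v, v)
    y = np.linalg.solve(gram, rhs)
    center = p0 + y @ v
    r2 = float(np.dot(center - p0, center - p0))
    return center, r2


def _jittered(points: np.ndarray) -> np.ndarray:
    """Deterministic tie-break jitter seeded from the coordinates themselves."""
    digest = np.asarray(np.round(points, 6)).tobytes()
    seed = int.from_bytes(digest[:8].ljust(8, b"\0"), "little") % (2**31)
    rng = np.random.default_rng(seed)
    return points + rng.normal(scale=DEGENERACY_JITTER, size=points.shape)


def _is_gabriel(points: np.ndarray, simplex: tuple) -> tuple[bool, float]:
    """Whether the simplex's smallest circumsphere is empty of other points.

    Returns (gabriel, squared circumradius).
    """
    center, r2 = _circumsphere(points[list(simplex)])
    d2 = np.einsum("ij,ij->i", points - center, points - center)
    margin = ALPHA_TOL * max(1.0, r2)
    inside = d2 < r2 - margin
    inside[list(simplex)] = False
    return not inside.any(), r2


def _alpha_values_delaunay(points: np.ndarray) -> dict[tuple, float]:
    """Alpha filtration values for all Delaunay simplices of dim <= 2.

    Standard characterization: a top (3-)simplex enters at its squared
    circumradius; a lower simplex enters at its own squared circumradius if
    it is Gabriel (smallest circumsphere empty), and otherwise inherits the
    minimum value of its Delaunay cofaces.
    """
    n = len(points)
    if n == 1:
        return {(0,): 0.0}
    if n == 2:
        _, r2 = _circumsphere(points)
        return {(0,): 0.0, (1,): 0.0, (0, 1): r2}
    if n == 3:
        return _alpha_values_triangle(points)

    try:
        tri = Delaunay(points)
    except QhullError:
        tri = Delaunay(_jittered(points))

    by_dim: dict[int, set[tuple]] = {1: set(), 2: set(), 3: set()}
    cofaces: dict[tuple, set[tuple]] = {}
    for tet in tri.simplices:
        tet = tuple(sorted(int(v) for v in tet))
        by_dim[3].add(tet)
        for face in combinations(tet, 3):
            by_dim[2].add(face)
            cofaces.setdefault(face, set()).add(tet)
    for triangle in by_dim[2]:
        for face in combinations(triangle, 2):
            by_dim[1].add(face)
            cofaces.setdefault(face, set()).add(triangle)

    alpha: dict[tuple, float] = {(i,): 0.0 for i in range(n)}
    for tet in by_dim[3]:
        try:
            _, alpha[tet] = _circumsphere(points[list(tet)])
        except np.linalg.LinAlgError:
            _, alpha[tet] = _circumsphere(_jittered(points[list(tet)]))
    for dim in (2, 1):
        for simplex in by_dim[dim]:
            try:
                gabriel, r2 = _is_gabriel(points, simplex)
            except np.linalg.LinAlgError:
                gabriel, r2 = False, np.inf
            if gabriel:
                alpha[simplex] = r2
            else:
                alpha[simplex] = min(alpha[c] for c in cofaces[simplex])
    # safety monotonization: a face never appears after a coface
    for dim in (2, 1):
        for simplex in by_dim[dim]:
            for coface in cofaces[simplex]:
                alpha[simplex] = min(alpha[simplex], alpha[coface])
    return {s: v for s, v in alpha.items() if len(s) <= 3}


def _alpha_values_triangle(points: np.ndarray) -> dict[tuple, float]:
    """Direct alpha values for exactly three points (Delaunay = the triangle)."""
    alpha: dict[tuple, float] = {(0,): 0.0, (1,): 0.0, (2,): 0.0}
    try:
        _, tri_r2 = _circumsphere(points)
    except np.linalg.LinAlgError:  # collinear: no triangle, edges by length
        tri_r2 = None
    for i, j in combinations(range(3), 2):
        center, r2 = _circumsphere(points[[i, j]])
        k = 3 - i - j
        inside = (
            np.dot(points[k] - center, points[k] - center)
            < r2 - ALPHA_TOL * max(1.0, r2)
        )
        if inside and tri_r2 is not None:
            alpha[(i, j)] = tri_r2
        else:
            alpha[(i, j)] = r2
    if tri_r2 is not None:
        alpha[(0, 1, 2)] = tri_r2
    return alpha


def _threshold(alpha: dict[tuple, float], n_points: int, radius: float) -> FiltrationComplex:
    r2 = radius * radius
    cut = r2 + ALPHA_TOL * max(1.0, r2)
    simplices = [
        Simplex(vertices=s, alpha_value=v)
        for s, v in alpha.items()
        if len(s) == 1 or v <= cut
    ]
    simplices.sort(key=lambda s: (s.dim, s.vertices))
    return FiltrationComplex(n_points=n_points, simplices=simplices)


def build_alpha_complex(cloud: LabeledPointCloud, radius: float) -> FiltrationComplex:
    """Alpha complex of the cloud at the given radius (angstroms).

    Keeps simplices of dimension <= 2 whose alpha value is at most
    ``radius**2`` (boundary inclusive); vertices are always present.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    alpha = _alpha_values_delaunay(cloud.points)
    return _threshold(alpha, len(cloud), radius)


def alpha_oracle(cloud: LabeledPointCloud, radius: float) -> FiltrationComplex:
    """Brute-force alpha complex for clouds of at most 10 points.

    For every candidate simplex the minimum-radius *empty* circumscribing
    sphere is found by enumerating the circumspheres of the simplex
    augmented with up to ``4 - |simplex|`` extra points (the only possible
    constrained minima) and checking the empty-sphere condition directly.
    Independent of the Delaunay route by construction.
    """
    points = cloud.points
    n = len(points)
    if n > 10:
        raise PslflexError("alpha_oracle limited to 10 points")
    if radius <= 0:
        raise ValueError("radius must be positive")

    alpha: dict[tuple, float] = {(i,): 0.0 for i in range(n)}
    for size in (2, 3):
        for simplex in combinations(range(n), size):
            others = [i for i in range(n) if i not in simplex]
            best = np.inf
            for extra in range(0, 4 - size + 1):
                for aug in combinations(others, extra):
                    idx = list(simplex) + list(aug)
                    try:
                        center, r2 = _circumsphere(points[idx])
                    except np.linalg.LinAlgError:
                        continue
                    if r2 >= best:
                        continue
                    d2 = np.einsum(
                        "ij,ij->i", points - center, points - center
                    )
                    margin = ALPHA_TOL * max(1.0, r2)
                    strictly_inside = d2 < r2 - margin
                    strictly_inside[idx] = False
                    if not strictly_inside.any():
                        best = r2
            if np.isfinite(best):
                alpha[simplex] = best
    # monotonize exactly as the filtration convention requires
    for simplex in [s for s in alpha if len(s) == 3]:
        for face in combinations(simplex, 2):
            if face in alpha:
                alpha[face] = min(alpha[face], alpha[simplex])
    return _threshold(alpha, n, radius)
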