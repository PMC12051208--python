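"""Cellular sheaves on alpha complexes and their (persistent) Laplacians.

A labeled point cloud induces a cellular sheaf on any complex built over
it: every simplex carries a one-dimensional stalk, and the restriction map
for a codimension-one face relation is scalar multiplication by

* ``q_j / r_ij``            for a vertex ``v_i <= edge v_i v_j``,
* ``q_k / (r_ik * r_jk)``   for an edge ``v_i v_j <= triangle v_i v_j v_k``,

where ``q`` are the vertex labels and ``r`` the Euclidean edge lengths.
With the focal atom labeled 0 and its neighbors 1, the spectra of the
resulting sheaf Laplacians L0 = d0^T d0 and L1 = d1^T d1 + d0 d0^T localize
the topology and geometry of the cloud at the focal atom. With all labels
equal to 1 and unit edge lengths the construction degenerates to the
combinatorial graph/simplicial Laplacian.

The persistent operator for a subcomplex pair X <= Y is assembled so that
its kernel dimension equals the rank of the restriction-induced map on
degree-q sheaf cohomology H^q(Y) -> H^q(X); at X = Y it reduces exactly to
the sheaf Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg

from .errors import PslflexError
from .filtration import FiltrationComplex, LabeledPointCloud

#: relative zero-eigenvalue threshold: lambda counts as zero iff
#: lambda < ZERO_EIG_RTOL * max(1, lambda_max)
ZERO_EIG_RTOL = 1e-8

#: numerical symmetry slack for spectrum()
SYMMETRY_TOL = 1e-9


@dataclass
class SheafStructure:
    """A sheaf over a filtration complex: labels, edge lengths, restrictions."""

    complex: FiltrationComplex
    labels: np.ndarray
    edge_lengths: dict
    restriction_scalars: dict  # {(face_tuple, coface_tuple): scalar}

    @property
    def vertices(self) -> list[tuple]:
        return self.complex.simplex_tuples(dim=0)

    @property
    def edges(self) -> list[tuple]:
        return self.complex.simplex_tuples(dim=1)

    @property
    def triangles(self) -> list[tuple]:
        return self.complex.simplex_tuples(dim=2)


@dataclass
class CoboundaryPair:
    """Coboundary matrices: d0 (edges x vertices), d1 (triangles x edges)."""

    d0: np.ndarray
    d1: np.ndarray


@dataclass
class SpectralSummary:
    """The five per-radius features: zero count + nonzero-eigenvalue stats."""

    n_zero: int
    max_nz: float
    min_nz: float
    mean_nz: float
    fourth_stat: float
    tol: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.n_zero, self.max_nz, self.min_nz, self.mean_nz, self.fourth_stat]
        )


def build_sheaf(complex_: FiltrationComplex, cloud: LabeledPointCloud) -> SheafStructure:
    """Populate restriction scalars and edge lengths for the labeled sheaf."""
    points = cloud.points
    labels = np.asarray(cloud.labels, dtype=float)
    if not np.all(np.isfinite(labels)):
        raise PslflexError("labels must be finite")

    lengths: dict = {}

    def r(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in lengths:
            d = float(np.linalg.norm(points[i] - points[j]))
            if d == 0.0:
                raise PslflexError(f"coincident points {i}, {j}")
            lengths[key] = d
        return lengths[key]

    scalars: dict = {}
    for i, j in complex_.simplex_tuples(dim=1):
        scalars[((i,), (i, j))] = labels[j] / r(i, j)
        scalars[((j,), (i, j))] = labels[i] / r(i, j)
    for i, j, k in complex_.simplex_tuples(dim=2):
        r(i, j), r(i, k), r(j, k)  # cache all three lengths
        scalars[((j, k), (i, j, k))] = labels[i] / (r(j, i) * r(k, i))
        scalars[((i, k), (i, j, k))] = labels[j] / (r(i, j) * r(k, j))
        scalars[((i, j), (i, j, k))] = labels[k] / (r(i, k) * r(j, k))
    return SheafStructure(
        complex=complex_,
        labels=labels,
        edge_lengths=lengths,
        restriction_scalars=scalars,
    )


def coboundaries(sheaf: SheafStructure) -> CoboundaryPair:
    """Assemble d0 and d1 with the ascending-index orientation.

    The incidence sign for the face obtained by dropping the vertex in
    position p of an ascending tuple is (-1)^p.
    """
    vertices = sheaf.vertices
    edges = sheaf.edges
    triangles = sheaf.triangles
    v_index = {v[0]: col for col, v in enumerate(vertices)}
    e_index = {e: col for col, e in enumerate(edges)}

    d0 = np.zeros((len(edges), len(vertices)))
    for row, (i, j) in enumerate(edges):
        # dropping position 0 leaves vertex j (sign +), position 1 leaves i (-)
        d0[row, v_index[j]] = +sheaf.restriction_scalars[((j,), (i, j))]
        d0[row, v_index[i]] = -sheaf.restriction_scalars[((i,), (i, j))]

    d1 = np.zeros((len(triangles), len(edges)))
    for row, tri in enumerate(triangles):
        for p in range(3):
            face = tri[:p] + tri[p + 1 :]
            d1[row, e_index[face]] = (-1.0) ** p * sheaf.restriction_scalars[
                (face, tri)
            ]
    return CoboundaryPair(d0=d0, d1=d1)


def sheaf_laplacian(sheaf: SheafStructure, q: int) -> np.ndarray:
    """The degree-q sheaf Laplacian: L0 = d0^T d0, L1 = d1^T d1 + d0 d0^T."""
    if q not in (0, 1):
        raise ValueError("q must be 0 or 1")
    pair = coboundaries(sheaf)
    if q == 0:
        n = len(sheaf.vertices)
        if pair.d0.size == 0:
            return np.zeros((n, n))
        return pair.d0.T @ pair.d0
    n_edges = len(sheaf.edges)
    if n_edges == 0:
        return np.zeros((0, 0))
    up = pair.d1.T @ pair.d1 if pair.d1.size else np.zeros((n_edges, n_edges))
    return up + pair.d0 @ pair.d0.T


def _check_subsheaf(sheafX: SheafStructure, sheafY: SheafStructure) -> None:
    setX = set(sheafX.complex.simplex_tuples())
    setY = set(sheafY.complex.simplex_tuples())
    if not setX <= setY:
        raise PslflexError("X is not a subcomplex of Y")
    for key, value in sheafX.restriction_scalars.items():
        other = sheafY.restriction_scalars.get(key)
        if other is None or abs(other - value) > 1e-12 * max(1.0, abs(value)):
            raise PslflexError(f"restriction scalars disagree on {key}")


def persistent_sheaf_laplacian(
    sheafX: SheafStructure, sheafY: SheafStructure, q: int
) -> np.ndarray:
    """Persistent sheaf Laplacian of the pair X <= Y on degree-q cochains of X.

    Built from the adjoint coboundary of the larger complex:

        Delta_q^{X,Y} = D D^T + d_{q-1}^X (d_{q-1}^X)^T,

    where ``D`` is ``(d_q^Y)^T`` restricted to the subspace of degree-(q+1)
    cochains of Y whose adjoint image is supported on simplices of X (the
    image then automatically lies in C^q(X) because X is face-closed). Its
    kernel dimension equals the rank of H^q(Y) -> H^q(X), and at X = Y the
    operator is the sheaf Laplacian itself.
    """
    if q not in (0, 1):
        raise ValueError("q must be 0 or 1")
    same = set(sheafX.complex.simplex_tuples()) == set(sheafY.complex.simplex_tuples())
    if same:
        return sheaf_laplacian(sheafX, q)
    _check_subsheaf(sheafX, sheafY)

    pairX = coboundaries(sheafX)
    pairY = coboundaries(sheafY)
    q_simplices_Y = sheafY.edges if q == 1 else sheafY.vertices
    q_simplices_X = sheafX.edges if q == 1 else sheafX.vertices
    nX = len(q_simplices_X)

    dqY = pairY.d1 if q == 1 else pairY.d0  # C^q(Y) -> C^{q+1}(Y)
    adjoint = dqY.T  # C^{q+1}(Y) -> C^q(Y), rows indexed by q-simplices of Y
    members_X = set(q_simplices_X)
    rows_out = [row for row, s in enumerate(q_simplices_Y) if s not in members_X]
    # X rows of the adjoint, in X's own simplex ordering
    y_pos = {s: row for row, s in enumerate(q_simplices_Y)}
    rows_X = [y_pos[s] for s in q_simplices_X]

    if adjoint.shape[1] == 0:
        up = np.zeros((nX, nX))
    else:
        if rows_out:
            basis = scipy.linalg.null_space(adjoint[rows_out, :])
        else:
            basis = np.eye(adjoint.shape[1])
        D = adjoint[rows_X, :] @ basis if basis.size else np.zeros((nX, 0))
        up = D @ D.T if D.size else np.zeros((nX, nX))

    if q == 0:
        down = np.zeros((nX, nX))
    else:
        down = (
            pairX.d0 @ pairX.d0.T
            if pairX.d0.size
            else np.zeros((nX, nX))
        )
    return up + down


def spectrum(matrix: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of a symmetric matrix, clipped at zero.

    Small negative values within the numerical tolerance are clipped to 0;
    genuine asymmetry raises.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        return np.zeros(0)
    scale = max(1.0, float(np.abs(matrix).max()))
    if np.abs(matrix - matrix.T).max() > SYMMETRY_TOL * scale:
        raise PslflexError("matrix is not symmetric")
    eigs = np.linalg.eigvalsh((matrix + matrix.T) / 2.0)
    floor = -ZERO_EIG_RTOL * max(1.0, float(eigs[-1]) if len(eigs) else 1.0)
    return np.where((eigs < 0) & (eigs >= floor), 0.0, eigs)


def summarize(
    eigs: np.ndarray,
    fourth_stat: str = "median",
    tol_abs: Optional[float] = None,
) -> SpectralSummary:
    """Zero-eigenvalue count plus statistics of the nonzero eigenvalues.

    ``fourth_stat`` selects the configuration-dependent fifth feature:
    "median" (per-protein regression preset) or "std" (blind-prediction
    preset). An eigenvalue counts as zero when it falls below the relative
    threshold ``ZERO_EIG_RTOL * max(1, lambda_max)``, or below ``tol_abs``
    when an absolute tolerance is given.
    """
    if fourth_stat not in ("median", "std"):
        raise ValueError("fourth_stat must be 'median' or 'std'")
    eigs = np.asarray(eigs, dtype=float)
    if eigs.size == 0:
        return SpectralSummary(0, 0.0, 0.0, 0.0, 0.0, tol=tol_abs or 0.0)
    tol = tol_abs if tol_abs is not None else ZERO_EIG_RTOL * max(1.0, float(eigs.max()))
    nonzero = eigs[eigs >= tol]
    n_zero = int(eigs.size - nonzero.size)
    if nonzero.size == 0:
        return SpectralSummary(n_zero, 0.0, 0.0, 0.0, 0.0, tol=tol)
    fourth = float(np.median(nonzero) if fourth_stat == "median" else np.std(nonzero))
    return SpectralSummary(
        n_zero=n_zero,
        max_nz=float(nonzero.max()),
        min_nz=float(nonzero.min()),
        mean_nz=float(nonzero.mean()),
        fourth_stat=fourth,
        tol=tol,
    )
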