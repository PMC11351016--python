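"""Filtered simplicial complexes: Vietoris–Rips and Alpha.

A filtration is a nested family of simplicial complexes indexed by a scale
parameter. Dimension-0 features are extracted from a Vietoris–Rips (VR)
filtration, which only needs a dissimilarity matrix and therefore accepts
the modified cross-set distance (excluded pairs simply never form edges).
Dimensions 1–2 use the Alpha complex, the subcomplex of the 3-D Delaunay
triangulation selected by a growing circumradius bound.

Scale conventions
-----------------
* VR filtration values are *edge lengths* (the diameter convention): an
  edge {i, j} enters at d(i, j) and a higher simplex at the maximum of its
  edge values.
* Alpha filtration values are reported on the *radius* scale in Å
  (square roots of the squared-circumradius values used internally), so VR
  and Alpha grids share units.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .siteselect import PairDistanceMatrix

__all__ = [
    "Simplex",
    "SimplicialComplex",
    "Filtration",
    "build_vr_filtration",
    "build_alpha_filtration",
    "snapshot",
    "DEFAULT_VR_GRID",
    "DEFAULT_ALPHA_GRID",
]

#: Default filtration grid for VR (dimension-0) features, Å.
DEFAULT_VR_GRID = np.arange(0.0, 12.0 + 1e-9, 0.25)
#: Default filtration grid for Alpha (dimension 1–2) features, Å.
DEFAULT_ALPHA_GRID = np.arange(0.0, 10.0 + 1e-9, 0.25)

_SNAP_TOL = 1e-9


@dataclass(frozen=True)
class Simplex:
    """A k-simplex given by its sorted vertex indices and entry scale."""

    vertices: tuple[int, ...]
    filtration_value: float

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.vertices, self.vertices[1:])):
            raise ValueError(f"vertices must be strictly increasing: {self.vertices}")

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1

    def faces(self) -> Iterable[tuple[int, ...]]:
        """The (k−1)-faces, each omitting one vertex."""
        for i in range(len(self.vertices)):
            yield self.vertices[:i] + self.vertices[i + 1:]


class SimplicialComplex:
    """A face-closed simplex collection with per-dimension index maps."""

    def __init__(self, simplices: Iterable[tuple[int, ...]]):
        by_dim: dict[int, list[tuple[int, ...]]] = {}
        seen = set()
        for v in simplices:
            v = tuple(v)
            if v in seen:
                continue
            seen.add(v)
            by_dim.setdefault(len(v) - 1, []).append(v)
        for d, simps in by_dim.items():
            simps.sort()
            for s in simps:
                for i in range(len(s)):
                    face = s[:i] + s[i + 1:]
                    if face and face not in seen:
                        raise ValueError(f"complex not face-closed: {s} lacks face {face}")
        self._by_dim = {d: by_dim.get(d, []) for d in range(max(by_dim, default=-1) + 1)}
        self._index = {
            d: {s: i for i, s in enumerate(simps)} for d, simps in self._by_dim.items()
        }

    @property
    def max_dim(self) -> int:
        return max((d for d, s in self._by_dim.items() if s), default=-1)

    def simplices(self, dim: int) -> list[tuple[int, ...]]:
        return self._by_dim.get(dim, [])

    def index(self, dim: int) -> dict[tuple[int, ...], int]:
        return self._index.get(dim, {})

    def n_simplices(self, dim: int) -> int:
        return len(self._by_dim.get(dim, []))

    def __contains__(self, vertices: tuple[int, ...]) -> bool:
        return vertices in self._index.get(len(vertices) - 1, {})

    def __le__(self, other: "SimplicialComplex") -> bool:
        return all(
            set(self.simplices(d)) <= set(other.simplices(d))
            for d in range(self.max_dim + 1)
        )


@dataclass
class Filtration:
    """An ordered, face-closed list of simplices with entry scales."""

    simplices: list[Simplex]
    kind: str
    max_dim: int = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in {"vietoris_rips", "alpha"}:
            raise ValueError(f"unknown filtration kind {self.kind!r}")
        self.simplices = sorted(
            self.simplices, key=lambda s: (s.filtration_value, s.dim, s.vertices)
        )
        self.max_dim = max((s.dim for s in self.simplices), default=-1)
        values = {s.vertices: s.filtration_value for s in self.simplices}
        for s in self.simplices:
            for face in s.faces():
                if not face:
                    continue
                if face not in values:
                    raise ValueError(f"filtration not face-closed: {s.vertices} lacks {face}")
                if values[face] > s.filtration_value + _SNAP_TOL:
                    raise ValueError(
                        f"face {face} enters at {values[face]} after coface "
                        f"{s.vertices} at {s.filtration_value}"
                    )

    def __len__(self) -> int:
        return len(self.simplices)

    @property
    def max_value(self) -> float:
        return max((s.filtration_value for s in self.simplices), default=0.0)

    def critical_values(self) -> np.ndarray:
        return np.unique([s.filtration_value for s in self.simplices])

    def to_csv(self, path) -> None:
        """Serialize as ``vertices|dim|value`` rows (debugging aid)."""
        import pandas as pd

        pd.DataFrame(
            {
                "vertices": [" ".join(map(str, s.vertices)) for s in self.simplices],
                "dim": [s.dim for s in self.simplices],
                "value": [s.filtration_value for s in self.simplices],
            }
        ).to_csv(path, sep="|", index=False)


def build_vr_filtration(
    distances: PairDistanceMatrix | np.ndarray,
    max_scale: float,
    max_dim: int = 1,
) -> Filtration:
    """Vietoris–Rips filtration from a distance matrix or 3-D point cloud.

    Vertices enter at 0; an edge {i, j} enters at d(i, j) when that distance
    is at most ``max_scale`` and the pair is not excluded; a k-simplex enters
    at the maximum of its edge values (diameter rule). Excluded pairs of a
    modified cross-set distance never appear in any simplex.
    """
    if max_scale <= 0:
        raise ValueError(f"max_scale must be positive, got {max_scale}")
    if isinstance(distances, PairDistanceMatrix):
        dmat = np.asarray(distances.values, dtype=float)
        excluded = distances.excluded.copy()
    else:
        arr = np.asarray(distances, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 3 and arr.shape[0] != 3:
            from scipy.spatial.distance import cdist

            dmat = cdist(arr, arr)
        else:
            dmat = arr
        if dmat.shape[0] != dmat.shape[1] or not np.allclose(dmat, dmat.T, atol=1e-9):
            raise ValueError("distance matrix must be square and symmetric")
        excluded = np.zeros_like(dmat, dtype=bool)
        np.fill_diagonal(excluded, True)

    n = dmat.shape[0]
    simplices = [Simplex((i,), 0.0) for i in range(n)]
    edge_value: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if excluded[i, j] or dmat[i, j] > max_scale:
                continue
            edge_value[(i, j)] = float(dmat[i, j])
            simplices.append(Simplex((i, j), float(dmat[i, j])))

    # Higher simplices: every pair must be an admissible edge (clique rule).
    prev = list(edge_value.keys())
    for dim in range(2, max_dim + 1):
        cur: list[tuple[int, ...]] = []
        for verts in prev:
            last = verts[-1]
            for k in range(last + 1, n):
                if all((v, k) in edge_value for v in verts):
                    simp = verts + (k,)
                    value = max(edge_value[(a, b)] for a, b in itertools.combinations(simp, 2))
                    simplices.append(Simplex(simp, value))
                    cur.append(simp)
        prev = cur
        if not cur:
            break
    return Filtration(simplices, kind="vietoris_rips")


def _circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Circumcenter and squared circumradius of a k-simplex in R^3.

    The circumcenter is the point of the simplex's affine hull equidistant
    from all vertices.
    """
    p0 = points[0]
    diffs = points[1:] - p0  # k x 3
    if diffs.shape[0] == 0:
        return p0.copy(), 0.0
    gram = diffs @ diffs.T
    rhs = 0.5 * np.einsum("ij,ij->i", diffs, diffs)
    coef = np.linalg.solve(gram, rhs)
    center = p0 + coef @ diffs
    r2 = float(np.dot(center - p0, center - p0))
    return center, r2


def build_alpha_filtration(
    points: np.ndarray,
    jitter_seed: int = 0,
    jitter_scale: float = 1e-6,
) -> Filtration:
    """Alpha filtration of a 3-D point cloud (radius scale, Å).

    Simplices are those of the Delaunay triangulation; each receives the
    standard alpha value — its squared circumradius if its circumsphere is
    empty (Gabriel), otherwise the minimum value over its cofaces — and
    values are reported as radii. Degenerate (coplanar/collinear) clouds are
    perturbed by a deterministic jitter before triangulation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"expected an (n, 3) point cloud, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("point cloud contains non-finite coordinates")
    n = pts.shape[0]
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    if n < 4:
        # Too few points for a 3-D triangulation: the Delaunay complex is the
        # full simplex on the points; fall through to direct alpha values.
        tets: list[tuple[int, ...]] = [tuple(range(n))] if n > 1 else []
        working = pts
        if n == 3 and np.linalg.matrix_rank(pts[1:] - pts[0], tol=1e-9) < 2:
            rng = np.random.default_rng(jitter_seed)
            working = pts + rng.normal(scale=jitter_scale, size=pts.shape)
    else:
        try:
            tri = Delaunay(pts)
            working = pts
        except QhullError:
            rng = np.random.default_rng(jitter_seed)
            working = pts + rng.normal(scale=jitter_scale, size=pts.shape)
            tri = Delaunay(working)
        tets = [tuple(sorted(int(v) for v in simp)) for simp in tri.simplices]

    # Collect every face of every top simplex, grouped by dimension.
    by_dim: dict[int, set[tuple[int, ...]]] = {d: set() for d in range(4)}
    top_dim = max((len(t) - 1 for t in tets), default=0)
    for t in tets:
        d = len(t) - 1
        for sub_d in range(d + 1):
            for face in itertools.combinations(t, sub_d + 1):
                by_dim[sub_d].add(face)
    for i in range(n):
        by_dim[0].add((i,))

    kdt_points = working
    value: dict[tuple[int, ...], float] = {}  # squared-radius scale

    def is_gabriel(face: tuple[int, ...]) -> bool:
        center, r2 = _circumsphere(kdt_points[list(face)])
        d2 = np.einsum("ij,ij->i", kdt_points - center, kdt_points - center)
        mask = np.ones(n, dtype=bool)
        mask[list(face)] = False
        return not np.any(d2[mask] < r2 - 1e-12)

    for dim in range(top_dim, 0, -1):
        for simp in sorted(by_dim[dim]):
            if simp not in value:
                _, r2 = _circumsphere(kdt_points[list(simp)])
                value[simp] = r2
            for i in range(len(simp)):
                face = simp[:i] + simp[i + 1:]
                if face in value:
                    value[face] = min(value[face], value[simp])
                elif not is_gabriel(face):
                    value[face] = value[simp]
    for v in by_dim[0]:
        value[v] = 0.0

    # Any remaining unassigned simplices (Gabriel faces) take their own
    # circumradius when reached in their dimension loop above; vertices are 0.
    simplices = [
        Simplex(s, float(np.sqrt(max(value[s], 0.0))))
        for d in range(top_dim + 1)
        for s in sorted(by_dim[d])
    ]
    return Filtration(simplices, kind="alpha")


def snapshot(filtration: Filtration, t: float) -> SimplicialComplex:
    """The complex K_t: all simplices entered at scale ≤ t."""
    if t < 0:
        raise ValueError(f"snapshot scale must be ≥ 0, got {t}")
    return SimplicialComplex(
        s.vertices for s in filtration.simplices if s.filtration_value <= t + _SNAP_TOL
    )
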