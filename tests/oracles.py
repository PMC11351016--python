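"""Independent oracles used by the test suite.

These deliberately avoid the library's computational paths: membership by
brute-force distance scans, Betti numbers by boundary-matrix rank over the
reals, and persistent homology by the classic GF(2) column-reduction
algorithm operating directly on a filtration's simplex list.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np


def brute_force_within(
    query: np.ndarray, targets: np.ndarray, r: float
) -> np.ndarray:
    """Boolean mask: which query points lie within r of any target (O(N·M))."""
    out = np.zeros(len(query), dtype=bool)
    for i, q in enumerate(query):
        for t in targets:
            if np.linalg.norm(q - t) <= r:
                out[i] = True
                break
    return out


def brute_force_vr_simplices(
    dist: np.ndarray, max_scale: float, max_dim: int, excluded: np.ndarray | None = None
) -> dict[int, set[tuple[int, ...]]]:
    """All VR simplices by exhaustive subset enumeration with the diameter rule."""
    n = dist.shape[0]
    if excluded is None:
        excluded = np.zeros_like(dist, dtype=bool)
        np.fill_diagonal(excluded, True)
    out: dict[int, set] = {0: {(i,) for i in range(n)}}
    for dim in range(1, max_dim + 1):
        out[dim] = set()
        for verts in itertools.combinations(range(n), dim + 1):
            ok = True
            for a, b in itertools.combinations(verts, 2):
                if excluded[a, b] or dist[a, b] > max_scale:
                    ok = False
                    break
            if ok:
                out[dim].add(verts)
    return out


def rank_betti(complex, k: int) -> int:
    """β_k by rank–nullity on independently constructed boundary matrices.

    β_k = dim ker ∂_k − rank ∂_{k+1} = n_k − rank B_k − rank B_{k+1};
    no eigensolver involved.
    """
    def boundary(dim: int) -> np.ndarray:
        rows = {s: i for i, s in enumerate(complex.simplices(dim - 1))}
        cols = complex.simplices(dim)
        mat = np.zeros((len(rows), len(cols)))
        for j, simp in enumerate(cols):
            for i in range(len(simp)):
                face = simp[:i] + simp[i + 1:]
                mat[rows[face], j] = (-1.0) ** i
        return mat

    n_k = complex.n_simplices(k)
    if n_k == 0:
        return 0
    rank_down = 0
    if k >= 1:
        bk = boundary(k)
        rank_down = int(np.linalg.matrix_rank(bk)) if bk.size else 0
    rank_up = 0
    if complex.n_simplices(k + 1) > 0:
        bk1 = boundary(k + 1)
        rank_up = int(np.linalg.matrix_rank(bk1)) if bk1.size else 0
    return n_k - rank_down - rank_up


class GF2Persistence:
    """Persistent homology of a filtration via GF(2) column reduction.

    Columns are stored as Python integers (bitsets over the filtration
    order); the standard reduction pairs each death simplex with the birth
    it kills. Betti numbers at scale t count classes born at ≤ t and not
    yet dead at t.
    """

    _TOL = 1e-9

    def __init__(self, filtration):
        simps = sorted(
            filtration.simplices, key=lambda s: (s.filtration_value, s.dim, s.vertices)
        )
        index = {s.vertices: i for i, s in enumerate(simps)}
        self.values = np.array([s.filtration_value for s in simps])
        self.dims = np.array([s.dim for s in simps])
        reduced: dict[int, int] = {}  # low row -> column index
        cols: dict[int, int] = {}  # death column -> reduced bitset
        self.death_of: dict[int, int] = {}  # birth index -> death index
        for j, s in enumerate(simps):
            col = 0
            if s.dim > 0:
                for i in range(len(s.vertices)):
                    face = s.vertices[:i] + s.vertices[i + 1:]
                    col |= 1 << index[face]
            while col:
                low = col.bit_length() - 1
                if low not in reduced:
                    break
                col ^= cols[reduced[low]]
            if col:
                low = col.bit_length() - 1
                reduced[low] = j
                cols[j] = col
                self.death_of[low] = j
        # a simplex is a birth iff its column reduced to zero
        self.birth_set = {j for j in range(len(simps)) if j not in cols}

    def betti(self, k: int, t: float) -> int:
        count = 0
        for b in self.birth_set:
            if self.dims[b] != k or self.values[b] > t + self._TOL:
                continue
            d = self.death_of.get(b)
            if d is None or self.values[d] > t + self._TOL:
                count += 1
        return count


def alpha_value_qp(points: np.ndarray, simplex: tuple[int, ...]) -> float:
    """Alpha filtration value (radius) of a Delaunay simplex by definition.

    A simplex enters the alpha complex at the smallest r for which some
    point x of its common Voronoi face lies within r of its vertices:
    minimize |x − v0| subject to equidistance to all simplex vertices and
    to no other point being closer. Both constraint families are linear in
    x, so this is a convex QP solved independently of any combinatorial
    propagation.
    """
    from scipy.linalg import null_space
    from scipy.optimize import minimize

    pts = np.asarray(points, dtype=float)
    v = pts[list(simplex)]
    v0 = v[0]
    others = [i for i in range(len(pts)) if i not in simplex]

    # Equidistance constraints are linear: 2 x·(vi−v0) = |vi|²−|v0|².
    # Parametrize their solution set as x = c + N z with c the circumcenter
    # (always feasible) and N a null-space basis, leaving a QP in z with
    # linear "no other point closer" inequalities.
    diffs = v[1:] - v0
    if diffs.shape[0]:
        gram = diffs @ diffs.T
        rhs = 0.5 * np.einsum("ij,ij->i", diffs, diffs)
        c = v0 + np.linalg.solve(gram, rhs) @ diffs
        nsp = null_space(diffs)
    else:
        c = v0.copy()
        nsp = np.eye(3)

    def point(z):
        return c + nsp @ z if nsp.shape[1] else c

    def fun(z):
        d = point(z) - v0
        return float(d @ d)

    cons = []
    for j in others:
        u = pts[j]
        # |x−u|² ≥ |x−v0|²  <=>  −2 x·(u−v0) + |u|²−|v0|² ≥ 0
        a = -2.0 * (u - v0)
        b = float(u @ u - v0 @ v0)
        cons.append({
            "type": "ineq",
            "fun": lambda z, a=a, b=b: a @ point(z) + b,
            "jac": lambda z, a=a: a @ nsp,
        })
    if nsp.shape[1] == 0:
        for con in cons:
            if con["fun"](np.zeros(0)) < -1e-9:
                raise RuntimeError(f"simplex {simplex} not Delaunay")
        return float(np.linalg.norm(c - v0))
    res = minimize(fun, np.zeros(nsp.shape[1]), constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-16})
    if not res.success and res.fun is None:
        raise RuntimeError(f"QP failed for simplex {simplex}: {res.message}")
    return float(np.sqrt(res.fun))


def pearson_direct(x: Sequence[float], y: Sequence[float]) -> float:
    """Textbook product-moment formula by direct summation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxy = float(np.sum(x * y))
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    num = n * sxy - sx * sy
    den = np.sqrt(n * sxx - sx * sx) * np.sqrt(n * syy - sy * sy)
    return num / den


def random_vr_complex(rng: np.random.Generator, n_min: int = 6, n_max: int = 14):
    """A random face-closed complex: VR snapshot of a random cloud."""
    from toplap.filtration import build_vr_filtration, snapshot

    n = int(rng.integers(n_min, n_max + 1))
    pts = rng.uniform(0, 2.5, size=(n, 3))
    filt = build_vr_filtration(pts, max_scale=2.0, max_dim=3)
    t = float(rng.uniform(0.4, 2.0))
    return snapshot(filt, t)
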