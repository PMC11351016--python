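"""Combinatorial Laplacian spectra of filtered simplicial complexes.

The k-combinatorial Laplacian of a simplicial complex is

    L_k = B_{k+1} B_{k+1}^T + B_k^T B_k,      L_0 = B_1 B_1^T,

where B_k is the signed boundary matrix over the reals (chains carry real
coefficients so the eigen-spectrum is meaningful and orientation-invariant).
By the combinatorial Hodge theorem the multiplicity of the zero eigenvalue
of L_k equals the k-th Betti number β_k (components, loops, cavities for
k = 0, 1, 2); the harmonic part of the spectrum therefore carries the
topology, while the nonzero (nonharmonic) eigenvalues add geometric shape
information that Betti numbers lack. Tracking both along a filtration
yields the spectral feature vectors used for binding-free-energy models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .filtration import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_VR_GRID,
    Filtration,
    SimplicialComplex,
    build_alpha_filtration,
    build_vr_filtration,
    snapshot,
)
from .siteselect import (
    DEFAULT_ELEMENT_PAIRS,
    DEFAULT_RADIUS,
    AtomSubset,
    MutationSpec,
    binding_site_atoms,
    dmod_matrix,
    mutation_site_atoms,
    neighborhood_atoms,
)
from .structio import ComplexStructure

__all__ = [
    "BoundaryMatrix",
    "LaplacianSpectrum",
    "SpectralFeatures",
    "FeatureConfig",
    "boundary_matrix",
    "combinatorial_laplacian",
    "laplacian_from_boundaries",
    "spectrum",
    "spectrum_of",
    "betti_curve",
    "spectral_features",
    "NONHARMONIC_STATS",
]

#: Relative zero-eigenvalue tolerance: λ < ZERO_TOL · max(1, λ_max) is harmonic.
ZERO_TOL = 1e-8

#: Order above which dense eigendecomposition gives way to extremal solvers.
DENSE_LIMIT = 2000

NONHARMONIC_STATS = ("min", "max", "mean", "std", "sum", "count")


@dataclass
class BoundaryMatrix:
    """Signed incidence matrix of the k-th boundary operator.

    Rows index (k−1)-simplices, columns k-simplices; the column of
    σ = [v_0 … v_k] has entry (−1)^i in the row of the face omitting v_i
    (sorted-vertex orientation).
    """

    k: int
    matrix: sp.csr_matrix
    rows: dict[tuple[int, ...], int]
    cols: dict[tuple[int, ...], int]


def boundary_matrix(complex: SimplicialComplex, k: int) -> BoundaryMatrix:
    """The boundary matrix ∂_k of a face-closed complex, k ≥ 1."""
    if k < 1:
        raise ValueError("boundary_matrix is defined for k ≥ 1 (∂_0 is the zero map)")
    rows = complex.index(k - 1)
    cols = complex.index(k)
    data, ri, ci = [], [], []
    for simp, j in cols.items():
        for i, _ in enumerate(simp):
            face = simp[:i] + simp[i + 1:]
            data.append((-1.0) ** i)
            ri.append(rows[face])
            ci.append(j)
    mat = sp.csr_matrix(
        (data, (ri, ci)), shape=(len(rows), len(cols)), dtype=float
    )
    return BoundaryMatrix(k=k, matrix=mat, rows=dict(rows), cols=dict(cols))


def laplacian_from_boundaries(
    b_k: Optional[sp.spmatrix], b_k1: Optional[sp.spmatrix]
) -> np.ndarray:
    """L_k from explicit boundary matrices B_k (down) and B_{k+1} (up)."""
    parts = []
    if b_k1 is not None and b_k1.shape[1] > 0:
        parts.append((b_k1 @ b_k1.T).toarray())
        order = b_k1.shape[0]
    if b_k is not None and b_k.shape[1] > 0:
        parts.append((b_k.T @ b_k).toarray())
        order = b_k.shape[1]
    if not parts:
        return np.zeros((0, 0))
    out = np.zeros((order, order))
    for p in parts:
        out += p
    return out


def combinatorial_laplacian(complex: SimplicialComplex, k: int) -> np.ndarray:
    """L_k = B_{k+1}B_{k+1}ᵀ + B_kᵀB_k (L_0 = B_1B_1ᵀ) as a dense array."""
    n_k = complex.n_simplices(k)
    if n_k == 0:
        return np.zeros((0, 0))
    up = boundary_matrix(complex, k + 1).matrix
    lap = (up @ up.T).toarray() if up.shape[1] else np.zeros((n_k, n_k))
    if k >= 1:
        down = boundary_matrix(complex, k).matrix
        lap += (down.T @ down).toarray()
    return lap


@dataclass
class LaplacianSpectrum:
    """Ascending eigenvalues of L_k with the harmonic/nonharmonic split."""

    k: int
    eigenvalues: np.ndarray
    tolerance: float = field(default=0.0)
    truncated: bool = False

    def __post_init__(self) -> None:
        self.eigenvalues = np.sort(np.asarray(self.eigenvalues, dtype=float))
        if self.tolerance == 0.0:
            lam_max = self.eigenvalues[-1] if self.eigenvalues.size else 0.0
            self.tolerance = ZERO_TOL * max(1.0, lam_max)

    @property
    def zero_multiplicity(self) -> int:
        return int(np.sum(self.eigenvalues < self.tolerance))

    @property
    def betti(self) -> int:
        return self.zero_multiplicity

    @property
    def nonharmonic(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues >= self.tolerance]


def spectrum(L: np.ndarray, k: int = 0, dense_limit: int = DENSE_LIMIT) -> LaplacianSpectrum:
    """Eigen-spectrum of a symmetric Laplacian matrix.

    Above ``dense_limit`` only the extremal ends of the spectrum are
    computed (64 smallest via shift-invert, 64 largest); the result is
    flagged ``truncated`` and its Betti count refers to the computed end
    of the spectrum only.
    """
    L = np.asarray(L, dtype=float)
    if L.size == 0:
        return LaplacianSpectrum(k=k, eigenvalues=np.array([]))
    if L.shape[0] != L.shape[1] or not np.allclose(L, L.T, atol=1e-8):
        raise ValueError("Laplacian must be square symmetric")
    n = L.shape[0]
    if n <= dense_limit:
        return LaplacianSpectrum(k=k, eigenvalues=np.linalg.eigvalsh(L))
    from scipy.sparse.linalg import eigsh

    k_ext = min(64, n - 2)
    sparse = sp.csr_matrix(L)
    low = eigsh(sparse, k=k_ext, sigma=-1e-3, which="LM", return_eigenvectors=False)
    high = eigsh(sparse, k=k_ext, which="LM", return_eigenvectors=False)
    return LaplacianSpectrum(
        k=k, eigenvalues=np.concatenate([low, high]), truncated=True
    )


def spectrum_of(complex: SimplicialComplex, k: int, dense_limit: int = DENSE_LIMIT) -> LaplacianSpectrum:
    """Spectrum of L_k(complex); an absent dimension gives an empty spectrum."""
    return spectrum(combinatorial_laplacian(complex, k), k=k, dense_limit=dense_limit)


def betti_curve(
    filtration: Filtration, k: int, grid: Sequence[float], dense_limit: int = DENSE_LIMIT
) -> np.ndarray:
    """β_k at every scale of an ascending grid."""
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be ascending")
    return np.array(
        [spectrum_of(snapshot(filtration, t), k, dense_limit).betti for t in grid]
    )


def _stats_block(spec: LaplacianSpectrum) -> np.ndarray:
    """(betti, min, max, mean, std, sum, count) of the nonharmonic spectrum."""
    nh = spec.nonharmonic
    if nh.size == 0:
        return np.array([spec.betti, 0, 0, 0, 0, 0, 0], dtype=float)
    return np.array(
        [spec.betti, nh.min(), nh.max(), nh.mean(), nh.std(), nh.sum(), nh.size],
        dtype=float,
    )


_STAT_NAMES = ("betti",) + NONHARMONIC_STATS


@dataclass
class FeatureConfig:
    """Configuration of the spectral featurization.

    ``radius`` (Å) selects the mutation neighborhood and binding sites;
    ``element_pairs`` drives the cross-set (modified-distance) dimension-0
    blocks; ``vr_grid``/``alpha_grid`` are the filtration grids in Å;
    ``alpha_dims`` the homology dimensions read off the Alpha complexes.
    """

    radius: float = DEFAULT_RADIUS
    element_pairs: tuple = DEFAULT_ELEMENT_PAIRS
    vr_grid: np.ndarray = field(default_factory=lambda: DEFAULT_VR_GRID.copy())
    alpha_grid: np.ndarray = field(default_factory=lambda: DEFAULT_ALPHA_GRID.copy())
    alpha_dims: tuple[int, ...] = (1, 2)
    alpha_elements: tuple[str, ...] = ("C", "N", "O")
    dense_limit: int = DENSE_LIMIT

    @classmethod
    def small(cls) -> "FeatureConfig":
        """A compact cohort-scale configuration: dimension-0 blocks only,
        on a coarse grid with the two extreme element pairings (hydrophobic
        C–C and hydrophilic N–O)."""
        return cls(
            element_pairs=(
                (frozenset("C"), frozenset("C")),
                (frozenset("N"), frozenset("O")),
            ),
            vr_grid=np.arange(0.0, 12.0 + 1e-9, 1.5),
            alpha_grid=np.arange(0.0, 10.0 + 1e-9, 2.0),
            alpha_dims=(),
        )


@dataclass
class SpectralFeatures:
    """A flat feature vector with a stable layout descriptor.

    ``names[i]`` documents ``values[i]`` as
    ``<block>|<subsets>|<elements>|t=<scale>|<statistic>``; ``empty_blocks``
    lists blocks whose atom subset was empty (their entries are zero with
    count 0).
    """

    values: np.ndarray
    names: list[str]
    empty_blocks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("layout descriptor does not match vector length")

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values, index=self.names)


def _elem_tag(group: frozenset) -> str:
    return "".join(sorted(group))


def _vr_block(
    name: str,
    set_a: AtomSubset,
    set_b: AtomSubset,
    grid: np.ndarray,
    dense_limit: int,
) -> tuple[np.ndarray, list[str], bool]:
    n_stats = len(_STAT_NAMES)
    names = [f"vr0|{name}|t={t:g}|{s}" for t in grid for s in _STAT_NAMES]
    if set_a.is_empty or set_b.is_empty:
        return np.zeros(len(grid) * n_stats), names, True
    pdm = dmod_matrix(set_a, set_b)
    filt = build_vr_filtration(pdm, max_scale=float(grid[-1]), max_dim=1)
    vals = np.concatenate(
        [
            _stats_block(spectrum_of(snapshot(filt, t), 0, dense_limit))
            for t in grid
        ]
    )
    return vals, names, False


def _alpha_block(
    name: str,
    coords: np.ndarray,
    dims: tuple[int, ...],
    grid: np.ndarray,
    dense_limit: int,
) -> tuple[np.ndarray, list[str], bool]:
    names = [
        f"alpha{k}|{name}|t={t:g}|{s}" for k in dims for t in grid for s in _STAT_NAMES
    ]
    n_stats = len(_STAT_NAMES)
    if coords.shape[0] < 2:
        return np.zeros(len(dims) * len(grid) * n_stats), names, True
    filt = build_alpha_filtration(coords)
    vals = []
    for k in dims:
        for t in grid:
            vals.append(_stats_block(spectrum_of(snapshot(filt, t), k, dense_limit)))
    return np.concatenate(vals), names, False


def spectral_features(
    structure: ComplexStructure,
    mutation: MutationSpec,
    config: Optional[FeatureConfig] = None,
) -> SpectralFeatures:
    """Element/site-specific persistent-spectral feature vector for a mutation.

    Dimension-0 blocks: Vietoris–Rips filtrations of the modified cross-set
    distance for (site, neighborhood) and (P1-binding, P2-binding) subset
    pairs under each configured element pairing. Dimension-1/2 blocks: Alpha
    filtrations of the raw coordinates of the site∪neighborhood and binding
    point clouds. Per scale, each block records β_k plus summary statistics
    of the nonharmonic spectrum. Deterministic for a fixed structure,
    mutation and configuration; atom input order does not matter.
    """
    cfg = config or FeatureConfig()
    heavy = tuple(sorted(cfg.alpha_elements))

    def site(elems):
        return mutation_site_atoms(structure, mutation, elems)

    def hood(elems):
        return neighborhood_atoms(structure, mutation, cfg.radius, elems)

    def binding(side, elems):
        return binding_site_atoms(structure, side, cfg.radius, elems)

    values: list[np.ndarray] = []
    names: list[str] = []
    empties: list[str] = []

    pairings = [
        ("site-neighborhood", site, hood),
        ("p1b-p2b", lambda e: binding("p1", e), lambda e: binding("p2", e)),
    ]
    for pname, fa, fb in pairings:
        for ga, gb in cfg.element_pairs:
            tag = f"{pname}|{_elem_tag(ga)}-{_elem_tag(gb)}"
            v, n, empty = _vr_block(
                tag, fa(tuple(sorted(ga))), fb(tuple(sorted(gb))),
                cfg.vr_grid, cfg.dense_limit,
            )
            values.append(v)
            names.extend(n)
            if empty:
                empties.append(tag)

    if cfg.alpha_dims:
        site_hood = np.vstack([
            c for c in (site(heavy).coords, hood(heavy).coords) if c.size
        ]) if (len(site(heavy)) + len(hood(heavy))) else np.empty((0, 3))
        bind_cloud = np.vstack([
            c
            for c in (binding("p1", heavy).coords, binding("p2", heavy).coords)
            if c.size
        ]) if (len(binding("p1", heavy)) + len(binding("p2", heavy))) else np.empty((0, 3))
        for aname, cloud in [("site-neighborhood", site_hood), ("binding", bind_cloud)]:
            cloud = _dedupe_rows(cloud)
            v, n, empty = _alpha_block(
                f"{aname}|{_elem_tag(frozenset(heavy))}",
                cloud, cfg.alpha_dims, cfg.alpha_grid, cfg.dense_limit,
            )
            values.append(v)
            names.extend(n)
            if empty:
                empties.append(f"alpha|{aname}")

    return SpectralFeatures(
        values=np.concatenate(values) if values else np.array([]),
        names=names,
        empty_blocks=empties,
    )


def _dedupe_rows(coords: np.ndarray) -> np.ndarray:
    """Drop duplicate coordinates (shared atoms across merged subsets)."""
    if coords.shape[0] == 0:
        return coords
    _, idx = np.unique(np.round(coords, 6), axis=0, return_index=True)
    return coords[np.sort(idx)]
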