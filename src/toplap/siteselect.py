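"""Element/site-specific atom subsets and the modified distance matrix.

The topological featurization works on four atom subsets of a complex —
the mutation site, its distance-``r`` neighborhood, and each partner's
binding-site atoms — intersected with element groups such as {C}, {N},
{O} or {C,N,O}. Cross-set interactions are encoded through a modified
distance: pairs of atoms drawn from the *same* subset are excluded
(pushed beyond every filtration scale), so only cross-subset contacts
can form simplices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structio import Atom, ComplexStructure, Residue, StructureError

__all__ = [
    "MutationSpec",
    "AtomSubset",
    "PairDistanceMatrix",
    "DEFAULT_RADIUS",
    "DEFAULT_ELEMENT_PAIRS",
    "parse_mutation_string",
    "read_mutation_table",
    "mutation_site_atoms",
    "neighborhood_atoms",
    "binding_site_atoms",
    "dmod_matrix",
]

#: Default selection radius (Å) for the mutation neighborhood and the
#: binding site. A configuration key, not a constant of the method.
DEFAULT_RADIUS = 10.0

#: Default element-group pairings for cross-set distance features:
#: hydrophobic C–C contacts plus the polar N/O combinations.
DEFAULT_ELEMENT_PAIRS: tuple[tuple[frozenset, frozenset], ...] = tuple(
    (frozenset(a), frozenset(b))
    for a, b in [("C", "C"), ("C", "N"), ("C", "O"), ("N", "N"), ("N", "O"), ("O", "O")]
)

_MUTATION_RE = re.compile(r"^([A-Z])([A-Za-z0-9])(\d+)([A-Za-z]?)([A-Z])$")


@dataclass(frozen=True)
class MutationSpec:
    """A single point mutation, SKEMPI-style.

    ``wt`` and ``mut`` are 1-letter amino-acid codes; ``position`` is the
    author residue number (with optional insertion code); ``ddg`` is the
    measured binding free energy change in kcal/mol, optional at
    selection time.
    """

    complex_id: str
    chain_id: str
    position: int
    wt: str
    mut: str
    icode: str = ""
    ddg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.wt == self.mut:
            raise ValueError(f"wild-type equals mutant ({self.wt}) at {self.position}")

    @property
    def label(self) -> str:
        return f"{self.wt}{self.chain_id}{self.position}{self.icode}{self.mut}"


def parse_mutation_string(complex_id: str, mutation: str, ddg: Optional[float] = None) -> MutationSpec:
    """Parse a SKEMPI-style mutation string, e.g. ``"EA38G"``.

    Layout: wild-type (1 letter), chain (2nd character), residue number,
    optional insertion code, mutant (last letter).
    """
    m = _MUTATION_RE.match(mutation.strip())
    if not m:
        raise ValueError(f"cannot parse mutation string {mutation!r}")
    wt, chain, pos, icode, mut = m.groups()
    return MutationSpec(
        complex_id=complex_id, chain_id=chain, position=int(pos),
        wt=wt, mut=mut, icode=icode, ddg=ddg,
    )


def read_mutation_table(path: str | Path) -> list[MutationSpec]:
    """Read a SKEMPI-2.0-style CSV with columns ``complex``, ``mutation``, ``ddg``."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for needed in ("complex", "mutation"):
        if needed not in cols:
            raise ValueError(f"mutation table lacks column {needed!r} (has {list(df.columns)})")
    out = []
    for _, row in df.iterrows():
        ddg = float(row[cols["ddg"]]) if "ddg" in cols and pd.notna(row[cols["ddg"]]) else None
        out.append(parse_mutation_string(str(row[cols["complex"]]), str(row[cols["mutation"]]), ddg))
    return out


@dataclass
class AtomSubset:
    """Atoms of one site/binding subset filtered to an element group."""

    label: str
    element_group: frozenset[str]
    atoms: list[Atom] = field(default_factory=list)
    structure_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in {"site", "neighborhood", "p1_binding", "p2_binding"}:
            raise ValueError(f"unknown subset label {self.label!r}")
        bad = [a.element for a in self.atoms if a.element not in self.element_group]
        if bad:
            raise ValueError(f"atoms with elements {sorted(set(bad))} outside group "
                             f"{sorted(self.element_group)}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.coords for a in self.atoms])

    @property
    def is_empty(self) -> bool:
        return len(self.atoms) == 0


@dataclass
class PairDistanceMatrix:
    """Modified cross-set distance matrix over the union of two subsets.

    The square matrix runs over the concatenated atoms of ``set_a`` then
    ``set_b``. Entries between atoms of different subsets hold the
    Euclidean distance; entries within a subset (both atoms from ``set_a``,
    or both from ``set_b``, including the diagonal) are *excluded* — they
    are flagged in ``excluded`` and, when a dense matrix is materialized,
    set to a sentinel strictly beyond the maximum filtration scale so the
    pair can never form a simplex.
    """

    set_a: AtomSubset
    set_b: AtomSubset
    values: np.ndarray
    excluded: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def dense(self, sentinel: float) -> np.ndarray:
        """Materialize with excluded pairs replaced by ``sentinel``."""
        finite = np.asarray(self.values, dtype=float)
        if np.any(finite[~self.excluded] >= sentinel):
            raise ValueError("sentinel must exceed every retained distance")
        out = finite.copy()
        out[self.excluded] = sentinel
        return out


def _filter_elements(pairs: list[tuple[Residue, Atom]], elements: frozenset[str]) -> list[Atom]:
    return [a for _, a in pairs if a.element in elements]


def mutation_site_atoms(
    structure: ComplexStructure,
    mutation: MutationSpec,
    elements: Sequence[str] = ("C", "N", "O"),
) -> AtomSubset:
    """Atoms of the mutated residue, filtered by element.

    Validates that the residue found at the mutation's (chain, position)
    carries the recorded wild-type amino acid.
    """
    res = structure.find_residue(mutation.chain_id, mutation.position, mutation.icode)
    if res.one_letter != mutation.wt:
        raise StructureError(
            f"{structure.id} {mutation.label}: wild-type mismatch — residue "
            f"{mutation.chain_id}{mutation.position} is {res.name} "
            f"({res.one_letter}), mutation says {mutation.wt}"
        )
    group = frozenset(elements)
    atoms = [a for a in res.atoms if a.element in group]
    return AtomSubset("site", group, atoms, structure.id)


def neighborhood_atoms(
    structure: ComplexStructure,
    mutation: MutationSpec,
    r: float = DEFAULT_RADIUS,
    elements: Sequence[str] = ("C", "N", "O"),
) -> AtomSubset:
    """Atoms within ``r`` Å of any mutation-site atom, excluding the site itself."""
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    site_res = structure.find_residue(mutation.chain_id, mutation.position, mutation.icode)
    site_coords = np.array([a.coords for a in site_res.atoms])
    group = frozenset(elements)
    candidates = [
        (res, a)
        for res, a in structure.atoms()
        if res.key != site_res.key and a.element in group
    ]
    if not candidates:
        return AtomSubset("neighborhood", group, [], structure.id)
    coords = np.array([a.coords for _, a in candidates])
    dmin = cKDTree(site_coords).query(coords)[0]
    atoms = [a for (res, a), d in zip(candidates, dmin) if d <= r]
    return AtomSubset("neighborhood", group, atoms, structure.id)


def binding_site_atoms(
    structure: ComplexStructure,
    side: str,
    r: float = DEFAULT_RADIUS,
    elements: Sequence[str] = ("C", "N", "O"),
) -> AtomSubset:
    """Atoms of partner ``side`` within ``r`` Å of any atom of the other side."""
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    own = structure.side_chain_ids(side)
    other = structure.side_chain_ids("p2" if side == "p1" else "p1")
    own_pairs = structure.atoms(sorted(own))
    other_coords = np.array([a.coords for _, a in structure.atoms(sorted(other))])
    if not own_pairs or other_coords.size == 0:
        raise StructureError(f"partner side {side!r} or its opposite has no atoms")
    group = frozenset(elements)
    candidates = [(res, a) for res, a in own_pairs if a.element in group]
    label = "p1_binding" if side == "p1" else "p2_binding"
    if not candidates:
        return AtomSubset(label, group, [], structure.id)
    coords = np.array([a.coords for _, a in candidates])
    dmin = cKDTree(other_coords).query(coords)[0]
    atoms = [a for (res, a), d in zip(candidates, dmin) if d <= r]
    return AtomSubset(label, group, atoms, structure.id)


def dmod_matrix(set_a: AtomSubset, set_b: AtomSubset) -> PairDistanceMatrix:
    """Modified distance matrix over the union of two atom subsets.

    Cross-subset entries carry the plain Euclidean distance; same-subset
    entries (both atoms in ``set_a``, or both in ``set_b``) are excluded so
    that only cross-set interactions are visible to the filtration.
    """
    if set_a.structure_id and set_b.structure_id and set_a.structure_id != set_b.structure_id:
        raise ValueError(
            f"subsets reference different structures: {set_a.structure_id!r} "
            f"vs {set_b.structure_id!r}"
        )
    if set_a is set_b:
        # Degenerate self-pairing: every pair is same-subset, all excluded.
        n = len(set_a)
        return PairDistanceMatrix(
            set_a=set_a, set_b=set_b,
            values=np.zeros((n, n)), excluded=np.ones((n, n), dtype=bool),
        )
    na, nb = len(set_a), len(set_b)
    coords = np.vstack([set_a.coords, set_b.coords]) if na + nb else np.empty((0, 3))
    values = cdist(coords, coords) if na + nb else np.empty((0, 0))
    excluded = np.zeros((na + nb, na + nb), dtype=bool)
    excluded[:na, :na] = True
    excluded[na:, na:] = True
    np.fill_diagonal(excluded, True)
    values[excluded] = 0.0
    return PairDistanceMatrix(set_a=set_a, set_b=set_b, values=values, excluded=excluded)
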