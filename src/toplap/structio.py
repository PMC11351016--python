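"""Macromolecular structure and confidence-metadata I/O.

Reads protein–protein complexes from PDB or mmCIF files into a light
in-memory model (chains → residues → atoms) tailored to the featurization
and evaluation stages, and reads the JSON confidence summaries (ipTM/pTM)
that structure-prediction servers emit alongside predicted models.

Conventions
-----------
* Author ("auth") chain IDs and residue numbers are kept verbatim — mutation
  tables reference author numbering, so nothing is renumbered.
* Only the first model of multi-model files is read.
* Heteroatoms and waters are excluded; alternate locations are resolved to
  the highest-occupancy conformer (ties: first encountered).
* Hydrogens are retained in the model; downstream element groups ({C,N,O})
  simply never select them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ComplexStructure",
    "ConfidenceScores",
    "StructureError",
    "read_structure",
    "write_pdb",
    "parse_confidence",
    "classify_confidence",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class StructureError(ValueError):
    """Raised for unreadable files or violated structural contracts."""


@dataclass
class Atom:
    """A heavy (or hydrogen) atom with coordinates in Å.

    ``bfactor`` is the isotropic temperature factor (Å²), a standard proxy
    for local flexibility; ``occupancy`` is the fractional occupancy used
    for alternate-location resolution.
    """

    element: str
    name: str
    coords: np.ndarray
    bfactor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: element symbol is empty")
        if self.bfactor < 0:
            raise StructureError(f"atom {self.name}: negative B-factor {self.bfactor}")
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    name: str
    number: int
    chain_id: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)


@dataclass
class ConfidenceScores:
    """Predicted-model confidence: interface (ipTM) and global (pTM) TM-scores."""

    iptm: Optional[float] = None
    ptm: Optional[float] = None

    def __post_init__(self) -> None:
        for label, v in (("iptm", self.iptm), ("ptm", self.ptm)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise StructureError(f"{label}={v} outside [0, 1]")


@dataclass
class ComplexStructure:
    """A protein–protein complex with a two-side partner partition.

    ``partner_split`` designates which chains form each interacting protein
    (P1, P2); the two chain-ID sets must be disjoint and non-empty.
    """

    id: str
    chains: list[Chain]
    partner_split: tuple[frozenset[str], frozenset[str]]
    confidence: Optional[ConfidenceScores] = None

    def __post_init__(self) -> None:
        p1, p2 = (frozenset(self.partner_split[0]), frozenset(self.partner_split[1]))
        self.partner_split = (p1, p2)
        if not p1 or not p2:
            raise StructureError("both partner sides must be non-empty")
        if p1 & p2:
            raise StructureError(f"partner sides overlap: {sorted(p1 & p2)}")
        available = {c.chain_id for c in self.chains}
        missing = (p1 | p2) - available
        if missing:
            raise StructureError(
                f"partner chains {sorted(missing)} not in structure "
                f"(available: {sorted(available)})"
            )

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise StructureError(f"no chain {chain_id!r} (available: {self.chain_ids})")

    def residues(self, chain_ids: Optional[Sequence[str]] = None) -> list[Residue]:
        wanted = set(chain_ids) if chain_ids is not None else None
        out: list[Residue] = []
        for c in self.chains:
            if wanted is None or c.chain_id in wanted:
                out.extend(c.residues)
        return out

    def atoms(self, chain_ids: Optional[Sequence[str]] = None) -> list[tuple[Residue, Atom]]:
        return [(r, a) for r in self.residues(chain_ids) for a in r.atoms]

    def side_chain_ids(self, side: str) -> frozenset[str]:
        if side == "p1":
            return self.partner_split[0]
        if side == "p2":
            return self.partner_split[1]
        raise StructureError(f"side must be 'p1' or 'p2', got {side!r}")

    def find_residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.chain(chain_id).residues:
            if r.number == number and r.icode == icode:
                return r
        raise StructureError(
            f"residue {number}{icode} not found in chain {chain_id} of {self.id}"
        )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom name: the highest occupancy wins."""
    best: dict[str, Atom] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occupancy > best[a.name].occupancy:
            best[a.name] = a
    return [best[n] for n in order]


def read_structure(
    path: str | Path,
    partner_split: tuple[Sequence[str], Sequence[str]],
    format: Optional[str] = None,
    complex_id: Optional[str] = None,
    confidence: Optional[ConfidenceScores] = None,
) -> ComplexStructure:
    """Read a PDB or mmCIF file into a :class:`ComplexStructure`.

    Parameters
    ----------
    path
        Structure file. ``format`` may be ``"pdb"`` or ``"mmcif"``; by
        default it is inferred from the extension.
    partner_split
        Two chain-ID sets naming the interacting proteins P1 and P2.

    Only the first model is read; waters and heteroatoms are dropped and
    alternate locations resolved to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        else:
            if format not in fmt_map:
                raise StructureError(f"format must be 'pdb' or 'mmcif', got {format!r}")
            st = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    st.setup_entities()
    model = st[0]

    chains: list[Chain] = []
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if res.name in WATER_NAMES:
                continue
            if res.het_flag == "H" and res.name not in THREE_TO_ONE:
                continue
            atoms = []
            for at in res:
                atoms.append(
                    Atom(
                        element=at.element.name,
                        name=at.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        bfactor=max(at.b_iso, 0.0),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        altloc=at.altloc or "",
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            residues.append(
                Residue(
                    name=res.name,
                    number=res.seqid.num,
                    chain_id=ch.name,
                    icode=(res.seqid.icode or "").strip(),
                    atoms=atoms,
                )
            )
        if residues:
            chains.append(Chain(chain_id=ch.name, residues=residues))

    return ComplexStructure(
        id=complex_id or (st.name or path.stem),
        chains=chains,
        partner_split=(frozenset(partner_split[0]), frozenset(partner_split[1])),
        confidence=confidence,
    )


def write_pdb(structure: ComplexStructure, path: str | Path) -> None:
    """Write the structure as a fixed-column PDB file (coordinates to 3 dp)."""
    lines: list[str] = []
    serial = 1
    for ch in structure.chains:
        for res in ch.residues:
            for at in res.atoms:
                name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
                lines.append(
                    f"ATOM  {serial:>5d} {name:<4.4s}{'':1s}{res.name:>3s} "
                    f"{ch.chain_id:1s}{res.number:>4d}{res.icode or ' ':1s}   "
                    f"{at.coords[0]:8.3f}{at.coords[1]:8.3f}{at.coords[2]:8.3f}"
                    f"{at.occupancy:6.2f}{at.bfactor:6.2f}          "
                    f"{at.element:>2s}  "
                )
                serial += 1
        lines.append(f"TER   {serial:>5d}      {ch.residues[-1].name:>3s} {ch.chain_id}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _chain_pair_cross_mean(matrix: list[list[float]]) -> float:
    """Mean of the off-diagonal entries of a per-chain-pair score matrix."""
    n = len(matrix)
    vals = [matrix[i][j] for i in range(n) for j in range(len(matrix[i])) if i != j]
    if not vals:
        raise StructureError("chain-pair matrix has no off-diagonal entries")
    return float(np.mean(vals))


def parse_confidence(path: str | Path) -> ConfidenceScores:
    """Parse a JSON confidence summary into :class:`ConfidenceScores`.

    Accepts the flat summary dialect (``{"iptm": ..., "ptm": ...}``) and the
    per-chain-pair dialect (``chain_pair_iptm`` matrix), which is reduced to
    the mean cross-chain value. A missing field yields an absent score, never
    an implicit zero.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StructureError(f"cannot parse confidence file {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise StructureError(f"{path}: expected a JSON object at top level")

    iptm = payload.get("iptm")
    ptm = payload.get("ptm")
    if iptm is None and "chain_pair_iptm" in payload:
        iptm = _chain_pair_cross_mean(payload["chain_pair_iptm"])
    for label, v in (("iptm", iptm), ("ptm", ptm)):
        if v is not None and not isinstance(v, (int, float)):
            raise StructureError(f"{path}: {label} is not numeric")
    return ConfidenceScores(
        iptm=None if iptm is None else float(iptm),
        ptm=None if ptm is None else float(ptm),
    )


#: ipTM above this marks a high-confidence interface prediction.
IPTM_HIGH = 0.8
#: ipTM below this marks a likely-incorrect prediction.
IPTM_LOW = 0.6
#: pTM at or above this marks an acceptable global fold prediction.
PTM_OK = 0.5


def classify_confidence(scores: ConfidenceScores) -> str:
    """Label a prediction by its interface confidence score.

    ipTM > 0.8 → ``high_confidence``; ipTM < 0.6 → ``likely_incorrect``;
    in between the prediction may be correct or wrong → ``ambiguous``.
    """
    if scores.iptm is None:
        raise StructureError("cannot classify confidence: ipTM absent")
    if scores.iptm > IPTM_HIGH:
        return "high_confidence"
    if scores.iptm < IPTM_LOW:
        return "likely_incorrect"
    return "ambiguous"
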