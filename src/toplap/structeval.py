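"""Predicted-vs-reference complex comparison and interface region classes.

Covers the structure-accuracy side of the evaluation: optimal rigid
superposition (Kabsch), sequence-based chain/residue correspondence,
global and per-residue backbone RMSD against the reference B-factors,
Shrake–Rupley relative accessible surface area (rASA), and the five-way
residue classification (interior / surface / support / rim / core) that
separates interface from non-interface residues at the 25% rASA cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import ComplexStructure, Residue, StructureError, ConfidenceScores
from .structio import IPTM_HIGH, IPTM_LOW, PTM_OK

__all__ = [
    "AlignmentReport",
    "RegionLabel",
    "kabsch_superpose",
    "chain_map",
    "per_residue_rmsd",
    "shrake_rupley_rasa",
    "classify_regions",
    "evaluation_summary",
    "write_summary",
    "RASA_CUTOFF",
    "INTERFACE_DELTA",
    "BACKBONE_ATOMS",
]

#: rASA cutoff separating buried from exposed residues.
RASA_CUTOFF = 0.25
#: Minimum monomer-vs-complex rASA change marking an interface residue.
#: Any measurable burial counts; the epsilon guards numerical noise.
INTERFACE_DELTA = 0.001

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Van der Waals radii (Å) for the accessible-surface computation.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
    "P": 1.80, "SE": 1.90,
}
DEFAULT_VDW = 1.70
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960

#: Theoretical maximum accessible surface areas (Å², Tien et al. 2013),
#: used to normalize per-residue ASA into rASA fractions.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def kabsch_superpose(
    ref_coords: np.ndarray, mov_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mov @ rotation.T + translation`` best fits ``ref`` in the
    least-squares sense; the rotation is proper (det = +1).
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(f"coordinate sets must be equal-shaped (n, 3): {ref.shape} vs {mov.shape}")
    n = ref.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    if min(np.linalg.matrix_rank(ref_c, tol=1e-9), np.linalg.matrix_rank(mov_c, tol=1e-9)) < 2:
        raise ValueError("degenerate (collinear) coordinates: rotation is underdetermined")
    h = mov_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref.mean(axis=0) - rot @ mov.mean(axis=0)
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, trans, rmsd


def _align_sequences(a: str, b: str):
    """Global pairwise alignment; returns (identity fraction, index pairs)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(a, b)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            pairs.append((i, j))
            if a[i] == b[j]:
                matches += 1
    identity = matches / max(1, min(len(a), len(b)))
    return identity, pairs


@dataclass
class ChainMap:
    """Chain pairing and residue correspondence between two structures."""

    chain_pairs: list[tuple[str, str]]
    residue_pairs: list[tuple[Residue, Residue]]
    unmapped_ref: list[Residue]
    unmapped_pred: list[Residue]
    identities: dict[tuple[str, str], float]


def chain_map(ref: ComplexStructure, pred: ComplexStructure, min_identity: float = 0.3) -> ChainMap:
    """Pair chains by sequence identity and map residues via alignment.

    A greedy assignment over all chain pairs maximizes summed identity
    (robust to renamed/reordered chains in predicted models); residues are
    matched along each chain pair's global alignment. The best pairing must
    reach ``min_identity``, otherwise the two files likely do not describe
    the same complex.
    """
    if not ref.chains or not pred.chains:
        raise StructureError("both structures need at least one chain")
    scored = []
    cached: dict[tuple[str, str], tuple[float, list[tuple[int, int]]]] = {}
    for rc in ref.chains:
        for pc in pred.chains:
            ident, pairs = _align_sequences(rc.sequence, pc.sequence)
            cached[(rc.chain_id, pc.chain_id)] = (ident, pairs)
            scored.append((ident, rc.chain_id, pc.chain_id))
    scored.sort(reverse=True)
    used_r: set[str] = set()
    used_p: set[str] = set()
    chain_pairs: list[tuple[str, str]] = []
    for ident, rid, pid in scored:
        if rid in used_r or pid in used_p:
            continue
        chain_pairs.append((rid, pid))
        used_r.add(rid)
        used_p.add(pid)
    identities = {cp: cached[cp][0] for cp in chain_pairs}
    if not identities or max(identities.values()) < min_identity:
        raise StructureError(
            f"best chain pairing identity {max(identities.values(), default=0):.2f} "
            f"below {min_identity:.2f} — are these the same complex?"
        )

    residue_pairs: list[tuple[Residue, Residue]] = []
    mapped_ref: set[tuple] = set()
    mapped_pred: set[tuple] = set()
    for rid, pid in chain_pairs:
        rres = ref.chain(rid).residues
        pres = pred.chain(pid).residues
        for i, j in cached[(rid, pid)][1]:
            residue_pairs.append((rres[i], pres[j]))
            mapped_ref.add(rres[i].key)
            mapped_pred.add(pres[j].key)
    unmapped_ref = [r for r in ref.residues() if r.key not in mapped_ref]
    unmapped_pred = [r for r in pred.residues() if r.key not in mapped_pred]
    return ChainMap(chain_pairs, residue_pairs, unmapped_ref, unmapped_pred, identities)


@dataclass
class AlignmentReport:
    """Superposition outcome: one global rigid fit on all mapped backbone
    atoms, plus per-residue backbone deviation under that single transform
    (no per-residue refitting) paired with the reference B-factor."""

    complex_id: str
    global_rmsd: float
    per_residue: pd.DataFrame  # chain, number, resname, rmsd, bfactor
    n_mapped: int
    n_unmapped_ref: int
    n_unmapped_pred: int
    confidence: Optional[ConfidenceScores] = None

    def __post_init__(self) -> None:
        if self.n_mapped <= 0:
            raise ValueError("a valid report needs at least one mapped residue")
        if self.global_rmsd < 0 or (self.per_residue["rmsd"] < 0).any():
            raise ValueError("RMSD cannot be negative")

    def to_csv(self, path) -> None:
        self.per_residue.to_csv(path, index=False)

    def plot_bfactor_vs_rmsd(self, ax=None, log_rmsd: bool = True):
        """Per-residue B-factor against backbone RMSD (flexibility check)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(self.per_residue["bfactor"], self.per_residue["rmsd"],
                   s=12, alpha=0.6, edgecolors="none")
        if log_rmsd and (self.per_residue["rmsd"] > 0).any():
            ax.set_yscale("log")
        ax.set_xlabel("B-factor (Å²)")
        ax.set_ylabel("per-residue backbone RMSD (Å)")
        ax.set_title(f"{self.complex_id}: global RMSD {self.global_rmsd:.2f} Å")
        return ax


def per_residue_rmsd(
    ref: ComplexStructure,
    pred: ComplexStructure,
    mapping: Optional[ChainMap] = None,
) -> AlignmentReport:
    """Global backbone superposition with per-residue deviations.

    Backbone atoms (N, CA, C, O) present in both members of each mapped
    residue pair enter one global Kabsch fit; the report's global RMSD and
    every per-residue RMSD are measured under that single transform. The
    per-residue table carries the reference B-factor (backbone mean) so
    flexibility can be compared against local prediction error.
    """
    mapping = mapping or chain_map(ref, pred)
    if not mapping.residue_pairs:
        raise StructureError("empty residue mapping")
    ref_pts, mov_pts, owners = [], [], []
    skipped = 0
    for rres, pres in mapping.residue_pairs:
        pair_atoms = [
            (rres.atom(nm), pres.atom(nm))
            for nm in BACKBONE_ATOMS
            if rres.atom(nm) is not None and pres.atom(nm) is not None
        ]
        if not pair_atoms:
            skipped += 1
            continue
        for ra, pa in pair_atoms:
            ref_pts.append(ra.coords)
            mov_pts.append(pa.coords)
            owners.append((rres, pair_atoms))
    rot, trans, global_rmsd = kabsch_superpose(np.array(ref_pts), np.array(mov_pts))

    rows = []
    seen = set()
    for rres, pres in mapping.residue_pairs:
        pair_atoms = [
            (rres.atom(nm), pres.atom(nm))
            for nm in BACKBONE_ATOMS
            if rres.atom(nm) is not None and pres.atom(nm) is not None
        ]
        if not pair_atoms or rres.key in seen:
            continue
        seen.add(rres.key)
        rcoords = np.array([ra.coords for ra, _ in pair_atoms])
        pcoords = np.array([pa.coords for _, pa in pair_atoms]) @ rot.T + trans
        rmsd = float(np.sqrt(np.mean(np.sum((pcoords - rcoords) ** 2, axis=1))))
        bfac = float(np.mean([ra.bfactor for ra, _ in pair_atoms]))
        rows.append(
            {
                "chain": rres.chain_id,
                "number": rres.number,
                "resname": rres.name,
                "rmsd": rmsd,
                "bfactor": bfac,
            }
        )
    table = pd.DataFrame(rows)
    return AlignmentReport(
        complex_id=ref.id,
        global_rmsd=global_rmsd,
        per_residue=table,
        n_mapped=len(rows),
        n_unmapped_ref=len(mapping.unmapped_ref) + skipped,
        n_unmapped_pred=len(mapping.unmapped_pred) + skipped,
        confidence=pred.confidence,
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_rasa(
    structure: ComplexStructure,
    chain_ids: Optional[Sequence[str]] = None,
    n_points: int = N_SPHERE_POINTS,
    probe: float = PROBE_RADIUS,
) -> dict[tuple[str, int, str], float]:
    """Per-residue relative accessible surface area via Shrake–Rupley.

    Heavy atoms of the selected chains are dressed with ``n_points`` sphere
    points at their solvent-extended radius; a point is accessible when no
    other atom's extended sphere contains it. Per-atom areas sum per residue
    and are divided by the residue's theoretical maximum ASA. Slightly
    exceeding 1 is possible for terminal residues.
    """
    pairs = [
        (res, a)
        for res, a in structure.atoms(chain_ids)
        if a.element != "H"
    ]
    if not pairs:
        raise StructureError("no heavy atoms in selection")
    coords = np.array([a.coords for _, a in pairs])
    radii = np.array(
        [VDW_RADII.get(a.element.upper(), DEFAULT_VDW) + probe for _, a in pairs]
    )
    tree = cKDTree(coords)
    unit = _sphere_points(n_points)
    asa_per_residue: dict[tuple[str, int, str], float] = {}
    max_r = radii.max()
    for i, (res, atom) in enumerate(pairs):
        pts = coords[i] + radii[i] * unit
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_idx:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
        asa_per_residue[res.key] = asa_per_residue.get(res.key, 0.0) + area

    rasa = {}
    for res in structure.residues(chain_ids):
        if res.key not in asa_per_residue:
            continue
        max_asa = MAX_ASA.get(res.name, float(np.mean(list(MAX_ASA.values()))))
        rasa[res.key] = asa_per_residue[res.key] / max_asa
    return rasa


@dataclass(frozen=True)
class RegionLabel:
    """One of the five structural regions with its two rASA values."""

    label: str
    rasa_monomer: float
    rasa_complex: float

    def __post_init__(self) -> None:
        if self.label not in {"interior", "surface", "support", "rim", "core"}:
            raise ValueError(f"unknown region label {self.label!r}")


def _region_rule(rasa_mono: float, rasa_cplx: float) -> str:
    """The five-region rule at the 25% rASA cutoff.

    Non-interface (no measurable burial on complexation): interior if buried
    in the complex, surface otherwise. Interface: support if buried already
    as a monomer; core if exposed as a monomer but buried in the complex;
    rim if still exposed in the complex.
    """
    if abs(rasa_mono - rasa_cplx) < INTERFACE_DELTA:
        return "interior" if rasa_cplx < RASA_CUTOFF else "surface"
    if rasa_mono < RASA_CUTOFF:
        return "support"
    if rasa_cplx < RASA_CUTOFF:
        return "core"
    return "rim"


def classify_regions(
    structure: ComplexStructure, n_points: int = N_SPHERE_POINTS
) -> dict[tuple[str, int, str], RegionLabel]:
    """Classify every partner-chain residue into the five structural regions.

    rASA is computed twice: for each side in isolation (monomer) and in the
    full complex; the difference detects interface burial.
    """
    p1, p2 = structure.partner_split
    all_ids = sorted(p1 | p2)
    rasa_complex = shrake_rupley_rasa(structure, all_ids, n_points=n_points)
    rasa_monomer: dict[tuple[str, int, str], float] = {}
    for side in (p1, p2):
        rasa_monomer.update(shrake_rupley_rasa(structure, sorted(side), n_points=n_points))
    out = {}
    for key, mono in rasa_monomer.items():
        cplx = rasa_complex.get(key)
        if cplx is None:
            continue
        out[key] = RegionLabel(_region_rule(mono, cplx), mono, cplx)
    return out


def evaluation_summary(
    reports: Sequence[AlignmentReport],
    region_labels: Optional[dict[str, dict[tuple, RegionLabel]]] = None,
    top_n: int = 40,
) -> dict:
    """Cohort statistics over alignment reports.

    Returns means/medians of RMSD, ipTM and pTM, the threshold fractions
    (ipTM ≥ 0.8 / < 0.6, pTM ≥ 0.5), top-n rankings by RMSD (worst first)
    and by ipTM (lowest first), the pooled per-residue (B-factor, RMSD)
    table, and — when region labels are supplied — per-region min/median/max
    RMSD statistics.
    """
    if not reports:
        raise ValueError("need at least one report")
    rmsds = np.array([r.global_rmsd for r in reports])
    iptms = np.array([
        r.confidence.iptm if r.confidence and r.confidence.iptm is not None else np.nan
        for r in reports
    ])
    ptms = np.array([
        r.confidence.ptm if r.confidence and r.confidence.ptm is not None else np.nan
        for r in reports
    ])
    with np.errstate(invalid="ignore"):
        summary = {
            "n_complexes": len(reports),
            "rmsd_mean": float(np.mean(rmsds)),
            "rmsd_median": float(np.median(rmsds)),
            "iptm_mean": float(np.nanmean(iptms)) if np.any(~np.isnan(iptms)) else None,
            "ptm_mean": float(np.nanmean(ptms)) if np.any(~np.isnan(ptms)) else None,
            "frac_iptm_high": _frac(iptms >= IPTM_HIGH, iptms),
            "frac_iptm_low": _frac(iptms < IPTM_LOW, iptms),
            "frac_ptm_ok": _frac(ptms >= PTM_OK, ptms),
        }
    order_rmsd = np.argsort(-rmsds)[:top_n]
    summary["worst_by_rmsd"] = [
        (reports[i].complex_id, float(rmsds[i])) for i in order_rmsd
    ]
    valid = [i for i in range(len(reports)) if not np.isnan(iptms[i])]
    order_iptm = sorted(valid, key=lambda i: iptms[i])[:top_n]
    summary["worst_by_iptm"] = [
        (reports[i].complex_id, float(iptms[i])) for i in order_iptm
    ]
    summary["per_residue"] = pd.concat(
        [r.per_residue.assign(complex_id=r.complex_id) for r in reports],
        ignore_index=True,
    )
    if region_labels is not None:
        rows = []
        for rep in reports:
            labels = region_labels.get(rep.complex_id, {})
            for _, row in rep.per_residue.iterrows():
                lab = None
                for (ch, num, icode), rl in labels.items():
                    if ch == row["chain"] and num == row["number"]:
                        lab = rl.label
                        break
                if lab is not None:
                    rows.append({"region": lab, "rmsd": row["rmsd"]})
        if rows:
            df = pd.DataFrame(rows)
            summary["per_region_rmsd"] = {
                region: {
                    "min": float(g["rmsd"].min()),
                    "median": float(g["rmsd"].median()),
                    "max": float(g["rmsd"].max()),
                    "n": int(len(g)),
                }
                for region, g in df.groupby("region")
            }
    return summary


def write_summary(summary: dict, outdir) -> None:
    """Write a cohort summary as JSON plus the pooled per-residue table.

    The per-residue CSV carries residue type, B-factor and RMSD columns
    (with chain/number/complex bookkeeping) for flexibility analyses.
    """
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {k: v for k, v in summary.items() if k != "per_residue"}
    (outdir / "summary.json").write_text(json.dumps(payload, indent=1))
    per_residue = summary.get("per_residue")
    if per_residue is not None:
        cols = ["complex_id", "chain", "number", "resname", "bfactor", "rmsd"]
        per_residue[[c for c in cols if c in per_residue.columns]].to_csv(
            outdir / "per_residue.csv", index=False
        )


def _frac(mask: np.ndarray, values: np.ndarray) -> Optional[float]:
    ok = ~np.isnan(values)
    if not np.any(ok):
        return None
    return float(np.sum(mask & ok) / np.sum(ok))
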