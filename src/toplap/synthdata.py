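"""Synthetic complexes, perturbed predictions, topology clouds, ΔΔG tables.

Everything downstream is testable without external downloads: this module
builds two-chain poly-alanine complexes on idealized helical backbone
geometry, "predicted" copies perturbed rigidly or with residue displacement
proportional to B-factor (emulating flexible-region prediction error),
point clouds with known Betti signatures, and mutation tables whose ΔΔG is
a sparse linear function of the complexes' own spectral features plus
Gaussian noise at a chosen signal strength.

The generated geometry is deliberately idealized (exact 3.8 Å Cα spacing,
fixed side-chain offsets): flexibility and topology tests need controlled
geometry, not physical realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .siteselect import MutationSpec
from .spectra import FeatureConfig, spectral_features
from .structio import Atom, Chain, ComplexStructure, ConfidenceScores, Residue

__all__ = [
    "SynthConfig",
    "SynthDataset",
    "make_toy_complex",
    "perturb_structure",
    "make_point_cloud",
    "make_ddg_table",
    "write_skempi_csv",
    "write_confidence_json",
]

_HELIX_RADIUS = 2.3  # Å
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TURN = np.deg2rad(100.0)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic two-chain complex.

    ``flex_span`` marks the flexible segment (0-based residue index range,
    inclusive-exclusive, within each chain); its residues get
    ``flex_bfactor_multiplier`` × the baseline B-factor, which the
    flexible perturbation mode converts into larger displacement.
    """

    n_residues: int = 20
    chain_gap: float = 4.5  # Å, closest inter-chain approach
    flex_span: tuple[int, int] = (8, 13)
    flex_bfactor_multiplier: float = 5.0
    bfactor_baseline: float = 20.0
    noise_sd: float = 0.05  # Å, jitter on idealized atom positions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues per chain")
        lo, hi = self.flex_span
        if not (0 <= lo <= hi <= self.n_residues):
            raise ValueError(f"flex_span {self.flex_span} outside chain of {self.n_residues}")
        if min(self.bfactor_baseline, self.flex_bfactor_multiplier, self.noise_sd) < 0:
            raise ValueError("amplitudes and multipliers must be ≥ 0")


def _helix_backbone(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(_HELIX_TURN * i),
            _HELIX_RADIUS * np.sin(_HELIX_TURN * i),
            _HELIX_RISE * i,
        ]
    )


def _chain_atoms(
    ca: np.ndarray, rng: np.random.Generator, noise_sd: float
) -> list[dict]:
    """Heavy-atom positions (N, CA, C, O, CB) around each Cα via local frames."""
    n = ca.shape[0]
    out = []
    for i in range(n):
        nxt = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
        t = nxt / np.linalg.norm(nxt)
        radial = np.array([ca[i][0], ca[i][1], 0.0])
        radial = radial - np.dot(radial, t) * t
        norm = np.linalg.norm(radial)
        nvec = radial / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        bvec = np.cross(t, nvec)
        offsets = {
            "N": -1.25 * t + 0.55 * nvec,
            "CA": np.zeros(3),
            "C": 1.20 * t + 0.50 * bvec,
            "O": 1.85 * t + 1.15 * bvec + 0.30 * nvec,
            "CB": 1.05 * nvec + 1.05 * bvec,
        }
        elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
        atoms = {}
        for name, off in offsets.items():
            pos = ca[i] + off + rng.normal(scale=noise_sd, size=3)
            atoms[name] = (elements[name], pos)
        out.append(atoms)
    return out


def make_toy_complex(config: SynthConfig, complex_id: Optional[str] = None) -> ComplexStructure:
    """Two poly-alanine chains (A, B) on idealized helical backbones.

    Chains face each other across an interface whose closest heavy-atom
    approach equals ``chain_gap``; B-factors are the baseline everywhere
    except over the flexible segment. Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    ca_a = _helix_backbone(config.n_residues)
    ca_b = _helix_backbone(config.n_residues)

    atoms_a = _chain_atoms(ca_a, rng, config.noise_sd)
    atoms_b = _chain_atoms(ca_b, rng, config.noise_sd)

    # Mirror chain B and slide it along +x until the closest heavy-atom
    # distance equals the requested gap.
    flip = np.diag([-1.0, 1.0, 1.0])
    for res in atoms_b:
        for name, (el, pos) in res.items():
            res[name] = (el, flip @ pos + np.array([30.0, 0.0, 0.0]))
    coords_a = np.array([p for res in atoms_a for _, p in res.values()])
    coords_b = np.array([p for res in atoms_b for _, p in res.values()])
    dmin = cdist(coords_a, coords_b).min()
    shift = np.array([-(dmin - config.chain_gap), 0.0, 0.0])
    for res in atoms_b:
        for name, (el, pos) in res.items():
            res[name] = (el, pos + shift)

    lo, hi = config.flex_span

    def build_chain(chain_id: str, atom_dicts: list[dict]) -> Chain:
        residues = []
        for i, res_atoms in enumerate(atom_dicts):
            b = config.bfactor_baseline * (
                config.flex_bfactor_multiplier if lo <= i < hi else 1.0
            )
            atoms = [
                Atom(element=el, name=name, coords=pos, bfactor=b)
                for name, (el, pos) in res_atoms.items()
            ]
            residues.append(
                Residue(name="ALA", number=i + 1, chain_id=chain_id, atoms=atoms)
            )
        return Chain(chain_id=chain_id, residues=residues)

    return ComplexStructure(
        id=complex_id or f"synth-{config.seed}",
        chains=[build_chain("A", atoms_a), build_chain("B", atoms_b)],
        partner_split=(frozenset({"A"}), frozenset({"B"})),
    )


def perturb_structure(
    structure: ComplexStructure,
    mode: str,
    amplitude: float,
    seed: int = 0,
) -> ComplexStructure:
    """A "predicted" copy: random rigid motion, optionally plus flexibility.

    ``rigid`` applies one random rotation + translation to everything
    (superposition recovers it exactly). ``flexible`` additionally displaces
    each residue by isotropic Gaussian noise whose standard deviation is
    proportional to its B-factor: sd_i = amplitude · B_i / mean(B), so the
    flexible segment moves the most — the mechanism behind the
    B-factor-vs-local-RMSD recovery experiment.
    """
    if mode not in {"rigid", "flexible"}:
        raise ValueError(f"mode must be 'rigid' or 'flexible', got {mode!r}")
    if amplitude < 0:
        raise ValueError("amplitude must be ≥ 0")
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    trans = rng.uniform(-10, 10, size=3)
    mean_b = np.mean([a.bfactor for _, a in structure.atoms()]) or 1.0

    chains = []
    for ch in structure.chains:
        residues = []
        for res in ch.residues:
            if mode == "flexible" and amplitude > 0:
                sd = amplitude * np.mean([a.bfactor for a in res.atoms]) / mean_b
                disp = rng.normal(scale=sd, size=3)
            else:
                disp = np.zeros(3)
            atoms = [
                Atom(
                    element=a.element,
                    name=a.name,
                    coords=rot @ (a.coords + disp) + trans,
                    bfactor=a.bfactor,
                    occupancy=a.occupancy,
                )
                for a in res.atoms
            ]
            residues.append(
                Residue(name=res.name, number=res.number, chain_id=res.chain_id,
                        icode=res.icode, atoms=atoms)
            )
        chains.append(Chain(chain_id=ch.chain_id, residues=residues))
    return ComplexStructure(
        id=f"{structure.id}-pred",
        chains=chains,
        partner_split=structure.partner_split,
        confidence=structure.confidence,
    )


def make_point_cloud(
    shape: str,
    n: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    radius: float = 5.0,
    gap: float = 10.0,
) -> np.ndarray:
    """Point clouds with known Betti signatures for spectral oracles.

    ``two_clusters``: β₀ = 2 below the gap, 1 above. ``circle``: β₁ = 1 at
    intermediate Alpha scales. ``sphere``: β₂ = 1 once the shell closes.
    ``tetrahedron``: the exact 4-point regular tetrahedron (unit edge).
    """
    rng = np.random.default_rng(seed)
    if shape == "tetrahedron":
        pts = np.array(
            [
                [1.0, 1.0, 1.0],
                [1.0, -1.0, -1.0],
                [-1.0, 1.0, -1.0],
                [-1.0, -1.0, 1.0],
            ]
        ) / np.sqrt(8.0)  # unit edge length
    elif shape == "two_clusters":
        if n < 2:
            raise ValueError("two_clusters needs n ≥ 2")
        half = n // 2
        spread = 0.05 * gap  # tight blobs so the gap dominates the topology
        a = rng.normal(scale=spread, size=(half, 3))
        b = rng.normal(scale=spread, size=(n - half, 3)) + np.array([gap, 0.0, 0.0])
        pts = np.vstack([a, b])
    elif shape == "circle":
        if n < 3:
            raise ValueError("circle needs n ≥ 3")
        theta = 2 * np.pi * np.arange(n) / n
        pts = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)]
        )
    elif shape == "sphere":
        if n < 4:
            raise ValueError("sphere needs n ≥ 4")
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        pts = radius * np.column_stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
        )
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return pts


@dataclass
class SynthDataset:
    """A generated mutation cohort with its ground truth."""

    records: list[MutationSpec]
    structures: dict[str, ComplexStructure]
    features: pd.DataFrame  # one row per record, spectral features
    truth: dict = field(default_factory=dict)


def make_ddg_table(
    n_complexes: int = 10,
    mutations_per_complex: int = 10,
    n_signal: int = 3,
    r2_target: float = 0.8,
    seed: int = 0,
    feature_config: Optional[FeatureConfig] = None,
    base_config: Optional[SynthConfig] = None,
) -> SynthDataset:
    """Mutation records whose ΔΔG carries a planted linear signal.

    Spectral features are computed for every (complex, mutation) pair;
    ``n_signal`` feature columns are drawn at random, standardized, and
    combined with Gaussian coefficients; Gaussian noise is scaled so the
    population R² matches ``r2_target`` (``r2_target = 0`` gives ΔΔG
    independent of all features). Ground-truth columns, coefficients and
    the empirical R² are returned for recovery assertions.
    """
    if not (0 <= r2_target < 1):
        raise ValueError("r2_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cfg = feature_config or FeatureConfig.small()
    base = base_config or SynthConfig()

    structures: dict[str, ComplexStructure] = {}
    records: list[MutationSpec] = []
    rows = []
    for c in range(n_complexes):
        cid = f"SYN{c:03d}"
        sc = SynthConfig(
            n_residues=base.n_residues,
            chain_gap=float(rng.uniform(4.0, 6.0)),
            flex_span=base.flex_span,
            flex_bfactor_multiplier=base.flex_bfactor_multiplier,
            bfactor_baseline=base.bfactor_baseline,
            noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        structure = make_toy_complex(sc, complex_id=cid)
        structures[cid] = structure
        n_res = base.n_residues
        positions = rng.choice(n_res, size=min(mutations_per_complex, n_res), replace=False)
        for p in positions:
            chain = "A" if rng.random() < 0.5 else "B"
            mut = AA_LETTERS[rng.integers(0, len(AA_LETTERS))]
            while mut == "A":
                mut = AA_LETTERS[rng.integers(0, len(AA_LETTERS))]
            rec = MutationSpec(
                complex_id=cid, chain_id=chain, position=int(p) + 1,
                wt="A", mut=mut,
            )
            feats = spectral_features(structure, rec, cfg)
            rows.append(pd.Series(feats.values, index=feats.names))
            records.append(rec)

    features = pd.DataFrame(rows).reset_index(drop=True)
    n = len(records)

    if r2_target == 0:
        ddg = rng.normal(scale=1.0, size=n)
        truth = {"signal_columns": [], "coefficients": [], "r2_target": 0.0,
                 "r2_empirical": 0.0}
    else:
        variable = [c for c in features.columns if features[c].std() > 1e-9]
        if len(variable) < n_signal:
            raise ValueError(f"only {len(variable)} variable features, need {n_signal}")
        cols = list(rng.choice(variable, size=n_signal, replace=False))
        x = features[cols].to_numpy()
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        coefs = rng.normal(scale=1.0, size=n_signal)
        signal = x @ coefs
        sig_var = signal.var()
        noise_var = sig_var * (1 - r2_target) / r2_target
        noise = rng.normal(scale=np.sqrt(noise_var), size=n)
        ddg = signal + noise
        r2_emp = float(1 - noise.var() / ddg.var()) if ddg.var() > 0 else 0.0
        truth = {
            "signal_columns": cols,
            "coefficients": coefs.tolist(),
            "r2_target": r2_target,
            "r2_empirical": r2_emp,
        }

    records = [
        MutationSpec(
            complex_id=r.complex_id, chain_id=r.chain_id, position=r.position,
            wt=r.wt, mut=r.mut, icode=r.icode, ddg=float(d),
        )
        for r, d in zip(records, ddg)
    ]
    return SynthDataset(records=records, structures=structures,
                        features=features, truth=truth)


def write_skempi_csv(records: list[MutationSpec], path: str | Path) -> None:
    """Write records as a SKEMPI-2.0-style CSV (complex, mutation, ddg)."""
    pd.DataFrame(
        {
            "complex": [r.complex_id for r in records],
            "mutation": [r.label for r in records],
            "ddg": [r.ddg for r in records],
        }
    ).to_csv(path, index=False)


def write_confidence_json(
    path: str | Path,
    seed: int = 0,
    iptm_mean: float = 0.8,
    iptm_sd: float = 0.1,
    ptm_mean: float = 0.85,
    ptm_sd: float = 0.08,
) -> ConfidenceScores:
    """Write a synthetic confidence summary (ipTM/pTM clipped to [0, 1])."""
    rng = np.random.default_rng(seed)
    iptm = float(np.clip(rng.normal(iptm_mean, iptm_sd), 0.0, 1.0))
    ptm = float(np.clip(rng.normal(ptm_mean, ptm_sd), 0.0, 1.0))
    Path(path).write_text(json.dumps({"iptm": round(iptm, 4), "ptm": round(ptm, 4)}))
    return ConfidenceScores(iptm=iptm, ptm=ptm)
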