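"""Superposition, per-residue RMSD, rASA and interface region classes."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from toplap.structio import Atom, Chain, ComplexStructure, ConfidenceScores, Residue, StructureError
from toplap.structeval import (
    AlignmentReport,
    RegionLabel,
    _region_rule,
    chain_map,
    classify_regions,
    evaluation_summary,
    kabsch_superpose,
    per_residue_rmsd,
    shrake_rupley_rasa,
)
from toplap.synthdata import perturb_structure


class TestKabsch:
    def test_identical_sets(self, rng):
        pts = rng.uniform(0, 10, size=(10, 3))
        _, _, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.uniform(0, 10, size=(10, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ rot90.T + np.array([1.0, 2.0, 3.0])
        _, _, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_proper_rotation(self, rng):
        pts = rng.uniform(0, 10, size=(8, 3))
        moved = pts * np.array([-1.0, 1.0, 1.0])  # mirrored set
        rot, _, _ = kabsch_superpose(pts, moved)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_numeric_minimization(self, rng):
        """Displaced 4-point set: compare against brute-force optimization
        over rotations and translations."""
        from scipy.optimize import minimize

        ref = rng.uniform(0, 5, size=(4, 3))
        mov = ref.copy()
        mov[2] += [1.0, -0.5, 0.7]
        _, _, rmsd = kabsch_superpose(ref, mov)

        def objective(p):
            rot = Rotation.from_rotvec(p[:3]).as_matrix()
            moved = mov @ rot.T + p[3:]
            return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000}).fun
            for x0 in [np.zeros(6), np.array([0.5, -0.3, 0.2, 1.0, 0.0, -1.0])]
        )
        assert rmsd == pytest.approx(best, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_degeneracy(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line, line)

    def test_rigid_invariance_of_rmsd(self, rng):
        ref = rng.uniform(0, 10, size=(12, 3))
        mov = ref + rng.normal(scale=0.5, size=(12, 3))
        _, _, rmsd0 = kabsch_superpose(ref, mov)
        rot = Rotation.random(random_state=np.random.RandomState(5)).as_matrix()
        _, _, rmsd1 = kabsch_superpose(ref @ rot.T + 3.0, mov)
        _, _, rmsd2 = kabsch_superpose(ref, mov @ rot.T - 7.0)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)
        assert rmsd2 == pytest.approx(rmsd0, abs=1e-9)


class TestChainMap:
    def test_identical_structures(self, toy_complex):
        cm = chain_map(toy_complex, toy_complex)
        assert set(cm.chain_pairs) == {("A", "A"), ("B", "B")}
        assert len(cm.residue_pairs) == len(toy_complex.residues())
        assert not cm.unmapped_ref and not cm.unmapped_pred

    def test_truncated_prediction(self, toy_complex):
        pred = ComplexStructure(
            "trunc",
            [Chain("A", toy_complex.chain("A").residues[5:]),
             toy_complex.chain("B")],
            toy_complex.partner_split,
        )
        cm = chain_map(toy_complex, pred)
        unmapped_a = [r for r in cm.unmapped_ref if r.chain_id == "A"]
        assert len(unmapped_a) == 5
        assert all(r.number <= 5 for r in unmapped_a)

    def test_swapped_chain_labels_recovered(self):
        # distinct sequences so identity scoring can discriminate the pairing
        ref = _two_seq_structure("AAAAAAAAAA", "GGGGGSSSSS")
        pred = _two_seq_structure("GGGGGSSSSS", "AAAAAAAAAA")
        cm = chain_map(ref, pred)
        assert set(cm.chain_pairs) == {("A", "B"), ("B", "A")}
        # exhaustive check on the 2-chain case: the chosen pairing maximizes
        # total identity over both possible assignments
        chosen = sum(cm.identities.values())
        assert chosen >= 2.0 - 1e-9  # perfect matches

    def test_unrelated_sequences_rejected(self):
        ref = _two_seq_structure("AAAAAAAAAA", "AAAAAAAAAA")
        pred = _two_seq_structure("WWWWWWWWWW", "WWWWWWWWWW")
        with pytest.raises(StructureError, match="identity"):
            chain_map(ref, pred)


def _two_seq_structure(seq_a: str, seq_b: str) -> ComplexStructure:
    from toplap.structio import ONE_TO_THREE

    def chain(cid, seq, xoff):
        residues = []
        for i, aa in enumerate(seq):
            atoms = [
                Atom("N", "N", [xoff + 3.8 * i - 1.2, 0.5, 0.1 * i]),
                Atom("C", "CA", [xoff + 3.8 * i, 0.0, 0.1 * i]),
                Atom("C", "C", [xoff + 3.8 * i + 1.2, 0.8, 0.1 * i]),
                Atom("O", "O", [xoff + 3.8 * i + 1.6, 1.9, 0.1 * i]),
            ]
            residues.append(Residue(ONE_TO_THREE[aa], i + 1, cid, atoms=atoms))
        return Chain(cid, residues)

    return ComplexStructure(
        "twoseq", [chain("A", seq_a, 0.0), chain("B", seq_b, 0.0)],
        (frozenset("A"), frozenset("B")),
    )


class TestPerResidueRmsd:
    def test_identical_gives_zero_everywhere(self, toy_complex):
        rep = per_residue_rmsd(toy_complex, toy_complex)
        assert rep.global_rmsd == pytest.approx(0.0, abs=1e-12)
        assert rep.per_residue["rmsd"].max() == pytest.approx(0.0, abs=1e-12)

    def test_single_shifted_residue_detected(self, big_complex):
        """One residue rigidly shifted 2 Å: its RMSD ≈ 2, others ≈ 0 up to
        the small global-fit leakage."""
        import copy

        pred = copy.deepcopy(big_complex)
        target = pred.chain("A").residues[10]
        for a in target.atoms:
            a.coords = a.coords + np.array([2.0, 0.0, 0.0])
        rep = per_residue_rmsd(big_complex, pred)
        tab = rep.per_residue.set_index(["chain", "number"])
        assert tab.loc[("A", 11), "rmsd"] == pytest.approx(2.0, abs=0.1)
        others = tab.drop(index=("A", 11))
        assert others["rmsd"].max() < 0.1

    def test_global_rmsd_consistent_with_kabsch(self, big_complex):
        pred = perturb_structure(big_complex, "flexible", 0.5, seed=2)
        cm = chain_map(big_complex, pred)
        rep = per_residue_rmsd(big_complex, pred, cm)
        ref_pts, mov_pts = [], []
        for rres, pres in cm.residue_pairs:
            for nm in ("N", "CA", "C", "O"):
                ra, pa = rres.atom(nm), pres.atom(nm)
                if ra is not None and pa is not None:
                    ref_pts.append(ra.coords)
                    mov_pts.append(pa.coords)
        _, _, rmsd = kabsch_superpose(np.array(ref_pts), np.array(mov_pts))
        assert rep.global_rmsd == pytest.approx(rmsd, abs=1e-9)

    def test_report_requires_mapped_residues(self, toy_complex):
        with pytest.raises(ValueError):
            AlignmentReport(
                complex_id="x", global_rmsd=1.0,
                per_residue=per_residue_rmsd(toy_complex, toy_complex).per_residue,
                n_mapped=0, n_unmapped_ref=0, n_unmapped_pred=0,
            )


def _isolated_residue_structure(atoms_main, cage_points=()):
    main = Residue("GLY", 1, "A", atoms=atoms_main)
    chain_a = Chain("A", [main])
    b_atoms = [Atom("C", "CA", np.asarray(p, dtype=float)) for p in cage_points]
    b_res = (
        [Residue("ALA", i + 1, "B", atoms=[a]) for i, a in enumerate(b_atoms)]
        if b_atoms
        else [Residue("ALA", 1, "B", atoms=[Atom("C", "CA", [999.0, 0, 0])])]
    )
    return ComplexStructure(
        "iso", [chain_a, Chain("B", b_res)], (frozenset("A"), frozenset("B"))
    )


class TestShrakeRupley:
    def test_isolated_atom_matches_analytic_sphere(self):
        st = _isolated_residue_structure([Atom("C", "CA", [0.0, 0.0, 0.0])])
        rasa = shrake_rupley_rasa(st, ["A"])
        area = rasa[("A", 1, "")] * 104.0  # undo glycine normalization
        analytic = 4 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(analytic, rel=0.01)

    def test_isolated_glycine_fully_exposed(self):
        atoms = [
            Atom("N", "N", [1.458, 0, 0]),
            Atom("C", "CA", [0.0, 0, 0]),
            Atom("C", "C", [-0.55, 1.42, 0]),
            Atom("O", "O", [-1.76, 1.64, 0]),
        ]
        st = _isolated_residue_structure(atoms)
        rasa = shrake_rupley_rasa(st, ["A"])
        # no burial at all: at or above the in-chain theoretical maximum
        assert rasa[("A", 1, "")] >= 1.0

    def test_caged_residue_is_buried(self, rng):
        # dense shell of atoms on a sphere of radius 6 Å around the residue
        n = 400
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        shell = 6.0 * np.column_stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
        )
        st = _isolated_residue_structure([Atom("C", "CA", [0.0, 0.0, 0.0])], shell)
        rasa = shrake_rupley_rasa(st)
        assert rasa[("A", 1, "")] < 0.01

    def test_sphere_point_convergence(self, toy_complex):
        """Doubling the sphere points from the default changes rASA < 2%."""
        default = shrake_rupley_rasa(toy_complex, n_points=960)
        doubled = shrake_rupley_rasa(toy_complex, n_points=1920)
        for key, v in doubled.items():
            if v > 0.05:
                assert abs(default[key] - v) / v < 0.02

    def test_monotone_burial(self, rng):
        st_free = _isolated_residue_structure([Atom("C", "CA", [0.0, 0.0, 0.0])])
        free = shrake_rupley_rasa(st_free, ["A"])[("A", 1, "")]
        near = rng.uniform(-4, 4, size=(12, 3))
        near = near[np.linalg.norm(near, axis=1) > 3.0]
        st_crowded = _isolated_residue_structure(
            [Atom("C", "CA", [0.0, 0.0, 0.0])], near
        )
        crowded = shrake_rupley_rasa(st_crowded)[("A", 1, "")]
        assert crowded <= free + 1e-12


class TestRegionRule:
    @pytest.mark.parametrize(
        "mono,cplx,label",
        [
            (0.40, 0.10, "core"),
            (0.10, 0.05, "support"),
            (0.50, 0.50, "surface"),
            (0.40, 0.30, "rim"),
            (0.10, 0.10, "interior"),
            (0.24, 0.24, "interior"),   # just below the 25% cutoff
            (0.26, 0.26, "surface"),
            (0.249, 0.10, "support"),   # monomer-buried interface
            (0.251, 0.249, "core"),
        ],
    )
    def test_rule_table(self, mono, cplx, label):
        assert _region_rule(mono, cplx) == label

    def test_label_validation(self):
        with pytest.raises(ValueError):
            RegionLabel("unknown", 0.5, 0.5)

    def test_partition_on_synthetic_complex(self, toy_complex):
        labels = classify_regions(toy_complex, n_points=240)
        partner_residues = [
            r.key for r in toy_complex.residues(sorted(set().union(*toy_complex.partner_split)))
        ]
        assert sorted(labels.keys()) == sorted(partner_residues)
        valid = {"interior", "surface", "support", "rim", "core"}
        assert {l.label for l in labels.values()} <= valid

    def test_interface_labels_symmetric_in_partner_order(self, toy_complex):
        labels = classify_regions(toy_complex, n_points=240)
        swapped = ComplexStructure(
            toy_complex.id, toy_complex.chains,
            (toy_complex.partner_split[1], toy_complex.partner_split[0]),
        )
        labels_swapped = classify_regions(swapped, n_points=240)
        assert {k: v.label for k, v in labels.items()} == {
            k: v.label for k, v in labels_swapped.items()
        }


class TestEvaluationSummary:
    def _report(self, cid, rmsd, iptm, ptm):
        import pandas as pd

        return AlignmentReport(
            complex_id=cid, global_rmsd=rmsd,
            per_residue=pd.DataFrame(
                {"chain": ["A"], "number": [1], "resname": ["ALA"],
                 "rmsd": [rmsd], "bfactor": [20.0]}
            ),
            n_mapped=1, n_unmapped_ref=0, n_unmapped_pred=0,
            confidence=ConfidenceScores(iptm=iptm, ptm=ptm),
        )

    def test_single_report(self):
        s = evaluation_summary([self._report("X", 1.0, 0.9, 0.9)])
        assert s["rmsd_mean"] == pytest.approx(1.0)
        assert s["iptm_mean"] == pytest.approx(0.9)
        assert s["frac_iptm_high"] == pytest.approx(1.0)
        assert s["frac_ptm_ok"] == pytest.approx(1.0)

    def test_two_reports_mean_median(self):
        s = evaluation_summary(
            [self._report("X", 1.0, 0.9, 0.9), self._report("Y", 3.0, 0.5, 0.4)]
        )
        assert s["rmsd_mean"] == pytest.approx(2.0)
        assert s["rmsd_median"] == pytest.approx(2.0)
        assert s["frac_iptm_low"] == pytest.approx(0.5)
        assert s["worst_by_rmsd"][0][0] == "Y"
        assert s["worst_by_iptm"][0][0] == "Y"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluation_summary([])


def test_report_plot_smoke(big_complex, tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    pred = perturb_structure(big_complex, "flexible", 1.0, seed=5)
    rep = per_residue_rmsd(big_complex, pred)
    ax = rep.plot_bfactor_vs_rmsd()
    assert ax.get_xlabel().startswith("B-factor")
    ax.figure.savefig(tmp_path / "bfac.png")


def test_write_summary_emits_json_and_csv(big_complex, tmp_path):
    import json

    pred = perturb_structure(big_complex, "flexible", 1.0, seed=6)
    summary = evaluation_summary([per_residue_rmsd(big_complex, pred)])
    from toplap.structeval import write_summary

    write_summary(summary, tmp_path / "out")
    payload = json.loads((tmp_path / "out" / "summary.json").read_text())
    assert payload["n_complexes"] == 1
    import pandas as pd

    table = pd.read_csv(tmp_path / "out" / "per_residue.csv")
    assert {"resname", "bfactor", "rmsd"} <= set(table.columns)
    assert len(table) == 100
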