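"""Boundary operators, combinatorial Laplacians, spectra and features."""

import numpy as np
import pytest

from oracles import GF2Persistence, random_vr_complex, rank_betti
from toplap.filtration import SimplicialComplex, build_alpha_filtration, build_vr_filtration
from toplap.siteselect import MutationSpec
from toplap.spectra import (
    FeatureConfig,
    betti_curve,
    boundary_matrix,
    combinatorial_laplacian,
    laplacian_from_boundaries,
    spectral_features,
    spectrum,
    spectrum_of,
)
from toplap.structio import Chain, ComplexStructure, Residue
from toplap.synthdata import SynthConfig, make_point_cloud, make_toy_complex

EDGE = SimplicialComplex([(0,), (1,), (0, 1)])
HOLLOW = SimplicialComplex([(0,), (1,), (2,), (0, 1), (0, 2), (1, 2)])
FILLED = SimplicialComplex([(0,), (1,), (2,), (0, 1), (0, 2), (1, 2), (0, 1, 2)])


class TestBoundaryMatrix:
    def test_single_edge_column(self):
        b1 = boundary_matrix(EDGE, 1).matrix.toarray()
        np.testing.assert_array_equal(b1, [[-1.0], [1.0]])

    def test_filled_triangle_b2(self):
        b2 = boundary_matrix(FILLED, 2).matrix.toarray()
        # faces of (0,1,2) against lexicographic edge order (01, 02, 12):
        # omit v0 -> (1,2) sign +? column is (-1)^i on face omitting v_i
        np.testing.assert_array_equal(b2[:, 0], [1.0, -1.0, 1.0])

    def test_chain_complex_identity(self, rng):
        for _ in range(10):
            cx = random_vr_complex(rng)
            if cx.n_simplices(2) == 0:
                continue
            b1 = boundary_matrix(cx, 1).matrix
            b2 = boundary_matrix(cx, 2).matrix
            assert abs((b1 @ b2)).max() == 0.0

    def test_column_structure(self, rng):
        cx = random_vr_complex(rng)
        for k in (1, 2):
            if cx.n_simplices(k) == 0:
                continue
            b = boundary_matrix(cx, k).matrix
            dense = b.toarray()
            assert ((dense != 0).sum(axis=0) == k + 1).all()

    def test_k_beyond_max_dim_gives_empty(self):
        b = boundary_matrix(EDGE, 2)
        assert b.matrix.shape == (1, 0)


class TestLaplacian:
    def test_single_edge_l0(self):
        np.testing.assert_array_equal(
            combinatorial_laplacian(EDGE, 0), [[1.0, -1.0], [-1.0, 1.0]]
        )

    def test_two_isolated_vertices(self):
        cx = SimplicialComplex([(0,), (1,)])
        np.testing.assert_array_equal(combinatorial_laplacian(cx, 0), np.zeros((2, 2)))

    def test_hollow_triangle_l1_spectrum(self):
        sp = spectrum_of(HOLLOW, 1)
        np.testing.assert_allclose(sp.eigenvalues, [0.0, 3.0, 3.0], atol=1e-9)
        assert sp.betti == 1

    def test_filled_triangle_l1_spectrum(self):
        sp = spectrum_of(FILLED, 1)
        np.testing.assert_allclose(sp.eigenvalues, [3.0, 3.0, 3.0], atol=1e-9)
        assert sp.betti == 0  # the 2-simplex kills the loop

    def test_absent_dimension_gives_empty_spectrum(self):
        sp = spectrum_of(EDGE, 2)
        assert sp.eigenvalues.size == 0
        assert sp.betti == 0

    def test_complete_graph_l0_nonharmonic(self):
        for m in (3, 5, 8):
            cx = SimplicialComplex(
                [(i,) for i in range(m)]
                + [(i, j) for i in range(m) for j in range(i + 1, m)]
            )
            sp = spectrum_of(cx, 0)
            assert sp.betti == 1
            np.testing.assert_allclose(sp.nonharmonic, np.full(m - 1, m), atol=1e-9)


class TestSpectrum:
    def test_single_edge_l0_closed_form(self):
        sp = spectrum_of(EDGE, 0)
        np.testing.assert_allclose(sp.eigenvalues, [0.0, 2.0], atol=1e-12)
        assert sp.betti == 1

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            spectrum(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_positive_semidefinite(self, rng):
        for _ in range(20):
            cx = random_vr_complex(rng)
            for k in range(cx.max_dim + 1):
                sp = spectrum_of(cx, k)
                if sp.eigenvalues.size:
                    assert sp.eigenvalues.min() >= -1e-8


class TestHodgeProperty:
    from hypothesis import given, settings, strategies as st

    @given(seed=st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_hodge_and_psd_for_any_random_complex(self, seed):
        rng = np.random.default_rng(seed)
        cx = random_vr_complex(rng)
        for k in range(3):
            sp = spectrum_of(cx, k)
            if sp.eigenvalues.size:
                assert sp.eigenvalues.min() >= -1e-8
            assert sp.betti == rank_betti(cx, k)


class TestHodgeConsistency:
    def test_zero_multiplicity_equals_rank_nullity_betti(self, rng):
        """Combinatorial Hodge theorem on random complexes, dims 0–2."""
        for _ in range(40):
            cx = random_vr_complex(rng)
            for k in range(3):
                assert spectrum_of(cx, k).betti == rank_betti(cx, k)

    def test_orientation_invariance(self, rng):
        """Reorienting simplices (sign flips of their boundary columns, and
        correspondingly their rows one dimension up) leaves spectra unchanged."""
        import scipy.sparse as sp

        for _ in range(15):
            cx = random_vr_complex(rng)
            for k in range(cx.max_dim + 1):
                b_down = boundary_matrix(cx, k).matrix if k >= 1 else None
                b_up = boundary_matrix(cx, k + 1).matrix
                ref = np.linalg.eigvalsh(laplacian_from_boundaries(b_down, b_up))
                n_k = cx.n_simplices(k)
                s = sp.diags(rng.choice([-1.0, 1.0], size=n_k))
                flip_down = (s @ b_down.T).T.tocsr() if b_down is not None else None
                flip_up = (s @ b_up).tocsr()
                if flip_up.shape[1]:
                    t = sp.diags(rng.choice([-1.0, 1.0], size=b_up.shape[1]))
                    flip_up = (flip_up @ t).tocsr()
                got = np.linalg.eigvalsh(laplacian_from_boundaries(flip_down, flip_up))
                np.testing.assert_allclose(got, ref, atol=1e-9)


class TestBettiCurve:
    def test_three_point_components(self):
        dm = np.full((3, 3), 1.0)
        np.fill_diagonal(dm, 0.0)
        filt = build_vr_filtration(dm, max_scale=2.0, max_dim=1)
        np.testing.assert_array_equal(betti_curve(filt, 0, [0.5, 1.0]), [3, 1])

    def test_circle_loop_against_persistence_oracle(self):
        pts = make_point_cloud("circle", n=20, radius=5.0, noise_sd=0.05, seed=4)
        filt = build_alpha_filtration(pts)
        oracle = GF2Persistence(filt)
        grid = [0.5, 1.0, 2.0, 4.0, 6.0]
        for k in (0, 1, 2):
            got = betti_curve(filt, k, grid)
            expected = [oracle.betti(k, t) for t in grid]
            assert list(got) == expected
        assert betti_curve(filt, 1, [2.0])[0] == 1  # the loop is seen mid-scale

    def test_betti_curve_matches_rank_oracle(self, rng):
        pts = rng.uniform(0, 2.0, size=(12, 3))
        filt = build_vr_filtration(pts, max_scale=1.5, max_dim=2)
        from toplap.filtration import snapshot

        grid = np.linspace(0, 1.5, 7)
        for k in (0, 1):
            curve = betti_curve(filt, k, grid)
            expected = [rank_betti(snapshot(filt, t), k) for t in grid]
            assert list(curve) == expected

    def test_beta0_non_increasing_for_vr(self, rng):
        pts = rng.uniform(0, 2.0, size=(15, 3))
        filt = build_vr_filtration(pts, max_scale=2.5, max_dim=1)
        curve = betti_curve(filt, 0, np.linspace(0, 2.5, 9))
        assert (np.diff(curve) <= 0).all()

    def test_rejects_descending_grid(self):
        filt = build_vr_filtration(np.zeros((2, 2)) + [[0, 1], [1, 0]], max_scale=2.0)
        with pytest.raises(ValueError):
            betti_curve(filt, 0, [1.0, 0.5])


def _permuted_copy(structure):
    """Same complex with chain order, residue order and atom order reversed."""
    chains = [
        Chain(
            chain_id=ch.chain_id,
            residues=[
                Residue(name=r.name, number=r.number, chain_id=r.chain_id,
                        icode=r.icode, atoms=list(reversed(r.atoms)))
                for r in reversed(ch.residues)
            ],
        )
        for ch in reversed(structure.chains)
    ]
    return ComplexStructure(structure.id, chains, structure.partner_split)


@pytest.fixture()
def mut():
    return MutationSpec("TOY1", "A", 5, "A", "G")


class TestSpectralFeatures:

    def test_deterministic(self, toy_complex, mut):
        f1 = spectral_features(toy_complex, mut, FeatureConfig.small())
        f2 = spectral_features(toy_complex, mut, FeatureConfig.small())
        np.testing.assert_array_equal(f1.values, f2.values)
        assert f1.names == f2.names

    def test_atom_order_invariance(self, toy_complex, mut):
        f1 = spectral_features(toy_complex, mut, FeatureConfig.small())
        f2 = spectral_features(_permuted_copy(toy_complex), mut, FeatureConfig.small())
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-9)

    def test_empty_neighborhood_gives_zero_block(self):
        # an isolated pair of chains far apart: binding subsets are empty
        st = make_toy_complex(SynthConfig(chain_gap=50.0, seed=2), complex_id="FAR")
        mut = MutationSpec("FAR", "A", 5, "A", "G")
        cfg = FeatureConfig.small()
        feats = spectral_features(st, mut, cfg)
        assert any("p1b-p2b" in b for b in feats.empty_blocks)
        block = [v for v, n in zip(feats.values, feats.names) if "p1b-p2b" in n]
        assert np.allclose(block, 0.0)

    def test_layout_matches_values(self, toy_complex, mut):
        feats = spectral_features(toy_complex, mut, FeatureConfig.small())
        assert len(feats.values) == len(feats.names)
        assert len(set(feats.names)) == len(feats.names)

    def test_alpha_blocks_present_in_full_config(self, toy_complex, mut):
        cfg = FeatureConfig(
            vr_grid=np.arange(0, 12.1, 3.0),
            alpha_grid=np.arange(0, 10.1, 2.5),
        )
        feats = spectral_features(toy_complex, mut, cfg)
        assert any(n.startswith("alpha1|") for n in feats.names)
        assert any(n.startswith("alpha2|") for n in feats.names)
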