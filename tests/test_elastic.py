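import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_connected_laplacian
from oracles import free_chain_msf, laplacian_pseudoinverse_diag
from seqgnm.couplings import ContactNetwork
from seqgnm.elastic import (
    DegeneracyError,
    Kirchhoff,
    chain_kirchhoff,
    combine,
    fluctuations,
    nonbonded_kirchhoff,
    pearson,
    seq_gnm,
    structure_gnm,
    structure_kirchhoff,
)
from seqgnm.io import CouplingTable, ProteinChain, Residue
from seqgnm.synthetic import make_chain


def linear_chain(coords_1d, spacing=1.0):
    coords = np.column_stack([np.asarray(coords_1d, float), np.zeros(len(coords_1d)), np.zeros(len(coords_1d))])
    res = [Residue("A", k + 1) for k in range(len(coords_1d))]
    return ProteinChain(residues=res, coords=coords)


class TestChainKirchhoff:
    def test_neighbour_enumeration_n5(self):
        k = chain_kirchhoff(5)
        np.testing.assert_allclose(np.diag(k.matrix), [3, 4, 4, 4, 3])
        assert k.matrix[0, 3] == -1 and k.matrix[0, 4] == 0

    def test_n2(self):
        np.testing.assert_allclose(chain_kirchhoff(2).matrix, [[1, -1], [-1, 1]])

    @pytest.mark.parametrize("n", [2, 5, 17, 100])
    def test_row_sums_zero(self, n):
        np.testing.assert_allclose(chain_kirchhoff(n).matrix.sum(axis=1), 0.0, atol=1e-12)

    def test_segments_have_no_cross_chain_bonds(self):
        k = chain_kirchhoff(10, segments=[6, 4])
        assert np.all(k.matrix[:6, 6:] == 0)
        np.testing.assert_allclose(k.matrix[6:, 6:], chain_kirchhoff(4).matrix)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            chain_kirchhoff(1)
        with pytest.raises(ValueError):
            chain_kirchhoff(10, segments=[3, 3])


class TestNonbondedKirchhoff:
    def test_single_contact(self):
        net = ContactNetwork(length=6, contacts=[(1, 5, 0.99)], threshold=0.9)
        m = nonbonded_kirchhoff(net).matrix
        assert m[0, 4] == m[4, 0] == -0.99
        assert m[0, 0] == m[4, 4] == 0.99
        assert np.abs(m).sum() == pytest.approx(4 * 0.99)

    def test_empty_network_is_zero_matrix(self):
        net = ContactNetwork(length=4, contacts=[])
        np.testing.assert_allclose(nonbonded_kirchhoff(net).matrix, 0.0)

    def test_shared_residue_accumulates_on_diagonal(self):
        net = ContactNetwork(length=8, contacts=[(1, 3, 0.99), (3, 8, 0.985)], threshold=0.9)
        assert nonbonded_kirchhoff(net).matrix[2, 2] == pytest.approx(1.975)


class TestStructureKirchhoff:
    def test_within_cutoff(self):
        k = structure_kirchhoff(linear_chain([0.0, 5.0]))
        np.testing.assert_allclose(k.matrix, [[1, -1], [-1, 1]])

    def test_beyond_cutoff(self):
        k = structure_kirchhoff(linear_chain([0.0, 15.0]))
        np.testing.assert_allclose(k.matrix, 0.0)

    def test_collinear_enumeration(self):
        k = structure_kirchhoff(linear_chain([0.0, 8.0, 16.0]))
        np.testing.assert_allclose(np.diag(k.matrix), [1, 2, 1])
        assert k.matrix[0, 2] == 0

    def test_cross_chain_contacts_included(self, pdb_text):
        from seqgnm.io import read_ca_trace

        chain = read_ca_trace(pdb_text)  # chain B starts 12.4 Å past chain A's end
        k = structure_kirchhoff(chain, cutoff=15.0)
        assert k.matrix[2, 3] == -1.0

    def test_bad_cutoff(self, walk_chain):
        with pytest.raises(ValueError):
            structure_kirchhoff(walk_chain, cutoff=0.0)


class TestCombine:
    def test_zero_nonbonded_is_identity(self):
        chain = chain_kirchhoff(5)
        zero = nonbonded_kirchhoff(ContactNetwork(length=5, contacts=[]))
        np.testing.assert_allclose(combine(chain, zero).matrix, chain.matrix)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            combine(chain_kirchhoff(5), chain_kirchhoff(6))

    def test_result_keeps_laplacian_invariants(self):
        net = ContactNetwork(length=7, contacts=[(1, 6, 0.95), (2, 7, 0.99)], threshold=0.9)
        total = combine(chain_kirchhoff(7), nonbonded_kirchhoff(net))
        total.validate()


class TestFluctuations:
    def test_two_node_closed_form(self):
        prof = fluctuations(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        np.testing.assert_allclose(prof.msf, [0.25, 0.25], atol=1e-12)

    @pytest.mark.parametrize("n", [5, 25, 100])
    def test_free_chain_matches_analytic_spectrum(self, n):
        prof = fluctuations(chain_kirchhoff(n, max_neighbor=1))
        np.testing.assert_allclose(prof.msf, free_chain_msf(n), atol=1e-8)

    def test_matches_dense_solver_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            lap = random_connected_laplacian(20, rng)
            prof = fluctuations(lap)
            np.testing.assert_allclose(prof.msf, laplacian_pseudoinverse_diag(lap), atol=1e-8)

    def test_scale_covariance(self):
        lap = random_connected_laplacian(15, np.random.default_rng(1))
        base = fluctuations(lap)
        scaled = fluctuations(Kirchhoff(3.0 * lap))
        np.testing.assert_allclose(scaled.msf, base.msf / 3.0, rtol=1e-9)
        np.testing.assert_allclose(scaled.percentile, base.percentile)

    def test_contacts_rigidify(self):
        """Adding a contact never increases the largest fluctuation."""
        rng = np.random.default_rng(2)
        lap = random_connected_laplacian(12, rng)
        before = fluctuations(lap).msf.max()
        i, j = 0, 7
        lap2 = lap.copy()
        lap2[i, j] -= 0.5
        lap2[j, i] -= 0.5
        lap2[i, i] += 0.5
        lap2[j, j] += 0.5
        after = fluctuations(lap2).msf.max()
        assert after <= before * (1 + 1e-9)

    def test_disconnected_components_warn_and_invert_per_component(self):
        lap = np.zeros((4, 4))
        lap[:2, :2] = [[1, -1], [-1, 1]]
        lap[2:, 2:] = [[2, -2], [-2, 2]]
        with pytest.warns(UserWarning, match="connected components"):
            prof = fluctuations(lap)
        np.testing.assert_allclose(prof.msf, [0.25, 0.25, 0.125, 0.125], atol=1e-12)

    def test_nonsymmetric_rejected(self):
        m = np.array([[1.0, -1.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            fluctuations(m)

    def test_bfactor_constant(self):
        prof = fluctuations(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        np.testing.assert_allclose(prof.bfactor, 8 * np.pi**2 / 3 * prof.msf)


class TestPearson:
    def test_limits(self):
        a = np.array([1.0, 2.0, 3.0, 5.0])
        assert pearson(a, a) == pytest.approx(1.0)
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov = 1, sigma_a = sqrt(2/3), sigma_b = sqrt(14)/3
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(
            1.0 / (np.sqrt(2.0 / 3.0) * np.sqrt(14.0) / 3.0)
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])
        with pytest.raises(ValueError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])


@given(st.integers(min_value=2, max_value=40))
def test_chain_kirchhoff_psd_and_single_zero_mode(n):
    k = chain_kirchhoff(n)
    k.validate()
    eig = np.linalg.eigvalsh(k.matrix)
    assert eig.min() >= -1e-9 * eig.max()
    assert np.sum(np.abs(eig) <= 1e-8 * eig.max()) == 1


def test_seq_gnm_on_empty_table_reduces_to_chain():
    from seqgnm.couplings import EmptyNetworkWarning

    with pytest.warns(EmptyNetworkWarning):
        prof = seq_gnm(CouplingTable(length=12, entries=[]))
    np.testing.assert_allclose(prof.msf, fluctuations(chain_kirchhoff(12)).msf)


def test_structure_gnm_profile_positive(walk_chain):
    prof = structure_gnm(walk_chain)
    assert prof.n_residues == walk_chain.n_residues
    assert np.all(prof.msf > 0)
    assert prof.percentile.max() == 1.0
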