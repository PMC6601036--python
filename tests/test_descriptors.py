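import math

import networkx as nx
import numpy as np
import pytest

from lbvs import chemio
from lbvs.chemio import embed_3d, heavy_graph, read_smiles, standardize
from lbvs.descriptors import (
    DEFAULT_REGISTRY,
    DescriptorRegistry,
    NAMED_ALIASES,
    compute_all,
    descriptor_table,
    read_table,
    write_table,
)
from lbvs.descriptors import topology as topo
from lbvs.descriptors.estate import estate_sums, estate_values, intrinsic_states
from lbvs.descriptors.geometry import rugosity
from lbvs.descriptors.subgraphs import connected_edge_subgraphs

from .oracles import (
    brute_centric,
    brute_chi,
    brute_connected_subgraphs,
    brute_kappa,
    brute_wiener,
)


def g_of(smiles: str) -> nx.Graph:
    return heavy_graph(standardize(read_smiles(smiles, smiles)))


class TestRegistry:
    def test_names_unique_and_mandatory_present(self):
        names = DEFAULT_REGISTRY.names
        assert len(names) == len(set(names))
        for alias in ("Rugty", "Tcent", "S(27)", "5chi_CH"):
            assert NAMED_ALIASES[alias] in names

    def test_families_cover_four_2d_plus_geometric(self):
        fams = {e.family for e in DEFAULT_REGISTRY.entries}
        assert fams == {
            "simple", "topological", "connectivity", "shape", "estate",
            "geometric",
        }

    def test_3d_flags_only_on_geometric(self):
        for e in DEFAULT_REGISTRY.entries:
            assert e.requires_3d == (e.family == "geometric")


class TestSimpleProperties:
    @pytest.mark.parametrize(
        "smiles,name,value",
        [
            ("CCO", "nHeavy", 3), ("CCO", "nRings", 0),
            ("CCO", "nHBD", 1), ("CCO", "nHBA", 1),
            ("c1ccccc1", "nRings", 1),
            ("c1ccc2ccccc2c1", "nRings", 2),  # naphthalene: 11 - 10 + 1
            ("CC(=O)O", "nRotBonds", 0), ("CCCC", "nRotBonds", 1),
        ],
    )
    def test_counts(self, smiles, name, value):
        dv = compute_all(standardize(read_smiles(smiles, smiles)))
        assert dv.values[DEFAULT_REGISTRY.index(name)] == value

    def test_monoisotopic_mass_benzene(self):
        dv = compute_all(standardize(read_smiles("c1ccccc1", "bz")))
        expected = 6 * 12.0 + 6 * 1.0078250319
        assert dv.values[DEFAULT_REGISTRY.index("MW")] == pytest.approx(expected)


class TestWienerCentric:
    @pytest.mark.parametrize(
        "smiles,wiener", [("CCC", 4), ("C1CCC1", 8)]
    )
    def test_wiener_examples(self, smiles, wiener):
        assert topo.wiener_index(g_of(smiles)) == wiener

    def test_wiener_single_atom(self):
        assert topo.wiener_index(g_of("C")) == 0

    def test_wiener_rejects_disconnected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError):
            topo.wiener_index(g)

    @pytest.mark.parametrize(
        "smiles,tcent", [("CCC", 5), ("CCCC", 8), ("C", 1)]
    )
    def test_centric_examples(self, smiles, tcent):
        assert topo.centric_index(g_of(smiles)) == tcent


class TestChi:
    def test_ethane_chi1(self):
        assert topo.chi_path(g_of("CC"), 1) == pytest.approx(1.0)

    def test_cyclopentane_chain5(self):
        assert topo.chi_chain(g_of("C1CCCC1"), 5) == pytest.approx(32**-0.5)

    def test_isobutane_cluster3(self):
        assert topo.chi_cluster(g_of("CC(C)C"), 3) == pytest.approx(3**-0.5)


class TestKappa:
    def test_propane(self):
        k = topo.kappa_indices(g_of("CCC"))
        assert k["k1"] == pytest.approx(3.0)
        assert k["k2"] == pytest.approx(2.0)

    def test_ethane_k2_masked(self):
        assert topo.kappa_indices(g_of("CC"))["k2"] is None


class TestOracleEquivalence:
    """Chi/Wiener/centric/kappa against exhaustive enumeration (<= 8 atoms)."""

    def test_subgraph_enumeration_matches_brute_force(self, test_molecules):
        for m in test_molecules:
            g = heavy_graph(m)
            if g.number_of_nodes() > 8:
                continue
            for order in range(1, 7):
                mine = set(connected_edge_subgraphs(g, order))
                assert mine == brute_connected_subgraphs(g, order), m.id

    def test_chi_all_orders_match_oracle(self, test_molecules):
        for m in test_molecules:
            g = heavy_graph(m)
            if g.number_of_nodes() > 8:
                continue
            for key, valence in (("delta", False), ("delta_v", True)):
                for order in range(7):
                    assert topo.chi_path(g, order, valence) == pytest.approx(
                        brute_chi(g, order, "path", key), abs=1e-12
                    ), (m.id, order, key)
                for order in range(3, 7):
                    assert topo.chi_cluster(g, order, valence) == pytest.approx(
                        brute_chi(g, order, "cluster", key), abs=1e-12
                    )
                    assert topo.chi_chain(g, order, valence) == pytest.approx(
                        brute_chi(g, order, "chain", key), abs=1e-12
                    )

    def test_wiener_centric_kappa_match_oracle(self, test_molecules):
        for m in test_molecules:
            g = heavy_graph(m)
            if g.number_of_nodes() > 8:
                continue
            assert topo.wiener_index(g) == brute_wiener(g)
            assert topo.centric_index(g) == brute_centric(g)
            ka, kb = topo.kappa_indices(g), brute_kappa(g)
            for key in ("k1", "k2", "k3"):
                if kb[key] is None:
                    assert ka[key] is None
                else:
                    assert ka[key] == pytest.approx(kb[key], abs=1e-12)


class TestEState:
    def test_ethane_symmetric_pair(self):
        s = estate_values(g_of("CC"))
        assert all(v == pytest.approx(2.0) for v in s.values())

    def test_perturbations_sum_to_zero(self, test_molecules):
        for m in test_molecules:
            g = heavy_graph(m)
            s = estate_values(g)
            intr = intrinsic_states(g)
            delta_sum = sum(s.values()) - sum(intr.values())
            assert abs(delta_sum) <= 1e-12 * max(len(s), 1)

    def test_benzene_s27_six_equivalent_carbons(self):
        sums = estate_sums(g_of("c1ccccc1"))
        # aromatic CH: I = ((2/2)^2 * 3 + 1) / 2 = 2; symmetry kills dI
        assert sums["S27_arom_C"] == pytest.approx(12.0)

    def test_s27_zero_without_aromatic_carbon(self):
        assert estate_sums(g_of("C1CCCCC1"))["S27_arom_C"] == 0.0


class TestRugosity:
    def test_single_united_atom_is_sphere(self):
        r = rugosity(np.zeros((1, 3)), np.array([1.7]))
        assert r == pytest.approx(1.0, abs=0.02)

    def test_linear_vs_cyclic_isomer(self):
        lin = embed_3d(standardize(read_smiles("CCCCCCCC", "octane")), seed=4)
        cyc = embed_3d(standardize(read_smiles("C1CCCCCCC1", "cyclooctane")), seed=4)
        reg = DEFAULT_REGISTRY
        r_lin = compute_all(lin).values[reg.index("Rugty")]
        r_cyc = compute_all(cyc).values[reg.index("Rugty")]
        assert r_lin >= r_cyc

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        xyz = rng.normal(size=(6, 3)) * 1.5
        radii = np.full(6, 1.7)
        a = rugosity(xyz, radii, probe=0.0)
        b = rugosity(2 * xyz, 2 * radii, probe=0.0)
        assert a == pytest.approx(b, rel=0.03)


class TestComputeAll:
    def test_benzene_fills_all_2d(self):
        dv = compute_all(standardize(read_smiles("c1ccccc1", "bz")))
        masked = {DEFAULT_REGISTRY.names[i] for i in np.flatnonzero(dv.mask)}
        assert masked == {"Rugty", "Rgyr", "Span3D", "SASArea", "SASVolume"}

    def test_3d_molecule_fills_geometric(self):
        m = embed_3d(standardize(read_smiles("CCO", "e")), seed=2)
        dv = compute_all(m)
        assert not dv.mask[DEFAULT_REGISTRY.index("Rugty")]

    def test_deterministic(self):
        m = standardize(read_smiles("CC(=O)Nc1ccccc1", "acetanilide"))
        a, b = compute_all(m), compute_all(m)
        assert np.array_equal(a.values, b.values, equal_nan=True)

    def test_atom_order_invariance(self, test_molecules):
        from rdkit import Chem

        for m in test_molecules[:8]:
            rd = chemio.to_rdkit(m)
            order = list(range(rd.GetNumAtoms()))[::-1]
            shuffled = Chem.RenumberAtoms(rd, order)
            m2 = chemio._from_rdkit(shuffled, m.id, m.provenance)
            a, b = compute_all(m), compute_all(m2)
            assert np.allclose(a.values, b.values, equal_nan=True, atol=1e-9)

    def test_table_round_trip(self, tmp_path):
        mols = [standardize(read_smiles(s, s)) for s in ("CCO", "c1ccccc1")]
        df = descriptor_table(mols)
        write_table(df, tmp_path / "t.csv")
        back = read_table(tmp_path / "t.csv")
        assert np.allclose(df.to_numpy(), back.to_numpy(), equal_nan=True)
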