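"""CATS pharmacophore typing, correlation vectors, distances and ranking."""

import itertools

import networkx as nx
import numpy as np
import pytest

from npdesign import compounds
from npdesign.cats import (
    N_BINS,
    PAIR_TYPES,
    assign_ppp_types,
    cats_distance,
    cats_vector,
    rank_by_cats,
    vector_labels,
)
from npdesign.chem import canonical_key, parse_structure

from .conftest import FIXTURE_SMILES, permute_atoms


def brute_force_raw_vector(mol, typing):
    """Independent oracle: all-pairs shortest paths via networkx, naive
    pair counting with the same declared same-atom convention."""
    graph = nx.Graph()
    graph.add_nodes_from(range(mol.GetNumAtoms()))
    for bond in mol.GetBonds():
        graph.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    spl = dict(nx.all_pairs_shortest_path_length(graph))
    counts = {pair: [0] * N_BINS for pair in PAIR_TYPES}
    for i in graph.nodes:
        for a, b in itertools.combinations_with_replacement(sorted(typing[i]), 2):
            counts[(a, b)][0] += 1
        for j in graph.nodes:
            if j <= i or j not in spl[i]:
                continue
            d = spl[i][j]
            if d >= N_BINS:
                continue
            for a in typing[i]:
                for b in typing[j]:
                    counts[tuple(sorted((a, b)))][d] += 1
    return np.array([counts[pair] for pair in PAIR_TYPES], dtype=float).ravel()


class TestTyping:
    def test_phenol_oxygen_is_donor_and_acceptor(self):
        mol = parse_structure("Oc1ccccc1")
        types = assign_ppp_types(mol)
        assert types[0] == {"D", "A"}

    def test_benzene_carbons_all_lipophilic(self):
        mol = parse_structure("c1ccccc1")
        assert all(t == {"L"} for t in assign_ppp_types(mol).values())

    def test_lophine_imidazole_nitrogens(self):
        mol = compounds.mol("lophine")
        types = assign_ppp_types(mol)
        nh = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N" and a.GetTotalNumHs() == 1]
        pyridine_type = [
            a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N" and a.GetTotalNumHs() == 0
        ]
        assert len(nh) == 1 and types[nh[0]] == {"D"}
        assert len(pyridine_type) == 1 and types[pyridine_type[0]] == {"A"}

    def test_charged_and_ionizable_rules(self):
        glycine = parse_structure("[NH3+]CC([O-])=O")
        types = assign_ppp_types(glycine)
        assert "P" in types[0]  # ammonium nitrogen
        assert any("N" in t for t in types.values())  # carboxylate oxygen
        acid = parse_structure("CC(=O)O")
        assert "N" in assign_ppp_types(acid)[1]  # acid carbon negatively ionizable


class TestVector:
    def test_dimension_and_labels(self):
        vec = cats_vector(parse_structure("CCO"))
        assert vec.values.shape == (150,)
        assert len(vector_labels()) == 150
        assert vec.as_matrix().shape == (15, 10)

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    def test_raw_vector_matches_brute_force_oracle(self, smiles):
        mol = parse_structure(smiles)
        assert mol.GetNumHeavyAtoms() <= 20
        vec = cats_vector(mol, scaling="raw")
        oracle = brute_force_raw_vector(mol, assign_ppp_types(mol))
        np.testing.assert_array_equal(vec.values, oracle)

    def test_raw_entries_are_integers(self, fixture_mols):
        for mol in fixture_mols:
            values = cats_vector(mol, scaling="raw").values
            np.testing.assert_array_equal(values, np.round(values))

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    @pytest.mark.parametrize("seed", [0, 3])
    def test_graph_invariance_under_renumbering(self, smiles, seed):
        mol = parse_structure(smiles)
        np.testing.assert_allclose(
            cats_vector(mol).values, cats_vector(permute_atoms(mol, seed)).values
        )

    def test_single_carbon_has_only_lipophilic_self_pair(self):
        vec = cats_vector(parse_structure("C"), scaling="raw")
        matrix = vec.as_matrix()
        ll = PAIR_TYPES.index(("L", "L"))
        assert matrix[ll, 0] == 1
        matrix_rest = np.delete(matrix, ll, axis=0)
        assert matrix_rest.sum() == 0

    def test_ethanol_donor_acceptor_block(self):
        # the hydroxyl O is both D and A -> one AD self-pair at distance 0
        vec = cats_vector(parse_structure("CCO"), scaling="raw").as_matrix()
        ad = PAIR_TYPES.index(("A", "D"))
        assert vec[ad, 0] == 1

    def test_occurrence_scaling_definition(self):
        # phenol: 1 D (the O), 1 A (the O), 7 heavy atoms, 6 L carbons?
        mol = parse_structure("Oc1ccccc1")
        raw = cats_vector(mol, scaling="raw").as_matrix()
        occ = cats_vector(mol, scaling="occurrence").as_matrix()
        typing = assign_ppp_types(mol)
        incidence = {t: sum(1 for s in typing.values() if t in s) for t in "DAPNL"}
        for k, (a, b) in enumerate(PAIR_TYPES):
            denom = incidence[a] + incidence[b]
            expected = raw[k] / denom if denom else np.zeros(N_BINS)
            np.testing.assert_allclose(occ[k], expected)

    def test_zero_heavy_atoms_rejected(self):
        from rdkit import Chem

        with pytest.raises(ValueError):
            cats_vector(Chem.MolFromSmiles(""))


class TestDistance:
    def test_identity(self, fixture_mols):
        for mol in fixture_mols[:5]:
            vec = cats_vector(mol)
            assert cats_distance(vec, vec) == 0.0

    def test_scaling_mismatch_rejected(self):
        a = cats_vector(parse_structure("CCO"), "raw")
        b = cats_vector(parse_structure("CCO"), "occurrence")
        with pytest.raises(ValueError):
            cats_distance(a, b)

    @pytest.mark.parametrize("metric", ["euclidean", "manhattan"])
    def test_metric_axioms_on_fixture_vectors(self, metric, fixture_mols):
        vecs = [cats_vector(m) for m in fixture_mols[:8]]
        for va, vb in itertools.combinations(vecs, 2):
            dab = cats_distance(va, vb, metric)
            assert dab >= 0
            assert dab == pytest.approx(cats_distance(vb, va, metric))
        for va, vb, vc in itertools.combinations(vecs, 3):
            assert cats_distance(va, vc, metric) <= (
                cats_distance(va, vb, metric) + cats_distance(vb, vc, metric) + 1e-12
            )

    def test_template_design_distances_ordered(self, template, designs):
        # the closest design by pharmacophore pattern is the glycolate ester
        d2 = cats_distance(cats_vector(template), cats_vector(designs["2"]))
        d3 = cats_distance(cats_vector(template), cats_vector(designs["3"]))
        assert 0 < d2 < d3 < 1.8


class TestRanking:
    def test_template_itself_ranks_first_at_zero(self, template, fixture_mols):
        ranked = rank_by_cats(template, fixture_mols[:5] + [template])
        first_mol, first_distance = ranked[0]
        assert canonical_key(first_mol) == canonical_key(template)
        assert first_distance == 0.0

    def test_order_independent_of_input_order(self, template, fixture_mols):
        mols = fixture_mols[:10]
        keys_fwd = [canonical_key(m) for m, _ in rank_by_cats(template, mols)]
        keys_rev = [canonical_key(m) for m, _ in rank_by_cats(template, mols[::-1])]
        assert keys_fwd == keys_rev

    def test_agrees_with_brute_force_sort(self, template, fixture_mols):
        mols = fixture_mols  # 20 molecules
        ranked = rank_by_cats(template, mols)
        ref = cats_vector(template)
        expected = sorted(
            ((cats_distance(ref, cats_vector(m)), canonical_key(m)) for m in mols)
        )
        assert [(d, canonical_key(m)) for m, d in ranked] == [
            (d, k) for d, k in expected
        ]

    def test_empty_candidates_rejected(self, template):
        with pytest.raises(ValueError):
            rank_by_cats(template, [])
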