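"""Macrocycle detection, canonical ordering, circuits and substituents."""
from __future__ import annotations

import numpy as np
import pytest

from porphgeom import make_template
from porphgeom.io_curation import MolecularStructure, perceive_bonds
from porphgeom.macrocycle import (
    canonical_atom_ordering,
    classify_substituents,
    enumerate_circuits,
    find_porphyrin_macrocycle,
    find_porphyrin_macrocycles,
    substituent_identity,
)


def _ring_structure(elements, bonds):
    """Bonds-only structure on a circle; detection is purely topological."""
    n = len(elements)
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    coords = np.stack([40 * np.cos(t), 40 * np.sin(t), np.zeros(n)], axis=1)
    return MolecularStructure(elements, coords,
                              bonds={(min(a, b), max(a, b)): 1 for a, b in bonds})


def _corrole_like():
    """Three meso bridges, one direct pyrrole-pyrrole bond: not a porphine."""
    elements, bonds = [], []
    alphas = []
    for p in range(4):
        base = len(elements)
        elements += ["N", "C", "C", "C", "C"]  # N, a1, b1, b2, a2
        bonds += [(base, base + 1), (base + 1, base + 2), (base + 2, base + 3),
                  (base + 3, base + 4), (base + 4, base)]
        alphas.append((base + 1, base + 4))
    for k in range(3):  # three meso bridges
        m = len(elements)
        elements.append("C")
        bonds += [(alphas[k][1], m), (m, alphas[(k + 1) % 4][0])]
    bonds.append((alphas[3][1], alphas[0][0]))  # direct link closes the ring
    return _ring_structure(elements, bonds)


class TestDetection:
    def test_porphine_roles(self, zn_porphine):
        st, m = zn_porphine
        assert len(m.n_idx) == 4
        assert len(m.c_alpha_idx) == 8 and len(m.c_beta_idx) == 8
        assert len(m.c_meso_idx) == 4
        assert len(m.macrocycle_atoms()) == 24
        assert all(st.elements[i] == "N" for i in m.n_idx)
        assert all(st.elements[i] == "C"
                   for i in m.c_alpha_idx + m.c_beta_idx + m.c_meso_idx)

    def test_role_adjacency_invariants(self, zn_porphine):
        st, m = zn_porphine
        adj = st.adjacency()
        for k in range(4):
            meso_nb = set(adj[m.c_meso_idx[k]]) & set(m.c_alpha_idx)
            assert len(meso_nb) == 2
            n_nb = set(adj[m.n_idx[k]])
            assert len(n_nb & set(m.c_alpha_idx)) == 2
            assert m.metal_idx in n_nb
        for k in range(8):
            b_nb = set(adj[m.c_beta_idx[k]])
            assert len(b_nb & set(m.c_alpha_idx)) == 1
            assert len(b_nb & set(m.c_beta_idx)) == 1

    def test_corrole_skeleton_is_rejected(self):
        assert find_porphyrin_macrocycles(_corrole_like()) == []

    def test_bis_porphyrin_reports_two_macrocycles(self, filter_fixtures):
        dimer = next(s for s in filter_fixtures if s.source_id == "fail_monomer")
        assert len(find_porphyrin_macrocycles(dimer)) == 2
        assert find_porphyrin_macrocycle(dimer) is None

    def test_detection_invariant_to_index_permutation(self, zn_porphine, rng):
        st, m = zn_porphine
        perm = rng.permutation(st.n_atoms)
        inv = np.argsort(perm)
        shuffled = MolecularStructure(
            [st.elements[i] for i in perm], st.coords[perm],
            bonds={(min(inv[a], inv[b]), max(inv[a], inv[b])): o
                   for (a, b), o in st.bonds.items()})
        m2 = find_porphyrin_macrocycle(shuffled)
        assert m2 is not None
        assert {perm[i] for i in m2.macrocycle_atoms()} == m.macrocycle_atoms()
        assert perm[m2.metal_idx] == m.metal_idx

    def test_metal_free_core_is_detected_without_metal(self):
        st, m = make_template(None, inner_h=True)
        assert m.metal_idx is None


class TestCanonicalOrdering:
    def test_idempotent(self, zn_porphine):
        st, m = zn_porphine
        again = canonical_atom_ordering(st, m)
        assert again.canonical_24() == m.canonical_24()

    def test_mono_meso_pattern_has_one_canonical_encoding(self):
        layouts = set()
        for site in range(4):
            st, m = make_template("Zn", meso={site: "Cl"})
            code = tuple(1 if any(st.elements[a] == "Cl" for a in r.atoms)
                         else 0
                         for i in m.c_meso_idx
                         for r in m.substituents if r.attachment_atom == i)
            layouts.add(code)
        assert len(layouts) == 1

    def test_different_patterns_differ(self):
        def code(st, m):
            out = []
            for i in list(m.c_beta_idx) + list(m.c_meso_idx):
                rec = next(r for r in m.substituents if r.attachment_atom == i)
                out.append(substituent_identity(st, rec.atoms))
            return tuple(out)

        a = code(*make_template("Zn", meso={0: "Cl"}))
        b = code(*make_template("Zn", meso={0: "Cl", 2: "Cl"}))
        assert a != b


class TestCircuits:
    def test_five_circuits_with_expected_sizes(self, zn_porphine):
        _, m = zn_porphine
        circuits = enumerate_circuits(m)
        assert [len(c.bonds) for c in circuits] == [16, 5, 5, 5, 5]
        assert [c.name for c in circuits][0] == "inner"

    def test_inner_circuit_excludes_all_betas(self, zn_porphine):
        _, m = zn_porphine
        inner = enumerate_circuits(m)[0]
        assert not set(inner.atoms) & set(m.c_beta_idx)
        assert set(inner.atoms) == set(m.n_idx) | set(m.c_alpha_idx) | \
            set(m.c_meso_idx)

    def test_pyrroles_plus_meso_partition_macrocycle(self, zn_porphine):
        _, m = zn_porphine
        circuits = enumerate_circuits(m)
        pyr_atoms = set().union(*(set(c.atoms) for c in circuits[1:]))
        assert pyr_atoms | set(m.c_meso_idx) == m.macrocycle_atoms()

    def test_circuit_bonds_exist_in_structure(self, zn_porphine):
        st, m = zn_porphine
        for c in enumerate_circuits(m):
            for (i, j) in c.bonds:
                assert (min(i, j), max(i, j)) in st.bonds


class TestSubstituents:
    def test_tetraphenyl_classification(self, tpp):
        st, m = tpp
        recs = classify_substituents(st, m)
        meso = [r for r in recs if r.position_class == "meso"]
        beta = [r for r in recs if r.position_class == "beta"]
        assert len(meso) == 4 and all(len(r.atoms) == 11 for r in meso)
        assert len(beta) == 8 and all(len(r.atoms) == 1 for r in beta)

    def test_octaethyl_classification(self, oep):
        st, m = oep
        recs = classify_substituents(st, m)
        beta = [r for r in recs if r.position_class == "beta"]
        meso = [r for r in recs if r.position_class == "meso"]
        assert len(beta) == 8 and all(len(r.atoms) == 7 for r in beta)
        assert len(meso) == 4 and all(len(r.atoms) == 1 for r in meso)

    def test_axial_pyridine_is_one_axial_record(self):
        st, m = make_template("Zn", axial="pyridine")
        recs = classify_substituents(st, m)
        axial = [r for r in recs if r.position_class == "axial"]
        assert len(axial) == 1
        assert axial[0].n_attachment_bonds == 1
        assert len(m.axial_idx) == 1

    def test_identity_is_position_independent(self):
        st_b, m_b = make_template("Zn", beta={0: "methyl"})
        st_m, m_m = make_template("Zn", meso={0: "methyl"})
        rb = next(r for r in m_b.substituents if len(r.atoms) == 4)
        rm = next(r for r in m_m.substituents if len(r.atoms) == 4)
        assert substituent_identity(st_b, rb.atoms) == \
            substituent_identity(st_m, rm.atoms)

    def test_flagged_attachment_detected(self):
        st, m = make_template(None, inner_h=True)
        with pytest.raises(Exception):
            classify_substituents(st, m, strict=True)
        recs = classify_substituents(st, m, strict=False)
        assert any(r.position_class == "flagged" for r in recs)
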