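"""Porphyrin macrocycle detection, canonical ordering and circuits.

Detection is purely topological (graph substructure), so arbitrarily
distorted macrocycles are found: four five-membered N-rings (pyrroles)
bridged by four single-carbon (meso) bridges into a closed 16-membered
inner ring.  The 24 macrocycle atoms are assigned canonical roles
(4 N, 8 C-alpha, 8 C-beta, 4 C-meso) in ring-traversal order, and the
labeling is canonicalized over the 8-element symmetry group (4 rotations x
reflection) so symmetry-equivalent substitution patterns get identical
descriptor layouts.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .io_curation import MolecularStructure

__all__ = [
    "MacrocycleMap",
    "Circuit",
    "SubstituentRecord",
    "find_porphyrin_macrocycles",
    "find_porphyrin_macrocycle",
    "canonical_atom_ordering",
    "enumerate_circuits",
    "classify_substituents",
    "substituent_identity",
]


@dataclass
class SubstituentRecord:
    """One substituent: the atoms hanging off a ring position or the metal."""

    attachment_atom: int          # macrocycle atom or metal the group binds to
    position_class: str           # 'beta' | 'meso' | 'axial' | 'flagged'
    atoms: frozenset[int]
    n_attachment_bonds: int       # bonds from the group to macrocycle+metal


@dataclass
class MacrocycleMap:
    """Canonical indices of the 24 macrocycle atoms plus metal and ligands.

    Ring-order layout for pyrrole k (k = 0..3):
    ``n_idx[k]`` is the nitrogen; ``c_alpha_idx[2k]`` the alpha carbon entered
    from meso k-1, ``c_alpha_idx[2k+1]`` the alpha carbon leading to meso k;
    ``c_beta_idx[2k]``/``[2k+1]`` the betas bonded to those alphas;
    ``c_meso_idx[k]`` the bridge between pyrroles k and k+1.
    """

    n_idx: tuple[int, int, int, int]
    c_alpha_idx: tuple[int, ...]
    c_beta_idx: tuple[int, ...]
    c_meso_idx: tuple[int, int, int, int]
    metal_idx: int | None = None
    axial_idx: tuple[int, ...] = ()
    substituents: list[SubstituentRecord] = field(default_factory=list)

    def macrocycle_atoms(self) -> frozenset[int]:
        return frozenset(self.n_idx) | frozenset(self.c_alpha_idx) | \
            frozenset(self.c_beta_idx) | frozenset(self.c_meso_idx)

    def inner_ring_sequence(self) -> list[int]:
        """The 16-membered inner ring in traversal order."""
        seq = []
        for k in range(4):
            seq += [self.n_idx[k], self.c_alpha_idx[2 * k + 1],
                    self.c_meso_idx[k], self.c_alpha_idx[(2 * k + 2) % 8]]
        return seq

    def canonical_24(self) -> list[int]:
        """Fixed slot order used by the nonplanarity basis: N, Ca, Cb, Cm."""
        return list(self.n_idx) + list(self.c_alpha_idx) + \
            list(self.c_beta_idx) + list(self.c_meso_idx)


@dataclass
class Circuit:
    """A closed bonded walk used for HOMA scoring."""

    name: str
    atoms: list[int]

    @property
    def bonds(self) -> list[tuple[int, int]]:
        n = len(self.atoms)
        return [(self.atoms[i], self.atoms[(i + 1) % n]) for i in range(n)]


def _pyrrole_candidates(structure: MolecularStructure) -> list[dict]:
    """5-rings with exactly one N and four C: {n, alphas, betas, atoms}."""
    adj = structure.adjacency()
    el = structure.elements
    seen: set[frozenset[int]] = set()
    out = []
    for n_at in range(structure.n_atoms):
        if el[n_at] != "N":
            continue
        c_nb = [j for j in adj[n_at] if el[j] == "C"]
        for ai in range(len(c_nb)):
            for aj in range(ai + 1, len(c_nb)):
                u, w = c_nb[ai], c_nb[aj]
                for x in adj[u]:
                    if el[x] != "C" or x in (n_at, u, w):
                        continue
                    for y in adj[w]:
                        if el[y] != "C" or y in (n_at, u, w, x):
                            continue
                        if (min(x, y), max(x, y)) in structure.bonds:
                            ring = frozenset((n_at, u, x, y, w))
                            if ring not in seen:
                                seen.add(ring)
                                out.append({"n": n_at, "alphas": (u, w),
                                            "betas": (x, y), "atoms": ring})
    return out


def find_porphyrin_macrocycles(structure: MolecularStructure) -> list[MacrocycleMap]:
    """All porphine skeletons in the structure (one map each, canonicalized)."""
    pyrroles = _pyrrole_candidates(structure)
    if len(pyrroles) < 4:
        return []
    adj = structure.adjacency()
    el = structure.elements
    pyrrole_atoms_all = set().union(*(p["atoms"] for p in pyrroles))
    # meso bridges: a carbon outside every pyrrole bonded to alpha carbons of
    # two different pyrroles
    bridges: dict[tuple[int, int], list[tuple[int, int, int]]] = {}
    for b in range(structure.n_atoms):
        if el[b] != "C" or b in pyrrole_atoms_all:
            continue
        hits = []
        for pi, p in enumerate(pyrroles):
            for a in p["alphas"]:
                if a in adj[b]:
                    hits.append((pi, a))
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                (pi, ai), (pj, aj) = hits[i], hits[j]
                if pi != pj:
                    key = (min(pi, pj), max(pi, pj))
                    bridges.setdefault(key, []).append((b, ai, aj) if pi < pj else (b, aj, ai))
    # pyrrole-level graph; 4-cycles with 4 distinct bridges are macrocycles
    pg = nx.Graph(list(bridges))
    maps: list[MacrocycleMap] = []
    seen_sets: set[frozenset[int]] = set()
    for cyc in nx.simple_cycles(pg, length_bound=4):
        if len(cyc) != 4:
            continue
        # walk the pyrrole cycle p0-p1-p2-p3
        seq16: list[int] = []
        ok = True
        used_bridges = []
        for k in range(4):
            pi, pj = cyc[k], cyc[(k + 1) % 4]
            key = (min(pi, pj), max(pi, pj))
            cand = bridges.get(key, [])
            if not cand:
                ok = False
                break
            b, a_lo, a_hi = cand[0]
            a_out = a_lo if pi < pj else a_hi    # alpha on pyrrole pi side
            a_in = a_hi if pi < pj else a_lo     # alpha on pyrrole pj side
            used_bridges.append((b, a_out, a_in))
        if not ok:
            continue
        for k in range(4):
            p = pyrroles[cyc[k]]
            b_prev, _, a_in = used_bridges[k - 1]
            b_this, a_out, _ = used_bridges[k]
            if a_in == a_out or a_in not in p["alphas"] or a_out not in p["alphas"]:
                ok = False
                break
            seq16 += [a_in, p["n"], a_out, b_this]
        if not ok:
            continue
        # rotate so a nitrogen sits at position 0 (layout N, A_out, M, A_in)
        seq16 = seq16[1:] + seq16[:1]
        atoms24 = set(seq16)
        for k in range(4):
            atoms24 |= set(pyrroles[cyc[k]]["betas"])
        if len(atoms24) != 24 or frozenset(atoms24) in seen_sets:
            continue
        seen_sets.add(frozenset(atoms24))
        m = _map_from_sequence(structure, seq16)
        if m is not None:
            maps.append(canonical_atom_ordering(structure, m))
    return maps


def _map_from_sequence(structure: MolecularStructure,
                       seq16: list[int]) -> MacrocycleMap | None:
    """Build a role map from a 16-ring sequence [N, A_out, M, A_in, N, ...]."""
    adj = structure.adjacency()
    n_idx, a_idx, b_idx, m_idx = [], [], [], []
    for k in range(4):
        n = seq16[4 * k]
        a_out = seq16[4 * k + 1]
        meso = seq16[4 * k + 2]
        a_in = seq16[(4 * k - 1) % 16]
        if structure.elements[n] != "N":
            return None
        betas_in = [j for j in adj[a_in]
                    if structure.elements[j] == "C" and j not in seq16]
        betas_out = [j for j in adj[a_out]
                     if structure.elements[j] == "C" and j not in seq16]
        b_in = [j for j in betas_in for jj in betas_out
                if (min(j, jj), max(j, jj)) in structure.bonds]
        if not b_in:
            return None
        b_i = b_in[0]
        b_o = [jj for jj in betas_out if (min(b_i, jj), max(b_i, jj)) in structure.bonds][0]
        n_idx.append(n)
        a_idx += [a_in, a_out]
        b_idx += [b_i, b_o]
        m_idx.append(meso)
    mm = MacrocycleMap(tuple(n_idx), tuple(a_idx), tuple(b_idx), tuple(m_idx))
    # central atom: bonded to all four pyrrole N, outside the macrocycle
    macro = mm.macrocycle_atoms()
    metal = None
    for cand in adj[n_idx[0]]:
        if cand in macro:
            continue
        if all(cand in adj[n] for n in n_idx):
            metal = cand
            break
    axial: tuple[int, ...] = ()
    if metal is not None:
        axial = tuple(sorted(j for j in adj[metal] if j not in n_idx))
    return replace(mm, metal_idx=metal, axial_idx=axial)


def find_porphyrin_macrocycle(structure: MolecularStructure) -> MacrocycleMap | None:
    """The unique macrocycle map, or ``None`` if zero or several are present."""
    maps = find_porphyrin_macrocycles(structure)
    return maps[0] if len(maps) == 1 else None


# ---------------------------------------------------------------------------
# Canonicalization over the 8 symmetry images
# ---------------------------------------------------------------------------

def _images_of_sequence(seq16: list[int]) -> list[list[int]]:
    images = [seq16[4 * r:] + seq16[:4 * r] for r in range(4)]
    rev = seq16[::-1]
    # reversed sequence has nitrogens at positions 3, 7, 11, 15
    rev = rev[3:] + rev[:3]
    images += [rev[4 * r:] + rev[:4 * r] for r in range(4)]
    return images


def _substituent_key(structure: MolecularStructure, atoms: frozenset[int]) -> str:
    return substituent_identity(structure, atoms)


def substituent_identity(structure: MolecularStructure, atoms: frozenset[int]) -> str:
    """Canonical identity of a substituent: formula + WL graph hash.

    Used both for canonical ordering and for the unseen-substituent split in
    the model-evaluation protocol.
    """
    idx = sorted(atoms)
    g = nx.Graph()
    for i in idx:
        g.add_node(i, el=structure.elements[i])
    for (a, b) in structure.bonds:
        if a in atoms and b in atoms:
            g.add_edge(a, b)
    formula = "".join(f"{el}{n}" for el, n in sorted(
        (el, sum(1 for i in idx if structure.elements[i] == el))
        for el in set(structure.elements[i] for i in idx)))
    h = nx.weisfeiler_lehman_graph_hash(g, node_attr="el")
    return f"{formula}:{h}"


def _attachment_codes(structure: MolecularStructure,
                      m: MacrocycleMap) -> dict[int, str]:
    """attachment atom -> substituent identity, for beta/meso positions."""
    recs = classify_substituents(structure, m, strict=False)
    return {r.attachment_atom: _substituent_key(structure, r.atoms)
            for r in recs if r.position_class in ("beta", "meso")}


def canonical_atom_ordering(structure: MolecularStructure,
                            m: MacrocycleMap) -> MacrocycleMap:
    """Relabel ring positions to the lexicographically smallest of the 8
    symmetry images of the substitution pattern (ties broken by atom index,
    harmless because descriptors are means over positions)."""
    by_attach = _attachment_codes(structure, m)
    best = None
    for img in _images_of_sequence(m.inner_ring_sequence()):
        cand = _map_from_sequence(structure, img)
        if cand is None:
            continue
        code = tuple(by_attach.get(i, "") for i in cand.c_beta_idx) + \
            tuple(by_attach.get(i, "") for i in cand.c_meso_idx)
        key = (code, cand.canonical_24())
        if best is None or key < best[0]:
            best = (key, cand)
    assert best is not None
    chosen = best[1]
    chosen.substituents = classify_substituents(structure, chosen, strict=False)
    return chosen


# ---------------------------------------------------------------------------
# Circuits
# ---------------------------------------------------------------------------

def enumerate_circuits(m: MacrocycleMap) -> list[Circuit]:
    """The inner 16-bond circuit and the four 5-bond pyrrole circuits."""
    circuits = [Circuit("inner", m.inner_ring_sequence())]
    for k in range(4):
        circuits.append(Circuit(
            f"pyrrole_{k + 1}",
            [m.n_idx[k], m.c_alpha_idx[2 * k], m.c_beta_idx[2 * k],
             m.c_beta_idx[2 * k + 1], m.c_alpha_idx[2 * k + 1]],
        ))
    return circuits


# ---------------------------------------------------------------------------
# Substituents
# ---------------------------------------------------------------------------

class SubstituentAttachmentError(ValueError):
    """A substituent attaches to an alpha carbon or ring nitrogen."""


def classify_substituents(structure: MolecularStructure, m: MacrocycleMap,
                          strict: bool = True) -> list[SubstituentRecord]:
    """Partition non-macrocycle atoms into substituents by attachment point.

    Components of the graph with the macrocycle and metal removed are
    classified by what they bind to: a beta carbon (beta substituent), a meso
    carbon (meso), the metal (axial ligand).  Hydrogens are substituents in
    their own right.  Attachment through an alpha carbon or ring nitrogen
    violates the curation assumptions and is flagged (or raised if strict).
    """
    macro = m.macrocycle_atoms()
    blocked = set(macro)
    if m.metal_idx is not None:
        blocked.add(m.metal_idx)
    adj = structure.adjacency()
    seen: set[int] = set()
    records: list[SubstituentRecord] = []
    beta_set, meso_set = set(m.c_beta_idx), set(m.c_meso_idx)
    for start in range(structure.n_atoms):
        if start in blocked or start in seen:
            continue
        stack, comp = [start], set()
        seen.add(start)
        while stack:
            v = stack.pop()
            comp.add(v)
            for w in adj[v]:
                if w not in blocked and w not in seen:
                    seen.add(w)
                    stack.append(w)
        attach_bonds = [(a, b) for (a, b) in structure.bonds
                        if (a in comp) != (b in comp)
                        and (a in blocked or b in blocked)]
        anchors = sorted({a if a in blocked else b for (a, b) in attach_bonds})
        if not anchors:
            continue  # separate component (counter molecule), not a substituent
        for anchor in anchors:
            if anchor in beta_set:
                cls = "beta"
            elif anchor in meso_set:
                cls = "meso"
            elif m.metal_idx is not None and anchor == m.metal_idx:
                cls = "axial"
            else:
                if strict:
                    raise SubstituentAttachmentError(
                        f"substituent attached to macrocycle atom {anchor}")
                cls = "flagged"
            records.append(SubstituentRecord(
                attachment_atom=anchor,
                position_class=cls,
                atoms=frozenset(comp),
                n_attachment_bonds=len(attach_bonds),
            ))
    return records
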