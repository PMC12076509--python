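"""Synthetic metalloporphyrin geometries and planted structure-property data.

Everything the analysis pipeline consumes can be generated here without any
external database: idealized porphine templates with substituents of
controlled bulk grafted at beta/meso/axial sites, pure-distortion scans of
the NSD modes, curation-filter fixtures, and whole populations whose
distortion amplitudes follow a planted linear law in the five steric
descriptors with additive Gaussian noise.

Distorted geometries displace macrocycle atoms along the reference-plane
normal with in-plane coordinates fixed (substituents ride along with their
attachment atom), so bonds elongate purely geometrically; no force field is
involved.  This is the minimal construction in which nonplanarity feeds back
into bond lengths and hence into the aromaticity scores.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aromaticity import HOMAParams, calibrate, homa
from .descriptors import FEATURE_NAMES, build_feature_vector
from .io_curation import MolecularStructure, perceive_bonds
from .macrocycle import (
    MacrocycleMap,
    enumerate_circuits,
    find_porphyrin_macrocycle,
)
from .nonplanarity import (
    MODE_NAMES,
    NSDBasis,
    build_nsd_basis,
    impose_distortion,
    nsd_decompose,
)
from .reference import hydrogen_directions, reference_macrocycle_coords

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSpec", "PopulationDataset", "RING_SUBSTITUENTS",
    "AXIAL_LIGANDS", "make_template", "impose_on_structure",
    "distortion_scan", "generate_population", "make_filter_fixtures",
    "default_calibration",
]


# ---------------------------------------------------------------------------
# Substituent library (local frames: apex at origin, bond along +x,
# secondary direction +y mapped onto the macrocycle normal)
# ---------------------------------------------------------------------------

def _tetrahedral_cap(center: np.ndarray, back: np.ndarray, bond: float,
                     element: str, phases=(90.0, 210.0, 330.0)) -> list[tuple]:
    """Three atoms completing a tetrahedron around ``center`` whose fourth
    vertex points along ``back`` (unit vector toward the previous atom)."""
    back = back / np.linalg.norm(back)
    # local frame perpendicular to back
    p = np.array([0.0, 1.0, 0.0])
    if abs(p @ back) > 0.9:
        p = np.array([0.0, 0.0, 1.0])
    e1 = p - (p @ back) * back
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(back, e1)
    out = []
    pol = np.deg2rad(180.0 - 109.471)
    for ph in np.deg2rad(phases):
        d = (-back * np.cos(pol) +
             (e1 * np.cos(ph) + e2 * np.sin(ph)) * np.sin(pol))
        out.append((element, center + bond * d))
    return out


def _ring6(first_element: str, d_attach: float) -> list[tuple]:
    """Planar six-ring (local xy plane) bound through its first atom."""
    atoms = []
    center = np.array([d_attach + 1.397, 0.0, 0.0])
    for k in range(6):
        a = np.pi + k * np.pi / 3
        pos = center + 1.397 * np.array([np.cos(a), np.sin(a), 0.0])
        el = first_element if k == 0 else "C"
        atoms.append((el, pos))
        if k != 0:
            h = center + (1.397 + 1.08) * np.array([np.cos(a), np.sin(a), 0.0])
            atoms.append(("H", h))
    return atoms


def _alkyl(n_carbons: int, d_attach: float) -> list[tuple]:
    """Straight-chain alkyl grown in the local xy plane, H-capped."""
    atoms: list[tuple] = []
    prev = np.zeros(3)
    pos = np.array([d_attach, 0.0, 0.0])
    for c in range(n_carbons):
        atoms.append(("C", pos.copy()))
        back = (prev - pos) / np.linalg.norm(prev - pos)
        if c < n_carbons - 1:
            # continue the chain along local +y (the macrocycle normal) so
            # the tail points out of plane, away from neighbouring groups
            nxt = _tetrahedral_cap(pos, back, 1.53, "C", phases=(0.0,))[0][1]
            atoms += _tetrahedral_cap(pos, back, 1.09, "H", phases=(120.0, 240.0))
            prev, pos = pos, nxt
        else:
            atoms += _tetrahedral_cap(pos, back, 1.09, "H")
    return atoms


def _branched(center_el: str, d_attach: float, arm_bond: float) -> list[tuple]:
    """Central atom with three identical arms (tert-butyl, NMe3, PMe3)."""
    atoms: list[tuple] = []
    center = np.array([d_attach, 0.0, 0.0])
    atoms.append((center_el, center.copy()))
    back = np.array([-1.0, 0.0, 0.0])
    # one arm along local +y (the macrocycle normal) keeps the bulk clear of
    # neighbouring attachment sites
    arms = _tetrahedral_cap(center, back, arm_bond, "C", phases=(0.0, 120.0, 240.0))
    for _, cpos in arms:
        atoms.append(("C", cpos))
        b = (center - cpos) / np.linalg.norm(center - cpos)
        atoms += _tetrahedral_cap(cpos, b, 1.09, "H")
    return atoms


def _hydride_cap(center_el: str, d_attach: float, bond: float,
                 n_h: int) -> list[tuple]:
    center = np.array([d_attach, 0.0, 0.0])
    atoms = [(center_el, center.copy())]
    back = np.array([-1.0, 0.0, 0.0])
    phases = {3: (90.0, 210.0, 330.0), 2: (90.0, 270.0), 1: (90.0,)}[n_h]
    atoms += _tetrahedral_cap(center, back, bond, "H", phases=phases)
    return atoms


def _single(element: str, d: float) -> list[tuple]:
    return [(element, np.array([d, 0.0, 0.0]))]


#: Ring substituents: local geometry builders keyed by name (bond to ring C).
RING_SUBSTITUENTS = {
    "H": lambda: _single("H", 1.08),
    "F": lambda: _single("F", 1.35),
    "Cl": lambda: _single("Cl", 1.73),
    "Br": lambda: _single("Br", 1.90),
    "I": lambda: _single("I", 2.10),
    "methyl": lambda: [("C", np.array([1.50, 0.0, 0.0]))] + _tetrahedral_cap(
        np.array([1.50, 0.0, 0.0]), np.array([-1.0, 0.0, 0.0]), 1.09, "H"),
    "ethyl": lambda: _alkyl(2, 1.50),
    "phenyl": lambda: _ring6("C", 1.49),
    "tbutyl": lambda: _branched("C", 1.53, 1.53),
}

#: Axial ligands bound to the metal (bond length metal-donor ~ 2.1 Å).
AXIAL_LIGANDS = {
    "aqua": lambda: _hydride_cap("O", 2.05, 0.96, 2),
    "ammine": lambda: _hydride_cap("N", 2.10, 1.01, 3),
    "phosphine": lambda: _hydride_cap("P", 2.30, 1.42, 3),
    "pyridine": lambda: _ring6("N", 2.10),
    "trimethylamine": lambda: _branched("N", 2.12, 1.47),
    "trimethylphosphine": lambda: _branched("P", 2.35, 1.84),
}

#: Metals with even atomic number, so the synthetic complexes keep even
#: electron counts with the even-electron ligand library above.
TEMPLATE_METALS = ("Zn", "Ni", "Ru", "Fe", "Pd", "Mg", "Sn", "Pt")


def _graft(atoms_local: list[tuple], pos: np.ndarray, e_x: np.ndarray,
           e_y: np.ndarray) -> list[tuple]:
    e_x = e_x / np.linalg.norm(e_x)
    e_y = e_y - (e_y @ e_x) * e_x
    e_y /= np.linalg.norm(e_y)
    e_z = np.cross(e_x, e_y)
    R = np.stack([e_x, e_y, e_z], axis=1)
    return [(el, R @ p + pos) for el, p in atoms_local]


def _normalize_sites(spec, n_sites: int, default: str = "H") -> list[str]:
    if spec is None:
        return [default] * n_sites
    if isinstance(spec, str):
        return [spec] * n_sites
    out = [default] * n_sites
    for k, v in dict(spec).items():
        out[int(k)] = v
    return out


def make_template(metal: str | None = "Zn", beta=None, meso=None,
                  axial: str | tuple = (), inner_h: bool = False,
                  source_id: str = "template"
                  ) -> tuple[MolecularStructure, MacrocycleMap]:
    """Idealized planar metalloporphine with substituents grafted on.

    ``beta``/``meso`` accept a single library key for all sites or a mapping
    of site index (0-7 beta, 0-3 meso) to key; unlisted sites get hydrogen.
    ``axial`` is up to two library keys, placed trans along ±z.  The result
    passes all seven curation filters by construction (for library
    substituents and even-Z metals).
    """
    ref = reference_macrocycle_coords()
    dirs = hydrogen_directions(ref)
    elements = ["N"] * 4 + ["C"] * 20
    coords = [ref[i] for i in range(24)]
    if metal is not None:
        elements.append(metal)
        coords.append(np.zeros(3))
    z_hat = np.array([0.0, 0.0, 1.0])
    beta_keys = _normalize_sites(beta, 8)
    meso_keys = _normalize_sites(meso, 4)
    for slot, key in [(12 + i, k) for i, k in enumerate(beta_keys)] + \
                     [(20 + i, k) for i, k in enumerate(meso_keys)]:
        if key not in RING_SUBSTITUENTS:
            raise KeyError(f"unknown ring substituent {key!r}")
        for el, p in _graft(RING_SUBSTITUENTS[key](), ref[slot],
                            dirs[slot], z_hat):
            elements.append(el)
            coords.append(p)
    axial_keys = (axial,) if isinstance(axial, str) else tuple(axial)
    if len(axial_keys) > 2:
        raise ValueError("at most two axial ligands")
    if axial_keys and metal is None:
        raise ValueError("axial ligands require a metal")
    for key, sign in zip(axial_keys, (1.0, -1.0)):
        if key not in AXIAL_LIGANDS:
            raise KeyError(f"unknown axial ligand {key!r}")
        for el, p in _graft(AXIAL_LIGANDS[key](), np.zeros(3),
                            sign * z_hat, np.array([1.0, 0.0, 0.0])):
            elements.append(el)
            coords.append(p)
    if inner_h:
        if metal is not None:
            raise ValueError("inner hydrogens require a metal-free core")
        for k in range(4):
            d = -ref[k] / np.linalg.norm(ref[k])
            elements.append("H")
            coords.append(ref[k] + 1.01 * d)
    st = MolecularStructure(elements, np.array(coords), source_id=source_id)
    st = perceive_bonds(st)
    m = find_porphyrin_macrocycle(st)
    if m is None:
        raise RuntimeError("template construction failed to produce a "
                           "detectable macrocycle")
    return st, m


def impose_on_structure(structure: MolecularStructure, m: MacrocycleMap,
                        basis: NSDBasis,
                        amplitudes: dict[str, float]) -> MolecularStructure:
    """Displace the macrocycle by pure modes; substituents ride along.

    Macrocycle atoms move along the plane normal by the mode pattern (their
    in-plane coordinates are untouched); each ring substituent is translated
    rigidly with its attachment atom.  Metal and axial ligands stay put.
    """
    disp = impose_distortion(basis, amplitudes)
    dz = disp[:, 2] - basis.reference[:, 2]
    out = structure.copy()
    slots = m.canonical_24()
    for s, atom in enumerate(slots):
        out.coords[atom, 2] += dz[s]
    slot_of = {atom: s for s, atom in enumerate(slots)}
    for rec in m.substituents:
        if rec.position_class in ("beta", "meso") and \
                rec.attachment_atom in slot_of:
            shift = dz[slot_of[rec.attachment_atom]]
            for a in sorted(rec.atoms):
                out.coords[a, 2] += shift
    return out


# ---------------------------------------------------------------------------
# Calibration helper and distortion scans
# ---------------------------------------------------------------------------

def default_calibration(mechanism: str = "class_anchor") -> HOMAParams:
    """HOMA calibration on the packaged planar unsubstituted reference."""
    st, m = make_template("Zn")
    return calibrate(st, enumerate_circuits(m), mechanism=mechanism)


def _annotate(structure: MolecularStructure, m: MacrocycleMap,
              basis: NSDBasis, params: HOMAParams) -> dict[str, float]:
    """NSD + HOMA summary of one structure (canonical macrocycle order)."""
    coords24 = structure.coords[m.canonical_24()]
    metal_pos = structure.coords[m.metal_idx] if m.metal_idx is not None else None
    nsd = nsd_decompose(coords24, basis, metal_pos=metal_pos)
    circuits = enumerate_circuits(m)
    scores = {c.name: homa(c, structure, params) for c in circuits}
    pyr = [scores[c.name] for c in circuits if c.name.startswith("pyrrole")]
    out = {
        "total_oop": nsd.total_oop,
        "residual": nsd.residual,
        "homa_inner": scores["inner"].homa,
        "en_inner": scores["inner"].en,
        "geo_inner": scores["inner"].geo,
        "homa_pyrrole_mean": float(np.mean([r.homa for r in pyr])),
        "en_pyrrole_mean": float(np.mean([r.en for r in pyr])),
        "geo_pyrrole_mean": float(np.mean([r.geo for r in pyr])),
    }
    for mode in MODE_NAMES:
        out[mode] = nsd.amplitudes[mode]
        out[f"abs_{mode}"] = abs(nsd.amplitudes[mode])
    return out


def distortion_scan(mode: str, amplitudes: np.ndarray | None = None,
                    metal: str = "Zn", params: HOMAParams | None = None,
                    basis: NSDBasis | None = None) -> pd.DataFrame:
    """Impose a pure mode over an amplitude grid and score every circuit.

    Default grid: total out-of-plane 0 to 4 Å in 0.1 Å steps.  For a pure
    mode of the orthonormal basis the imposed amplitude equals the total
    out-of-plane value.
    """
    if mode not in MODE_NAMES:
        raise KeyError(f"unknown NSD mode {mode!r}")
    if amplitudes is None:
        amplitudes = np.round(np.arange(0.0, 4.0 + 1e-9, 0.1), 10)
    basis = basis or build_nsd_basis()
    params = params or default_calibration()
    st, m = make_template(metal)
    rows = []
    for a in np.asarray(amplitudes, dtype=float):
        displaced = impose_on_structure(st, m, basis, {mode: float(a)})
        row = {"amplitude": float(a)}
        row.update(_annotate(displaced, m, basis, params))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Planted-population generator
# ---------------------------------------------------------------------------

#: Planted standardized-scale coefficients (Å per SD of each cone-variant
#: feature).  Signs encode the qualitative law: bulk increases distortion,
#: larger metals / higher coordination / bigger axial ligands planarize;
#: ruffling leans on the metal and axial sphere, saddling on the macrocycle.
DEFAULT_BETA = {
    "abs_sad": {"metal_radius": -0.15, "coordination_number": -0.12,
                "mean_axial_cone": -0.12, "mean_meso_cone": 0.32,
                "mean_beta_cone": 0.28},
    "abs_ruf": {"metal_radius": -0.28, "coordination_number": -0.20,
                "mean_axial_cone": -0.24, "mean_meso_cone": 0.14,
                "mean_beta_cone": 0.12},
}
DEFAULT_INTERCEPT = {"abs_sad": 0.8, "abs_ruf": 0.7}

_METAL_WEIGHTS = {"Zn": 0.28, "Ni": 0.20, "Ru": 0.12, "Fe": 0.10,
                  "Pd": 0.10, "Mg": 0.08, "Sn": 0.07, "Pt": 0.05}
_CN_WEIGHTS = {4: 0.33, 5: 0.42, 6: 0.25}
_MESO_KINDS = {"phenyl": 0.40, "methyl": 0.14, "ethyl": 0.10, "Cl": 0.08,
               "F": 0.07, "Br": 0.06, "I": 0.05, "tbutyl": 0.10}
_BETA_KINDS = {"ethyl": 0.45, "methyl": 0.25, "Cl": 0.10, "Br": 0.08,
               "phenyl": 0.07, "F": 0.05}
_AXIAL_KINDS = {"pyridine": 0.30, "aqua": 0.22, "ammine": 0.18,
                "trimethylamine": 0.12, "trimethylphosphine": 0.10,
                "phosphine": 0.08}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted population."""

    n: int = 400
    seed: int = 0
    sigma: dict | None = None          # per-target noise SD (Å); None = auto
    r2_target: float = 0.7             # used when sigma is None
    beta: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in DEFAULT_BETA.items()})
    intercept: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPT))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma is not None and any(s < 0 for s in self.sigma.values()):
            raise ValueError("noise sigma must be non-negative")


@dataclass
class PopulationDataset:
    structures: list[MolecularStructure]
    maps: list[MacrocycleMap]
    X: dict[str, pd.DataFrame]            # variant -> feature matrix
    Y: pd.DataFrame                       # measured targets
    substituent_sets: list[frozenset[str]]
    beta_true: dict
    sigma: dict
    seed: int


def _is_clean(st: MolecularStructure, m: MacrocycleMap) -> bool:
    """Drawn structures must be curation-clean: monodentate substituents and
    three-connected macrocycle atoms (no steric fusion of neighbours)."""
    adj = st.adjacency()
    if any(len(adj[i]) != 3 for i in sorted(m.macrocycle_atoms())):
        return False
    return all(r.n_attachment_bonds == 1 for r in m.substituents)


def _weighted_choice(rng: np.random.Generator, table: dict):
    keys = list(table)
    w = np.array([table[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


def _draw_substitution(rng: np.random.Generator) -> tuple:
    """Substitution pattern mimicking the common synthetic families:
    meso-tetrasubstituted (most), beta-octasubstituted, fully substituted,
    then sparse random patterns."""
    u = rng.random()
    meso: dict[int, str] = {}
    beta: dict[int, str] = {}
    if u < 0.55:                                    # meso-tetra
        kind = _weighted_choice(rng, _MESO_KINDS)
        meso = {k: kind for k in range(4)}
    elif u < 0.70:                                  # beta-octa
        kind = _weighted_choice(rng, _BETA_KINDS)
        beta = {k: kind for k in range(8)}
    elif u < 0.80:                                  # fully substituted
        # the bulkiest meso groups cannot coexist with substituted betas
        slim = {k: w for k, w in _MESO_KINDS.items()
                if k not in ("tbutyl", "I")}
        mk = _weighted_choice(rng, slim)
        bk = _weighted_choice(rng, _BETA_KINDS)
        meso = {k: mk for k in range(4)}
        beta = {k: bk for k in range(8)}
    else:                                           # sparse random
        for k in range(4):
            if rng.random() < 0.4:
                meso[k] = _weighted_choice(rng, _MESO_KINDS)
        for k in range(8):
            if rng.random() < 0.2:
                beta[k] = _weighted_choice(rng, _BETA_KINDS)
    return beta, meso


def generate_population(spec: SyntheticSpec,
                        params: HOMAParams | None = None,
                        basis: NSDBasis | None = None) -> PopulationDataset:
    """Draw structures, plant the linear law, build geometries, re-measure.

    Saddling and ruffling amplitudes are set to X_std · beta + intercept +
    Gaussian noise (clipped at zero), imposed as pure modes, and then *all*
    targets — including total out-of-plane and the HOMA scores — are
    re-measured from the generated geometries, so the dataset is exactly
    what the measurement pipeline would produce on these structures.
    With ``sigma=None`` the noise SD is set per target so the linear signal
    explains about ``r2_target`` of the amplitude variance.
    """
    rng = np.random.default_rng(spec.seed)
    basis = basis or build_nsd_basis()
    params = params or default_calibration()
    cone_cache: dict = {}
    structures, maps, feats = [], [], {v: [] for v in FEATURE_NAMES}
    sub_sets = []
    for i in range(spec.n):
        metal = _weighted_choice(rng, _METAL_WEIGHTS)
        cn = _weighted_choice(rng, _CN_WEIGHTS)
        axial = tuple(_weighted_choice(rng, _AXIAL_KINDS)
                      for _ in range(cn - 4))
        for _attempt in range(25):
            beta, meso = _draw_substitution(rng)
            st, m = make_template(metal, beta=beta, meso=meso, axial=axial,
                                  source_id=f"synthetic_{spec.seed}_{i}")
            if _is_clean(st, m):
                break
        else:
            raise RuntimeError("could not draw a sterically clean "
                               "substitution pattern")
        structures.append(st)
        maps.append(m)
        vecs = {}
        for variant in FEATURE_NAMES:
            vecs[variant] = build_feature_vector(st, m, variant,
                                                 cone_cache=cone_cache)
            feats[variant].append(vecs[variant].features)
        sub_sets.append(vecs["cone_angles"].substituent_ids)
    X = {v: pd.DataFrame(feats[v], columns=list(FEATURE_NAMES[v]))
         for v in FEATURE_NAMES}
    Xc = X["cone_angles"].to_numpy(dtype=float)
    mean, std = Xc.mean(axis=0), Xc.std(axis=0)
    std = np.where(std < 1e-12, 1.0, std)
    Z = (Xc - mean) / std
    planted = {}
    sigma = dict(spec.sigma or {})
    noise_rng = np.random.default_rng(spec.seed + 1)
    for t in ("abs_sad", "abs_ruf"):
        b = np.array([spec.beta[t][f] for f in FEATURE_NAMES["cone_angles"]])
        pred = spec.intercept[t] + Z @ b
        if t not in sigma:
            r2 = spec.r2_target
            sigma[t] = float(pred.std() * np.sqrt((1 - r2) / r2))
        amp = pred + noise_rng.normal(0.0, sigma[t], size=spec.n)
        planted[t] = np.clip(amp, 0.0, None)
    rows = []
    for i, (st, m) in enumerate(zip(structures, maps)):
        displaced = impose_on_structure(
            st, m, basis,
            {"sad": planted["abs_sad"][i], "ruf": planted["abs_ruf"][i]})
        structures[i] = displaced
        rows.append(_annotate(displaced, m, basis, params))
    ann = pd.DataFrame(rows)
    Y = ann[["total_oop", "abs_sad", "abs_ruf", "homa_inner",
             "homa_pyrrole_mean"]].copy()
    return PopulationDataset(structures=structures, maps=maps, X=X, Y=Y,
                             substituent_sets=sub_sets,
                             beta_true={t: dict(spec.beta[t])
                                        for t in spec.beta},
                             sigma=sigma, seed=spec.seed)


# ---------------------------------------------------------------------------
# Curation-filter fixtures
# ---------------------------------------------------------------------------

def make_filter_fixtures() -> list[MolecularStructure]:
    """One all-pass structure plus, per filter, one structure violating
    exactly that filter.  Source ids name the designated violation."""
    fixtures: list[MolecularStructure] = []

    st, _ = make_template("Zn", source_id="pass")
    fixtures.append(st)

    st, _ = make_template(None, inner_h=True, source_id="fail_central_metal")
    fixtures.append(st)

    st, _ = make_template("Zn", source_id="fail_connected")
    ref = reference_macrocycle_coords()
    frag_c = ref[20] + np.array([0.0, 0.0, 2.2])     # above a meso carbon
    extra = [("C", frag_c),
             ("H", frag_c + np.array([0.89, 0.0, 0.63])),
             ("H", frag_c + np.array([-0.89, 0.0, 0.63]))]
    st = _append_atoms(st, extra)
    fixtures.append(st)

    a, _ = make_template("Zn")
    b, _ = make_template("Zn")
    b = b.copy()
    b.coords = b.coords + np.array([0.0, 0.0, 30.0])
    dimer = MolecularStructure(
        elements=a.elements + b.elements,
        coords=np.vstack([a.coords, b.coords]),
        source_id="fail_monomer",
    )
    fixtures.append(perceive_bonds(dimer))

    st, _ = make_template("Zn", source_id="fail_saturation")
    extra = [("H", ref[12] + np.array([0.0, 0.0, 1.05])),
             ("H", ref[13] + np.array([0.0, 0.0, 1.05]))]
    fixtures.append(_append_atoms(st, extra))

    st, _ = make_template("Zn", source_id="fail_monodentate")
    hydrazine = [("N", np.array([0.72, 0.0, 1.97])),
                 ("N", np.array([-0.72, 0.0, 1.97])),
                 ("H", np.array([1.27, 0.76, 2.32])),
                 ("H", np.array([1.27, -0.76, 2.32])),
                 ("H", np.array([-1.27, 0.76, 2.32])),
                 ("H", np.array([-1.27, -0.76, 2.32]))]
    fixtures.append(_append_atoms(st, hydrazine))

    st, _ = make_template("Cu", source_id="fail_even_electrons")
    fixtures.append(st)

    st, _ = make_template("Zn", source_id="fail_counter_ions")
    # triethylamine counter molecule: 22 atoms, even electrons, metal-free
    fixtures.append(_append_atoms(st, _triethylamine(np.array([14.0, 14.0, 6.0]))))
    return fixtures


def _append_atoms(st: MolecularStructure, extra: list[tuple]
                  ) -> MolecularStructure:
    pts = np.array([np.asarray(p, dtype=float) for _, p in extra])
    out = MolecularStructure(
        elements=st.elements + [el for el, _ in extra],
        coords=np.vstack([st.coords, pts]),
        source_id=st.source_id,
    )
    return perceive_bonds(out)


def _triethylamine(origin: np.ndarray) -> list[tuple]:
    """N(C2H5)3: 22 atoms, 58 electrons, metal-free."""
    atoms: list[tuple] = [("N", origin.copy())]
    back = np.array([0.0, 0.0, -1.0])
    arms = _tetrahedral_cap(origin, back, 1.47, "C")
    for _, c1 in arms:
        atoms.append(("C", c1))
        b = (origin - c1) / np.linalg.norm(origin - c1)
        caps = _tetrahedral_cap(c1, b, 1.53, "C", phases=(90.0,))
        c2 = caps[0][1]
        atoms.append(("C", c2))
        atoms += _tetrahedral_cap(c1, b, 1.09, "H", phases=(210.0, 330.0))
        b2 = (c1 - c2) / np.linalg.norm(c1 - c2)
        atoms += _tetrahedral_cap(c2, b2, 1.09, "H")
    return atoms
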