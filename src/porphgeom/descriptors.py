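"""Steric substituent descriptors and the five-feature representations.

Two interchangeable representations describe a curated metalloporphyrin by
its substituents only:

* cone-angle variant: metal radius, coordination number, mean axial-ligand
  cone angle, mean meso cone angle, mean beta cone angle;
* distance variant: metal radius, coordination number, mean axial cone
  angle, mean beta-beta and mean meso-beta inter-substituent distances
  measured on a fixed surrogate frame so no macrocycle information leaks
  into the representation.

The (maximal) cone angle of a substituent is the full apex angle of the
smallest cone, anchored at the attachment atom (ring atom for beta/meso
groups, the metal for axial ligands), that contains every substituent atom
with its radius.  Radii default to the covalent table: with the apex one
bond away, a van der Waals sphere of the directly bonded atom always engulfs
the apex and no finite enclosing cone exists, whereas covalent spheres keep
the descriptor defined for every substituent, hydrogen included.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .elements import covalent_radius, vdw_radius
from .io_curation import MolecularStructure
from .macrocycle import MacrocycleMap
from .reference import attachment_frame, reference_macrocycle_coords

logger = logging.getLogger(__name__)

__all__ = [
    "SubstituentGeometry", "DescriptorVector", "ConeAngleError",
    "cone_angle", "surrogate_distance", "metal_radius",
    "build_feature_vector", "FEATURE_NAMES", "TARGET_NAMES",
]

FEATURE_NAMES = {
    "cone_angles": ("metal_radius", "coordination_number", "mean_axial_cone",
                    "mean_meso_cone", "mean_beta_cone"),
    "distances": ("metal_radius", "coordination_number", "mean_axial_cone",
                  "mean_beta_beta_dist", "mean_meso_beta_dist"),
}
TARGET_NAMES = ("total_oop", "abs_sad", "abs_ruf", "homa_inner",
                "homa_pyrrole_mean")
#: Sentinel for the axial cone angle of four-coordinate structures.
NO_AXIAL_SENTINEL = -1.0


class ConeAngleError(ValueError):
    """An atom's sphere engulfs the apex: no finite enclosing cone exists."""


@dataclass
class SubstituentGeometry:
    """Apex plus substituent atom positions and radii (Å)."""

    apex: np.ndarray
    positions: np.ndarray
    radii: np.ndarray
    position_class: str = ""

    def __post_init__(self) -> None:
        self.apex = np.asarray(self.apex, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        if len(self.positions) == 0:
            raise ValueError("substituent has no atoms")
        if np.any(np.linalg.norm(self.positions - self.apex, axis=1) < 1e-8):
            raise ValueError("substituent atom coincides with the apex")


def _cone_halfangle_field(sub: SubstituentGeometry, use_radii: bool
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Unit direction and angular padding per atom; raises if ill-posed."""
    v = sub.positions - sub.apex
    d = np.linalg.norm(v, axis=1)
    r = sub.radii if use_radii else np.zeros_like(d)
    if np.any(r >= d):
        raise ConeAngleError(
            "atom sphere contains the apex (r >= distance); no finite cone")
    return v / d[:, None], np.arcsin(r / d)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def cone_angle(sub: SubstituentGeometry, use_radii: bool = True,
               method: str = "optimize", grid_points: int = 8192) -> float:
    """Full apex angle (degrees) of the minimal enclosing cone.

    The half angle is min over unit axes u of max_i [angle(u, v_i) +
    arcsin(r_i / |v_i|)].  ``method='optimize'`` refines the best directions
    of a deterministic Fibonacci grid with Nelder-Mead; ``method='grid'``
    is the brute-force oracle (dense grid only).
    """
    units, pad = _cone_halfangle_field(sub, use_radii)

    def objective(u: np.ndarray) -> float:
        u = u / np.linalg.norm(u)
        ang = np.arccos(np.clip(units @ u, -1.0, 1.0))
        return float(np.max(ang + pad))

    axes = np.vstack([_fibonacci_sphere(grid_points if method == "grid" else 512),
                      units, [units.mean(axis=0) / max(np.linalg.norm(units.mean(axis=0)), 1e-12)]])
    vals = np.arccos(np.clip(axes @ units.T, -1.0, 1.0)) + pad[None, :]
    best = vals.max(axis=1)
    if method == "grid":
        half = float(best.min())
    else:
        order = np.argsort(best)[:4]
        half = float(best.min())
        for k in order:
            res = minimize(objective, axes[k], method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12,
                                    "maxiter": 500})
            half = min(half, float(res.fun))
    return float(np.degrees(2.0 * half))


# ---------------------------------------------------------------------------
# Surrogate-frame distances
# ---------------------------------------------------------------------------

def _surrogate_frames() -> dict[str, tuple]:
    """Fixed attachment frames presenting two neighbouring sites.

    The frame reuses the idealized macrocycle's attachment geometry for a
    beta-beta pair (the two betas of one pyrrole) and a meso-beta pair (a
    meso bridge and its nearest beta), but nothing else about the macrocycle
    enters the descriptor: substituents are rigidly transplanted onto these
    fixed sites in their own conformation.
    """
    ref = reference_macrocycle_coords()
    b_in, b_out, meso = 12, 13, 20
    return {
        "beta_beta": (attachment_frame(ref, b_in), attachment_frame(ref, b_out)),
        "meso_beta": (attachment_frame(ref, meso), attachment_frame(ref, b_out)),
    }


_FRAMES = _surrogate_frames()


def _min_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180° about any perpendicular axis
        p = np.array([1.0, 0.0, 0.0])
        if abs(a @ p) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, p)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _transplant(sub: SubstituentGeometry, site: tuple[np.ndarray, np.ndarray]
                ) -> np.ndarray:
    """Rigidly move a substituent onto a surrogate site.

    The apex goes to the site position and the apex->nearest-atom bond
    direction onto the site's ideal bond vector; the substituent keeps its
    own conformation (minimal rotation, no re-minimization).
    """
    pos, direction = site
    rel = sub.positions - sub.apex
    d = np.linalg.norm(rel, axis=1)
    bond_dir = rel[np.argmin(d)] / d.min()
    rot = _min_rotation(bond_dir, direction / np.linalg.norm(direction))
    return (rot @ rel.T).T + pos


def surrogate_distance(sub_a: SubstituentGeometry, sub_b: SubstituentGeometry,
                       pair_class: str) -> float:
    """Minimal interatomic distance between two substituents transplanted
    onto the fixed surrogate frame of the given pair class
    (``'beta_beta'`` or ``'meso_beta'``).  Symmetric in its arguments."""
    if pair_class not in _FRAMES:
        raise KeyError(f"unknown surrogate pair class {pair_class!r}")
    site_a, site_b = _FRAMES[pair_class]
    # the two sites of a mixed frame are inequivalent; evaluating both
    # assignments keeps the descriptor orderless
    d1 = cdist(_transplant(sub_a, site_a), _transplant(sub_b, site_b)).min()
    d2 = cdist(_transplant(sub_b, site_a), _transplant(sub_a, site_b)).min()
    return float(min(d1, d2))


def metal_radius(element: str, table: str = "covalent") -> float:
    """Radius of the central atom from the configured table (Å)."""
    if table == "covalent":
        return covalent_radius(element)
    if table == "vdw":
        return vdw_radius(element)
    raise KeyError(f"unknown radius table {table!r}")


# ---------------------------------------------------------------------------
# Feature vectors
# ---------------------------------------------------------------------------

@dataclass
class DescriptorVector:
    """Five steric features plus the geometric target properties."""

    variant: str
    features: dict[str, float]
    targets: dict[str, float] = field(default_factory=dict)
    structure_id: str = ""
    substituent_ids: frozenset[str] = frozenset()

    def values(self) -> np.ndarray:
        return np.array([self.features[n] for n in FEATURE_NAMES[self.variant]])


def _substituent_geometry(structure: MolecularStructure, apex_idx: int,
                          atoms: frozenset[int], position_class: str,
                          radius_table: str = "covalent") -> SubstituentGeometry:
    idx = sorted(atoms)
    get_r = covalent_radius if radius_table == "covalent" else vdw_radius
    return SubstituentGeometry(
        apex=structure.coords[apex_idx],
        positions=structure.coords[idx],
        radii=np.array([get_r(structure.elements[i]) for i in idx]),
        position_class=position_class,
    )


def build_feature_vector(structure: MolecularStructure, m: MacrocycleMap,
                         variant: str, targets: dict[str, float] | None = None,
                         radius_table: str = "covalent",
                         cone_cache: dict | None = None) -> DescriptorVector:
    """Assemble the five-feature representation of a curated structure.

    Coordination number is 4 (pyrrole N) plus the number of axial ligands;
    four-coordinate structures carry the -1 sentinel as their axial cone.
    Means run over all positions of a class, hydrogen substituents included.
    The distance variant averages surrogate-frame distances over the four
    same-pyrrole beta-beta pairs and the eight meso-beta neighbour pairs of
    the canonical layout.
    """
    from .macrocycle import substituent_identity

    if variant not in FEATURE_NAMES:
        raise KeyError(f"unknown descriptor variant {variant!r}")
    if m.metal_idx is None:
        raise ValueError("feature vector requires a metalated macrocycle")
    recs = {r.attachment_atom: r for r in m.substituents
            if r.position_class in ("beta", "meso")}
    axial_recs = [r for r in m.substituents if r.position_class == "axial"]

    def cone_of(rec, apex_idx) -> float:
        key = None
        if cone_cache is not None:
            key = (substituent_identity(structure, rec.atoms),
                   rec.position_class, radius_table)
            if key in cone_cache:
                return cone_cache[key]
        sub = _substituent_geometry(structure, apex_idx, rec.atoms,
                                    rec.position_class, radius_table)
        val = cone_angle(sub)
        if cone_cache is not None:
            cone_cache[key] = val
        return val

    cn = 4 + len(axial_recs)
    feats: dict[str, float] = {
        "metal_radius": metal_radius(structure.elements[m.metal_idx]),
        "coordination_number": float(cn),
    }
    if axial_recs:
        feats["mean_axial_cone"] = float(np.mean(
            [cone_of(r, m.metal_idx) for r in axial_recs]))
    else:
        feats["mean_axial_cone"] = NO_AXIAL_SENTINEL

    if variant == "cone_angles":
        for cls, sites in (("meso", m.c_meso_idx), ("beta", m.c_beta_idx)):
            vals = [cone_of(recs[i], i) for i in sites if i in recs]
            if not vals:
                raise ValueError(f"no {cls} substituents found")
            feats[f"mean_{cls}_cone"] = float(np.mean(vals))
    else:
        geoms = {i: _substituent_geometry(structure, i, recs[i].atoms,
                                          recs[i].position_class, radius_table)
                 for i in recs}
        bb = []
        for k in range(4):
            i, j = m.c_beta_idx[2 * k], m.c_beta_idx[2 * k + 1]
            if i in geoms and j in geoms:
                bb.append(surrogate_distance(geoms[i], geoms[j], "beta_beta"))
        mb = []
        for k in range(4):
            meso = m.c_meso_idx[k]
            flank = (m.c_beta_idx[2 * k + 1], m.c_beta_idx[(2 * k + 2) % 8])
            for b in flank:
                if meso in geoms and b in geoms:
                    mb.append(surrogate_distance(geoms[meso], geoms[b],
                                                 "meso_beta"))
        if not bb or not mb:
            raise ValueError("missing substituents for distance descriptors")
        feats["mean_beta_beta_dist"] = float(np.mean(bb))
        feats["mean_meso_beta_dist"] = float(np.mean(mb))

    ids = frozenset(substituent_identity(structure, r.atoms)
                    for r in m.substituents
                    if r.position_class in ("beta", "meso", "axial"))
    return DescriptorVector(variant=variant, features=feats,
                            targets=dict(targets or {}),
                            structure_id=structure.source_id,
                            substituent_ids=ids)
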