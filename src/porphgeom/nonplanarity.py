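"""Normal-coordinate structural decomposition (NSD) of macrocycle nonplanarity.

Out-of-plane displacements of the 24 macrocycle atoms are projected onto six
orthonormal symmetry-adapted modes of the D4h reference: saddling (B2u),
ruffling (B1u), doming (A2u), waving x/y (Eg) and propellering (A1u).  The
basis vectors are built from geometric seed patterns on the reference —
alternating pyrrole tilts (saddle), alternating pyrrole twists about the M-N
axes with smooth meso continuation (ruffle), a pyramidalizing orbit pattern
(dome), a differential tilt (wave) and a same-sense twist (propeller) — then
purged of rigid-body content (net translation and tilts) and Gram-Schmidt
orthonormalized.  Amplitudes are signed; their squares plus the residual
square partition the squared out-of-plane norm exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .reference import reference_macrocycle_coords, slot_pyrrole, slot_roles

logger = logging.getLogger(__name__)

__all__ = [
    "MODE_NAMES", "NSDBasis", "NSDResult", "build_nsd_basis",
    "fit_reference_plane", "nsd_decompose", "impose_distortion",
    "mean_per_atom_deviation",
]

MODE_NAMES = ("sad", "ruf", "dom", "wav_x", "wav_y", "pro")
_MODE_SYMMETRY = {"sad": "B2u", "ruf": "B1u", "dom": "A2u",
                  "wav_x": "Eg", "wav_y": "Eg", "pro": "A1u"}


@dataclass(frozen=True)
class NSDBasis:
    """Reference coordinates and six orthonormal out-of-plane mode vectors."""

    reference: np.ndarray       # (24, 3), planar, canonical slot order
    vectors: np.ndarray         # (6, 24), rows ordered as MODE_NAMES

    def vector(self, name: str) -> np.ndarray:
        return self.vectors[MODE_NAMES.index(name)]


def _rigid_space(xy: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3, 24) of rigid out-of-plane content: net
    translation along the normal and the two tilts (z linear in x, y)."""
    ones = np.ones(len(xy))
    raw = np.stack([ones, xy[:, 0], xy[:, 1]])
    q, _ = np.linalg.qr(raw.T)
    return q.T


def _project_out(v: np.ndarray, space: np.ndarray) -> np.ndarray:
    return v - space.T @ (space @ v)


def build_nsd_basis() -> NSDBasis:
    ref = reference_macrocycle_coords()
    xy = ref[:, :2]
    roles = slot_roles()
    pyr = slot_pyrrole()
    n = 24
    # radial/tangential unit vectors of each pyrrole axis
    axes = [np.array([np.cos(a), np.sin(a)]) for a in
            (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)]
    perps = [np.array([-u[1], u[0]]) for u in axes]

    sad = np.zeros(n)
    ruf = np.zeros(n)
    pro = np.zeros(n)
    for i in range(n):
        k = pyr[i]
        if k is None:
            continue
        s = 1.0 if k % 2 == 0 else -1.0
        radial = xy[i] @ axes[k]
        tang = xy[i] @ perps[k]
        sad[i] = s * (radial - abs(xy[0] @ axes[0]))  # zero at the nitrogens
        ruf[i] = s * tang
        pro[i] = tang
    # meso continuation of the ruffle twist: smooth sin(2*phi) extrapolation
    # scaled to match the alpha-carbon twist amplitude
    phi_a = np.arctan2(abs(xy[5][1]), xy[5][0])
    w_meso = abs(xy[5] @ perps[0]) / np.sin(2 * phi_a)
    for k in range(4):
        ruf[20 + k] = w_meso * (1.0 if k % 2 == 0 else -1.0)

    dome_w = {"N": 1.0, "CA": 0.4, "CB": 0.1, "CM": 0.25}
    dom = np.array([dome_w[r] for r in roles])
    wav_w = {"N": 0.4, "CA": 0.7, "CB": 1.0, "CM": 0.8}
    wav_x = np.array([wav_w[r] for r in roles]) * xy[:, 0]
    wav_y = np.array([wav_w[r] for r in roles]) * xy[:, 1]

    rigid = _rigid_space(xy)
    seeds = [sad, ruf, dom, wav_x, wav_y, pro]
    vectors = []
    for v in seeds:
        u = _project_out(v, rigid)
        for w in vectors:
            u = u - (w @ u) * w
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            raise RuntimeError("degenerate NSD seed")
        vectors.append(u / norm)
    return NSDBasis(reference=ref, vectors=np.array(vectors))


@dataclass
class NSDResult:
    """Signed mode amplitudes (Å), total out-of-plane norm and residual."""

    amplitudes: dict[str, float]
    total_oop: float
    residual: float

    def abs_amplitudes(self) -> dict[str, float]:
        return {k: abs(v) for k, v in self.amplitudes.items()}

    def as_array(self) -> np.ndarray:
        return np.array([self.amplitudes[m] for m in MODE_NAMES])


class PlaneFitError(ValueError):
    """Plane fit is degenerate (collinear or coincident points)."""


def fit_reference_plane(coords: np.ndarray, mode: str = "N4",
                        n_indices: tuple[int, ...] = (0, 1, 2, 3),
                        metal_pos: np.ndarray | None = None
                        ) -> tuple[np.ndarray, float]:
    """Least-squares plane (unit normal, offset) with normal·x = offset.

    ``mode='N4'`` fits the four pyrrole nitrogens (the conventional
    porphyrin reference plane); ``mode='mean24'`` fits all given atoms.  The
    normal points toward the metal's hemisphere when a metal position is
    given and off-plane, otherwise toward the +z majority of the input frame.
    """
    pts = coords[list(n_indices)] if mode == "N4" else coords
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8:
        raise PlaneFitError("degenerate plane fit: points are collinear")
    normal = vt[2]
    if metal_pos is not None and abs((metal_pos - centroid) @ normal) > 1e-6:
        if (metal_pos - centroid) @ normal < 0:
            normal = -normal
    elif normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or
                                               (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return normal, float(normal @ centroid)


def _inplane_frame(coords24: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """In-plane coordinates (24, 2) of the atoms in the fitted plane."""
    centroid = coords24.mean(axis=0)
    # deterministic in-plane axes
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ normal) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - (seed @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = coords24 - centroid
    return np.stack([rel @ e1, rel @ e2], axis=1)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||P @ R.T - Q|| for centered point sets."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def nsd_decompose(coords24: np.ndarray, basis: NSDBasis,
                  plane_mode: str = "N4",
                  metal_pos: np.ndarray | None = None) -> NSDResult:
    """Project the out-of-plane displacements onto the six modes.

    ``coords24`` must be in canonical slot order.  The structure is rigidly
    superposed onto the planar reference (centroid shift + Kabsch rotation
    under the slot correspondence); its z coordinates in the reference frame
    are then the out-of-plane displacement vector, purged of any remaining
    rigid content (net offset and tilts).  Because the mode vectors are
    orthonormal and rigid-free, imposing pure modes and decomposing
    round-trips exactly, at any amplitude, and the result is invariant under
    rigid motion of the input.  When a metal position is supplied the
    reference normal is oriented toward the metal's axial hemisphere
    (amplitude signs flip with the side the metal sits on).
    """
    coords24 = np.asarray(coords24, dtype=float)
    if coords24.shape != (24, 3):
        raise ValueError("nsd_decompose expects 24 macrocycle atoms in "
                         "canonical order")
    centroid = coords24.mean(axis=0)
    P = coords24 - centroid
    R = _kabsch(P, basis.reference)
    aligned = P @ R.T
    z = aligned[:, 2]
    z = _project_out(z, _rigid_space(aligned[:, :2]))
    if metal_pos is not None:
        metal_z = float(((np.asarray(metal_pos, dtype=float) - centroid)
                         @ R.T)[2])
        if metal_z < -1e-6:
            z = -z
    amps = basis.vectors @ z
    recon = basis.vectors.T @ amps
    return NSDResult(
        amplitudes={m: float(a) for m, a in zip(MODE_NAMES, amps)},
        total_oop=float(np.linalg.norm(z)),
        residual=float(np.linalg.norm(z - recon)),
    )


def impose_distortion(basis: NSDBasis,
                      amplitudes: dict[str, float] | np.ndarray) -> np.ndarray:
    """Reference coordinates displaced along the plane normal by pure modes.

    Round-trips through :func:`nsd_decompose` to numerical precision because
    the modes are orthonormal and rigid-free.
    """
    if isinstance(amplitudes, dict):
        unknown = set(amplitudes) - set(MODE_NAMES)
        if unknown:
            raise KeyError(f"unknown NSD mode(s): {sorted(unknown)}")
        a = np.array([amplitudes.get(m, 0.0) for m in MODE_NAMES])
    else:
        a = np.asarray(amplitudes, dtype=float)
    z = basis.vectors.T @ a
    out = basis.reference.copy()
    out[:, 2] += z
    return out


def mean_per_atom_deviation(result: "NSDResult | float") -> float:
    """Total out-of-plane converted to mean per-atom deviation (total / 24)."""
    total = result.total_oop if isinstance(result, NSDResult) else float(result)
    return total / 24.0
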