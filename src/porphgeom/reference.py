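"""Idealized planar D4h metalloporphine reference geometry.

The reference macrocycle is the solution of the planar closure problem for
standard aromatic bond lengths (M-N 2.01, N-Ca 1.38, Ca-Cb 1.44, Cb-Cb 1.35,
Ca-Cm 1.395 Å and a 125° Ca-Cm-Ca meso angle) under exact D4h symmetry.  The
quarter-unit coordinates below were solved once to machine precision and are
frozen; everything else (full 24-atom layout, hydrogen positions, substituent
attachment frames) is generated from them.

Slot layout follows :meth:`MacrocycleMap.canonical_24`:
indices 0-3 N, 4-11 C-alpha (in/out per pyrrole), 12-19 C-beta, 20-23 C-meso.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "REF_MN", "REF_QUARTER", "reference_macrocycle_coords",
    "slot_roles", "slot_pyrrole", "hydrogen_directions", "attachment_frame",
]

#: Frozen quarter-unit constants (Å): alpha carbon (AX, ±AY),
#: beta carbon (BX, ±BY), meso carbon (MX, MX), nitrogen (RN, 0).
REF_MN = 2.01
_AX = 2.847063567057
_AY = 1.097143830455
_BX = 4.223796869628
_BY = 0.675
_MX = 2.427578976749
REF_QUARTER = {"N": (REF_MN, 0.0), "CA": (_AX, _AY), "CB": (_BX, _BY),
               "CM": (_MX, _MX)}

_ROT = [np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        for a in (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)]


def reference_macrocycle_coords() -> np.ndarray:
    """(24, 3) planar reference coordinates in canonical slot order (z = 0).

    Pyrrole k points along the +x axis rotated by 90k degrees; traversal is
    counterclockwise, so the 'out' alpha/beta of pyrrole k sit on the +y side
    of its axis and meso k lies on the diagonal between pyrroles k and k+1.
    """
    pts = np.zeros((24, 3))
    for k in range(4):
        R = _ROT[k]
        pts[k, :2] = R @ np.array([REF_MN, 0.0])
        pts[4 + 2 * k, :2] = R @ np.array([_AX, -_AY])      # alpha in
        pts[4 + 2 * k + 1, :2] = R @ np.array([_AX, _AY])   # alpha out
        pts[12 + 2 * k, :2] = R @ np.array([_BX, -_BY])     # beta in
        pts[12 + 2 * k + 1, :2] = R @ np.array([_BX, _BY])  # beta out
        pts[20 + k, :2] = R @ np.array([_MX, _MX])
    return pts


def slot_roles() -> list[str]:
    return ["N"] * 4 + ["CA"] * 8 + ["CB"] * 8 + ["CM"] * 4


def slot_pyrrole() -> list[int | None]:
    """Pyrrole membership per slot (None for meso bridges)."""
    out: list[int | None] = [0, 1, 2, 3]
    out += [k for k in range(4) for _ in (0, 1)]   # alphas
    out += [k for k in range(4) for _ in (0, 1)]   # betas
    out += [None] * 4
    return out


def hydrogen_directions(coords24: np.ndarray) -> dict[int, np.ndarray]:
    """Outward in-plane unit vectors for the 12 substitutable ring slots.

    For a beta carbon the direction points away from the midpoint of its two
    ring neighbours (the bonded alpha and beta); for a meso carbon it is
    radial.  Used both for hydrogen placement and as substituent bond axes.
    """
    dirs: dict[int, np.ndarray] = {}
    for k in range(4):
        b_in, b_out = 12 + 2 * k, 12 + 2 * k + 1
        a_in, a_out = 4 + 2 * k, 4 + 2 * k + 1
        for b, a, other in ((b_in, a_in, b_out), (b_out, a_out, b_in)):
            mid = 0.5 * (coords24[a] + coords24[other])
            d = coords24[b] - mid
            dirs[b] = d / np.linalg.norm(d)
        m = 20 + k
        d = coords24[m].copy()
        dirs[m] = d / np.linalg.norm(d)
    return dirs


def attachment_frame(coords24: np.ndarray, slot: int) -> tuple[np.ndarray, np.ndarray]:
    """(site position, outward bond direction) for a substitutable ring slot."""
    dirs = hydrogen_directions(coords24)
    return coords24[slot], dirs[slot]
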