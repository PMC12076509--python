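"""Structural aromaticity: HOMA scores with EN/GEO decomposition.

HOMA (harmonic oscillator model of aromaticity) measures how far a bonded
circuit deviates from a single ideal aromatic bond length: HOMA = 1 - EN -
GEO, where EN = alpha*(R_opt - R_mean)^2 penalizes mean elongation or
compression and GEO = (alpha/n)*sum (R_mean - R_i)^2 penalizes bond-length
alternation.  Heteroatom (C-N) bonds are handled either by per-class ideal
lengths or by the Pauling bond-number mapping onto the CC scale.

Calibration pins the score of the packaged planar unsubstituted
metalloporphine at exactly 1 for the inner 16-membered circuit.  Because the
pyrrole circuits of the planar reference mix three different bond lengths,
no choice of alpha or R_opt can make them score 1 as well; they score < 1,
dominated by GEO, consistent with pyrroles being the less aromatic
subsystems of metalated porphyrins.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_curation import MolecularStructure
from .macrocycle import Circuit

logger = logging.getLogger(__name__)

__all__ = [
    "HOMAParams", "HOMAResult", "homa", "calibrate",
    "ALPHA_CC", "R_OPT_CC",
]

#: Literature HOMA constants for CC bonds (Å^-2, Å).
ALPHA_CC = 257.7
R_OPT_CC = 1.388
#: Pauling single/double bond lengths used for the C-N -> CC conversion (Å).
_R1_CC, _R2_CC = 1.467, 1.349
_R1_CN, _R2_CN = 1.465, 1.269
_C_CC = (_R1_CC - _R2_CC) / math.log(2.0)
_C_CN = (_R1_CN - _R2_CN) / math.log(2.0)


class CircuitTopologyError(ValueError):
    """A circuit bond is missing from the structure's bond set."""


class EmptyCircuitError(ValueError):
    """A circuit with no bonds cannot be scored."""


@dataclass(frozen=True)
class HOMAParams:
    """Calibration of the HOMA score.

    ``mechanism='class_anchor'`` (default): per circuit type and bond class,
    R_opt is the reference circuit's mean bond length of that class, so all
    deviations vanish on the planar reference and the reference scores
    exactly 1 with the literature alpha.

    ``mechanism='baseline_shift'``: literature R_opt(CC) with the Pauling
    C-N conversion; the reference circuit's raw EN and GEO are subtracted as
    a baseline so the reference again scores exactly 1 while preserving the
    identity HOMA = 1 - EN - GEO.
    """

    mechanism: str = "class_anchor"
    alpha: float = ALPHA_CC
    r_opt: dict = field(default_factory=dict)       # (circuit_type, class) -> Å
    baseline: dict = field(default_factory=dict)    # circuit_type -> (EN0, GEO0)
    reference_id: str = "idealized planar metalloporphine"

    def circuit_type(self, name: str) -> str:
        if name == "inner":
            return "inner"
        if name.startswith("pyrrole"):
            return "pyrrole"
        raise KeyError(f"no calibration for circuit {name!r}")


@dataclass
class HOMAResult:
    circuit: str
    homa: float
    en: float
    geo: float
    n_bonds: int
    r_mean: float  # mean raw bond length, Å


def _bond_class(el_i: str, el_j: str) -> str:
    pair = frozenset((el_i, el_j))
    if pair == frozenset(("C",)):
        return "CC"
    if pair == frozenset(("C", "N")):
        return "CN"
    raise CircuitTopologyError(f"unsupported circuit bond {el_i}-{el_j}")


def _pauling_to_cc(length: float) -> float:
    """Map a C-N bond length onto the CC scale via Pauling bond numbers."""
    n = math.exp((_R1_CN - length) / _C_CN)
    return _R1_CC - _C_CC * math.log(n)


def _circuit_lengths(circuit: Circuit, structure: MolecularStructure
                     ) -> tuple[np.ndarray, list[str]]:
    lengths, classes = [], []
    if not circuit.atoms:
        raise EmptyCircuitError(f"circuit {circuit.name!r} has no bonds")
    for (i, j) in circuit.bonds:
        if (min(i, j), max(i, j)) not in structure.bonds:
            raise CircuitTopologyError(
                f"circuit {circuit.name!r} bond ({i},{j}) is not a bond of "
                "the structure")
        lengths.append(float(np.linalg.norm(structure.coords[i] -
                                            structure.coords[j])))
        classes.append(_bond_class(structure.elements[i], structure.elements[j]))
    return np.array(lengths), classes


def homa(circuit: Circuit, structure: MolecularStructure,
         params: HOMAParams) -> HOMAResult:
    """HOMA, EN and GEO of one circuit under the given calibration."""
    lengths, classes = _circuit_lengths(circuit, structure)
    ctype = params.circuit_type(circuit.name)
    if params.mechanism == "class_anchor":
        r_opt = np.array([params.r_opt[(ctype, c)] for c in classes])
        dev = lengths - r_opt
        en = params.alpha * float(dev.mean()) ** 2
        geo = params.alpha / len(dev) * float(((dev - dev.mean()) ** 2).sum())
    elif params.mechanism == "baseline_shift":
        conv = np.array([
            length if cls == "CC" else _pauling_to_cc(length)
            for length, cls in zip(lengths, classes)
        ])
        en = params.alpha * float(R_OPT_CC - conv.mean()) ** 2
        geo = params.alpha / len(conv) * float(((conv.mean() - conv) ** 2).sum())
        en0, geo0 = params.baseline.get(ctype, (0.0, 0.0))
        en, geo = en - en0, geo - geo0
    else:
        raise ValueError(f"unknown calibration mechanism {params.mechanism!r}")
    score = 1.0 - en - geo
    if not (0.0 <= score <= 1.0):
        logger.warning("HOMA %.4f outside [0, 1] for circuit %s",
                       score, circuit.name)
    return HOMAResult(circuit=circuit.name, homa=score, en=en, geo=geo,
                      n_bonds=len(lengths), r_mean=float(lengths.mean()))


def calibrate(reference: MolecularStructure, circuits: list[Circuit],
              mechanism: str = "class_anchor",
              alpha: float = ALPHA_CC) -> HOMAParams:
    """Build calibration parameters from the planar reference circuits.

    Pyrrole statistics are pooled over the four rings.  Calibrating twice on
    the same reference yields identical parameters.
    """
    probe = HOMAParams(mechanism="class_anchor", alpha=alpha)
    by_type: dict[str, list[tuple[np.ndarray, list[str]]]] = {}
    for c in circuits:
        lengths, classes = _circuit_lengths(c, reference)
        if np.any(lengths < 1e-6):
            raise ValueError("degenerate reference: zero-length bond")
        by_type.setdefault(probe.circuit_type(c.name), []).append((lengths, classes))
    r_opt: dict[tuple[str, str], float] = {}
    baseline: dict[str, tuple[float, float]] = {}
    for ctype, items in by_type.items():
        all_len = np.concatenate([ln for ln, _ in items])
        all_cls = [c for _, cls in items for c in cls]
        for cls in sorted(set(all_cls)):
            sel = np.array([c == cls for c in all_cls])
            r_opt[(ctype, cls)] = float(all_len[sel].mean())
        conv = np.array([
            ln if c == "CC" else _pauling_to_cc(ln)
            for ln, c in zip(all_len, all_cls)
        ])
        en0 = alpha * float(R_OPT_CC - conv.mean()) ** 2
        geo0 = alpha / len(conv) * float(((conv.mean() - conv) ** 2).sum())
        baseline[ctype] = (en0, geo0)
    return HOMAParams(mechanism=mechanism, alpha=alpha, r_opt=r_opt,
                      baseline=baseline)
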