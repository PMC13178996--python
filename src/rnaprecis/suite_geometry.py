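"""Backbone dihedrals, ribose pucker and the pucker-pair gate.

An RNA *suite* is the sugar-to-sugar backbone unit spanning two adjacent
residues.  At high detail its shape is described by 7 backbone dihedral
angles (delta of the first sugar, then epsilon, zeta, alpha, beta, gamma
along the linkage, then delta of the second sugar), a point on the
7-torus.  At low detail only the phosphate and the two glycosidic bonds
are trusted, and the pucker state of each ribose is inferred from the
*Pperp* criterion: the perpendicular distance from the next-in-sequence
phosphorus to the extended glycosidic bond line is >= 2.9 A for
C3'-endo and < 2.9 A for C2'-endo sugars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structure_io import ResidueRecord, SuiteAtoms

__all__ = [
    "GeometryError",
    "PPERP_CUTOFF",
    "DIHEDRAL_NAMES",
    "TorusPoint",
    "Pucker",
    "dihedral",
    "wrap_degrees",
    "suite_dihedrals",
    "pucker_from_nu",
    "pperp",
    "pucker_from_pperp",
    "suite_pperps",
    "pucker_pair",
]

#: Pperp decision boundary in Angstrom; the C3'-endo side is closed
#: (d == cutoff classifies as C3'-endo).
PPERP_CUTOFF = 2.9

#: Names of the 7 suite dihedrals in their conventional order.
DIHEDRAL_NAMES = ("delta_prev", "epsilon", "zeta", "alpha", "beta", "gamma", "delta")


class GeometryError(ValueError):
    """Degenerate geometry (collinear atoms, zero-length bonds, ...)."""


def wrap_degrees(angles) -> np.ndarray:
    """Wrap angles (degrees) into [0, 360)."""
    return np.asarray(angles, dtype=float) % 360.0


#: A point on the 7-torus: array of 7 dihedrals in degrees, wrapped to
#: [0, 360), ordered as in :data:`DIHEDRAL_NAMES`.
TorusPoint = np.ndarray


def _as_vec(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


def dihedral(a, b, c, d) -> float:
    """Torsion angle of the four points ``a-b-c-d`` in degrees, in [0, 360).

    The angle measures the rotation of the plane (b, c, d) relative to the
    plane (a, b, c) about the b-c axis; 0 is cis (eclipsed), 180 is trans.
    Invariant under rigid motion, negated (mod 360) by reflection.
    """
    a, b, c, d = _as_vec(a), _as_vec(b), _as_vec(c), _as_vec(d)
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12:
        raise GeometryError("central bond has zero length")
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear atom triple: dihedral undefined")
    m1 = np.cross(n1, b2 / nb2)
    x = float(n1 @ n2)
    y = -float(m1 @ n2)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


# Atom quadruples defining the 7 suite torsions; 'p' = first (5') residue,
# 'c' = second (3') residue of the suite.
_TORSION_ATOMS = {
    "delta_prev": (("p", "C5'"), ("p", "C4'"), ("p", "C3'"), ("p", "O3'")),
    "epsilon": (("p", "C4'"), ("p", "C3'"), ("p", "O3'"), ("c", "P")),
    "zeta": (("p", "C3'"), ("p", "O3'"), ("c", "P"), ("c", "O5'")),
    "alpha": (("p", "O3'"), ("c", "P"), ("c", "O5'"), ("c", "C5'")),
    "beta": (("c", "P"), ("c", "O5'"), ("c", "C5'"), ("c", "C4'")),
    "gamma": (("c", "O5'"), ("c", "C5'"), ("c", "C4'"), ("c", "C3'")),
    "delta": (("c", "C5'"), ("c", "C4'"), ("c", "C3'"), ("c", "O3'")),
}


def suite_dihedrals(suite: "SuiteAtoms") -> TorusPoint:
    """The 7 backbone dihedrals of a suite, degrees in [0, 360).

    Raises :class:`GeometryError` naming the incomputable torsions if any
    required atom is missing.
    """
    residues = {"p": suite.res_prev, "c": suite.res_curr}
    missing = []
    for name, quad in _TORSION_ATOMS.items():
        for which, atom in quad:
            if atom not in residues[which].atoms:
                missing.append((name, atom))
    if missing:
        torsions = sorted({name for name, _ in missing})
        atoms = sorted({atom for _, atom in missing})
        raise GeometryError(
            f"cannot compute torsion(s) {', '.join(torsions)}: "
            f"missing atom(s) {', '.join(atoms)}"
        )
    out = np.empty(7)
    for i, name in enumerate(DIHEDRAL_NAMES):
        quad = _TORSION_ATOMS[name]
        pts = [residues[w].atoms[atom].position for w, atom in quad]
        out[i] = dihedral(*pts)
    return out


@dataclass(frozen=True)
class Pucker:
    """Ribose pucker state with its provenance.

    state
        ``"C3_endo"`` or ``"C2_endo"``.
    source
        ``"nu"`` (high-detail, from the ring atoms) or ``"pperp"``.
    pperp_value
        The Pperp distance in Angstrom when ``source == "pperp"``.
    """

    state: str
    source: str
    pperp_value: Optional[float] = None

    @property
    def digit(self) -> str:
        return "3" if self.state == "C3_endo" else "2"


_RING_ATOMS = ("C1'", "C2'", "C3'", "C4'", "O4'")


def pucker_from_nu(res: "ResidueRecord") -> Pucker:
    """High-detail pucker call from the ribose ring geometry.

    The ring plane is taken as the oriented plane spanned by the bond
    vectors C4'-O4' and C1'-O4'; the signed heights of C3' and C2' over
    that plane decide the call: the sugar is C3'-endo when C3' sits on the
    positive side and higher than C2', else C2'-endo.  (The positive side
    is the base/C5' face of the ring.)
    """
    missing = [a for a in _RING_ATOMS if a not in res.atoms]
    if missing:
        raise GeometryError(f"ribose ring atoms missing: {', '.join(missing)}")
    pos = {a: res.atoms[a].position for a in _RING_ATOMS}
    o4 = pos["O4'"]
    u = pos["C4'"] - o4
    t = pos["C1'"] - o4
    n = np.cross(u, t)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("degenerate ribose: C4', O4', C1' collinear")
    n = n / nn
    h3 = float(n @ (pos["C3'"] - o4))
    h2 = float(n @ (pos["C2'"] - o4))
    if abs(h3) < 1e-9 and abs(h2) < 1e-9:
        raise GeometryError("degenerate (planar) ribose ring: pucker undefined")
    state = "C3_endo" if (h3 > 0.0 and h3 > h2) else "C2_endo"
    return Pucker(state=state, source="nu")


def pperp(n_glyc, c1p, next_p) -> float:
    """Perpendicular distance (A) from ``next_p`` to the extended
    glycosidic bond line through ``c1p`` and ``n_glyc``."""
    n_glyc, c1p, next_p = _as_vec(n_glyc), _as_vec(c1p), _as_vec(next_p)
    u = n_glyc - c1p
    nu = np.linalg.norm(u)
    if nu < 1e-10:
        raise GeometryError("glycosidic bond endpoints coincide")
    u = u / nu
    r = next_p - c1p
    return float(np.linalg.norm(r - (r @ u) * u))


def pucker_from_pperp(d: float) -> Pucker:
    """Low-detail pucker call from a Pperp distance (C3'-endo iff d >= 2.9 A)."""
    if d < 0:
        raise ValueError("Pperp distance must be nonnegative")
    state = "C3_endo" if d >= PPERP_CUTOFF else "C2_endo"
    return Pucker(state=state, source="pperp", pperp_value=float(d))


def suite_pperps(suite: "SuiteAtoms") -> tuple[float, Optional[float]]:
    """(Pperp of the 5' sugar, Pperp of the 3' sugar or None).

    The 5' sugar's Pperp drops the suite's own P onto the first glycosidic
    bond line; the 3' sugar needs the *next* residue's P, which may be
    absent at a chain end.
    """
    rp, rc = suite.res_prev, suite.res_curr
    p5 = pperp(rp.atoms[rp.glyco_n].position, rp.atoms["C1'"].position,
               rc.atoms["P"].position)
    p3 = None
    if suite.next_P is not None:
        p3 = pperp(rc.atoms[rc.glyco_n].position, rc.atoms["C1'"].position,
                   suite.next_P)
    return p5, p3


def pucker_pair(suite: "SuiteAtoms", mode: str = "LD") -> str:
    """Pucker configuration pair of a suite: 'P33', 'P32', 'P23' or 'P22'.

    mode="HD" reads both puckers from the ribose ring geometry; mode="LD"
    uses the Pperp criterion and requires the following residue's
    phosphorus for the 3' sugar.
    """
    if mode == "HD":
        pk5 = pucker_from_nu(suite.res_prev)
        pk3 = pucker_from_nu(suite.res_curr)
    elif mode == "LD":
        if suite.next_P is None:
            raise GeometryError(
                f"suite {suite.suite_id}: next-residue P required for the "
                "3' sugar's Pperp; suite is un-gateable at low detail"
            )
        p5, p3 = suite_pperps(suite)
        pk5 = pucker_from_pperp(p5)
        pk3 = pucker_from_pperp(p3)
    else:
        raise ValueError(f"mode must be 'HD' or 'LD', got {mode!r}")
    return f"P{pk5.digit}{pk3.digit}"


def suites_report(suites: Iterable["SuiteAtoms"]):
    """Per-suite geometry table: dihedrals, Pperp values, pucker pairs.

    Returns a pandas DataFrame (one row per suite; un-computable fields
    are NaN/empty).
    """
    import pandas as pd

    rows = []
    for s in suites:
        row = {
            "structure_id": s.suite_id[0],
            "chain": s.suite_id[1],
            "resnum": s.suite_id[2],
            "icode": s.suite_id[3],
        }
        try:
            angles = suite_dihedrals(s)
            row.update(dict(zip(DIHEDRAL_NAMES, angles)))
        except GeometryError:
            pass
        try:
            p5, p3 = suite_pperps(s)
            row["pperp5"] = p5
            row["pperp3"] = p3
        except (GeometryError, KeyError):
            pass
        try:
            row["pucker_pair_HD"] = pucker_pair(s, "HD")
        except GeometryError:
            row["pucker_pair_HD"] = ""
        try:
            row["pucker_pair_LD"] = pucker_pair(s, "LD")
        except GeometryError:
            row["pucker_pair_LD"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
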