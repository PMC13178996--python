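"""Synthetic suite generator: Cartesian suites from internal coordinates.

Everything downstream (geometry, landmarks, clustering, classification)
is testable without downloads because this module builds 3D suites from
the 7 backbone dihedrals with ideal bond lengths/angles (real backbones
deviate by ~0.01 A in lengths and ~2 degrees in angles), closes each
ribose from a pseudorotation template per pucker state, and samples
cluster mixtures of suites on the 7-torus with known labels.

The generated data emulate the clustered, rotameric structure of curated
RNA suites: wrapped-Gaussian dihedral noise around well-separated class
centres, one class set per pucker pair.  It does not emulate map-driven
modelling artifacts, heterogeneous per-structure error levels, or the
heavily unbalanced class frequencies of real RNA (the A-form class
dominance), except through the configurable cluster sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, LabelTable, ResidueRecord, SuiteAtoms
from .suite_geometry import GeometryError, wrap_degrees

log = logging.getLogger(__name__)

__all__ = [
    "IdealGeometry",
    "SyntheticConfig",
    "GoldStandard",
    "nerf_place",
    "build_residue_chain",
    "build_cartesian",
    "perturb_rigid",
    "sample_gold_standard",
    "DEFAULT_CENTERS",
]


@dataclass(frozen=True)
class IdealGeometry:
    """Ideal bond lengths (A) and angles (degrees) for suite building.

    Values are standard small-molecule nucleic-acid geometry; all lengths
    lie in (1.2, 1.7) A and all angles in (90, 130) degrees.
    """

    # backbone bonds
    c5_c4: float = 1.510
    c4_c3: float = 1.524
    c3_o3: float = 1.423
    o3_p: float = 1.607
    p_o5: float = 1.593
    o5_c5: float = 1.440
    # ribose / glycosidic bonds
    c4_o4: float = 1.451
    o4_c1: float = 1.414
    c3_c2: float = 1.525
    c1_n: float = 1.470
    # backbone angles
    a_c5_c4_c3: float = 115.5
    a_c4_c3_o3: float = 110.7
    a_c3_o3_p: float = 119.7
    a_o3_p_o5: float = 104.0
    a_p_o5_c5: float = 120.9
    a_o5_c5_c4: float = 111.5
    # ribose angles
    a_c4_c3_c2: float = 102.7
    a_c3_c4_o4: float = 105.5
    a_c4_o4_c1: float = 109.7
    a_o4_c1_n: float = 108.4
    # pseudorotation template: phase (deg) per pucker state, amplitude (deg)
    phase_c3_endo: float = 18.0
    phase_c2_endo: float = 162.0
    amplitude: float = 38.0

    def __post_init__(self):
        for name in ("c5_c4", "c4_c3", "c3_o3", "o3_p", "p_o5", "o5_c5",
                     "c4_o4", "o4_c1", "c3_c2", "c1_n"):
            v = getattr(self, name)
            if not 1.2 < v < 1.7:
                raise ValueError(f"bond length {name}={v} outside (1.2, 1.7) A")
        for name in ("a_c5_c4_c3", "a_c4_c3_o3", "a_c3_o3_p", "a_o3_p_o5",
                     "a_p_o5_c5", "a_o5_c5_c4", "a_c4_c3_c2", "a_c3_c4_o4",
                     "a_c4_o4_c1", "a_o4_c1_n"):
            v = getattr(self, name)
            if not 90.0 < v < 130.0:
                raise ValueError(f"bond angle {name}={v} outside (90, 130) deg")

    def nu(self, pucker_digit: str) -> np.ndarray:
        """Ring torsions nu0..nu4 (deg) from the pseudorotation template."""
        P = self.phase_c3_endo if pucker_digit == "3" else self.phase_c2_endo
        j = np.arange(5)
        return self.amplitude * np.cos(np.radians(P + 144.0 * (j - 2)))


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion (degrees); the NeRF construction."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("NeRF reference atoms collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# Exocyclic branch offsets (degrees), calibrated once so that the built
# ring closes (C1'-C2' ~ 1.53 A) and the base nitrogen sits on the
# beta face (same side as C5'); see docs/methods.md.
_OFF_C2_FROM_C5 = -121.0   # torsion(C5'-C4'-C3'-C2') = nu3 + this
_OFF_N_FROM_C2 = -119.0    # torsion(C4'-O4'-C1'-N)   = nu0 + this

# Canonical epsilon (deg) used to place the *next* phosphorus after the
# suite's second residue, per that residue's pucker state.
_EPS_NEXT = {"3": 212.0, "2": 245.0}


def _ring_atoms(c5, c4, c3, nu: np.ndarray, geom: IdealGeometry
                ) -> Dict[str, np.ndarray]:
    """Place C2', O4', C1' and the glycosidic N given the backbone
    C5'-C4'-C3' and the ring torsion template."""
    c2 = nerf_place(c5, c4, c3, geom.c3_c2, geom.a_c4_c3_c2,
                    nu[3] + _OFF_C2_FROM_C5)
    o4 = nerf_place(c2, c3, c4, geom.c4_o4, geom.a_c3_c4_o4, nu[3])
    c1 = nerf_place(c3, c4, o4, geom.o4_c1, geom.a_c4_o4_c1, nu[4])
    n = nerf_place(c4, o4, c1, geom.c1_n, geom.a_o4_c1_n,
                   nu[0] + _OFF_N_FROM_C2)
    return {"C2'": c2, "O4'": o4, "C1'": c1, "N": n}


def _residue_record(chain_id: str, resnum: int, base: str,
                    atoms: Dict[str, np.ndarray]) -> ResidueRecord:
    recs = {}
    for name, pos in atoms.items():
        if name == "N":
            name = "N9" if base in ("A", "G") else "N1"
        recs[name] = AtomRecord(name=name, element=name[0], position=pos)
    return ResidueRecord(chain_id=chain_id, resnum=resnum, base_type=base,
                         atoms=recs)


def build_residue_chain(deltas: Sequence[float],
                        linkers: Sequence[Sequence[float]],
                        puckers: str,
                        bases: Optional[Sequence[str]] = None,
                        geom: IdealGeometry = IdealGeometry(),
                        chain_id: str = "A",
                        first_resnum: int = 1) -> List[ResidueRecord]:
    """Build an n-residue chain from internal coordinates.

    deltas
        n per-residue delta torsions (C5'-C4'-C3'-O3'), degrees.
    linkers
        n-1 tuples (epsilon, zeta, alpha, beta, gamma) joining residue j
        to residue j+1.
    puckers
        string of n pucker digits, '3' (C3'-endo) or '2' (C2'-endo).
    """
    n = len(deltas)
    if len(linkers) != n - 1 or len(puckers) != n:
        raise ValueError("need n deltas, n-1 linker tuples, n pucker digits")
    if bases is None:
        bases = ["G"] * n
    # seed frame for residue 0: C5' at origin, C4' on x, C3' in xy-plane
    c5 = np.zeros(3)
    c4 = np.array([geom.c5_c4, 0.0, 0.0])
    ang = np.radians(geom.a_c5_c4_c3)
    c3 = c4 + geom.c4_c3 * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues = []
    atoms: Dict[str, np.ndarray] = {"C5'": c5, "C4'": c4, "C3'": c3}
    for j in range(n):
        o3 = nerf_place(atoms["C5'"], atoms["C4'"], atoms["C3'"],
                        geom.c3_o3, geom.a_c4_c3_o3, deltas[j])
        atoms["O3'"] = o3
        atoms.update(_ring_atoms(atoms["C5'"], atoms["C4'"], atoms["C3'"],
                                 geom.nu(puckers[j]), geom))
        residues.append(_residue_record(chain_id, first_resnum + j,
                                        bases[j], dict(atoms)))
        if j == n - 1:
            break
        eps, zeta, alpha, beta, gamma = linkers[j]
        p = nerf_place(atoms["C4'"], atoms["C3'"], o3,
                       geom.o3_p, geom.a_c3_o3_p, eps)
        o5 = nerf_place(atoms["C3'"], o3, p, geom.p_o5, geom.a_o3_p_o5, zeta)
        c5n = nerf_place(o3, p, o5, geom.o5_c5, geom.a_p_o5_c5, alpha)
        c4n = nerf_place(p, o5, c5n, geom.c5_c4, geom.a_o5_c5_c4, beta)
        c3n = nerf_place(o5, c5n, c4n, geom.c4_c3, geom.a_c5_c4_c3, gamma)
        atoms = {"P": p, "O5'": o5, "C5'": c5n, "C4'": c4n, "C3'": c3n}
    return residues


def build_cartesian(dihedrals: Sequence[float], pucker_pair: str,
                    geom: IdealGeometry = IdealGeometry(),
                    bases: Tuple[str, str] = ("G", "G"),
                    structure_id: str = "synthetic",
                    chain_id: str = "A",
                    resnum: int = 2,
                    with_next_p: bool = True) -> SuiteAtoms:
    """Build one suite (two residues + following P) from its 7 dihedrals.

    ``dihedrals`` are (delta_prev, epsilon, zeta, alpha, beta, gamma,
    delta) in degrees; ``pucker_pair`` is 'P33', 'P32', 'P23' or 'P22'.
    The measured dihedrals of the result reproduce the input to well
    below 1e-6 degrees.
    """
    if len(dihedrals) != 7:
        raise ValueError("a suite has exactly 7 dihedrals")
    if pucker_pair not in ("P33", "P32", "P23", "P22"):
        raise ValueError(f"unknown pucker pair {pucker_pair!r}")
    dp, eps, zeta, alpha, beta, gamma, dc = (float(x) for x in dihedrals)
    puckers = pucker_pair[1:]
    residues = build_residue_chain(
        deltas=[dp, dc], linkers=[(eps, zeta, alpha, beta, gamma)],
        puckers=puckers, bases=list(bases), geom=geom, chain_id=chain_id,
        first_resnum=resnum - 1)
    prev, curr = residues
    next_P = None
    if with_next_p:
        next_P = nerf_place(curr.atoms["C4'"].position,
                            curr.atoms["C3'"].position,
                            curr.atoms["O3'"].position,
                            geom.o3_p, geom.a_c3_o3_p, _EPS_NEXT[puckers[1]])
    return SuiteAtoms(suite_id=(structure_id, chain_id, resnum, ""),
                      res_prev=prev, res_curr=curr, next_P=next_P)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _transform_residue(res: ResidueRecord, R: np.ndarray, t: np.ndarray
                       ) -> ResidueRecord:
    atoms = {name: replace(a, position=R @ a.position + t)
             for name, a in res.atoms.items()}
    return replace(res, atoms=atoms)


def perturb_rigid(suite: SuiteAtoms, seed=None,
                  max_translation: float = 20.0) -> SuiteAtoms:
    """Apply a uniformly random rotation plus bounded translation to all
    atoms of a suite; internal geometry is preserved exactly."""
    rng = np.random.default_rng(seed)
    R = _random_rotation(rng)
    t = rng.uniform(-max_translation, max_translation, size=3)
    next_P = None if suite.next_P is None else R @ suite.next_P + t
    return SuiteAtoms(suite_id=suite.suite_id,
                      res_prev=_transform_residue(suite.res_prev, R, t),
                      res_curr=_transform_residue(suite.res_curr, R, t),
                      next_P=next_P)


# ---------------------------------------------------------------------------
# gold-standard mixtures on the torus

# Default class centres per pucker pair: (epsilon, zeta, alpha, beta,
# gamma) for four synthetic conformer classes.  delta values are set by
# the pucker state (84 for C3'-endo, 147 for C2'-endo).  Centres are
# mutually well separated both on the torus (>= 60 deg in >= 2
# coordinates) and in the low-detail shape coordinates, emulating
# distinct rotameric families rather than crankshaft-related twins.
_LINKER_CENTERS = (
    (212.0, 288.0, 295.0, 172.0, 54.0),   # A-form-like
    (242.0, 170.0, 170.0, 170.0, 55.0),
    (212.0, 288.0, 295.0, 110.0, 180.0),
    (155.0, 65.0, 65.0, 245.0, 290.0),
)

_DELTA = {"3": 84.0, "2": 147.0}

#: Synthetic conformer-class labels per pucker pair (2-character scheme).
_CLASS_NAMES = {
    "P33": ("1a", "1c", "1e", "1g"),
    "P32": ("1b", "1o", "5z", "7p"),
    "P23": ("2a", "4a", "0a", "6g"),
    "P22": ("2o", "4b", "6p", "8p"),
}


def default_centers(pair: str, n_clusters: int = 4) -> np.ndarray:
    """(n_clusters, 7) default torus centres for a pucker pair."""
    if n_clusters > len(_LINKER_CENTERS):
        raise ValueError("at most 4 default centres per pair")
    d5, d3 = _DELTA[pair[1]], _DELTA[pair[2]]
    rows = [(d5, *link, d3) for link in _LINKER_CENTERS[:n_clusters]]
    return np.array(rows)


DEFAULT_CENTERS: Dict[str, np.ndarray] = {
    p: default_centers(p) for p in ("P33", "P32", "P23", "P22")
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic gold standard.

    Four pucker pairs, four classes each, 40 training suites per class
    with wrapped-Gaussian dihedral noise of 8 degrees, plus 10 held-out
    test suites per class; random rigid motions on, no Cartesian noise.
    """

    pairs: Tuple[str, ...] = ("P33", "P32", "P23", "P22")
    n_clusters: int = 4
    n_per_cluster: int = 40
    n_test_per_cluster: int = 10
    sigma_noise: float = 8.0        # degrees, per dihedral
    coordinate_noise: float = 0.0   # Angstrom, isotropic per atom
    rigid_motion: bool = True
    min_separation_factor: float = 4.0  # for random-separated centres
    centers: Optional[Dict[str, np.ndarray]] = None  # else defaults
    seed: int = 0


@dataclass
class GoldStandard:
    """Synthetic training and test data with ground truth.

    train_suites / test_suites are lists of SuiteAtoms; labels and the
    answer manifest use the tabular formats of structure_io.  truth maps
    suite_id -> (pucker pair, cluster index, class label).
    """

    train_suites: List[SuiteAtoms]
    train_labels: LabelTable
    test_suites: List[SuiteAtoms]
    answers: LabelTable
    truth: Dict[Tuple[str, str, int, str], Tuple[str, int, str]]
    centers: Dict[str, np.ndarray]
    config: SyntheticConfig = field(repr=False, default=None)


def _noise_suite(center: np.ndarray, pair: str, rng: np.random.Generator,
                 cfg: SyntheticConfig, structure_id: str, resnum: int
                 ) -> SuiteAtoms:
    angles = wrap_degrees(center + rng.normal(0.0, cfg.sigma_noise, size=7)
                          if cfg.sigma_noise > 0 else center.copy())
    s = build_cartesian(angles, pair, structure_id=structure_id,
                        resnum=resnum)
    if cfg.coordinate_noise > 0:
        def jitter(res):
            atoms = {n: replace(a, position=a.position + rng.normal(
                0.0, cfg.coordinate_noise, size=3))
                for n, a in res.atoms.items()}
            return replace(res, atoms=atoms)
        s = SuiteAtoms(suite_id=s.suite_id, res_prev=jitter(s.res_prev),
                       res_curr=jitter(s.res_curr),
                       next_P=s.next_P + rng.normal(
                           0.0, cfg.coordinate_noise, size=3))
    if cfg.rigid_motion:
        s = perturb_rigid(s, seed=rng)
    return s


def sample_gold_standard(cfg: SyntheticConfig = None) -> GoldStandard:
    """Draw the synthetic gold standard defined by ``cfg`` (deterministic
    under its seed)."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    centers = dict(cfg.centers) if cfg.centers else {
        p: default_centers(p, cfg.n_clusters) for p in cfg.pairs}
    for p, C in centers.items():
        C = np.asarray(C, dtype=float)
        if C.shape[1] != 7:
            raise ValueError("cluster centres must have 7 dihedrals")
        centers[p] = C
    train_suites, test_suites = [], []
    label_rows, answer_rows = [], []
    truth = {}
    for pair in cfg.pairs:
        names = _CLASS_NAMES.get(pair, ())
        for k, center in enumerate(centers[pair]):
            label = names[k] if k < len(names) else f"{k}{pair[-1]}"
            for split, n_draw, sink, rows in (
                    ("train", cfg.n_per_cluster, train_suites, label_rows),
                    ("test", cfg.n_test_per_cluster, test_suites, answer_rows)):
                for j in range(n_draw):
                    sid = f"syn-{split}-{pair}-{k}"
                    s = _noise_suite(center, pair, rng, cfg, sid,
                                     resnum=2 + 10 * j)
                    sink.append(s)
                    row = {"structure_id": s.suite_id[0],
                           "chain": s.suite_id[1],
                           "resnum": s.suite_id[2], "icode": "",
                           "conformer": label}
                    if split == "test":
                        row["answer_conformer"] = label
                        row["answer_pucker_pair"] = pair
                    rows.append(row)
                    truth[s.suite_id] = (pair, k, label)
    return GoldStandard(
        train_suites=train_suites,
        train_labels=LabelTable(pd.DataFrame(label_rows)),
        test_suites=test_suites,
        answers=LabelTable(pd.DataFrame(answer_rows)),
        truth=truth, centers=centers, config=cfg)
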