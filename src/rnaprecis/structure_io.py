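"""Reading coordinate files, assembling suites, and label/manifest tables.

PDB and mmCIF parsing is delegated to gemmi; this module extracts RNA
residues (standard bases A, U, C, G by their common aliases), applies a
single-altloc policy, and assembles sugar-to-sugar suites from adjacent,
covalently connectable residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "SuiteAtoms",
    "LabelTable",
    "ParseError",
    "O3P_BOND_CUTOFF",
    "LOW_DETAIL_ATOMS",
    "parse_structure",
    "write_structure",
    "build_suites",
    "read_label_table",
    "write_label_table",
]

#: Maximum O3'(i-1) - P(i) distance (A) for two residues to count as bonded.
#: The covalent bond is ~1.6 A; the cutoff is generous for poorly
#: refined models.
O3P_BOND_CUTOFF = 2.5

#: The five atoms of the low-detail representation (per suite):
#: N1/N9 and C1' of both residues plus the central P.
LOW_DETAIL_ATOMS = ("N1/N9(i-1)", "C1'(i-1)", "P(i)", "C1'(i)", "N1/N9(i)")

_BASE_ALIASES = {
    "A": "A", "ADE": "A", "RA": "A", "A5": "A", "A3": "A",
    "U": "U", "URA": "U", "URI": "U", "RU": "U", "U5": "U", "U3": "U",
    "C": "C", "CYT": "C", "RC": "C", "C5": "C", "C3": "C",
    "G": "G", "GUA": "G", "RG": "G", "G5": "G", "G3": "G",
}

_PURINES = {"A", "G"}

# Atoms worth keeping: anything used downstream by geometry or landmarks.
_ATOMS_OF_INTEREST = {
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'",
    "C2'", "C1'", "O4'", "O2'", "N1", "N9",
}


class ParseError(ValueError):
    """A coordinate file could not be parsed."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom centre: name, element, position (A), altloc, occupancy."""

    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be nonempty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("atom position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class ResidueRecord:
    """One nucleotide: chain, author numbering, base type and atom map."""

    chain_id: str
    resnum: int
    icode: str = ""
    base_type: str = "other"  # one of A, U, C, G, other
    atoms: Dict[str, AtomRecord] = field(default_factory=dict)
    has_altloc: bool = False

    @property
    def glyco_n(self) -> str:
        """Name of the glycosidic nitrogen: N9 for purines, N1 for pyrimidines."""
        return "N9" if self.base_type in _PURINES else "N1"

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)


@dataclass
class SuiteAtoms:
    """A sugar-to-sugar suite: two bonded residues plus the next P.

    The suite is named by the (chain, residue number) of its second
    member residue, the one contributing the suite's own phosphorus.
    ``next_P`` is the position of the following residue's P (needed for
    the 3' sugar's Pperp) when that residue exists and is bonded.
    """

    suite_id: Tuple[str, str, int, str]  # (structure_id, chain, resnum, icode)
    res_prev: ResidueRecord
    res_curr: ResidueRecord
    next_P: Optional[np.ndarray] = None

    def landmarks(self) -> np.ndarray:
        """The (5, 3) low-detail landmark array:
        N1/N9(i-1), C1'(i-1), P(i), C1'(i), N1/N9(i)."""
        rp, rc = self.res_prev, self.res_curr
        return np.array([
            rp.atoms[rp.glyco_n].position,
            rp.atoms["C1'"].position,
            rc.atoms["P"].position,
            rc.atoms["C1'"].position,
            rc.atoms[rc.glyco_n].position,
        ])


def _pick_altloc(atom_group) -> Optional["object"]:
    """Altloc policy: blank or 'A' preferred; highest occupancy on tie."""
    blanks = [a for a in atom_group if a.altloc in ("", "\0", " ")]
    if blanks:
        return max(blanks, key=lambda a: a.occ)
    alts_a = [a for a in atom_group if a.altloc == "A"]
    if alts_a:
        return max(alts_a, key=lambda a: a.occ)
    return max(atom_group, key=lambda a: a.occ, default=None)


def parse_structure(path, fmt: str = "auto") -> List[List[ResidueRecord]]:
    """Read a PDB or mmCIF file and return RNA residues grouped by chain.

    Only the first model is read; coordinates are in Angstrom.  Residues
    are kept when they contain at least one atom used downstream.  Files
    with zero RNA residues yield an empty list with a warning.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path))[0])
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError, IndexError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        log.warning("%s: no models", path)
        return []
    model = st[0]  # first model only
    chains: List[List[ResidueRecord]] = []
    for chain in model:
        residues: List[ResidueRecord] = []
        for res in chain:
            base = _BASE_ALIASES.get(res.name.strip().upper(), "other")
            # group atoms by name, resolve altlocs
            by_name: Dict[str, list] = {}
            has_altloc = False
            for atom in res:
                if atom.name not in _ATOMS_OF_INTEREST:
                    continue
                if atom.altloc not in ("", "\0"):
                    has_altloc = True
                by_name.setdefault(atom.name, []).append(atom)
            atoms: Dict[str, AtomRecord] = {}
            for name, group in by_name.items():
                a = _pick_altloc(group)
                if a is None:
                    continue
                atoms[name] = AtomRecord(
                    name=name,
                    element=a.element.name,
                    position=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    altloc="" if a.altloc in ("", "\0") else a.altloc,
                    occupancy=a.occ,
                )
            if not atoms:
                continue
            residues.append(ResidueRecord(
                chain_id=chain.name,
                resnum=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                base_type=base,
                atoms=atoms,
                has_altloc=has_altloc,
            ))
        if residues:
            chains.append(residues)
    if not any(r.base_type != "other" for ch in chains for r in ch):
        log.warning("%s: no standard RNA residues found", path)
    return chains


_BASE_FULL = {"A": "A", "U": "U", "C": "C", "G": "G", "other": "N"}


def write_structure(chains: Sequence[Sequence[ResidueRecord]], path,
                    fmt: str = "auto") -> None:
    """Write residues back out as PDB or mmCIF (via gemmi)."""
    import gemmi

    path = Path(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = path.stem
    model = gemmi.Model("1")
    for residues in chains:
        if not residues:
            continue
        chain = gemmi.Chain(residues[0].chain_id)
        for rr in residues:
            res = gemmi.Residue()
            res.name = _BASE_FULL.get(rr.base_type, "N")
            res.seqid = gemmi.SeqId(rr.resnum, rr.icode or " ")
            for ar in rr.atoms.values():
                atom = gemmi.Atom()
                atom.name = ar.name
                atom.element = gemmi.Element(ar.element or ar.name[0])
                atom.pos = gemmi.Position(*ar.position)
                atom.occ = ar.occupancy
                atom.altloc = ar.altloc or "\0"
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _bonded(prev: ResidueRecord, curr: ResidueRecord,
            cutoff: float = O3P_BOND_CUTOFF) -> bool:
    if "O3'" not in prev.atoms or "P" not in curr.atoms:
        return False
    d = np.linalg.norm(prev.atoms["O3'"].position - curr.atoms["P"].position)
    return bool(d <= cutoff)


def _has_low_detail_atoms(res: ResidueRecord, need_p: bool) -> bool:
    if res.base_type == "other":
        return False
    if res.glyco_n not in res.atoms or "C1'" not in res.atoms:
        return False
    if need_p and "P" not in res.atoms:
        return False
    return True


def build_suites(chains, structure_id: str = "",
                 bond_cutoff: float = O3P_BOND_CUTOFF,
                 drop_altloc: bool = False) -> List[SuiteAtoms]:
    """Assemble suites from residues grouped by chain.

    One suite per adjacent bonded residue pair (O3'-P distance within
    ``bond_cutoff``); suites missing any of the 5 low-detail atoms, or
    involving a non-standard base, are excluded and logged.  ``next_P``
    is filled when residue i+1 exists and is bonded.  ``drop_altloc``
    additionally excludes suites whose residues carry alternate
    conformations.
    """
    if chains and isinstance(chains[0], ResidueRecord):
        chains = [chains]
    suites: List[SuiteAtoms] = []
    for residues in chains:
        for i in range(1, len(residues)):
            prev, curr = residues[i - 1], residues[i]
            if prev.chain_id != curr.chain_id:
                continue
            if not _bonded(prev, curr, cutoff=bond_cutoff):
                log.info("chain break before %s:%s%s", curr.chain_id,
                         curr.resnum, curr.icode)
                continue
            if not (_has_low_detail_atoms(prev, need_p=False)
                    and _has_low_detail_atoms(curr, need_p=True)):
                log.info("suite %s:%s%s excluded: missing low-detail atoms "
                         "or non-standard base", curr.chain_id, curr.resnum,
                         curr.icode)
                continue
            if drop_altloc and (prev.has_altloc or curr.has_altloc):
                log.info("suite %s:%s%s excluded: alternate conformations",
                         curr.chain_id, curr.resnum, curr.icode)
                continue
            next_P = None
            if i + 1 < len(residues):
                nxt = residues[i + 1]
                if _bonded(curr, nxt, cutoff=bond_cutoff) and "P" in nxt.atoms:
                    next_P = nxt.atoms["P"].position
            suites.append(SuiteAtoms(
                suite_id=(structure_id, curr.chain_id, curr.resnum, curr.icode),
                res_prev=prev, res_curr=curr, next_P=next_P,
            ))
    return suites


# ---------------------------------------------------------------------------
# label / manifest tables

LABEL_COLUMNS = ["structure_id", "chain", "resnum", "icode", "conformer"]
OPTIONAL_COLUMNS = ["answer_conformer", "answer_pucker_pair"]


def _valid_conformer(s: str) -> bool:
    """Conformer class strings are 2 characters ('1a', '5z', '1[', '!!', ...)."""
    return isinstance(s, str) and len(s) == 2 and not s.isspace()


@dataclass
class LabelTable:
    """Tabular mapping from suite ids to conformer-class strings.

    Backed by a DataFrame with columns structure_id, chain, resnum,
    icode, conformer (plus optional answer columns for test manifests).
    """

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def lookup(self) -> Dict[Tuple[str, str, int, str], str]:
        """suite_id -> conformer class."""
        return {
            (r.structure_id, r.chain, int(r.resnum), r.icode): r.conformer
            for r in self.df.itertuples()
        }


def read_label_table(path) -> LabelTable:
    """Read a label/manifest CSV; malformed conformer rows are rejected
    with a diagnostic, the rest are kept."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"structure_id": str, "chain": str,
                                      "icode": str, "conformer": str},
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        return LabelTable(pd.DataFrame(columns=LABEL_COLUMNS))
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    ok = df["conformer"].map(_valid_conformer)
    for idx in df.index[~ok]:
        log.warning("%s row %d: malformed conformer %r rejected",
                    path, idx, df.at[idx, "conformer"])
    df = df[ok].reset_index(drop=True)
    df["resnum"] = df["resnum"].astype(int)
    return LabelTable(df)


def write_label_table(table: LabelTable, path) -> None:
    table.df.to_csv(path, index=False)
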