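"""Structure model: PDB parsing, ASA, secondary structure, surface residues.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Residue` objects, each holding heavy-atom coordinates, radii,
and (once computed) per-residue accessible surface area and a 3-state
secondary-structure label.  Residues are addressed everywhere by the triple
``(chain_id, resseq, icode)``.

Parsing goes through biopython's PDB parser; waters and heteroatoms are
dropped (selenomethionine is kept and mapped to Met), hydrogens are ignored,
and alternate locations are resolved to the highest-occupancy conformer
(ties broken by altloc identifier).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
from Bio.PDB import PDBParser

from . import sasa
from .constants import JANJ780101, PROBE_RADIUS, SURFACE_ASA_MIN, VDW_DEFAULT, VDW_RADII
from .errors import (
    AlignmentError,
    EmptyStructureError,
    FormatError,
    ParameterError,
    PartitionError,
    StateError,
)

ResidueId = Tuple[str, int, str]

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",  # selenomethionine, treated as Met
}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    vdw_radius: float
    is_sidechain: bool
    asa: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError(f"atom {self.name}: non-finite coordinates")
        if self.vdw_radius <= 0:
            raise ParameterError(f"atom {self.name}: vdW radius must be > 0")


@dataclass
class Residue:
    chain_id: str
    resseq: int
    icode: str
    res_type: str  # one-letter code, 'X' for nonstandard
    atoms: List[Atom]
    standard: bool = True
    seq_index: int = 0  # ordinal within the structure
    asa: Optional[float] = None
    ss_state: Optional[str] = None  # 'H', 'E' or 'C'

    @property
    def id(self) -> ResidueId:
        return (self.chain_id, self.resseq, self.icode)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def sidechain_atoms(self) -> List[Atom]:
        return [a for a in self.atoms if a.is_sidechain]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class Structure:
    id: str
    residues: List[Residue]
    source_path: Optional[str] = None
    _index: Dict[ResidueId, Residue] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.reindex()

    def reindex(self) -> None:
        self._index = {r.id: r for r in self.residues}
        for i, r in enumerate(self.residues):
            r.seq_index = i

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, rid: ResidueId) -> Residue:
        return self._index[rid]

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self._index

    @property
    def total_asa(self) -> float:
        """Domain size: sum of per-residue ASA (A^2)."""
        if any(r.asa is None for r in self.residues):
            raise StateError("ASA not computed; call compute_asa first")
        return float(sum(r.asa for r in self.residues))

    def chain_ids(self) -> List[str]:
        seen: List[str] = []
        for r in self.residues:
            if r.chain_id not in seen:
                seen.append(r.chain_id)
        return seen

    def chain(self, chain_id: str) -> List[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def subset(self, chain_ids: Iterable[str], new_id: Optional[str] = None) -> "Structure":
        """Deep-copied sub-structure restricted to the given chains.

        ASA and secondary-structure fields are reset: they are context
        dependent and must be recomputed on the subset.
        """
        wanted = set(chain_ids)
        residues = []
        for r in self.residues:
            if r.chain_id in wanted:
                atoms = [
                    Atom(a.name, a.element, a.coords.copy(), a.vdw_radius, a.is_sidechain)
                    for a in r.atoms
                ]
                residues.append(
                    Residue(r.chain_id, r.resseq, r.icode, r.res_type, atoms, r.standard)
                )
        label = new_id or f"{self.id}:{''.join(sorted(wanted))}"
        return Structure(label, residues, source_path=self.source_path)

    def atom_arrays(self) -> Tuple[np.ndarray, np.ndarray, List[Tuple[int, int]]]:
        """Flat coordinate/radius arrays plus (residue, atom) index pairs."""
        coords, radii, owners = [], [], []
        for ri, r in enumerate(self.residues):
            for ai, a in enumerate(r.atoms):
                coords.append(a.coords)
                radii.append(a.vdw_radius)
                owners.append((ri, ai))
        return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float), owners


@dataclass
class ComplexPartition:
    """A complex split into two sides by chain identifiers."""

    complex: Structure
    side_a: Set[str]
    side_b: Set[str]

    def __post_init__(self) -> None:
        self.side_a = set(self.side_a)
        self.side_b = set(self.side_b)
        if not self.side_a or not self.side_b:
            raise PartitionError("both sides must be non-empty")
        if self.side_a & self.side_b:
            raise PartitionError(f"sides overlap: {sorted(self.side_a & self.side_b)}")
        present = set(self.complex.chain_ids())
        missing = (self.side_a | self.side_b) - present
        if missing:
            raise PartitionError(f"chains not in structure: {sorted(missing)}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _vdw_for(element: str) -> float:
    return VDW_RADII.get(element.upper(), VDW_DEFAULT)


def read_structure(
    pdb_source, model_policy: str = "first", model_index: int = 0, id: str = ""
) -> Structure:
    """Parse a PDB file (path or raw text) into a :class:`Structure`.

    ``model_policy`` is ``"first"`` (use the first MODEL) or ``"index"``
    (use ``model_index``, 0-based).  Waters and non-protein heteroatoms are
    excluded, hydrogens ignored, altlocs resolved to highest occupancy with
    ties broken by altloc identifier.
    """
    label = id
    if isinstance(pdb_source, (str, Path)) and "\n" not in str(pdb_source):
        path = Path(pdb_source)
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        handle = path.open()
        label = label or path.stem
        source_path: Optional[str] = str(path)
    else:
        handle = io.StringIO(str(pdb_source))
        label = label or "structure"
        source_path = None

    parser = PDBParser(QUIET=True)
    try:
        with handle:
            bio_struct = parser.get_structure(label, handle)
    except Exception as exc:  # biopython raises bare ValueError/Exception
        raise FormatError(f"cannot parse PDB input: {exc}") from exc

    models = list(bio_struct.get_models())
    if not models:
        raise EmptyStructureError("PDB input contains no models")
    if model_policy == "first":
        model = models[0]
    elif model_policy == "index":
        if not 0 <= model_index < len(models):
            raise ParameterError(f"model index {model_index} out of range")
        model = models[model_index]
    else:
        raise ParameterError(f"unknown model_policy {model_policy!r}")

    residues: List[Residue] = []
    for chain in model:
        chain_residues = []
        for res in chain:
            hetflag, resseq, icode = res.id
            resname = res.get_resname().strip()
            if hetflag == "W":
                continue
            if hetflag.startswith("H_") and resname != "MSE":
                continue
            one = _THREE_TO_ONE.get(resname)
            standard = one is not None
            atoms: List[Atom] = []
            # resolve altlocs: group unpacked atoms by name, keep best occupancy
            by_name: Dict[str, list] = {}
            for bio_atom in res.get_unpacked_list():
                elem = (bio_atom.element or "").strip().upper()
                if elem in ("H", "D"):
                    continue
                by_name.setdefault(bio_atom.get_name(), []).append(bio_atom)
            for name, alts in by_name.items():
                best = min(
                    alts,
                    key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc() or "~"),
                )
                elem = (best.element or "").strip().upper() or name[:1]
                atoms.append(
                    Atom(
                        name=name,
                        element=elem,
                        coords=np.array(best.get_coord(), dtype=float),
                        vdw_radius=_vdw_for(elem),
                        is_sidechain=name not in BACKBONE_NAMES,
                    )
                )
            if not atoms:
                continue
            chain_residues.append(
                Residue(
                    chain_id=chain.id,
                    resseq=int(resseq),
                    icode=(icode or " ").strip() or "",
                    res_type=one if standard else "X",
                    atoms=atoms,
                    standard=standard,
                )
            )
        chain_residues.sort(key=lambda r: (r.resseq, r.icode))
        residues.extend(chain_residues)

    if not residues:
        raise EmptyStructureError("no protein residues in PDB input")
    return Structure(label, residues, source_path=source_path)


# ---------------------------------------------------------------------------
# ASA
# ---------------------------------------------------------------------------

def compute_asa(
    struct: Structure, probe_radius: float = PROBE_RADIUS, n_points: int = 960
) -> Structure:
    """Fill per-atom and per-residue ASA in place (and return the structure).

    Deterministic Shrake-Rupley sampling (see :mod:`qipi.sasa`); per-residue
    ASA is the sum over the residue's heavy atoms.
    """
    coords, radii, owners = struct.atom_arrays()
    if len(coords) == 0:
        raise EmptyStructureError("structure has no atoms")
    areas = sasa.shrake_rupley(coords, radii, probe_radius=probe_radius, n_points=n_points)
    for r in struct.residues:
        r.asa = 0.0
    for (ri, ai), area in zip(owners, areas):
        struct.residues[ri].atoms[ai].asa = float(area)
        struct.residues[ri].asa += float(area)
    return struct


def surface_residues(struct: Structure, asa_min: float = SURFACE_ASA_MIN) -> Set[ResidueId]:
    """Residues with ASA strictly greater than ``asa_min`` (default 1 A^2)."""
    if any(r.asa is None for r in struct.residues):
        raise StateError("ASA not computed; call compute_asa first")
    return {r.id for r in struct.residues if r.asa > asa_min}


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(struct: Structure) -> Dict[ResidueId, Tuple[Optional[float], Optional[float]]]:
    """Per-residue (phi, psi); None at chain termini or with missing atoms."""
    out: Dict[ResidueId, Tuple[Optional[float], Optional[float]]] = {}
    for cid in struct.chain_ids():
        chain = struct.chain(cid)
        for i, res in enumerate(chain):
            phi = psi = None
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            if n is not None and ca is not None and c is not None:
                if i > 0:
                    cprev = chain[i - 1].atom("C")
                    if cprev is not None:
                        phi = dihedral(cprev.coords, n.coords, ca.coords, c.coords)
                if i < len(chain) - 1:
                    nnext = chain[i + 1].atom("N")
                    if nnext is not None:
                        psi = dihedral(n.coords, ca.coords, c.coords, nnext.coords)
            out[res.id] = (phi, psi)
    return out


def _helix_like(phi: Optional[float], psi: Optional[float]) -> bool:
    return (
        phi is not None and psi is not None
        and -100.0 <= phi <= -30.0 and -80.0 <= psi <= 0.0
    )


def _strand_like(phi: Optional[float], psi: Optional[float]) -> bool:
    return (
        phi is not None and psi is not None
        and -180.0 <= phi <= -40.0
        and (60.0 <= psi <= 180.0 or -180.0 <= psi <= -170.0)
    )


DSSP_8_TO_3 = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def map_dssp_state(code: str) -> str:
    """Collapse a DSSP 8-state code to 3 states (H/G/I->H, E/B->E, else C)."""
    return DSSP_8_TO_3.get(code.strip().upper(), "C")


def _parse_dssp(path) -> Dict[ResidueId, Tuple[str, str]]:
    """Map residue id -> (one-letter aa, 8-state code) from classic DSSP."""
    entries: Dict[ResidueId, Tuple[str, str]] = {}
    started = False
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#  RESIDUE"):
                started = True
                continue
            if not started or len(line) < 17:
                continue
            if line[13] == "!":  # chain break
                continue
            try:
                resseq = int(line[5:10])
            except ValueError:
                continue
            icode = line[10].strip()
            chain = line[11].strip()
            aa = line[13].upper()
            if aa.islower():  # DSSP lowercases SS-bonded cysteines
                aa = "C"
            ss = line[16]
            entries[(chain, resseq, icode)] = (aa, ss)
    if not entries:
        raise FormatError(f"no residue records found in DSSP file {path}")
    return entries


def assign_secondary_structure(struct: Structure, dssp_file=None) -> Structure:
    """Assign a 3-state secondary structure label to every residue.

    With ``dssp_file`` the classic DSSP output is read and collapsed 8->3.
    Without it, a dihedral-run assigner is used: residues in helical
    (phi in [-100,-30], psi in [-80,0]) runs of length >= 4 become H, residues
    in extended (phi in [-180,-40], psi in [60,180] or [-180,-170]) runs of
    length >= 3 become E, everything else (including residues with undefined
    dihedrals) is coil.
    """
    if dssp_file is not None:
        entries = _parse_dssp(dssp_file)
        mismatches = []
        for res in struct.residues:
            hit = entries.get(res.id)
            if hit is None:
                mismatches.append(f"{res.id}: missing from DSSP")
                continue
            aa, ss8 = hit
            if res.standard and aa.isalpha() and aa != "X" and aa != res.res_type:
                mismatches.append(f"{res.id}: structure {res.res_type} vs DSSP {aa}")
                continue
            res.ss_state = map_dssp_state(ss8)
        if mismatches:
            raise AlignmentError(
                "DSSP/structure mismatch: " + "; ".join(mismatches[:20])
            )
        return struct

    dih = backbone_dihedrals(struct)
    for cid in struct.chain_ids():
        chain = struct.chain(cid)
        flags = []
        for res in chain:
            phi, psi = dih[res.id]
            if _helix_like(phi, psi):
                flags.append("H")
            elif _strand_like(phi, psi):
                flags.append("E")
            else:
                flags.append("C")
        # enforce minimum run lengths (H >= 4, E >= 3)
        i = 0
        n = len(flags)
        while i < n:
            j = i
            while j < n and flags[j] == flags[i]:
                j += 1
            run_len = j - i
            state = flags[i]
            min_run = {"H": 4, "E": 3}.get(state, 1)
            final = state if run_len >= min_run else "C"
            for k in range(i, j):
                chain[k].ss_state = final
            i = j
    return struct


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_asa_table(struct: Structure, path) -> None:
    """Write the per-residue ASA table as TSV.

    ``rel_asa`` is the ASA normalised by the residue type's average
    accessible surface area (JANJ780101); blank for nonstandard residues.
    """
    with open(path, "w") as fh:
        fh.write("chain\tresseq\ticode\tres_type\tasa\trel_asa\tss_state\n")
        for r in struct.residues:
            asa = "" if r.asa is None else f"{r.asa:.3f}"
            rel = ""
            if r.asa is not None and r.standard:
                rel = f"{r.asa / JANJ780101[r.res_type]:.3f}"
            fh.write(
                f"{r.chain_id}\t{r.resseq}\t{r.icode}\t{r.res_type}\t"
                f"{asa}\t{rel}\t{r.ss_state or ''}\n"
            )
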