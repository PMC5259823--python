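"""Deterministic synthetic structures, complexes and PSSMs for testing.

The generator builds poly-residue bodies from ideal backbone geometry
(standard bond lengths/angles, caller-chosen dihedrals) with a single
carbon-sized side-chain pseudo-atom per non-glycine residue, docks two such
bodies so a
contiguous face is in heavy-atom contact below 5 A, and plants the interface
composition by enriching chosen residue types at the contact positions.
Everything is a pure function of the :class:`FixtureSpec`, so identical
specs give byte-identical PDB text.

The geometry is plausible rather than physical: it exercises the ASA,
distance, patch and scoring machinery, not molecular mechanics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np

from .constants import AMINO_ACIDS, QIPI, constant_tables
from .errors import ConfigError, ParameterError
from .pssm import PssmProfile
from .structure import ComplexPartition, ResidueId, Structure, compute_asa, read_structure

constants = constant_tables

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: background residue composition of the generated bodies: a typical
#: protein *surface* composition (charged/polar enriched, aromatics and
#: buried hydrophobics depleted), so that planted interface enrichment
#: stands against a realistic reference, as it does in real complexes
BACKGROUND_COMPOSITION: Mapping[str, float] = {
    "A": 0.07, "R": 0.05, "N": 0.05, "D": 0.07, "C": 0.01,
    "Q": 0.05, "E": 0.08, "G": 0.07, "H": 0.02, "I": 0.03,
    "L": 0.06, "K": 0.08, "M": 0.02, "F": 0.03, "P": 0.05,
    "S": 0.08, "T": 0.06, "W": 0.01, "Y": 0.03, "V": 0.04,
}

#: residue types with the highest interface propensity, used for the default
#: planted enrichment (Met, Tyr, Arg, Phe, Trp)
HIGH_QIPI = tuple(sorted(QIPI, key=QIPI.get, reverse=True)[:5])
HIGH_QIPI_BIAS: Mapping[str, float] = {aa: 3.0 for aa in HIGH_QIPI}

_GEOMETRIES = ("two-sheet-pack", "two-helix-pack", "blob")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic two-body complex."""

    seed: int = 0
    n_residues_per_side: int = 30
    interface_fraction: float = 0.3
    composition_bias: Mapping[str, float] = field(
        default_factory=lambda: dict(HIGH_QIPI_BIAS)
    )
    geometry: str = "two-sheet-pack"

    def __post_init__(self) -> None:
        if not 0.0 < self.interface_fraction < 1.0:
            raise ConfigError("interface_fraction must be in (0, 1)")
        if self.n_residues_per_side < 4:
            raise ConfigError("need at least 4 residues per side")
        if any(v <= 0 for v in self.composition_bias.values()):
            raise ConfigError("enrichment factors must be positive")
        if self.geometry not in _GEOMETRIES:
            raise ConfigError(f"geometry must be one of {_GEOMETRIES}")


# ---------------------------------------------------------------------------
# Ideal-geometry peptide builder
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: return d with |cd| = bond, angle(b,c,d) = angle and
    torsion(a,b,c,d) = torsion."""
    angle = math.radians(angle_deg)
    torsion = -math.radians(torsion_deg)  # sign matches the IUPAC measurement
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: Sequence[float], psi: Sequence[float], omega: float = 180.0
) -> Dict[str, np.ndarray]:
    """Backbone N/CA/C/O plus a virtual CB for every residue.

    ``phi[0]`` and ``psi[-1]`` are not used by construction (undefined at the
    termini).  Returns arrays of shape (n, 3) per atom name.
    """
    n_res = len(phi)
    if len(psi) != n_res:
        raise ParameterError("phi and psi must have the same length")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (1.458, 0.0, 0.0)
    ang = math.radians(180.0 - 111.2)
    C[0] = CA[0] + 1.525 * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], 1.329, 116.2, psi[i - 1])
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], 1.458, 121.7, omega)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], 1.525, 111.2, phi[i])
    O = np.zeros((n_res, 3))
    for i in range(n_res):
        psi_eff = psi[i] if i < n_res - 1 else 140.0
        O[i] = _place_atom(N[i], CA[i], C[i], 1.231, 120.8, psi_eff + 180.0)
    # tetrahedral CB from the backbone frame
    CB = np.zeros((n_res, 3))
    for i in range(n_res):
        b1 = CA[i] - N[i]
        b2 = CA[i] - C[i]
        bis = b1 + b2
        bis = bis / np.linalg.norm(bis)
        perp = np.cross(b1, b2)
        perp = perp / np.linalg.norm(perp)
        half = math.radians(54.75)
        CB[i] = CA[i] + 1.53 * (bis * math.cos(half) + perp * math.sin(half))
    return {"N": N, "CA": CA, "C": C, "O": O, "CB": CB}


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _dihedrals_for(geometry: str, n: int, rng: np.random.Generator):
    if geometry == "two-sheet-pack":
        return [-130.0] * n, [135.0] * n
    if geometry == "two-helix-pack":
        return [-60.0] * n, [-45.0] * n
    # blob: irregular mixture of backbone states
    states = [(-60.0, -45.0), (-130.0, 135.0), (-75.0, 150.0), (-100.0, 10.0)]
    idx = rng.integers(0, len(states), size=n)
    phi = [states[k][0] for k in idx]
    psi = [states[k][1] for k in idx]
    return phi, psi


def _stack_atoms(bb: Dict[str, np.ndarray]) -> np.ndarray:
    return np.concatenate([bb[k] for k in ("N", "CA", "C", "O", "CB")], axis=0)


def _dock_offset(
    atoms_a: np.ndarray, atoms_b_local: np.ndarray, axis: np.ndarray,
    perp: np.ndarray, shift: float, target_gap: float = 4.2
) -> np.ndarray:
    """Smallest perpendicular offset placing body B clash-free at ~target gap."""
    from scipy.spatial.distance import cdist

    for g in np.arange(3.0, 30.0, 0.1):
        offset = shift * axis + g * perp
        dmin = cdist(atoms_a, atoms_b_local + offset).min()
        if dmin >= target_gap:
            return offset
    raise ConfigError("could not dock fixture bodies without clashes")


def _draw_sequence(
    rng: np.random.Generator, n: int, planted: Set[int], bias: Mapping[str, float]
) -> str:
    base = np.array([BACKGROUND_COMPOSITION[a] for a in AMINO_ACIDS])
    base /= base.sum()
    enriched = np.array([bias.get(a, 1.0) for a in AMINO_ACIDS]) * base
    enriched /= enriched.sum()
    seq = []
    for i in range(n):
        p = enriched if i in planted else base
        seq.append(AMINO_ACIDS[int(rng.choice(len(AMINO_ACIDS), p=p))])
    return "".join(seq)


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resseq: int, coords, element: str
) -> str:
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded:<4s} {resname:<3s} {chain:1s}{resseq:4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


@dataclass
class ToyComplex:
    """A generated two-body complex with its construction-time truth."""

    spec: FixtureSpec
    pdb_text: str
    sequences: Dict[str, str]  # chain id -> one-letter sequence
    truth: Dict[str, Set[ResidueId]]  # side ('a'/'b') -> planted interface ids

    def structure(self) -> Structure:
        return read_structure(self.pdb_text, id=f"toy{self.spec.seed}")

    def partition(self) -> ComplexPartition:
        return ComplexPartition(self.structure(), {"A"}, {"B"})

    def unbound_side(self, side: str = "a", n_points: int = 960) -> Structure:
        chain = "A" if side == "a" else "B"
        sub = self.structure().subset({chain}, new_id=f"toy{self.spec.seed}:{side}")
        compute_asa(sub, n_points=n_points)
        return sub


def make_toy_complex(spec: FixtureSpec) -> ToyComplex:
    """Build a docked two-body complex with a planted interface.

    The two bodies share ideal backbone geometry; body B is a rigid
    translation of body A, shifted along the chain axis so only a contiguous
    face overlaps and offset perpendicular to the smallest clash-free gap
    around 4.2 A.  Planted interface positions are the residues whose
    backbone-frame atoms (including a virtual CB, so the truth does not
    depend on the drawn sequence) lie within 5 A of the other body; the
    biased composition is drawn on exactly those positions.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues_per_side
    phi, psi = _dihedrals_for(spec.geometry, n, rng)
    bb = build_backbone(phi, psi)
    atoms_a = _stack_atoms(bb)

    ca = bb["CA"]
    axis = ca[-1] - ca[0]
    axis = axis / np.linalg.norm(axis)
    # dock along the backbone-plane normal (orthogonal to the chain axis) so
    # every residue of the contact face sits at a similar distance
    backbone = np.concatenate([bb[k] for k in ("N", "CA", "C")], axis=0)
    centred = backbone - backbone.mean(axis=0)
    normal = np.linalg.svd(centred, full_matrices=False)[2][-1]
    perp = normal - np.dot(normal, axis) * axis
    perp = perp / np.linalg.norm(perp)
    idx = int(np.argmax(np.abs(perp)))
    if perp[idx] < 0:  # deterministic orientation
        perp = -perp

    overlap = max(2, int(round(spec.interface_fraction * n)))
    rise = float(np.dot(ca[-1] - ca[0], axis)) / (n - 1)

    # body B is a copy of A rotated about the docking direction through the
    # mid-chain pivot: the two chain axes become skew lines whose closest
    # approach sits at both chains' midpoints, so the contact face is
    # central and no chain end is geometrically privileged; the crossing
    # angle sets the face length
    sin_alpha = min(0.9, 5.4 / (overlap * abs(rise)))
    alpha = math.asin(sin_alpha)
    rot = _rotation_about(perp, alpha)
    centre = ca[n // 2]
    atoms_b_local = (atoms_a - centre) @ rot.T + centre

    # flat sheet faces tolerate a wider gap than curved helix/blob surfaces
    gap = 4.2 if spec.geometry == "two-sheet-pack" else 3.6
    offset = _dock_offset(atoms_a, atoms_b_local, axis, perp, 0.0, target_gap=gap)

    bb_b = {
        k: (v - centre) @ rot.T + centre + offset for k, v in bb.items()
    }
    atoms_b = _stack_atoms(bb_b)

    # construction-time truth: any backbone-frame atom within the contact
    # distance of the other body
    from scipy.spatial.distance import cdist

    dmat = cdist(atoms_a, atoms_b)
    per_res_a = dmat.reshape(5, n, 5 * n).min(axis=(0, 2))
    per_res_b = dmat.reshape(5 * n, 5, n).min(axis=(0, 1))
    planted_a = {int(i) for i in np.nonzero(per_res_a < 5.0)[0]}
    planted_b = {int(i) for i in np.nonzero(per_res_b < 5.0)[0]}
    if not planted_a or not planted_b:
        raise ConfigError("infeasible spec: docking produced no contact face")

    seq_a = _draw_sequence(rng, n, planted_a, spec.composition_bias)
    seq_b = _draw_sequence(rng, n, planted_b, spec.composition_bias)

    lines: List[str] = []
    serial = 1
    for chain, seq, coords in (("A", seq_a, bb), ("B", seq_b, bb_b)):
        for i, aa in enumerate(seq):
            resname = _THREE[aa]
            names = ["N", "CA", "C", "O"] + ([] if aa == "G" else ["CB"])
            for name in names:
                elem = name[0]
                lines.append(
                    _pdb_atom_line(serial, name, resname, chain, i + 1, coords[name][i], elem)
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {_THREE[seq[-1]]:<3s} {chain:1s}{len(seq):4d}")
        serial += 1
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    truth = {
        "a": {("A", i + 1, "") for i in planted_a},
        "b": {("B", i + 1, "") for i in planted_b},
    }
    return ToyComplex(spec, pdb_text, {"A": seq_a, "B": seq_b}, truth)


def build_peptide(
    sequence: str,
    phi: Optional[Sequence[float]] = None,
    psi: Optional[Sequence[float]] = None,
    chain_id: str = "A",
    struct_id: str = "peptide",
) -> Structure:
    """Single-chain :class:`Structure` from ideal backbone geometry.

    Defaults to an extended conformation; pass per-residue dihedrals for
    helices etc.  Non-glycine residues carry one CB pseudo-atom.
    """
    from .structure import Atom, Residue

    n = len(sequence)
    if phi is None:
        phi = [-130.0] * n
    if psi is None:
        psi = [135.0] * n
    bb = build_backbone(list(phi), list(psi))
    residues = []
    for i, aa in enumerate(sequence):
        if aa not in _THREE:
            raise ParameterError(f"unknown residue code {aa!r}")
        names = ["N", "CA", "C", "O"] + ([] if aa == "G" else ["CB"])
        atoms = [
            Atom(
                name=name,
                element=name[0],
                coords=bb[name][i].copy(),
                vdw_radius=1.65 if name == "N" else (1.40 if name == "O" else 1.87),
                is_sidechain=name == "CB",
            )
            for name in names
        ]
        residues.append(Residue(chain_id, i + 1, "", aa, atoms))
    return Structure(struct_id, residues)


# ---------------------------------------------------------------------------
# Toy PSSMs
# ---------------------------------------------------------------------------

def _blosum62_matrix() -> Dict[str, Dict[str, int]]:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    return {
        a: {b: int(m[a, b]) for b in AMINO_ACIDS} for a in AMINO_ACIDS
    }


def make_toy_pssm(chain_residues, conservation_profile=0, chain_id=None) -> PssmProfile:
    """Toy PSI-BLAST profile: BLOSUM62 rows with the self-substitution score
    offset by ``conservation_profile`` (scalar or per-position sequence).

    ``chain_residues`` is a one-letter sequence or a list of residues.
    """
    if isinstance(chain_residues, str):
        seq = list(chain_residues)
    else:
        seq = [r.res_type for r in chain_residues]
    bad = [a for a in seq if a not in AMINO_ACIDS]
    if bad:
        raise ParameterError(f"nonstandard residues in PSSM request: {bad[:5]}")
    if np.isscalar(conservation_profile):
        offsets = [int(conservation_profile)] * len(seq)
    else:
        offsets = [int(v) for v in conservation_profile]
        if len(offsets) != len(seq):
            raise ParameterError("conservation_profile length mismatch")
    blosum = _blosum62_matrix()
    scores = np.array([[blosum[aa][b] for b in AMINO_ACIDS] for aa in seq], dtype=int)
    for i, aa in enumerate(seq):
        scores[i, AMINO_ACIDS.index(aa)] += offsets[i]
    return PssmProfile(seq, scores, chain_id=chain_id)


# ---------------------------------------------------------------------------
# Fixture sets on disk
# ---------------------------------------------------------------------------

def write_fixture_set(
    out_dir,
    n_complexes: int,
    base_spec: FixtureSpec = FixtureSpec(),
    seed: Optional[int] = None,
    pssm_offset: int = 0,
) -> Dict[str, Path]:
    """Write a batch of toy complexes plus manifests and toy PSSMs.

    Complex ``k`` uses ``seed + k`` (from ``base_spec.seed`` when ``seed`` is
    None).  Produces ``complexes.tsv`` (file, side_a, side_b), ``truth.tsv``
    (case, side, chain, resseq, icode) and one PSSM per chain.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed0 = base_spec.seed if seed is None else seed
    manifest_rows = ["file\tside_a\tside_b"]
    truth_rows = ["case\tside\tchain\tresseq\ticode"]
    for k in range(n_complexes):
        spec = FixtureSpec(
            seed=seed0 + k,
            n_residues_per_side=base_spec.n_residues_per_side,
            interface_fraction=base_spec.interface_fraction,
            composition_bias=dict(base_spec.composition_bias),
            geometry=base_spec.geometry,
        )
        toy = make_toy_complex(spec)
        name = f"complex_{k:03d}"
        (out / f"{name}.pdb").write_text(toy.pdb_text)
        manifest_rows.append(f"{name}.pdb\tA\tB")
        for side in ("a", "b"):
            for cid, resseq, icode in sorted(toy.truth[side]):
                truth_rows.append(f"{name}\t{side}\t{cid}\t{resseq}\t{icode}")
            chain = "A" if side == "a" else "B"
            profile = make_toy_pssm(toy.sequences[chain], pssm_offset, chain_id=chain)
            profile.write(out / f"{name}_{chain}.pssm")
            # unbound side structure, for prediction runs
            lines = [
                ln for ln in toy.pdb_text.splitlines()
                if len(ln) > 21 and ln[21] == chain
            ]
            (out / f"{name}_{chain}.pdb").write_text("\n".join(lines) + "\nEND\n")
    (out / "complexes.tsv").write_text("\n".join(manifest_rows) + "\n")
    (out / "truth.tsv").write_text("\n".join(truth_rows) + "\n")
    return {
        "manifest": out / "complexes.tsv",
        "truth": out / "truth.tsv",
        "dir": out,
    }
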