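"""Single-domain patch recognition: candidate interface patches and scoring.

The predictor works on an unbound domain in four steps: identify surface
residues; build the capped minimum side-chain distance matrix; grow one
candidate patch per surface residue (neighbours join when their distance bin
and ASA pass the packaged thresholds); merge overlapping patches (identity
ratio against a domain-size-dependent threshold).  Each candidate is then
scored by

    E_patch = E_res + w1 * E_hydro + w2 * E_cons + w3 * E_sol

where E_res sums ASA-weighted interface propensities normalised by reference
ASA, E_hydro sums a structure-derived hydrophobicity scale, E_cons sums
profile self-substitution scores minus the BLOSUM62 diagonal, and E_sol is a
curvature-like solvation term from the exposed volume of a 1.2 A probe
sphere per residue.  The top-ranked patch is the predicted interface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .constants import (
    DEFAULT_WEIGHTS,
    DISTANCE_CAP,
    PATCH_GROWTH,
    PROBE_RADIUS,
    SEED_CORE_DIST,
    SOLV_SPHERE_RADIUS,
    ConstantTables,
    constant_tables,
    merge_threshold_for,
)
from .errors import (
    ConfigError,
    ConstantsError,
    EmptyStructureError,
    GeometryError,
    ParameterError,
    StateError,
)
from .pssm import PssmProfile, check_alignment
from .structure import ResidueId, Structure, compute_asa, surface_residues

logger = logging.getLogger(__name__)

ESOL_CAP = 1e6  # documented cap for a probe sphere entirely outside the surface


@dataclass(frozen=True)
class ScoreWeights:
    w1: float = DEFAULT_WEIGHTS[0]  # hydrophobic
    w2: float = DEFAULT_WEIGHTS[1]  # conservation
    w3: float = DEFAULT_WEIGHTS[2]  # solvation

    def __post_init__(self) -> None:
        for name in ("w1", "w2", "w3"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


@dataclass
class SurfacePatch:
    """A candidate interface: a set of surface residues with its scores."""

    members: frozenset
    seed: Optional[ResidueId] = None  # unset after merging
    e_res: Optional[float] = None
    e_hydro: Optional[float] = None
    e_cons: Optional[float] = None
    e_sol: Optional[float] = None
    e_patch: Optional[float] = None
    flags: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if self.seed is not None and self.seed not in self.members:
            raise ParameterError("seed must be a patch member")

    def sort_key(self) -> Tuple:
        return tuple(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DistanceMatrix:
    """Capped minimum side-chain heavy-atom distances over surface residues."""

    ids: List[ResidueId]
    d: np.ndarray
    index: Dict[ResidueId, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.index = {rid: i for i, rid in enumerate(self.ids)}

    def distance(self, a: ResidueId, b: ResidueId) -> float:
        return float(self.d[self.index[a], self.index[b]])


def _distance_atoms(res) -> np.ndarray:
    """Side-chain heavy atoms; CA for glycine or missing side chains."""
    side = res.sidechain_atoms()
    if side:
        return np.array([a.coords for a in side])
    ca = res.atom("CA")
    if ca is None:
        if not res.atoms:
            raise GeometryError(f"residue {res.id} has no atoms")
        return np.array([res.atoms[0].coords])
    return ca.coords.reshape(1, 3)


def sidechain_distance_matrix(
    struct: Structure,
    surface: Optional[Iterable[ResidueId]] = None,
    cap: float = DISTANCE_CAP,
) -> DistanceMatrix:
    """Symmetric capped distance matrix over the domain's surface residues."""
    ids = sorted(surface) if surface is not None else sorted(surface_residues(struct))
    atom_sets = [_distance_atoms(struct[rid]) for rid in ids]
    n = len(ids)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            dij = float(cdist(atom_sets[i], atom_sets[j]).min())
            d[i, j] = d[j, i] = min(dij, cap)
    return DistanceMatrix(ids, d)


def grow_patch(
    seed: ResidueId,
    dm: DistanceMatrix,
    struct: Structure,
    thresholds: Sequence[Tuple[float, float, float]] = PATCH_GROWTH,
) -> SurfacePatch:
    """Grow one candidate patch around a seed surface residue.

    A neighbour at seed distance d joins when d falls in a threshold bin
    (lo, hi] and its ASA strictly exceeds the bin's minimum; d <=
    SEED_CORE_DIST joins unconditionally, beyond the last bin never.
    """
    if seed not in dm.index:
        raise ParameterError(f"seed {seed} is not a surface residue")
    members = {seed}
    row = dm.d[dm.index[seed]]
    for rid, d in zip(dm.ids, row):
        if rid == seed:
            continue
        if d <= SEED_CORE_DIST:
            members.add(rid)
            continue
        for lo, hi, min_asa in thresholds:
            if lo < d <= hi:
                if struct[rid].asa > min_asa:
                    members.add(rid)
                break
    return SurfacePatch(members=frozenset(members), seed=seed)


def generate_patches(
    struct: Structure, dm: Optional[DistanceMatrix] = None
) -> List[SurfacePatch]:
    """One grown patch per surface residue, in (chain, resseq, icode) order."""
    if dm is None:
        dm = sidechain_distance_matrix(struct)
    if not dm.ids:
        raise EmptyStructureError("no surface residues; nothing to predict")
    return [grow_patch(rid, dm, struct) for rid in dm.ids]


def identity_ratio(p1: SurfacePatch, p2: SurfacePatch) -> float:
    """Shared members over the smaller patch size."""
    inter = len(p1.members & p2.members)
    return inter / min(len(p1), len(p2))


def merge_patches(
    patches: Sequence[SurfacePatch],
    domain_asa: float,
    thresholds=None,
) -> List[SurfacePatch]:
    """Iteratively merge the most-overlapping admissible patch pair.

    Two patches are mergeable when their identity ratio is at least the
    threshold for the domain's ASA.  The currently highest-ratio pair (ties:
    lexicographically smallest member sets) is replaced by its union until no
    pair qualifies.  Deterministic; output sorted by member sets.
    """
    if thresholds is None:
        thr = merge_threshold_for(domain_asa)
    else:
        thr = None
        for lo, hi, t in thresholds:
            if lo < domain_asa <= hi:
                thr = t
                break
        if thr is None:
            raise ParameterError(f"no merge threshold covers domain ASA {domain_asa}")
    current = list(patches)
    while len(current) > 1:
        best = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                r = identity_ratio(current[i], current[j])
                if r < thr:
                    continue
                key = (-r, *sorted((current[i].sort_key(), current[j].sort_key())))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        union = SurfacePatch(members=current[i].members | current[j].members)
        current = [p for k, p in enumerate(current) if k not in (i, j)]
        current.append(union)
    return sorted(current, key=SurfacePatch.sort_key)


# ---------------------------------------------------------------------------
# Scoring terms
# ---------------------------------------------------------------------------

def _require_asa(struct: Structure) -> None:
    if any(r.asa is None for r in struct.residues):
        raise StateError("ASA not computed; call compute_asa first")


def score_eres(
    patch: SurfacePatch, struct: Structure, tables: Optional[ConstantTables] = None
) -> float:
    """Propensity term: sum of ASA_i * RIR_r / REF_r over patch members."""
    tables = tables or constant_tables()
    _require_asa(struct)
    total = 0.0
    for rid in patch.members:
        res = struct[rid]
        if not res.standard:
            logger.info("nonstandard residue %s contributes 0 to E_res", rid)
            continue
        try:
            total += res.asa * tables.qipi[res.res_type] / tables.ref_asa[res.res_type]
        except KeyError as exc:
            raise ConstantsError(f"missing constant for residue {res.res_type}") from exc
    return total


def score_ehydro(
    patch: SurfacePatch, struct: Structure, tables: Optional[ConstantTables] = None
) -> float:
    """Hydrophobic term: sum of the CASG920101 scale over patch members."""
    tables = tables or constant_tables()
    total = 0.0
    for rid in patch.members:
        res = struct[rid]
        if not res.standard:
            continue
        try:
            total += tables.hydro[res.res_type]
        except KeyError as exc:
            raise ConstantsError(f"missing constant for residue {res.res_type}") from exc
    return total


def _position_maps(struct: Structure, profiles: Mapping[str, PssmProfile]):
    """rid -> (profile, position) for every chain with a profile."""
    mapping = {}
    for cid, profile in profiles.items():
        chain = struct.chain(cid)
        check_alignment(profile, chain)
        for pos, res in enumerate(chain):
            mapping[res.id] = (profile, pos)
    return mapping


def score_econs(
    patch: SurfacePatch,
    struct: Structure,
    pssm,
    tables: Optional[ConstantTables] = None,
) -> float:
    """Conservation term: sum of (self-substitution score - BLOSUM62 diagonal).

    ``pssm`` is a :class:`PssmProfile` (single-chain domain) or a mapping
    chain id -> profile.
    """
    tables = tables or constant_tables()
    if pssm is None:
        raise ConfigError("conservation term requested but no PSSM provided")
    if isinstance(pssm, PssmProfile):
        cid = pssm.chain_id or struct.chain_ids()[0]
        profiles: Mapping[str, PssmProfile] = {cid: pssm}
    else:
        profiles = pssm
    pos_map = _position_maps(struct, profiles)
    total = 0.0
    for rid in patch.members:
        res = struct[rid]
        if not res.standard:
            continue
        if rid not in pos_map:
            raise ConfigError(f"no PSSM covers residue {rid}")
        profile, pos = pos_map[rid]
        total += profile.self_score(pos) - tables.blosum62_diag[res.res_type]
    return total


def _sphere_grid(radius: float, spacing: float) -> np.ndarray:
    """Deterministic cell-centred cubic grid inside a sphere at the origin.

    Cell centres (midpoint rule) avoid placing whole grid planes exactly on
    axis-aligned boundaries."""
    ax = np.arange(-radius + spacing / 2, radius, spacing)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    return pts[np.einsum("ij,ij->i", pts, pts) <= radius * radius]


def residue_esol(
    res,
    coords: np.ndarray,
    sas_radii: np.ndarray,
    tree: cKDTree,
    sphere_radius: float,
    grid: np.ndarray,
    flags: Optional[List[str]] = None,
) -> float:
    """Solvation term of one residue: V_out / (V_sphere - V_out).

    The probe sphere sits at the centroid of the residue's solvent-exposed
    heavy atoms (all atoms when none is exposed); V_out is the fraction of
    grid points outside every atom's solvent-accessible sphere.
    """
    exposed = [a for a in res.atoms if (a.asa or 0.0) > 0.0]
    anchor_atoms = exposed if exposed else res.atoms
    center = np.mean([a.coords for a in anchor_atoms], axis=0)
    pts = center + grid
    reach = sphere_radius + sas_radii.max()
    nbrs = tree.query_ball_point(center, r=reach)
    if nbrs:
        nbr = np.asarray(nbrs, dtype=int)
        diff = pts[:, None, :] - coords[nbr][None, :, :]
        dist2 = np.einsum("pkd,pkd->pk", diff, diff)
        inside = (dist2 < (sas_radii[nbr] ** 2)[None, :]).any(axis=1)
        frac_out = 1.0 - inside.mean()
    else:
        frac_out = 1.0
    if frac_out >= 1.0:
        if flags is not None:
            flags.append(f"esol_capped:{res.id}")
        return ESOL_CAP
    return frac_out / (1.0 - frac_out)


def score_esol(
    patch: SurfacePatch,
    struct: Structure,
    sphere_radius: float = SOLV_SPHERE_RADIUS,
    grid_spacing: float = 0.2,
    probe_radius: float = PROBE_RADIUS,
) -> float:
    """Solvation term: sum of per-residue exposed-volume ratios.

    V_out / (V_sphere - V_out) equals 0 for a probe sphere buried inside the
    solvent-accessible volume and ~1 for one bisected by a planar surface;
    a sphere entirely outside is capped at a large documented constant.
    """
    _require_asa(struct)
    coords, radii, _ = struct.atom_arrays()
    sas_radii = radii + probe_radius
    tree = cKDTree(coords)
    grid = _sphere_grid(sphere_radius, grid_spacing)
    total = 0.0
    for rid in sorted(patch.members):
        total += residue_esol(
            struct[rid], coords, sas_radii, tree, sphere_radius, grid, patch.flags
        )
    return total


def score_patch(
    patch: SurfacePatch,
    struct: Structure,
    weights: ScoreWeights = ScoreWeights(),
    pssm=None,
    tables: Optional[ConstantTables] = None,
    include_cons: bool = True,
    esol_grid_spacing: float = 0.2,
) -> SurfacePatch:
    """Fill all four component scores and the combined E_patch.

    When no PSSM is available and ``include_cons`` is False the conservation
    term contributes 0 (flagged); requesting it without a profile is an
    error.
    """
    tables = tables or constant_tables()
    patch.e_res = score_eres(patch, struct, tables)
    patch.e_hydro = score_ehydro(patch, struct, tables)
    if include_cons and pssm is not None:
        patch.e_cons = score_econs(patch, struct, pssm, tables)
    elif include_cons and pssm is None:
        raise ConfigError(
            "conservation term enabled but no PSSM given; pass include_cons=False"
        )
    else:
        if patch.e_cons is None:
            patch.flags.append("cons_disabled")
        patch.e_cons = 0.0
    patch.e_sol = score_esol(patch, struct, grid_spacing=esol_grid_spacing)
    patch.e_patch = (
        patch.e_res
        + weights.w1 * patch.e_hydro
        + weights.w2 * patch.e_cons
        + weights.w3 * patch.e_sol
    )
    return patch


def rank_patches(patches: Sequence[SurfacePatch]) -> List[SurfacePatch]:
    """Scored patches in rank order: higher E_patch, larger, lexicographic."""
    if any(p.e_patch is None for p in patches):
        raise StateError("patches must be scored before ranking")
    return sorted(patches, key=lambda p: (-p.e_patch, -len(p), p.sort_key()))


def predict_interface(
    struct: Structure,
    weights: ScoreWeights = ScoreWeights(),
    pssm=None,
    include_cons: Optional[bool] = None,
    n_points: int = 960,
    esol_grid_spacing: float = 0.2,
    return_all: bool = False,
):
    """Full pipeline on an unbound domain; returns the top-ranked patch.

    ``include_cons`` defaults to "use the conservation term iff a PSSM was
    given".  With ``return_all`` the complete ranking is returned instead.
    """
    if include_cons is None:
        include_cons = pssm is not None
    if any(r.asa is None for r in struct.residues):
        compute_asa(struct, n_points=n_points)
    dm = sidechain_distance_matrix(struct)
    patches = generate_patches(struct, dm)
    merged = merge_patches(patches, struct.total_asa)
    scored = [
        score_patch(
            p, struct, weights, pssm=pssm, include_cons=include_cons,
            esol_grid_spacing=esol_grid_spacing,
        )
        for p in merged
    ]
    ranking = rank_patches(scored)
    return ranking if return_all else ranking[0]
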