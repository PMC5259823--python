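"""Packaged constant tables used by the analysis and the patch predictor.

All residue-keyed tables cover exactly the 20 standard amino acids, one-letter
codes, in the PSI-BLAST column order ``ARNDCQEGHILKMFPSTWYV``.

Provenance of the numeric tables:

* ``QIPI`` -- the quantitative residue interface propensity index, i.e. the
  relative interface ratio (interface frequency over non-interface surface
  frequency) of each residue type estimated on a large non-redundant domain
  interface set.
* ``JANJ780101`` -- AAindex entry "Average accessible surface area
  (Janin et al., 1978)", used as the reference ASA in the propensity score.
* ``CASG920101`` -- AAindex entry "Hydrophobicity scale from native protein
  structures (Casari-Sippl, 1992)", the hydrophobic score.
* ``BLOSUM62_DIAG`` -- diagonal of BLOSUM62, the self-substitution baseline
  of the conservation score (cross-checked against biopython's matrix in the
  test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Tuple

from .errors import ParameterError

#: Canonical residue order (PSI-BLAST PSSM column order).
AMINO_ACIDS: str = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX: Mapping[str, int] = MappingProxyType({a: i for i, a in enumerate(AMINO_ACIDS)})

QIPI: Mapping[str, float] = MappingProxyType({
    "H": 1.147, "R": 1.346, "K": 0.784, "A": 0.841, "V": 0.994,
    "I": 1.084, "L": 1.144, "M": 1.451, "P": 1.109, "F": 1.334,
    "W": 1.284, "Y": 1.368, "G": 0.823, "C": 1.172, "S": 0.873,
    "T": 0.966, "N": 0.958, "Q": 0.909, "D": 0.830, "E": 0.805,
})

#: Average accessible surface area (A^2), AAindex JANJ780101.
JANJ780101: Mapping[str, float] = MappingProxyType({
    "A": 27.8, "R": 94.7, "N": 60.1, "D": 60.6, "C": 15.5,
    "Q": 68.7, "E": 68.2, "G": 24.5, "H": 50.7, "I": 22.8,
    "L": 27.6, "K": 103.0, "M": 33.5, "F": 25.5, "P": 51.5,
    "S": 42.0, "T": 45.0, "W": 34.7, "Y": 55.2, "V": 23.7,
})

#: Structure-derived hydrophobicity, AAindex CASG920101.
CASG920101: Mapping[str, float] = MappingProxyType({
    "A": 0.2, "R": -0.7, "N": -0.5, "D": -1.4, "C": 1.9,
    "Q": -1.1, "E": -1.3, "G": -0.1, "H": 0.4, "I": 1.4,
    "L": 0.5, "K": -1.6, "M": 0.5, "F": 1.0, "P": -1.0,
    "S": -0.7, "T": -0.4, "W": 1.6, "Y": 0.5, "V": 0.7,
})

#: Diagonal of BLOSUM62 (self-substitution scores).
BLOSUM62_DIAG: Mapping[str, int] = MappingProxyType({
    "A": 4, "R": 5, "N": 6, "D": 6, "C": 9, "Q": 5, "E": 5, "G": 6,
    "H": 8, "I": 4, "L": 4, "K": 5, "M": 5, "F": 6, "P": 7, "S": 4,
    "T": 5, "W": 11, "Y": 7, "V": 4,
})

#: Patch growth rule: (distance_lo, distance_hi, min ASA) -- a neighbour at
#: seed distance d in (lo, hi] joins the patch when its ASA exceeds min ASA.
#: Neighbours at d <= SEED_CORE_DIST join unconditionally; d > PATCH_MAX_DIST
#: never join.
PATCH_GROWTH: Tuple[Tuple[float, float, float], ...] = (
    (2.0, 5.0, 0.0),
    (5.0, 7.0, 20.0),
    (7.0, 9.0, 40.0),
    (9.0, 11.0, 60.0),
    (11.0, 13.0, 80.0),
    (13.0, 15.0, 100.0),
)
SEED_CORE_DIST: float = 2.0
PATCH_MAX_DIST: float = 15.0

#: Patch merge rule: (domain ASA lo, domain ASA hi, identity-ratio threshold).
MERGE_THRESHOLDS: Tuple[Tuple[float, float, float], ...] = (
    (0.0, 5000.0, 0.8),
    (5000.0, 7500.0, 0.7),
    (7500.0, 10000.0, 0.6),
    (10000.0, math.inf, 0.5),
)

#: Chemical groups used for the 4x4 aggregated contact preferences.
RESIDUE_GROUPS: Mapping[str, str] = MappingProxyType({
    **{a: "basic" for a in "HRK"},
    **{a: "hydrophobic" for a in "AVILMPFWGC"},
    **{a: "polar" for a in "YSTNQ"},
    **{a: "acidic" for a in "DE"},
})
GROUP_ORDER: Tuple[str, ...] = ("basic", "hydrophobic", "polar", "acidic")

#: Chothia-style van der Waals radii by element (A); unknown elements get
#: VDW_DEFAULT.
VDW_RADII: Mapping[str, float] = MappingProxyType({
    "C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80, "SE": 1.90,
})
VDW_DEFAULT: float = 1.80

PROBE_RADIUS: float = 1.4  # water probe, A
SURFACE_ASA_MIN: float = 1.0  # surface residue: ASA > 1 A^2
DELTA_ASA_MIN: float = 1.0  # interface residue: burial > 1 A^2 per site
CONTACT_DIST: float = 5.0  # cross-interface heavy-atom contact, A
DISTANCE_CAP: float = 25.0  # side-chain distance matrix cap, A
SOLV_SPHERE_RADIUS: float = 1.2  # solvation-term probe sphere, A

#: Default scoring weights (w1 hydrophobic, w2 conservation, w3 solvation):
#: the grid-search optimum from training on the packaged synthetic corpus
#: (40 annotated toy domains, grid {0, 0.25, 0.5, 1, 2} per weight, mean-F
#: objective); override via a weights JSON for structure-specific work.
DEFAULT_WEIGHTS: Tuple[float, float, float] = (2.0, 2.0, 0.0)


@dataclass(frozen=True)
class ConstantTables:
    """Bundle of every packaged constant table.

    Obtain the shared immutable instance via :func:`constant_tables` (also
    re-exported as ``qipi.fixtures.constants``).
    """

    qipi: Mapping[str, float] = field(default_factory=lambda: QIPI)
    ref_asa: Mapping[str, float] = field(default_factory=lambda: JANJ780101)
    hydro: Mapping[str, float] = field(default_factory=lambda: CASG920101)
    blosum62_diag: Mapping[str, int] = field(default_factory=lambda: BLOSUM62_DIAG)
    patch_growth: Tuple[Tuple[float, float, float], ...] = PATCH_GROWTH
    merge_thresholds: Tuple[Tuple[float, float, float], ...] = MERGE_THRESHOLDS


_TABLES = ConstantTables()


def constant_tables() -> ConstantTables:
    """Return the packaged constant tables (shared immutable instance)."""
    return _TABLES


def merge_threshold_for(domain_asa: float) -> float:
    """Identity-ratio threshold for merging patches on a domain of given ASA."""
    for lo, hi, thr in MERGE_THRESHOLDS:
        if lo < domain_asa <= hi:
            return thr
    raise ParameterError(f"domain ASA must be positive, got {domain_asa}")
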