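"""Interface extraction and propensity statistics.

Given a complex partitioned into two sides, a residue is an *interface*
residue when (i) it is a surface residue of its isolated side (ASA > 1 A^2),
(ii) its ASA drops by more than 1 A^2 upon complexation, and (iii) it has at
least one heavy atom within 5 A of the other side.  The remaining surface
residues are the *non-interface surface*, which serves as the reference state
for every propensity in this module: using surface residues as the reference
removes the solvent-accessibility bias that plagues whole-chain residue
compositions.

The statistics computed here are the relative interface ratio (RIR) per
residue type (the 20-type table is the quantitative interface propensity
index), per secondary-structure state and per residue x SS class (60 classes),
the per-type ASA threshold A_t with its 2x2 ASA-RIR, cross-interface contact
frequencies and log2 preferences, and interface/domain size distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    AMINO_ACIDS,
    AA_INDEX,
    CONTACT_DIST,
    DELTA_ASA_MIN,
    GROUP_ORDER,
    RESIDUE_GROUPS,
    SURFACE_ASA_MIN,
)
from .errors import EmptyStructureError, ParameterError, StateError
from .structure import ComplexPartition, ResidueId, Structure, compute_asa, surface_residues

SIDES = ("a", "b")


@dataclass
class InterfaceAnnotation:
    """Interface/non-interface partition of a complex's surface residues."""

    partition: ComplexPartition
    side_structures: Dict[str, Structure]
    interface_residues: Dict[str, Set[ResidueId]]
    noninterface_surface: Dict[str, Set[ResidueId]]
    delta_asa: Dict[ResidueId, float]
    interface_area: Dict[str, float]
    cross_contacts: Set[Tuple[ResidueId, ResidueId]]  # (side-a residue, side-b residue)

    def residues(self, side: str, which: str) -> List:
        """Residue objects (with unbound ASA/SS) for one side and category."""
        ids = (
            self.interface_residues if which == "interface" else self.noninterface_surface
        )[side]
        struct = self.side_structures[side]
        return [struct[rid] for rid in sorted(ids)]

    def iter_residues(self, which: str):
        for side in SIDES:
            yield from self.residues(side, which)


def extract_interface(
    partition: ComplexPartition,
    delta_asa_min: float = DELTA_ASA_MIN,
    contact_dist: float = CONTACT_DIST,
    surface_asa_min: float = SURFACE_ASA_MIN,
    n_points: int = 960,
) -> InterfaceAnnotation:
    """Classify each side's surface residues as interface / non-interface.

    ASA is computed on the full complex and on each isolated side; the
    per-residue burial is ``delta_asa = ASA(isolated side) - ASA(complex)``.
    Contacts are heavy-atom pairs across the partition at strictly less than
    ``contact_dist``; ``cross_contacts`` records every such residue pair
    regardless of the burial criterion.
    """
    cx = partition.complex
    if any(r.asa is None for r in cx.residues):
        compute_asa(cx, n_points=n_points)
    sides = {
        "a": cx.subset(partition.side_a, new_id=f"{cx.id}:a"),
        "b": cx.subset(partition.side_b, new_id=f"{cx.id}:b"),
    }
    for s in sides.values():
        if not s.residues:
            raise EmptyStructureError("empty partition side")
        compute_asa(s, n_points=n_points)
        # carry secondary structure over from the complex (sequence-local)
        for r in s.residues:
            r.ss_state = cx[r.id].ss_state

    complex_asa = {r.id: r.asa for r in cx.residues}
    delta: Dict[ResidueId, float] = {}
    surface: Dict[str, Set[ResidueId]] = {}
    for key, s in sides.items():
        for r in s.residues:
            delta[r.id] = r.asa - complex_asa[r.id]
        surface[key] = surface_residues(s, asa_min=surface_asa_min)

    # cross-side heavy-atom contacts
    coords = {}
    owner = {}
    for key, chain_set in (("a", partition.side_a), ("b", partition.side_b)):
        pts, own = [], []
        for r in cx.residues:
            if r.chain_id in chain_set:
                for a in r.atoms:
                    pts.append(a.coords)
                    own.append(r.id)
        coords[key] = np.asarray(pts)
        owner[key] = own
    tree_b = cKDTree(coords["b"])
    contacts: Set[Tuple[ResidueId, ResidueId]] = set()
    pairs = cKDTree(coords["a"]).query_ball_tree(tree_b, r=contact_dist)
    for ia, hits in enumerate(pairs):
        for ib in hits:
            d = np.linalg.norm(coords["a"][ia] - coords["b"][ib])
            if d < contact_dist:  # strict
                contacts.add((owner["a"][ia], owner["b"][ib]))

    in_contact = {
        "a": {p[0] for p in contacts},
        "b": {p[1] for p in contacts},
    }
    interface: Dict[str, Set[ResidueId]] = {}
    noniface: Dict[str, Set[ResidueId]] = {}
    area: Dict[str, float] = {}
    for key in SIDES:
        iface = {
            rid
            for rid in surface[key]
            if delta[rid] > delta_asa_min and rid in in_contact[key]
        }
        interface[key] = iface
        noniface[key] = surface[key] - iface
        area[key] = float(sum(delta[rid] for rid in iface))
    return InterfaceAnnotation(
        partition=partition,
        side_structures=sides,
        interface_residues=interface,
        noninterface_surface=noniface,
        delta_asa=delta,
        interface_area=area,
        cross_contacts=contacts,
    )


# ---------------------------------------------------------------------------
# Propensity tables
# ---------------------------------------------------------------------------

@dataclass
class PropensityTable:
    """Interface vs non-interface surface frequencies and their ratio (RIR).

    ``rir[key]`` is None when the non-interface frequency is zero and no
    pseudocount was applied (undefined, deliberately not smoothed).
    """

    keys: List
    f: Dict  # interface counts
    F: Dict  # non-interface surface counts
    w: Dict  # interface frequencies
    W: Dict  # non-interface frequencies
    rir: Dict
    pseudocount: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "key": [str(k) for k in self.keys],
                "f": [self.f[k] for k in self.keys],
                "F": [self.F[k] for k in self.keys],
                "w": [self.w[k] for k in self.keys],
                "W": [self.W[k] for k in self.keys],
                "RIR": [
                    float("nan") if self.rir[k] is None else self.rir[k]
                    for k in self.keys
                ],
            }
        )

    def write_tsv(self, path) -> None:
        df = self.to_frame().copy()
        for col in ("w", "W", "RIR"):
            df[col] = df[col].map(lambda v: f"{v:.3f}" if v == v else "NA")
        df.to_csv(path, sep="\t", index=False)


def compute_rir(
    interface_counts: Mapping,
    noninterface_counts: Mapping,
    pseudocount: float = 0.0,
) -> PropensityTable:
    """Build a propensity table from raw interface / non-interface counts.

    ``w_i = f_i / sum(f)``, ``W_i = F_i / sum(F)``, ``RIR_i = w_i / W_i``.
    A pseudocount, when given, is added to every class on both sides before
    normalisation.  Values are kept at full precision; rounding is left to
    report time.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be >= 0")
    keys = list(dict.fromkeys(list(interface_counts) + list(noninterface_counts)))
    f = {k: interface_counts.get(k, 0) + pseudocount for k in keys}
    F = {k: noninterface_counts.get(k, 0) + pseudocount for k in keys}
    tot_f, tot_F = sum(f.values()), sum(F.values())
    if tot_f <= 0 or tot_F <= 0:
        raise ParameterError("total counts must be positive on both sides")
    w = {k: f[k] / tot_f for k in keys}
    W = {k: F[k] / tot_F for k in keys}
    rir = {k: (w[k] / W[k] if W[k] > 0 else None) for k in keys}
    return PropensityTable(keys, f, F, w, W, rir, pseudocount)


def propensity_counts(
    annotations: Iterable[InterfaceAnnotation], key: str = "res_type"
) -> Tuple[Dict, Dict]:
    """Count standard residues by class over a set of annotations.

    ``key``: ``"res_type"`` (20 classes), ``"ss"`` (3 states) or ``"res_ss"``
    (60 classes).  Secondary structure must be assigned for the SS keys.
    """

    def classify(res):
        if key == "res_type":
            return res.res_type
        if res.ss_state is None:
            raise StateError(f"residue {res.id}: secondary structure not assigned")
        if key == "ss":
            return res.ss_state
        if key == "res_ss":
            return (res.res_type, res.ss_state)
        raise ParameterError(f"unknown propensity key {key!r}")

    f: Dict = {}
    F: Dict = {}
    for ann in annotations:
        for res in ann.iter_residues("interface"):
            if res.standard:
                c = classify(res)
                f[c] = f.get(c, 0) + 1
        for res in ann.iter_residues("noninterface"):
            if res.standard:
                c = classify(res)
                F[c] = F.get(c, 0) + 1
    return f, F


def residue_rir(
    annotations: Sequence[InterfaceAnnotation], pseudocount: float = 0.0
) -> PropensityTable:
    """The 20-type RIR table (regeneration path for the propensity index)."""
    f, F = propensity_counts(annotations, "res_type")
    return compute_rir(f, F, pseudocount)


def ss_and_class60_rir(
    annotations: Sequence[InterfaceAnnotation], pseudocount: float = 0.0
) -> Tuple[PropensityTable, PropensityTable]:
    """3-state secondary-structure RIR and the 60-class (residue x SS) RIR."""
    anns = list(annotations)
    f3, F3 = propensity_counts(anns, "ss")
    f60, F60 = propensity_counts(anns, "res_ss")
    return compute_rir(f3, F3, pseudocount), compute_rir(f60, F60, pseudocount)


# ---------------------------------------------------------------------------
# ASA threshold and ASA-RIR
# ---------------------------------------------------------------------------

@dataclass
class AsaClassCounts:
    """2x2 ASA-class counts around the threshold A_t for one residue type.

    ``asa_rir = (f_IL/f_IS) / (f_SL/f_SS)`` with I = interface, S(first
    subscript) = non-interface surface, S/L (second subscript) = ASA below /
    at-or-above A_t.  ``a_t`` is None when the two normalised ASA histograms
    never cross (threshold undefined).
    """

    res_type: str
    a_t: Optional[float]
    f_IS: int = 0
    f_IL: int = 0
    f_SS: int = 0
    f_SL: int = 0

    @property
    def asa_rir(self) -> Optional[float]:
        if self.a_t is None or min(self.f_IS, self.f_SL, self.f_SS) <= 0:
            return None
        return (self.f_IL / self.f_IS) / (self.f_SL / self.f_SS)


def asa_threshold_from_samples(
    iface_asa: Sequence[float],
    non_asa: Sequence[float],
    bin_width: float = 5.0,
    res_type: str = "",
) -> AsaClassCounts:
    """A_t and 2x2 counts from raw ASA samples.

    Both samples are histogrammed on shared ``bin_width`` bins; A_t is the
    lower edge of the first bin at which the difference of normalised
    frequencies changes sign (smallest such ASA on ties); None when the
    histograms never cross.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if not len(iface_asa) or not len(non_asa):
        return AsaClassCounts(res_type, None)
    hi = max(max(iface_asa), max(non_asa))
    edges = np.arange(0.0, hi + 2 * bin_width, bin_width)
    p_int, _ = np.histogram(iface_asa, bins=edges)
    p_non, _ = np.histogram(non_asa, bins=edges)
    diff = p_int / p_int.sum() - p_non / p_non.sum()
    signs = np.sign(diff)
    nonzero = np.nonzero(signs)[0]
    a_t: Optional[float] = None
    if nonzero.size:
        s0 = signs[nonzero[0]]
        flip = [i for i in nonzero if signs[i] == -s0]
        if flip:
            a_t = float(edges[flip[0]])
    counts = AsaClassCounts(res_type, a_t)
    if a_t is not None:
        counts.f_IS = sum(1 for x in iface_asa if x < a_t)
        counts.f_IL = sum(1 for x in iface_asa if x >= a_t)
        counts.f_SS = sum(1 for x in non_asa if x < a_t)
        counts.f_SL = sum(1 for x in non_asa if x >= a_t)
    return counts


def asa_threshold_and_rir(
    annotations: Sequence[InterfaceAnnotation],
    res_type: str,
    bin_width: float = 5.0,
) -> AsaClassCounts:
    """A_t and the 2x2 ASA-RIR for one residue type over an annotation set.

    The samples are the unbound-side ASA values of interface and of
    non-interface surface residues of the type; see
    :func:`asa_threshold_from_samples` for the threshold rule.
    """
    iface_asa = [
        r.asa for ann in annotations for r in ann.iter_residues("interface")
        if r.res_type == res_type
    ]
    non_asa = [
        r.asa for ann in annotations for r in ann.iter_residues("noninterface")
        if r.res_type == res_type
    ]
    return asa_threshold_from_samples(iface_asa, non_asa, bin_width, res_type)


def asa_threshold_table(
    annotations: Sequence[InterfaceAnnotation], bin_width: float = 5.0
) -> pd.DataFrame:
    """A_t / ASA-RIR rows for all 20 residue types."""
    rows = []
    for aa in AMINO_ACIDS:
        c = asa_threshold_and_rir(annotations, aa, bin_width)
        rows.append(
            {
                "res_type": aa,
                "A_t": c.a_t,
                "f_IS": c.f_IS,
                "f_IL": c.f_IL,
                "f_SS": c.f_SS,
                "f_SL": c.f_SL,
                "asa_rir": c.asa_rir,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contact statistics
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Cross-interface residue-type contact counts, frequencies, preferences.

    ``counts`` holds one count per contacting residue pair (unordered types,
    i=j counted once); ``freq`` is counts normalised by the total number of
    contacts.  ``pref`` is the log2 ratio of the observed contact frequency to
    the frequency expected if the two sides' interface residues paired
    independently: the expected probability of an unordered type pair {i,j}
    is ``(2 - delta_ij) * w_i * w_j`` (equivalently, the textbook formula
    evaluated on the symmetric contact matrix with a doubled diagonal).
    Cells with zero observed contacts are NaN, not zero.
    """

    labels: List[str]
    counts: pd.DataFrame
    freq: pd.DataFrame
    pref: pd.DataFrame
    groups4: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.labels):
            for b in self.labels[i:]:
                rows.append(
                    {
                        "type_i": a,
                        "type_j": b,
                        "count": self.counts.loc[a, b],
                        "freq": self.freq.loc[a, b],
                        "pref": self.pref.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def preference_from_counts(
    counts: np.ndarray, labels: Sequence[str], weights: np.ndarray
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts / frequency / log2-preference frames from a symmetric contact
    count matrix (off-diagonal mirrored, diagonal counted once) and the
    per-type frequencies ``weights``.  See :class:`ContactMatrix` for the
    conventions."""
    # counts is symmetric (off-diagonal mirrored, diagonal once); the number
    # of distinct contacts is the upper triangle including the diagonal
    total = (counts.sum() + np.trace(counts)) / 2.0
    freq = counts.astype(float) / total
    expected = np.outer(weights, weights) * (2.0 - np.eye(len(labels)))
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = np.where(
            (freq > 0) & (expected > 0), np.log2(freq / expected), np.nan
        )
    cdf = pd.DataFrame(counts, index=labels, columns=labels)
    fdf = pd.DataFrame(freq, index=labels, columns=labels)
    pdf = pd.DataFrame(pref, index=labels, columns=labels)
    return cdf, fdf, pdf


def contact_statistics(annotations: Sequence[InterfaceAnnotation]) -> ContactMatrix:
    """Contact counts/frequencies/preferences between interface residue types.

    Counting unit: one count per contacting residue pair whose two residues
    are both interface residues of their sides and both standard.  ``w_i``
    used in the preference is the interface residue frequency from the same
    annotation set.
    """
    n = len(AMINO_ACIDS)
    C = np.zeros((n, n), dtype=float)
    total_pairs = 0
    for ann in annotations:
        struct_a, struct_b = ann.side_structures["a"], ann.side_structures["b"]
        for rid_a, rid_b in ann.cross_contacts:
            if rid_a not in ann.interface_residues["a"]:
                continue
            if rid_b not in ann.interface_residues["b"]:
                continue
            ra, rb = struct_a[rid_a], struct_b[rid_b]
            if not (ra.standard and rb.standard):
                continue
            i, j = AA_INDEX[ra.res_type], AA_INDEX[rb.res_type]
            C[i, j] += 1
            if i != j:
                C[j, i] += 1
            total_pairs += 1
    if total_pairs == 0:
        raise EmptyStructureError("no cross-interface contacts in annotation set")

    tbl = residue_rir(list(annotations))
    w = np.array([tbl.w.get(a, 0.0) for a in AMINO_ACIDS])
    labels = list(AMINO_ACIDS)
    cdf, fdf, pdf = preference_from_counts(C, labels, w)

    # 4-group aggregation: pool counts and frequencies by chemical group
    g = len(GROUP_ORDER)
    gidx = {name: k for k, name in enumerate(GROUP_ORDER)}
    Cg = np.zeros((g, g), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if j < i:
                continue
            gi, gj = gidx[RESIDUE_GROUPS[a]], gidx[RESIDUE_GROUPS[b]]
            cnt = C[i, j]
            if gi == gj:
                Cg[gi, gj] += cnt
            else:
                Cg[gi, gj] += cnt
                Cg[gj, gi] += cnt
    wg = np.array(
        [sum(w[AA_INDEX[a]] for a in AMINO_ACIDS if RESIDUE_GROUPS[a] == gname)
         for gname in GROUP_ORDER]
    )
    _, gfdf, gpdf = preference_from_counts(Cg, list(GROUP_ORDER), wg)
    groups4 = pd.concat({"freq": gfdf, "pref": gpdf}, axis=0)
    return ContactMatrix(labels, cdf, fdf, pdf, groups4)


# ---------------------------------------------------------------------------
# Size distributions
# ---------------------------------------------------------------------------

def _gamma_mom(values: np.ndarray) -> Tuple[float, float]:
    """Method-of-moments gamma fit: shape k = mean^2/var, scale = var/mean."""
    mean = float(np.mean(values))
    var = float(np.var(values))
    if mean <= 0 or var <= 0:
        return float("nan"), float("nan")
    return mean * mean / var, var / mean


@dataclass
class SizeSummary:
    per_side: pd.DataFrame  # one row per interface side
    per_domain: pd.DataFrame  # one row per domain
    stats: pd.DataFrame  # mean/median/gamma parameters per quantity
    histograms: Dict[str, Tuple[np.ndarray, np.ndarray]] = None  # counts, edges


def size_distributions(annotations: Sequence[InterfaceAnnotation]) -> SizeSummary:
    """Interface area / residue-count / domain-size summaries.

    Interface size per side is the sum of per-residue burial (delta ASA) over
    that side's interface residues; domain size is the isolated side's total
    ASA.  The stats table reports mean, median and a method-of-moments gamma
    fit per quantity.
    """
    side_rows, dom_rows = [], []
    for ann in annotations:
        for side in SIDES:
            side_rows.append(
                {
                    "complex": ann.partition.complex.id,
                    "side": side,
                    "interface_area": ann.interface_area[side],
                    "n_interface": len(ann.interface_residues[side]),
                }
            )
            dom_rows.append(
                {
                    "complex": ann.partition.complex.id,
                    "side": side,
                    "domain_asa": ann.side_structures[side].total_asa,
                }
            )
    per_side = pd.DataFrame(side_rows)
    per_domain = pd.DataFrame(dom_rows)
    stat_rows = []
    series = [
        ("interface_area", per_side["interface_area"] if len(per_side) else pd.Series(dtype=float)),
        ("n_interface", per_side["n_interface"] if len(per_side) else pd.Series(dtype=float)),
        ("domain_asa", per_domain["domain_asa"] if len(per_domain) else pd.Series(dtype=float)),
    ]
    histograms: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for name, s in series:
        vals = np.asarray(s, dtype=float)
        if vals.size == 0:
            continue
        k, theta = _gamma_mom(vals)
        counts, edges = np.histogram(vals, bins="auto")
        histograms[name] = (counts, edges)
        stat_rows.append(
            {
                "quantity": name,
                "n": vals.size,
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "gamma_shape": k,
                "gamma_scale": theta,
            }
        )
    return SizeSummary(per_side, per_domain, pd.DataFrame(stat_rows), histograms)
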