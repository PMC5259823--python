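"""Interface extraction rules and propensity statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qipi.constants import AMINO_ACIDS
from qipi.errors import ParameterError
from qipi.interface import (
    AsaClassCounts,
    InterfaceAnnotation,
    asa_threshold_from_samples,
    compute_rir,
    contact_statistics,
    extract_interface,
    propensity_counts,
    residue_rir,
    size_distributions,
    ss_and_class60_rir,
    _gamma_mom,
)
from qipi.structure import Atom, ComplexPartition, Residue, Structure


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def single_atom_complex(distance, radius_b=1.87, radius_a=1.87):
    """Two chains of one single-atom residue each, a controlled gap apart."""
    residues = [
        Residue("A", 1, "", "G", [Atom("CA", "C", np.zeros(3), radius_a, False)]),
        Residue("B", 1, "", "G", [Atom("CA", "C", np.array([distance, 0.0, 0.0]), radius_b, False)]),
    ]
    struct = Structure("pair", residues)
    return ComplexPartition(struct, {"A"}, {"B"})


def fabricate_annotation(side_a, side_b, interface_a, interface_b, contacts=(),
                         delta=None):
    """Annotation from explicit residue specs.

    ``side_a``/``side_b``: list of (resseq, res_type, ss, asa).
    ``interface_a``/``interface_b``: resseq sets.
    """
    def build(chain, entries):
        residues = []
        for resseq, aa, ss, asa in entries:
            res = Residue(chain, resseq, "", aa,
                          [Atom("CA", "C", np.array([float(resseq), 0, 0]), 1.87, False)])
            res.ss_state = ss
            res.asa = asa
            res.atoms[0].asa = asa
            residues.append(res)
        return Structure(chain, residues)

    sa, sb = build("A", side_a), build("B", side_b)
    cx = Structure("cx", [*build("A", side_a).residues, *build("B", side_b).residues])
    for r in cx.residues:
        r.asa = 0.0
    part = ComplexPartition(cx, {"A"}, {"B"})
    iface = {
        "a": {("A", i, "") for i in interface_a},
        "b": {("B", i, "") for i in interface_b},
    }
    surf = {
        "a": {r.id for r in sa.residues} - iface["a"],
        "b": {r.id for r in sb.residues} - iface["b"],
    }
    delta = delta or {}
    return InterfaceAnnotation(
        partition=part,
        side_structures={"a": sa, "b": sb},
        interface_residues=iface,
        noninterface_surface=surf,
        delta_asa=delta,
        interface_area={
            s: sum(delta.get(rid, 0.0) for rid in iface[s]) for s in ("a", "b")
        },
        cross_contacts=set(contacts),
    )


# ---------------------------------------------------------------------------
# extraction rules
# ---------------------------------------------------------------------------

class TestExtractionRules:
    def test_contact_inside_cutoff_is_interface(self):
        ann = extract_interface(single_atom_complex(4.9))
        assert ("A", 1, "") in ann.interface_residues["a"]

    def test_contact_outside_cutoff_is_not_interface(self):
        """Large burial but nearest cross atom at 5.1 A fails the rule."""
        ann = extract_interface(single_atom_complex(5.1))
        assert ann.delta_asa[("A", 1, "")] > 1.0  # burial alone is not enough
        assert ("A", 1, "") in ann.noninterface_surface["a"]

    def test_small_burial_is_not_interface(self):
        """In contact but ASA change ~0.5 A^2 stays below the 1 A^2 rule."""
        ann = extract_interface(single_atom_complex(4.9, radius_b=0.3))
        assert 0.0 < ann.delta_asa[("A", 1, "")] < 1.0
        assert ("A", 1, "") in ann.noninterface_surface["a"]

    def test_burial_above_threshold_is_interface(self):
        ann = extract_interface(single_atom_complex(4.9, radius_b=0.5))
        assert ann.delta_asa[("A", 1, "")] > 1.0
        assert ("A", 1, "") in ann.interface_residues["a"]

    def test_interface_and_noninterface_disjoint(self, toy_annotation):
        for side in ("a", "b"):
            assert not (
                toy_annotation.interface_residues[side]
                & toy_annotation.noninterface_surface[side]
            )

    def test_every_interface_residue_has_contact_and_burial(self, toy_annotation):
        contact_a = {p[0] for p in toy_annotation.cross_contacts}
        contact_b = {p[1] for p in toy_annotation.cross_contacts}
        for side, in_contact in (("a", contact_a), ("b", contact_b)):
            for rid in toy_annotation.interface_residues[side]:
                assert rid in in_contact
                assert toy_annotation.delta_asa[rid] > 1.0

    def test_interface_area_is_burial_sum(self, toy_annotation):
        for side in ("a", "b"):
            expected = sum(
                toy_annotation.delta_asa[rid]
                for rid in toy_annotation.interface_residues[side]
            )
            assert toy_annotation.interface_area[side] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# RIR
# ---------------------------------------------------------------------------

class TestRir:
    def test_hand_example(self):
        tbl = compute_rir({"A": 30, "G": 10}, {"A": 60, "G": 140})
        assert tbl.w["A"] == pytest.approx(0.75)
        assert tbl.W["A"] == pytest.approx(0.3)
        assert tbl.rir["A"] == pytest.approx(2.5)
        assert tbl.rir["G"] == pytest.approx(0.357, abs=5e-4)

    def test_identical_composition_gives_unity(self):
        counts = {"A": 5, "G": 7, "M": 3}
        tbl = compute_rir(counts, counts)
        assert all(v == pytest.approx(1.0) for v in tbl.rir.values())

    def test_zero_reference_flagged_not_raised(self):
        tbl = compute_rir({"A": 2, "W": 1}, {"A": 4})
        assert tbl.rir["W"] is None
        smoothed = compute_rir({"A": 2, "W": 1}, {"A": 4}, pseudocount=1)
        assert smoothed.rir["W"] is not None

    def test_frequencies_normalised(self):
        tbl = compute_rir({"A": 3, "G": 9, "M": 1}, {"A": 4, "G": 1, "M": 7})
        assert sum(tbl.w.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(tbl.W.values()) == pytest.approx(1.0, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_recount_oracle(self, seed):
        """compute_rir equals a from-scratch recount on raw residue lists."""
        rng = np.random.default_rng(seed)
        types = list("AGMWK")
        iface = [types[i] for i in rng.integers(0, 5, size=40)]
        non = [types[i] for i in rng.integers(0, 5, size=60)]
        tbl = compute_rir(
            {t: iface.count(t) for t in types}, {t: non.count(t) for t in types}
        )
        for t in types:
            w = iface.count(t) / len(iface)
            W = non.count(t) / len(non)
            assert tbl.w[t] == pytest.approx(w)
            if W > 0:
                assert tbl.rir[t] == pytest.approx(w / W)
            else:
                assert tbl.rir[t] is None

    def test_sixty_class_marginalises_exactly(self, batch_annotations):
        f60, F60 = propensity_counts(batch_annotations, "res_ss")
        f20, F20 = propensity_counts(batch_annotations, "res_type")
        f3, F3 = propensity_counts(batch_annotations, "ss")
        for aa in {k[0] for k in f60}:
            assert sum(v for (a, s), v in f60.items() if a == aa) == f20.get(aa, 0)
        for ss in "HEC":
            assert sum(v for (a, s), v in f60.items() if s == ss) == f3.get(ss, 0)
            assert sum(v for (a, s), v in F60.items() if s == ss) == F3.get(ss, 0)

    def test_ss_imbalance_direction(self):
        """All-coil interface against a mixed surface turns RIR_C above 1."""
        side_a = [(i, "A", "C" if i <= 6 else "H", 50.0) for i in range(1, 13)]
        ann = fabricate_annotation(side_a, side_a, {1, 2, 3, 4}, {1, 2, 3, 4})
        t3, _ = ss_and_class60_rir([ann])
        assert t3.rir["C"] > 1.0
        assert t3.rir["H"] is None or t3.rir["H"] < 1.0

    def test_batch_enrichment_detected(self, batch_annotations):
        """Types planted at 3x enrichment come out with RIR above 1."""
        tbl = residue_rir(batch_annotations)
        for aa in "MYRFW":
            assert tbl.rir[aa] is not None and tbl.rir[aa] > 1.0


# ---------------------------------------------------------------------------
# ASA threshold
# ---------------------------------------------------------------------------

class TestAsaThreshold:
    def test_overlapping_uniforms_cross_in_overlap(self):
        rng = np.random.default_rng(0)
        iface = rng.uniform(20, 60, 2000)
        non = rng.uniform(0, 40, 2000)
        counts = asa_threshold_from_samples(iface, non, bin_width=5.0)
        assert counts.a_t is not None and 20.0 <= counts.a_t <= 40.0
        # when the crossing coincides with the support edge the low-ASA
        # interface cell is empty and the 2x2 ratio is flagged undefined
        if counts.f_IS > 0:
            assert counts.asa_rir > 1.0

    def test_ratio_above_one_when_interface_shifted_high(self):
        rng = np.random.default_rng(2)
        iface = rng.uniform(15, 60, 2000)
        non = rng.uniform(0, 40, 2000)
        counts = asa_threshold_from_samples(iface, non, bin_width=5.0)
        assert counts.a_t is not None and 15.0 <= counts.a_t <= 40.0
        assert counts.asa_rir is not None and counts.asa_rir > 1.0

    def test_identical_distributions_near_unity(self):
        rng = np.random.default_rng(1)
        iface = rng.uniform(0, 80, 4000)
        non = rng.uniform(0, 80, 4000)
        counts = asa_threshold_from_samples(iface, non, bin_width=5.0)
        if counts.asa_rir is not None:
            assert counts.asa_rir == pytest.approx(1.0, rel=0.25)

    def test_disjoint_samples_cross_at_gap(self):
        iface = np.linspace(50, 70, 100)
        non = np.linspace(5, 30, 100)
        counts = asa_threshold_from_samples(iface, non, bin_width=5.0)
        assert 30.0 <= counts.a_t <= 50.0
        # brute-force recount around the reported threshold
        assert counts.f_IS == int(np.sum(iface < counts.a_t))
        assert counts.f_IL == int(np.sum(iface >= counts.a_t))
        assert counts.f_SS == int(np.sum(non < counts.a_t))
        assert counts.f_SL == int(np.sum(non >= counts.a_t))
        assert counts.f_IS == 0  # interface sample entirely above the gap
        assert counts.asa_rir is None  # 2x2 ratio undefined with empty cell

    def test_empty_sample_flagged(self):
        counts = asa_threshold_from_samples([], [1.0, 2.0])
        assert counts.a_t is None and counts.asa_rir is None


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def two_type_annotation(pairs, extra_iface_a=()):
    """Annotation over 8 residues per side: odd resseq type A, even type G.

    Interface residues are those named in ``pairs`` (plus ``extra_iface_a``
    on side a); the remaining residues form the non-interface surface.
    """
    def typ(i):
        return "A" if i % 2 else "G"

    side = [(i, typ(i), "C", 50.0) for i in range(1, 9)]
    iface_a = {p[0] for p in pairs} | set(extra_iface_a)
    iface_b = {p[1] for p in pairs}
    contacts = {(("A", i, ""), ("B", j, "")) for i, j in pairs}
    return fabricate_annotation(side, side, iface_a, iface_b, contacts)


class TestContacts:
    def test_same_type_only_contacts(self):
        """Contacts only between type-A residues: freq_AA = 1 and the
        preference equals the log-ratio against the independence null."""
        ann = two_type_annotation([(1, 1), (3, 3), (1, 3), (3, 1)],
                                  extra_iface_a=(2, 4))
        cm = contact_statistics([ann])
        w_a = residue_rir([ann]).w["A"]
        assert cm.freq.loc["A", "A"] == pytest.approx(1.0)
        assert cm.pref.loc["A", "A"] == pytest.approx(np.log2(1.0 / w_a**2))

    def test_single_cross_type_contact_normalisation(self):
        ann = two_type_annotation([(1, 2)])
        cm = contact_statistics([ann])
        assert cm.freq.loc["A", "G"] == pytest.approx(1.0)
        upper = np.triu(cm.freq.values)
        assert np.nansum(upper) == pytest.approx(1.0, abs=1e-9)

    def test_counts_symmetric(self, batch_annotations):
        cm = contact_statistics(batch_annotations)
        assert np.array_equal(cm.counts.values, cm.counts.values.T)
        upper = np.triu(cm.freq.values)
        assert np.nansum(upper) == pytest.approx(1.0, abs=1e-9)

    def test_zero_count_cells_are_nan_not_zero(self, batch_annotations):
        cm = contact_statistics(batch_annotations)
        zero = cm.counts.values == 0
        assert np.all(np.isnan(cm.pref.values[zero]))


# ---------------------------------------------------------------------------
# sizes
# ---------------------------------------------------------------------------

class TestSizes:
    def test_direct_sum_example(self):
        ann = fabricate_annotation(
            [(1, "A", "C", 50.0), (2, "G", "C", 50.0)],
            [(1, "A", "C", 50.0)],
            {1, 2}, {1},
            delta={("A", 1, ""): 3.0, ("A", 2, ""): 4.0, ("B", 1, ""): 5.0},
        )
        summary = size_distributions([ann])
        row = summary.per_side.set_index("side")
        assert row.loc["a", "interface_area"] == pytest.approx(7.0)
        assert row.loc["a", "n_interface"] == 2

    def test_gamma_moment_recovery(self):
        rng = np.random.default_rng(5)
        sample = rng.gamma(shape=2.0, scale=400.0, size=500)
        k, theta = _gamma_mom(sample)
        assert k == pytest.approx(2.0, rel=0.2)
        assert k * theta == pytest.approx(sample.mean())

    def test_empty_input_no_crash(self):
        summary = size_distributions([])
        assert summary.per_side.empty and summary.stats.empty
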