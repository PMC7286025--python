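import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import brute_expansions, brute_scan

from cyanogst.motifs import (
    GLOBAL_ARCHITECTURE,
    MotifParseError,
    build_incidence,
    classify,
    classify_all,
    is_gst_like,
    parse_motif,
    reference_incidence,
    scan,
)
from cyanogst.seqio import ProteinRecord, ValidationError

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestParseMotif:
    def test_bracket_groups(self):
        m = parse_motif("SNA(IV)L")
        assert len(m) == 5
        assert set(m.expansions()) == {"SNAIL", "SNAVL"}

    def test_singletons(self):
        m = parse_motif("SKDIL")
        assert m.cardinality == 1
        assert m.expansions() == ["SKDIL"]

    def test_global_architecture_cardinality_by_enumeration(self):
        m = parse_motif("S[GLNTARS][ADE]I[LAI]")
        oracle = brute_expansions([sorted(p) for p in m.positions])
        assert m.cardinality == 7 * 3 * 3 == 63
        assert set(m.expansions()) == oracle

    def test_asx_code_reads_as_n_or_d(self):
        m = parse_motif("BADIA[TC]YP")
        assert m.positions[0] == frozenset("ND")

    def test_invertible_up_to_bracket_style(self):
        spec = "S[FL]AI[LM]"
        assert parse_motif(parse_motif(spec).to_spec()).positions == parse_motif(
            spec
        ).positions

    @pytest.mark.parametrize("bad", ["SNA(IV", "S()AIL", "S(1X)L", "SNA]L", ""])
    def test_malformed_specs_rejected(self, bad):
        with pytest.raises(MotifParseError):
            parse_motif(bad)


class TestScan:
    def test_direct_containment(self):
        assert scan("AASKDILAA", parse_motif("SKDIL")) == [2]

    def test_sequence_shorter_than_motif(self):
        assert scan("SKD", parse_motif("SKDIL")) == []

    @given(st.integers(0, 10_000))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("SGAILXNV"), size=200))
        motif = parse_motif("SGA(IL)L")
        assert scan(seq, motif) == brute_scan(seq, [sorted(p) for p in motif.positions])

    def test_large_random_sequence_against_oracle(self):
        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list(AA), size=10_000))
        motif = parse_motif("SGAIL")
        assert scan(seq, motif) == brute_scan(seq, [sorted(p) for p in motif.positions])


class TestClassDefinitions:
    def test_twelve_classes_with_expected_type_split(self, classes):
        names = [c.name for c in classes]
        assert len(names) == 12
        types = {c.name: c.catalytic_type for c in classes}
        assert [n for n in names if types[n] == "Y"] == [
            "Chi", "cyGSTX1", "cyGSTX2", "cyGSTX3", "cyGSTX4", "cyGSTX8", "cyGSTX10",
        ]
        assert [n for n in names if types[n] == "S"] == ["cyGSTX5", "cyGSTX7", "cyGSTX11"]
        assert [n for n in names if types[n] == "C"] == ["cyGSTX6", "cyGSTX9"]

    def test_every_order_variant_is_subpattern_of_architecture(self, classes):
        """No exceptions: each order-level motif refines its class architecture."""
        exceptions = []
        for cdef in classes:
            for order, variant in cdef.per_order_variants.items():
                if not cdef.architecture.contains(variant):
                    exceptions.append((cdef.name, order))
        assert exceptions == []

    def test_exactly_four_motifs_escape_global_architecture(self):
        m_motifs = {
            "SGAIL": True, "SLAIL": True, "SNAIL": True, "STEIA": True,
            "SDDII": False, "SAEII": True, "SSAIA": True, "SAIIN": False,
            "SLEII": True, "SAVIN": False, "SKDIL": False,
        }
        for motif, inside in m_motifs.items():
            assert GLOBAL_ARCHITECTURE.matches_at(motif, 0) is inside
        assert is_gst_like("XXXSTEIAXXX") and not is_gst_like("XXXSKDILXXX")

    def test_variant_presence_matches_reference_incidence(self, classes):
        ref = reference_incidence().table
        for cdef in classes:
            for order in ref.index:
                assert (order in cdef.per_order_variants) == bool(
                    ref.loc[order, cdef.name]
                )


def _seq(residues, sid="s"):
    return ProteinRecord(sid, residues)


class TestClassify:
    def test_unique_motif_assigns_directly(self, classes, zero_noise):
        seqs, _ = zero_noise
        a = classify(seqs["cyGSTX11_01"], classes)
        assert a.class_name == "cyGSTX11"
        assert a.matched_motif == "SKDIL"
        assert not a.ambiguous

    def test_sgail_with_x1_signatures_resolves_to_x1(self, classes):
        seq = _seq("A" * 10 + "ISPNSRIP" + "A" * 10 + "SGAIL" + "A" * 10 + "NADIATYP")
        a = classify(seq, classes)
        assert a.class_name == "cyGSTX1"
        assert a.signature_evidence["cyGSTX1"] == 2
        assert a.signature_evidence["Chi"] == 0
        assert not a.ambiguous

    def test_sgail_without_signatures_is_flagged_never_silent(self, classes):
        a = classify(_seq("A" * 20 + "SGAIL" + "A" * 20), classes)
        assert a.ambiguous
        assert set(a.candidates) >= {"Chi", "cyGSTX1"}

    def test_saiin_tie_breaks_to_x8_with_flag(self, classes):
        a = classify(_seq("A" * 20 + "SAIIN" + "A" * 20), classes)
        assert tuple(a.candidates) == ("cyGSTX8", "cyGSTX10")
        assert a.class_name == "cyGSTX8"
        assert a.ambiguous

    def test_strict_policy_refuses_ties(self, classes):
        a = classify(_seq("A" * 20 + "SAIIN" + "A" * 20), classes, policy="strict")
        assert a.class_name == "unclassified"
        assert a.ambiguous

    def test_no_motif_is_unclassified(self, classes):
        a = classify(_seq("A" * 50), classes)
        assert a.class_name == "unclassified"
        assert a.candidates == ()

    def test_catalytic_concordance(self, classes):
        # cyGSTX11 expects S at 1-based 8 or 66
        good = _seq("AAAAAAASAAAAAAAAAAAA" + "SKDIL" + "A" * 10)
        a = classify(good, classes)
        assert a.catalytic_type_called == "S" and a.catalytic_concordant
        bad = _seq("AAAAAAAAAAAAAAAAAAAA" + "SKDIL" + "A" * 10)
        b = classify(bad, classes)
        assert not b.catalytic_concordant


class TestIncidence:
    def test_reference_per_order_counts(self):
        counts = reference_incidence().counts
        assert counts["Nostocales"] == 9
        assert counts["Chroococcales"] == 8
        assert counts["Oscillatoriales"] == 7
        assert counts["Stigonematales"] == 5
        assert counts["Pleurocapsales"] == 4

    def test_no_assignments_gives_all_false(self, classes):
        inc = build_incidence([], {}, [c.name for c in classes])
        assert not inc.table.any().any()
        assert (inc.counts == 0).all()

    def test_unknown_order_label_rejected(self, classes, zero_noise):
        seqs, _ = zero_noise
        assignments = classify_all(seqs, classes)
        with pytest.raises(ValidationError):
            build_incidence(assignments, {a.sequence_id: "Atlantis" for a in assignments})

    def test_exhaustive_zero_noise_sampling_reproduces_reference_grid(self, classes):
        """One clean record per (class, order) cell rebuilds the survey grid."""
        from cyanogst.synthetic import SyntheticConfig, generate

        ref = reference_incidence().table
        assignments, orders = [], {}
        for order in ref.index:
            present = [c for c in classes if order in c.per_order_variants]
            cfg = SyntheticConfig(
                n_per_class=1,
                mutation_rate=0.0,
                seed=17,
                order_sampling={c.name: (order,) for c in present},
            )
            seqs, truth = generate(cfg, present)
            for rec in seqs:
                renamed = ProteinRecord(
                    f"{order}_{rec.id}", rec.residues, rec.order_label
                )
                assignments.append(classify(renamed, classes))
                orders[renamed.id] = order
        inc = build_incidence(assignments, orders, [c.name for c in classes])
        assert inc.table.equals(ref)
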