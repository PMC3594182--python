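import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ntproc.errors import InputError, ParseError
from ntproc.io import AcetylationEvidence, ProteinRecord
from ntproc.pipeline import parsed_from_evidence
from ntproc.rules import (
    NME_SMALL_RESIDUES,
    NmeStatusKind,
    ParsedNTerm,
    assign_nat,
    classify_from_nterm_only,
    classify_nme_status,
    parse_nterm,
    predict_nme,
    summarize,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestParseNTerm:
    @pytest.mark.parametrize("label, residues, acetylated", [
        ("Ac-Met-Glu-Thr-", ("M", "E", "T"), True),
        ("Ac-Ser-Asp-Glu-", ("S", "D", "E"), True),
        ("Met-Glu-Thr-", ("M", "E", "T"), False),
        ("Ac-Ala-Gly-Lys", ("A", "G", "K"), True),   # trailing dash optional
        ("ac-met-glu-", ("M", "E"), True),           # case-insensitive
    ])
    def test_examples(self, label, residues, acetylated):
        parsed = parse_nterm(label)
        assert parsed.residues == residues
        assert parsed.acetylated is acetylated

    def test_phospho_marker(self):
        parsed = parse_nterm("Ac-Ser(p)-Asp-Glu-")
        assert parsed.phospho_flags == (True, False, False)
        assert parsed.residues == ("S", "D", "E")

    @pytest.mark.parametrize("label", ["Ac-Qqq-Glu-", "Ac-Met-", "", "Ac-"])
    def test_errors(self, label):
        with pytest.raises(ParseError):
            parse_nterm(label)

    @given(st.lists(st.sampled_from(AA), min_size=2, max_size=14),
           st.booleans())
    @settings(max_examples=100, deadline=None)
    def test_render_parse_round_trip(self, residues, acetylated):
        parsed = ParsedNTerm(tuple(residues), acetylated,
                             tuple(False for _ in residues))
        assert parse_nterm(parsed.render()) == parsed

    def test_render_reproduces_dialect_exactly(self):
        assert parse_nterm("Ac-Met-Glu-Thr-").render() == "Ac-Met-Glu-Thr-"


class TestClassifyNme:
    def test_dependent_anchor(self):
        status = classify_nme_status(ProteinRecord("p", "MASTQK"),
                                     parse_nterm("Ac-Ala-Ser-Thr-"))
        assert status.status is NmeStatusKind.NME_DEPENDENT
        assert status.exposed_residue == "A"
        assert status.position_in_precursor == 2

    def test_independent_anchor(self):
        status = classify_nme_status(ProteinRecord("p", "METGKL"),
                                     parse_nterm("Ac-Met-Glu-Thr-"))
        assert status.status is NmeStatusKind.NME_INDEPENDENT
        assert status.position_in_precursor == 1

    def test_no_anchor_is_inconsistent(self):
        status = classify_nme_status(ProteinRecord("p", "MGKLLA"),
                                     parse_nterm("Ac-Ser-Asp-Glu-"))
        assert status.status is NmeStatusKind.INCONSISTENT

    def test_short_precursor_is_input_error(self):
        with pytest.raises(InputError):
            classify_nme_status(ProteinRecord("p", "MET"),
                                parse_nterm("Ac-Met-Glu-Thr-"))

    @pytest.mark.parametrize("label, kind", [
        ("Ac-Met-Glu-Thr-", NmeStatusKind.NME_INDEPENDENT),
        ("Ac-Ala-Gly-Lys-", NmeStatusKind.NME_DEPENDENT),
        ("Ac-Val-Ser-Arg-", NmeStatusKind.NME_DEPENDENT),
    ])
    def test_nterm_only(self, label, kind):
        assert classify_from_nterm_only(parse_nterm(label)).status is kind

    def test_nterm_only_requires_acetylation(self):
        with pytest.raises(InputError):
            classify_from_nterm_only(parse_nterm("Met-Glu-Thr-"))


class TestPredictNme:
    @pytest.mark.parametrize("seq, expected", [
        ("MAKT", True), ("MPRS", True), ("MEKT", False), ("MKVL", False),
    ])
    def test_examples(self, seq, expected):
        assert predict_nme(ProteinRecord("p", seq)) is expected

    def test_every_small_residue_licenses_excision(self):
        for aa in "AVSTCGP":
            assert predict_nme(ProteinRecord("p", "M" + aa + "KL"))

    def test_errors(self):
        with pytest.raises(InputError):
            predict_nme(ProteinRecord("p", "M"))
        with pytest.raises(InputError):
            predict_nme(ProteinRecord("p", "AKVL"))


class TestAssignNat:
    @pytest.mark.parametrize("label, expected, rule", [
        ("Ac-Met-Glu-Thr-", {"NatB"}, "R2"),
        ("Ac-Met-Asn-Gly-", {"NatB"}, "R2"),
        ("Ac-Met-Leu-Gly-", {"NatC", "NatE", "NatF"}, "R3"),
        ("Ac-Met-Gly-Asn-", {"NatF"}, "R4"),
        ("Ac-Met-Cys-Gly-", {"NatF"}, "R4"),
        ("Ac-Ala-Ser-Thr-", {"NatA"}, "R1"),
        ("Ac-Cys-Ser-Thr-", {"NatA"}, "R1"),
        ("Ac-Met-Lys-Val-", set(), None),
        ("Ac-Met-Pro-Arg-", set(), None),
        ("Ac-Pro-Arg-Ser-", set(), None),  # exposed Pro: excised, no Nat rule
    ])
    def test_rule_table(self, label, expected, rule):
        parsed = parse_nterm(label)
        nat = assign_nat(parsed, classify_from_nterm_only(parsed))
        assert set(nat.candidates) == expected
        assert nat.rule_id == rule
        assert nat.ambiguous == (len(expected) > 1)
        assert nat.unassigned == (not expected)

    def test_natd_never_emitted(self, table1):
        for ev in table1:
            parsed = parsed_from_evidence(ev)
            nat = assign_nat(parsed, classify_from_nterm_only(parsed))
            assert "NatD" not in nat.candidates

    def test_inconsistent_status_rejected(self):
        parsed = parse_nterm("Ac-Ser-Asp-Glu-")
        status = classify_nme_status(ProteinRecord("p", "MGKLLA"), parsed)
        with pytest.raises(InputError):
            assign_nat(parsed, status)

    def test_pure_function(self):
        parsed = parse_nterm("Ac-Met-Leu-Gly-")
        status = classify_from_nterm_only(parsed)
        assert assign_nat(parsed, status) == assign_nat(parsed, status)


def _call(ev):
    parsed = parsed_from_evidence(ev)
    status = classify_from_nterm_only(parsed)
    return status, assign_nat(parsed, status)


class TestSummarize:
    def test_fixture_headline_counts(self, table1):
        rep = summarize(table1, [_call(ev) for ev in table1])
        assert rep.total == 58
        assert rep.n_group_i == 11 and rep.n_group_ii == 47
        assert rep.n_inconsistent == 0
        assert rep.nat_counts["NatA"] == 47
        assert rep.nat_counts["NatB"] == 9
        assert rep.nat_counts["NatCEF_ambiguous"] == 1
        assert rep.nat_counts["NatF"] == 1
        assert rep.group_i_motif_counts == {
            "Met-Glu": 8, "Met-Asp": 1, "Met-Gly": 1, "Met-Leu": 1}
        assert rep.group_ii_exposed_counts == {
            "Ala": 25, "Ser": 13, "Gly": 7, "Thr": 1, "Val": 1}

    def test_fixture_group_ii_residues_are_small(self, table1):
        rep = summarize(table1, [_call(ev) for ev in table1])
        assert set(rep.group_ii_exposed_counts) <= {"Ala", "Ser", "Gly",
                                                    "Thr", "Val"}
        assert rep.nat_counts["NatA"] == rep.n_group_ii

    def test_fixture_percentages_derived(self, table1):
        rep = summarize(table1, [_call(ev) for ev in table1])
        pct = rep.percentages()
        assert pct["group_ii_pct"] == 81.0
        assert pct["group_i_pct"] == 19.0

    def test_empty_is_all_zero(self):
        rep = summarize([], [])
        assert rep.total == 0
        assert rep.n_group_i == rep.n_group_ii == rep.n_inconsistent == 0
        assert all(v == 0 for v in rep.nat_counts.values())

    def test_length_mismatch_rejected(self, table1):
        with pytest.raises(InputError):
            summarize(table1, [])

    def test_phospho_counting(self):
        evs = [
            AcetylationEvidence("1", "Ac-Ser(p)-Asp-Glu-", ["S", "D", "E"],
                                True, [1]),
            AcetylationEvidence("2", "Ac-Met-Glu-Thr(p)-", ["M", "E", "T"],
                                True, [3]),
            AcetylationEvidence("3", "Ac-Ala-Gly-Lys-", ["A", "G", "K"],
                                True, []),
        ]
        rep = summarize(evs, [_call(ev) for ev in evs])
        assert rep.phospho["n_with_phospho"] == 2
        assert rep.phospho["n_group_i_phospho"] == 1
        assert rep.phospho["n_group_ii_phospho"] == 1
        assert rep.phospho["n_acetyl_residue_also_phospho"] == 1

    @given(st.lists(st.tuples(
        st.sampled_from(AA), st.sampled_from(AA), st.sampled_from(AA)),
        max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_partition_identity(self, triples):
        evs, calls = [], []
        for i, (a, b, c) in enumerate(triples):
            parsed = ParsedNTerm((a, b, c), True, (False,) * 3)
            ev = AcetylationEvidence(str(i), parsed.render(), [a, b, c], True)
            status = classify_from_nterm_only(parsed)
            calls.append((status, assign_nat(parsed, status)))
            evs.append(ev)
        rep = summarize(evs, calls)
        assert rep.n_group_i + rep.n_group_ii + rep.n_inconsistent == rep.total
        assert sum(rep.nat_counts.values()) == rep.total - rep.n_inconsistent


def test_nme_consistency_between_anchor_and_prediction():
    """Anchored NME-dependent classification implies the excision rule fired
    whenever position 2 is small (Pro aside, which never yields a Nat)."""
    for aa in NME_SMALL_RESIDUES:
        precursor = ProteinRecord("p", "M" + aa + "KLRT")
        parsed = ParsedNTerm((aa, "K", "L"), True, (False,) * 3)
        status = classify_nme_status(precursor, parsed)
        assert status.status is NmeStatusKind.NME_DEPENDENT
        assert predict_nme(precursor)
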