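import textwrap

import pytest

from sisterates.wordlist_io import (
    CognateForm,
    Status,
    WordlistFormatError,
    WordlistValidationError,
    apply_exclusions,
    read_nexus_matrix,
    read_wordlist,
    write_wordlist,
)


def _form(lang="L1", concept="hand", cid="1", loan=False, status=Status.OK):
    return CognateForm(language=lang, concept=concept, class_id=cid, loan=loan, status=status)


class TestApplyExclusions:
    def test_empty_input(self):
        assert apply_exclusions([]) == []

    @pytest.mark.parametrize(
        "forms, surviving_ids",
        [
            # doubtful and exclude statuses are dropped, ok kept
            (
                [
                    _form(cid="1", status=Status.OK),
                    _form(cid="2", status=Status.DOUBTFUL),
                    _form(cid="3", status=Status.EXCLUDE),
                ],
                {"1"},
            ),
            # loan words are dropped even with ok status
            ([_form(cid="1", loan=True)], set()),
            ([_form(cid="1"), _form(cid="2", loan=True)], {"1"}),
        ],
    )
    def test_exclusion_rules(self, forms, surviving_ids):
        assert {f.class_id for f in apply_exclusions(forms)} == surviving_ids

    def test_idempotent(self):
        forms = [
            _form(cid="1"),
            _form(cid="2", status=Status.DOUBTFUL),
            _form(cid="3", loan=True),
        ]
        once = apply_exclusions(forms)
        assert apply_exclusions(once) == once


WORDLIST = textwrap.dedent(
    """\
    language_id,concept,form,cognate_class,loan,status
    A,hand,mano,1,false,ok
    A,hand,hand,2,false,ok
    B,hand,mano,1,false,ok
    A,eye,auge,5,false,ok
    B,eye,occhio,6,false,doubtful
    B,leg,jambe,9,true,ok
    """
)


class TestReadWordlist:
    def test_identity_ingestion(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            "language_id,concept,form,cognate_class,loan,status\n"
            "A,hand,x,1,false,ok\nB,hand,y,1,false,ok\nA,eye,z,2,false,ok\n"
        )
        m = read_wordlist(p)
        assert m.n_forms() == 3
        assert m.classes("A", "hand") == {"1"}

    def test_doubtful_and_loans_absent_but_cell_attested(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(WORDLIST)
        m = read_wordlist(p)
        # B's only eye form was doubtful: excluded from presence, but the
        # cell counts as attested (the database did record data there)
        assert m.classes("B", "eye") == frozenset()
        assert m.attested("B", "eye")
        # loan dropped likewise
        assert m.classes("B", "leg") == frozenset()
        assert m.attested("B", "leg")
        # no rows at all -> missing, not attested
        assert not m.attested("A", "leg")

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("language_id,concept,cognate_class,loan\nA,hand,1,false\n")
        with pytest.raises(WordlistFormatError, match="status"):
            read_wordlist(p)

    def test_conflicting_duplicate_status_names_triple(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            "language_id,concept,form,cognate_class,loan,status\n"
            "A,hand,x,1,false,ok\nA,hand,x,1,false,doubtful\n"
        )
        with pytest.raises(WordlistValidationError, match=r"\('A', 'hand', '1'\)"):
            read_wordlist(p)

    def test_unknown_status_fails_loud(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            "language_id,concept,form,cognate_class,loan,status\nA,hand,x,1,false,maybe\n"
        )
        with pytest.raises(WordlistValidationError, match="maybe"):
            read_wordlist(p)

    def test_status_case_insensitive(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            "language_id,concept,form,cognate_class,loan,status\n"
            "A,hand,x,1,false,OK\nB,hand,y,2,false,Doubtful\n"
        )
        m = read_wordlist(p)
        assert m.classes("A", "hand") == {"1"}
        assert m.classes("B", "hand") == frozenset()

    def test_unknown_concept_rejected(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text(
            "language_id,concept,form,cognate_class,loan,status\nA,wing,x,1,false,ok\n"
        )
        with pytest.raises(WordlistValidationError, match="wing"):
            read_wordlist(p, concepts=["hand", "eye"])


def test_roundtrip_preserves_surviving_forms(tmp_path):
    src = tmp_path / "w.csv"
    src.write_text(WORDLIST)
    m1 = read_wordlist(src)
    out = tmp_path / "out.csv"
    write_wordlist(m1, out)
    m2 = read_wordlist(out)
    assert m1 == m2


NEXUS = textwrap.dedent(
    """\
    #NEXUS
    BEGIN DATA;
    DIMENSIONS NTAX=2 NCHAR=3;
    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;
    CHARSTATELABELS
        1 hand_1, 2 hand_2, 3 eye_1;
    MATRIX
    A 111
    B 111
    ;
    END;
    """
)


class TestReadNexusMatrix:
    def test_all_present(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS)
        m = read_nexus_matrix(p)
        assert m.classes("A", "hand") == {"1", "2"}
        assert m.classes("B", "eye") == {"1"}
        assert m.n_forms() == 6

    def test_all_question_marks_means_concept_missing(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS.replace("A 111", "A ??1"))
        m = read_nexus_matrix(p)
        assert not m.attested("A", "hand")
        assert m.attested("A", "eye")

    def test_partial_question_mark_keeps_concept(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS.replace("A 111", "A ?11"))
        m = read_nexus_matrix(p)
        assert m.attested("A", "hand")
        assert m.classes("A", "hand") == {"2"}

    def test_non_binary_symbol_is_format_error(self, tmp_path):
        p = tmp_path / "m.nex"
        p.write_text(NEXUS.replace("A 111", "A 121"))
        with pytest.raises(WordlistFormatError, match="non-binary"):
            read_nexus_matrix(p)

    def test_equivalent_encodings_give_identical_matrix(self, tmp_path):
        nex = tmp_path / "m.nex"
        nex.write_text(NEXUS)
        csv_path = tmp_path / "w.csv"
        csv_path.write_text(
            "language_id,concept,form,cognate_class,loan,status\n"
            "A,hand,,1,false,ok\nA,hand,,2,false,ok\nA,eye,,1,false,ok\n"
            "B,hand,,1,false,ok\nB,hand,,2,false,ok\nB,eye,,1,false,ok\n"
        )
        assert read_nexus_matrix(nex) == read_wordlist(csv_path)


def test_empty_class_id_rejected():
    with pytest.raises(WordlistValidationError):
        CognateForm(language="A", concept="hand", class_id="")
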