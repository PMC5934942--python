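import itertools
import random

import pytest

from sisterates.rate_counter import (
    ClassPattern,
    GainLossCount,
    classify,
    count_pair,
    standardize,
)
from sisterates.sister_pairs import SisterPair
from sisterates.wordlist_io import CognateMatrix

PAIR_AB = SisterPair(lang1="A", lang2="B")


class TestClassify:
    # full truth table over (in1, in2, elsewhere) with the concept attested
    @pytest.mark.parametrize(
        "in1, in2, elsewhere, expected",
        [
            (True, True, True, "noninformative"),
            (True, True, False, "noninformative"),
            (True, False, True, "loss2"),
            (True, False, False, "gain1"),
            (False, True, True, "loss1"),
            (False, True, False, "gain2"),
            (False, False, True, "excluded"),
            (False, False, False, "excluded"),
        ],
    )
    def test_truth_table(self, in1, in2, elsewhere, expected):
        pattern = ClassPattern(in1=in1, in2=in2, elsewhere=elsewhere)
        assert classify(pattern) == expected

    def test_unattested_concept_always_excluded(self):
        for in1, in2, elsewhere in itertools.product([True, False], repeat=3):
            pattern = ClassPattern(in1, in2, elsewhere, concept_attested=False)
            assert classify(pattern) == "excluded"


def brute_force_count(matrix: CognateMatrix, pair: SisterPair) -> GainLossCount:
    """Independent oracle: classify every (concept, class) via classify()."""
    tally = {k: 0 for k in ("gain1", "gain2", "loss1", "loss2", "noninformative", "excluded")}
    for concept in matrix.concepts:
        attested = matrix.attested(pair.lang1, concept) and matrix.attested(
            pair.lang2, concept
        )
        for class_id in matrix.classes_by_concept[concept]:
            in1 = class_id in matrix.classes(pair.lang1, concept)
            in2 = class_id in matrix.classes(pair.lang2, concept)
            elsewhere = any(
                class_id in matrix.classes(lang, concept)
                for lang in matrix.languages
                if lang not in pair.languages
            )
            tally[classify(ClassPattern(in1, in2, elsewhere, attested))] += 1
    return GainLossCount(
        gains1=tally["gain1"], gains2=tally["gain2"],
        losses1=tally["loss1"], losses2=tally["loss2"],
        noninformative=tally["noninformative"], excluded=tally["excluded"],
    )


def random_matrix(rng: random.Random, n_langs: int, n_concepts: int) -> CognateMatrix:
    languages = [f"L{i}" for i in range(n_langs)]
    concepts = [f"c{i}" for i in range(n_concepts)]
    presence = {}
    attested = set()
    for lang in languages:
        for concept in concepts:
            if rng.random() < 0.15:
                continue  # missing data for this cell
            attested.add((lang, concept))
            n_classes = rng.choice([0, 1, 1, 2])
            chosen = {
                f"{concept}k{rng.randint(0, 4)}" for _ in range(n_classes)
            }
            if chosen:
                presence[(lang, concept)] = chosen
    return CognateMatrix(languages, concepts, presence, attested)


class TestCountPair:
    def test_hand_constructed_family(self, toy_family_matrix):
        count = count_pair(toy_family_matrix, PAIR_AB)
        assert count == GainLossCount(
            gains1=1, gains2=0, losses1=0, losses2=1, noninformative=2, excluded=3
        )
        assert count.total == 7

    def test_identical_members_have_no_events(self, toy_family_matrix):
        m = toy_family_matrix
        presence = {k: set(v) for k, v in m.presence.items()}
        # make B a copy of A
        for concept in m.concepts:
            presence[("B", concept)] = set(m.classes("A", concept))
        m2 = CognateMatrix(m.languages, m.concepts, presence,
                           [(l, c) for l in m.languages for c in m.concepts])
        count = count_pair(m2, PAIR_AB)
        assert count.gains1 == count.gains2 == count.losses1 == count.losses2 == 0
        shared = sum(len(m2.classes("A", c)) for c in m2.concepts)
        assert count.noninformative == shared

    def test_swap_symmetry(self, toy_family_matrix):
        ab = count_pair(toy_family_matrix, PAIR_AB)
        ba = count_pair(toy_family_matrix, SisterPair(lang1="B", lang2="A"))
        assert ba == ab.swapped()

    def test_missing_member_raises(self, toy_family_matrix):
        with pytest.raises(KeyError, match="Z"):
            count_pair(toy_family_matrix, SisterPair(lang1="A", lang2="Z"))

    def test_unattested_concept_classes_all_excluded(self, toy_family_matrix):
        m = toy_family_matrix
        attested = {
            (lang, concept)
            for lang in m.languages
            for concept in m.concepts
            if m.attested(lang, concept) and not (lang == "B" and concept == "hand")
        }
        presence = {k: set(v) for k, v in m.presence.items() if k != ("B", "hand")}
        m2 = CognateMatrix(m.languages, m.concepts, presence, attested)
        count = count_pair(m2, PAIR_AB)
        # all 3 hand classes excluded; eye/leg unchanged (1 gain, 1 noninf, 2 excl)
        assert count.excluded == 3 + 2
        assert count.losses2 == 0 and count.noninformative == 1

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = random.Random(777)
        for rep in range(40):
            m = random_matrix(rng, n_langs=rng.randint(3, 6), n_concepts=rng.randint(2, 5))
            pair = SisterPair(lang1="L0", lang2="L1")
            assert count_pair(m, pair) == brute_force_count(m, pair)

    def test_relabeling_nonpair_languages_changes_nothing(self):
        rng = random.Random(123)
        m = random_matrix(rng, n_langs=5, n_concepts=4)
        pair = SisterPair(lang1="L0", lang2="L1")
        base = count_pair(m, pair)
        # permute the presence rows of the non-pair languages
        others = ["L2", "L3", "L4"]
        perm = {"L2": "L4", "L3": "L2", "L4": "L3"}
        presence = {}
        attested = set()
        for lang in m.languages:
            src = perm.get(lang, lang)
            for concept in m.concepts:
                if m.attested(src, concept):
                    attested.add((lang, concept))
                classes = m.classes(src, concept)
                if classes:
                    presence[(lang, concept)] = set(classes)
        m2 = CognateMatrix(m.languages, m.concepts, presence, attested)
        assert count_pair(m2, pair) == base

    def test_duplicating_lang1_converts_gains_to_losses(self):
        rng = random.Random(99)
        for rep in range(10):
            m = random_matrix(rng, n_langs=4, n_concepts=4)
            pair = SisterPair(lang1="L0", lang2="L1")
            base = count_pair(m, pair)
            # add a language identical to L0
            languages = list(m.languages) + ["COPY"]
            presence = {k: set(v) for k, v in m.presence.items()}
            attested = {(l, c) for l in m.languages for c in m.concepts if m.attested(l, c)}
            for concept in m.concepts:
                if m.attested("L0", concept):
                    attested.add(("COPY", concept))
                    classes = m.classes("L0", concept)
                    if classes:
                        presence[("COPY", concept)] = set(classes)
            m2 = CognateMatrix(languages, m.concepts, presence, attested)
            new = count_pair(m2, pair)
            assert new.gains1 == 0
            assert new.losses2 == base.losses2 + base.gains1
            assert new.noninformative == base.noninformative
            assert new.gains2 == base.gains2 and new.losses1 == base.losses1


class TestStandardize:
    def test_fractions(self):
        count = GainLossCount(gains1=2, gains2=1, losses1=0, losses2=3,
                              noninformative=2, excluded=2)
        rates = standardize(count)
        assert rates.gain1 == pytest.approx(0.2)
        assert rates.loss2 == pytest.approx(0.3)

    def test_all_noninformative_gives_zero_rates(self):
        rates = standardize(GainLossCount(noninformative=5))
        assert rates.gain1 == rates.gain2 == rates.loss1 == rates.loss2 == 0.0

    def test_rates_sum_at_most_one(self, toy_family_matrix):
        rates = standardize(count_pair(toy_family_matrix, PAIR_AB))
        assert 0 <= rates.gain1 + rates.gain2 + rates.loss1 + rates.loss2 <= 1

    def test_zero_total_raises(self):
        with pytest.raises(ZeroDivisionError):
            standardize(GainLossCount())


def test_gainloss_invariant_rejects_negative():
    with pytest.raises(ValueError):
        GainLossCount(gains1=-1)
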