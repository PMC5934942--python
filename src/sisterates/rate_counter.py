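"""Classify cognate classes into gains and losses for a sister pair.

For each cognate class of each semantic category, presence in the two
members of a sister pair plus presence anywhere else in the family
determines what (if anything) the class says about rates of change:

* present in both members -- inherited from the common ancestor, lost by
  neither: *non-informative*.
* present in one member and somewhere else in the family -- the class was
  ancestral, so its absence from the other member is a *loss* by that
  member.
* present in one member only, nowhere else in the family -- a brand-new
  form: a *gain* by the member that has it.
* absent from both members -- assumed absent from their common ancestor,
  *excluded* from the informative tally (but part of the comparison
  denominator).
* the class's concept unattested in either member -- *excluded*: absence
  of data, not absence of the word.

Counts are standardized by the total number of comparisons (gains +
losses + non-informative + excluded) so pairs with different amounts of
data are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

from .wordlist_io import CognateMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .sister_pairs import SisterPair

__all__ = [
    "ClassPattern",
    "GainLossCount",
    "StandardizedRates",
    "classify",
    "count_pair",
    "standardize",
]

LABELS = ("gain1", "gain2", "loss1", "loss2", "noninformative", "excluded")


@dataclass(frozen=True)
class ClassPattern:
    """Presence pattern of one cognate class relative to a sister pair."""

    in1: bool
    in2: bool
    elsewhere: bool
    concept_attested: bool = True


@dataclass(frozen=True)
class GainLossCount:
    """Per-pair tallies over all compared cognate classes."""

    gains1: int = 0
    gains2: int = 0
    losses1: int = 0
    losses2: int = 0
    noninformative: int = 0
    excluded: int = 0

    def __post_init__(self) -> None:
        for name in ("gains1", "gains2", "losses1", "losses2", "noninformative", "excluded"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count {name}")

    @property
    def total(self) -> int:
        return (
            self.gains1 + self.gains2 + self.losses1 + self.losses2
            + self.noninformative + self.excluded
        )

    def swapped(self) -> "GainLossCount":
        """The same tally with the pair members' roles exchanged."""
        return GainLossCount(
            gains1=self.gains2,
            gains2=self.gains1,
            losses1=self.losses2,
            losses2=self.losses1,
            noninformative=self.noninformative,
            excluded=self.excluded,
        )


def classify(pattern: ClassPattern) -> str:
    """Label a presence pattern; total over all patterns.

    The returned label is one of ``gain1, gain2, loss1, loss2,
    noninformative, excluded``; ``lossX``/``gainX`` name the member that
    lost or gained the class.
    """
    if not pattern.concept_attested:
        return "excluded"
    if pattern.in1 and pattern.in2:
        return "noninformative"
    if not pattern.in1 and not pattern.in2:
        return "excluded"
    if pattern.in1:  # present in member 1 only
        return "loss2" if pattern.elsewhere else "gain1"
    return "loss1" if pattern.elsewhere else "gain2"


def count_pair(matrix: CognateMatrix, pair: "SisterPair") -> GainLossCount:
    """Tally gains/losses/non-informative/excluded classes for one pair.

    Every cognate class known anywhere in the family enters the tally
    exactly once per concept; a class recurring under two concepts is two
    independent classes (semantic shift is not modelled).  Classes whose
    concept is unattested in either member are excluded wholesale, since
    their absence cannot be told apart from missing data.
    """
    lang1, lang2 = pair.lang1, pair.lang2
    for lang in (lang1, lang2):
        if lang not in matrix.languages:
            raise KeyError(f"pair member {lang!r} not in matrix")

    tally = dict.fromkeys(LABELS, 0)
    for concept in matrix.concepts:
        family_classes = matrix.classes_by_concept[concept]
        if not family_classes:
            continue
        if not (matrix.attested(lang1, concept) and matrix.attested(lang2, concept)):
            tally["excluded"] += len(family_classes)
            continue
        in1 = matrix.classes(lang1, concept)
        in2 = matrix.classes(lang2, concept)
        both = in1 & in2
        only1 = in1 - in2
        only2 = in2 - in1
        tally["noninformative"] += len(both)
        tally["excluded"] += len(family_classes - in1 - in2)
        counts = matrix.class_counts[concept]
        for class_id in only1:
            # presence anywhere outside the pair = family count minus the
            # single pair member that has it
            if counts[class_id] > 1:
                tally["loss2"] += 1
            else:
                tally["gain1"] += 1
        for class_id in only2:
            if counts[class_id] > 1:
                tally["loss1"] += 1
            else:
                tally["gain2"] += 1
    return GainLossCount(
        gains1=tally["gain1"],
        gains2=tally["gain2"],
        losses1=tally["loss1"],
        losses2=tally["loss2"],
        noninformative=tally["noninformative"],
        excluded=tally["excluded"],
    )


@dataclass(frozen=True)
class StandardizedRates:
    """Per-language gain/loss counts as fractions of all comparisons."""

    gain1: float
    gain2: float
    loss1: float
    loss2: float


def standardize(count: GainLossCount) -> StandardizedRates:
    """Divide each event count by the total number of comparisons."""
    total = count.total
    if total == 0:
        raise ZeroDivisionError("no comparisons: standardized rates undefined")
    return StandardizedRates(
        gain1=count.gains1 / total,
        gain2=count.gains2 / total,
        loss1=count.losses1 / total,
        loss2=count.losses2 / total,
    )
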