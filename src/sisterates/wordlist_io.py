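"""Reading, validating and filtering cognate-coded wordlists.

Cognate databases of basic vocabulary (ABVD- or IELex-style exports) record,
for each language and semantic category ("concept"), one or more lexemes,
each assigned to a cognate class.  Two flags matter for rate counting:
a *loan* flag (borrowed forms must not be counted as inherited cognates)
and a *status* field (forms coded ``doubtful`` or ``exclude`` by the
database compilers are unreliable cognate judgements).  This module reads
two interchangeable encodings of the same information -- a long-format
tabular wordlist and a binary presence/absence NEXUS character matrix --
into a single in-memory container, :class:`CognateMatrix`, applying the
exclusion rules on the way in.

A concept is *attested* for a language only if the source data contain at
least one surviving form (or an explicit empty-but-attested marker) for
that (language, concept) cell; a bare absence of rows is treated as
missing data, not as absence of the word.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Status",
    "CognateForm",
    "CognateMatrix",
    "WordlistFormatError",
    "WordlistValidationError",
    "apply_exclusions",
    "read_wordlist",
    "write_wordlist",
    "read_nexus_matrix",
]


class WordlistFormatError(ValueError):
    """The file does not conform to the expected format."""


class WordlistValidationError(ValueError):
    """The file parses but its content violates an invariant."""


class Status(enum.Enum):
    OK = "ok"
    DOUBTFUL = "doubtful"
    EXCLUDE = "exclude"

    @classmethod
    def parse(cls, raw: str) -> "Status":
        norm = raw.strip().lower()
        for member in cls:
            if norm == member.value:
                return member
        raise WordlistValidationError(
            f"unknown status {raw!r}: expected one of "
            f"{[m.value for m in cls]}"
        )


@dataclass(frozen=True)
class CognateForm:
    """One lexeme record: a cognate-class assignment for a language/concept.

    ``class_id`` is scoped to its concept: the same label under two
    different concepts denotes two unrelated cognate classes.
    """

    language: str
    concept: str
    class_id: str
    loan: bool = False
    status: Status = Status.OK

    def __post_init__(self) -> None:
        if not self.class_id:
            raise WordlistValidationError(
                f"empty cognate class for ({self.language}, {self.concept})"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.language, self.concept, self.class_id)


class CognateMatrix:
    """Presence/absence of cognate classes per (language, concept).

    ``presence[(lang, concept)]`` is the set of cognate-class IDs attested
    for that cell after exclusions.  ``attested(lang, concept)`` is False
    where the source data are missing for that cell, which is distinct
    from an attested cell with an empty presence set.
    """

    def __init__(
        self,
        languages: Iterable[str],
        concepts: Iterable[str],
        presence: Mapping[tuple[str, str], set[str]],
        attested: Iterable[tuple[str, str]] | None = None,
    ) -> None:
        self.languages: tuple[str, ...] = tuple(dict.fromkeys(languages))
        self.concepts: tuple[str, ...] = tuple(dict.fromkeys(concepts))
        self._lang_set = set(self.languages)
        self._concept_set = set(self.concepts)
        self.presence: dict[tuple[str, str], frozenset[str]] = {}
        for (lang, concept), classes in presence.items():
            if concept not in self._concept_set:
                raise WordlistValidationError(f"unknown concept {concept!r}")
            if lang not in self._lang_set:
                raise WordlistValidationError(f"unknown language {lang!r}")
            if classes:
                self.presence[(lang, concept)] = frozenset(classes)
        self._attested: set[tuple[str, str]] = set(self.presence)
        if attested is not None:
            self._attested.update(attested)
        for cell in self._attested:
            if cell[0] not in self._lang_set or cell[1] not in self._concept_set:
                raise WordlistValidationError(f"attestation for unknown cell {cell}")
        # registries: concept -> class ids seen anywhere in the family, and
        # concept -> class id -> number of languages possessing the class
        counts: dict[str, dict[str, int]] = {c: {} for c in self.concepts}
        for (lang, concept), classes in self.presence.items():
            bucket = counts[concept]
            for cid in classes:
                bucket[cid] = bucket.get(cid, 0) + 1
        self.class_counts: dict[str, dict[str, int]] = counts
        self.classes_by_concept: dict[str, frozenset[str]] = {
            c: frozenset(bucket) for c, bucket in counts.items()
        }

    def classes(self, language: str, concept: str) -> frozenset[str]:
        return self.presence.get((language, concept), frozenset())

    def attested(self, language: str, concept: str) -> bool:
        return (language, concept) in self._attested

    def n_forms(self) -> int:
        return sum(len(s) for s in self.presence.values())

    def languages_with(self, concept: str, class_id: str) -> set[str]:
        return {
            lang
            for lang in self.languages
            if class_id in self.classes(lang, concept)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CognateMatrix):
            return NotImplemented
        return (
            set(self.languages) == set(other.languages)
            and set(self.concepts) == set(other.concepts)
            and self.presence == other.presence
            and self._attested == other._attested
        )

    def __repr__(self) -> str:
        return (
            f"CognateMatrix({len(self.languages)} languages, "
            f"{len(self.concepts)} concepts, {self.n_forms()} forms)"
        )


def apply_exclusions(forms: Iterable[CognateForm]) -> list[CognateForm]:
    """Drop loan words and forms flagged doubtful/exclude.

    Only inherited, confidently coded forms survive: ``status == ok`` and
    ``loan == False``.  Idempotent.
    """
    return [f for f in forms if f.status is Status.OK and not f.loan]


_REQUIRED_COLUMNS = ("language_id", "concept", "cognate_class", "loan", "status")
_TRUE_VALUES = {"true", "1", "yes", "t"}
_FALSE_VALUES = {"false", "0", "no", "f", ""}


def _parse_bool(raw: str, context: str) -> bool:
    norm = raw.strip().lower()
    if norm in _TRUE_VALUES:
        return True
    if norm in _FALSE_VALUES:
        return False
    raise WordlistValidationError(f"cannot parse boolean {raw!r} in {context}")


def read_wordlist(
    path: str | Path,
    delimiter: str = ",",
    concepts: Iterable[str] | None = None,
) -> CognateMatrix:
    """Read a long-format tabular wordlist into a :class:`CognateMatrix`.

    The file must have a header naming at least the columns
    ``language_id, concept, cognate_class, loan, status`` (a ``form``
    column is tolerated and ignored: counting operates on cognate classes,
    not orthography).  Exclusion rules are applied before the matrix is
    built, but a cell that had rows (of any status) counts as attested:
    the compilers did record data for it.

    If ``concepts`` is given, rows with concepts outside that list are
    rejected with a validation error.
    """
    path = Path(path)
    forms: list[CognateForm] = []
    attested: set[tuple[str, str]] = set()
    lang_order: dict[str, None] = {}
    concept_order: dict[str, None] = {}
    allowed = set(concepts) if concepts is not None else None

    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise WordlistFormatError(
                f"{path.name}: missing required column(s) {missing}; found {header}"
            )
        for i, row in enumerate(reader, start=2):
            lang = row["language_id"].strip()
            concept = row["concept"].strip()
            if allowed is not None and concept not in allowed:
                raise WordlistValidationError(
                    f"{path.name}:{i}: unknown concept {concept!r}"
                )
            lang_order.setdefault(lang, None)
            concept_order.setdefault(concept, None)
            attested.add((lang, concept))
            class_id = row["cognate_class"].strip()
            if not class_id:
                # explicit empty-but-attested marker row
                continue
            forms.append(
                CognateForm(
                    language=lang,
                    concept=concept,
                    class_id=class_id,
                    loan=_parse_bool(row["loan"], f"{path.name}:{i}"),
                    status=Status.parse(row["status"]),
                )
            )

    _check_consistent_duplicates(forms)
    surviving = apply_exclusions(forms)
    presence: dict[tuple[str, str], set[str]] = {}
    for f in surviving:
        presence.setdefault((f.language, f.concept), set()).add(f.class_id)
    if allowed is not None:
        concept_order = dict.fromkeys(list(concepts))  # type: ignore[arg-type]
    return CognateMatrix(lang_order, concept_order, presence, attested)


def _check_consistent_duplicates(forms: list[CognateForm]) -> None:
    seen: dict[tuple[str, str, str], tuple[bool, Status]] = {}
    for f in forms:
        flags = (f.loan, f.status)
        prior = seen.setdefault(f.key, flags)
        if prior != flags:
            raise WordlistValidationError(
                f"conflicting loan/status for {f.key}: {prior} vs {flags}"
            )


def write_wordlist(matrix: CognateMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write the surviving forms of a matrix back to the tabular format.

    Only surviving forms exist in a matrix, so the emitted rows all carry
    ``loan=false, status=ok``; attested-but-empty cells are preserved with
    an explicit empty ``cognate_class`` marker row.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter)
        writer.writerow(["language_id", "concept", "form", "cognate_class", "loan", "status"])
        for lang in matrix.languages:
            for concept in matrix.concepts:
                if not matrix.attested(lang, concept):
                    continue
                classes = sorted(matrix.classes(lang, concept))
                if not classes:
                    writer.writerow([lang, concept, "", "", "false", "ok"])
                for cid in classes:
                    writer.writerow([lang, concept, "", cid, "false", "ok"])


_NEXUS_MATRIX_RE = re.compile(r"matrix(.*?);", re.IGNORECASE | re.DOTALL)
_NEXUS_CHARLABELS_RE = re.compile(r"charstatelabels(.*?);", re.IGNORECASE | re.DOTALL)


def read_nexus_matrix(path: str | Path) -> CognateMatrix:
    """Read a binary cognate presence/absence NEXUS matrix.

    Characters are cognate classes; CHARSTATELABELS entries of the form
    ``<index> <concept>_<class>`` map characters to (concept, class_id)
    pairs.  Symbol ``1`` means the class is attested for the language,
    ``0`` that it is absent, and ``?`` that the datum is missing.  A
    concept counts as missing for a language only when *every* one of its
    characters is ``?`` for that language.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    m = _NEXUS_CHARLABELS_RE.search(text)
    if m is None:
        raise WordlistFormatError(f"{path.name}: no CHARSTATELABELS block")
    labels: list[tuple[str, str]] = []
    for token in m.group(1).replace(",", " ").split():
        if token.isdigit():
            continue
        if "_" not in token:
            raise WordlistFormatError(
                f"{path.name}: character label {token!r} not of form concept_class"
            )
        concept, class_id = token.rsplit("_", 1)
        labels.append((concept, class_id))

    m = _NEXUS_MATRIX_RE.search(text)
    if m is None:
        raise WordlistFormatError(f"{path.name}: no MATRIX block")
    rows: dict[str, str] = {}
    for line in m.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise WordlistFormatError(f"{path.name}: cannot parse matrix row {line!r}")
        taxon, states = parts
        if len(states) != len(labels):
            raise WordlistFormatError(
                f"{path.name}: row {taxon!r} has {len(states)} states, "
                f"expected {len(labels)}"
            )
        bad = set(states) - set("01?")
        if bad:
            raise WordlistFormatError(
                f"{path.name}: non-binary symbol(s) {sorted(bad)} in row {taxon!r}"
            )
        rows[taxon] = states

    concepts = list(dict.fromkeys(c for c, _ in labels))
    presence: dict[tuple[str, str], set[str]] = {}
    attested: set[tuple[str, str]] = set()
    by_concept: dict[str, list[int]] = {}
    for idx, (concept, _) in enumerate(labels):
        by_concept.setdefault(concept, []).append(idx)
    for taxon, states in rows.items():
        for concept, idxs in by_concept.items():
            cell_states = [states[i] for i in idxs]
            if all(s == "?" for s in cell_states):
                continue  # missing data for this concept
            attested.add((taxon, concept))
            chosen = {
                labels[i][1] for i, s in zip(idxs, cell_states) if s == "1"
            }
            if chosen:
                presence[(taxon, concept)] = chosen
    return CognateMatrix(rows.keys(), concepts, presence, attested)
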