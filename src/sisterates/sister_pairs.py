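"""Sister-pair (cherry) extraction from dated phylogenies.

Two languages joined directly at their most recent common ancestor form a
*cherry*: every difference between them arose after that split, so the
pair is one phylogenetically independent comparison (sidestepping
Galton's problem of shared descent).  Cherries are accepted only when the
parent node is well supported (default: posterior probability >= 0.8) and
both members are extant, non-creole languages with a known speaker
population and a pairing consistent with the reference taxonomy.

The pair's *branch length* is the height of its ancestral node above the
tips -- for a non-ultrametric cherry, the mean of the two tip-to-ancestor
path lengths, reported with a warning.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "LanguageMeta",
    "SisterPair",
    "DroppedPair",
    "extract_cherries",
    "pair_branch_length",
    "filter_pairs",
    "read_language_meta",
    "read_taxonomy_pairs",
]


@dataclass(frozen=True)
class LanguageMeta:
    """Per-language metadata: speaker population ('in area') and flags."""

    language: str
    population: int
    creole: bool = False
    extinct: bool = False


@dataclass(frozen=True)
class SisterPair:
    """A pair of tip languages joined at their most recent common ancestor.

    ``lang1``/``lang2`` keep the orientation given by the source (tree
    traversal order or the row order of a fixture table); the statistical
    engines are either orientation-invariant or apply the source's
    orientation uniformly.
    """

    lang1: str
    lang2: str
    N1: int | None = None
    N2: int | None = None
    support: float = 1.0
    branch_length: float = 0.0

    def __post_init__(self) -> None:
        if self.lang1 == self.lang2:
            raise ValueError(f"degenerate pair ({self.lang1}, {self.lang2})")
        if not 0.0 <= self.support <= 1.0:
            raise ValueError(f"support {self.support} outside [0, 1]")
        if self.branch_length < 0:
            raise ValueError(f"negative branch length {self.branch_length}")

    @property
    def languages(self) -> tuple[str, str]:
        return (self.lang1, self.lang2)


@dataclass(frozen=True)
class DroppedPair:
    pair: SisterPair
    reason: str


def _node_support(node: "dendropy.Node") -> float:
    """Posterior support of an internal node, normalized to [0, 1].

    Values are taken from the node label (or bracketed support annotation);
    values above 1 are read as percentages.  Unannotated nodes are treated
    as fully supported (the published summary trees fix them).
    """
    raw = None
    if node.label is not None:
        raw = node.label
    elif node.taxon is not None and node.taxon.label is not None:
        raw = node.taxon.label
    if raw is None:
        return 1.0
    try:
        value = float(raw)
    except ValueError:
        return 1.0
    if value > 1.0:
        value /= 100.0
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"node support {raw!r} outside [0, 1] after normalization")
    return value


def _load_tree(tree: "str | Path | dendropy.Tree") -> "dendropy.Tree":
    if isinstance(tree, dendropy.Tree):
        return tree
    source = str(tree)
    if source.lstrip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def extract_cherries(
    tree: "str | Path | dendropy.Tree",
    min_support: float = 0.8,
) -> list[SisterPair]:
    """Return all two-tip clades whose parent support >= ``min_support``.

    Cherries are disjoint by construction (a tip has a unique parent), so
    the returned comparisons are phylogenetically independent.  Pairs are
    returned in tree traversal order with member order as in the tree.
    """
    t = _load_tree(tree)
    pairs: list[SisterPair] = []
    for node in t.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            support = _node_support(node)
            if support < min_support:
                continue
            left, right = children
            for c in children:
                if c.edge.length is not None and c.edge.length < 0:
                    raise ValueError(
                        f"negative edge length under cherry "
                        f"({left.taxon.label}, {right.taxon.label})"
                    )
            bl = _cherry_height(children)
            pairs.append(
                SisterPair(
                    lang1=left.taxon.label,
                    lang2=right.taxon.label,
                    support=support,
                    branch_length=bl,
                )
            )
    return pairs


def _cherry_height(children: list["dendropy.Node"]) -> float:
    lengths = [c.edge.length if c.edge.length is not None else 0.0 for c in children]
    if lengths[0] != lengths[1]:
        warnings.warn(
            "non-ultrametric cherry: using mean tip-to-ancestor path length",
            stacklevel=3,
        )
    return (lengths[0] + lengths[1]) / 2.0


def pair_branch_length(tree: "str | Path | dendropy.Tree", pair: SisterPair) -> float:
    """Height of the pair's ancestral node above the tips.

    The two tip edges of a cherry both measure the divergence of the pair;
    when they disagree (non-ultrametric tree) the mean is used.
    """
    t = _load_tree(tree)
    taxa = {pair.lang1, pair.lang2}
    for node in t.preorder_node_iter():
        children = node.child_nodes()
        if len(children) == 2 and all(c.is_leaf() for c in children):
            labels = {c.taxon.label for c in children}
            if labels == taxa:
                for c in children:
                    if c.edge.length is not None and c.edge.length < 0:
                        raise ValueError("negative edge length in cherry")
                return _cherry_height(children)
    raise ValueError(f"({pair.lang1}, {pair.lang2}) is not a cherry of the tree")


def filter_pairs(
    pairs: Iterable[SisterPair],
    meta: Mapping[str, LanguageMeta],
    taxonomy: Iterable[tuple[str, str]] | None = None,
) -> tuple[list[SisterPair], list[DroppedPair]]:
    """Attach populations and drop pairs failing the selection criteria.

    Dropped reasons: ``creole`` (either member is a creole), ``extinct``
    (either member extinct or ancient), ``missing_metadata`` /
    ``missing_population``, and ``taxonomy_conflict`` (pair absent from
    the reference taxonomy pair list, when one is supplied).
    """
    taxo_set = None
    if taxonomy is not None:
        taxo_set = {frozenset(p) for p in taxonomy}
    kept: list[SisterPair] = []
    dropped: list[DroppedPair] = []
    for pair in pairs:
        m1 = meta.get(pair.lang1)
        m2 = meta.get(pair.lang2)
        if m1 is None or m2 is None:
            dropped.append(DroppedPair(pair, "missing_metadata"))
            continue
        if m1.creole or m2.creole:
            dropped.append(DroppedPair(pair, "creole"))
            continue
        if m1.extinct or m2.extinct:
            dropped.append(DroppedPair(pair, "extinct"))
            continue
        if m1.population <= 0 or m2.population <= 0:
            dropped.append(DroppedPair(pair, "missing_population"))
            continue
        if taxo_set is not None and frozenset(pair.languages) not in taxo_set:
            dropped.append(DroppedPair(pair, "taxonomy_conflict"))
            continue
        kept.append(
            SisterPair(
                lang1=pair.lang1,
                lang2=pair.lang2,
                N1=m1.population,
                N2=m2.population,
                support=pair.support,
                branch_length=pair.branch_length,
            )
        )
    return kept, dropped


def read_language_meta(path: str | Path, delimiter: str = ",") -> dict[str, LanguageMeta]:
    """Read a language metadata table (language_id, population, creole, extinct)."""
    path = Path(path)
    out: dict[str, LanguageMeta] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter=delimiter)
        required = {"language_id", "population"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path.name}: missing column(s) {sorted(missing)}")
        for row in reader:
            lang = row["language_id"].strip()
            out[lang] = LanguageMeta(
                language=lang,
                population=int(float(row["population"])) if row["population"].strip() else 0,
                creole=row.get("creole", "false").strip().lower() in {"true", "1", "yes"},
                extinct=row.get("extinct", "false").strip().lower() in {"true", "1", "yes"},
            )
    return out


def read_taxonomy_pairs(path: str | Path, delimiter: str = ",") -> list[tuple[str, str]]:
    """Read a two-column reference pair list (header optional)."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(newline="", encoding="utf-8") as handle:
        for row in csv.reader(handle, delimiter=delimiter):
            if not row or row[0].strip().lower() in {"lang1", "language1", "language_id"}:
                continue
            pairs.append((row[0].strip(), row[1].strip()))
    return pairs
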