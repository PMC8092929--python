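"""Core data model for family-history (FH) notes and their annotations.

A note is a :class:`Document`: raw text segmented into paragraphs,
sentences and tokens, all carrying 0-based half-open ``[start, end)``
character offsets into the document text.  Extraction results are
document-scoped *sets* of :class:`FamilyMemberAnnotation` (a normalized
``(relative, side)`` pair) and :class:`ObservationAnnotation` (a disease
mention string).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 15 family-relationship types of the entity-identification task.
RELATIVES: tuple[str, ...] = (
    "Father", "Mother", "Parent",
    "Sister", "Brother", "Sibling",
    "Daughter", "Son", "Child",
    "Grandmother", "Grandfather", "Grandparent",
    "Cousin", "Aunt", "Uncle",
)

#: Relatives that are first degree (parents, siblings, children); by task
#: convention they always carry side-of-family NA.
FIRST_DEGREE: frozenset[str] = frozenset(
    {"Father", "Mother", "Parent", "Sister", "Brother", "Sibling",
     "Daughter", "Son", "Child"}
)

SIDES: tuple[str, ...] = ("Maternal", "Paternal", "NA")


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int
    tokens: tuple[Token, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Paragraph:
    index: int
    start: int
    end: int
    sentences: tuple[Sentence, ...]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    paragraphs: tuple[Paragraph, ...] = field(default_factory=tuple)

    def sentences(self) -> list[Sentence]:
        """All sentences in reading order, across paragraphs."""
        return [s for p in self.paragraphs for s in p.sentences]

    def paragraph_of(self, sentence: Sentence) -> Paragraph:
        for p in self.paragraphs:
            if p.start <= sentence.start and sentence.end <= p.end:
                return p
        raise ValueError("sentence does not lie inside any paragraph")


def normalize_ws(text: str) -> str:
    """Collapse internal whitespace runs to single spaces and strip."""
    return " ".join(text.split())


@dataclass(frozen=True)
class FamilyMemberAnnotation:
    """Normalized (relative, side-of-family) pair at document scope.

    First-degree relatives always carry side ``NA``; equality is by the
    pair, so document-level results deduplicate naturally in a set.
    """

    relative: str
    side: str = "NA"

    def __post_init__(self) -> None:
        if self.relative not in RELATIVES:
            raise ValueError(f"unknown relative type: {self.relative!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side of family: {self.side!r}")
        if self.relative in FIRST_DEGREE and self.side != "NA":
            raise ValueError(
                f"first-degree relative {self.relative} must have side NA, "
                f"got {self.side}"
            )


@dataclass(frozen=True)
class ObservationAnnotation:
    """A disease/condition mention, whitespace-normalized span text."""

    text: str

    def __post_init__(self) -> None:
        norm = normalize_ws(self.text)
        if not norm:
            raise ValueError("observation text must be non-empty")
        object.__setattr__(self, "text", norm)
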