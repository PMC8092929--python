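"""Hybrid rule/graph-based FamilyMember annotation.

Documents are analyzed sentence by sentence with the previous sentence
as context (sentence bigrams).  Candidate mentions are occurrences of
family-relationship words from a lexicon; a directed candidate graph is
built from linguistic patterns between adjacent candidates —
``X's *Y``, ``X *has/had *Y`` and ``Y of *X``, each meaning "Y is a
relative of X" — plus optional coreference links into the previous
sentence.  A small set of normalization rules then rewrites graph
vertices into final ``(relative, side-of-family)`` annotations:

  R1 uncle rule:          parent -> brother        => (Uncle, side of parent)
  R2 aunt rule:           parent -> sister         => (Aunt, side of parent)
  R3 grandparents rule:   parent -> parent         => (Grandparent*, side)
  R4 sibling's kids rule: sibling -> son/daughter  => suppressed (niece/nephew)
  R5 cousin rule 1:       aunt/uncle -> child      => (Cousin, side of aunt/uncle)
  R6 cousin rule 2:       grandparent -> cousin    => suppressed (too distant)

Vertices without an incoming edge keep their raw relation; relation
chains not covered by any rule (e.g. grandparent -> brother, a
great-uncle) are suppressed as too distant.  Where the graph does not
fix the side of family, a heuristic assigns it from the last occurrence
of *maternal*/*mother* vs *paternal*/*father* before the mention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .model import (
    FIRST_DEGREE,
    Document,
    FamilyMemberAnnotation,
    Paragraph,
    Sentence,
)

ALL_RULES: frozenset[str] = frozenset({"R1", "R2", "R3", "R4", "R5", "R6"})

#: Relationship words recognized as candidate mentions (plural and
#: informal variants map to the same normalized relation type).
LEXICON_WORDS: dict[str, str] = {
    "father": "Father", "dad": "Father",
    "mother": "Mother", "mom": "Mother", "mum": "Mother",
    "parent": "Parent", "parents": "Parent",
    "sister": "Sister", "sisters": "Sister",
    "brother": "Brother", "brothers": "Brother",
    "sibling": "Sibling", "siblings": "Sibling",
    "daughter": "Daughter", "daughters": "Daughter",
    "son": "Son", "sons": "Son",
    "child": "Child", "children": "Child", "kid": "Child", "kids": "Child",
    "grandmother": "Grandmother", "grandmothers": "Grandmother",
    "grandma": "Grandmother",
    "grandfather": "Grandfather", "grandfathers": "Grandfather",
    "grandpa": "Grandfather",
    "grandparent": "Grandparent", "grandparents": "Grandparent",
    "cousin": "Cousin", "cousins": "Cousin",
    "aunt": "Aunt", "aunts": "Aunt",
    "uncle": "Uncle", "uncles": "Uncle",
}

#: Relations dropped in the restricted 11-type configuration: their
#: surface words rarely introduce a specific family member (e.g. "She
#: has 4 siblings: two brothers and two sisters").
RESTRICTED_EXCLUDED: frozenset[str] = frozenset(
    {"Child", "Sibling", "Parent", "Grandparent"})

_PARENT_CLASS = {"Mother", "Father", "Parent"}
_SIBLING_CLASS = {"Brother", "Sister", "Sibling"}
_CHILD_CLASS = {"Son", "Daughter", "Child"}
_GRANDPARENT_CLASS = {"Grandmother", "Grandfather", "Grandparent"}

_MATERNAL_CUE = re.compile(r"\b(maternal|mother)\b", re.IGNORECASE)
_PATERNAL_CUE = re.compile(r"\b(paternal|father)\b", re.IGNORECASE)
_HAVE_WORDS = {"has", "had", "have"}


@dataclass(frozen=True)
class RelationLexicon:
    """Candidate-word lexicon, full (15 relations) or restricted (11)."""

    mode: int = 11

    def __post_init__(self) -> None:
        if self.mode not in (11, 15):
            raise ValueError("lexicon mode must be 11 or 15")

    def lookup(self, word: str) -> str | None:
        rel = LEXICON_WORDS.get(word.lower())
        if rel is None:
            return None
        if self.mode == 11 and rel in RESTRICTED_EXCLUDED:
            return None
        return rel


@dataclass(frozen=True)
class CandidateMention:
    """A relationship-word occurrence: raw relation + token position."""

    raw_relation: str
    token_index: int          # index into its sentence's token tuple
    start: int                # character offsets into document text
    end: int
    sentence_start: int       # identifies the owning sentence


@dataclass(frozen=True)
class CoreferenceLink:
    """A pronoun/alternative reference resolved to a previous-sentence
    candidate, supplied by an external coreference hook."""

    span: tuple[int, int]          # char span of the referring expression
    antecedent: CandidateMention   # candidate in the previous sentence


@dataclass
class CandidateGraph:
    """Directed 'is-a-relative-of' graph over one sentence bigram."""

    vertices: list[CandidateMention] = field(default_factory=list)
    context_vertices: list[CandidateMention] = field(default_factory=list)
    # edge (head, dependent, provenance): dependent is a relative of head
    edges: list[tuple[CandidateMention, CandidateMention, str]] = \
        field(default_factory=list)

    def heads_of(self, v: CandidateMention) -> list[CandidateMention]:
        return [h for h, d, _ in self.edges if d == v]


def detect_candidates(
    sentence: Sentence, lexicon: RelationLexicon,
) -> list[CandidateMention]:
    """Lexicon hits over sentence tokens, in reading order.

    Matching is case-insensitive at token boundaries; possessive forms
    ("mother's") yield the base-word candidate because the clitic is a
    separate token.
    """
    out = []
    for idx, tok in enumerate(sentence.tokens):
        rel = lexicon.lookup(tok.surface)
        if rel is not None:
            out.append(CandidateMention(
                rel, idx, tok.start, tok.end, sentence.start))
    return out


def _match_pattern(
    surfaces: Sequence[str],
    i: int, j: int,
    wildcard_max: int,
) -> tuple[str, str] | None:
    """Pattern between candidate tokens at positions i < j.

    Returns (direction, provenance): direction "fwd" means edge
    first -> second (X .. Y), "rev" means second -> first (Y of X).
    Wildcards span non-candidate tokens only (the pair is adjacent) and
    are capped at ``wildcard_max`` tokens per gap.
    """
    between = [s.lower() for s in surfaces[i + 1:j]]
    if between and between[0] == "'s" and len(between) - 1 <= wildcard_max:
        return ("fwd", "X's *Y")
    if between and between[0] == "of" and len(between) - 1 <= wildcard_max:
        return ("rev", "Y of *X")
    for k, w in enumerate(between):
        if w in _HAVE_WORDS and k <= wildcard_max \
                and len(between) - k - 1 <= wildcard_max:
            return ("fwd", "X *has/had *Y")
    return None


def build_graph(
    bigram: tuple[Sentence | None, Sentence],
    candidates: list[CandidateMention],
    prev_candidates: list[CandidateMention] | None = None,
    coref: Iterable[CoreferenceLink] = (),
    wildcard_max: int = 6,
) -> CandidateGraph:
    """Candidate graph for one sentence bigram.

    Edges are added between adjacent candidate pairs of the current
    sentence matching a pattern, and from previous-sentence antecedents
    to current candidates when a coreferring expression (resolved by the
    supplied links) takes the X slot of a pattern.
    """
    prev_sent, sent = bigram
    graph = CandidateGraph(vertices=list(candidates),
                           context_vertices=list(prev_candidates or []))
    surfaces = [t.surface for t in sent.tokens]

    for a in range(len(candidates)):
        b = a + 1
        if b >= len(candidates):
            break
        ci, cj = candidates[a], candidates[b]
        m = _match_pattern(surfaces, ci.token_index, cj.token_index,
                           wildcard_max)
        if m is None:
            continue
        direction, prov = m
        if direction == "fwd":
            graph.edges.append((ci, cj, prov))
        else:
            graph.edges.append((cj, ci, prov))

    # Coreference: a pronoun span resolved to a previous-sentence
    # candidate acts as the X slot for patterns against each current
    # candidate that has no nearer preceding candidate.
    for link in coref:
        # token index of the referring expression in the current sentence
        ref_idx = None
        for idx, tok in enumerate(sent.tokens):
            if tok.start >= link.span[0] and tok.end <= link.span[1]:
                ref_idx = idx
                break
        if ref_idx is None:
            continue
        for cand in candidates:
            if cand.token_index <= ref_idx:
                continue
            if any(c.token_index > ref_idx and c.token_index < cand.token_index
                   for c in candidates):
                continue
            m = _match_pattern(surfaces, ref_idx, cand.token_index,
                               wildcard_max)
            if m is not None and m[0] == "fwd":
                graph.edges.append((link.antecedent, cand, "coref:" + m[1]))
    return graph


def assign_family_side(position: int, document: Document) -> str:
    """Heuristic side of family for a mention starting at ``position``.

    The last occurrence before the mention of *maternal*/*mother* vs
    *paternal*/*father* (case-insensitive) decides; NA when neither
    appears earlier in the document.
    """
    prefix = document.text[:position]
    m_last = -1
    for m in _MATERNAL_CUE.finditer(prefix):
        m_last = m.start()
    p_last = -1
    for m in _PATERNAL_CUE.finditer(prefix):
        p_last = m.start()
    if m_last < 0 and p_last < 0:
        return "NA"
    return "Maternal" if m_last > p_last else "Paternal"


def _side_of_parent(head: CandidateMention, document: Document) -> str:
    if head.raw_relation == "Mother":
        return "Maternal"
    if head.raw_relation == "Father":
        return "Paternal"
    return assign_family_side(head.start, document)


def _finalize(relative: str, side: str) -> FamilyMemberAnnotation:
    if relative in FIRST_DEGREE:
        return FamilyMemberAnnotation(relative, "NA")
    return FamilyMemberAnnotation(relative, side)


def _resolved_side(
    vertex: CandidateMention,
    graph: CandidateGraph,
    document: Document,
) -> str:
    """Side of an aunt/uncle vertex: from its own parent-class head when
    one exists (R1/R2 structure), else the document heuristic."""
    for head in graph.heads_of(vertex):
        if head.raw_relation in _PARENT_CLASS:
            return _side_of_parent(head, document)
    return assign_family_side(vertex.start, document)


def normalize_graph(
    graph: CandidateGraph,
    document: Document,
    rules_enabled: frozenset[str] = ALL_RULES,
) -> set[FamilyMemberAnnotation]:
    """Apply the rule table to every current-sentence vertex.

    With no rules enabled the graph edges are ignored entirely and every
    vertex maps to its raw relation (the no-rules baseline).  With rules
    active, a vertex whose incoming edge matches no (enabled or
    disabled) rule is suppressed as a too-distant relationship.
    """
    out: set[FamilyMemberAnnotation] = set()
    for v in graph.vertices:
        heads = graph.heads_of(v)
        if not heads or not rules_enabled:
            out.add(_finalize(
                v.raw_relation, assign_family_side(v.start, document)))
            continue
        # nearest preceding head wins when several edges point at v
        head = max(heads, key=lambda h: (h.sentence_start, h.start))
        rule = _dispatch(head.raw_relation, v.raw_relation)
        if rule is None:
            continue  # uncovered chain: too distant, suppress
        name, action = rule
        if name not in rules_enabled:
            out.add(_finalize(
                v.raw_relation, assign_family_side(v.start, document)))
            continue
        if action == "suppress":
            continue
        if action == "uncle":
            out.add(_finalize("Uncle", _side_of_parent(head, document)))
        elif action == "aunt":
            out.add(_finalize("Aunt", _side_of_parent(head, document)))
        elif action == "grand":
            grand = {"Mother": "Grandmother", "Father": "Grandfather",
                     "Parent": "Grandparent"}[v.raw_relation]
            out.add(_finalize(grand, _side_of_parent(head, document)))
        elif action == "cousin":
            out.add(_finalize("Cousin", _resolved_side(head, graph, document)))
    return out


def _dispatch(head_rel: str, dep_rel: str) -> tuple[str, str] | None:
    """(rule name, action) for a head -> dependent relation pair."""
    if head_rel in _PARENT_CLASS:
        if dep_rel == "Brother":
            return ("R1", "uncle")
        if dep_rel == "Sister":
            return ("R2", "aunt")
        if dep_rel in _PARENT_CLASS:
            return ("R3", "grand")
    if head_rel in _SIBLING_CLASS and dep_rel in _CHILD_CLASS:
        return ("R4", "suppress")
    if head_rel in {"Aunt", "Uncle"} and dep_rel in _CHILD_CLASS:
        return ("R5", "cousin")
    if head_rel in _GRANDPARENT_CLASS and dep_rel == "Cousin":
        return ("R6", "suppress")
    return None


CoreferenceHook = Callable[
    [Document, Sentence | None, Sentence, list[CandidateMention]],
    list[CoreferenceLink],
]


@dataclass(frozen=True)
class AnnotatorConfig:
    lexicon_mode: int = 11
    rules_enabled: frozenset[str] = ALL_RULES
    use_paragraph_filter: bool = True
    wildcard_max_tokens: int = 6
    bigrams_cross_paragraphs: bool = True


def annotate_document(
    document: Document,
    config: AnnotatorConfig | None = None,
    paragraph_filter: "object | None" = None,
    coref_hook: CoreferenceHook | None = None,
) -> set[FamilyMemberAnnotation]:
    """Document-level FamilyMember annotation set.

    Sentences inside paragraphs predicted invalid by the (optional)
    paragraph filter are skipped; each remaining sentence is processed
    with its predecessor as context and the per-sentence annotation
    sets are unioned.  ``paragraph_filter`` is any object with a
    ``predict_valid(prev_text, text) -> (prob, bool)`` method.
    """
    from .preprocess import SegmenterConfig, sentence_bigrams

    config = config or AnnotatorConfig()
    lexicon = RelationLexicon(config.lexicon_mode)

    invalid_paragraphs: set[int] = set()
    if paragraph_filter is not None and config.use_paragraph_filter:
        prev_p: Paragraph | None = None
        for p in document.paragraphs:
            prev_text = document.text[prev_p.start:prev_p.end] if prev_p else ""
            _, valid = paragraph_filter.predict_valid(
                prev_text, document.text[p.start:p.end])
            if not valid:
                invalid_paragraphs.add(p.index)
            prev_p = p

    seg = SegmenterConfig(
        bigrams_cross_paragraphs=config.bigrams_cross_paragraphs)
    result: set[FamilyMemberAnnotation] = set()
    for prev_sent, sent in sentence_bigrams(document, seg):
        para = document.paragraph_of(sent)
        if para.index in invalid_paragraphs:
            continue
        candidates = detect_candidates(sent, lexicon)
        if not candidates:
            continue
        prev_candidates = (detect_candidates(prev_sent, lexicon)
                           if prev_sent is not None else [])
        links: list[CoreferenceLink] = []
        if coref_hook is not None and prev_sent is not None:
            links = coref_hook(document, prev_sent, sent, prev_candidates)
        graph = build_graph((prev_sent, sent), candidates,
                            prev_candidates, links,
                            config.wildcard_max_tokens)
        result |= normalize_graph(graph, document, config.rules_enabled)
    return result
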