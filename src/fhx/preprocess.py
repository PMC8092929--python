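"""Deterministic paragraph / sentence / token segmentation with offsets.

The segmenter is intentionally rule based so that the pipeline is fully
reproducible: paragraphs are blank-line separated blocks, sentence
boundaries sit after ``.``, ``?`` or ``!`` followed by whitespace and a
capital letter (with an abbreviation escape list), and tokens are
alphanumeric runs, apostrophe clitics (``mother's`` -> ``mother`` +
``'s``) and single punctuation characters.  Every unit records exact
``[start, end)`` character offsets into the document text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import Document, Paragraph, Sentence, Token

#: Strings that never terminate a sentence even when followed by
#: whitespace + capital (case-insensitive matching on the final word).
DEFAULT_ABBREVIATIONS: tuple[str, ...] = (
    "mr.", "mrs.", "ms.", "dr.", "prof.", "st.", "jr.", "sr.", "vs.",
    "e.g.", "i.e.", "etc.",
)

_PARAGRAPH_SEP = re.compile(r"\n[ \t]*\n(?:[ \t]*\n)*")
_TOKEN = re.compile(r"[A-Za-z0-9]+|'[A-Za-z0-9]+|[^\sA-Za-z0-9]")
_BOUNDARY = re.compile(r"[.?!](?=\s+[A-Z\"'(])")


@dataclass(frozen=True)
class SegmenterConfig:
    """Segmentation knobs.

    abbreviations: lowercase-folded words (with trailing period) that are
        never treated as sentence ends.
    bigrams_cross_paragraphs: whether the sentence-bigram context window
        runs across paragraph boundaries.
    """

    abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS
    bigrams_cross_paragraphs: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "abbreviations",
            tuple(a.lower() for a in self.abbreviations),
        )


def split_paragraphs(text: str) -> list[tuple[int, int]]:
    """Spans of blank-line separated paragraphs, in reading order.

    Runs of blank lines collapse into a single separator; leading and
    trailing whitespace of the whole text belongs to no paragraph.
    """
    spans: list[tuple[int, int]] = []
    pos = 0
    for m in _PARAGRAPH_SEP.finditer(text):
        spans.append((pos, m.start()))
        pos = m.end()
    spans.append((pos, len(text)))
    out = []
    for start, end in spans:
        chunk = text[start:end]
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            out.append((start + lstrip, end - rstrip))
    return out


def split_sentences(
    text: str, config: SegmenterConfig | None = None,
    offset: int = 0,
) -> list[tuple[int, int]]:
    """Sentence spans within ``text``; offsets shifted by ``offset``.

    A boundary is a ``.?!`` followed by whitespace and a capital (or an
    opening quote/parenthesis), unless the word ending at the period is
    on the abbreviation list.
    """
    config = config or SegmenterConfig()
    if not text.strip():
        return []
    cuts: list[int] = []
    for m in _BOUNDARY.finditer(text):
        end = m.end()
        # word ending at this period, e.g. "Mrs." or "e.g."
        wstart = end - 1
        while wstart > 0 and not text[wstart - 1].isspace():
            wstart -= 1
        if text[wstart:end].lower() in config.abbreviations:
            continue
        cuts.append(end)
    spans = []
    pos = 0
    for cut in cuts + [len(text)]:
        chunk = text[pos:cut]
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((offset + pos + lstrip, offset + cut - rstrip))
        pos = cut
    return spans


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Tokens with exact offsets (shifted by ``offset``).

    Alphanumeric runs stay whole, apostrophe clitics split off as one
    token (``'s``), and every other non-space character is its own token.
    """
    return [
        Token(m.group(), offset + m.start(), offset + m.end())
        for m in _TOKEN.finditer(text)
    ]


def segment(doc_id: str, text: str,
            config: SegmenterConfig | None = None) -> Document:
    """Full segmentation of a raw note into a :class:`Document`."""
    config = config or SegmenterConfig()
    paragraphs = []
    for idx, (pstart, pend) in enumerate(split_paragraphs(text)):
        sentences = []
        for sstart, send in split_sentences(
                text[pstart:pend], config, offset=pstart):
            tokens = tuple(tokenize(text[sstart:send], offset=sstart))
            sentences.append(Sentence(sstart, send, tokens))
        paragraphs.append(Paragraph(idx, pstart, pend, tuple(sentences)))
    return Document(doc_id, text, tuple(paragraphs))


def sentence_bigrams(
    document: Document, config: SegmenterConfig | None = None,
) -> list[tuple[Sentence | None, Sentence]]:
    """Pairs ``(previous sentence or None, sentence)`` in reading order.

    The previous sentence serves as context for cross-sentence cues; by
    default the window crosses paragraph boundaries, configurable off.
    """
    config = config or SegmenterConfig()
    pairs: list[tuple[Sentence | None, Sentence]] = []
    if config.bigrams_cross_paragraphs:
        sents = document.sentences()
        prev: Sentence | None = None
        for s in sents:
            pairs.append((prev, s))
            prev = s
    else:
        for p in document.paragraphs:
            prev = None
            for s in p.sentences:
                pairs.append((prev, s))
                prev = s
    return pairs
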