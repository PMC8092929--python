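"""Corpus and annotation readers/writers.

Notes are one UTF-8 ``.txt`` file per document (doc_id = file stem).
Annotations — gold or predicted — use a one-entity-per-line TSV:

    <doc_id>\\tFamilyMember\\t<Relative>\\t<Side>
    <doc_id>\\tObservation\\t<text>

``#``-prefixed lines are comments.  Reading collapses duplicates into
set semantics; writing is deterministic (sorted rows) and round-trips
through reading to identical sets.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .model import (
    Document,
    FamilyMemberAnnotation,
    ObservationAnnotation,
)
from .preprocess import SegmenterConfig, segment

log = logging.getLogger(__name__)

PerDoc = dict[str, tuple[set[FamilyMemberAnnotation],
                         set[ObservationAnnotation]]]


def read_corpus(
    directory: str | Path, config: SegmenterConfig | None = None,
) -> list[Document]:
    """All ``.txt`` notes under ``directory``, segmented, sorted by id."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.txt"))
    if not paths:
        raise FileNotFoundError(f"no documents found in {directory}")
    docs = []
    for path in paths:
        try:
            text = path.read_text(encoding="utf-8")
        except (OSError, UnicodeDecodeError) as exc:
            raise RuntimeError(f"cannot read note file {path}: {exc}") from exc
        if not text.strip():
            log.warning("empty note file %s", path)
        docs.append(segment(path.stem, text, config))
    return docs


def read_annotations(tsv: str | Path) -> PerDoc:
    """Parse an annotation TSV into per-document annotation sets."""
    result: PerDoc = {}
    for lineno, raw in enumerate(
            Path(tsv).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 3:
            raise ValueError(f"{tsv}:{lineno}: expected >=3 tab-separated "
                             f"columns, got {len(cols)}")
        doc_id, etype = cols[0], cols[1]
        fm, obs = result.setdefault(doc_id, (set(), set()))
        if etype == "FamilyMember":
            if len(cols) != 4:
                raise ValueError(
                    f"{tsv}:{lineno}: FamilyMember rows need 4 columns")
            try:
                fm.add(FamilyMemberAnnotation(cols[2], cols[3]))
            except ValueError as exc:
                raise ValueError(f"{tsv}:{lineno}: {exc}") from exc
        elif etype == "Observation":
            if len(cols) != 3:
                raise ValueError(
                    f"{tsv}:{lineno}: Observation rows need 3 columns")
            try:
                obs.add(ObservationAnnotation(cols[2]))
            except ValueError as exc:
                raise ValueError(f"{tsv}:{lineno}: {exc}") from exc
        else:
            raise ValueError(f"{tsv}:{lineno}: unknown entity type {etype!r}")
    return result


def write_annotations(results: PerDoc, out: str | Path) -> None:
    """Write per-document sets as a deterministic, sorted TSV."""
    rows: list[str] = []
    for doc_id in sorted(results):
        fm, obs = results[doc_id]
        for a in sorted(fm, key=lambda a: (a.relative, a.side)):
            rows.append(f"{doc_id}\tFamilyMember\t{a.relative}\t{a.side}")
        for o in sorted(obs, key=lambda o: o.text):
            rows.append(f"{doc_id}\tObservation\t{o.text}")
    Path(out).write_text(
        "".join(r + "\n" for r in rows), encoding="utf-8")


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` configuration file; ``#`` comments allowed."""
    config: dict[str, str] = {}
    for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    log.info("resolved config: %s", config)
    return config
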