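"""Synthetic family-history note generator with exact gold annotations.

The generator emulates the structure of shared-task FH corpora so the
whole pipeline is trainable and testable without access-restricted
data: multi-paragraph notes, relationship mentions over the 15-type
set, disease mentions from a bundled lexicon, partner-family
distractor paragraphs, enumeration sentences, cross-sentence pronoun
references, negated/general disease contexts and non-mention usages
("on her father's side").

Gold annotations are emitted *by construction* from the sampled family
structure — never by running the extractor on its own output — so
tests against generated corpora are non-circular.  Distractor content
(partner's family, nieces/nephews, too-distant relatives, negated
contexts) contributes no gold.  Paragraph validity labels follow the
task's rule: a paragraph is valid iff at least one gold annotation
lies within its scope.

Each relative-mention sentence is built from a template; the core
templates are exactly invertible by the rule engine, so a corpus drawn
with all distractor probabilities at zero is one the annotator should
solve perfectly.  A held-out template subset (alternative disease verb
phrasings) supports generalization tests of the trained tagger.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .model import FIRST_DEGREE, Document, FamilyMemberAnnotation, \
    ObservationAnnotation
from .preprocess import segment

# ---------------------------------------------------------------------
# Lexicon and configuration
# ---------------------------------------------------------------------


def load_disease_lexicon() -> tuple[str, ...]:
    """The bundled disease/condition lexicon (~200 entries)."""
    text = resources.files("fhx").joinpath("data/diseases.txt") \
        .read_text(encoding="utf-8")
    return tuple(line.strip() for line in text.splitlines()
                 if line.strip() and not line.startswith("#"))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus simulation.

    Probabilities gate the per-document distractor phenomena; the
    defaults aim at a realistic mix in which partner paragraphs,
    enumerations and negated contexts are common but not dominant.
    ``n_documents`` defaults to 99, the size of the shared task's
    training split.
    """

    n_documents: int = 99
    seed: int = 0
    partner_prob: float = 0.3
    enum_prob: float = 0.3
    pronoun_chain_prob: float = 0.2
    negation_prob: float = 0.35
    nonmention_prob: float = 0.15
    sibling_kids_prob: float = 0.2
    distant_relative_prob: float = 0.1
    template_set: str = "train"            # "train" | "heldout"
    disease_pool: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("partner_prob", "enum_prob", "pronoun_chain_prob",
                     "negation_prob", "nonmention_prob",
                     "sibling_kids_prob", "distant_relative_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.template_set not in ("train", "heldout"):
            raise ValueError("template_set must be 'train' or 'heldout'")

    def rule_covered(self) -> "GeneratorConfig":
        """Variant with every distractor phenomenon switched off."""
        return replace(self, partner_prob=0.0, enum_prob=0.0,
                       pronoun_chain_prob=0.0, negation_prob=0.0,
                       nonmention_prob=0.0, sibling_kids_prob=0.0,
                       distant_relative_prob=0.0)


@dataclass(frozen=True)
class Relative:
    relation: str
    side: str
    diseases: tuple[str, ...] = ()


@dataclass(frozen=True)
class FamilyStructure:
    surname: str
    female: bool            # patient gender, drives pronouns
    relatives: tuple[Relative, ...]
    # distractor content (contributes no gold)
    partner_paragraph: bool = False
    partner_diseases: tuple[str, ...] = ()
    enum_sentence: bool = False
    pronoun_chain: bool = False
    negation_diseases: tuple[str, ...] = ()
    nonmention: bool = False
    nonmention_disease: str = ""
    sibling_kids: bool = False
    distant_relative: bool = False

    @property
    def poss(self) -> str:
        return "Her" if self.female else "His"

    @property
    def title(self) -> str:
        return "Ms." if self.female else "Mr."

    def has(self, relation: str, side: str | None = None) -> bool:
        return any(r.relation == relation and (side is None or r.side == side)
                   for r in self.relatives)


_SURNAMES = ("Taylor", "Williams", "Chen", "Alexander", "Garcia", "Nguyen",
             "Smith", "Patel", "Brown", "Okafor", "Kim", "Rossi")

_GRANDPARENTS = (("Grandmother", "Maternal"), ("Grandfather", "Maternal"),
                 ("Grandmother", "Paternal"), ("Grandfather", "Paternal"))


def sample_family(config: GeneratorConfig,
                  rng: np.random.Generator) -> FamilyStructure:
    """Sample a kinship-consistent family with distractor phenomena.

    Sided relatives imply the corresponding parent (a maternal uncle is
    the mother's brother); cousins imply an aunt or uncle on the same
    side.  At least one first-degree relative is always present.
    """
    pool = list(config.disease_pool or load_disease_lexicon())
    used: set[str] = set()

    def draw_diseases(p_none: float = 0.2) -> tuple[str, ...]:
        u = rng.random()
        k = 0 if u < p_none else (1 if u < 1 - 0.15 else 2)
        out = []
        for _ in range(k):
            avail = [d for d in pool if d not in used]
            if not avail:
                break
            d = avail[int(rng.integers(len(avail)))]
            used.add(d)
            out.append(d)
        return tuple(out)

    rels: list[Relative] = []

    def add(relation: str, side: str = "NA", p_none: float = 0.2) -> None:
        rels.append(Relative(relation, side, draw_diseases(p_none)))

    has_mother = rng.random() < 0.85
    has_father = rng.random() < 0.85
    for _ in range(int(rng.choice([0, 1, 2], p=[0.4, 0.45, 0.15]))):
        add("Brother")
    for _ in range(int(rng.choice([0, 1, 2], p=[0.4, 0.45, 0.15]))):
        add("Sister")
    for _ in range(int(rng.choice([0, 1], p=[0.65, 0.35]))):
        add("Son" if rng.random() < 0.5 else "Daughter")

    grandparents = [gp for gp in _GRANDPARENTS if rng.random() < 0.3]
    aunts_uncles = []
    for relation in ("Aunt", "Uncle"):
        if rng.random() < 0.45:
            side = "Maternal" if rng.random() < 0.5 else "Paternal"
            aunts_uncles.append((relation, side))
    cousins = []
    if rng.random() < 0.3:
        side = "Maternal" if rng.random() < 0.5 else "Paternal"
        cousins.append(("Cousin", side))
        # a cousin is a child of an aunt/uncle on that side
        if not any(s == side for _, s in aunts_uncles):
            aunts_uncles.append(
                ("Aunt" if rng.random() < 0.5 else "Uncle", side))

    # sided relatives imply the corresponding parent
    if any(s == "Maternal" for _, s in grandparents + aunts_uncles + cousins):
        has_mother = True
    if any(s == "Paternal" for _, s in grandparents + aunts_uncles + cousins):
        has_father = True
    if not (has_mother or has_father or rels):
        has_mother = True

    if has_mother:
        rels.insert(0, Relative("Mother", "NA", draw_diseases(0.15)))
    if has_father:
        idx = 1 if has_mother else 0
        rels.insert(idx, Relative("Father", "NA", draw_diseases(0.15)))
    for relation, side in grandparents:
        add(relation, side, p_none=0.15)
    for relation, side in aunts_uncles:
        add(relation, side)
    for relation, side in cousins:
        add(relation, side)

    enum = (rng.random() < config.enum_prob
            and any(r.relation == "Brother" for r in rels)
            and any(r.relation == "Sister" for r in rels))
    chain = (rng.random() < config.pronoun_chain_prob
             and has_father
             and any(r.relation == "Uncle" and r.side == "Paternal"
                     for r in rels))
    kids = (rng.random() < config.sibling_kids_prob
            and any(r.relation == "Sister" for r in rels))
    distant = (rng.random() < config.distant_relative_prob
               and any(r.relation == "Grandmother" and r.side == "Maternal"
                       for r in rels))

    def unused(k: int) -> tuple[str, ...]:
        avail = [d for d in pool if d not in used]
        picked = []
        for _ in range(min(k, len(avail))):
            d = avail[int(rng.integers(len(avail)))]
            avail.remove(d)
            used.add(d)
            picked.append(d)
        return tuple(picked)

    partner = rng.random() < config.partner_prob
    negated = unused(2) if rng.random() < config.negation_prob else ()
    nonmention = rng.random() < config.nonmention_prob and has_father
    nm_disease = unused(1)[0] if nonmention else ""

    return FamilyStructure(
        surname=_SURNAMES[int(rng.integers(len(_SURNAMES)))],
        female=bool(rng.random() < 0.5),
        relatives=tuple(rels),
        partner_paragraph=partner,
        partner_diseases=unused(2) if partner else (),
        enum_sentence=enum,
        pronoun_chain=chain,
        negation_diseases=negated,
        nonmention=nonmention,
        nonmention_disease=nm_disease,
        sibling_kids=kids,
        distant_relative=distant,
    )


# ---------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------

#: Disease verb phrases.  The "train" set is used by default; the
#: "heldout" set is reserved for generalization tests of the tagger.
_DISEASE_PHRASES = {
    "train": ("has {d}", "had {d}", "died of {d}",
              "was diagnosed with {d}", "suffers from {d}"),
    "heldout": ("is being treated for {d}", "struggles with {d}",
                "passed away from {d}"),
}

_SIDE_WORD = {"Maternal": "maternal", "Paternal": "paternal"}
_PARENT_OF_SIDE = {"Maternal": "mother", "Paternal": "father"}


@dataclass(frozen=True)
class RenderedSentence:
    text: str
    fm_gold: frozenset[FamilyMemberAnnotation] = frozenset()
    obs_gold: tuple[str, ...] = ()


@dataclass(frozen=True)
class RenderedNote:
    text: str
    fm_gold: set[FamilyMemberAnnotation]
    obs_gold: set[ObservationAnnotation]
    paragraph_valid: list[bool]

    def document(self, doc_id: str) -> Document:
        return segment(doc_id, self.text)


def _fm(relation: str, side: str = "NA") -> FamilyMemberAnnotation:
    if relation in FIRST_DEGREE:
        side = "NA"
    return FamilyMemberAnnotation(relation, side)


def _disease_clause(disease: str, config: GeneratorConfig,
                    rng: np.random.Generator) -> str:
    phrases = _DISEASE_PHRASES[config.template_set]
    return phrases[int(rng.integers(len(phrases)))].format(d=disease)


def _health_clause(rng: np.random.Generator) -> str:
    options = ("is alive and well", "is healthy",
               "is doing well", "remains in good health")
    return options[int(rng.integers(len(options)))]


def _desc(diseases: tuple[str, ...], config: GeneratorConfig,
          rng: np.random.Generator) -> str:
    """Verb phrase mentioning every disease of a relative (or health)."""
    if not diseases:
        return _health_clause(rng)
    return " and ".join(_disease_clause(d, config, rng) for d in diseases)


def _render_relative(
    fam: FamilyStructure, rel: Relative,
    config: GeneratorConfig, rng: np.random.Generator,
) -> list[RenderedSentence]:
    """Sentences introducing one blood relative (rule-invertible)."""
    poss = fam.poss
    out: list[RenderedSentence] = []
    desc = _desc(rel.diseases, config, rng)
    word = rel.relation.lower()
    gold = {_fm(rel.relation, rel.side)}
    obs = rel.diseases

    if rel.relation in FIRST_DEGREE:
        out.append(RenderedSentence(
            f"{poss} {word} {desc}.", frozenset(gold), obs))
        return out

    side_word = _SIDE_WORD[rel.side]
    parent_word = _PARENT_OF_SIDE[rel.side]
    parent_rel = "Mother" if rel.side == "Maternal" else "Father"
    style = rng.random()

    if rel.relation in ("Aunt", "Uncle"):
        sib = "sister" if rel.relation == "Aunt" else "brother"
        if style < 0.35:
            text = f"{poss} {side_word} {word} {desc}."
        elif style < 0.6:
            text = f"{poss} {parent_word}'s {sib} {desc}."
            gold.add(_fm(parent_rel))
        elif style < 0.8:
            text = f"{poss} {parent_word} has a {sib} who {desc}."
            gold.add(_fm(parent_rel))
        else:
            text = f"The {sib} of {poss.lower()} {parent_word} {desc}."
            gold.add(_fm(parent_rel))
        out.append(RenderedSentence(text, frozenset(gold), obs))
    elif rel.relation in ("Grandmother", "Grandfather"):
        gp_parent = "mother" if rel.relation == "Grandmother" else "father"
        if style < 0.5:
            text = f"{poss} {side_word} {word} {desc}."
        else:
            text = f"{poss} {parent_word}'s {gp_parent} {desc}."
            gold.add(_fm(parent_rel))
        out.append(RenderedSentence(text, frozenset(gold), obs))
    elif rel.relation == "Cousin":
        helper = next(
            (r for r in fam.relatives
             if r.relation in ("Aunt", "Uncle") and r.side == rel.side),
            None)
        if style < 0.5 or helper is None:
            text = f"{poss} {side_word} cousin {desc}."
        else:
            child = "son" if rng.random() < 0.5 else "daughter"
            text = (f"{poss} {side_word} {helper.relation.lower()}'s "
                    f"{child} {desc}.")
            gold.add(_fm(helper.relation, helper.side))
        out.append(RenderedSentence(text, frozenset(gold), obs))
    else:
        # Parent / Sibling / Child / Grandparent surface words are only
        # produced by enumeration-style content, handled elsewhere.
        out.append(RenderedSentence(
            f"{poss} {word} {desc}.", frozenset(gold), obs))
    return out


def render_note(
    fam: FamilyStructure, config: GeneratorConfig,
    rng: np.random.Generator,
) -> RenderedNote:
    """Instantiate a full note for a sampled family.

    Gold sets come from the structure members each template mentions;
    partner-family, niece/nephew, too-distant and negated content
    contributes no gold.  Paragraph validity is true iff a paragraph
    holds at least one gold annotation.
    """
    poss = fam.poss
    pron = "She" if fam.female else "He"
    paragraphs: list[list[RenderedSentence]] = []

    age = int(rng.integers(22, 68))
    intro = RenderedSentence(
        f"{fam.title} {fam.surname} is a {age}-year-old "
        f"{'woman' if fam.female else 'man'} seen today for review of "
        f"family medical risk factors.")
    paragraphs.append([intro])

    first_degree = [r for r in fam.relatives if r.relation in FIRST_DEGREE]
    extended = [r for r in fam.relatives if r.relation not in FIRST_DEGREE]

    core: list[RenderedSentence] = []
    enum_done = False
    chain_done = False
    skip_paternal_uncle = fam.pronoun_chain
    for rel in first_degree:
        if fam.enum_sentence and not enum_done \
                and rel.relation in ("Brother", "Sister"):
            n_b = sum(1 for r in first_degree if r.relation == "Brother")
            n_s = sum(1 for r in first_degree if r.relation == "Sister")
            core.append(RenderedSentence(
                f"{pron} has {n_b + n_s} siblings: {n_b} "
                f"{'brother' if n_b == 1 else 'brothers'} and {n_s} "
                f"{'sister' if n_s == 1 else 'sisters'}.",
                frozenset({_fm('Brother'), _fm('Sister')})))
            enum_done = True
        if fam.pronoun_chain and not chain_done and rel.relation == "Father":
            uncle = next(r for r in fam.relatives
                         if r.relation == "Uncle" and r.side == "Paternal")
            core.append(RenderedSentence(
                f"{poss} father {_desc(rel.diseases, config, rng)}.",
                frozenset({_fm('Father')}), rel.diseases))
            core.append(RenderedSentence(
                f"His brother {_desc(uncle.diseases, config, rng)}.",
                frozenset({_fm('Uncle', 'Paternal')}), uncle.diseases))
            chain_done = True
            continue
        core.extend(_render_relative(fam, rel, config, rng))
    if fam.sibling_kids:
        core.append(RenderedSentence(
            f"{poss} sister has a healthy son.",
            frozenset({_fm('Sister')})))
    if fam.nonmention:
        core.append(RenderedSentence(
            f"{pron} states on {poss.lower()} father's side, there is "
            f"{fam.nonmention_disease}."))
    if core:
        paragraphs.append(core)

    ext: list[RenderedSentence] = []
    for rel in extended:
        if skip_paternal_uncle and rel.relation == "Uncle" \
                and rel.side == "Paternal":
            skip_paternal_uncle = False  # already rendered in the chain
            continue
        ext.extend(_render_relative(fam, rel, config, rng))
    if fam.distant_relative:
        ext.append(RenderedSentence(
            f"{poss} maternal grandmother's cousin was recently seen "
            f"at the same clinic.",
            frozenset({_fm('Grandmother', 'Maternal')})))
    if ext:
        paragraphs.append(ext)

    if fam.partner_paragraph:
        spouse = "husband" if fam.female else "wife"
        sp_poss = "His" if fam.female else "Her"
        d1, d2 = (fam.partner_diseases + ("", ""))[:2]
        partner = [
            RenderedSentence(
                f"{fam.title} {fam.surname}'s {spouse} also reports a "
                f"significant family history."),
            RenderedSentence(
                f"{sp_poss} father has a brother who is currently healthy."),
        ]
        if d1:
            partner.append(RenderedSentence(
                f"{sp_poss} maternal aunt has {d1}."))
        if d2:
            partner.append(RenderedSentence(
                f"{sp_poss} paternal cousin had {d2}."))
        paragraphs.append(partner)

    if fam.negation_diseases:
        d1, d2 = (fam.negation_diseases + ("",))[:2]
        tail = f"{d1} or {d2}" if d2 else d1
        paragraphs.append([RenderedSentence(
            f"There is no known family history of {tail}.")])

    fm_gold: set[FamilyMemberAnnotation] = set()
    obs_gold: set[ObservationAnnotation] = set()
    validity: list[bool] = []
    blocks: list[str] = []
    for para in paragraphs:
        valid = False
        for sent in para:
            fm_gold |= sent.fm_gold
            for d in sent.obs_gold:
                obs_gold.add(ObservationAnnotation(d))
            if sent.fm_gold or sent.obs_gold:
                valid = True
        validity.append(valid)
        blocks.append(" ".join(s.text for s in para))
    return RenderedNote("\n\n".join(blocks) + "\n",
                        fm_gold, obs_gold, validity)


# ---------------------------------------------------------------------
# Corpus-level API
# ---------------------------------------------------------------------


def generate_notes(
    config: GeneratorConfig,
) -> list[tuple[str, RenderedNote]]:
    """``n_documents`` rendered notes with ids ``doc_000``, ``doc_001``…

    Byte-identical across runs for the same (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    out = []
    for i in range(config.n_documents):
        fam = sample_family(config, rng)
        note = render_note(fam, config, rng)
        out.append((f"doc_{i:03d}", note))
    return out


def generate_corpus(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Write a corpus directory: notes, gold TSV, paragraph labels,
    and a manifest recording the exact generation settings."""
    from .io import write_annotations

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    notes = generate_notes(config)
    gold = {}
    label_rows = []
    for doc_id, note in notes:
        (out_dir / f"{doc_id}.txt").write_text(note.text, encoding="utf-8")
        gold[doc_id] = (note.fm_gold, note.obs_gold)
        for idx, valid in enumerate(note.paragraph_valid):
            label_rows.append(f"{doc_id}\t{idx}\t{int(valid)}")
    write_annotations(gold, out_dir / "gold.tsv")
    (out_dir / "paragraph_labels.tsv").write_text(
        "".join(r + "\n" for r in label_rows), encoding="utf-8")
    manifest = {"n_documents": config.n_documents, "seed": config.seed,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in vars(config).items()}}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8")
    return out_dir
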