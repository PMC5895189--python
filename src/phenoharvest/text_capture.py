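"""Ingestion and semantic annotation of telegraphic taxonomic descriptions.

Telegraphic descriptions ("Leaves ovate, 6-10 cm long; petiole red.") drop
verbs and articles; each sentence opens with the structure under discussion
and subsequent clauses state its characters.  This module loads description
batches, strips explanatory parentheticals, segments sentences into clauses,
and parses each clause into :class:`Annotation` triples
(structure, character, value) using the glossary, finally serializing each
taxon to an annotated XML document.

The numeric-measurement grammar follows the conventional four-part botanical
range notation ``(A-)B-C(-D) unit``: ``B-C`` is the typical range and the
parenthesized extremes are atypical minima/maxima.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

from lxml import etree

from .errors import BatchFormatError, MalformedRangeError
from .glossary import Glossary, normalize_term, _DASHES

RANKS = ("family", "genus", "species", "infraspecies")

#: Rank ordering, family = highest.
RANK_LEVEL = {r: i for i, r in enumerate(RANKS)}

#: Dimension words that bind a trailing measurement to a named dimension.
DIMENSION_WORDS: dict[str, str] = {
    "long": "length",
    "length": "length",
    "wide": "width",
    "broad": "width",
    "width": "width",
    "thick": "thickness",
    "tall": "height",
    "high": "height",
    "diam": "diameter",
    "diameter": "diameter",
    "across": "diameter",
}

#: Frequency/hedge adverbs captured as annotation modifiers.
MODIFIER_WORDS = frozenset(
    "sometimes usually often rarely occasionally mostly frequently seldom "
    "generally typically".split()
)

#: Connectives skipped during clause parsing ("to" keeps its range meaning).
CONNECTIVES = frozenset("and or with in at of on per than when becoming".split())

#: Categories whose terms may act as structure constraints when they precede
#: a clause-initial Structure term ("adult leaves", "female cones").
CONSTRAINT_CATEGORIES = frozenset({"Duration", "Sex", "Position"})

#: Unit words recognized for measurements, with factors to millimetres.
UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}

# Sentence-internal abbreviations that must not end a sentence.
_ABBREVIATIONS = frozenset(
    "ca diam var subsp cf aff sect ser approx alt fig no".split()
)


# -- domain types ----------------------------------------------------------

@dataclass
class Description:
    """One taxon's telegraphic description plus its taxonomic placement."""

    taxon_name: str
    rank: str
    body: str
    parent_taxon: str | None = None
    source: str | None = None
    author_year: str | None = None

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise BatchFormatError(
                f"taxon {self.taxon_name!r}: invalid rank {self.rank!r} "
                f"(expected one of {', '.join(RANKS)})"
            )


@dataclass(frozen=True)
class NumericRange:
    """Measurement range with optional atypical extremes.

    A single measurement is represented with ``typical_min == typical_max``.
    ``unit`` is one of mm/cm/m or None for dimensionless counts.
    """

    typical_min: float
    typical_max: float
    atypical_min: float | None = None
    atypical_max: float | None = None
    unit: str | None = None

    def __post_init__(self) -> None:
        if self.typical_min > self.typical_max:
            raise MalformedRangeError(
                f"typical range inverted: {self.typical_min} > {self.typical_max}"
            )
        if self.atypical_min is not None and self.atypical_min > self.typical_min:
            raise MalformedRangeError("atypical minimum exceeds typical minimum")
        if self.atypical_max is not None and self.typical_max > self.atypical_max:
            raise MalformedRangeError("typical maximum exceeds atypical maximum")

    def to_mm(self) -> "NumericRange":
        """The same range expressed in mm (dimensionless ranges unchanged)."""
        if self.unit is None:
            return self
        f = UNIT_TO_MM[self.unit]
        return NumericRange(
            typical_min=self.typical_min * f,
            typical_max=self.typical_max * f,
            atypical_min=None if self.atypical_min is None else self.atypical_min * f,
            atypical_max=None if self.atypical_max is None else self.atypical_max * f,
            unit="mm",
        )

    @property
    def midpoint(self) -> float:
        return (self.typical_min + self.typical_max) / 2.0


@dataclass(frozen=True)
class Annotation:
    """One extracted (structure, character, value) triple.

    ``value_kind`` is ``state`` (one or more independent states),
    ``state_range`` ("ovate to obovate": endpoints of a morphocline), or
    ``numeric`` (a measurement range).  ``verbatim`` is the contiguous source
    span the annotation was read from.
    """

    structure: str
    character: str
    value_kind: str
    states: tuple[str, ...] = ()
    range: NumericRange | None = None
    structure_constraint: str | None = None
    modifier: str | None = None
    verbatim: str = ""

    def __post_init__(self) -> None:
        if self.value_kind == "numeric":
            if self.range is None:
                raise ValueError("numeric annotation requires a range")
        elif self.value_kind in ("state", "state_range"):
            if not self.states:
                raise ValueError(f"{self.value_kind} annotation requires states")
            if self.value_kind == "state_range" and len(self.states) < 2:
                raise ValueError("state_range requires at least two states")
        else:
            raise ValueError(f"invalid value_kind {self.value_kind!r}")


@dataclass(frozen=True)
class Clause:
    """A clause with its absolute character offsets in the body text."""

    text: str
    start: int
    end: int


@dataclass(frozen=True)
class Sentence:
    text: str
    start: int
    end: int
    clauses: tuple[Clause, ...]


@dataclass(frozen=True)
class UnknownTerm:
    """A token the glossary does not know, surfaced to term learning."""

    surface_form: str
    clause: str


@dataclass
class ClauseParse:
    """Result of parsing one clause: annotations plus the new subject."""

    annotations: list[Annotation]
    subject: str | None
    subject_constraint: str | None = None
    unknown_terms: list[UnknownTerm] = field(default_factory=list)
    unparsed: bool = False

    def __iter__(self):  # unpack as (annotations, subject)
        return iter((self.annotations, self.subject))


@dataclass
class Statement:
    """One sentence of a treatment with everything parsed from it."""

    text: str
    annotations: list[Annotation] = field(default_factory=list)
    unparsed: list[str] = field(default_factory=list)


@dataclass
class AnnotatedDocument:
    """Per-taxon parse product, serializable to XML."""

    taxon_name: str
    rank: str
    parent_taxon: str | None
    statements: list[Statement]
    unknown_terms: list[UnknownTerm] = field(default_factory=list)


# -- batch loading ---------------------------------------------------------

def load_descriptions(path: str | Path) -> list[Description]:
    """Load a batch of descriptions from a CSV file or a directory of .txt.

    CSV columns: ``taxon,rank,parent,description`` plus optional ``source``
    and ``author_year``.  A directory holds one ``<taxon>.txt`` per taxon
    whose first line is a tab-separated header ``taxon<TAB>rank[<TAB>parent]``
    and whose remaining lines are the body.

    Dangling parent links are reported as warnings, not errors; duplicate
    taxon names and empty bodies are errors.
    """
    path = Path(path)
    descriptions: list[Description] = []
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            lines = f.read_text(encoding="utf-8").splitlines()
            if not lines:
                raise BatchFormatError(f"{f}: empty description file")
            header = lines[0].split("\t")
            if len(header) < 2:
                raise BatchFormatError(
                    f"{f}: header must be 'taxon<TAB>rank[<TAB>parent]'"
                )
            taxon, rank = header[0].strip(), header[1].strip()
            parent = header[2].strip() if len(header) > 2 and header[2].strip() else None
            body = "\n".join(lines[1:]).strip()
            if not body:
                raise BatchFormatError(f"empty description body for taxon {taxon!r}")
            descriptions.append(Description(taxon, rank, body, parent))
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise BatchFormatError(f"{path}: empty batch file")
            for col in ("taxon", "rank", "description"):
                if col not in reader.fieldnames:
                    raise BatchFormatError(f"{path}: missing required column {col!r}")
            for row in reader:
                taxon = (row["taxon"] or "").strip()
                if not taxon:
                    continue
                body = (row["description"] or "").strip()
                if not body:
                    raise BatchFormatError(
                        f"empty description body for taxon {taxon!r}"
                    )
                parent = (row.get("parent") or "").strip() or None
                descriptions.append(
                    Description(
                        taxon_name=taxon,
                        rank=(row["rank"] or "").strip(),
                        body=body,
                        parent_taxon=parent,
                        source=(row.get("source") or "").strip() or None,
                        author_year=(row.get("author_year") or "").strip() or None,
                    )
                )
    names = [d.taxon_name for d in descriptions]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise BatchFormatError("duplicate taxon names: " + ", ".join(dupes))
    known = set(names)
    for d in descriptions:
        if d.parent_taxon is not None and d.parent_taxon not in known:
            warnings.warn(
                f"taxon {d.taxon_name!r} has dangling parent {d.parent_taxon!r}"
            )
    return descriptions


# -- parenthetical stripping ----------------------------------------------

_NUM = r"\d+(?:\.\d+)?"
# Atypical-extreme groups "(5-)" and "(-12)" are part of the range grammar
# and must survive parenthetical stripping.
_ATYPICAL_OPEN = re.compile(rf"^\(\s*{_NUM}\s*-\s*\)$")
_ATYPICAL_CLOSE = re.compile(rf"^\(\s*-\s*{_NUM}\s*\)$")


def strip_parentheticals(body: str) -> str:
    """Remove explanatory parenthetical remarks, keeping range extremes.

    Explanatory remarks ("cone (larger than other species) 10 cm long")
    violate telegraphic syntax and are dropped.  Parenthesis groups that are
    atypical-extreme range notation -- "(5-)" or "(-12)" -- are preserved.
    Unbalanced parentheses trigger a warning and the unmatched span is kept.
    """
    text = body.translate(_DASHES)
    out: list[str] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch != "(":
            out.append(ch)
            i += 1
            continue
        depth, j = 1, i + 1
        while j < len(text) and depth:
            if text[j] == "(":
                depth += 1
            elif text[j] == ")":
                depth -= 1
            j += 1
        if depth:  # unbalanced: keep as-is
            warnings.warn("unbalanced parenthesis in description body")
            out.append(text[i:])
            break
        group = text[i:j]
        if _ATYPICAL_OPEN.match(group) or _ATYPICAL_CLOSE.match(group):
            out.append(group)
        # else: drop the group entirely
        i = j
    stripped = "".join(out)
    # re-normalize whitespace left by removed groups, keep sentence structure
    stripped = re.sub(r"[ \t]+", " ", stripped)
    stripped = re.sub(r" +([,;.])", r"\1", stripped)
    return stripped.strip()


# -- segmentation ----------------------------------------------------------

def _is_sentence_end(text: str, i: int) -> bool:
    """True if the period at index ``i`` ends a sentence."""
    # decimal point
    if 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
        return False
    # abbreviation check: word immediately before the period
    m = re.search(r"([A-Za-z-]+)$", text[:i])
    if m and m.group(1).lower() in _ABBREVIATIONS:
        return False
    return True


def segment(body: str, glossary: Glossary | None = None) -> list[Sentence]:
    """Split a body into sentences and clauses, preserving offsets.

    Sentences end at abbreviation-safe periods.  Clauses split on semicolons
    always, and on commas that open a new character expression: the next
    token starts a measurement (digit or atypical-extreme parenthesis) or,
    when a glossary is supplied, resolves to a Structure term.  Comma-joined
    state lists ("ovate, oblong") therefore stay inside one clause.
    """
    body = body.translate(_DASHES)
    sentences: list[Sentence] = []
    # sentence boundaries
    bounds: list[tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(body):
        if ch == "." and _is_sentence_end(body, i):
            if body[start:i].strip():
                bounds.append((start, i))
            start = i + 1
    if body[start:].strip():
        bounds.append((start, len(body)))

    for s0, s1 in bounds:
        sent_text = body[s0:s1]
        clauses: list[Clause] = []
        c_start = s0
        i = s0
        while i < s1:
            ch = body[i]
            split_here = False
            if ch == ";":
                split_here = True
            elif ch == ",":
                rest = body[i + 1:s1].lstrip()
                if rest[:1].isdigit() or re.match(rf"^\(\s*{_NUM}\s*-\s*\)", rest):
                    split_here = True
                elif glossary is not None:
                    m = re.match(r"^([A-Za-z][A-Za-z-]*)", rest)
                    if m:
                        word = _singularize(m.group(1).lower(), glossary)
                        term = glossary.lookup(word) if word else None
                        if term is not None and "Structure" in term.categories:
                            split_here = True
            if split_here:
                if body[c_start:i].strip():
                    clauses.append(_mk_clause(body, c_start, i))
                c_start = i + 1
            i += 1
        if body[c_start:s1].strip():
            clauses.append(_mk_clause(body, c_start, s1))
        sentences.append(Sentence(sent_text, s0, s1, tuple(clauses)))
    return sentences


def _mk_clause(body: str, start: int, end: int) -> Clause:
    text = body[start:end]
    lead = len(text) - len(text.lstrip())
    trail = len(text) - len(text.rstrip())
    return Clause(text.strip(), start + lead, end - trail)


# -- numeric range grammar -------------------------------------------------

_CORE_RANGE = re.compile(
    rf"(?:\(\s*(?P<amin>{_NUM})\s*-\s*\)\s*)?"
    rf"(?P<tmin>{_NUM})"
    rf"(?:\s*-\s*(?P<tmax>{_NUM}))?"
    rf"(?:\s*\(\s*-\s*(?P<amax>{_NUM})\s*\))?"
    rf"(?:\s+(?P<unit>mm|cm|m)\b\.?)?"
)


def parse_numeric_range(span: str) -> NumericRange:
    """Parse a measurement span ``(A-)B(-C)((-D)) [unit]``.

    Decimal points are accepted, decimal commas are not.  An unrecognized
    trailing unit word leaves the unit absent with a warning; an inverted
    typical range raises :class:`MalformedRangeError`.
    """
    text = span.translate(_DASHES).strip()
    m = _CORE_RANGE.match(text)
    if not m or not m.group("tmin"):
        raise MalformedRangeError(f"not a numeric range: {span!r}")
    rest = text[m.end():].strip().rstrip(".")
    unit = m.group("unit")
    if rest:
        if re.fullmatch(r"[A-Za-zµ]+", rest) and unit is None:
            warnings.warn(f"unknown unit word {rest!r}; unit left absent")
        else:
            raise MalformedRangeError(f"trailing text in range span: {span!r}")
    tmin = float(m.group("tmin"))
    tmax = float(m.group("tmax")) if m.group("tmax") else tmin
    if tmin > tmax:
        raise MalformedRangeError(f"inverted range in {span!r}: {tmin} > {tmax}")
    return NumericRange(
        typical_min=tmin,
        typical_max=tmax,
        atypical_min=float(m.group("amin")) if m.group("amin") else None,
        atypical_max=float(m.group("amax")) if m.group("amax") else None,
        unit=unit,
    )


# -- clause parsing --------------------------------------------------------

_WORD = re.compile(r"[A-Za-z][A-Za-z-]*")

_PLURAL_RULES = (("ies", "y"), ("ves", "f"), ("ches", "ch"), ("shes", "sh"),
                 ("xes", "x"), ("ses", "s"), ("s", ""))


def _singularize(word: str, glossary: Glossary) -> str:
    """Map a plural surface form onto a glossary entry, if one exists."""
    if word in glossary:
        return word
    for suffix, repl in _PLURAL_RULES:
        if word.endswith(suffix) and len(word) > len(suffix) + 1:
            candidate = word[: -len(suffix)] + repl
            if candidate in glossary:
                return candidate
    return word


def _match_terms(tokens: list[tuple[str, int, int]], glossary: Glossary):
    """Greedy longest-match of token runs (up to 3 words) against the glossary.

    Yields (canonical_or_None, surface, start, end, n_tokens); unmatched
    tokens come back with canonical None.
    """
    i = 0
    while i < len(tokens):
        matched = False
        for n in (3, 2, 1):
            if i + n > len(tokens):
                continue
            words = [t[0] for t in tokens[i:i + n]]
            surface = " ".join(words)
            candidate = _singularize(surface, glossary)
            if candidate in glossary:
                yield (glossary.resolve(candidate), surface,
                       tokens[i][1], tokens[i + n - 1][2], n)
                i += n
                matched = True
                break
        if not matched:
            tok, s, e = tokens[i]
            yield (None, tok, s, e, 1)
            i += 1


def parse_clause(
    clause: str,
    subject: str | None,
    glossary: Glossary,
    subject_constraint: str | None = None,
) -> ClauseParse:
    """Parse one clause into annotations under the running structure subject.

    A clause-initial Structure term (optionally preceded by constraint terms
    such as "adult" or "female") becomes the new subject.  Remaining tokens
    are matched against the glossary: state terms yield qualitative
    annotations ("X to Y" between same-category states yields a state range,
    "X, Y"/"X or Y" a multi-state annotation), measurement spans yield
    numeric annotations whose dimension comes from a trailing dimension word
    ("long" -> length), and frequency adverbs become modifiers.  Unknown
    tokens are surfaced as :class:`UnknownTerm` events, never guessed.
    """
    text = clause.translate(_DASHES)
    result = ClauseParse([], subject, subject_constraint)

    # 1. locate measurement spans first; they own their tokens
    ranges: list[tuple[int, int, NumericRange]] = []
    consumed: set[int] = set()
    for m in _CORE_RANGE.finditer(text):
        if not m.group("tmin"):
            continue
        if not (m.group("tmax") or m.group("amin") or m.group("amax")
                or m.group("unit")):
            # bare single number with no unit: still a measurement ("leaflets 12")
            pass
        try:
            rng = parse_numeric_range(text[m.start():m.end()])
        except MalformedRangeError:
            continue
        ranges.append((m.start(), m.end(), rng))
        consumed.update(range(m.start(), m.end()))

    # 2. tokenize the rest
    tokens = [
        (m.group(0).lower(), m.start(), m.end())
        for m in _WORD.finditer(text)
        if m.start() not in consumed
    ]

    items: list[dict] = []  # mixed stream of term matches in source order
    for canonical, surface, s, e, _n in _match_terms(tokens, glossary):
        items.append({"kind": "term", "canonical": canonical, "surface": surface,
                      "start": s, "end": e})
    for s, e, rng in ranges:
        items.append({"kind": "range", "range": rng, "start": s, "end": e})
    items.sort(key=lambda d: d["start"])

    # 3. clause-initial structure (with optional leading constraint terms)
    idx = 0
    constraint_words: list[str] = []
    subject_set_here = False
    while idx < len(items) and items[idx]["kind"] == "term":
        canonical = items[idx]["canonical"]
        if canonical is None:
            break
        cats = glossary.terms[canonical].categories
        if "Structure" in cats:
            result.subject = canonical
            result.subject_constraint = (
                " ".join(constraint_words) if constraint_words else None
            )
            subject_set_here = True
            idx += 1
            break
        if idx < 2 and set(cats) & CONSTRAINT_CATEGORIES:
            # potential constraint adjective preceding the structure word
            # ("adult leaves", "female cones")
            constraint_words.append(canonical)
            idx += 1
            continue
        break
    if not subject_set_here:
        idx = 0
        constraint_words = []

    if result.subject is None:
        # no structure context at all: diagnostic, not a crash
        for it in items[idx:]:
            if it["kind"] == "term" and it["canonical"] is None:
                if not _is_noise_token(it["surface"]):
                    result.unknown_terms.append(UnknownTerm(it["surface"], text))
        result.unparsed = True
        return result

    structure = result.subject
    constraint = result.subject_constraint

    # 4. scan remaining items into annotations
    pending_modifier: str | None = None
    current: dict | None = None  # open state annotation being extended
    i = idx
    while i < len(items):
        it = items[i]
        if it["kind"] == "range":
            _close(result, current, structure, constraint, text)
            current = None
            # trailing dimension word ("6-10 cm long", "2-4 cm in diameter"):
            # connectives between the measurement and the dimension word are
            # skipped along with it
            dim = "size"
            j = i + 1
            while (j < len(items) and items[j]["kind"] == "term"
                   and items[j]["surface"].lower() in CONNECTIVES):
                j += 1
            if (j < len(items) and items[j]["kind"] == "term"):
                word = items[j]["surface"].lower()
                if word in DIMENSION_WORDS:
                    dim = DIMENSION_WORDS[word]
                    it = {**it, "end": items[j]["end"]}
                    i = j
            result.annotations.append(Annotation(
                structure=structure,
                structure_constraint=constraint,
                character=dim,
                value_kind="numeric",
                range=it["range"],
                modifier=pending_modifier,
                verbatim=text[it["start"]:it["end"]],
            ))
            pending_modifier = None
            i += 1
            continue

        word = it["surface"].lower()
        canonical = it["canonical"]

        if word in MODIFIER_WORDS:
            pending_modifier = word
            i += 1
            continue
        if word == "to" and current is not None:
            # possible state range "X to Y"
            j = i + 1
            if (j < len(items) and items[j]["kind"] == "term"
                    and items[j]["canonical"] is not None):
                nxt = items[j]["canonical"]
                ncats = _quality_categories(glossary, nxt)
                if current["character"] in ncats:
                    current["states"].append(nxt)
                    current["value_kind"] = "state_range"
                    current["end"] = items[j]["end"]
                    i = j + 1
                    continue
            i += 1
            continue
        if word in CONNECTIVES or word == "to":
            i += 1
            continue
        if canonical is None:
            if not _is_noise_token(word):
                result.unknown_terms.append(UnknownTerm(word, text))
            i += 1
            continue

        cats = _quality_categories(glossary, canonical)
        if not cats:
            # Structure-only term in non-initial position: recorded as a
            # descriptive state under the generic Character category
            # (e.g. "exfoliating in fine scales").
            cats = ("Character",)
        category = cats[0]
        if (current is not None and current["value_kind"] == "state"
                and current["character"] == category):
            current["states"].append(canonical)
            current["end"] = it["end"]
        else:
            _close(result, current, structure, constraint, text)
            current = {
                "character": category,
                "states": [canonical],
                "value_kind": "state",
                "start": it["start"],
                "end": it["end"],
                "modifier": pending_modifier,
            }
            pending_modifier = None
        i += 1

    _close(result, current, structure, constraint, text)
    if not result.annotations and not subject_set_here:
        result.unparsed = True
    return result


def _quality_categories(glossary: Glossary, canonical: str) -> tuple[str, ...]:
    """Non-Structure categories of a term (quality reading)."""
    return tuple(c for c in glossary.terms[canonical].categories if c != "Structure")


def _is_noise_token(word: str) -> bool:
    from .term_learning import STOPWORDS
    return word in STOPWORDS or word in UNIT_TO_MM or word in DIMENSION_WORDS


def _close(result: ClauseParse, current: dict | None, structure: str,
           constraint: str | None, text: str) -> None:
    if current is None:
        return
    result.annotations.append(Annotation(
        structure=structure,
        structure_constraint=constraint,
        character=current["character"],
        value_kind=current["value_kind"],
        states=tuple(current["states"]),
        modifier=current["modifier"],
        verbatim=text[current["start"]:current["end"]],
    ))


# -- treatment-level annotation -------------------------------------------

def annotate(
    d: Description,
    glossary: Glossary,
    strip_parens: bool = False,
    carry_subject_across_sentences: bool = False,
) -> AnnotatedDocument:
    """Parse a full description into an :class:`AnnotatedDocument`.

    The structure subject is scoped to the sentence; with
    ``carry_subject_across_sentences`` a sentence lacking a leading structure
    term inherits the previous sentence's subject.
    """
    body = d.body.translate(_DASHES)
    if strip_parens:
        body = strip_parentheticals(body)
    doc = AnnotatedDocument(d.taxon_name, d.rank, d.parent_taxon, [])
    carried_subject: str | None = None
    carried_constraint: str | None = None
    for sentence in segment(body, glossary):
        stmt = Statement(sentence.text.strip())
        subject = carried_subject if carry_subject_across_sentences else None
        constraint = carried_constraint if carry_subject_across_sentences else None
        for clause in sentence.clauses:
            parsed = parse_clause(clause.text, subject, glossary, constraint)
            subject = parsed.subject
            constraint = parsed.subject_constraint
            stmt.annotations.extend(parsed.annotations)
            doc.unknown_terms.extend(parsed.unknown_terms)
            if parsed.unparsed:
                stmt.unparsed.append(clause.text)
        carried_subject, carried_constraint = subject, constraint
        doc.statements.append(stmt)
    return doc


# -- XML serialization -----------------------------------------------------

def document_to_xml(doc: AnnotatedDocument) -> etree._Element:
    """Serialize to the package's annotated-treatment XML dialect."""
    root = etree.Element("treatment", taxon=doc.taxon_name, rank=doc.rank)
    if doc.parent_taxon:
        root.set("parent", doc.parent_taxon)
    for stmt in doc.statements:
        s = etree.SubElement(root, "statement", text=stmt.text)
        for a in stmt.annotations:
            el = etree.SubElement(
                s, "annotation",
                structure=a.structure,
                character=a.character,
                value_kind=a.value_kind,
                verbatim=a.verbatim,
            )
            if a.structure_constraint:
                el.set("constraint", a.structure_constraint)
            if a.modifier:
                el.set("modifier", a.modifier)
            for st in a.states:
                etree.SubElement(el, "state", canonical=st)
            if a.range is not None:
                r = etree.SubElement(el, "range")
                r.set("typical_min", repr(a.range.typical_min))
                r.set("typical_max", repr(a.range.typical_max))
                if a.range.atypical_min is not None:
                    r.set("atypical_min", repr(a.range.atypical_min))
                if a.range.atypical_max is not None:
                    r.set("atypical_max", repr(a.range.atypical_max))
                if a.range.unit:
                    r.set("unit", a.range.unit)
        for u in stmt.unparsed:
            etree.SubElement(s, "unparsed", text=u)
    return root


def write_annotated(doc: AnnotatedDocument, path: str | Path) -> None:
    tree = etree.ElementTree(document_to_xml(doc))
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def read_annotated(path: str | Path) -> AnnotatedDocument:
    """Inverse of :func:`write_annotated` (unknown-term events are not stored)."""
    root = etree.parse(str(path)).getroot()
    return xml_to_document(root)


def xml_to_document(root: etree._Element) -> AnnotatedDocument:
    doc = AnnotatedDocument(
        taxon_name=root.get("taxon"),
        rank=root.get("rank"),
        parent_taxon=root.get("parent"),
        statements=[],
    )
    for s in root.findall("statement"):
        stmt = Statement(s.get("text"))
        for el in s.findall("annotation"):
            rng = None
            r = el.find("range")
            if r is not None:
                rng = NumericRange(
                    typical_min=float(r.get("typical_min")),
                    typical_max=float(r.get("typical_max")),
                    atypical_min=(float(r.get("atypical_min"))
                                  if r.get("atypical_min") else None),
                    atypical_max=(float(r.get("atypical_max"))
                                  if r.get("atypical_max") else None),
                    unit=r.get("unit"),
                )
            stmt.annotations.append(Annotation(
                structure=el.get("structure"),
                structure_constraint=el.get("constraint"),
                character=el.get("character"),
                value_kind=el.get("value_kind"),
                states=tuple(st.get("canonical") for st in el.findall("state")),
                range=rng,
                modifier=el.get("modifier"),
                verbatim=el.get("verbatim"),
            ))
        for u in s.findall("unparsed"):
            stmt.unparsed.append(u.get("text"))
        doc.statements.append(stmt)
    return doc
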