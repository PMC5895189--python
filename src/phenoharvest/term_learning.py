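"""Unsupervised term learning and the review workflow.

Before parsing, tokens absent from the glossary are collected and a category
is proposed for each by a small set of deterministic, auditable rules:

* **R1** -- a clause-initial token followed by at least one known quality term
  is proposed as a Structure ("phyllode green" with "green" known).
* **R2** -- a token coordinated with known states of one quality category
  ("green or <X>") is proposed into that category.
* **R3** -- a documented suffix table (-ate/-oid/-like -> Shape; -ose/-ous ->
  ambiguous between Texture and Pubescence, left unknown with both suggested).
* **R4** -- everything else stays ``unknown``.

Rules fire in order per occurrence; a term's proposal takes the category of
the highest-priority rule that fired anywhere in the batch, and every
triggering occurrence is recorded as evidence so decisions are auditable.
Confirmed decisions are merged back into the glossary through the ordinary
glossary operations; rejected terms enter the glossary stoplist so they are
never re-proposed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import PhenoHarvestError
from .glossary import Glossary, normalize_term
from .text_capture import (
    Description,
    DIMENSION_WORDS,
    UNIT_TO_MM,
    MODIFIER_WORDS,
    segment,
    _CORE_RANGE,
    _WORD,
    _singularize,
    _DASHES,
)

#: English function words never proposed as phenotypic terms.
STOPWORDS = frozenset(
    """a an and are as at be but by for from has have if in into is it its
    more most not of on or per rather so than that the their then there
    these this those to under upon usually very when where which while with
    without becoming ca approximately about""".split()
)

_SUFFIX_TABLE: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("ate", ("Shape",)),
    ("oid", ("Shape",)),
    ("like", ("Shape",)),
    ("ose", ("Texture", "Pubescence")),
    ("ous", ("Texture", "Pubescence")),
)

_RULE_PRIORITY = {"R1": 0, "R2": 1, "R3": 2}


@dataclass
class TermProposal:
    """A proposed categorization for one out-of-glossary surface form."""

    surface_form: str
    proposed_category: str  # category name or "unknown"
    evidence: list[tuple[str, int, str]] = field(default_factory=list)
    suggestions: tuple[str, ...] = ()
    status: str = "proposed"


def _tokens_of(clause_text: str, glossary: Glossary) -> list[str]:
    """Lowercased word tokens with measurement spans removed."""
    text = clause_text.translate(_DASHES)
    consumed: set[int] = set()
    for m in _CORE_RANGE.finditer(text):
        if m.group("tmin") and (m.group("tmax") or m.group("unit")
                                or m.group("amin") or m.group("amax")):
            consumed.update(range(m.start(), m.end()))
    return [m.group(0).lower() for m in _WORD.finditer(text)
            if m.start() not in consumed]


def _is_candidate(word: str, glossary: Glossary) -> bool:
    if word in STOPWORDS or word in UNIT_TO_MM or word in DIMENSION_WORDS:
        return False
    if word in MODIFIER_WORDS or word in ("to",):
        return False
    if normalize_term(word) in glossary.stoplist:
        return False
    return _singularize(word, glossary) not in glossary


def learn_terms(batch: list[Description], glossary: Glossary) -> list[TermProposal]:
    """Propose a category for every out-of-glossary token in the batch.

    Pure function of (batch, glossary): the glossary is never modified.
    Exactly one proposal per unique surface form, with every triggering
    occurrence recorded as (taxon, sentence index, rule) evidence.
    """
    proposals: dict[str, TermProposal] = {}
    rule_used: dict[str, str] = {}  # rule that set each proposal's category

    def propose(word: str, category: str, rule: str,
                taxon: str, sent_idx: int, suggestions: tuple[str, ...] = ()):
        p = proposals.setdefault(word, TermProposal(word, "unknown"))
        p.evidence.append((taxon, sent_idx, rule))
        if category != "unknown":
            # highest-priority rule across occurrences wins
            current = rule_used.get(word)
            if current is None or _RULE_PRIORITY[rule] < _RULE_PRIORITY[current]:
                p.proposed_category = category
                p.suggestions = suggestions
                rule_used[word] = rule
        elif suggestions and not p.suggestions:
            p.suggestions = suggestions

    for d in batch:
        for s_idx, sentence in enumerate(segment(d.body, glossary)):
            for clause in sentence.clauses:
                words = _tokens_of(clause.text, glossary)
                for w_idx, word in enumerate(words):
                    if not _is_candidate(word, glossary):
                        continue
                    rule, category, sugg = _classify(word, w_idx, words, glossary)
                    propose(word, category, rule, d.taxon_name, s_idx, sugg)
    return sorted(proposals.values(), key=lambda p: p.surface_form)


def _classify(word: str, w_idx: int, words: list[str],
              glossary: Glossary) -> tuple[str, str, tuple[str, ...]]:
    # R1: clause-initial token followed by >=1 known quality term
    if w_idx == 0 and len(words) > 1:
        for nxt in words[1:]:
            term = glossary.lookup(_singularize(nxt, glossary))
            if term is not None and any(c != "Structure" for c in term.categories):
                return "R1", "Structure", ()
    # R2: coordination with a known state ("green or X" / "X or green")
    for offset in (-2, 2):
        j = w_idx + offset
        if 0 <= j < len(words) and words[w_idx + offset // 2] in ("or", "and", "to"):
            term = glossary.lookup(_singularize(words[j], glossary))
            if term is not None:
                quality = [c for c in term.categories if c != "Structure"]
                if quality:
                    return "R2", quality[0], ()
    # R3: suffix table
    for suffix, cats in _SUFFIX_TABLE:
        if word.endswith(suffix) and len(word) > len(suffix) + 2:
            if len(cats) == 1:
                return "R3", cats[0], ()
            return "R3", "unknown", cats  # ambiguous: both suggested
    return "R4", "unknown", ()


# -- review ---------------------------------------------------------------

@dataclass(frozen=True)
class ReviewDecision:
    """One reviewer decision: categorize, synonymize, or reject a term."""

    surface_form: str
    action: str  # "categorize" | "synonymize" | "reject"
    target: str | None = None  # category name or canonical form


def apply_review(
    glossary: Glossary,
    decisions: list[ReviewDecision],
    proposals: list[TermProposal] | None = None,
) -> Glossary:
    """Merge confirmed review decisions into the glossary.

    Conflicting decisions for one term resolve last-wins with a warning.
    Rejected terms enter the stoplist so re-learning does not re-propose
    them.  A decision naming a term with neither a proposal nor a glossary
    entry is an error (it cannot have come from the review queue).
    """
    known = {p.surface_form for p in proposals} if proposals is not None else None
    seen: dict[str, ReviewDecision] = {}
    for dec in decisions:
        s = normalize_term(dec.surface_form)
        if known is not None and s not in known and s not in glossary:
            raise PhenoHarvestError(
                f"decision for {dec.surface_form!r}: term has no proposal "
                "and is not in the glossary"
            )
        if s in seen and seen[s] != dec:
            warnings.warn(
                f"conflicting decisions for {s!r}; keeping the last one"
            )
        seen[s] = dec

    for s, dec in seen.items():
        if dec.action == "categorize":
            glossary.categorize_term(s, dec.target)
        elif dec.action == "synonymize":
            glossary.add_synonym(s, dec.target)
        elif dec.action == "reject":
            glossary.stoplist.add(s)
        else:
            raise PhenoHarvestError(f"unknown review action {dec.action!r}")
    return glossary


# -- CSV round-trip for proposals and decisions ----------------------------

def save_proposals(proposals: list[TermProposal], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["term", "proposed_category", "suggestions",
                    "evidence_count", "examples"])
        for p in proposals:
            examples = "; ".join(
                f"{t}#{i}:{r}" for t, i, r in p.evidence[:3]
            )
            w.writerow([p.surface_form, p.proposed_category,
                        "|".join(p.suggestions), len(p.evidence), examples])


def load_decisions(path: str | Path) -> list[ReviewDecision]:
    """Read a decisions CSV with columns ``term,action,target``."""
    out: list[ReviewDecision] = []
    with Path(path).open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(ReviewDecision(
                surface_form=row["term"].strip(),
                action=row["action"].strip(),
                target=(row.get("target") or "").strip() or None,
            ))
    return out
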