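"""Controlled vocabulary driving the parser.

A glossary maps surface forms (lowercased, hyphen-normalized tokens) to one or
more categories -- ``Structure`` for anatomical parts, and quality categories
such as ``Coloration`` or ``Shape`` for character states.  Synonym sets let
several surface forms ("shiny", "glossy") share one canonical form; lookups on
any member return the categories of the canonical form.  A term may belong to
several categories at once ("scale" is both a Structure and a Shape), which the
clause parser disambiguates by position.

Glossary files are UTF-8 CSV with header ``term,category,canonical`` and
optional directive lines before the header::

    #categories: Sex,Venation
    #stoplist: versus,cf
    term,category,canonical
    ash-gray,Coloration,
    shiny,Coloration,glossy

The ``canonical`` column, when non-empty, declares the row's term a synonym of
the named canonical term.  ``#categories`` declares user-defined categories
beyond the reserved set; ``#stoplist`` lists terms the learning stage must
never re-propose.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    GlossaryConsistencyError,
    GlossaryFormatError,
    SynonymConflictError,
    UnknownCategoryError,
)

#: Categories every glossary declares, mirroring the core of an OTO-style
#: botanical vocabulary.  ``Structure`` holds anatomical parts; ``Character``
#: is the generic quality category; the rest are the common quality classes.
RESERVED_CATEGORIES: tuple[str, ...] = (
    "Structure",
    "Character",
    "Coloration",
    "Shape",
    "Size",
    "Count",
    "Texture",
    "Orientation",
    "Architecture",
    "Duration",
    "Pubescence",
    "LifeForm",
)

# Dash variants seen in scanned botanical text, all normalized to ASCII "-".
_DASHES = str.maketrans({"‐": "-", "‑": "-", "‒": "-",
                         "–": "-", "—": "-"})


def normalize_term(surface: str) -> str:
    """Lowercase, normalize dash typography, collapse internal whitespace."""
    s = surface.strip().lower().translate(_DASHES)
    return " ".join(s.split())


@dataclass
class GlossaryTerm:
    """One canonical vocabulary entry.

    ``categories`` is an ordered, duplicate-free tuple; ``canonical_form``
    equals ``surface_form`` for canonical entries (variants are held in the
    glossary's synonym map, not as independent terms).
    """

    surface_form: str
    categories: tuple[str, ...]
    canonical_form: str

    def __post_init__(self) -> None:
        if not self.surface_form:
            raise GlossaryConsistencyError("term surface form must be non-empty")
        if not self.categories:
            raise GlossaryConsistencyError(
                f"term {self.surface_form!r} has no categories"
            )
        if len(set(self.categories)) != len(self.categories):
            raise GlossaryConsistencyError(
                f"term {self.surface_form!r} lists a duplicate category"
            )


@dataclass
class Glossary:
    """Term -> categories mapping with synonymy and multi-category membership.

    Synonym chains are collapsed eagerly at insertion, so ``_synonyms`` always
    maps a variant directly to the terminal canonical form and resolution is a
    single dictionary lookup with no possibility of cycles.
    """

    terms: dict[str, GlossaryTerm] = field(default_factory=dict)
    category_names: set[str] = field(default_factory=lambda: set(RESERVED_CATEGORIES))
    _synonyms: dict[str, str] = field(default_factory=dict)
    stoplist: set[str] = field(default_factory=set)

    # -- lookup ------------------------------------------------------------

    def resolve(self, surface: str) -> str | None:
        """Return the canonical form for ``surface``, or None if unknown."""
        s = normalize_term(surface)
        if s in self.terms:
            return s
        return self._synonyms.get(s)

    def lookup(self, surface: str) -> GlossaryTerm | None:
        """Return the canonical :class:`GlossaryTerm` for any member surface form."""
        canonical = self.resolve(surface)
        return self.terms.get(canonical) if canonical is not None else None

    def categories_of(self, surface: str) -> tuple[str, ...]:
        term = self.lookup(surface)
        return term.categories if term is not None else ()

    def __contains__(self, surface: str) -> bool:
        return self.resolve(surface) is not None

    @property
    def synonym_sets(self) -> dict[str, set[str]]:
        """canonical form -> set of member surface forms (canonical included)."""
        sets: dict[str, set[str]] = {}
        for variant, canonical in self._synonyms.items():
            sets.setdefault(canonical, {canonical}).add(variant)
        return sets

    def structures(self) -> set[str]:
        return {s for s, t in self.terms.items() if "Structure" in t.categories}

    # -- mutation ----------------------------------------------------------

    def add_term(self, surface: str, category: str) -> "Glossary":
        return self.categorize_term(surface, category)

    def categorize_term(self, surface: str, category: str) -> "Glossary":
        """Add ``category`` to ``surface``'s category set (creating the term).

        Existing categories are retained; repeating a categorization is a
        no-op, so category sets only ever grow.
        """
        if category not in self.category_names:
            raise UnknownCategoryError(
                f"unknown category {category!r}; valid categories: "
                + ", ".join(sorted(self.category_names))
            )
        s = normalize_term(surface)
        canonical = self.resolve(s) or s
        existing = self.terms.get(canonical)
        if existing is None:
            self.terms[canonical] = GlossaryTerm(canonical, (category,), canonical)
        elif category not in existing.categories:
            existing.categories = existing.categories + (category,)
        return self

    def add_synonym(self, variant: str, canonical: str) -> "Glossary":
        """Declare ``variant`` a synonym of ``canonical``.

        The chain is collapsed eagerly: if ``canonical`` is itself a variant,
        the terminal canonical form is used, and any variants currently
        pointing at ``variant`` are re-pointed at the terminal form.
        """
        v = normalize_term(variant)
        target = self.resolve(canonical)
        if target is None:
            raise GlossaryConsistencyError(
                f"synonym target {canonical!r} is not in the glossary"
            )
        if v == target:
            return self  # self-synonym: no-op
        if v in self._synonyms and self._synonyms[v] != target:
            # v is already a variant of a different set; silently moving it
            # would re-route established lookups, so an explicit remap
            # (remove + re-add) is required.
            raise SynonymConflictError(
                f"{v!r} already resolves to {self._synonyms[v]!r}; remove "
                "that declaration before remapping it"
            )
        if v in self.terms:
            # demoting a canonical entry: its set (if any) collapses onto the
            # new terminal form
            del self.terms[v]
        self._synonyms[v] = target
        # Collapse chains: anything that pointed at v now points at target.
        for other, canon in list(self._synonyms.items()):
            if canon == v:
                self._synonyms[other] = target
        return self

    def merge(self, other: "Glossary") -> "Glossary":
        """Union of two glossaries; category sets union, synonyms last-wins."""
        self.category_names |= other.category_names
        for surface, term in other.terms.items():
            for cat in term.categories:
                self.categorize_term(surface, cat)
        for variant, canonical in other._synonyms.items():
            if canonical not in self.terms:
                cats = other.terms[canonical].categories
                for cat in cats:
                    self.categorize_term(canonical, cat)
            try:
                self.add_synonym(variant, canonical)
            except SynonymConflictError:
                warnings.warn(
                    f"synonym {variant!r} -> {canonical!r} skipped: "
                    f"{variant!r} heads an existing synonym set"
                )
        self.stoplist |= other.stoplist
        return self


def start_empty_glossary(extra_categories: Iterable[str] = ()) -> Glossary:
    """A glossary with the reserved categories and no terms."""
    g = Glossary()
    g.category_names |= set(extra_categories)
    return g


# -- file I/O --------------------------------------------------------------

_REQUIRED_COLUMNS = ("term", "category")


def load_glossary(path: str | Path) -> Glossary:
    """Read a glossary CSV (dialect documented in the module docstring).

    Repeated ``(term, category)`` rows are deduplicated; a term listed with
    two categories yields one entry with both.  ``canonical`` cells are
    resolved after all rows are read, so forward references are fine.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise GlossaryFormatError(f"{path}: empty glossary file")

    extra_categories: list[str] = []
    stop: list[str] = []
    body_lines: list[str] = []
    for line in text.splitlines():
        if line.startswith("#categories:"):
            extra_categories += [c.strip() for c in line.split(":", 1)[1].split(",") if c.strip()]
        elif line.startswith("#stoplist:"):
            stop += [normalize_term(c) for c in line.split(":", 1)[1].split(",") if c.strip()]
        elif line.startswith("#"):
            continue
        else:
            body_lines.append(line)

    reader = csv.DictReader(io.StringIO("\n".join(body_lines)))
    if reader.fieldnames is None:
        raise GlossaryFormatError(f"{path}: no header row")
    for col in _REQUIRED_COLUMNS:
        if col not in reader.fieldnames:
            raise GlossaryFormatError(f"{path}: missing required column {col!r}")

    g = start_empty_glossary(extra_categories)
    g.stoplist |= set(stop)
    synonym_rows: list[tuple[str, str]] = []
    n_rows = 0
    for row in reader:
        term = normalize_term(row["term"] or "")
        if not term:
            continue
        n_rows += 1
        canonical = normalize_term(row.get("canonical") or "")
        if canonical and canonical != term:
            synonym_rows.append((term, canonical))
            continue
        category = (row["category"] or "").strip()
        if not category:
            raise GlossaryFormatError(f"{path}: term {term!r} has empty category")
        if category not in g.category_names:
            raise UnknownCategoryError(
                f"{path}: category {category!r} for term {term!r} is not "
                "declared; add a '#categories:' directive line"
            )
        g.categorize_term(term, category)
    if n_rows == 0:
        raise GlossaryConsistencyError(
            f"{path}: glossary declares no terms (use start_empty_glossary "
            "for an empty vocabulary)"
        )
    for variant, canonical in synonym_rows:
        if canonical not in g.terms and canonical not in g._synonyms:
            raise GlossaryConsistencyError(
                f"{path}: canonical form {canonical!r} (for {variant!r}) "
                "does not appear in the glossary"
            )
        g.add_synonym(variant, canonical)
    return g


def save_glossary(g: Glossary, path: str | Path) -> None:
    """Write a glossary in the CSV dialect that :func:`load_glossary` reads."""
    path = Path(path)
    extra = sorted(g.category_names - set(RESERVED_CATEGORIES))
    lines: list[str] = []
    if extra:
        lines.append("#categories: " + ",".join(extra))
    if g.stoplist:
        lines.append("#stoplist: " + ",".join(sorted(g.stoplist)))
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["term", "category", "canonical"])
    for surface in sorted(g.terms):
        for cat in g.terms[surface].categories:
            writer.writerow([surface, cat, ""])
    for variant in sorted(g._synonyms):
        canonical = g._synonyms[variant]
        writer.writerow([variant, g.terms[canonical].categories[0], canonical])
    path.write_text("\n".join(lines + [buf.getvalue()]), encoding="utf-8")


def load_seed_glossary() -> Glossary:
    """The glossary shipped with the package (a few hundred botanical terms)."""
    from importlib.resources import as_file, files

    seed = files("phenoharvest").joinpath("data/seed_glossary.csv")
    with as_file(seed) as p:
        return load_glossary(p)
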