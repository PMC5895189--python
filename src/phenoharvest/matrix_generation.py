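"""Assembly of the raw taxon-by-character matrix from annotated documents.

The raw matrix holds, per (taxon, character) cell, the verbatim phrases
extracted from the descriptions together with their parsed annotations.  Two
optional enrichment passes mirror the standard workflow for multi-rank
description sets:

* **propagation** -- an empty species cell inherits the value its nearest
  described ancestor (e.g. the genus) states for that character;
* **presence inference** -- any taxon whose description mentions a structure
  at all gets ``<structure>: presence = present``; taxa that never mention
  the structure stay *missing*, never "absent" (absence is a human call).

Cell provenance (direct / propagated / inferred) is tracked throughout and
direct cells are never overwritten.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from .errors import TaxonomyError
from .text_capture import AnnotatedDocument, Annotation, NumericRange, RANK_LEVEL

PRESENCE = "presence"


@dataclass(frozen=True, order=True)
class CharacterKey:
    """Identity of one matrix column: structure (+constraint) x character."""

    structure: str
    character: str
    constraint: str | None = None

    @property
    def label(self) -> str:
        head = f"{self.constraint} {self.structure}" if self.constraint else self.structure
        return f"{head}: {self.character}"


@dataclass
class Cell:
    """One matrix cell: verbatim phrases plus their parsed annotations."""

    phrases: tuple[str, ...] = ()
    annotations: tuple[Annotation, ...] = ()
    provenance: str = "direct"  # direct | propagated | inferred

    def merged_with(self, other: "Cell") -> "Cell":
        phrases = list(self.phrases)
        for p in other.phrases:
            if p not in phrases:
                phrases.append(p)
        return Cell(tuple(phrases), self.annotations + other.annotations,
                    self.provenance)


@dataclass
class Taxon:
    name: str
    rank: str
    parent: str | None = None


@dataclass
class RawMatrix:
    """Taxa x characters grid of verbatim extracted phrase sets."""

    taxa: list[Taxon] = field(default_factory=list)
    characters: list[CharacterKey] = field(default_factory=list)
    cells: dict[tuple[str, CharacterKey], Cell] = field(default_factory=dict)

    def cell(self, taxon: str, key: CharacterKey) -> Cell | None:
        return self.cells.get((taxon, key))

    def copy(self) -> "RawMatrix":
        return RawMatrix(
            taxa=list(self.taxa),
            characters=list(self.characters),
            cells=dict(self.cells),
        )

    @property
    def fill_fraction(self) -> float:
        denom = len(self.taxa) * len(self.characters)
        return len(self.cells) / denom if denom else 0.0

    def column(self, key: CharacterKey) -> dict[str, Cell]:
        return {t.name: self.cells[(t.name, key)]
                for t in self.taxa if (t.name, key) in self.cells}


def build_raw_matrix(
    docs: list[AnnotatedDocument],
    propagate_traits: bool = False,
    infer_structure_presence: bool = False,
) -> RawMatrix:
    """Assemble the raw matrix from annotated documents.

    Column order and row order follow first appearance, so serialized
    matrices are byte-stable across runs.  With both options off the matrix
    contains only direct cells.
    """
    m = RawMatrix()
    seen_chars: set[CharacterKey] = set()
    for doc in docs:
        m.taxa.append(Taxon(doc.taxon_name, doc.rank, doc.parent_taxon))
        for stmt in doc.statements:
            for a in stmt.annotations:
                key = CharacterKey(a.structure, a.character, a.structure_constraint)
                if key not in seen_chars:
                    seen_chars.add(key)
                    m.characters.append(key)
                cell = m.cells.get((doc.taxon_name, key))
                new = Cell((a.verbatim,), (a,), "direct")
                m.cells[(doc.taxon_name, key)] = (
                    new if cell is None else cell.merged_with(new)
                )
    if propagate_traits:
        m = propagate(m)
    if infer_structure_presence:
        m = infer_presence(m)
    return m


# -- propagation -----------------------------------------------------------

def _ancestors(taxon: str, parents: dict[str, str | None]) -> Iterable[str]:
    seen = {taxon}
    cur = parents.get(taxon)
    while cur is not None:
        if cur in seen:
            raise TaxonomyError(f"cyclic parent links at taxon {cur!r}")
        seen.add(cur)
        yield cur
        cur = parents.get(cur)


def propagate(m: RawMatrix) -> RawMatrix:
    """Fill empty cells from the nearest ancestor's *direct* value.

    Idempotent: propagated cells are never used as sources, and filled cells
    are never touched.  Raises :class:`TaxonomyError` on cyclic parent links
    before mutating anything.
    """
    parents = {t.name: t.parent for t in m.taxa}
    for t in m.taxa:  # validate acyclicity up front
        list(_ancestors(t.name, parents))
    out = m.copy()
    for t in m.taxa:
        for key in m.characters:
            if (t.name, key) in out.cells:
                continue
            for anc in _ancestors(t.name, parents):
                src = m.cells.get((anc, key))
                if src is not None and src.provenance == "direct":
                    out.cells[(t.name, key)] = replace(src, provenance="propagated")
                    break
    return out


# -- presence inference ----------------------------------------------------

def infer_presence(m: RawMatrix) -> RawMatrix:
    """Add ``<structure>: presence = present`` for every mentioning taxon.

    Taxa that never mention a structure keep the cell empty (missing
    information); absence is never inferred.  Direct presence values are
    never overwritten.  Idempotent.
    """
    out = m.copy()
    structures: list[str] = []
    for key in m.characters:
        if key.structure not in structures:
            structures.append(key.structure)
    for s in structures:
        pkey = CharacterKey(s, PRESENCE)
        mentioned = [
            t.name for t in m.taxa
            if any((t.name, k) in m.cells for k in m.characters
                   if k.structure == s)
        ]
        if not mentioned:
            continue
        if pkey not in out.characters:
            out.characters.append(pkey)
        for name in mentioned:
            if (name, pkey) not in out.cells:
                ann = Annotation(structure=s, character=PRESENCE,
                                 value_kind="state", states=("present",),
                                 verbatim="present")
                out.cells[(name, pkey)] = Cell(("present",), (ann,), "inferred")
    return out


# -- statistics ------------------------------------------------------------

def matrix_stats(m: RawMatrix) -> dict:
    """Summary counts over direct + propagated + inferred cells.

    An empty matrix reports zero counts and, by convention, fill 0.
    """
    per_char = {key: 0 for key in m.characters}
    for (_taxon, key) in m.cells:
        per_char[key] += 1
    return {
        "n_taxa": len(m.taxa),
        "n_characters": len(m.characters),
        "n_filled_cells": len(m.cells),
        "fill_fraction": m.fill_fraction,
        "per_character_taxon_counts": {k.label: v for k, v in per_char.items()},
    }


def characters_only_in_rank(m: RawMatrix, rank: str) -> int:
    """Characters whose direct data come exclusively from taxa of ``rank``.

    Counts e.g. characters found only in genus-level descriptions.
    """
    rank_of = {t.name: t.rank for t in m.taxa}
    n = 0
    for key in m.characters:
        ranks = {
            rank_of[taxon]
            for (taxon, k), cell in m.cells.items()
            if k == key and cell.provenance == "direct"
        }
        if ranks == {rank}:
            n += 1
    return n


# -- serialization ---------------------------------------------------------

_CELL_COLUMNS = [
    "row_type", "taxon", "rank", "parent", "structure", "constraint",
    "character", "provenance", "value_kind", "states",
    "atypical_min", "typical_min", "typical_max", "atypical_max", "unit",
    "modifier", "phrases",
]


def save_raw_matrix(m: RawMatrix, path: str | Path) -> None:
    """Write the lossless long-format cells CSV plus a wide CSV for humans.

    ``<path>`` gets the wide taxa-by-characters view (phrases joined with
    " | "); ``<path stem>.cells.csv`` gets the long format that
    :func:`load_raw_matrix` reads back, including taxa, column order, parsed
    values, and provenance.
    """
    path = Path(path)
    wide = path
    long = path.parent / (path.stem + ".cells.csv")

    with wide.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["taxon", "rank"] + [k.label for k in m.characters])
        for t in m.taxa:
            row = [t.name, t.rank]
            for key in m.characters:
                cell = m.cells.get((t.name, key))
                row.append(" | ".join(cell.phrases) if cell else "")
            w.writerow(row)

    with long.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_CELL_COLUMNS)
        for t in m.taxa:
            w.writerow(["taxon", t.name, t.rank, t.parent or ""] + [""] * 13)
        for key in m.characters:
            w.writerow(["character", "", "", "", key.structure,
                        key.constraint or "", key.character] + [""] * 10)
        for t in m.taxa:
            for key in m.characters:
                cell = m.cells.get((t.name, key))
                if cell is None:
                    continue
                for a in cell.annotations:
                    r = a.range
                    w.writerow([
                        "cell", t.name, "", "", key.structure,
                        key.constraint or "", key.character, cell.provenance,
                        a.value_kind, "|".join(a.states),
                        _num(r.atypical_min) if r else "",
                        _num(r.typical_min) if r else "",
                        _num(r.typical_max) if r else "",
                        _num(r.atypical_max) if r else "",
                        (r.unit or "") if r else "",
                        a.modifier or "", a.verbatim,
                    ])


def _num(x: float | None) -> str:
    if x is None:
        return ""
    return repr(int(x)) if float(x).is_integer() else repr(x)


def load_raw_matrix(path: str | Path) -> RawMatrix:
    """Read the long-format cells CSV written by :func:`save_raw_matrix`."""
    path = Path(path)
    if not path.name.endswith(".cells.csv"):
        candidate = path.parent / (path.stem + ".cells.csv")
        if candidate.exists():
            path = candidate
    m = RawMatrix()
    with path.open(encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            kind = row["row_type"]
            if kind == "taxon":
                m.taxa.append(Taxon(row["taxon"], row["rank"],
                                    row["parent"] or None))
            elif kind == "character":
                m.characters.append(CharacterKey(
                    row["structure"], row["character"],
                    row["constraint"] or None))
            elif kind == "cell":
                key = CharacterKey(row["structure"], row["character"],
                                   row["constraint"] or None)
                rng = None
                if row["value_kind"] == "numeric":
                    rng = NumericRange(
                        typical_min=float(row["typical_min"]),
                        typical_max=float(row["typical_max"]),
                        atypical_min=(float(row["atypical_min"])
                                      if row["atypical_min"] else None),
                        atypical_max=(float(row["atypical_max"])
                                      if row["atypical_max"] else None),
                        unit=row["unit"] or None,
                    )
                a = Annotation(
                    structure=row["structure"],
                    structure_constraint=row["constraint"] or None,
                    character=row["character"],
                    value_kind=row["value_kind"],
                    states=tuple(s for s in row["states"].split("|") if s),
                    range=rng,
                    modifier=row["modifier"] or None,
                    verbatim=row["phrases"],
                )
                cell = m.cells.get((row["taxon"], key))
                new = Cell((a.verbatim,), (a,), row["provenance"])
                m.cells[(row["taxon"], key)] = (
                    new if cell is None else cell.merged_with(new)
                )
    return m
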