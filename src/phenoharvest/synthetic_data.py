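"""Synthetic telegraphic corpora with known ground truth.

Every pipeline stage is testable by round-trip recovery: a
:class:`TruthMatrix` fixes taxa (with ranks and parent links), characters,
and true cell values; :func:`generate_corpus` renders it as telegraphic
descriptions ("Leaves ovate, 6-10 cm long; petiole red.") together with the
exactly-covering glossary, and recovery compares the pipeline's raw matrix
against the truth.

The generator emulates the data pathologies of real description sets: high
missingness (characters described for few taxa), genus-level descriptions
carrying characters absent from species descriptions (exercising
propagation), synonym noise (different authorities wording the same state
differently), explanatory parentheticals, and mixed mm/cm units.  It does
not emulate free natural-language prose, misspellings, or inconsistent
clause syntax; recovery results bound parser correctness on well-formed
telegraphic text, not on arbitrary literature.

Everything is a deterministic function of (truth matrix, style parameters,
seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .glossary import Glossary, start_empty_glossary
from .matrix_generation import CharacterKey, RawMatrix
from .text_capture import Description, NumericRange

# -- vocabulary pools ------------------------------------------------------

#: structure -> plural surface form used in rendering
_STRUCTURES: dict[str, str] = {
    "leaf": "leaves", "petiole": "petioles", "cone": "cones",
    "bract": "bracts", "seed": "seeds", "bark": "bark", "trunk": "trunk",
    "branchlet": "branchlets", "crown": "crown", "stem": "stems",
    "bud": "buds", "sheath": "sheaths",
}

_STATE_POOLS: dict[str, list[str]] = {
    "Coloration": ["red", "green", "brown", "gray", "yellowish", "purple",
                   "glaucous", "black", "white", "orange"],
    "Shape": ["ovate", "obovate", "lanceolate", "elliptic", "oblong",
              "linear", "conical", "globose", "cylindrical", "triangular"],
    "Texture": ["smooth", "rough", "leathery", "woody", "papery", "glossy",
                "resinous"],
    "Pubescence": ["glabrous", "pubescent", "tomentose", "villous"],
    "Orientation": ["erect", "spreading", "pendulous", "ascending",
                    "appressed"],
    "Architecture": ["imbricate", "whorled", "opposite", "alternate",
                     "decussate"],
    "Duration": ["deciduous", "persistent", "evergreen"],
}

#: canonical state -> synonym variants available for synonym noise
_SYNONYMS: dict[str, list[str]] = {
    "gray": ["ash-gray"],
    "glossy": ["shiny"],
    "pendulous": ["drooping"],
    "globose": ["spherical"],
    "pubescent": ["hairy"],
    "elliptic": ["elliptical"],
}

#: dimension -> rendering after the measurement
_DIMENSIONS: dict[str, str] = {
    "length": "long", "width": "wide", "diameter": "in diameter",
    "height": "tall",
}

_CONSTRAINTS: dict[str, str] = {"adult": "Duration", "juvenile": "Duration",
                                "female": "Sex", "male": "Sex"}

_PARENTHETICALS = [
    "(larger than in related taxa)",
    "(fide earlier authors)",
    "(a diagnostic feature)",
    "(seen only on herbarium material)",
]


# -- truth matrix ----------------------------------------------------------

@dataclass(frozen=True)
class TruthCharacter:
    key: CharacterKey
    kind: str  # "qualitative" | "quantitative"
    states: tuple[str, ...] = ()  # allowed states (qualitative)
    unit: str | None = None  # preferred unit (quantitative)


@dataclass
class TruthMatrix:
    """Ground truth the generator renders and the pipeline must recover."""

    taxa: list[tuple[str, str, str | None]]  # (name, rank, parent)
    characters: list[TruthCharacter]
    cells: dict[tuple[str, CharacterKey], object] = field(default_factory=dict)
    # cell value: tuple[str, ...] (+ value_kind via len/flag) or NumericRange

    def non_missing(self) -> list[tuple[str, CharacterKey, object]]:
        return [(t, k, v) for (t, k), v in self.cells.items()]


def random_truth_matrix(
    n_taxa: int = 40,
    n_characters: int = 80,
    missingness: float = 0.9,
    seed: int = 0,
    n_genera: int = 2,
    n_genus_only_characters: int = 0,
) -> TruthMatrix:
    """Sample a plausible truth matrix.

    ``missingness`` is the per-character probability that a species cell is
    empty.  ``n_genus_only_characters`` characters receive values only at
    the genus level, so species can acquire them solely through propagation.
    """
    if not 0.0 <= missingness <= 1.0:
        raise ValueError("missingness must be in [0, 1]")
    rng = random.Random(seed)

    genera = [f"Genusa", f"Genusb", f"Genusc", f"Genusd"][:max(1, n_genera)]
    taxa: list[tuple[str, str, str | None]] = []
    for g in genera:
        taxa.append((g, "genus", None))
    n_species = n_taxa - len(genera)
    for i in range(n_species):
        g = genera[i % len(genera)]
        taxa.append((f"{g} species{i + 1:02d}", "species", g))

    # enumerate candidate (structure, constraint, character) keys
    candidates: list[TruthCharacter] = []
    for structure in _STRUCTURES:
        for cat, pool in _STATE_POOLS.items():
            candidates.append(TruthCharacter(
                CharacterKey(structure, cat), "qualitative", tuple(pool)))
        for dim, unit in (("length", "cm"), ("width", "mm"),
                          ("diameter", "cm"), ("height", "m")):
            candidates.append(TruthCharacter(
                CharacterKey(structure, dim), "quantitative", unit=unit))
    for constraint in ("adult", "juvenile"):
        for cat in ("Shape", "Coloration"):
            candidates.append(TruthCharacter(
                CharacterKey("leaf", cat, constraint), "qualitative",
                tuple(_STATE_POOLS[cat])))
    if n_characters > len(candidates):
        raise ValueError(
            f"at most {len(candidates)} distinct characters are available"
        )
    characters = rng.sample(candidates, n_characters)
    genus_only = set(rng.sample(range(n_characters),
                                min(n_genus_only_characters, n_characters)))

    t = TruthMatrix(taxa=taxa, characters=characters)
    species = [name for name, rank, _p in taxa if rank == "species"]
    for ci, tc in enumerate(characters):
        if ci in genus_only:
            for g in genera:
                t.cells[(g, tc.key)] = _random_value(tc, rng)
            continue
        for name in species:
            if rng.random() < missingness:
                continue
            t.cells[(name, tc.key)] = _random_value(tc, rng)
        # genus-level data for a few ordinary characters too
        if rng.random() < 0.15:
            g = rng.choice(genera)
            t.cells[(g, tc.key)] = _random_value(tc, rng)
    # every species must say something, or its description would be empty
    for name in species:
        if not any(taxon == name for (taxon, _k) in t.cells):
            tc = rng.choice([c for ci, c in enumerate(characters)
                             if ci not in genus_only])
            t.cells[(name, tc.key)] = _random_value(tc, rng)
    return t


def _random_value(tc: TruthCharacter, rng: random.Random):
    if tc.kind == "qualitative":
        if len(tc.states) >= 2 and rng.random() < 0.2:
            pair = rng.sample(list(tc.states), 2)
            return ("state_range", tuple(pair))
        return ("state", (rng.choice(list(tc.states)),))
    lo = round(rng.uniform(1, 40), 1)
    hi = round(lo + rng.uniform(0, 30), 1)
    if rng.random() < 0.25:
        amin = round(max(0.1, lo - rng.uniform(0.5, 5)), 1)
        amax = round(hi + rng.uniform(0.5, 5), 1)
        return NumericRange(lo, hi, atypical_min=amin, atypical_max=amax,
                            unit=tc.unit)
    return NumericRange(lo, hi, unit=tc.unit)


# -- rendering -------------------------------------------------------------

def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def _render_range(r: NumericRange, unit_out: str | None) -> str:
    """Render in ``unit_out`` (converting from the stored unit)."""
    factor = 1.0
    if r.unit is not None and unit_out is not None and unit_out != r.unit:
        from .text_capture import UNIT_TO_MM
        factor = UNIT_TO_MM[r.unit] / UNIT_TO_MM[unit_out]

    def f(x: float) -> str:
        return _fmt_num(round(x * factor, 4))

    parts = []
    if r.atypical_min is not None:
        parts.append(f"({f(r.atypical_min)}-)")
    if r.typical_min == r.typical_max:
        parts.append(f(r.typical_min))
    else:
        parts.append(f"{f(r.typical_min)}-{f(r.typical_max)}")
    if r.atypical_max is not None:
        parts.append(f"(-{f(r.atypical_max)})")
    body = "".join(parts)
    return f"{body} {unit_out}" if unit_out else body


def build_covering_glossary(t: TruthMatrix) -> Glossary:
    """The glossary that exactly covers the generator's vocabulary."""
    g = start_empty_glossary(extra_categories=("Sex",))
    for structure in _STRUCTURES:
        g.categorize_term(structure, "Structure")
    for cat, pool in _STATE_POOLS.items():
        for s in pool:
            g.categorize_term(s, cat)
    for term, cat in _CONSTRAINTS.items():
        g.categorize_term(term, cat if cat != "Sex" else "Sex")
    for canonical, variants in _SYNONYMS.items():
        if canonical not in g:
            g.categorize_term(canonical, "Texture")
        for v in variants:
            g.add_synonym(v, canonical)
    return g


def generate_corpus(
    t: TruthMatrix,
    synonym_noise: float = 0.0,
    parenthetical_noise: float = 0.0,
    unit_mix: float = 0.0,
    seed: int = 0,
) -> tuple[list[Description], Glossary]:
    """Render a truth matrix as telegraphic descriptions plus its glossary.

    ``synonym_noise`` is the probability a state with declared synonyms is
    rendered as a variant; ``parenthetical_noise`` the probability a clause
    grows an explanatory parenthetical (which ``strip_parentheticals`` must
    remove); ``unit_mix`` the probability a measurement is rendered in a
    different unit than stored (mm as cm etc.).  Same inputs and seed give
    a byte-identical corpus.
    """
    for name, frac in (("synonym_noise", synonym_noise),
                       ("parenthetical_noise", parenthetical_noise),
                       ("unit_mix", unit_mix)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = random.Random(seed)
    glossary = build_covering_glossary(t)

    char_order = {tc.key: i for i, tc in enumerate(t.characters)}
    descriptions: list[Description] = []
    for name, rank, parent in t.taxa:
        mine = sorted(
            ((k, v) for (taxon, k), v in t.cells.items() if taxon == name),
            key=lambda kv: char_order[kv[0]],
        )
        if not mine:
            continue
        # group cells by (constraint, structure), preserving character order
        groups: dict[tuple[str | None, str], list] = {}
        for k, v in mine:
            groups.setdefault((k.constraint, k.structure), []).append((k, v))
        sentences = []
        for (constraint, structure), cells in groups.items():
            clauses = []
            for k, v in cells:
                clauses.append(_render_cell(k, v, rng, synonym_noise, unit_mix))
            head = _STRUCTURES[structure]
            if constraint:
                head = f"{constraint} {head}"
            head = head[0].upper() + head[1:]
            sentence = head + " " + ", ".join(clauses)
            if parenthetical_noise and rng.random() < parenthetical_noise:
                sentence += " " + rng.choice(_PARENTHETICALS)
            sentences.append(sentence + ".")
        descriptions.append(Description(
            taxon_name=name, rank=rank, body=" ".join(sentences),
            parent_taxon=parent,
        ))
    return descriptions, glossary


def _render_cell(k: CharacterKey, v, rng: random.Random,
                 synonym_noise: float, unit_mix: float) -> str:
    if isinstance(v, NumericRange):
        unit_out = v.unit
        if v.unit is not None and unit_mix and rng.random() < unit_mix:
            unit_out = {"mm": "cm", "cm": "mm", "m": "cm"}[v.unit]
        rendered = _render_range(v, unit_out)
        return f"{rendered} {_DIMENSIONS[k.character]}"
    kind, states = v
    surfaces = []
    for s in states:
        variants = _SYNONYMS.get(s)
        if variants and synonym_noise and rng.random() < synonym_noise:
            surfaces.append(rng.choice(variants))
        else:
            surfaces.append(s)
    joiner = " to " if kind == "state_range" else ", "
    return joiner.join(surfaces)


# -- recovery scoring ------------------------------------------------------

def recovery_report(t: TruthMatrix, m: RawMatrix) -> dict:
    """Compare a pipeline raw matrix against the truth.

    A qualitative cell is recovered when the canonical state tuple matches
    exactly (order included for state ranges); a quantitative cell when the
    mm-normalized range fields all match.  Returns counts plus the list of
    missed (taxon, character) pairs for diagnosis.
    """
    total = 0
    recovered = 0
    missed: list[tuple[str, str]] = []
    for (taxon, key), truth_value in t.cells.items():
        total += 1
        cell = m.cells.get((taxon, key))
        if cell is not None and _matches(truth_value, cell):
            recovered += 1
        else:
            missed.append((taxon, key.label))
    return {
        "n_truth_cells": total,
        "n_recovered": recovered,
        "recovery_fraction": recovered / total if total else 1.0,
        "missed": missed,
    }


def _ranges_close(a: NumericRange, b: NumericRange) -> bool:
    from math import isclose

    def close(x: float | None, y: float | None) -> bool:
        if x is None or y is None:
            return x is y
        # unit conversion introduces float noise (0.11 cm * 10 vs 1.1 mm)
        return isclose(x, y, rel_tol=1e-9, abs_tol=1e-9)

    return (close(a.typical_min, b.typical_min)
            and close(a.typical_max, b.typical_max)
            and close(a.atypical_min, b.atypical_min)
            and close(a.atypical_max, b.atypical_max))


def _matches(truth_value, cell) -> bool:
    if isinstance(truth_value, NumericRange):
        want = truth_value.to_mm()
        for a in cell.annotations:
            if a.range is not None and _ranges_close(a.range.to_mm(), want):
                return True
        return False
    _kind, states = truth_value
    got: list[str] = []
    for a in cell.annotations:
        for s in a.states:
            if s not in got:
                got.append(s)
    return tuple(got) == tuple(states)


# -- corpus files ----------------------------------------------------------

def write_corpus(
    descriptions: list[Description],
    glossary: Glossary,
    t: TruthMatrix,
    out_dir: str | Path,
) -> None:
    """Emit batch CSV + glossary CSV + truth-matrix CSV under ``out_dir``."""
    import csv

    from .glossary import save_glossary

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "batch.csv").open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["taxon", "rank", "parent", "description"])
        for d in descriptions:
            w.writerow([d.taxon_name, d.rank, d.parent_taxon or "", d.body])
    save_glossary(glossary, out / "glossary.csv")
    with (out / "truth.csv").open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["taxon", "structure", "constraint", "character", "value"])
        for (taxon, key), v in sorted(
            t.cells.items(), key=lambda kv: (kv[0][0], kv[0][1].label)
        ):
            if isinstance(v, NumericRange):
                val = _render_range(v, v.unit)
            else:
                kind, states = v
                val = (" to " if kind == "state_range" else ", ").join(states)
            w.writerow([taxon, key.structure, key.constraint or "",
                        key.character, val])
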