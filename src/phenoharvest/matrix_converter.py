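"""Character evaluation, discretization, coding, and phylogenetic export.

This stage turns the raw phrase matrix into a state-coded matrix usable by
phylogenetic inference software: columns referring to the same structure
under different names are merged, low-coverage characters filtered, state
lists and measurement ranges discretized into symbol-coded states, and the
result exported to NEXUS, relaxed PHYLIP, TSV, or NeXML.

Quantitative discretization offers three methods:

* ``gap`` (default) -- sort taxa by the midpoint of their typical range and
  split wherever the gap between consecutive midpoints exceeds ``g`` times
  the median adjacent gap (default g = 2).  Scale-free, so unit rescaling
  never changes the state assignment.
* ``bins(k)`` -- k equal-width bins over the pooled typical range.
* ``thresholds`` -- user-supplied cut points.

A taxon whose typical range spans a cut point is coded polymorphic across
the spanned states.  Atypical extremes are ignored unless requested.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median_low
from typing import Sequence

from lxml import etree

from .errors import CodingError, ExportError
from .matrix_generation import Cell, CharacterKey, RawMatrix, Taxon
from .text_capture import NumericRange

#: Symbol alphabet for coded states (32 symbols).
SYMBOLS = "0123456789ABCDEFGHIJKLMNOPQRSTUV"

MISSING = "?"

#: Names used for gap/bin classes of quantitative characters.
_SIZE_LADDER = {1: ("all",), 2: ("small", "large"),
                3: ("small", "medium", "large")}


@dataclass
class CodedCharacter:
    """One discretized character with its state labels and symbol map."""

    label: str
    kind: str  # "qualitative" | "quantitative"
    state_labels: tuple[str, ...]
    source_keys: tuple[CharacterKey, ...] = ()
    state_bounds: tuple[tuple[float, float], ...] = ()  # quantitative only, mm

    def __post_init__(self) -> None:
        if len(self.state_labels) > len(SYMBOLS):
            raise CodingError(
                f"character {self.label!r} needs {len(self.state_labels)} "
                f"states; the symbol alphabet allows {len(SYMBOLS)}"
            )
        if len(set(self.state_labels)) != len(self.state_labels):
            raise CodingError(f"duplicate state labels in {self.label!r}")

    @property
    def symbol_map(self) -> dict[int, str]:
        return {i: SYMBOLS[i] for i in range(len(self.state_labels))}

    @property
    def is_constant(self) -> bool:
        return len(self.state_labels) <= 1


@dataclass
class CodedMatrix:
    """Discretized, symbol-coded matrix ready for export.

    ``cells`` maps (taxon, character index) to a frozenset of state indices;
    a missing cell is simply absent (exported as "?").  Polymorphic cells
    hold two or more indices.
    """

    taxa: list[str] = field(default_factory=list)
    characters: list[CodedCharacter] = field(default_factory=list)
    cells: dict[tuple[str, int], frozenset[int]] = field(default_factory=dict)

    def symbols_at(self, taxon: str, char_idx: int) -> str:
        states = self.cells.get((taxon, char_idx))
        if not states:
            return MISSING
        syms = "".join(SYMBOLS[i] for i in sorted(states))
        return syms if len(syms) == 1 else "{" + syms + "}"

    def __eq__(self, other: object) -> bool:
        # Equality is over what interchange formats carry: taxa, character
        # labels, state labels, and cells.  ``kind`` is a coding-stage
        # attribute (TSV preserves it; NEXUS cannot).
        if not isinstance(other, CodedMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and [(c.label, c.state_labels) for c in self.characters]
            == [(c.label, c.state_labels) for c in other.characters]
            and self.cells == other.cells
        )


# -- raw-matrix editing ----------------------------------------------------

@dataclass(frozen=True)
class MergeGroup:
    """A set of raw columns to fold into one character."""

    keys: tuple[CharacterKey, ...]
    label: str


def merge_characters(m: RawMatrix, groups: Sequence[MergeGroup]) -> RawMatrix:
    """Fold each group of columns into one, unioning cell phrase sets.

    All keys in a group must share the character category ("bract: Shape"
    cannot merge into "bract: length"); the merged column keeps the group's
    target label as its structure name and records its source keys via the
    returned matrix's ``merged_from`` attribute.
    """
    out = RawMatrix(taxa=list(m.taxa))
    merged_from: dict[CharacterKey, tuple[CharacterKey, ...]] = {}
    key_to_target: dict[CharacterKey, CharacterKey] = {}
    for grp in groups:
        cats = {k.character for k in grp.keys}
        if len(cats) != 1:
            raise CodingError(
                "cannot merge characters of different categories: "
                + ", ".join(k.label for k in grp.keys)
            )
        missing = [k for k in grp.keys if k not in m.characters]
        if missing:
            raise CodingError(
                "merge group names absent columns: "
                + ", ".join(k.label for k in missing)
            )
        target = CharacterKey(grp.label, grp.keys[0].character)
        merged_from[target] = grp.keys
        for k in grp.keys:
            key_to_target[k] = target

    seen: set[CharacterKey] = set()
    for key in m.characters:
        target = key_to_target.get(key, key)
        if target not in seen:
            seen.add(target)
            out.characters.append(target)
    for (taxon, key), cell in m.cells.items():
        target = key_to_target.get(key, key)
        existing = out.cells.get((taxon, target))
        out.cells[(taxon, target)] = (
            cell if existing is None else existing.merged_with(cell)
        )
    out.merged_from = merged_from  # type: ignore[attr-defined]
    return out


def filter_by_coverage(m: RawMatrix, min_taxa: int) -> RawMatrix:
    """Keep exactly the characters with data from at least ``min_taxa`` taxa.

    Antitone in ``min_taxa``: a larger threshold never keeps more characters.
    """
    if min_taxa < 1:
        raise CodingError("min_taxa must be >= 1")
    counts = {key: 0 for key in m.characters}
    for (_taxon, key) in m.cells:
        counts[key] += 1
    keep = {key for key, n in counts.items() if n >= min_taxa}
    out = RawMatrix(
        taxa=list(m.taxa),
        characters=[k for k in m.characters if k in keep],
        cells={(t, k): c for (t, k), c in m.cells.items() if k in keep},
    )
    return out


# -- discretization --------------------------------------------------------

def discretize_qualitative(
    column: dict[str, Cell],
    label: str,
    taxa_order: Sequence[str],
    source_keys: tuple[CharacterKey, ...] = (),
) -> tuple[CodedCharacter, dict[str, frozenset[int]]]:
    """Code a state-valued column: one symbol per canonical state.

    State labels are collected in first-appearance order over the taxa;
    multi-state and state-range cells become polymorphic symbol sets.  A
    numeric annotation in the column is a type error pointing the user back
    to merge review.
    """
    states: list[str] = []
    coded: dict[str, frozenset[int]] = {}
    for taxon in taxa_order:
        cell = column.get(taxon)
        if cell is None:
            continue
        cell_states: list[str] = []
        for a in cell.annotations:
            if a.value_kind == "numeric":
                raise CodingError(
                    f"numeric value in qualitative character {label!r} "
                    f"(taxon {taxon!r}); review the merge configuration"
                )
            for s in a.states:
                if s not in cell_states:
                    cell_states.append(s)
        if not cell_states:  # phrase-only cell (no parsed annotation)
            cell_states = [p.strip().lower() for p in cell.phrases]
        for s in cell_states:
            if s not in states:
                states.append(s)
        coded[taxon] = frozenset(states.index(s) for s in cell_states)
    char = CodedCharacter(label, "qualitative", tuple(states),
                          source_keys=source_keys)
    if char.is_constant and states:
        warnings.warn(f"character {label!r} is constant (parsimony-uninformative)")
    return char, coded


def _gap_cuts(midpoints: Sequence[float], gap_factor: float) -> list[float]:
    """Cut points from the gap rule on sorted unique midpoints.

    A cut falls between consecutive midpoints whose gap exceeds
    ``gap_factor`` times the median adjacent gap (low median, so the
    reference is an actually observed gap even with an even count).
    Scale-free by construction: gaps and their median rescale together.
    """
    pts = sorted(set(midpoints))
    if len(pts) < 2:
        return []
    gaps = [b - a for a, b in zip(pts, pts[1:])]
    med = median_low(gaps)
    if med <= 0:
        return []
    return [
        (a + b) / 2.0
        for a, b, g in zip(pts, pts[1:], gaps)
        if g > gap_factor * med
    ]


def discretize_quantitative(
    column: dict[str, Cell],
    label: str,
    taxa_order: Sequence[str],
    method: str = "gap",
    gap_factor: float = 2.0,
    n_bins: int | None = None,
    thresholds: Sequence[float] | None = None,
    use_atypical: bool = False,
    source_keys: tuple[CharacterKey, ...] = (),
) -> tuple[CodedCharacter, dict[str, frozenset[int]]]:
    """Code a measurement column into ordered size classes.

    All ranges are normalized to mm before comparison, so descriptions that
    mix cm and mm reconcile.  A taxon whose typical range spans a cut point
    is coded polymorphic across the spanned states; atypical extremes widen
    the range only with ``use_atypical``.
    """
    ranges: dict[str, NumericRange] = {}
    has_unit = False
    dimensionless = False
    for taxon in taxa_order:
        cell = column.get(taxon)
        if cell is None:
            continue
        cell_ranges = [a.range for a in cell.annotations if a.range is not None]
        if not cell_ranges or any(a.value_kind != "numeric"
                                  for a in cell.annotations):
            raise CodingError(
                f"non-numeric value in quantitative character {label!r} "
                f"(taxon {taxon!r})"
            )
        for r in cell_ranges:
            if r.unit is None:
                dimensionless = True
            else:
                has_unit = True
        r = cell_ranges[0].to_mm()
        for extra in cell_ranges[1:]:  # a taxon stated twice: envelope
            e = extra.to_mm()
            r = NumericRange(min(r.typical_min, e.typical_min),
                             max(r.typical_max, e.typical_max),
                             unit=r.unit)
        ranges[taxon] = r
    if has_unit and dimensionless:
        raise CodingError(
            f"character {label!r} mixes measurements with units and "
            "dimensionless counts"
        )
    if not ranges:
        raise CodingError(f"quantitative character {label!r} has no data")

    def span(r: NumericRange) -> tuple[float, float]:
        lo, hi = r.typical_min, r.typical_max
        if use_atypical:
            if r.atypical_min is not None:
                lo = min(lo, r.atypical_min)
            if r.atypical_max is not None:
                hi = max(hi, r.atypical_max)
        return lo, hi

    if method == "gap":
        cuts = _gap_cuts([r.midpoint for r in ranges.values()], gap_factor)
    elif method == "bins":
        if n_bins is None or n_bins < 2:
            raise CodingError("bins method requires n_bins >= 2")
        lo = min(span(r)[0] for r in ranges.values())
        hi = max(span(r)[1] for r in ranges.values())
        if hi <= lo:
            cuts = []
        else:
            width = (hi - lo) / n_bins
            cuts = [lo + width * i for i in range(1, n_bins)]
        cuts = sorted(cuts)
    elif method == "thresholds":
        if not thresholds:
            raise CodingError("thresholds method requires cut points")
        cuts = sorted(thresholds)
    else:
        raise CodingError(f"unknown discretization method {method!r}")

    n_states = len(cuts) + 1
    bounds: list[tuple[float, float]] = []
    edges = [float("-inf")] + list(cuts) + [float("inf")]
    for i in range(n_states):
        bounds.append((edges[i], edges[i + 1]))

    labels = list(_SIZE_LADDER.get(n_states,
                                   tuple(f"class_{i}" for i in range(n_states))))

    coded: dict[str, frozenset[int]] = {}
    for taxon, r in ranges.items():
        lo, hi = span(r)
        hit = {
            i for i, (a, b) in enumerate(bounds)
            # closed-interval overlap; a range touching a cut exactly spans it
            if lo <= b and hi >= a
        }
        coded[taxon] = frozenset(hit)

    char = CodedCharacter(label, "quantitative", tuple(labels),
                          source_keys=source_keys,
                          state_bounds=tuple(bounds))
    return char, coded


def code_matrix(
    m: RawMatrix,
    method: str = "gap",
    gap_factor: float = 2.0,
    n_bins: int | None = None,
    thresholds: dict[str, Sequence[float]] | None = None,
    use_atypical: bool = False,
) -> CodedMatrix:
    """Discretize every column of a raw matrix into a :class:`CodedMatrix`.

    A column is quantitative when all its cells are numeric, qualitative
    when all are state-valued; a mixed column raises :class:`CodingError`
    naming the character so the user can fix the merge configuration.
    """
    cm = CodedMatrix(taxa=[t.name for t in m.taxa])
    taxa_order = cm.taxa
    for key in m.characters:
        column = m.column(key)
        kinds = {
            a.value_kind == "numeric"
            for cell in column.values() for a in cell.annotations
        }
        if kinds == {True}:
            per_char_cuts = (thresholds or {}).get(key.label)
            char, coded = discretize_quantitative(
                column, key.label, taxa_order,
                method="thresholds" if per_char_cuts else method,
                gap_factor=gap_factor, n_bins=n_bins,
                thresholds=per_char_cuts, use_atypical=use_atypical,
                source_keys=(key,),
            )
        else:
            char, coded = discretize_qualitative(
                column, key.label, taxa_order, source_keys=(key,),
            )
        idx = len(cm.characters)
        cm.characters.append(char)
        for taxon, states in coded.items():
            cm.cells[(taxon, idx)] = states
    return cm


# -- export ----------------------------------------------------------------

def _nexus_quote(s: str) -> str:
    if re.fullmatch(r"[\w.-]+", s):
        return s
    return "'" + s.replace("'", "''") + "'"


def export_matrix(cm: CodedMatrix, fmt: str, path: str | Path) -> None:
    """Write a coded matrix as ``nexus``, ``phylip``, ``tsv``, or ``nexml``."""
    if not cm.taxa or not cm.characters:
        raise ExportError("refusing to export an empty matrix")
    writers = {"nexus": write_nexus, "phylip": write_phylip,
               "tsv": write_tsv, "nexml": write_nexml}
    if fmt not in writers:
        raise ExportError(f"unknown export format {fmt!r}")
    writers[fmt](cm, path)


def write_nexus(cm: CodedMatrix, path: str | Path) -> None:
    """NEXUS with a standard-datatype CHARACTERS block.

    Polymorphic cells serialize as "{01}", missing as "?"; taxon and state
    labels with characters outside [A-Za-z0-9_.-] are single-quoted.
    """
    if not cm.taxa or not cm.characters:
        raise ExportError("refusing to export an empty matrix")
    nchar = len(cm.characters)
    max_state = max((len(c.state_labels) for c in cm.characters), default=1)
    symbols = SYMBOLS[:max(max_state, 1)]
    lines = ["#NEXUS", "", "BEGIN TAXA;",
             f"    DIMENSIONS NTAX={len(cm.taxa)};",
             "    TAXLABELS " + " ".join(_nexus_quote(t) for t in cm.taxa) + ";",
             "END;", "", "BEGIN CHARACTERS;",
             f"    DIMENSIONS NCHAR={nchar};",
             f"    FORMAT DATATYPE=STANDARD SYMBOLS=\"{symbols}\" MISSING={MISSING};"]
    labels = []
    for i, c in enumerate(cm.characters, start=1):
        states = " ".join(_nexus_quote(s) for s in c.state_labels)
        labels.append(f"        {i} {_nexus_quote(c.label)} / {states}")
    lines.append("    CHARSTATELABELS")
    lines.append(",\n".join(labels) + ";")
    lines.append("    MATRIX")
    width = max(len(_nexus_quote(t)) for t in cm.taxa) + 2
    for t in cm.taxa:
        row = "".join(cm.symbols_at(t, i) for i in range(nchar))
        lines.append(f"        {_nexus_quote(t):<{width}}{row}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


_CHARSTATE_RE = re.compile(
    r"(\d+)\s+('(?:[^']|'')*'|\S+)\s*/\s*((?:'(?:[^']|'')*'|[^,;])*)"
)


def _nexus_unquote(tok: str) -> str:
    tok = tok.strip()
    if tok.startswith("'") and tok.endswith("'"):
        return tok[1:-1].replace("''", "'")
    return tok


def read_nexus(path: str | Path) -> CodedMatrix:
    """Read back the NEXUS dialect written by :func:`write_nexus`."""
    text = Path(path).read_text(encoding="utf-8")
    cm = CodedMatrix()
    m = re.search(r"TAXLABELS\s+(.*?);", text, re.S | re.I)
    if not m:
        raise ExportError(f"{path}: no TAXLABELS block")
    cm.taxa = [_nexus_unquote(t) for t in re.findall(r"'(?:[^']|'')*'|\S+",
                                                     m.group(1))]
    m = re.search(r"CHARSTATELABELS\s+(.*?);", text, re.S | re.I)
    if not m:
        raise ExportError(f"{path}: no CHARSTATELABELS block")
    for entry in m.group(1).split(",\n"):
        cm_match = _CHARSTATE_RE.search(entry.strip())
        if not cm_match:
            continue
        label = _nexus_unquote(cm_match.group(2))
        states = tuple(
            _nexus_unquote(s)
            for s in re.findall(r"'(?:[^']|'')*'|\S+", cm_match.group(3))
        )
        cm.characters.append(CodedCharacter(label, "qualitative", states))
    m = re.search(r"MATRIX\s*\n(.*?)\n\s*;", text, re.S)
    if not m:
        raise ExportError(f"{path}: no MATRIX block")
    for line in m.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        tok = re.match(r"('(?:[^']|'')*'|\S+)\s+(\S+)$", line)
        if not tok:
            raise ExportError(f"{path}: unreadable matrix row {line!r}")
        taxon = _nexus_unquote(tok.group(1))
        row = tok.group(2)
        idx = 0
        char_idx = 0
        while idx < len(row):
            ch = row[idx]
            if ch == "{":
                close = row.index("}", idx)
                syms = row[idx + 1:close]
                cm.cells[(taxon, char_idx)] = frozenset(
                    SYMBOLS.index(s) for s in syms
                )
                idx = close + 1
            elif ch == MISSING:
                idx += 1
            else:
                cm.cells[(taxon, char_idx)] = frozenset({SYMBOLS.index(ch)})
                idx += 1
            char_idx += 1
    return cm


def write_phylip(cm: CodedMatrix, path: str | Path) -> None:
    """Relaxed PHYLIP; polymorphic cells collapse to "?" (format limit).

    Taxon names are transliterated to [A-Za-z0-9_]; when any name changes, a
    ``<path>.names.tsv`` sidecar maps the output names to the originals.
    """
    if not cm.taxa or not cm.characters:
        raise ExportError("refusing to export an empty matrix")
    nchar = len(cm.characters)
    mapping: list[tuple[str, str]] = []
    out_names: list[str] = []
    for t in cm.taxa:
        safe = re.sub(r"[^A-Za-z0-9_]", "_", t)
        out_names.append(safe)
        if safe != t:
            mapping.append((safe, t))
    n_poly = 0
    lines = [f"{len(cm.taxa)} {nchar}"]
    width = max(len(n) for n in out_names) + 2
    for t, name in zip(cm.taxa, out_names):
        row = []
        for i in range(nchar):
            sym = cm.symbols_at(t, i)
            if len(sym) > 1:  # "{01}"
                n_poly += 1
                sym = MISSING
            row.append(sym)
        lines.append(f"{name:<{width}}{''.join(row)}")
    if n_poly:
        warnings.warn(
            f"{n_poly} polymorphic cell(s) collapsed to '?' in PHYLIP output"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if mapping:
        side = Path(str(path) + ".names.tsv")
        side.write_text(
            "\n".join(f"{a}\t{b}" for a, b in mapping) + "\n", encoding="utf-8"
        )


def write_tsv(cm: CodedMatrix, path: str | Path) -> None:
    """Lossless TSV: character definitions in "#char" header lines, then the
    taxa-by-characters grid with the same cell tokens as NEXUS."""
    if not cm.taxa or not cm.characters:
        raise ExportError("refusing to export an empty matrix")
    lines = []
    for c in cm.characters:
        lines.append("#char\t" + "\t".join(
            [c.label, c.kind, "|".join(c.state_labels)]
        ))
    lines.append("taxon\t" + "\t".join(c.label for c in cm.characters))
    for t in cm.taxa:
        lines.append(t + "\t" + "\t".join(
            cm.symbols_at(t, i) for i in range(len(cm.characters))
        ))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_tsv(path: str | Path) -> CodedMatrix:
    """Inverse of :func:`write_tsv`."""
    cm = CodedMatrix()
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#char\t"):
            _tag, label, kind, states = line.split("\t")
            cm.characters.append(CodedCharacter(
                label, kind, tuple(s for s in states.split("|") if s)
            ))
        else:
            body_start = i
            break
    for line in lines[body_start + 1:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        taxon = parts[0]
        cm.taxa.append(taxon)
        for idx, tok in enumerate(parts[1:]):
            if tok == MISSING:
                continue
            syms = tok[1:-1] if tok.startswith("{") else tok
            cm.cells[(taxon, idx)] = frozenset(SYMBOLS.index(s) for s in syms)
    return cm


_NEXML_NS = "http://www.nexml.org/2009"
_XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"


def write_nexml(cm: CodedMatrix, path: str | Path) -> None:
    """Minimal NeXML standard-characters document."""
    if not cm.taxa or not cm.characters:
        raise ExportError("refusing to export an empty matrix")
    nsmap = {"nex": _NEXML_NS, "xsi": _XSI_NS}
    root = etree.Element(f"{{{_NEXML_NS}}}nexml", nsmap=nsmap, version="0.9")
    otus = etree.SubElement(root, f"{{{_NEXML_NS}}}otus", id="otus1")
    otu_ids = {}
    for i, t in enumerate(cm.taxa):
        oid = f"otu{i}"
        otu_ids[t] = oid
        etree.SubElement(otus, f"{{{_NEXML_NS}}}otu", id=oid, label=t)
    chars = etree.SubElement(root, f"{{{_NEXML_NS}}}characters",
                             id="chars1", otus="otus1")
    chars.set(f"{{{_XSI_NS}}}type", "nex:StandardCells")
    fmt = etree.SubElement(chars, f"{{{_NEXML_NS}}}format")
    state_ids: list[dict[int, str]] = []
    for ci, c in enumerate(cm.characters):
        states_el = etree.SubElement(fmt, f"{{{_NEXML_NS}}}states",
                                     id=f"states{ci}")
        ids = {}
        for si, s in enumerate(c.state_labels):
            sid = f"s{ci}_{si}"
            ids[si] = sid
            etree.SubElement(states_el, f"{{{_NEXML_NS}}}state",
                             id=sid, label=s, symbol=str(si))
        # polymorphic combinations present in the data
        combos = {
            tuple(sorted(v)) for (t, idx), v in cm.cells.items()
            if idx == ci and len(v) > 1
        }
        for pi, combo in enumerate(sorted(combos)):
            pid = f"p{ci}_{pi}"
            poly = etree.SubElement(
                states_el, f"{{{_NEXML_NS}}}polymorphic_state_set",
                id=pid, symbol=str(len(ids) + pi),
            )
            for si in combo:
                etree.SubElement(poly, f"{{{_NEXML_NS}}}member", state=ids[si])
            ids[("poly",) + combo] = pid  # type: ignore[index]
        state_ids.append(ids)
    char_ids = []
    for ci, c in enumerate(cm.characters):
        cid = f"c{ci}"
        char_ids.append(cid)
        etree.SubElement(fmt, f"{{{_NEXML_NS}}}char", id=cid,
                         states=f"states{ci}", label=c.label)
    mat = etree.SubElement(chars, f"{{{_NEXML_NS}}}matrix")
    for t in cm.taxa:
        row = etree.SubElement(mat, f"{{{_NEXML_NS}}}row",
                               id=f"row_{otu_ids[t]}", otu=otu_ids[t])
        for ci in range(len(cm.characters)):
            v = cm.cells.get((t, ci))
            if not v:
                continue
            if len(v) == 1:
                sid = state_ids[ci][next(iter(v))]
            else:
                sid = state_ids[ci][("poly",) + tuple(sorted(v))]  # type: ignore[index]
            etree.SubElement(row, f"{{{_NEXML_NS}}}cell",
                             char=char_ids[ci], state=sid)
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")
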