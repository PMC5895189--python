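# Methods

## The extraction model

phenoharvest treats a telegraphic taxonomic description as a sequence of
sentences, each governed by one anatomical *structure subject*: the sentence
opens with the structure term ("Leaves …", "Adult leaves …", "Bark …") and
the following clauses state its characters. A clause is parsed against a
controlled vocabulary (the glossary) into annotations
*(structure, character, value)*:

- a glossary term in a quality category yields a **state** value under that
  category ("petiole red" → petiole / Coloration / red);
- "X to Y" between two states of one category yields a **state range**, the
  endpoints of a morphocline ("ovate to obovate"); "X, Y" and "X or Y"
  yield one annotation with several independent states;
- a measurement span matching the range grammar `(A–)B–C(–D) [mm|cm|m]`
  yields a **numeric** value whose dimension comes from the trailing
  dimension word (long → length, wide/broad → width, diam./diameter/across
  → diameter, tall/high → height, thick → thickness; none → "size");
  `B–C` is the typical range, the parenthesized parts are atypical extremes;
- frequency adverbs (sometimes, usually, rarely, …) become annotation
  modifiers; unknown words are never guessed into categories — they are
  surfaced as events for the term-learning stage and its human review.

Assumptions this model makes: descriptions are genuinely telegraphic
(structure-first, no finite verbs); one clause talks about one structure;
authors use sentence-final periods and the conventional abbreviations
(ca., diam., var., subsp.); decimal values use points, not commas.
Free-prose passages (habitat, diagnosis discussion) are out of scope and
should not be fed to the parser.

## Key behaviors and their rationale

**Subject scope.** The structure subject is scoped to the sentence. A
sentence that opens without a structure term is recorded as unparsed unless
`carry_subject_across_sentences` is set, in which case it inherits the
previous sentence's subject. Sentence scope is the safer default for
descriptions whose sentences are independent structure blocks.

**Ambiguous terms.** A term carrying both a Structure and a quality
category ("scale") takes the Structure reading clause-initially
("Scales ovate") and the quality reading elsewhere ("leaves scale-like"),
matching how telegraphic syntax fronts its subject. A Structure-only term
appearing mid-clause ("bark exfoliating in fine **scales**") is recorded as
a descriptive state under the generic `Character` category rather than
spawning a sub-structure; relating sub-structures to parents needs an
ontology, which is out of scope.

**Constraints.** Terms from stage/sex/position categories directly before a
clause-initial structure ("adult leaves", "female cones") become a
*structure constraint*, and constrained columns ("adult leaf: Shape") are
kept distinct from unconstrained ones. Deciding whether they describe the
same character is a homology judgment, so merging is deferred to the
user-controlled merge step in the converter.

**Synonymy.** Synonym declarations collapse eagerly to the terminal
canonical form: `add_synonym(a, b)` followed by `add_synonym(b, c)` leaves
every member resolving to `c` in one dictionary lookup, so resolution is
trivially acyclic and O(1). Re-mapping an established variant to a
different set raises a conflict and requires explicit removal first.

**Units.** Measurements are stored in their source unit and compared after
normalization to millimetres, so corpora that mix cm and mm reconcile; a
column mixing united measurements with dimensionless counts is rejected.

**Propagation.** An empty cell inherits the value of the *nearest* ancestor
with a direct value, through any number of rank levels; direct cells are
never overwritten, and propagated cells are never themselves sources, which
makes the pass idempotent. Cyclic parent links abort before any mutation.

**Presence inference.** Any taxon with at least one annotation on structure
S receives `S: presence = present`. A taxon that never mentions S keeps the
cell empty: silence in a description is missing information, not absence.
Absence values are a human judgment and can be entered in the raw-matrix
CSV by hand.

**Cells are phrase sets.** A taxon may state one character several times;
all verbatim phrases are kept (joined with " | " on export) and all parsed
annotations retained, so nothing is lost before the human evaluation step.

## Discretization

Qualitative columns code each canonical state, in first-appearance order
over the taxa, to a symbol from `0–9A–V` (32 states maximum); multi-state
cells and state ranges become polymorphic symbol sets; empty cells export
as `?`. Constant characters are kept but flagged parsimony-uninformative,
since dropping them is an analysis decision.

Quantitative columns offer three methods (all operating on mm-normalized
typical ranges; atypical extremes are ignored unless `use_atypical`):

- **gap** (default): taxa are ordered by typical-range midpoint and split
  where an adjacent gap exceeds `gap_factor` (default 2.0) times the *low
  median* adjacent gap. The low median keeps the reference an actually
  observed gap even with an even gap count (with two gaps, an interpolated
  median would average a tiny within-cluster gap with the true break and
  suppress it). The rule depends only on gap ratios, so rescaling all
  values (cm → mm) never changes the state assignment.
- **bins(k)**: k equal-width bins over the pooled typical range.
- **thresholds**: user-supplied cut points.

A taxon whose typical range spans a cut point is coded polymorphic across
the spanned states (closed-interval overlap, so a range touching a cut
exactly belongs to both sides). State classes are labeled small/medium/
large for up to three states, `class_i` beyond, with the numeric bounds
retained on the character.

## Exports

NEXUS (standard datatype, `SYMBOLS`, `CHARSTATELABELS`, polymorphism as
`{01}`, missing `?`), relaxed PHYLIP (polymorphic cells collapse to `?`
with a warning — a limitation of the format — and transliterated names get
a sidecar mapping), lossless TSV (character definitions in `#char` header
lines), and a minimal NeXML standard-characters document. NEXUS and TSV
round-trip to equal coded matrices; all writers are byte-deterministic
given identical input. Equality between coded matrices compares taxa,
character labels, state labels, and cells — the content interchange
formats carry.

## Term learning

The learning pass is a small set of deterministic rules (clause-initial
token before a known quality term → Structure; coordination with known
states of category C → C; suffix table: -ate/-oid/-like → Shape,
-ose/-ous → ambiguous Texture/Pubescence, left unknown with both
suggested), applied in priority order, with every triggering occurrence
recorded as evidence. This is deliberately not a statistical classifier:
the pipeline's contract is that proposals are auditable and the human
review step is authoritative. Rejected terms enter a stoplist carried in
the glossary file so they are never re-proposed.

## The synthetic corpus generator

The generator renders a known truth matrix as telegraphic descriptions and
returns the exactly-covering glossary, emulating the pathologies of real
description sets: high missingness (default 90% per character, matching
the sparsely filled matrices typical of real literature extractions),
genus-level descriptions carrying characters the species never state (to
exercise propagation), synonym noise (different authorities wording one
state differently), explanatory parentheticals, and mixed mm/cm/m units.
Defaults for the round-trip study: 40 taxa (2 genera + 38 species), 80
characters drawn from 12 structures × 7 quality categories + 4 dimensions,
90% missingness, all noise fractions 0. Every output is a deterministic
function of (truth matrix, style fractions, seed).

What passing round-trip tests shows: on well-formed telegraphic text fully
covered by the glossary, extraction is lossless — segmentation, parsing,
canonicalization, unit handling, and matrix assembly introduce no errors.
What it does not show: robustness to prose interludes, misspellings,
out-of-glossary vocabulary, or clause constructions outside the template
grammar (those surface as unparsed clauses and unknown-term events rather
than silent errors).

## Numerical and formatting choices

- Dash typography (hyphen, en/em dash, unicode hyphens) is normalized to
  ASCII `-` everywhere; Unicode minus is not accepted in ranges.
- Terms are lowercased with whitespace collapsed; plural structure words
  map onto singular glossary entries via a small suffix-rule table
  (leaves → leaf, branches → branch).
- Row and column order is first-appearance order throughout, making every
  serialized artifact byte-stable across reruns.
- An empty matrix reports fill 0 by convention; exporting an empty coded
  matrix is refused.
- Problem sizes in the test suite and acceptance script (40 × 80 for the
  round-trip study, 100 random fixtures for the filter oracle) are chosen
  to exercise every code path at desk scale; recovery results are
  size-independent because the check is exact, not statistical.

## Known limitations

- No ontology: sub-structures ("base", "apex") are not linked to parent
  structures, and constrained vs unconstrained columns must be merged by
  hand where they denote one character.
- The learning rules approximate, not reproduce, full bootstrapping-based
  term classification; there is no confidence model, so all proposals rank
  equally in review.
- PHYLIP export loses polymorphism by design of the format.
- The clause grammar does not handle nested prepositional attachment;
  such phrases end up as generic `Character` states flagged for review.
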