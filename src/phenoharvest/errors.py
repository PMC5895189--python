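"""Exception hierarchy shared across the pipeline stages."""


class PhenoHarvestError(Exception):
    """Base class for all phenoharvest errors."""


class GlossaryFormatError(PhenoHarvestError):
    """A glossary file is structurally malformed (missing column, empty file)."""


class GlossaryConsistencyError(PhenoHarvestError):
    """A glossary violates its own invariants (dangling canonical, empty term set)."""


class SynonymConflictError(PhenoHarvestError):
    """A synonym declaration would demote the canonical form of an existing set."""


class UnknownCategoryError(PhenoHarvestError):
    """A term was assigned to a category the glossary does not declare."""


class BatchFormatError(PhenoHarvestError):
    """A description batch file is malformed (duplicate taxa, empty bodies)."""


class MalformedRangeError(PhenoHarvestError):
    """A numeric measurement span does not satisfy the range grammar."""


class TaxonomyError(PhenoHarvestError):
    """Parent links among taxa are inconsistent (e.g. cyclic)."""


class CodingError(PhenoHarvestError):
    """A character column cannot be discretized as requested."""


class ExportError(PhenoHarvestError):
    """A coded matrix cannot be serialized to the requested format."""
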