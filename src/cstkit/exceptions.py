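"""Exception hierarchy for cstkit.

Every error raised on purpose by the package derives from :class:`CstkitError`
so callers (and the CLI) can catch one type and report the failing stage.
"""


class CstkitError(Exception):
    """Base class for all cstkit errors."""


class IdentifierError(CstkitError):
    """Duplicate or otherwise invalid sample/taxon identifiers."""


class ValidationError(CstkitError):
    """A table violates a structural invariant (negative value, bad row sum...)."""


class TableParseError(CstkitError):
    """A cell or header could not be parsed."""


class VocabularyError(CstkitError):
    """A categorical value is outside its accepted vocabulary."""


class EmptyDatasetError(CstkitError):
    """An alignment or filter left no samples."""


class DegenerateSampleError(CstkitError):
    """A sample has zero variance and no Pearson correlation is defined."""


class ParameterError(CstkitError):
    """An operation parameter is out of its valid range."""


class UndefinedScoreError(CstkitError):
    """A score (e.g. silhouette at k=1) is undefined for the given input."""


class NoCSTError(CstkitError):
    """Every cluster was filtered out; no community state type could be called."""


class UnknownTaxonError(CstkitError):
    """A requested taxon is not present in the abundance table."""


class GroupSizeError(CstkitError):
    """A statistical test received a group that is too small."""


class UndefinedStatisticError(CstkitError):
    """A test statistic is undefined (e.g. t-test on identical constants)."""


class RankDeficiencyError(CstkitError):
    """The design matrix of a linear model is rank deficient."""


class FeasibilityError(CstkitError):
    """A synthetic-data specification cannot be realized."""


class AlignmentError(CstkitError):
    """Two objects that must share a sample set do not."""
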