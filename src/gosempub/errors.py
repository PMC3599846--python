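"""Exception hierarchy.

All package-specific failures derive from :class:`GosempubError` so callers
can catch one base class at CLI boundaries.
"""


class GosempubError(Exception):
    """Base class for all gosempub errors."""


class OboParseError(GosempubError):
    """A stanza or line of an OBO file could not be parsed."""


class StructuralError(GosempubError):
    """The ontology violates a structural requirement (cycle, bad edge)."""


class UnknownTermError(GosempubError):
    """No ontology term matches the given identifier, name or synonym."""


class AmbiguousTermError(GosempubError):
    """Two or more terms match at the winning resolution tier."""

    def __init__(self, text: str, candidates):
        self.candidates = sorted(candidates)
        super().__init__(
            f"{text!r} is ambiguous; candidates: {', '.join(self.candidates)}"
        )


class ObsoleteTermError(GosempubError):
    """The matched term is flagged obsolete."""


class UnknownSpeciesError(GosempubError):
    """No species-directory entry matches the given text."""


class EmptyQueryError(GosempubError):
    """Query composition was attempted with an empty gene keyword pool."""


class UnsplittableQueryError(GosempubError):
    """A single gene atom plus the fixed clause exceeds the length budget."""


class CorpusLoadError(GosempubError):
    """The citation corpus could not be loaded (e.g. duplicate PMID)."""


class UndefinedKappaError(GosempubError):
    """Cohen's kappa is undefined (expected agreement equals 1)."""
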