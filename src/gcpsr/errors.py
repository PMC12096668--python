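"""Exception hierarchy shared by all gcpsr modules."""


class GcpsrError(Exception):
    """Base class for all errors raised by this package."""


class TreeParseError(GcpsrError):
    """A tree string could not be parsed (malformed Newick/NEXUS)."""


class SupportValueError(GcpsrError):
    """A node-support token is not a number in [0, 100]."""


class TaxonSetError(GcpsrError):
    """Taxon sets of two objects that must agree do not agree."""

    def __init__(self, message, symmetric_difference=()):
        super().__init__(message)
        self.symmetric_difference = frozenset(symmetric_difference)


class AlignmentError(GcpsrError):
    """An alignment block or supermatrix violates its invariants."""


class MatingDataError(GcpsrError):
    """Pairing records reference unknown isolates/groups or are unscorable."""


class MorphometryError(GcpsrError):
    """Spore measurements are insufficient or inconsistent for a statistic."""


class RankingError(GcpsrError):
    """A candidate clade is not displayed by the species tree, or the
    partition contract (exhaustive subdivision) cannot be met."""


class ConfigError(GcpsrError):
    """A run configuration is invalid (missing paths, out-of-range values)."""
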