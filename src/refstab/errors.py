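"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`RefstabError`,
so callers can catch one type at the CLI boundary.
"""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class DuplicateIdError(RefstabError):
    """A gene or sample identifier occurs more than once."""


class DomainError(RefstabError):
    """A value lies outside its scientific domain (negative FPKM, Ct > 45, ...)."""


class ShapeError(RefstabError):
    """Too few genes/samples, or mismatched matrix shapes."""


class MissingDataError(RefstabError):
    """A required cell has no observation."""


class DesignMismatchError(RefstabError):
    """Samples and the study design disagree (unassigned sample, unpaired sample, ...)."""


class GeneSetError(RefstabError):
    """Gene sets that must match do not."""


class OrientationError(RefstabError):
    """A stability series is oriented higher-is-more-stable where lower is required."""


class EmptySetError(RefstabError):
    """A filtering step removed every gene."""


class SpecError(RefstabError):
    """A simulation specification is invalid."""


class ConfigError(RefstabError):
    """A pipeline configuration is invalid or references missing artifacts."""
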