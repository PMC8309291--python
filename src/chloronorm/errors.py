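"""Exception hierarchy.

All package-specific failures derive from :class:`ChloronormError` so callers
can catch one base class at batch level and tally per-record failures.
"""


class ChloronormError(Exception):
    """Base class for all chloronorm errors."""


class FormatError(ChloronormError):
    """A file could not be parsed or written under the named standard."""


class MissingAnnotationError(ChloronormError):
    """A sequence was supplied without the companion annotation it requires."""


class NoIRError(ChloronormError):
    """No usable inverted-repeat pair: the quadripartite partition is
    undeterminable and the record must be omitted from standardization."""


class AmbiguousStructureError(ChloronormError):
    """Repeat annotations exist but cannot be reduced to a single coherent
    LSC/IRb/SSC/IRa partition (overlapping copies, >2 unmergeable repeats,
    equal-length single-copy regions, ...)."""


class UndeterminedOrientationError(ChloronormError):
    """A region's orientation test tied even after the all-genes fallback,
    or the IR copies carry no usable rRNA evidence."""
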