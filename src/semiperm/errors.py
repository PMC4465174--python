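"""Exception hierarchy with CLI exit-code classes.

Exit codes: 0 success, 2 usage errors, 3 data/input errors, 4 numeric/
simulation errors.
"""


class SemipermError(Exception):
    """Base class for all package errors."""

    exit_code = 3


class UsageError(SemipermError):
    """Caller misused an interface (wrong flag combination, wrong pair)."""

    exit_code = 2


class InputError(SemipermError):
    """Input data violates a precondition."""

    exit_code = 3


class SchemaError(InputError):
    """A tabular input is missing required columns."""


class MetadataError(InputError):
    """Sample metadata and sequence data disagree."""


class PloidyError(MetadataError):
    """More gene copies than ploidy allows for one sample/locus."""


class AlignmentError(InputError):
    """Sequences in one locus file have unequal lengths."""


class AlphabetError(AlignmentError):
    """Illegal character in a sequence record."""


class ConfigError(InputError):
    """Invalid run or simulation configuration."""


class UnresolvedAncestryError(InputError):
    """Diagnostic classification impossible: recipient species lacks an
    allopatric reference population and the locus is not excluded."""


class UndefinedStatisticError(SemipermError):
    """Statistic undefined for the given sample (e.g. n < 2)."""

    exit_code = 4


class SimulationError(SemipermError):
    """Simulation cannot proceed (e.g. more mutations than columns)."""

    exit_code = 4


class BootstrapError(SemipermError):
    """Too many bootstrap replicates were dropped."""

    exit_code = 4
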