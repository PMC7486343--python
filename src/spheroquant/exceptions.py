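"""Exception hierarchy.

Everything derives from :class:`SpheroquantError` so callers can catch the
package's failures in one clause; contract violations additionally derive
from :class:`ValueError` so they behave like ordinary bad-argument errors.
"""


class SpheroquantError(Exception):
    """Base class for all spheroquant errors."""


class ContractError(SpheroquantError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class ConfigurationError(SpheroquantError, ValueError):
    """Invalid generator or analysis configuration."""


class FormatError(SpheroquantError, ValueError):
    """Input files are malformed or mutually inconsistent."""


class LayoutError(SpheroquantError, ValueError):
    """Invalid plate layout (duplicate wells, bad roles, ...)."""


class NormalizationError(SpheroquantError, ValueError):
    """A plate cannot be normalized (e.g. no usable control wells)."""
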