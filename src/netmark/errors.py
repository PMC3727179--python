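"""Exception hierarchy.

Every error raised on a contract or format violation derives from
:class:`NetmarkError`, so callers can catch one base class at pipeline level.
"""


class NetmarkError(Exception):
    """Base class for all netmark errors."""


class FormatError(NetmarkError):
    """A file is structurally invalid (duplicate ids, empty, wrong columns)."""


class ParseError(NetmarkError):
    """A specific cell or line could not be parsed; message carries coordinates."""


class LabeledDataError(NetmarkError):
    """Sample labels are missing, duplicated, or do not form two classes."""


class EmptyResultError(NetmarkError):
    """An operation produced an empty result where a non-empty one is required."""


class ConfigError(NetmarkError):
    """A configuration value violates its documented bounds."""


class ContractError(NetmarkError):
    """An operation precondition was violated by the caller."""


class IntegrationError(NetmarkError):
    """Expression data and interaction network share no genes."""


class PlacementError(NetmarkError):
    """Disjoint module placement failed after bounded retries."""


class FeatureError(NetmarkError):
    """A feature (subnetwork or gene list) has no measured members."""


class FoldError(NetmarkError):
    """A cross-validation training fold is missing one of the two classes."""
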