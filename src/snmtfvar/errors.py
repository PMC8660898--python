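"""Exception hierarchy shared by all snmtfvar modules.

The CLI maps these onto exit codes: usage/format problems exit 2,
data/validation problems exit 3, numerical failures exit 4.
"""


class SnmtfVarError(Exception):
    """Base class for all snmtfvar errors."""


class FormatError(SnmtfVarError):
    """A file does not conform to the expected dialect (bad header, malformed line)."""


class ValidationError(SnmtfVarError):
    """Inputs are well-formed but violate a contract (duplicate IDs, bad label values, shape mismatch)."""


class EmptyDatasetError(SnmtfVarError):
    """An operation was left with no usable rows."""


class NumericalError(SnmtfVarError):
    """The optimizer produced a non-finite objective; typically the regularization weights are too large."""
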