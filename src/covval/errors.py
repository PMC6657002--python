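"""Exception taxonomy.

ConfigurationError: the caller asked for something incoherent (bad rates,
unknown derivation rule or dialect).  DataError: the data violate a contract
(duplicate IDs, out-of-range raw values).  The CLI maps these to distinct
exit codes.
"""


class CovvalError(Exception):
    """Base class for all covval errors."""


class ConfigurationError(CovvalError):
    """Invalid configuration, catalogue entry, or parameter set."""


class DataError(CovvalError):
    """Input data violate a structural or range contract."""
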