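"""Exception hierarchy shared by all crpcoord modules."""


class CrpcoordError(Exception):
    """Base class for all crpcoord-specific errors."""


class SchemaError(CrpcoordError):
    """A delimited input file does not expose the declared columns."""


class DataError(CrpcoordError):
    """Input values violate an invariant (non-monotone time, missing samples, ...)."""


class ParameterError(CrpcoordError):
    """A caller-supplied parameter is outside its valid range."""


class DegenerateSignalError(DataError):
    """The operation is undefined on this signal (all-zero, zero variance, ...)."""


class UndefinedEntropyError(DataError):
    """Sample entropy is undefined because no template pairs matched (A = 0 or B = 0)."""
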